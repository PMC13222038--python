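"""Independent brute-force reference for scores and lag-CRP counts.

Deliberately naive and list-based: for every transition it materialises the
full set of still-recallable items, sorts their distances, and assigns
reverse ranks by hand (mean rank over ties).  No shared code with the
package implementation beyond the Python standard library.
"""

from __future__ import annotations

import math


def brute_transition_percentile(from_pos: int, to_pos: int, available: set[int]) -> float:
    n = len(available)
    if n == 1:
        return math.nan
    dists = sorted(abs(p - from_pos) for p in available)
    # reverse ranks: smallest distance -> rank n, next -> n-1, ...
    rev = {i: n - i for i in range(n)}
    actual = abs(to_pos - from_pos)
    ranks = [rev[i] for i, d in enumerate(dists) if d == actual]
    r = sum(ranks) / len(ranks)
    return (r - 1.0) / (n - 1.0)


def brute_score(order: tuple[int, ...], n_items: int) -> float:
    percs = []
    for i in range(len(order) - 1):
        recalled = set(order[: i + 1])
        available = {p for p in range(1, n_items + 1) if p not in recalled}
        p = brute_transition_percentile(order[i], order[i + 1], available)
        if not math.isnan(p):
            percs.append(p)
    return sum(percs) / len(percs) if percs else math.nan


def brute_lag_crp(order: tuple[int, ...], n_items: int, max_lag: int = 5):
    lags = [l for l in range(-max_lag, max_lag + 1) if l != 0]
    occurred = {l: 0 for l in lags}
    possible = {l: 0 for l in lags}
    for i in range(len(order) - 1):
        frm = order[i]
        recalled = set(order[: i + 1])
        for l in lags:
            tgt = frm + l
            if 1 <= tgt <= n_items and tgt not in recalled:
                possible[l] += 1
        actual = order[i + 1] - frm
        if abs(actual) <= max_lag:
            occurred[actual] += 1
    return occurred, possible


def all_recall_orders(n_items: int, length: int):
    """Every ordered sequence of `length` distinct positions from 1..n_items."""
    def rec(prefix):
        if len(prefix) == length:
            yield tuple(prefix)
            return
        for p in range(1, n_items + 1):
            if p not in prefix:
                prefix.append(p)
                yield from rec(prefix)
                prefix.pop()

    yield from rec([])
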