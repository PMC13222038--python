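"""Sequence-level measures of temporal organization in free recall.

Free-recall order data is compared against the original study order with two
classic measures:

* the **percentile-rank temporal organization score**: for each transition
  between successively recalled items, the absolute lag of the transition is
  ranked against the lags of every item still available for recall (smallest
  distance = highest rank, tied distances share the mean rank) and converted
  to a percentile ``(R - 1) / (N - 1)``.  The per-sequence score is the mean
  percentile over transitions; 1.0 is perfect temporal clustering and 0.5 is
  chance.
* the **lag-conditional response probability (lag-CRP)**: for each signed lag
  in a truncation window (default -5..+5), the number of times that lag
  transition occurred divided by the number of times it could possibly have
  occurred given the list length and the items already recalled.

Study positions are 1-based.  Repetitions of already-recalled items are
removed before analysis ("ignored"); out-of-list intrusions carry no study
position and are dropped, with transitions bridging across the removed item.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: sentinel study-position code for an out-of-list (intrusion) recall
INTRUSION = -1

DEFAULT_MAX_LAG = 5


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyList:
    """A studied unit (story or wordlist) with ``n_items`` ordered items."""

    unit_id: str
    n_items: int
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_items < 2:
            raise ValueError(f"study list {self.unit_id!r} needs n_items >= 2")
        if self.labels is not None and len(self.labels) != self.n_items:
            raise ValueError("labels length must equal n_items")

    @property
    def positions(self) -> range:
        """All study positions, 1..n_items inclusive."""
        return range(1, self.n_items + 1)


@dataclass(frozen=True)
class RecallSequence:
    """One participant x unit x timepoint cleaned recall order.

    ``positions`` holds distinct 1-based study positions in recall order.
    ``segments`` is only set under ``repeat_policy='break'`` where a removed
    repetition splits the transition chain; when ``None`` the whole sequence
    is a single chain.
    """

    participant_id: str = ""
    group: str = ""
    task: str = ""
    unit_id: str = ""
    timepoint: str = ""
    positions: tuple[int, ...] = ()
    segments: tuple[tuple[int, ...], ...] | None = None
    n_intrusions: int = 0
    n_repetitions: int = 0

    def chains(self) -> tuple[tuple[int, ...], ...]:
        """Transition chains to walk (one chain unless repeats broke it)."""
        if self.segments is not None:
            return self.segments
        return (self.positions,)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class TransitionRecord:
    """A single recall transition and its percentile score.

    ``available`` is the set of study positions not yet recalled at the step
    (it contains ``to_pos`` but not ``from_pos``); ``rank`` is the reverse
    rank R of the actual absolute lag among the available distances (smallest
    distance gets the largest rank, ties share the mean rank) and
    ``percentile`` is ``(R - 1)/(N - 1)`` with ``N = len(available)``,
    undefined (NaN) when N == 1.
    """

    from_pos: int
    to_pos: int
    lag: int
    available: frozenset[int]
    n_possible: int
    rank: float
    percentile: float


@dataclass(frozen=True)
class TOScore:
    """Temporal organization score for one sequence; NaN when undefined."""

    participant_id: str
    group: str
    task: str
    unit_id: str
    timepoint: str
    score: float
    n_transitions: int
    n_scored: int
    n_recalled: int
    percent_recall: float


@dataclass
class LagCRPTable:
    """Occurrence/possibility counts and CRP per signed lag for one unit."""

    participant_id: str = ""
    group: str = ""
    task: str = ""
    unit_id: str = ""
    timepoint: str = ""
    max_lag: int = DEFAULT_MAX_LAG
    occurred: dict[int, int] = field(default_factory=dict)
    possible: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        for lag in self.lags():
            self.occurred.setdefault(lag, 0)
            self.possible.setdefault(lag, 0)

    def lags(self) -> list[int]:
        """Signed lags in the truncation window, excluding 0."""
        m = self.max_lag
        return [*range(-m, 0), *range(1, m + 1)]

    def crp(self, lag: int) -> float:
        """CRP at ``lag``; NaN when the lag was never possible."""
        poss = self.possible[lag]
        return self.occurred[lag] / poss if poss > 0 else math.nan

    def to_rows(self) -> list[dict]:
        rows = []
        for lag in self.lags():
            rows.append(
                {
                    "participant_id": self.participant_id,
                    "group": self.group,
                    "task": self.task,
                    "unit_id": self.unit_id,
                    "timepoint": self.timepoint,
                    "lag": lag,
                    "abs_lag": abs(lag),
                    "direction": 0.5 if lag > 0 else -0.5,
                    "occurred": self.occurred[lag],
                    "possible": self.possible[lag],
                    "crp": self.crp(lag),
                }
            )
        return rows


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def clean_recall(
    raw_positions: Sequence,
    study: StudyList,
    *,
    participant_id: str = "",
    group: str = "",
    task: str = "",
    unit_id: str | None = None,
    timepoint: str = "",
    repeat_policy: str = "bridge",
    intrusion: int = INTRUSION,
) -> RecallSequence:
    """Drop intrusions, reduce repeats to their first occurrence.

    ``raw_positions`` may contain the ``intrusion`` sentinel (or None/NaN) for
    out-of-list recalls.  Under ``repeat_policy='bridge'`` (default) the
    remaining recalls form one transition chain; under ``'break'`` a removed
    repetition splits the chain so no transition is formed across it.
    An input that cleans to fewer than one item yields an empty (valid)
    sequence whose downstream score is undefined.
    """
    if repeat_policy not in ("bridge", "break"):
        raise ValueError(f"unknown repeat_policy {repeat_policy!r}")
    seen: set[int] = set()
    kept: list[int] = []
    segments: list[list[int]] = [[]]
    n_intr = 0
    n_rep = 0
    for raw in raw_positions:
        if raw is None or raw == intrusion or (isinstance(raw, float) and math.isnan(raw)):
            n_intr += 1
            continue
        pos = int(raw)
        if not 1 <= pos <= study.n_items:
            raise ValueError(
                f"study position {pos} outside 1..{study.n_items} for unit "
                f"{study.unit_id!r} (unflagged intrusion?)"
            )
        if pos in seen:
            n_rep += 1
            if repeat_policy == "break" and segments[-1]:
                segments.append([])
            continue
        seen.add(pos)
        kept.append(pos)
        segments[-1].append(pos)
    segs = tuple(tuple(s) for s in segments if s) if repeat_policy == "break" else None
    return RecallSequence(
        participant_id=participant_id,
        group=group,
        task=task,
        unit_id=unit_id if unit_id is not None else study.unit_id,
        timepoint=timepoint,
        positions=tuple(kept),
        segments=segs,
        n_intrusions=n_intr,
        n_repetitions=n_rep,
    )


def available_positions(study: StudyList, recalled_so_far: Iterable[int]) -> set[int]:
    """Study positions not yet recalled: ``{1..n_items} \\ recalled_so_far``."""
    recalled = set(recalled_so_far)
    if not recalled <= set(study.positions):
        raise ValueError("recalled_so_far contains positions outside the study list")
    return set(study.positions) - recalled


# ---------------------------------------------------------------------------
# percentile ranking
# ---------------------------------------------------------------------------

def _reverse_rank(distances: np.ndarray, actual_index: int) -> float:
    """Rank of ``distances[actual_index]`` when the smallest distance gets the
    largest rank N and tied distances share the mean of their ranks.

    Closed form: with c_lt distances strictly smaller and c_eq equal to the
    actual one, the tied block occupies ascending-sort positions
    c_lt..c_lt+c_eq-1 whose reverse ranks are n-c_lt..n-c_lt-c_eq+1, so the
    shared mean rank is ``n - c_lt - (c_eq - 1)/2``.
    """
    a = distances[actual_index]
    n = distances.size
    c_lt = int(np.count_nonzero(distances < a))
    c_eq = int(np.count_nonzero(distances == a))
    return n - c_lt - (c_eq - 1) / 2.0


def transition_percentile(
    from_pos: int, to_pos: int, available: Iterable[int]
) -> float:
    """Percentile score (R-1)/(N-1) of one transition; NaN when N == 1.

    ``available`` must contain ``to_pos`` and not ``from_pos``: it is the set
    of items still recallable at this step.
    """
    avail = np.asarray(sorted(set(available)), dtype=np.int64)
    if from_pos in avail:
        raise ValueError("from_pos must not be in the available set")
    where = np.flatnonzero(avail == to_pos)
    if where.size == 0:
        raise ValueError(
            f"transition to unavailable position {to_pos} (coding bug upstream)"
        )
    n = avail.size
    if n == 1:
        return math.nan
    rank = _reverse_rank(np.abs(avail - from_pos), int(where[0]))
    return (rank - 1.0) / (n - 1.0)


def iter_transitions(seq: RecallSequence, study: StudyList) -> Iterator[TransitionRecord]:
    """Yield one TransitionRecord per successive recall pair.

    Availability accumulates over the whole sequence (items recalled in an
    earlier chain stay unavailable even when a repeat broke the chain).
    """
    all_positions = set(study.positions)
    seen: set[int] = set()
    for chain in seq.chains():
        for j, pos in enumerate(chain):
            if pos not in all_positions:
                raise ValueError(f"position {pos} outside study list {study.unit_id!r}")
            if j > 0:
                frm = chain[j - 1]
                avail = all_positions - seen
                avail_arr = np.asarray(sorted(avail), dtype=np.int64)
                n = avail_arr.size
                if n == 1:
                    rank, perc = 1.0, math.nan
                else:
                    idx = int(np.flatnonzero(avail_arr == pos)[0])
                    rank = _reverse_rank(np.abs(avail_arr - frm), idx)
                    perc = (rank - 1.0) / (n - 1.0)
                yield TransitionRecord(
                    from_pos=frm,
                    to_pos=pos,
                    lag=pos - frm,
                    available=frozenset(avail),
                    n_possible=n,
                    rank=rank,
                    percentile=perc,
                )
            seen.add(pos)


# ---------------------------------------------------------------------------
# single-pass walk shared by score and lag-CRP
# ---------------------------------------------------------------------------

def _walk_metrics(
    chains: Sequence[Sequence[int]], n_items: int, max_lag: int
) -> tuple[list[float], int, np.ndarray, np.ndarray]:
    """One pass over the transition chains.

    Returns (defined percentiles, n_transitions, occurred, possible) where
    the count arrays are indexed by ``lag + max_lag`` (the lag-0 slot stays
    zero).
    """
    avail = np.ones(n_items + 1, dtype=bool)
    avail[0] = False
    percs: list[float] = []
    width = 2 * max_lag + 1
    occurred = np.zeros(width, dtype=np.int64)
    possible = np.zeros(width, dtype=np.int64)
    n_trans = 0
    for chain in chains:
        prev: int | None = None
        for pos in chain:
            if prev is not None:
                n_trans += 1
                # possibility window around the just-recalled item
                lo = max(1, prev - max_lag)
                hi = min(n_items, prev + max_lag)
                for q in range(lo, hi + 1):
                    if avail[q]:
                        possible[q - prev + max_lag] += 1
                lag = pos - prev
                if abs(lag) <= max_lag:
                    occurred[lag + max_lag] += 1
                idx = np.flatnonzero(avail)
                if idx.size >= 2:
                    rank = _reverse_rank(
                        np.abs(idx - prev), int(np.searchsorted(idx, pos))
                    )
                    percs.append((rank - 1.0) / (idx.size - 1.0))
            avail[pos] = False
            prev = pos
    return percs, n_trans, occurred, possible


def temporal_organization_score(seq: RecallSequence, study: StudyList) -> TOScore:
    """Mean transition percentile for one sequence (NaN when unscoreable)."""
    percs, n_trans, _, _ = _walk_metrics(seq.chains(), study.n_items, 1)
    score = float(np.mean(percs)) if percs else math.nan
    return TOScore(
        participant_id=seq.participant_id,
        group=seq.group,
        task=seq.task,
        unit_id=seq.unit_id,
        timepoint=seq.timepoint,
        score=score,
        n_transitions=n_trans,
        n_scored=len(percs),
        n_recalled=len(seq.positions),
        percent_recall=len(seq.positions) / study.n_items,
    )


def lag_crp(
    seq: RecallSequence, study: StudyList, max_lag: int = DEFAULT_MAX_LAG
) -> LagCRPTable:
    """Lag-CRP count table for one sequence, truncated to ±``max_lag``.

    Denominators are opened only at steps where an actual transition was
    made; a transition whose true |lag| exceeds ``max_lag`` still contributes
    to the possibility counts of in-window lags but to no occurrence bin.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    _, _, occurred, possible = _walk_metrics(seq.chains(), study.n_items, max_lag)
    table = LagCRPTable(
        participant_id=seq.participant_id,
        group=seq.group,
        task=seq.task,
        unit_id=seq.unit_id,
        timepoint=seq.timepoint,
        max_lag=max_lag,
    )
    for lag in table.lags():
        table.occurred[lag] = int(occurred[lag + max_lag])
        table.possible[lag] = int(possible[lag + max_lag])
    return table


def score_and_crp(
    seq: RecallSequence, study: StudyList, max_lag: int = DEFAULT_MAX_LAG
) -> tuple[TOScore, LagCRPTable]:
    """Compute both measures in a single walk (the batch-pipeline path)."""
    percs, n_trans, occurred, possible = _walk_metrics(
        seq.chains(), study.n_items, max_lag
    )
    score = TOScore(
        participant_id=seq.participant_id,
        group=seq.group,
        task=seq.task,
        unit_id=seq.unit_id,
        timepoint=seq.timepoint,
        score=float(np.mean(percs)) if percs else math.nan,
        n_transitions=n_trans,
        n_scored=len(percs),
        n_recalled=len(seq.positions),
        percent_recall=len(seq.positions) / study.n_items,
    )
    table = LagCRPTable(
        participant_id=seq.participant_id,
        group=seq.group,
        task=seq.task,
        unit_id=seq.unit_id,
        timepoint=seq.timepoint,
        max_lag=max_lag,
    )
    for lag in table.lags():
        table.occurred[lag] = int(occurred[lag + max_lag])
        table.possible[lag] = int(possible[lag + max_lag])
    return score, table


# ---------------------------------------------------------------------------
# aggregation and tabulation
# ---------------------------------------------------------------------------

_KEY_FIELDS = ("participant_id", "group", "task", "unit_id", "timepoint")


def aggregate_crp(
    tables: Iterable[LagCRPTable], by: Sequence[str] | None = None
):
    """Pool lag-CRP count tables.

    With ``by=None`` returns a single pooled table (counts summed; pooled
    CRP = sum occurred / sum possible).  With ``by`` a sequence of key-field
    names, returns a dict mapping each key tuple to its pooled table.  All
    inputs must share ``max_lag``.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to aggregate")
    max_lag = tables[0].max_lag
    if any(t.max_lag != max_lag for t in tables):
        raise ValueError("cannot aggregate tables with mixed max_lag")
    if by is None:
        return _pool(tables, max_lag)
    unknown = set(by) - set(_KEY_FIELDS)
    if unknown:
        raise ValueError(f"unknown grouping keys: {sorted(unknown)}")
    groups: dict[tuple, list[LagCRPTable]] = {}
    for t in tables:
        key = tuple(getattr(t, f) for f in by)
        groups.setdefault(key, []).append(t)
    return {key: _pool(ts, max_lag) for key, ts in groups.items()}


def _pool(tables: list[LagCRPTable], max_lag: int) -> LagCRPTable:
    keys = {
        f: (getattr(tables[0], f) if len({getattr(t, f) for t in tables}) == 1 else "pooled")
        for f in _KEY_FIELDS
    }
    pooled = LagCRPTable(max_lag=max_lag, **keys)
    for t in tables:
        for lag in pooled.lags():
            pooled.occurred[lag] += t.occurred[lag]
            pooled.possible[lag] += t.possible[lag]
    return pooled


def mean_crp_curve(tables: Iterable[LagCRPTable]) -> pd.DataFrame:
    """Per-lag mean of defined per-unit CRPs (the plotting variant)."""
    df = pd.DataFrame([row for t in tables for row in t.to_rows()])
    out = (
        df.groupby("lag", sort=True)["crp"]
        .agg(mean_crp="mean", n_defined="count")
        .reset_index()
    )
    return out


def sequence_metrics(
    seqs: Iterable[RecallSequence],
    studies: dict[str, StudyList],
    max_lag: int = DEFAULT_MAX_LAG,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score table and long-format lag-CRP table for a collection of
    sequences; the CRP frame carries ``abs_lag`` and ``direction`` (±0.5)
    columns ready for the inference stage."""
    score_rows = []
    crp_rows = []
    for seq in seqs:
        study = studies[seq.unit_id]
        score, table = score_and_crp(seq, study, max_lag)
        score_rows.append(vars(score))
        crp_rows.extend(table.to_rows())
    return pd.DataFrame(score_rows), pd.DataFrame(crp_rows)
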