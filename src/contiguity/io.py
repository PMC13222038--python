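"""Reading, validation and report writing for recall-order tables.

The interchange format is a long-format CSV: one row per recalled item with
columns ``participant_id, group, task, unit_id, timepoint, output_position,
study_position, is_intrusion`` plus a study-list manifest CSV
(``unit_id, n_items`` and optionally ``task``).  Timepoint labels are free
strings; each task's display/model order is declared once here so narrative
delays and wordlist trials share one schema.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_metrics import (
    INTRUSION,
    RecallSequence,
    StudyList,
    clean_recall,
)

RECALL_COLUMNS = [
    "participant_id",
    "group",
    "task",
    "unit_id",
    "timepoint",
    "output_position",
    "study_position",
    "is_intrusion",
]

#: canonical timepoint order per task (reference level listed first is NOT
#: implied here; reference levels are an inference-stage concern)
TIMEPOINT_ORDER: dict[str, tuple[str, ...]] = {
    "narrative": ("No Delay", "Short Delay", "Long Delay"),
    "wordlist": ("Trial 1", "Trial 5", "Delayed"),
}


@dataclass
class RunConfig:
    """Top-level run parameters; every output manifest records the seed."""

    max_lag: int = 5
    repeat_policy: str = "bridge"
    beta_link: str = "logit"
    bootstrap_B: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if self.bootstrap_B < 0:
            raise ValueError("bootstrap_B must be >= 0")
        if self.repeat_policy not in ("bridge", "break"):
            raise ValueError("repeat_policy must be 'bridge' or 'break'")
        if self.beta_link not in ("logit", "log"):
            raise ValueError("beta_link must be 'logit' or 'log'")


def read_manifest(path: str | Path) -> dict[str, StudyList]:
    df = pd.read_csv(path)
    missing = {"unit_id", "n_items"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["unit_id"].duplicated().any():
        dups = df.loc[df["unit_id"].duplicated(), "unit_id"].tolist()
        raise ValueError(f"duplicate unit_id in manifest: {dups}")
    return {
        str(r.unit_id): StudyList(unit_id=str(r.unit_id), n_items=int(r.n_items))
        for r in df.itertuples()
    }


def sequences_from_frame(
    recalls: pd.DataFrame,
    studies: dict[str, StudyList],
    *,
    repeat_policy: str = "bridge",
) -> tuple[list[RecallSequence], dict]:
    """Group long-format rows into cleaned RecallSequences.

    Rows are ordered by ``output_position`` within each
    (participant, unit, timepoint) cell; intrusion rows (``is_intrusion`` = 1)
    are passed to the cleaner as sentinel positions.  Returns the sequences
    plus a validation report of dropped rows.
    """
    df = recalls.copy()
    missing = set(RECALL_COLUMNS) - {"is_intrusion"} - set(df.columns)
    if missing:
        raise ValueError(f"recall table missing columns: {sorted(missing)}")
    if "is_intrusion" not in df.columns:
        df["is_intrusion"] = 0

    dup_keys = ["participant_id", "unit_id", "timepoint", "output_position"]
    dup = df.duplicated(subset=dup_keys, keep=False)
    if dup.any():
        first = df.loc[dup, dup_keys].iloc[0].to_dict()
        raise ValueError(f"duplicate output_position rows, first at {first}")

    # range check with row numbers before any grouping
    for row in df.itertuples():
        if int(row.is_intrusion):
            continue
        unit = str(row.unit_id)
        if unit not in studies:
            raise ValueError(f"row {row.Index}: unknown unit_id {unit!r}")
        pos = int(row.study_position)
        if not 1 <= pos <= studies[unit].n_items:
            raise ValueError(
                f"row {row.Index}: study_position {pos} outside "
                f"1..{studies[unit].n_items} for unit {unit!r}"
            )

    seqs: list[RecallSequence] = []
    n_intr = n_rep = 0
    keys = ["participant_id", "group", "task", "unit_id", "timepoint"]
    df = df.sort_values(keys + ["output_position"], kind="mergesort")
    raw_all = np.where(
        df["is_intrusion"].to_numpy(dtype=np.int64) != 0,
        INTRUSION,
        df["study_position"].fillna(INTRUSION).to_numpy(dtype=np.int64),
    )
    grouped = df.groupby(keys, sort=True).indices
    order = {tuple(map(str, k)): np.sort(v) for k, v in grouped.items()}
    for (pid, group, task, unit, tp), idx in order.items():
        seq = clean_recall(
            raw_all[idx].tolist(),
            studies[unit],
            participant_id=pid,
            group=group,
            task=task,
            unit_id=unit,
            timepoint=tp,
            repeat_policy=repeat_policy,
        )
        n_intr += seq.n_intrusions
        n_rep += seq.n_repetitions
        seqs.append(seq)
    report = {
        "n_rows": int(len(df)),
        "n_sequences": len(seqs),
        "n_intrusions_dropped": n_intr,
        "n_repetitions_dropped": n_rep,
    }
    return seqs, report


def read_recall_csv(
    path: str | Path,
    manifest_path: str | Path,
    *,
    repeat_policy: str = "bridge",
) -> tuple[list[RecallSequence], dict[str, StudyList], dict]:
    """Load and validate a recall CSV against its study-list manifest."""
    studies = read_manifest(manifest_path)
    recalls = pd.read_csv(path)
    seqs, report = sequences_from_frame(
        recalls, studies, repeat_policy=repeat_policy
    )
    return seqs, studies, report


def item_outcomes(recalls: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Expand recall rows to one row per studied item with a binary
    ``recalled`` outcome (the response of the recall-accuracy model)."""
    n_items = dict(zip(manifest["unit_id"].astype(str), manifest["n_items"].astype(int)))
    real = recalls[recalls["is_intrusion"] == 0] if "is_intrusion" in recalls else recalls
    keys = ["participant_id", "group", "task", "unit_id", "timepoint"]
    cells = real[keys].drop_duplicates()
    grids = []
    for unit, n in n_items.items():
        sub = cells[cells["unit_id"].astype(str) == unit]
        if sub.empty:
            continue
        grids.append(
            sub.merge(pd.DataFrame({"item": np.arange(1, n + 1)}), how="cross")
        )
    grid = pd.concat(grids, ignore_index=True)
    hits = real[keys + ["study_position"]].rename(columns={"study_position": "item"})
    hits["item"] = hits["item"].astype(np.int64)
    hits = hits.assign(recalled=1).drop_duplicates()
    out = grid.merge(hits, on=keys + ["item"], how="left")
    out["recalled"] = out["recalled"].fillna(0).astype(int)
    return out.sort_values(keys + ["item"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def config_hash(obj) -> str:
    """Stable short hash of any JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def write_report(bundle: dict, outdir: str | Path) -> list[Path]:
    """Write the deterministic report file set.

    ``bundle`` maps stage names to DataFrames (``scores``, ``crp``, ``fits``,
    optionally ``chance_tests`` folded into fits upstream) plus a
    ``manifest`` dict.  Re-running with identical inputs reproduces identical
    bytes.  Stages missing from the bundle are listed in the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expected = ("scores", "crp", "fits")
    written: list[Path] = []
    missing = [name for name in expected if name not in bundle]
    for name in expected:
        if name in bundle:
            path = outdir / f"{name}.csv"
            write_csv(bundle[name], path)
            written.append(path)
    manifest = dict(bundle.get("manifest", {}))
    manifest["missing_stages"] = missing
    path = outdir / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    written.append(path)
    return written


def write_dataset(dataset, outdir: str | Path) -> list[Path]:
    """Write a synthetic dataset (recall, manifest, ground truth) as CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in (
        ("recall", dataset.recalls),
        ("manifest", dataset.manifest),
        ("truth", dataset.truth),
    ):
        path = outdir / f"{name}.csv"
        write_csv(df, path)
        paths.append(path)
    return paths
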