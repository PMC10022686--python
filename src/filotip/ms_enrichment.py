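"""Spectral-count enrichment filtering of bait-vs-control MS datasets.

Putative bait interactors are called from spectral counts with the
dataset-specific rules used for the two MYO10 screens:

* FERM pulldown (GFP-trap, 2 replicates): enriched at least twofold
  over *both* the GFP and the TLN1-FERM controls, and detected with
  more than 10 spectral counts summed across both repeats.
* MYO10-BioID (5 replicates): enriched at least twofold over the
  GFP-MYO10 control and detected with more than 5 spectral counts
  summed across all repeats.

Fold changes are ratios of replicate-summed counts.  The count
threshold is strict (">", per "more than ten" / "over five"); the fold
change is inclusive (">=", per "at least twofold").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from filotip.stats import welch_t_test

__all__ = [
    "DatasetFilter",
    "EnrichmentRecord",
    "FERM_FILTER",
    "BIOID_FILTER",
    "fold_change",
    "apply_filter",
    "volcano_table",
    "dataset_overlap",
    "read_count_table",
    "write_count_table",
    "records_to_frame",
]


@dataclass(frozen=True)
class DatasetFilter:
    """Dataset-specific enrichment rule.

    A protein passes when its bait/control fold change is at least
    ``min_fold_change`` against every control and its bait counts,
    aggregated across replicates (``count_aggregation="sum"`` by
    default, ``"min"`` for a per-replicate minimum), strictly exceed
    ``count_threshold``.
    """

    dataset_id: str
    bait: str
    controls: tuple[str, ...]
    min_fold_change: float = 2.0
    count_threshold: int = 10
    count_aggregation: str = "sum"

    def __post_init__(self) -> None:
        if self.min_fold_change < 1:
            raise ValueError("min_fold_change must be >= 1")
        if self.count_threshold < 0:
            raise ValueError("count_threshold must be >= 0")
        if self.count_aggregation not in ("sum", "min"):
            raise ValueError("count_aggregation must be 'sum' or 'min'")
        object.__setattr__(self, "controls", tuple(self.controls))


#: GFP-trap MYO10-FERM pulldown: 2 repeats, GFP and TLN1-FERM controls
FERM_FILTER = DatasetFilter(
    dataset_id="FERM", bait="MYO10_FERM", controls=("GFP", "TLN1_FERM"),
    min_fold_change=2.0, count_threshold=10,
)

#: MYO10-BioID: 5 repeats, GFP-MYO10 control
BIOID_FILTER = DatasetFilter(
    dataset_id="BioID", bait="MYO10_BioID", controls=("GFP_MYO10",),
    min_fold_change=2.0, count_threshold=5,
)


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per-protein verdict of one dataset filter plus volcano coordinates."""

    protein_id: str
    dataset_id: str
    total_bait_count: int
    fold_change_vs_control: dict[str, float]
    log2_fc: float
    neg_log10_p: float
    passes_filter: bool


def _totals(table: pd.DataFrame, sample: str) -> pd.Series:
    if sample not in table.columns.get_level_values("sample"):
        raise KeyError(f"sample column {sample!r} missing from count table")
    return table[sample].sum(axis=1)


def fold_change(
    bait_total: float, control_total: float, pseudocount: float = 1.0
) -> float:
    """Ratio of replicate-summed counts, with a zero-control guard.

    The pseudocount is added to both totals only when the control total
    is zero; otherwise the raw ratio is returned.
    """
    if control_total == 0:
        return (bait_total + pseudocount) / (control_total + pseudocount)
    return bait_total / control_total


def apply_filter(
    table: pd.DataFrame, f: DatasetFilter, pseudocount: float = 1.0
) -> list[EnrichmentRecord]:
    """Evaluate the dataset filter for every protein in the table.

    ``table`` is indexed by protein_id with (sample, replicate)
    MultiIndex columns of nonnegative integer spectral counts.  The
    verdict is a pure function of the counts and the filter parameters.
    Volcano coordinates (log2 fold change vs the first control, Welch p
    on per-replicate counts) are filled in alongside.
    """
    bait_tot = _totals(table, f.bait)
    control_tot = {c: _totals(table, c) for c in f.controls}
    if f.count_aggregation == "sum":
        bait_agg = bait_tot
    else:
        bait_agg = table[f.bait].min(axis=1)

    bait_reps = table[f.bait].to_numpy(float)
    ctrl_reps = table[f.controls[0]].to_numpy(float)

    records = []
    for i, pid in enumerate(table.index):
        fcs = {
            c: fold_change(float(bait_tot.iloc[i]), float(control_tot[c].iloc[i]), pseudocount)
            for c in f.controls
        }
        passes = (
            all(fc >= f.min_fold_change for fc in fcs.values())
            and float(bait_agg.iloc[i]) > f.count_threshold
        )
        p = _welch_p(bait_reps[i], ctrl_reps[i])
        fc0 = fcs[f.controls[0]]
        records.append(
            EnrichmentRecord(
                protein_id=str(pid),
                dataset_id=f.dataset_id,
                total_bait_count=int(bait_tot.iloc[i]),
                fold_change_vs_control=fcs,
                log2_fc=float(np.log2(fc0)) if fc0 > 0 else float("-inf"),
                neg_log10_p=float(-np.log10(p)) if np.isfinite(p) else float("nan"),
                passes_filter=passes,
            )
        )
    return records


def _welch_p(bait: np.ndarray, ctrl: np.ndarray) -> float:
    if bait.size < 2 or ctrl.size < 2:
        warnings.warn("single-replicate input: p-value set to missing", stacklevel=3)
        return float("nan")
    try:
        with warnings.catch_warnings():
            # nearly-identical replicate counts trip scipy's moment warning
            warnings.simplefilter("ignore", RuntimeWarning)
            _, _, p = welch_t_test(ctrl, bait)
    except ValueError:
        return float("nan")
    return p


def volcano_table(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Plot-ready volcano coordinates: one row per protein."""
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "dataset_id": [r.dataset_id for r in records],
            "log2_fc": [r.log2_fc for r in records],
            "neg_log10_p": [r.neg_log10_p for r in records],
            "passes_filter": [r.passes_filter for r in records],
        }
    )


def normalize_protein_id(pid: str) -> str:
    """Gene-symbol style normalization: strip and uppercase.  Idempotent."""
    return pid.strip().upper()


def dataset_overlap(
    passing_sets: dict[str, set[str]]
) -> tuple[set[str], dict[str, set[str]]]:
    """Intersection and per-dataset exclusives over passing-protein sets.

    Identifiers are normalized (uppercased gene symbols) before the set
    algebra; returns ``(intersection, {dataset_id: exclusive set})``.
    """
    if len(passing_sets) < 2:
        raise ValueError("overlap needs at least 2 datasets")
    norm = {
        ds: {normalize_protein_id(p) for p in s} for ds, s in passing_sets.items()
    }
    inter = set.intersection(*norm.values())
    exclusives = {
        ds: s - set.union(*(o for d, o in norm.items() if d != ds))
        for ds, s in norm.items()
    }
    return inter, exclusives


# ---------------------------------------------------------------------------
# I/O: wide CSV with columns like "MYO10_FERM_r1", "GFP_r2", ...


def write_count_table(path: str | Path, table: pd.DataFrame) -> None:
    flat = table.copy()
    flat.columns = [f"{s}_r{r}" for s, r in table.columns]
    flat.to_csv(path)


def read_count_table(path: str | Path) -> pd.DataFrame:
    flat = pd.read_csv(path, index_col=0)
    cols = []
    for c in flat.columns:
        sample, _, rep = c.rpartition("_r")
        if not sample or not rep.isdigit():
            raise ValueError(f"column {c!r} does not follow the '<sample>_r<replicate>' scheme")
        cols.append((sample, int(rep)))
    flat.columns = pd.MultiIndex.from_tuples(cols, names=["sample", "replicate"])
    return flat


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "protein_id": r.protein_id,
            "dataset_id": r.dataset_id,
            "total_bait_count": r.total_bait_count,
            "log2_fc": r.log2_fc,
            "neg_log10_p": r.neg_log10_p,
            "passes_filter": r.passes_filter,
        }
        for c, fc in r.fold_change_vs_control.items():
            row[f"fc_vs_{c}"] = fc
        rows.append(row)
    return pd.DataFrame(rows)
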