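"""Whole-genome bisulfite pipeline at bin resolution.

Per-CpG methylation calls are filtered to informative sites (coverage
between 4 and 100 reads inclusive), pooled into fixed-size bins (a bin
needs more than five informative CpGs to report a level), categorized
as highly (HMR, >=80%), moderately (MMR, 20-80%) or lowly (LMR, <20%)
methylated, and compared between genotypes via per-bin deltas and the
affected / unaffected region criteria.

The bin level is the pooled (read-weighted) estimator
``100 * sum(meth) / sum(total)`` over the bin's informative CpGs, not the
mean of per-site levels; replicates are merged by summing counts per CpG
before any filtering, so the coverage filter applies to merged coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import AUTOSOME, CHRX, BinGrid, GenomeLayout

HMR = "HMR"
MMR = "MMR"
LMR = "LMR"
CATEGORIES = (HMR, MMR, LMR)

# paper-default thresholds, overridable in every entry point
INFORMATIVE_MIN = 4
INFORMATIVE_MAX = 100
MIN_INFORMATIVE_SITES = 6  # "more than five informative CG sites"
HMR_MIN = 80.0
LMR_MAX = 20.0

CALL_COLUMNS = ["chrom", "pos", "meth_count", "total_count"]


@dataclass
class CpgCallSet:
    """Per-CpG (chrom, pos, methylated reads, total reads) for one sample."""

    sample_id: str
    df: pd.DataFrame  # columns CALL_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in CALL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"call table missing columns {missing}")
        if len(self.df):
            if (self.df["meth_count"] > self.df["total_count"]).any():
                raise ValueError("meth_count exceeds total_count")
            if (self.df["meth_count"] < 0).any():
                raise ValueError("negative counts")
            if self.df.duplicated(["chrom", "pos"]).any():
                raise ValueError("duplicate CpG positions within a sample")

    def __len__(self) -> int:
        return len(self.df)


def merge_replicates(replicates: list[CpgCallSet], sample_id: str) -> CpgCallSet:
    """Sum counts per CpG across replicates (merge before filtering)."""
    if not replicates:
        raise ValueError("no replicates to merge")
    cat = pd.concat([r.df[CALL_COLUMNS] for r in replicates], ignore_index=True)
    merged = (
        cat.groupby(["chrom", "pos"], as_index=False, sort=True)[
            ["meth_count", "total_count"]
        ].sum()
    )
    return CpgCallSet(sample_id, merged[CALL_COLUMNS])


def filter_informative_calls(
    calls: CpgCallSet,
    min_coverage: int = INFORMATIVE_MIN,
    max_coverage: int = INFORMATIVE_MAX,
) -> CpgCallSet:
    """Retain CpGs covered by ``min_coverage`` to ``max_coverage`` reads, inclusive."""
    t = calls.df["total_count"]
    keep = (t >= min_coverage) & (t <= max_coverage)
    return CpgCallSet(calls.sample_id, calls.df.loc[keep].reset_index(drop=True))


@dataclass
class BinMethylation:
    """Per-bin methylation level (%) with missing-bin semantics.

    ``level`` is NaN wherever ``n_informative`` is below the minimum site
    count; both arrays are aligned to the grid rows.
    """

    sample_id: str
    grid: BinGrid
    n_informative: np.ndarray
    level: np.ndarray

    def present(self) -> np.ndarray:
        return ~np.isnan(self.level)


def compute_bin_methylation(
    calls: CpgCallSet,
    grid: BinGrid,
    min_sites: int = MIN_INFORMATIVE_SITES,
) -> BinMethylation:
    """Pooled bin methylation from informative-filtered calls.

    For each bin: count informative CpGs; if the count is at least
    ``min_sites`` the level is ``100 * sum(meth_count) / sum(total_count)``
    over those CpGs, otherwise the bin is missing (NaN).
    """
    n = np.zeros(grid.n_bins, dtype=np.int64)
    meth = np.zeros(grid.n_bins, dtype=np.float64)
    tot = np.zeros(grid.n_bins, dtype=np.float64)
    for chrom, sub in calls.df.groupby("chrom", sort=False):
        if chrom not in grid.layout.names:
            raise KeyError(f"calls on chromosome {chrom!r} absent from grid")
        idx = grid.locate_indices(chrom, sub["pos"].to_numpy())
        n += np.bincount(idx, minlength=grid.n_bins)
        meth += np.bincount(idx, weights=sub["meth_count"].to_numpy(), minlength=grid.n_bins)
        tot += np.bincount(idx, weights=sub["total_count"].to_numpy(), minlength=grid.n_bins)
    level = np.full(grid.n_bins, np.nan)
    ok = (n >= min_sites) & (tot > 0)
    level[ok] = 100.0 * meth[ok] / tot[ok]
    return BinMethylation(calls.sample_id, grid, n, level)


def categorize_bin(meth_level: float) -> str | None:
    """HMR (>=80), MMR ([20, 80)), or LMR (<20); missing level -> None."""
    if meth_level is None or np.isnan(meth_level):
        return None
    if not 0.0 <= meth_level <= 100.0:
        raise ValueError(f"methylation level {meth_level} outside [0, 100]")
    if meth_level >= HMR_MIN:
        return HMR
    if meth_level < LMR_MAX:
        return LMR
    return MMR


def categorize_levels(level: np.ndarray) -> np.ndarray:
    """Vectorized category labels; missing levels get None."""
    out = np.full(level.shape, None, dtype=object)
    present = ~np.isnan(level)
    out[present & (level >= HMR_MIN)] = HMR
    out[present & (level < LMR_MAX)] = LMR
    out[present & (level >= LMR_MAX) & (level < HMR_MIN)] = MMR
    return out


@dataclass
class MethylomeSummary:
    sample_id: str
    global_mean: float
    n_bins: int  # non-missing bins
    category_fractions: dict[str, float]
    per_class: dict[str, dict]  # klass -> {mean, n_bins, category_fractions}

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "global_mean": self.global_mean,
            "n_bins": self.n_bins,
            "category_fractions": self.category_fractions,
            "per_class": self.per_class,
        }


def _class_summary(level: np.ndarray) -> dict:
    present = ~np.isnan(level)
    cats = categorize_levels(level[present])
    nn = int(present.sum())
    return {
        "mean": float(np.mean(level[present])),
        "n_bins": nn,
        "category_fractions": {c: float(np.mean(cats == c)) for c in CATEGORIES},
    }


def methylome_summary(binmeth: BinMethylation, layout: GenomeLayout | None = None) -> MethylomeSummary:
    """Global and per-chromosome-class means and HMR/MMR/LMR fractions.

    The global mean is the unweighted mean over non-missing bins (the
    quantity marked on bin-distribution violin plots).  A chromosome class
    with no non-missing bin is omitted with a warning.
    """
    level = binmeth.level
    present = ~np.isnan(level)
    if not present.any():
        raise ValueError("no bins with a methylation level")
    klass = binmeth.grid.klass
    per_class = {}
    for kl in (AUTOSOME, CHRX):
        sel = klass == kl
        if not sel.any():
            continue
        if not (~np.isnan(level[sel])).any():
            warnings.warn(f"all bins missing for class {kl}; omitted from summary")
            continue
        per_class[kl] = _class_summary(level[sel])
    cats = categorize_levels(level[present])
    return MethylomeSummary(
        sample_id=binmeth.sample_id,
        global_mean=float(np.mean(level[present])),
        n_bins=int(present.sum()),
        category_fractions={c: float(np.mean(cats == c)) for c in CATEGORIES},
        per_class=per_class,
    )


@dataclass
class DeltaTrack:
    """Per-bin mutant-minus-control methylation difference (percentage points)."""

    mutant_id: str
    control_id: str
    grid: BinGrid
    values: np.ndarray  # NaN where either sample is missing


def delta_methylation(mutant: BinMethylation, control: BinMethylation) -> DeltaTrack:
    """ΔCGme = mutant − control, defined where both bins have a level."""
    if mutant.grid is not control.grid and not mutant.grid.df.equals(control.grid.df):
        raise ValueError("mutant and control are on different bin grids")
    delta = mutant.level - control.level  # NaN propagates
    return DeltaTrack(mutant.sample_id, control.sample_id, control.grid, delta)


AFFECTED = "affected"
UNAFFECTED = "unaffected"
NEITHER = "neither"


def classify_affected_bins(
    delta: DeltaTrack,
    control: BinMethylation,
    affected_delta: float = -20.0,
    affected_control_min: float = 40.0,
    unaffected_delta_low: float = -10.0,
    unaffected_delta_high: float = 10.0,
    unaffected_control_min: float = 40.0,
) -> np.ndarray:
    """Affected / unaffected / neither labels per bin.

    affected:   ΔCGme < −20 and control level > 40 (strict both)
    unaffected: −10 ≤ ΔCGme < 10 and control level ≥ 40
    Bins failing both (or missing either input) are "neither"; the two sets
    are disjoint by construction.
    """
    d = delta.values
    c = control.level
    labels = np.full(d.shape, NEITHER, dtype=object)
    defined = ~np.isnan(d) & ~np.isnan(c)
    aff = defined & (d < affected_delta) & (c > affected_control_min)
    unaff = (
        defined
        & (d >= unaffected_delta_low)
        & (d < unaffected_delta_high)
        & (c >= unaffected_control_min)
    )
    labels[aff] = AFFECTED
    labels[unaff] = UNAFFECTED
    return labels
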