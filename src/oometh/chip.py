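"""Spike-in-normalized histone-mark enrichment over genomic bins.

Two distinct normalizations coexist, matching common ChIP practice:

* within-sample enrichment is the ratio of RPKM-normalized ChIP to
  RPKM-normalized input per bin (never spike-scaled);
* cross-sample level comparisons first rescale raw ChIP counts by
  spike-in derived factors (reference total / sample total) so that
  genotypes sequenced to different depths become comparable.

The same ratio machinery serves DamID lamina tracks (Dam-LaminB1 over
Dam-only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import AUTOSOME, CHRX, BinGrid, GeneAnnotation, GenomeLayout

ME2_THRESHOLD = 1.4
ME3_THRESHOLD = 1.5
GENE_LOSS_CONTROL_MIN = 1.0
GENE_LOSS_RATIO = 0.67

K36_STATES = ("K36me1", "K36me2", "K36me3")


@dataclass
class BinCountTrack:
    """Raw (or rescaled) read counts per bin for one sample."""

    sample_id: str
    grid: BinGrid
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != (self.grid.n_bins,):
            raise ValueError("counts not aligned to grid")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class EnrichmentTrack:
    """Per-bin treatment/control RPKM ratio; NaN where undefined."""

    sample_id: str
    mark: str
    grid: BinGrid
    ratio: np.ndarray
    spike_scaled: bool = False

    def present(self) -> np.ndarray:
        return ~np.isnan(self.ratio)


@dataclass
class SpikeInCounts:
    """Reads per barcoded nucleosome species for one sample."""

    sample_id: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative spike-in counts")
        missing = [s for s in K36_STATES if s not in self.counts]
        if missing:
            raise ValueError(f"spike-in panel missing K36 states {missing}")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


def rpkm(track: BinCountTrack) -> np.ndarray:
    """Reads per kilobase per million mapped reads, per bin.

    RPKM(bin) = count * 1e9 / (bin_length_bp * total reads in track);
    truncated terminal bins use their actual length.
    """
    total = track.total
    if total <= 0:
        raise ValueError(f"track {track.sample_id} has zero total reads")
    return track.counts * 1e9 / (track.grid.lengths * total)


def bin_enrichment_ratio(
    treatment: BinCountTrack,
    control: BinCountTrack,
    mark: str = "",
    spike_scaled: bool = False,
) -> EnrichmentTrack:
    """Per-bin RPKM(treatment)/RPKM(control); control count 0 -> missing."""
    if treatment.grid is not control.grid and not treatment.grid.df.equals(control.grid.df):
        raise ValueError("treatment and control on different grids")
    t = rpkm(treatment)
    c = rpkm(control)
    ratio = np.full(treatment.grid.n_bins, np.nan)
    ok = control.counts > 0
    ratio[ok] = t[ok] / c[ok]
    return EnrichmentTrack(treatment.sample_id, mark, treatment.grid, ratio, spike_scaled)


def spike_in_scale_factors(
    panel: dict[str, SpikeInCounts], reference: str
) -> dict[str, float]:
    """Per-sample multipliers from spike-in totals.

    factor(s) = spike_total(reference) / spike_total(s); the reference
    factor is 1.  Applied multiplicatively to genome ChIP counts before
    cross-sample level comparison.
    """
    if reference not in panel:
        raise KeyError(f"reference sample {reference!r} not in panel")
    ref_total = panel[reference].total
    factors = {}
    for sid, spike in panel.items():
        if spike.total <= 0:
            raise ValueError(f"sample {sid} has zero spike-in reads")
        factors[sid] = ref_total / spike.total
    return factors


def apply_scale_factor(track: BinCountTrack, factor: float) -> BinCountTrack:
    """Rescale a count track (spike-in normalization step)."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return BinCountTrack(track.sample_id, track.grid, track.counts * factor)


def antibody_specificity(panel: SpikeInCounts, target_state: str) -> float:
    """Fraction of K36-methyl spike reads landing on the target state."""
    if target_state not in K36_STATES:
        raise ValueError(f"target state must be one of {K36_STATES}")
    denom = sum(panel.counts[s] for s in K36_STATES)
    if denom == 0:
        raise ValueError("no reads on K36 methyl states")
    return panel.counts[target_state] / denom


def enriched_occupancy(
    track: EnrichmentTrack, layout: GenomeLayout, threshold: float
) -> dict[str, float]:
    """Per chromosome class, fraction of non-missing bins with ratio >= threshold."""
    klass = track.grid.klass
    present = track.present()
    out = {}
    for kl in (AUTOSOME, CHRX):
        sel = (klass == kl) & present
        if not sel.any():
            continue
        out[kl] = float(np.mean(track.ratio[sel] >= threshold))
    return out


def gene_body_ratio(
    treatment: BinCountTrack, control: BinCountTrack, gene: GeneAnnotation
) -> float:
    """Gene-body RPKM ratio with reads pooled over the gene's bins.

    Counts of all bins overlapping the gene body are summed for each track;
    the shared interval length cancels, leaving
    (sum_t / total_t) / (sum_c / total_c).  Returns NaN when the control
    has no reads over the gene.
    """
    idx = treatment.grid.overlapping_indices(gene.chrom, gene.start, gene.end)
    if idx.size == 0:
        return float("nan")
    t_sum = treatment.counts[idx].sum()
    c_sum = control.counts[idx].sum()
    if c_sum <= 0:
        return float("nan")
    return float((t_sum / treatment.total) / (c_sum / control.total))


def call_h3k36me2_loss_genes(
    control_ratio: dict[str, float],
    mutant_ratio: dict[str, float],
    control_min: float = GENE_LOSS_CONTROL_MIN,
    loss_ratio: float = GENE_LOSS_RATIO,
) -> list[str]:
    """Genes losing the mark: control ChIP/input > 1 and mutant/control < 0.67.

    Genes with a missing ratio in either genotype are skipped.
    """
    called = []
    for gene_id, c in control_ratio.items():
        m = mutant_ratio.get(gene_id, float("nan"))
        if np.isnan(c) or np.isnan(m):
            continue
        if c > control_min and m / c < loss_ratio:
            called.append(gene_id)
    return called
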