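"""Synthetic oocyte-epigenome cohort generator.

Builds a miniature genome (three 30 Mb autosomes plus a 17 Mb X by
default) carrying the domain structure seen in fully grown oocytes:

* broad H3K36me2 domains (contiguous multi-bin segments) occupying a much
  larger fraction of the X (45% by default) than of autosomes (10%);
* H3K36me3-high bins over placed, transcribed genes, which are also the
  highly methylated regions;
* per-bin true CG methylation decomposed into a DNMT3A-independent
  pre-existing component plus de novo components laid down on H3K36me2
  and H3K36me3 chromatin respectively.

Genotype effects act multiplicatively on mark enrichment and
component-wise on methylation: the K36M onco-histone removes the
me2-dependent de novo component, Setd2 knockout removes the me3-dependent
component and adds a gain inside me2 domains, the double mutant (DM)
keeps only the pre-existing component, and Dnmt3a knockout keeps a
slightly reduced pre-existing residue.

Component means are solved in closed form from the configured global
means (control 36.4%, K36M 31.0%, DM 7.5%, Dnmt3a-KO 6.5%) and the
realized domain bin fractions, so the truth-level calibration is exact;
the simulated read data then carry realistic coverage, site-level Beta
noise, Poisson ChIP counts, per-sample library-depth factors, and a
barcoded spike-in panel with configurable antibody specificity.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chip import BinCountTrack, K36_STATES, SpikeInCounts
from .genome import (
    AUTOSOME,
    CHRX,
    BinGrid,
    Chromosome,
    GeneAnnotation,
    GenomeLayout,
    SnpRecord,
    make_bin_grid,
)
from .wgbs import CALL_COLUMNS, CpgCallSet

GENOTYPES = ("control", "K36M", "Setd2KO", "DM", "Dnmt3aKO")
MARKS = ("me2", "me3", "lamina")
SPIKE_STATES = ("H3", "K36me1", "K36me2", "K36me3")


def _rng(seed: int, *tags: str) -> np.random.Generator:
    """Independent, reproducible stream keyed by (seed, tag names)."""
    key = [int(seed)] + [zlib.crc32(t.encode()) & 0x7FFFFFFF for t in tags]
    return np.random.default_rng(key)


@dataclass(frozen=True)
class GenotypeProfile:
    """How a genotype perturbs marks and methylation components.

    ``me2_scale`` / ``me3_scale`` multiply true enrichment ratios;
    ``*_meth_retained`` are the fractions of the mark-dependent de novo
    methylation component that survive; ``preexisting_retained`` scales the
    DNMT3A-independent residue (used to put Dnmt3a-KO slightly below DM);
    ``gain_in_me2_domains`` adds percentage points inside me2 domains
    (the Setd2-KO gain).
    """

    name: str
    me2_scale: float = 1.0
    me3_scale: float = 1.0
    me2_dependent_meth_retained: float = 1.0
    me3_dependent_meth_retained: float = 1.0
    preexisting_retained: float = 1.0
    gain_in_me2_domains: float = 0.0

    def __post_init__(self) -> None:
        if self.me2_scale < 0 or self.me3_scale < 0:
            raise ValueError("mark scales must be >= 0")
        for f in (
            self.me2_dependent_meth_retained,
            self.me3_dependent_meth_retained,
            self.preexisting_retained,
        ):
            if not 0.0 <= f <= 1.0:
                raise ValueError("retained fractions must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    seed: int = 0
    bin_size: int = 10_000
    autosome_lengths: tuple[int, ...] = (30_000_000, 30_000_000, 30_000_000)
    chrx_length: int = 17_000_000

    # WGBS read model
    cpg_spacing_mean: float = 100.0
    coverage_mean: float = 15.0
    coverage_dispersion: float = 0.3  # var = mean + dispersion * mean^2
    site_noise_concentration: float = 50.0

    # domain structure
    x_me2_occupancy: float = 0.45
    autosome_me2_occupancy: float = 0.10
    genic_fraction: float = 0.245
    domain_mean_bins: float = 25.0
    gene_length_mean: float = 60_000.0

    # genotype global methylation means (%) the truth is calibrated to
    global_means: dict[str, float] = field(
        default_factory=lambda: {
            "control": 36.4,
            "K36M": 31.0,
            "DM": 7.5,
            "Dnmt3aKO": 6.5,
        }
    )
    setd2ko_gain: float = 15.0  # points added in me2 domains (no printed value)
    k36m_me2_scale: float = 0.2
    setd2ko_me2_scale: float = 1.1

    # per-bin jitter around component means (recentred, so means are exact)
    preexisting_sd: float = 1.0
    denovo_me2_sd: float = 6.0
    denovo_me3_sd: float = 2.0

    # true enrichment ratio model (domain bins sit above the call threshold,
    # background bins below it)
    me2_domain_ratio_median: float = 2.2
    me2_domain_ratio_sigma: float = 0.30
    me2_domain_ratio_min: float = 1.6
    me3_genic_ratio_median: float = 2.0
    me3_genic_ratio_sigma: float = 0.30
    me3_genic_ratio_min: float = 1.7
    background_ratio_sd: float = 0.10
    lamina_x_ratio: float = 2.0
    lamina_autosome_ratio: float = 0.8

    # ChIP read model; the background term is the nonspecific pulldown, so a
    # genotype with mark scale 0 yields flat, input-like counts
    chip_depth_per_bp: float = 0.04
    input_depth_per_bp: float = 0.04
    chip_background_fraction: float = 0.01
    library_factor_sigma: float = 0.4
    spike_base_total: int = 100_000
    spike_specificity: float = 0.95
    spike_unmod_fraction: float = 0.10

    # allelic read model
    reads_per_gene: int = 300
    read_length: int = 100
    maternal_fraction: float = 0.5
    base_error_rate: float = 0.005
    snp_spacing_mean: float = 400.0
    snp_shared_fraction: float = 0.15

    def __post_init__(self) -> None:
        for occ in (self.x_me2_occupancy, self.autosome_me2_occupancy):
            if not 0.0 <= occ <= 1.0:
                raise ValueError("me2 occupancy targets must lie in [0, 1]")
        if not 0.0 < self.genic_fraction < 1.0:
            raise ValueError("genic_fraction must lie in (0, 1)")

    def layout(self) -> GenomeLayout:
        chroms = [
            Chromosome(f"chr{i + 1}", l, AUTOSOME)
            for i, l in enumerate(self.autosome_lengths)
        ]
        if self.chrx_length > 0:
            chroms.append(Chromosome("chrX", self.chrx_length, CHRX))
        return GenomeLayout(tuple(chroms))


def paper_default_profiles(config: SimulationConfig) -> dict[str, GenotypeProfile]:
    """The five genotype profiles implied by the configured global means."""
    means = config.global_means
    pre_retained = means["Dnmt3aKO"] / means["DM"] if means["DM"] > 0 else 1.0
    return {
        "control": GenotypeProfile("control"),
        "K36M": GenotypeProfile(
            "K36M",
            me2_scale=config.k36m_me2_scale,
            me2_dependent_meth_retained=0.0,
        ),
        "Setd2KO": GenotypeProfile(
            "Setd2KO",
            me2_scale=config.setd2ko_me2_scale,
            me3_scale=0.0,
            me3_dependent_meth_retained=0.0,
            gain_in_me2_domains=config.setd2ko_gain,
        ),
        "DM": GenotypeProfile(
            "DM",
            me2_scale=config.k36m_me2_scale,
            me3_scale=0.0,
            me2_dependent_meth_retained=0.0,
            me3_dependent_meth_retained=0.0,
        ),
        "Dnmt3aKO": GenotypeProfile(
            "Dnmt3aKO",
            me2_dependent_meth_retained=0.0,
            me3_dependent_meth_retained=0.0,
            preexisting_retained=pre_retained,
        ),
    }


@dataclass
class EpigenomeTruth:
    """Ground truth per bin: domain states, true ratios, methylation components."""

    grid: BinGrid
    genes: list[GeneAnnotation]
    me2_domain: np.ndarray  # bool
    me3_genic: np.ndarray  # bool
    true_me2_ratio: np.ndarray
    true_me3_ratio: np.ndarray
    true_lamina_ratio: np.ndarray
    preexisting: np.ndarray  # %
    denovo_me2: np.ndarray  # %
    denovo_me3: np.ndarray  # %

    @property
    def baseline_meth(self) -> np.ndarray:
        return self.preexisting + self.denovo_me2 + self.denovo_me3

    def genotype_methylation(self, profile: GenotypeProfile) -> np.ndarray:
        """True per-bin methylation (%) for one genotype."""
        meth = (
            self.preexisting * profile.preexisting_retained
            + self.denovo_me2 * profile.me2_dependent_meth_retained
            + self.denovo_me3 * profile.me3_dependent_meth_retained
        )
        if profile.gain_in_me2_domains:
            meth = meth + profile.gain_in_me2_domains * self.me2_domain
        return np.clip(meth, 0.0, 100.0)

    def true_ratio(self, mark: str) -> np.ndarray:
        if mark == "me2":
            return self.true_me2_ratio
        if mark == "me3":
            return self.true_me3_ratio
        if mark == "lamina":
            return self.true_lamina_ratio
        raise ValueError(f"unknown mark {mark!r}")

    def as_frame(self) -> pd.DataFrame:
        df = self.grid.df[["chrom", "start", "end", "klass"]].copy()
        df["me2_domain"] = self.me2_domain.astype(int)
        df["me3_genic"] = self.me3_genic.astype(int)
        df["true_me2_ratio"] = self.true_me2_ratio
        df["true_me3_ratio"] = self.true_me3_ratio
        df["preexisting"] = self.preexisting
        df["denovo_me2"] = self.denovo_me2
        df["denovo_me3"] = self.denovo_me3
        return df


def _place_genes(
    grid: BinGrid, config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[GeneAnnotation], np.ndarray]:
    """Non-overlapping transcribed genes covering ~genic_fraction of each chromosome."""
    genes: list[GeneAnnotation] = []
    me3 = np.zeros(grid.n_bins, dtype=bool)
    g = config.genic_fraction
    mean_len = config.gene_length_mean
    gap_mean = mean_len * (1.0 - g) / g
    k = 0
    for chrom in grid.layout.chromosomes:
        pos = float(rng.exponential(gap_mean / 2.0))
        while True:
            length = float(rng.lognormal(np.log(mean_len) - 0.125, 0.5))
            length = max(2_000.0, length)
            start, end = int(pos), int(min(pos + length, chrom.length))
            if end - start < 2_000 or start >= chrom.length:
                break
            gene = GeneAnnotation(
                f"gene_{k:05d}", chrom.name, start, end, "+" if rng.random() < 0.5 else "-"
            )
            genes.append(gene)
            me3[grid.overlapping_indices(chrom.name, start, end)] = True
            k += 1
            pos = end + rng.exponential(gap_mean)
            if pos >= chrom.length:
                break
    return genes, me3


def _place_domains(
    grid: BinGrid,
    free: np.ndarray,
    klass_mask: np.ndarray,
    target_fraction: float,
    mean_bins: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Contiguous me2 domains (geometric lengths) until class occupancy hits
    the target within one bin."""
    domain = np.zeros(grid.n_bins, dtype=bool)
    n_class = int(klass_mask.sum())
    target = int(round(target_fraction * n_class))
    if target == 0:
        return domain
    chrom_arr = grid.df["chrom"].to_numpy()
    placed = 0
    attempts = 0
    max_attempts = 200 * max(1, target)
    while placed < target:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("could not reach me2 occupancy target; too few free bins")
        candidates = np.flatnonzero(free & klass_mask & ~domain)
        if candidates.size == 0:
            raise RuntimeError("no free bins left for me2 domain placement")
        start = int(rng.choice(candidates))
        length = int(rng.geometric(1.0 / mean_bins))
        length = min(length, target - placed)
        chrom = chrom_arr[start]
        for i in range(start, min(start + length, grid.n_bins)):
            if chrom_arr[i] != chrom or not free[i] or domain[i]:
                break
            domain[i] = True
            placed += 1
    return domain


def _centered_component(
    rng: np.random.Generator, mask: np.ndarray, mean: float, sd: float, n: int
) -> np.ndarray:
    """Non-negative per-bin values on ``mask`` whose mean over the mask is
    exactly ``mean``."""
    vals = np.zeros(n)
    k = int(mask.sum())
    if k == 0 or mean <= 0:
        return vals
    x = rng.normal(mean, sd, size=k)
    x += mean - x.mean()
    x = np.clip(x, 0.0, None)
    m = x.mean()
    if m > 0:
        x *= mean / m
    vals[mask] = x
    return vals


def solve_component_means(
    config: SimulationConfig, f_me2: float, f_me3: float
) -> tuple[float, float, float]:
    """Closed-form (preexisting, per-bin me2, per-bin me3) component means.

    With genome-wide me2-domain bin fraction ``f_me2`` and me3-genic
    fraction ``f_me3``::

        mean(DM)      = p                         -> p
        mean(control) - mean(K36M) = f_me2 * m2   -> m2  (K36M retains none)
        mean(control) = p + f_me2*m2 + f_me3*m3   -> m3
    """
    means = config.global_means
    p = means["DM"]
    # degenerate genomes without one domain class simply drop that component
    # (the corresponding global-mean target is then unreachable by design)
    m2 = (means["control"] - means["K36M"]) / f_me2 if f_me2 > 0 else 0.0
    m3 = (means["control"] - p - f_me2 * m2) / f_me3 if f_me3 > 0 else 0.0
    if m2 < 0 or m3 < 0:
        raise ValueError("infeasible global means: negative component solved")
    if p + m3 > 97.0:
        raise ValueError(
            "infeasible calibration: me3-genic baseline would exceed 100%; "
            "increase genic_fraction"
        )
    return p, m2, m3


def build_truth_epigenome(
    config: SimulationConfig, layout: GenomeLayout | None = None
) -> EpigenomeTruth:
    """Place domains and genes, draw true ratios, and calibrate methylation.

    Deterministic given ``config.seed``.  me2 domains and me3-genic bins
    are disjoint (the two marks show a reciprocal pattern); realized
    per-class me2 occupancy matches the targets within one bin.
    """
    if layout is None:
        layout = config.layout()
    grid = make_bin_grid(layout, config.bin_size)
    rng = _rng(config.seed, "truth")

    genes, me3_genic = _place_genes(grid, config, rng)
    klass = grid.klass
    free = ~me3_genic
    me2_domain = np.zeros(grid.n_bins, dtype=bool)
    me2_domain |= _place_domains(
        grid, free, klass == AUTOSOME, config.autosome_me2_occupancy,
        config.domain_mean_bins, rng,
    )
    if (klass == CHRX).any():
        me2_domain |= _place_domains(
            grid, free, klass == CHRX, config.x_me2_occupancy,
            config.domain_mean_bins, rng,
        )

    # An RPKM(ChIP)/RPKM(input) ratio self-normalizes by the genome-mean
    # enrichment, so observed ratios equal truth only when the truth's
    # length-weighted mean is 1.  Domain bins are drawn above the call
    # threshold; the background level is solved to balance the mean.
    w = grid.lengths / grid.lengths.sum()

    def draw_ratio(mask, median, sigma, lo):
        r = np.empty(grid.n_bins)
        r[mask] = np.maximum(rng.lognormal(np.log(median), sigma, mask.sum()), lo)
        bg = ~mask
        bg_target = 1.0 - float((w[mask] * r[mask]).sum())
        if bg_target <= 0:
            raise ValueError(
                "domain enrichment mass exceeds the genome total; lower the "
                "domain ratio or occupancy"
            )
        shape = np.clip(rng.normal(1.0, config.background_ratio_sd, bg.sum()), 0.3, None)
        r[bg] = shape * bg_target / float((w[bg] * shape).sum())
        if mask.any() and bg.any() and r[bg].max() >= r[mask].min():
            raise ValueError("background ratios overlap domain ratios; widen the gap")
        return r

    true_me2 = draw_ratio(
        me2_domain, config.me2_domain_ratio_median,
        config.me2_domain_ratio_sigma, config.me2_domain_ratio_min,
    )
    true_me3 = draw_ratio(
        me3_genic, config.me3_genic_ratio_median,
        config.me3_genic_ratio_sigma, config.me3_genic_ratio_min,
    )
    lamina = np.where(
        klass == CHRX, config.lamina_x_ratio, config.lamina_autosome_ratio
    ) * np.exp(rng.normal(0.0, 0.1, grid.n_bins))

    f_me2 = me2_domain.mean()
    f_me3 = me3_genic.mean()
    p_mean, m2, m3 = solve_component_means(config, f_me2, f_me3)
    all_bins = np.ones(grid.n_bins, dtype=bool)
    preexisting = _centered_component(
        rng, all_bins, p_mean, config.preexisting_sd, grid.n_bins
    )
    denovo_me2 = _centered_component(
        rng, me2_domain, m2, config.denovo_me2_sd, grid.n_bins
    )
    denovo_me3 = _centered_component(
        rng, me3_genic, m3, config.denovo_me3_sd, grid.n_bins
    )
    truth = EpigenomeTruth(
        grid, genes, me2_domain, me3_genic, true_me2, true_me3, lamina,
        preexisting, denovo_me2, denovo_me3,
    )
    if truth.baseline_meth.max() > 100.0:
        raise ValueError("calibrated baseline methylation exceeds 100% in some bin")
    return truth


def simulate_wgbs_calls(
    truth: EpigenomeTruth,
    genotype: GenotypeProfile,
    config: SimulationConfig,
    seed: int | None = None,
) -> CpgCallSet:
    """Per-CpG bisulfite calls for one genotype.

    CpG positions have exponential spacing; coverage is negative binomial
    (mean ``coverage_mean``, variance mean + dispersion*mean^2); each
    site's methylation probability is the bin-level genotype truth plus
    Beta noise at the configured concentration; methylated counts are
    binomial.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "wgbs", genotype.name)
    meth_truth = truth.genotype_methylation(genotype) / 100.0
    disp = config.coverage_dispersion
    nb_n = 1.0 / disp
    nb_p = nb_n / (nb_n + config.coverage_mean)
    conc = config.site_noise_concentration

    frames = []
    for chrom in truth.grid.layout.chromosomes:
        n_est = int(chrom.length / config.cpg_spacing_mean * 1.3) + 10
        gaps = 1 + np.floor(rng.exponential(config.cpg_spacing_mean - 1, n_est))
        pos = np.cumsum(gaps).astype(np.int64) - 1
        pos = pos[pos < chrom.length]
        bin_idx = truth.grid.locate_indices(chrom.name, pos)
        p_bin = meth_truth[bin_idx]
        coverage = rng.negative_binomial(nb_n, nb_p, size=pos.size)
        a = np.clip(p_bin * conc, 1e-9, None)
        b = np.clip((1.0 - p_bin) * conc, 1e-9, None)
        p_site = rng.beta(a, b)
        p_site[p_bin <= 0.0] = 0.0
        p_site[p_bin >= 1.0] = 1.0
        meth = rng.binomial(coverage, p_site)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom.name,
                    "pos": pos,
                    "meth_count": meth,
                    "total_count": coverage,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return CpgCallSet(f"{genotype.name}_wgbs", df[CALL_COLUMNS])


@dataclass
class ChipExperiment:
    """One simulated ChIP (or DamID) experiment with its input and spike-in."""

    sample_id: str
    mark: str
    genotype: str
    chip: BinCountTrack
    input: BinCountTrack
    spike_in: SpikeInCounts | None


def simulate_chip_experiment(
    truth: EpigenomeTruth,
    mark: str,
    genotype: GenotypeProfile,
    config: SimulationConfig,
    seed: int | None = None,
) -> ChipExperiment:
    """Poisson bin counts for ChIP and input plus a spike-in panel.

    Each sample draws a library-depth factor (lognormal) once; ChIP counts
    scale with it while spike-in totals scale with it too, so the spike-in
    factor (reference total / sample total) undoes depth and exposes the
    genotype's true mark scale.  The lamina mark (DamID) has no spike-in.
    """
    if mark not in MARKS:
        raise ValueError(f"unsupported mark {mark!r}")
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "chip", mark, genotype.name)
    scale = {"me2": genotype.me2_scale, "me3": genotype.me3_scale, "lamina": 1.0}[mark]
    ratio = truth.true_ratio(mark)
    lengths = truth.grid.lengths

    lib_chip = float(rng.lognormal(0.0, config.library_factor_sigma))
    lib_input = float(rng.lognormal(0.0, config.library_factor_sigma))
    input_counts = rng.poisson(config.input_depth_per_bp * lengths * lib_input)
    chip_rate = config.chip_background_fraction + ratio * scale
    chip_counts = rng.poisson(config.chip_depth_per_bp * lengths * chip_rate * lib_chip)
    sample_id = f"{genotype.name}_{mark}"
    chip = BinCountTrack(sample_id, truth.grid, chip_counts.astype(float))
    inp = BinCountTrack(f"{sample_id}_input", truth.grid, input_counts.astype(float))

    spike: SpikeInCounts | None = None
    if mark in ("me2", "me3"):
        total = max(1, int(round(config.spike_base_total * lib_chip)))
        target = f"K36{mark}"
        s = config.spike_specificity
        u = config.spike_unmod_fraction
        probs = []
        for state in SPIKE_STATES:
            if state == "H3":
                probs.append(u)
            elif state == target:
                probs.append((1.0 - u) * s)
            else:
                probs.append((1.0 - u) * (1.0 - s) / 2.0)
        counts = rng.multinomial(total, probs)
        spike = SpikeInCounts(sample_id, dict(zip(SPIKE_STATES, (int(c) for c in counts))))
    return ChipExperiment(sample_id, mark, genotype.name, chip, inp, spike)


@dataclass
class ReadSnpObservation:
    """One read with the base observed at each SNP it overlaps."""

    read_id: str
    gene_id: str
    observations: list[tuple[SnpRecord, str]]


def make_snps(
    genes: Sequence[GeneAnnotation],
    config: SimulationConfig,
    seed: int | None = None,
) -> list[SnpRecord]:
    """Strain-specific SNPs scattered across gene bodies; a configured
    fraction is flagged as shared with the third strain (and must later be
    excluded)."""
    seed = (config.seed if seed is None else seed)
    rng = _rng(seed, "snps")
    bases = np.array(list("ACGT"))
    snps: list[SnpRecord] = []
    for gene in genes:
        pos = gene.start
        while True:
            pos += int(1 + rng.exponential(config.snp_spacing_mean))
            if pos >= gene.end:
                break
            mat, pat = rng.choice(4, size=2, replace=False)
            snps.append(
                SnpRecord(
                    gene.chrom,
                    pos,
                    str(bases[mat]),
                    str(bases[pat]),
                    bool(rng.random() < config.snp_shared_fraction),
                )
            )
    return snps


def simulate_allelic_reads(
    genes: Sequence[GeneAnnotation],
    snps: Sequence[SnpRecord],
    config: SimulationConfig,
    seed: int | None = None,
    maternal_fraction: dict[str, float] | float | None = None,
) -> list[ReadSnpObservation]:
    """RNA-seq-like reads with base calls at overlapped SNPs.

    Each read's true allele is maternal with the gene's configured
    fraction; base calls match the true allele except for a uniform error
    rate (errors draw any base).  Reads overlapping no SNP are still
    emitted (they must end up unassigned downstream).
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "allelic")
    if maternal_fraction is None:
        maternal_fraction = config.maternal_fraction
    bases = "ACGT"
    by_chrom: dict[str, list[SnpRecord]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    for lst in by_chrom.values():
        lst.sort(key=lambda s: s.pos)
    reads: list[ReadSnpObservation] = []
    for gene in genes:
        frac = (
            maternal_fraction.get(gene.gene_id, config.maternal_fraction)
            if isinstance(maternal_fraction, dict)
            else maternal_fraction
        )
        gene_snps = [
            s for s in by_chrom.get(gene.chrom, []) if gene.start <= s.pos < gene.end
        ]
        positions = np.array([s.pos for s in gene_snps], dtype=np.int64)
        span = max(1, gene.end - gene.start - config.read_length)
        starts = gene.start + rng.integers(0, span, size=config.reads_per_gene)
        is_mat = rng.random(config.reads_per_gene) < frac
        for j in range(config.reads_per_gene):
            lo, hi = starts[j], starts[j] + config.read_length
            obs: list[tuple[SnpRecord, str]] = []
            if positions.size:
                i0, i1 = np.searchsorted(positions, (lo, hi))
                for s in gene_snps[i0:i1]:
                    true_base = s.maternal_allele if is_mat[j] else s.paternal_allele
                    if rng.random() < config.base_error_rate:
                        base = bases[rng.integers(0, 4)]
                    else:
                        base = true_base
                    obs.append((s, base))
            reads.append(ReadSnpObservation(f"{gene.gene_id}_read{j:06d}", gene.gene_id, obs))
    return reads


@dataclass
class SyntheticCohort:
    """Everything one simulated study produces, ready for analysis."""

    config: SimulationConfig
    profiles: dict[str, GenotypeProfile]
    truth: EpigenomeTruth
    wgbs: dict[str, CpgCallSet]
    chip: dict[tuple[str, str], ChipExperiment]  # (mark, genotype) -> experiment
    snps: list[SnpRecord]

    @property
    def grid(self) -> BinGrid:
        return self.truth.grid

    @property
    def genes(self) -> list[GeneAnnotation]:
        return self.truth.genes


def generate_cohort(
    config: SimulationConfig,
    genotypes: Iterable[str] = GENOTYPES,
    chip_experiments: Iterable[tuple[str, str]] = (
        ("me2", "control"),
        ("me2", "K36M"),
        ("me3", "control"),
        ("me3", "Setd2KO"),
    ),
) -> SyntheticCohort:
    """Build truth, WGBS calls per genotype, and the requested ChIP panel."""
    genotypes = list(genotypes)
    profiles = paper_default_profiles(config)
    unknown = [g for g in genotypes if g not in profiles]
    if unknown:
        raise ValueError(f"unknown genotypes {unknown}; expected {sorted(profiles)}")
    truth = build_truth_epigenome(config)
    wgbs = {g: simulate_wgbs_calls(truth, profiles[g], config) for g in genotypes}
    chip = {
        (mark, g): simulate_chip_experiment(truth, mark, profiles[g], config)
        for mark, g in chip_experiments
    }
    snps = make_snps(truth.genes, config)
    return SyntheticCohort(config, profiles, truth, wgbs, chip, snps)


def write_fixture_set(cohort: SyntheticCohort, out_dir) -> None:
    """Write the cohort as plain-text fixtures that round-trip losslessly."""
    from . import io as oio  # deferred: io imports nothing from here
    from pathlib import Path
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = cohort.grid.layout
    oio.write_chrom_sizes(layout, out / "genome.chrom.sizes")
    oio.write_bed6(cohort.genes, out / "genes.bed")
    oio.write_snps(cohort.snps, out / "snps.tsv")
    truth_df = cohort.truth.as_frame()
    oio.write_table(truth_df, out / "truth_bins.tsv")
    for g, calls in cohort.wgbs.items():
        oio.write_cpg_calls(calls, out / f"cpg_calls_{g}.tsv")
    spike_rows = []
    for (mark, g), exp in cohort.chip.items():
        oio.write_bin_counts(exp.chip, out / f"chip_{mark}_{g}.tsv")
        oio.write_bin_counts(exp.input, out / f"input_{mark}_{g}.tsv")
        if exp.spike_in is not None:
            for state, count in exp.spike_in.counts.items():
                spike_rows.append((exp.sample_id, state, count))
    oio.write_spikein_table(spike_rows, out / "spikein.tsv")
    manifest = {
        "seed": cohort.config.seed,
        "bin_size": cohort.config.bin_size,
        "genotypes": sorted(cohort.wgbs),
        "chip_experiments": sorted(f"{m}:{g}" for m, g in cohort.chip),
        "config": {k: v if not isinstance(v, tuple) else list(v)
                   for k, v in asdict(cohort.config).items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
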