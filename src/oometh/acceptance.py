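"""Headline statistics recomputed end-to-end from a synthetic cohort.

Runs the full default-scale simulation and analysis and returns the
quantities the pipeline is calibrated to recover: per-genotype global
bin-methylation means and the control H3K36me2 occupancy per chromosome
class.  Used by the acceptance script and the round-trip tests.
"""

from __future__ import annotations

from .chip import bin_enrichment_ratio, enriched_occupancy
from .simulate import SimulationConfig, generate_cohort
from .wgbs import compute_bin_methylation, filter_informative_calls, methylome_summary

WGBS_GENOTYPES = ("control", "K36M", "DM", "Dnmt3aKO")


def headline_statistics(seed: int = 42, config: SimulationConfig | None = None) -> dict:
    """Simulate the default cohort and recompute the calibrated statistics.

    Returns global mean CG methylation (%) per genotype over informative
    10 kb bins, plus the fraction (%) of chrX / autosomal bins whose
    control H3K36me2 ChIP/input ratio reaches the 1.4 enrichment
    threshold, with the bin counts used.
    """
    if config is None:
        config = SimulationConfig(seed=seed)
    else:
        config.seed = seed
    cohort = generate_cohort(
        config, genotypes=WGBS_GENOTYPES, chip_experiments=(("me2", "control"),)
    )
    out: dict = {"global_mean": {}, "n_bins": {}}
    for g in WGBS_GENOTYPES:
        calls = filter_informative_calls(cohort.wgbs[g])
        bm = compute_bin_methylation(calls, cohort.grid)
        s = methylome_summary(bm)
        out["global_mean"][g] = s.global_mean
        out["n_bins"][g] = s.n_bins
    exp = cohort.chip[("me2", "control")]
    track = bin_enrichment_ratio(exp.chip, exp.input, mark="me2")
    occ = enriched_occupancy(track, cohort.grid.layout, 1.4)
    klass = cohort.grid.klass
    out["me2_occupancy_pct"] = {kl: 100.0 * f for kl, f in occ.items()}
    out["n_class_bins"] = {
        kl: int((klass == kl).sum()) for kl in ("autosome", "chrX")
    }
    return out
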