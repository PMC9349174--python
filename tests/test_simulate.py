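"""Synthetic cohort: determinism, calibration, occupancy and recovery."""

import numpy as np
import pandas as pd
import pytest

import oometh as om
from oometh.simulate import make_snps, paper_default_profiles, simulate_allelic_reads


def test_truth_deterministic(small_config):
    a = om.build_truth_epigenome(small_config)
    b = om.build_truth_epigenome(small_config)
    pd.testing.assert_frame_equal(a.as_frame(), b.as_frame())
    ca = om.simulate_wgbs_calls(a, paper_default_profiles(small_config)["control"], small_config)
    cb = om.simulate_wgbs_calls(b, paper_default_profiles(small_config)["control"], small_config)
    pd.testing.assert_frame_equal(ca.df, cb.df)


def test_genotypes_have_distinct_streams(small_cohort):
    assert not small_cohort.wgbs["control"].df["meth_count"].equals(
        small_cohort.wgbs["K36M"].df["meth_count"]
    )


def test_occupancy_targets_within_one_bin(small_cohort):
    cfg = small_cohort.config
    truth = small_cohort.truth
    klass = truth.grid.klass
    for kl, target in (("autosome", cfg.autosome_me2_occupancy), ("chrX", cfg.x_me2_occupancy)):
        sel = klass == kl
        realized = int(truth.me2_domain[sel].sum())
        assert abs(realized - round(target * sel.sum())) <= 1


def test_zero_occupancy_targets():
    cfg = om.SimulationConfig(
        seed=1, autosome_lengths=(4_000_000,), chrx_length=2_000_000,
        x_me2_occupancy=0.0, autosome_me2_occupancy=0.0, genic_fraction=0.32,
    )
    truth = om.build_truth_epigenome(cfg)
    assert truth.me2_domain.sum() == 0


def test_infeasible_occupancy_rejected():
    with pytest.raises(ValueError):
        om.SimulationConfig(x_me2_occupancy=1.5)


def test_truth_mean_calibration(small_cohort):
    """Realized truth means match the configured global means within 0.2 points."""
    cfg = small_cohort.config
    truth = small_cohort.truth
    profiles = small_cohort.profiles
    for g, target in cfg.global_means.items():
        realized = truth.genotype_methylation(profiles[g]).mean()
        assert realized == pytest.approx(target, abs=0.2)


def test_closed_form_weights_reproduce_control_mean(small_cohort):
    """w . m over the truth decomposition equals the configured control mean."""
    truth = small_cohort.truth
    cfg = small_cohort.config
    f2, f3 = truth.me2_domain.mean(), truth.me3_genic.mean()
    m_pre = truth.preexisting.mean()
    m2 = truth.denovo_me2[truth.me2_domain].mean()
    m3 = truth.denovo_me3[truth.me3_genic].mean()
    assert m_pre + f2 * m2 + f3 * m3 == pytest.approx(cfg.global_means["control"], abs=1e-6)
    # and direct summation over truth bins agrees
    assert truth.baseline_meth.mean() == pytest.approx(cfg.global_means["control"], abs=1e-6)


def test_dm_residual_is_preexisting_only(small_cohort):
    dm = small_cohort.truth.genotype_methylation(small_cohort.profiles["DM"])
    np.testing.assert_allclose(dm, small_cohort.truth.preexisting)


def test_me2_domains_avoid_me3_genic(small_cohort):
    truth = small_cohort.truth
    assert not (truth.me2_domain & truth.me3_genic).any()
    assert truth.baseline_meth.max() <= 100.0


def test_truth_ratio_mean_is_one(small_cohort):
    grid = small_cohort.grid
    w = grid.lengths / grid.lengths.sum()
    for arr in (small_cohort.truth.true_me2_ratio, small_cohort.truth.true_me3_ratio):
        assert float((w * arr).sum()) == pytest.approx(1.0, abs=1e-9)


def _flat_truth(meth_pct, n_bins=1, bin_size=100_000):
    """Single-chromosome truth with uniform methylation (helper fixture)."""
    cfg = om.SimulationConfig(
        seed=3, autosome_lengths=(n_bins * bin_size,), chrx_length=0, bin_size=bin_size
    )
    grid = om.make_bin_grid(cfg.layout(), bin_size)
    z = np.zeros(grid.n_bins)
    return cfg, om.EpigenomeTruth(
        grid, [], z.astype(bool), z.astype(bool),
        np.ones(grid.n_bins), np.ones(grid.n_bins), np.ones(grid.n_bins),
        np.full(grid.n_bins, float(meth_pct)), z.copy(), z.copy(),
    )


def test_wgbs_bin_recovery_at_50pct():
    """~1000 sites at coverage ~15 pool to within 3 points of the truth."""
    cfg, truth = _flat_truth(50.0)
    calls = om.simulate_wgbs_calls(truth, om.GenotypeProfile("control"), cfg)
    bm = om.compute_bin_methylation(om.filter_informative_calls(calls), truth.grid)
    assert bm.level[0] == pytest.approx(50.0, abs=3.0)


def test_wgbs_zero_truth_stays_near_zero():
    cfg, truth = _flat_truth(0.0)
    calls = om.simulate_wgbs_calls(truth, om.GenotypeProfile("DM"), cfg)
    bm = om.compute_bin_methylation(om.filter_informative_calls(calls), truth.grid)
    assert bm.level[0] < 2.0


def test_coverage_model_mean():
    cfg, truth = _flat_truth(50.0, n_bins=20)  # ~2 Mb -> >=1e4 CpGs
    calls = om.simulate_wgbs_calls(truth, om.GenotypeProfile("control"), cfg)
    assert len(calls) >= 10_000
    assert calls.df["total_count"].mean() == pytest.approx(cfg.coverage_mean, abs=0.5)


def test_chip_scale_recovery(small_cohort):
    """Spike-in normalization recovers the configured K36M me2 scale."""
    ctl = small_cohort.chip[("me2", "control")]
    mut = small_cohort.chip[("me2", "K36M")]
    panel = {ctl.sample_id: ctl.spike_in, mut.sample_id: mut.spike_in}
    f = om.spike_in_scale_factors(panel, ctl.sample_id)
    assert f[ctl.sample_id] == 1.0
    scaled_ratio = (mut.chip.counts.sum() * f[mut.sample_id]) / (
        ctl.chip.counts.sum() * f[ctl.sample_id]
    )
    expected = small_cohort.config.k36m_me2_scale
    assert scaled_ratio == pytest.approx(expected, rel=0.10)
    # without the spike factors the depth difference corrupts the comparison
    raw_ratio = mut.chip.counts.sum() / ctl.chip.counts.sum()
    assert raw_ratio != pytest.approx(expected, rel=0.02)


def test_simulated_specificity(small_cohort):
    spike = small_cohort.chip[("me2", "control")].spike_in
    s = om.antibody_specificity(spike, "K36me2")
    assert s == pytest.approx(small_cohort.config.spike_specificity, abs=0.02)


def test_me3_scale_near_zero_looks_like_background(small_cohort):
    """Setd2KO me3 ChIP loses genic enrichment down to the 5% floor."""
    exp = small_cohort.chip[("me3", "Setd2KO")]
    tr = om.bin_enrichment_ratio(exp.chip, exp.input, mark="me3")
    genic = small_cohort.truth.me3_genic
    ctl = small_cohort.chip[("me3", "control")]
    tr_ctl = om.bin_enrichment_ratio(ctl.chip, ctl.input, mark="me3")
    # RPKM self-normalization rescales levels, but the genic/background
    # contrast must collapse toward flat
    contrast_ko = np.nanmean(tr.ratio[genic]) / np.nanmean(tr.ratio[~genic])
    contrast_ctl = np.nanmean(tr_ctl.ratio[genic]) / np.nanmean(tr_ctl.ratio[~genic])
    assert contrast_ko == pytest.approx(1.0, abs=0.1)
    assert contrast_ctl > 2.0


def test_allelic_reads_pure_maternal(small_cohort):
    cfg = om.SimulationConfig(seed=5, base_error_rate=0.0, reads_per_gene=200)
    genes = small_cohort.genes[:3]
    snps = make_snps(genes, cfg)
    reads = simulate_allelic_reads(genes, snps, cfg, maternal_fraction=1.0)
    from oometh import assign_reads

    labels = {a.label for a in assign_reads(reads) if a.label != "unassigned"}
    assert labels == {"maternal"}


def test_allelic_reads_balanced_fraction(small_cohort):
    cfg = om.SimulationConfig(seed=6, base_error_rate=0.0, reads_per_gene=2500)
    genes = small_cohort.genes[:4]  # 10^4 reads
    snps = make_snps(genes, cfg)
    reads = simulate_allelic_reads(genes, snps, cfg, maternal_fraction=0.5)
    from oometh import allelic_gene_counts, assign_reads

    counts = allelic_gene_counts(assign_reads(reads))
    m, p = counts["maternal"].sum(), counts["paternal"].sum()
    assert m / (m + p) == pytest.approx(0.5, abs=0.02)


def test_fixture_round_trip(tmp_path, small_cohort):
    from oometh import io as oio

    out = tmp_path / "cohort"
    om.write_fixture_set(small_cohort, out)
    layout = oio.read_chrom_sizes(out / "genome.chrom.sizes")
    assert layout.names == small_cohort.grid.layout.names
    calls = oio.read_cpg_calls(out / "cpg_calls_control.tsv")
    pd.testing.assert_frame_equal(
        calls.df, small_cohort.wgbs["control"].df, check_dtype=False
    )
    grid = om.make_bin_grid(layout, small_cohort.config.bin_size)
    chip = oio.read_bin_counts(out / "chip_me2_control.tsv", grid)
    np.testing.assert_allclose(chip.counts, small_cohort.chip[("me2", "control")].chip.counts)
    spikes = oio.read_spikein_table(out / "spikein.tsv")
    assert spikes["control_me2"].counts == small_cohort.chip[("me2", "control")].spike_in.counts
    genes = oio.read_bed6(out / "genes.bed")
    assert genes == small_cohort.genes
    snps = oio.read_snps(out / "snps.tsv")
    assert snps == small_cohort.snps


def test_fixture_byte_identical(tmp_path, small_config):
    a = om.generate_cohort(small_config, genotypes=("control",))
    b = om.generate_cohort(small_config, genotypes=("control",))
    om.write_fixture_set(a, tmp_path / "a")
    om.write_fixture_set(b, tmp_path / "b")
    for fa in sorted((tmp_path / "a").iterdir()):
        fb = tmp_path / "b" / fa.name
        assert fa.read_bytes() == fb.read_bytes(), fa.name


def test_unknown_genotype_rejected(small_config):
    with pytest.raises(ValueError, match="unknown genotypes"):
        om.generate_cohort(small_config, genotypes=("control", "Tet3KO"))
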