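"""WGBS filtering, bin pooling, categories, deltas and region calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import oometh as om
from oometh.wgbs import AFFECTED, HMR, LMR, MMR, NEITHER, UNAFFECTED, categorize_levels


def calls_from(records, sample="s"):
    df = pd.DataFrame(records, columns=["chrom", "pos", "meth_count", "total_count"])
    return om.CpgCallSet(sample, df)


@pytest.mark.parametrize(
    "total,kept",
    [(3, False), (4, True), (100, True), (101, False), (50, True)],
)
def test_informative_filter_boundaries(total, kept):
    calls = calls_from([("chr1", 10, 0, total)])
    out = om.filter_informative_calls(calls)
    assert len(out) == (1 if kept else 0)


def test_informative_filter_empty():
    out = om.filter_informative_calls(calls_from([]))
    assert len(out) == 0


def test_bin_rule_five_vs_six_sites(tiny_grid):
    # 5 informative CpGs -> missing; 6 -> level reported
    recs5 = [("chr1", 100 * i, 5, 10) for i in range(5)]
    recs6 = recs5 + [("chr1", 900, 5, 10)]
    bm5 = om.compute_bin_methylation(calls_from(recs5), tiny_grid)
    bm6 = om.compute_bin_methylation(calls_from(recs6), tiny_grid)
    assert np.isnan(bm5.level[0]) and bm5.n_informative[0] == 5
    assert bm6.level[0] == pytest.approx(50.0)


def test_bin_level_is_pooled_not_site_mean(tiny_grid):
    # heavily covered unmethylated site dominates the pooled estimator
    recs = [("chr1", 0, 9, 10), ("chr1", 100, 0, 90)] + [
        ("chr1", 200 + i, 5, 10) for i in range(4)
    ]
    bm = om.compute_bin_methylation(calls_from(recs), tiny_grid)
    meth = 9 + 0 + 4 * 5
    total = 10 + 90 + 4 * 10
    pooled = 100 * meth / total
    site_mean = 100 * np.mean([9 / 10, 0 / 90] + [0.5] * 4)
    assert bm.level[0] == pytest.approx(pooled)
    assert abs(pooled - site_mean) > 5  # the two estimators genuinely differ


@given(
    st.lists(
        st.tuples(st.integers(0, 99_999), st.integers(4, 100)),
        min_size=6, max_size=40, unique_by=lambda t: t[0],
    ),
    st.data(),
)
def test_monotonicity_in_meth_counts(tiny_grid, sites, data):
    """Raising any site's methylated count never lowers a bin level."""
    meth = [data.draw(st.integers(0, t)) for _, t in sites]
    base = calls_from([("chr1", p, m, t) for (p, t), m in zip(sites, meth)])
    bumped = calls_from(
        [("chr1", p, min(t, m + 1), t) for (p, t), m in zip(sites, meth)]
    )
    lv0 = om.compute_bin_methylation(base, tiny_grid).level
    lv1 = om.compute_bin_methylation(bumped, tiny_grid).level
    ok = ~np.isnan(lv0)
    assert (lv1[ok] >= lv0[ok] - 1e-12).all()


@pytest.mark.parametrize(
    "level,category",
    [(80.0, HMR), (20.0, MMR), (19.99, LMR), (0.0, LMR), (100.0, HMR), (79.99, MMR)],
)
def test_category_boundaries(level, category):
    assert om.categorize_bin(level) == category


def test_category_missing_and_partition():
    assert om.categorize_bin(float("nan")) is None
    levels = np.concatenate([np.linspace(0, 100, 401), [np.nan]])
    cats = categorize_levels(levels)
    present = cats[:-1]
    assert cats[-1] is None
    assert set(present) <= {HMR, MMR, LMR}
    assert all(c is not None for c in present)  # exhaustive on [0, 100]


def test_methylome_summary_two_bins(tiny_grid):
    recs = [("chr1", i * 100, 1, 10) for i in range(6)] + [
        ("chr1", 10_000 + i * 100, 9, 10) for i in range(6)
    ]
    bm = om.compute_bin_methylation(calls_from(recs), tiny_grid)
    s = om.methylome_summary(bm)
    assert s.global_mean == pytest.approx(50.0)
    assert s.category_fractions == {HMR: 0.5, MMR: 0.0, LMR: 0.5}
    assert s.n_bins == 2


def test_summary_warns_when_class_all_missing(tiny_grid):
    # only autosomal bins have data; chrX omitted with a warning
    recs = [("chr1", i * 100, 1, 10) for i in range(6)]
    bm = om.compute_bin_methylation(calls_from(recs), tiny_grid)
    with pytest.warns(UserWarning):
        s = om.methylome_summary(bm)
    assert "chrX" not in s.per_class


def test_summary_requires_some_bins(tiny_grid):
    bm = om.compute_bin_methylation(calls_from([]), tiny_grid)
    with pytest.raises(ValueError):
        om.methylome_summary(bm)


def _binmeth(tiny_grid, levels):
    lv = np.full(tiny_grid.n_bins, np.nan)
    lv[: len(levels)] = levels
    n = np.where(~np.isnan(lv), 10, 0)
    return om.BinMethylation("s", tiny_grid, n, lv)


def test_delta_methylation(tiny_grid):
    control = _binmeth(tiny_grid, [50.0, np.nan, 30.0])
    mutant = _binmeth(tiny_grid, [30.0, 20.0, 30.0])
    d = om.delta_methylation(mutant, control)
    assert d.values[0] == pytest.approx(-20.0)
    assert np.isnan(d.values[1])  # control missing -> delta missing
    assert d.values[2] == pytest.approx(0.0)


def test_delta_grid_mismatch(tiny_grid, tiny_layout):
    other = om.make_bin_grid(tiny_layout, 5_000)
    a = _binmeth(tiny_grid, [50.0])
    b = om.BinMethylation("s", other, np.zeros(other.n_bins, int), np.full(other.n_bins, np.nan))
    with pytest.raises(ValueError):
        om.delta_methylation(b, a)


@pytest.mark.parametrize(
    "control,mutant,expected",
    [
        (50.0, 25.0, AFFECTED),       # delta -25, control > 40
        (45.0, 40.0, UNAFFECTED),     # delta -5, control >= 40
        (40.0, 15.0, NEITHER),        # control must be strictly > 40 for affected
        (40.0, 35.0, UNAFFECTED),     # control >= 40 suffices for unaffected
        (50.0, 30.0, NEITHER),        # delta -20 exactly: not < -20
        (50.0, 60.0, NEITHER),        # delta +10: not < 10
        (50.0, 59.99, UNAFFECTED),
        (39.9, 35.0, NEITHER),        # control below both cutoffs
    ],
)
def test_affected_unaffected_criteria(tiny_grid, control, mutant, expected):
    c = _binmeth(tiny_grid, [control])
    m = _binmeth(tiny_grid, [mutant])
    labels = om.classify_affected_bins(om.delta_methylation(m, c), c)
    assert labels[0] == expected


@given(
    st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)), min_size=1, max_size=30)
)
def test_affected_unaffected_disjoint(tiny_grid, pairs):
    n = min(len(pairs), tiny_grid.n_bins)
    c = _binmeth(tiny_grid, [p[0] for p in pairs[:n]])
    m = _binmeth(tiny_grid, [p[1] for p in pairs[:n]])
    labels = om.classify_affected_bins(om.delta_methylation(m, c), c)
    assert not ((labels == AFFECTED) & (labels == UNAFFECTED)).any()
    assert set(labels) <= {AFFECTED, UNAFFECTED, NEITHER}


def test_merge_replicates_sums_before_filter():
    r1 = calls_from([("chr1", 10, 1, 2)], "r1")
    r2 = calls_from([("chr1", 10, 1, 2)], "r2")
    merged = om.merge_replicates([r1, r2], "m")
    assert merged.df.loc[0, "total_count"] == 4
    # each replicate alone fails the coverage filter; the merge passes
    assert len(om.filter_informative_calls(merged)) == 1
    assert len(om.filter_informative_calls(r1)) == 0


def test_bin_estimates_unbiased_on_cohort(small_cohort):
    """Parameter recovery: mean(estimate - truth) below 0.5 points."""
    profile = small_cohort.profiles["control"]
    truth_level = small_cohort.truth.genotype_methylation(profile)
    calls = om.filter_informative_calls(small_cohort.wgbs["control"])
    bm = om.compute_bin_methylation(calls, small_cohort.grid)
    ok = bm.present()
    bias = np.mean(bm.level[ok] - truth_level[ok])
    assert abs(bias) < 0.5
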