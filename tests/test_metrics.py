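"""ME / CD / SE criteria: closed-form examples, hand oracles, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paritynet import metrics
from paritynet.metrics import (
    DiscretizationGrid,
    benjamini_hochberg,
    cd_differential,
    combine_metrics,
    criteria_correlations,
    ecdf_area,
    hierarchical_order,
    me_differential,
    relative_profile,
    se_bootstrap_differential,
    shannon_entropy,
    zscore_rows,
)

from _oracles import complete_linkage_heights
from conftest import make_dataset

# -- Benjamini-Hochberg ----------------------------------------------------


def bh_oracle(p):
    """Literal step-up evaluation of p(i) * m / i with monotone enforcement."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0, 1)
    return out


@pytest.mark.parametrize(
    "pvals,expected",
    [
        ([0.03], [0.03]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
    ],
)
def test_bh_hand_examples(pvals, expected):
    assert benjamini_hochberg(pvals) == pytest.approx(expected)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
def test_bh_matches_oracle_and_never_decreases(pvals):
    adj = benjamini_hochberg(pvals)
    assert adj == pytest.approx(bh_oracle(pvals))
    assert (adj >= np.asarray(pvals) - 1e-12).all()
    assert (adj <= 1).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        benjamini_hochberg([0.5, 1.2])


# -- ECDF area -------------------------------------------------------------


@pytest.mark.parametrize(
    "series,bounds,expected",
    [([0.2], (0, 1), 0.8), ([0.0, 1.0], (0, 1), 0.5), ([2.0, 2.0], (0, 4), 2.0)],
)
def test_ecdf_area_examples(series, bounds, expected):
    assert ecdf_area(series, *bounds) == pytest.approx(expected)


@given(
    st.lists(st.floats(-5, 5), min_size=1, max_size=40),
    st.floats(0.01, 3),
)
def test_ecdf_area_equals_upper_minus_mean(series, pad):
    lo, hi = min(series) - pad, max(series) + pad
    assert ecdf_area(series, lo, hi) == pytest.approx(hi - np.mean(series))


def test_ecdf_area_rejects_out_of_bounds():
    with pytest.raises(ValueError):
        ecdf_area([0.5, 2.0], 0, 1)


# -- Shannon entropy -------------------------------------------------------


def test_entropy_closed_forms():
    grid = DiscretizationGrid(0, 10, 10)
    assert shannon_entropy([0.5] * 20, grid) == 0.0
    uniform = np.arange(10) + 0.5
    assert shannon_entropy(uniform, grid) == pytest.approx(np.log2(10))
    two_bins = [0.5] * 4 + [9.5] * 4
    assert shannon_entropy(two_bins, grid) == pytest.approx(1.0)


@given(st.lists(st.floats(0.01, 9.99), min_size=2, max_size=60))
def test_entropy_bounds_and_affine_invariance(series):
    grid = DiscretizationGrid(0, 10, 10)
    h = shannon_entropy(series, grid)
    assert 0 <= h <= np.log2(10) + 1e-12
    # strictly monotone affine map with matching grid keeps bin counts
    mapped = [3 * x + 7 for x in series]
    grid2 = DiscretizationGrid(7, 37, 10)
    assert shannon_entropy(mapped, grid2) == pytest.approx(h)


# -- ME --------------------------------------------------------------------


def test_me_identical_groups_yield_no_calls():
    rng = np.random.default_rng(0)
    block = rng.normal(8, 1, size=(50, 40))
    values = np.hstack([block, block])  # contrast group duplicates reference
    ds = make_dataset(values, 40, 40)
    me = me_differential(ds)
    assert me["me_delta"].abs().max() == 0
    assert not me["me_significant"].any()
    assert (me["me_p"] == 1).all()


def test_me_flags_degenerate_constant_probe():
    rng = np.random.default_rng(1)
    values = rng.normal(size=(5, 20))
    values[2] = 3.14
    ds = make_dataset(values, 10, 10)
    me = me_differential(ds)
    assert me["degenerate"].iloc[2]
    assert np.isnan(me["me_p"].iloc[2])
    assert me["me_p"].drop(me.index[2]).notna().all()


def test_me_direction_follows_contrast_minus_reference():
    rng = np.random.default_rng(2)
    values = rng.normal(0, 0.1, size=(2, 30))
    values[0, 15:] += 5  # up in contrast
    values[1, 15:] -= 5
    ds = make_dataset(values, 15, 15)
    me = me_differential(ds)
    assert list(me["me_direction"]) == ["up", "down"]
    assert me["me_significant"].all()


# -- CD --------------------------------------------------------------------


def test_cd_identical_groups():
    rng = np.random.default_rng(3)
    block = rng.normal(size=(20, 25))
    ds = make_dataset(np.hstack([block, block]), 25, 25)
    cd = cd_differential(ds)
    assert cd["cd_delta"].abs().max() == pytest.approx(0)
    assert (cd["ks_p"] == 1).all()


def test_cd_disjoint_supports_give_ks_one():
    values = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
    ds = make_dataset(values, 3, 3)
    cd = cd_differential(ds)
    assert cd["ks_stat"].iloc[0] == pytest.approx(1.0)


def test_cd_delta_negates_me_delta():
    # common support makes integral(F) = upper - mean, so deltas mirror
    rng = np.random.default_rng(4)
    ds = make_dataset(rng.normal(size=(30, 40)), 20, 20)
    cd = cd_differential(ds)
    me = me_differential(ds)
    assert cd["cd_delta"].to_numpy() == pytest.approx(-me["me_delta"].to_numpy())


def test_cd_sees_shape_change_that_me_misses(study_data):
    ds, truth = study_data
    shape = truth.probes_with_label("shape_shift")
    cd = cd_differential(ds)
    me = me_differential(ds)
    assert (cd.loc[shape, "ks_p"] < 0.05).mean() >= 0.8
    assert me.loc[shape, "me_significant"].mean() <= 0.1


# -- SE --------------------------------------------------------------------


def test_se_fixed_seed_reproducible(null_data):
    sub = null_data.subset_probes(null_data.probe_ids[:30])
    a = se_bootstrap_differential(sub, n_boot=100, seed=5)
    b = se_bootstrap_differential(sub, n_boot=100, seed=5)
    pd.testing.assert_frame_equal(a, b)


def test_se_forced_entropy_gain_direction():
    # reference concentrated in one bin, contrast spread across the grid
    rng = np.random.default_rng(6)
    ref = rng.uniform(4.9, 5.1, size=(10, 30))
    con = rng.uniform(0, 10, size=(10, 30))
    ds = make_dataset(np.hstack([ref, con]), 30, 30)
    for method in ("collection", "null_bootstrap"):
        se = se_bootstrap_differential(ds, n_boot=200, seed=7, method=method)
        assert (se["se_delta"] > 0).all()
        assert (se["se_direction"] == "gain").all()
        assert se["se_significant"].all()


def test_se_constant_probe_flagged_degenerate():
    values = np.vstack([np.full(20, 2.0), np.random.default_rng(8).normal(size=20)])
    ds = make_dataset(values, 10, 10)
    se = se_bootstrap_differential(ds, n_boot=50, seed=0)
    assert se["degenerate"].iloc[0]
    assert not se["degenerate"].iloc[1]


def test_se_collection_method_overstates_null_significance(null_data):
    """The literal two-collection t-test treats each resample as an
    observation and so rejects massively under an independent-sampling null;
    the pooled null bootstrap does not."""
    sub = null_data.subset_probes(null_data.probe_ids[:150])
    lit = se_bootstrap_differential(sub, n_boot=300, seed=9, method="collection")
    cal = se_bootstrap_differential(sub, n_boot=300, seed=9, method="null_bootstrap")
    assert (lit["se_p"] < 0.05).mean() > 0.5
    assert (cal["se_p"] < 0.05).mean() < 0.15


# -- combined views --------------------------------------------------------


def _tiny_metrics_frame():
    rng = np.random.default_rng(10)
    ds = make_dataset(rng.normal(8, 1, size=(40, 30)), 15, 15)
    return combine_metrics(
        me_differential(ds),
        cd_differential(ds),
        se_bootstrap_differential(ds, n_boot=60, seed=1),
    )


def test_criteria_correlations_bounds_and_degenerate_cases():
    records = _tiny_metrics_frame()
    corr = criteria_correlations(records)
    assert set(corr) == {"cd_me", "se_me", "se_cd"}
    assert all(-1 <= v <= 1 for v in corr.values())
    with pytest.raises(ValueError):
        criteria_correlations(records.iloc[:2])


def test_relative_profile_sorted_and_homogeneous():
    records = _tiny_metrics_frame()
    prof = relative_profile(records, "me")
    vals = prof["relative_value"].to_numpy()
    assert (np.diff(vals) <= 1e-12).all()  # non-increasing
    # doubling contrast values doubles the curve
    doubled = records.copy()
    doubled["mean_group2"] *= 2
    prof2 = relative_profile(doubled, "me")
    assert prof2["relative_value"].to_numpy() == pytest.approx(2 * vals)


def test_relative_profile_constant_when_groups_equal():
    rng = np.random.default_rng(11)
    block = rng.normal(8, 1, size=(20, 12))
    ds = make_dataset(np.hstack([block, block]), 12, 12)
    records = combine_metrics(
        me_differential(ds), cd_differential(ds),
        se_bootstrap_differential(ds, n_boot=50, seed=2),
    )
    prof = relative_profile(records, "me")
    assert prof["relative_value"].to_numpy() == pytest.approx(1.0)


# -- clustering ------------------------------------------------------------


def test_identical_rows_merge_first_at_height_zero():
    m = np.array([[1.0, 2.0, 3.0], [9.0, 9.0, 9.0], [1.0, 2.0, 3.0]])
    order, link, _ = hierarchical_order(m)
    assert link[0, 2] == 0.0
    assert {int(link[0, 0]), int(link[0, 1])} == {0, 2}


def test_zscore_rows_are_standardized_and_flags_constant():
    m = np.array([[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]])
    z, skipped = zscore_rows(m)
    assert z[0].mean() == pytest.approx(0)
    assert z[0].std() == pytest.approx(1)
    assert skipped.tolist() == [False, True]
    assert z[1] == pytest.approx(m[1])  # untouched


def test_complete_linkage_matches_brute_force_oracle():
    rng = np.random.default_rng(12)
    for _ in range(5):
        m = rng.normal(size=(6, 4))
        _, link, _ = hierarchical_order(m)
        assert link[:, 2] == pytest.approx(complete_linkage_heights(m))
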