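"""Moderated t/F statistics against classical oracles and the hierarchical
variance model's own generator."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ubichain.io import IntensityMatrix, SampleDesign
from ubichain.modstats import (
    VariancePrior,
    bh_adjust,
    estimate_variance_prior,
    fit_groups,
    moderated_F,
    moderated_t,
)

try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    HAVE_HYPOTHESIS = True
except ImportError:  # pragma: no cover
    HAVE_HYPOTHESIS = False


def _matrix_from_rows(rows, baits):
    rows = np.asarray(rows, dtype=float)
    m = IntensityMatrix(
        [f"P{i}" for i in range(rows.shape[0])],
        [f"S{j + 1}" for j in range(rows.shape[1])],
        rows,
        np.zeros_like(rows, dtype=bool),
        "log2",
    )
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": m.sample_ids,
                "bait": baits,
                "replicate": list(range(1, len(baits) + 1)),
                "dataset": "CAA",
            }
        )
    )
    return m, design


def test_fit_groups_hand_arithmetic():
    m, design = _matrix_from_rows(
        [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
        ["bead_control"] * 3 + ["K48_Ub3"] * 3,
    )
    fit = fit_groups(m, design)
    np.testing.assert_allclose(fit.means[0], [2.0, 5.0])
    assert fit.s2[0] == pytest.approx(1.0)  # pooled ((1+1)+(1+1))/4
    assert fit.df == 4


def test_fit_groups_constant_rows_have_zero_variance():
    m, design = _matrix_from_rows(
        [[7.0] * 6], ["bead_control"] * 3 + ["K63_Ub2"] * 3
    )
    fit = fit_groups(m, design)
    assert fit.s2[0] == 0.0


def test_fit_groups_single_group():
    m, design = _matrix_from_rows([[1.0, 2.0, 3.0]], ["bead_control"] * 3)
    fit = fit_groups(m, design, groups=["bead_control"])
    assert fit.means[0, 0] == pytest.approx(2.0)
    assert fit.df == 2


def test_fit_groups_rejects_incomplete_matrix(small_matrix, two_group_design):
    logm = small_matrix.to_log2()
    with pytest.raises(ValueError, match="complete"):
        fit_groups(logm, two_group_design)


def test_moderated_t_classical_limit():
    """At d0 = 0 the moderated t must equal the classical pooled two-sample t;
    oracle: scipy.stats.ttest_ind on {1,2,3} vs {4,5,6}."""
    m, design = _matrix_from_rows(
        [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
        ["bead_control"] * 3 + ["K48_Ub3"] * 3,
    )
    fit = fit_groups(m, design)
    res = moderated_t(fit, VariancePrior(d0=0.0, s0_sq=1.0), "bead_control", "K48_Ub3")
    oracle = stats.ttest_ind([1, 2, 3], [4, 5, 6])
    assert res.table["stat"].iloc[0] == pytest.approx(oracle.statistic)
    assert res.table["stat"].iloc[0] == pytest.approx(-3.674, abs=5e-4)
    assert res.table["p"].iloc[0] == pytest.approx(oracle.pvalue)
    assert res.table["p"].iloc[0] == pytest.approx(0.0214, abs=5e-4)


def test_moderated_t_infinite_prior_limit():
    m, design = _matrix_from_rows(
        [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
        ["bead_control"] * 3 + ["K48_Ub3"] * 3,
    )
    fit = fit_groups(m, design)
    prior = VariancePrior(d0=math.inf, s0_sq=4.0)
    res = moderated_t(fit, prior, "K48_Ub3", "bead_control")
    expected = 3.0 / (2.0 * np.sqrt(2.0 / 3.0))
    assert res.table["stat"].iloc[0] == pytest.approx(expected)
    assert res.table["df"].iloc[0] == 1e6


def test_moderated_t_zero_logfc_gives_p_one():
    m, design = _matrix_from_rows(
        [[1.0, 3.0, 1.0, 3.0]], ["bead_control"] * 2 + ["K48_Ub3"] * 2
    )
    fit = fit_groups(m, design)
    res = moderated_t(fit, VariancePrior(d0=4.0, s0_sq=1.0), "K48_Ub3", "bead_control")
    assert res.table["stat"].iloc[0] == 0.0
    assert res.table["p"].iloc[0] == 1.0


def test_moderated_t_identical_groups_rejected():
    m, design = _matrix_from_rows(
        [[1.0, 2.0, 3.0, 4.0]], ["bead_control"] * 2 + ["K48_Ub3"] * 2
    )
    fit = fit_groups(m, design)
    with pytest.raises(ValueError, match="differ"):
        moderated_t(fit, VariancePrior(d0=0, s0_sq=1), "K48_Ub3", "K48_Ub3")


def test_moderated_f_classical_anova_limit():
    """At d0 = 0 the moderated F equals classical one-way ANOVA; oracle:
    scipy.stats.f_oneway on random three-group fixtures."""
    rng = np.random.default_rng(12)
    rows = rng.normal(20, 1, size=(30, 12))
    baits = ["bead_control"] * 4 + ["K48_Ub3"] * 4 + ["K63_Ub3"] * 4
    m, design = _matrix_from_rows(rows, baits)
    fit = fit_groups(m, design)
    res = moderated_F(fit, VariancePrior(d0=0.0, s0_sq=1.0))
    oracle = stats.f_oneway(rows[:, :4], rows[:, 4:8], rows[:, 8:], axis=1)
    np.testing.assert_allclose(res.table["stat"], oracle.statistic, rtol=1e-10)
    np.testing.assert_allclose(res.table["p"], oracle.pvalue, rtol=1e-8)


def test_moderated_f_equals_t_squared_for_two_groups():
    rng = np.random.default_rng(3)
    rows = rng.normal(20, 1, size=(20, 8))
    baits = ["bead_control"] * 4 + ["Br_Ub3"] * 4
    m, design = _matrix_from_rows(rows, baits)
    fit = fit_groups(m, design)
    prior = VariancePrior(d0=3.0, s0_sq=0.5)
    f = moderated_F(fit, prior)
    t = moderated_t(fit, prior, "bead_control", "Br_Ub3")
    np.testing.assert_allclose(f.table["stat"], t.table["stat"] ** 2, rtol=1e-10)


def test_moderated_f_flat_means_give_p_one():
    m, design = _matrix_from_rows(
        [[5.0, 5.0, 5.0, 5.0]], ["bead_control"] * 2 + ["K48_Ub3"] * 2
    )
    fit = fit_groups(m, design)
    res = moderated_F(fit, VariancePrior(d0=2.0, s0_sq=1.0))
    assert res.table["stat"].iloc[0] == 0.0
    assert res.table["p"].iloc[0] == 1.0


# ---------------------------------------------------------------------------
# prior estimation


def test_prior_all_equal_variances_degenerates_to_infinite_d0():
    prior = estimate_variance_prior(np.full(100, 2.0), 4)
    assert math.isinf(prior.d0)


def test_prior_recovery_from_known_generator():
    """Variances drawn from the scaled inverse-chi-square hierarchy with
    d0 = 4, s0^2 = 1, d = 21 are recovered within 20% / 10% at n = 1e4."""
    rng = np.random.default_rng(7)
    d0, s0_sq, d, n = 4.0, 1.0, 21, 10_000
    sigma2 = s0_sq * d0 / rng.chisquare(d0, size=n)
    s2 = sigma2 * rng.chisquare(d, size=n) / d
    prior = estimate_variance_prior(s2, d)
    assert prior.d0 == pytest.approx(d0, rel=0.2)
    assert prior.s0_sq == pytest.approx(s0_sq, rel=0.1)


def test_prior_fallback_with_few_variances():
    with pytest.warns(UserWarning, match="usable"):
        prior = estimate_variance_prior(np.array([1.0, 2.0, 3.0]), 4)
    assert math.isinf(prior.d0)


def test_zero_variances_still_get_positive_moderated_variance():
    rng = np.random.default_rng(5)
    s2 = np.concatenate([rng.chisquare(4, 200) / 4, [0.0, 0.0]])
    prior = estimate_variance_prior(s2, 4)
    s2_mod, _ = prior.moderate(s2, 4)
    assert (s2_mod > 0).all()


def test_shrinkage_pulls_toward_prior():
    """|s~^2 - s0^2| <= |s^2 - s0^2| elementwise, and s~^2 lies between."""
    rng = np.random.default_rng(8)
    s2 = rng.chisquare(4, 500) / 4
    prior = VariancePrior(d0=3.0, s0_sq=1.0)
    s2_mod, _ = prior.moderate(s2, 6)
    assert (np.abs(s2_mod - prior.s0_sq) <= np.abs(s2 - prior.s0_sq) + 1e-12).all()
    lo = np.minimum(s2, prior.s0_sq)
    hi = np.maximum(s2, prior.s0_sq)
    assert ((s2_mod >= lo - 1e-12) & (s2_mod <= hi + 1e-12)).all()


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_hand_step_up():
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_single_p_is_itself():
    assert bh_adjust([0.3])[0] == pytest.approx(0.3)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(10)
    p = rng.random(200)
    _, expected, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)


if HAVE_HYPOTHESIS:

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_bh_properties(p):
        adj = bh_adjust(p)
        p = np.asarray(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()  # preserves p-rank order
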