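"""Prefilter, cross-bait selection, clustering, correlation and the
classification rules, checked against planted truth and brute-force rule
evaluation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ubichain.io import IntensityMatrix, SampleDesign
from ubichain.modstats import ContrastResult
from ubichain.preprocess import run_preprocess
from ubichain.simulate import SimConfig, simulate_interactome
from ubichain.specificity import (
    bait_profiles,
    classify_branch,
    classify_length,
    classify_linkage,
    cluster_profiles,
    interactome_correlation,
    prefilter_ub_enriched,
    significant_across_baits,
    zscore_rows,
)

try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    HAVE_HYPOTHESIS = True
except ImportError:  # pragma: no cover
    HAVE_HYPOTHESIS = False


def _prefilter_run(seed=7, **kwargs):
    cfg = SimConfig(seed=seed, **kwargs)
    matrix, design, records, truth = simulate_interactome(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, raw_filtered, _, _ = run_preprocess(matrix, records, design, seed=seed)
        pf = prefilter_ub_enriched(raw_filtered, design, seed=seed)
    return pf, design, truth


def test_prefilter_retains_planted_k48_specific():
    """Planted 8-fold K48 binders pass the bead-control prefilter: all of the
    fully observed ones, and >= 90% overall (low-baseline proteins can lose
    their contrast to imputation-inflated pooled variance)."""
    cfg = SimConfig(seed=7)
    matrix, design, records, truth = simulate_interactome(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, raw, _, _ = run_preprocess(matrix, records, design, seed=7)
        pf = prefilter_ub_enriched(raw, design, seed=7)
    planted = set(truth.members("K48_specific"))
    retained = set(pf.retained)
    idx = {p: i for i, p in enumerate(raw.protein_ids)}
    complete = {p for p in planted if p in idx and not raw.missing[idx[p]].any()}
    assert complete and complete <= retained
    assert len(planted & retained) / len(planted) >= 0.9


def test_prefilter_background_retention_is_low():
    pf, _, truth = _prefilter_run(seed=7)
    background = set(truth.members("background")) | set(truth.members("bead_binder"))
    retained = set(pf.retained)
    rate = len(background & retained) / len(background)
    assert rate <= 0.05  # any-of-6 BH-corrected contrasts stay near nominal


def test_prefilter_all_equal_to_control_returns_empty():
    rng = np.random.default_rng(0)
    values = np.exp2(rng.normal(25, 0.1, size=(60, 8)))
    m = IntensityMatrix(
        [f"P{i}" for i in range(60)],
        [f"S{j}" for j in range(8)],
        values,
        np.zeros_like(values, dtype=bool),
    )
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": m.sample_ids,
                "bait": ["bead_control"] * 4 + ["K48_Ub3"] * 4,
                "replicate": [1, 2, 3, 4] * 2,
                "dataset": "CAA",
            }
        )
    )
    with pytest.warns(UserWarning, match="no proteins"):
        pf = prefilter_ub_enriched(m, design, seed=1)
    assert pf.retained == []
    assert pf.matrix.n_proteins == 0


def test_prefilter_deterministic_given_seed():
    pf1, _, _ = _prefilter_run(seed=3, n_proteins=500)
    pf2, _, _ = _prefilter_run(seed=3, n_proteins=500)
    assert pf1.retained == pf2.retained
    np.testing.assert_array_equal(pf1.matrix.values, pf2.matrix.values)


def test_f_test_recovers_planted_classes():
    pf, design, truth = _prefilter_run(seed=7)
    sig, _ = significant_across_baits(pf.matrix, design, fit=pf.fit, prior=pf.prior)
    differential = set()
    for cls in (
        "K48_specific", "K63_specific", "length_dependent_K48",
        "length_dependent_K63", "branch_specific", "branch_excluded",
    ):
        differential |= set(truth.members(cls))
    found = len(differential & set(sig)) / len(differential)
    assert found >= 0.9


def test_f_test_identical_rows_give_empty_set():
    values = np.full((30, 8), 23.0)
    m = IntensityMatrix(
        [f"P{i}" for i in range(30)], [f"S{j}" for j in range(8)],
        values, np.zeros_like(values, dtype=bool), "log2",
    )
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": m.sample_ids,
                "bait": ["bead_control"] * 2 + ["K48_Ub3"] * 3 + ["K63_Ub3"] * 3,
                "replicate": [1, 2, 1, 2, 3, 1, 2, 3],
                "dataset": "CAA",
            }
        )
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sig, res = significant_across_baits(m, design)
    assert sig == []


def test_f_test_needs_two_bait_groups(two_group_design, small_matrix):
    complete = IntensityMatrix(
        small_matrix.protein_ids, small_matrix.sample_ids,
        np.nan_to_num(small_matrix.to_log2().values, nan=10.0),
        np.zeros_like(small_matrix.missing), "log2",
    )
    with pytest.raises(ValueError, match="2 bait groups"):
        significant_across_baits(complete, two_group_design)


# ---------------------------------------------------------------------------
# clustering and correlation


def test_zscore_rows_definition():
    rng = np.random.default_rng(4)
    frame = pd.DataFrame(rng.normal(size=(40, 6)))
    z = zscore_rows(frame)
    np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
    np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-9)


def test_cluster_two_archetypes_perfectly():
    rng = np.random.default_rng(6)
    up = np.hstack([rng.normal(20, 0.2, (25, 4)), rng.normal(26, 0.2, (25, 4))])
    down = np.hstack([rng.normal(26, 0.2, (25, 4)), rng.normal(20, 0.2, (25, 4))])
    values = np.vstack([up, down])
    m = IntensityMatrix(
        [f"P{i}" for i in range(50)], [f"S{j}" for j in range(8)],
        values, np.zeros_like(values, dtype=bool), "log2",
    )
    labels = cluster_profiles(m, m.protein_ids, k=2)
    truth = [0] * 25 + [1] * 25
    assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0


def test_duplicate_rows_co_cluster():
    rng = np.random.default_rng(2)
    base = rng.normal(size=(10, 6)) + 20
    values = np.vstack([base, base[:1]])  # last row duplicates the first
    m = IntensityMatrix(
        [f"P{i}" for i in range(11)], [f"S{j}" for j in range(6)],
        values, np.zeros_like(values, dtype=bool), "log2",
    )
    labels = cluster_profiles(m, m.protein_ids, k=4)
    assert labels["P0"] == labels["P10"]


def test_cluster_k_exceeding_proteins_rejected():
    values = np.random.default_rng(0).normal(20, 1, size=(3, 4))
    m = IntensityMatrix(
        ["A", "B", "C"], [f"S{j}" for j in range(4)],
        values, np.zeros_like(values, dtype=bool), "log2",
    )
    with pytest.raises(ValueError, match="k="):
        cluster_profiles(m, m.protein_ids, k=5)


def test_spearman_correlation_identities():
    prof_a = pd.DataFrame(
        {"K48_Ub3": [1.0, 2.0, 3.0, 4.0, 5.0], "K63_Ub3": [5.0, 4.0, 3.0, 2.0, 1.0]},
        index=[f"P{i}" for i in range(5)],
    )
    rho = interactome_correlation(prof_a, prof_a)
    assert rho.loc["K48_Ub3", "K48_Ub3"] == pytest.approx(1.0)
    assert rho.loc["K48_Ub3", "K63_Ub3"] == pytest.approx(-1.0)
    prof_b = prof_a.copy()
    prof_b["K48_Ub3"] = [2.0, 1.0, 4.0, 3.0, 5.0]
    # hand rank computation: d^2 = (1,1,1,1,0) -> rho = 1 - 6*4/(5*24) = 0.8
    rho2 = interactome_correlation(prof_a, prof_b)
    assert rho2.loc["K48_Ub3", "K48_Ub3"] == pytest.approx(0.8)


def test_correlation_needs_three_common_proteins():
    a = pd.DataFrame({"K48_Ub3": [1.0, 2.0]}, index=["P0", "P1"])
    with pytest.raises(ValueError, match=">= 3"):
        interactome_correlation(a, a)


def test_bait_profiles_are_zscored_group_means(default_study):
    ds = default_study.per_dataset["CAA"]
    prof = bait_profiles(ds.prefilter.fit, ds.f_significant[:20])
    np.testing.assert_allclose(prof.mean(axis=1), 0.0, atol=1e-9)
    np.testing.assert_allclose(prof.std(axis=1, ddof=1), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# classification rules


def _contrast(label, rows):
    """rows: {protein: (logFC, adj_p)}"""
    table = pd.DataFrame(
        {
            "logFC": [v[0] for v in rows.values()],
            "stat": 0.0,
            "df": 10.0,
            "p": [v[1] for v in rows.values()],
            "adj_p": [v[1] for v in rows.values()],
        },
        index=pd.Index(list(rows), name="protein_id"),
    )
    return ContrastResult(label=label, table=table)


def test_classify_linkage_rules():
    res = _contrast(
        "K48_Ub3_vs_K63_Ub3",
        {"A": (2.0, 0.001), "B": (-1.0, 0.01), "C": (1.5, 0.2)},
    )
    calls = {c.protein_id: c.call for c in classify_linkage(res)}
    assert calls == {"A": "linkage_K48", "B": "linkage_K63", "C": "unclassified"}


def test_classify_length_k48_direction_consistency():
    results = {
        "CAA": {"K48": _contrast("K48_Ub3_vs_K48_Ub2", {"A": (1.2, 0.01), "B": (0.6, 0.01)})},
        "NEM": {"K48": _contrast("K48_Ub3_vs_K48_Ub2", {"A": (0.8, 0.3), "B": (-0.2, 0.3)})},
    }
    for ds in results.values():
        ds["K63"] = _contrast("K63_Ub3_vs_K63_Ub2", {"A": (0.0, 0.9), "B": (0.0, 0.9)})
    calls = {}
    for c in classify_length(results):
        calls.setdefault(c.protein_id, set()).add(c.call)
    assert "length_Ub3_K48" in calls["A"]  # significant + > 0.5 in both
    assert calls["B"] == {"unclassified"}  # inconsistent direction


def test_classify_length_k63_sign_only_threshold():
    results = {
        "CAA": {
            "K48": _contrast("K48_Ub3_vs_K48_Ub2", {"A": (0.0, 0.9)}),
            "K63": _contrast("K63_Ub3_vs_K63_Ub2", {"A": (0.3, 0.01)}),
        },
        "NEM": {
            "K48": _contrast("K48_Ub3_vs_K48_Ub2", {"A": (0.0, 0.9)}),
            "K63": _contrast("K63_Ub3_vs_K63_Ub2", {"A": (0.1, 0.4)}),
        },
    }
    calls = {c.call for c in classify_length(results)}
    assert "length_Ub3_K63" in calls  # 0.3 and 0.1 both exceed the 0 threshold


def test_classify_branch_tiers():
    def per_ds(fcs, ps):
        labels = (
            "Br_Ub3_vs_K48_Ub3", "Br_Ub3_vs_K63_Ub3",
            "Br_Ub3_vs_K48_Ub2", "Br_Ub3_vs_K63_Ub2",
        )
        return {
            lab: _contrast(lab, {"A": (fc, p)}) for lab, fc, p in zip(labels, fcs, ps)
        }

    # all four contrasts significant-positive in both datasets -> strict
    results = {
        "CAA": per_ds([2, 2, 3, 3], [0.01] * 4),
        "NEM": per_ds([1, 1, 2, 2], [0.01] * 4),
    }
    assert classify_branch(results)[0].call == "branch_specific_strict"

    # one Ub3 contrast not significant -> unclassified
    results_half = {"CAA": per_ds([2, 1], [0.01, 0.4])}
    results_half["CAA"] = {
        k: v for k, v in results_half["CAA"].items() if k.endswith("Ub3")
    }
    assert classify_branch(results_half)[0].call == "unclassified"

    # both Ub3 contrasts reversed -> homotypic preference
    results_rev = {
        "CAA": {
            "Br_Ub3_vs_K48_Ub3": _contrast("Br_Ub3_vs_K48_Ub3", {"A": (-2, 0.001)}),
            "Br_Ub3_vs_K63_Ub3": _contrast("Br_Ub3_vs_K63_Ub3", {"A": (-1, 0.02)}),
        }
    }
    assert classify_branch(results_rev)[0].call == "homotypic_preferring"


def test_classify_branch_missing_contrast_errors():
    results = {"CAA": {"Br_Ub3_vs_K48_Ub3": _contrast("Br_Ub3_vs_K48_Ub3", {"A": (1, 0.01)})}}
    with pytest.raises(KeyError, match="Br_Ub3_vs_K63_Ub3"):
        classify_branch(results)


if HAVE_HYPOTHESIS:

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=-3, max_value=3),
                st.floats(min_value=0, max_value=1),
                st.floats(min_value=-3, max_value=3),
                st.floats(min_value=0, max_value=1),
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_classify_linkage_matches_brute_force(rows):
        """Linkage calls equal a direct brute-force evaluation of the rule on
        randomly generated contrast tables (single dataset)."""
        table = {f"P{i}": (fc, q) for i, (fc, q, _, _) in enumerate(rows)}
        res = _contrast("K48_Ub3_vs_K63_Ub3", table)
        calls = {c.protein_id: c.call for c in classify_linkage(res)}
        for pid, (fc, q) in table.items():
            if q < 0.05 and fc > 0:
                assert calls[pid] == "linkage_K48"
            elif q < 0.05 and fc < 0:
                assert calls[pid] == "linkage_K63"
            else:
                assert calls[pid] == "unclassified"

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.tuples(
            st.floats(min_value=-2, max_value=2),
            st.floats(min_value=0, max_value=1),
            st.floats(min_value=-2, max_value=2),
            st.floats(min_value=0, max_value=1),
        )
    )
    def test_classify_branch_matches_brute_force(vals):
        fc1, q1, fc2, q2 = vals
        results = {
            "CAA": {
                "Br_Ub3_vs_K48_Ub3": _contrast("Br_Ub3_vs_K48_Ub3", {"A": (fc1, q1)}),
                "Br_Ub3_vs_K63_Ub3": _contrast("Br_Ub3_vs_K63_Ub3", {"A": (fc2, q2)}),
            }
        }
        call = classify_branch(results)[0].call
        both_pos = q1 < 0.05 and fc1 > 0 and q2 < 0.05 and fc2 > 0
        both_neg = q1 < 0.05 and fc1 < 0 and q2 < 0.05 and fc2 < 0
        if both_pos:
            assert call == "branch_specific"
        elif both_neg:
            assert call == "homotypic_preferring"
        else:
            assert call == "unclassified"
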