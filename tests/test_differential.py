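import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import lipidlink as ll
from lipidlink.differential import (
    Comparison,
    bh_adjust,
    cross_model_common,
    dal_analysis,
    enrichment,
    nb_wald_deg,
    overlap_analysis,
    size_factors,
    t_test_feature,
)

from conftest import toy_matrix


# ---------------------------------------------------------------------------
# t-test


def _two_group_matrix(a, b, feature="FFA(16:0)"):
    vals = np.array(list(a) + list(b), dtype=float)[:, None]
    groups = ["HFD"] * len(a) + ["SD"] * len(b)
    return toy_matrix(vals, [feature], groups=groups)


def test_t_identical_groups():
    m = _two_group_matrix([1, 2, 3], [1, 2, 3])
    t, p, lfc = t_test_feature(m, "FFA(16:0)", "HFD", "SD")
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    assert lfc == pytest.approx(0.0)


def test_t_matches_pooled_variance_closed_form():
    a, b = np.array([5.0, 6.0, 7.0]), np.array([1.0, 2.0, 3.0])
    m = _two_group_matrix(a, b)
    t, p, _ = t_test_feature(m, "FFA(16:0)", "HFD", "SD")
    sp = np.sqrt(((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4)
    t_hand = (a.mean() - b.mean()) / (sp * np.sqrt(2 / 3))
    assert t == pytest.approx(t_hand)
    assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), df=4))


def test_log2_fold_change_of_doubling():
    m = _two_group_matrix([4.0, 4.1, 3.9], [2.0, 2.1, 1.9])
    _, _, lfc = t_test_feature(m, "FFA(16:0)", "HFD", "SD")
    assert lfc == pytest.approx(1.0, abs=0.02)


def test_t_scale_invariance_and_lfc_shift():
    rng = np.random.default_rng(0)
    a, b = rng.uniform(5, 9, 6), rng.uniform(1, 5, 6)
    m1 = _two_group_matrix(a, b)
    m2 = _two_group_matrix(3.7 * a, 3.7 * b)   # common positive scaling
    m3 = _two_group_matrix(4 * a, b)           # scale A by 2^2
    t1, _, l1 = t_test_feature(m1, "FFA(16:0)", "HFD", "SD")
    t2, _, l2 = t_test_feature(m2, "FFA(16:0)", "HFD", "SD")
    _, _, l3 = t_test_feature(m3, "FFA(16:0)", "HFD", "SD")
    assert t2 == pytest.approx(t1)
    assert l2 == pytest.approx(l1)
    assert l3 == pytest.approx(l1 + 2.0)


def test_t_requires_two_samples_and_variance():
    m = _two_group_matrix([1.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="2 samples"):
        t_test_feature(m, "FFA(16:0)", "HFD", "SD")
    m2 = _two_group_matrix([2.0, 2.0], [2.0, 2.0])
    with pytest.raises(ValueError, match="no variance"):
        t_test_feature(m2, "FFA(16:0)", "HFD", "SD")


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def brute_force_bh(p):
    """Literal step-up definition: q_i = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            p[order[rank_j - 1]] * m / rank_j for rank_j in range(rank_i, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def test_bh_single_p():
    assert bh_adjust([0.03])[0] == pytest.approx(0.03)


def test_bh_hand_example():
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
             min_size=1, max_size=60)
)
def test_bh_properties(p):
    q = bh_adjust(p)
    assert np.all(q >= np.asarray(p) - 1e-12)
    assert np.all(q <= 1.0)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in sorted order
    np.testing.assert_allclose(q, brute_force_bh(p), rtol=1e-12)


# ---------------------------------------------------------------------------
# DAL analysis


def test_dal_alpha_zero_empty(small_study):
    from lipidlink.pipeline import RunConfig, preprocess_lipids

    merged, _ = preprocess_lipids(small_study.lipids, RunConfig(knn_k=5))
    res = dal_analysis(merged, Comparison("HFD", "SD", "24wk"), alpha=0.0)
    assert res["significant"].sum() == 0
    assert (res["adjusted_p"] >= res["raw_p"] - 1e-12).all()


def test_dal_recovers_planted_effects():
    from lipidlink.pipeline import RunConfig, preprocess_lipids

    recalls = []
    for seed in range(3):
        study = ll.simulate_study(
            ll.StudyDesign(),
            ll.SimulationConfig(seed=seed),
        )
        merged, _ = preprocess_lipids(study.lipids, RunConfig())
        res = dal_analysis(merged, Comparison("HFD", "SD", "24wk"))
        sig = set(res.loc[res["significant"], "feature"])
        planted = set(study.truth["lipidome"]["affected_lipids"])
        recalls.append(len(sig & planted) / len(planted))
    assert np.median(recalls) >= 0.8


def test_dal_unknown_group_errors(small_study):
    with pytest.raises(ValueError):
        dal_analysis(small_study.genes, Comparison("HFD", "NOPE", "24wk"))


# ---------------------------------------------------------------------------
# NB Wald DEG


def test_size_factors_recover_scalar_multiples():
    rng = np.random.default_rng(2)
    base = rng.uniform(10, 100, size=50)
    scalars = np.array([0.5, 1.0, 2.0, 4.0])
    counts = np.outer(scalars, base)
    sf = size_factors(counts)
    ratio = sf / scalars
    np.testing.assert_allclose(ratio, ratio[0])  # equal up to common constant


def test_nb_wald_null_p_uniform():
    rng = np.random.default_rng(5)
    n, g = 10, 2000
    mu = rng.uniform(20, 200, g)
    counts = rng.negative_binomial(20, 20 / (20 + mu), size=(2 * n, g))
    groups = ["HFD"] * n + ["SD"] * n
    ids = [f"G{i}" for i in range(g)]
    m = toy_matrix(counts, ids, groups=groups, lipid_meta=False, stage="raw")
    res = nb_wald_deg(m, Comparison("HFD", "SD"))
    ks = stats.kstest(res["raw_p"], "uniform").statistic
    assert ks < 0.1


def test_nb_wald_power_on_planted_fold_change():
    rng = np.random.default_rng(6)
    n, g = 10, 200
    mu = rng.uniform(30, 300, g)
    disp = 0.05
    nparam = 1 / disp
    mu_a = mu.copy()
    mu_a[:40] *= 2.0  # planted two-fold genes
    a = rng.negative_binomial(nparam, nparam / (nparam + mu_a), size=(n, g))
    b = rng.negative_binomial(nparam, nparam / (nparam + mu), size=(n, g))
    counts = np.vstack([a, b])
    m = toy_matrix(counts, [f"G{i}" for i in range(g)],
                   groups=["HFD"] * n + ["SD"] * n, lipid_meta=False, stage="raw")
    res = nb_wald_deg(m, Comparison("HFD", "SD"))
    power = res.iloc[:40]["significant"].mean()
    assert power >= 0.7


def test_nb_wald_drops_and_reports_zero_genes():
    counts = np.array([[0, 5, 8], [0, 6, 7], [0, 4, 9], [0, 5, 8]])
    m = toy_matrix(counts, ["Gz", "Ga", "Gb"],
                   groups=["HFD", "HFD", "SD", "SD"], lipid_meta=False, stage="raw")
    res = nb_wald_deg(m, Comparison("HFD", "SD"))
    assert res.attrs["dropped_genes"] == ["Gz"]
    assert set(res["feature"]) == {"Ga", "Gb"}


# ---------------------------------------------------------------------------
# overlaps


def _result_frame(features, sig, lfc, comparison="HFD vs SD @24wk"):
    return pd.DataFrame(
        {
            "feature": features,
            "comparison": comparison,
            "log2_fold_change": lfc,
            "raw_p": 0.01,
            "adjusted_p": [0.01 if s else 0.5 for s in sig],
            "significant": sig,
        }
    )


def test_overlap_toy_intersection():
    feats = list("abcd")
    d = _result_frame(feats, [True, True, True, False], [1.0, 2.0, -1.0, 0.5])
    r = _result_frame(feats, [False, True, True, True], [-0.5, -1.0, -2.0, 1.0],
                      "HFD-DR vs HFD @24wk")
    ov = overlap_analysis(d, r)
    assert ov.common == ["b", "c"]
    # b: disease |2.0| dominates, positive -> increased_with_disease
    # c: reversal |-2.0| dominates, negative -> decreased_with_reversal
    assert ov.n_increased_with_disease == 1
    assert ov.n_decreased_with_reversal == 1


def test_overlap_disjoint_sets_empty():
    d = _result_frame(["a", "b"], [True, False], [1.0, 1.0])
    r = _result_frame(["a", "b"], [False, True], [1.0, 1.0])
    assert overlap_analysis(d, r).common == []


def test_overlap_mismatched_universe_errors():
    d = _result_frame(["a"], [True], [1.0])
    r = _result_frame(["b"], [True], [1.0])
    with pytest.raises(ValueError, match="universe"):
        overlap_analysis(d, r)


def test_overlap_direction_labels_sum_to_common():
    rng = np.random.default_rng(4)
    feats = [f"f{i}" for i in range(30)]
    d = _result_frame(feats, rng.random(30) < 0.5, rng.normal(size=30))
    r = _result_frame(feats, rng.random(30) < 0.5, rng.normal(size=30), "rev")
    ov = overlap_analysis(d, r)
    counts = ov.table["direction"].value_counts()
    assert counts.sum() == len(ov.common)


def test_cross_model_common_identical_and_disjoint():
    feats = list("abc")
    d = _result_frame(feats, [True] * 3, [1.0] * 3)
    r = _result_frame(feats, [True] * 3, [-1.0] * 3, "rev")
    ov = overlap_analysis(d, r)
    shared, _ = cross_model_common(ov, ov)
    assert shared == ov.common
    empty = overlap_analysis(
        _result_frame(feats, [False] * 3, [1.0] * 3),
        _result_frame(feats, [False] * 3, [1.0] * 3, "rev"),
    )
    assert cross_model_common(ov, empty)[0] == []


def test_cross_model_class_tally(small_study):
    """On the simulated study the cross-model common DALs are TG/DG."""
    from lipidlink.pipeline import RunConfig, run_all

    cfg = ll.RunConfig(sim=small_study.config, n_per_group=5,
                       outdir="scratch/_tally", transcript_variance_floor=50)
    report = run_all(cfg, write_outputs=False)
    tally = report["cross_model_lipids"]["class_tally"]
    assert set(tally) <= {"TG", "DG"}


# ---------------------------------------------------------------------------
# enrichment


def test_enrichment_exact_tail():
    universe = [f"g{i}" for i in range(20)]
    sets = {"S": universe[:5]}
    res = enrichment(universe[:5], sets, universe)
    from math import comb

    assert res.loc[0, "raw_p"] == pytest.approx(1 / comb(20, 5))
    assert res.loc[0, "overlap_genes"] == ",".join(sorted(universe[:5]))


def test_enrichment_disjoint_set_p_one():
    universe = [f"g{i}" for i in range(20)]
    res = enrichment(universe[:5], {"S": universe[10:15]}, universe)
    assert res.loc[0, "raw_p"] == pytest.approx(1.0)
    assert res.loc[0, "overlap_size"] == 0


def test_enrichment_list_equals_universe_degenerate():
    universe = [f"g{i}" for i in range(10)]
    res = enrichment(universe, {"S": universe[:4], "T": universe[4:]}, universe)
    assert (res["raw_p"] == 1.0).all()


def test_enrichment_validates_inputs():
    with pytest.raises(ValueError, match="empty universe"):
        enrichment(["a"], {"S": ["a"]}, [])
    with pytest.raises(ValueError, match="subset"):
        enrichment(["zz"], {"S": ["a"]}, ["a"])


def test_enrichment_flags_planted_set(small_study):
    """The planted gene set is the most enriched among the GMT sets when fed
    the true affected genes."""
    affected = small_study.truth["transcriptome"]["affected_genes"]
    res = enrichment(
        affected, small_study.gene_sets, small_study.genes.feature_ids
    )
    assert res.iloc[0]["gene_set"] == "PLANTED_LIPID_METABOLISM"
    assert res.iloc[0]["adjusted_p"] < 0.05
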