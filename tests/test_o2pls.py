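import numpy as np
import pandas as pd
import pytest

import lipidlink as ll
from lipidlink.o2pls import (
    filter_transcripts,
    fit_o2pls,
    scale_transform,
    select_components,
    top_loadings,
    variance_decomposition,
)

from conftest import toy_matrix


def random_xy(seed=0, n=20, p=15, q=12):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    Y = rng.normal(size=(n, q))
    X -= X.mean(axis=0)
    Y -= Y.mean(axis=0)
    return X, Y


# ---------------------------------------------------------------------------
# scale_transform


def test_scale_transform_hand_example():
    df = pd.DataFrame({"f": [1.0, 3.0]})
    out = scale_transform(df, pseudocount=1.0)
    np.testing.assert_allclose(out["f"], [-np.sqrt(0.5), np.sqrt(0.5)])


def test_scale_transform_postconditions(small_study):
    out = scale_transform(small_study.genes)
    np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-10)
    np.testing.assert_allclose(out.std(axis=0, ddof=1), 1, atol=1e-10)


def test_scale_transform_center_scale_idempotent():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.uniform(1, 5, (6, 3)), columns=list("abc"))
    once = scale_transform(df, log=False)
    twice = scale_transform(once, log=False)
    np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)


def test_scale_transform_constant_feature_errors():
    df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 3.0]})
    with pytest.raises(ValueError, match="constant"):
        scale_transform(df)


# ---------------------------------------------------------------------------
# transcript filter


def _fake_de(features, raw_p):
    return pd.DataFrame({"feature": features, "raw_p": raw_p})


def test_filter_transcripts_keep_all_at_p_one(small_study):
    genes = small_study.genes
    de = _fake_de(genes.feature_ids, np.full(genes.n_features, 0.5))
    out = filter_transcripts(genes, [de], p_keep=1.0)
    assert out.n_features == genes.n_features


def test_filter_transcripts_variance_floor(small_study):
    genes = small_study.genes
    de = _fake_de(genes.feature_ids, np.ones(genes.n_features))
    out = filter_transcripts(genes, [de], p_keep=0.0, variance_floor=100)
    assert out.n_features == 100
    # the floor keeps exactly the top-variance genes
    var = genes.values.var(axis=0, ddof=1).sort_values(ascending=False)
    assert set(out.feature_ids) == set(var.index[:100])


def test_filter_transcripts_empty_errors(small_study):
    de = _fake_de(small_study.genes.feature_ids,
                  np.ones(small_study.genes.n_features))
    with pytest.raises(ValueError, match="no genes"):
        filter_transcripts(small_study.genes, [de], p_keep=0.0)


def test_filter_transcripts_recall_of_planted_genes(small_study):
    from lipidlink.differential import Comparison, nb_wald_deg

    de = [
        nb_wald_deg(small_study.genes, Comparison("HFD", "SD", tp))
        for tp in ("16wk", "24wk")
    ]
    out = filter_transcripts(small_study.genes, de)
    affected = set(small_study.truth["transcriptome"]["affected_genes"])
    recall = len(affected & set(out.feature_ids)) / len(affected)
    assert recall >= 0.9


# ---------------------------------------------------------------------------
# fit invariants


@pytest.mark.parametrize("K,nx,ny", [(2, 0, 0), (2, 1, 1), (3, 2, 2), (2, 2, 2)])
def test_fit_orthogonality_invariants(K, nx, ny):
    X, Y = random_xy(0)
    m = fit_o2pls(X, Y, K, nx, ny)
    np.testing.assert_allclose(m.W.T @ m.W, np.eye(K), atol=1e-10)
    np.testing.assert_allclose(m.C.T @ m.C, np.eye(K), atol=1e-10)
    if nx:
        np.testing.assert_allclose(m.W.T @ m.W_Yo, 0, atol=1e-10)
    if ny:
        np.testing.assert_allclose(m.C.T @ m.C_Xo, 0, atol=1e-10)
    for side in ("X", "Y"):
        parts = m.r2[side]
        assert sum(parts.values()) == pytest.approx(1.0, abs=1e-8)
        assert all(0 <= v <= 1 for v in parts.values())


def test_reduction_to_cross_covariance_svd():
    """With no orthogonal components the model is exactly the rank-K SVD of
    X'Y: scores equal X/Y projected on the leading singular vectors."""
    X, Y = random_xy(3)
    K = 3
    m = fit_o2pls(X, Y, K, 0, 0)
    u, s, vt = np.linalg.svd(X.T @ Y, full_matrices=False)
    W_ref, C_ref = u[:, :K], vt[:K].T
    # align signs per component before comparing
    for k in range(K):
        if np.sign(W_ref[np.argmax(np.abs(W_ref[:, k])), k]) < 0:
            W_ref[:, k] *= -1
            C_ref[:, k] *= -1
    np.testing.assert_allclose(m.W, W_ref, atol=1e-8)
    np.testing.assert_allclose(m.C, C_ref, atol=1e-8)
    np.testing.assert_allclose(m.T, X @ W_ref, atol=1e-8)
    np.testing.assert_allclose(m.U, Y @ C_ref, atol=1e-8)


def test_y_equals_x_perfect_correlation():
    X, _ = random_xy(5)
    m = fit_o2pls(X, X.copy(), 1, 0, 0)
    r = np.corrcoef(m.T[:, 0], m.U[:, 0])[0, 1]
    assert r == pytest.approx(1.0, abs=1e-10)


def test_noiseless_joint_data_has_joint_fraction_near_one():
    rng = np.random.default_rng(8)
    n, p, q, K = 30, 10, 8, 2
    T = rng.normal(size=(n, K))
    Wt = np.linalg.qr(rng.normal(size=(p, K)))[0]
    Ct = np.linalg.qr(rng.normal(size=(q, K)))[0]
    X = T @ Wt.T
    Y = T @ Ct.T
    m = fit_o2pls(X - X.mean(0), Y - Y.mean(0), K, 0, 0)
    assert m.r2["X"]["joint"] >= 0.99
    assert m.r2["Y"]["joint"] >= 0.99


def test_independent_noise_has_small_joint_fraction():
    X, Y = random_xy(11, n=200, p=15, q=12)
    m = fit_o2pls(X, Y, 2, 0, 0)
    assert m.r2["X"]["joint"] < m.r2["X"]["noise"]


def test_r2_scale_invariance():
    X, Y = random_xy(6)
    m1 = fit_o2pls(X, Y, 2, 1, 1)
    m2 = fit_o2pls(5.0 * X, Y, 2, 1, 1)
    for side in ("X", "Y"):
        for part in ("joint", "orthogonal", "noise"):
            assert m2.r2[side][part] == pytest.approx(m1.r2[side][part], abs=1e-10)


def test_deflation_never_increases_energy():
    X, Y = random_xy(7)
    m = fit_o2pls(X, Y, 2, 2, 2)
    # orthogonal + joint energy cannot exceed the original
    assert m.r2["X"]["joint"] + m.r2["X"]["orthogonal"] <= 1 + 1e-10


def test_fit_validates_dimensions():
    X, Y = random_xy(0)
    with pytest.raises(ValueError, match="share the sample axis"):
        fit_o2pls(X, Y[:-1], 1)
    with pytest.raises(ValueError, match="exceeds"):
        fit_o2pls(X, Y, 10, 5, 5)
    with pytest.raises(ValueError, match="nx and ny"):
        fit_o2pls(X, Y, 1, 2, 0)


def test_rank_deficiency_reported():
    # X with two identical columns of rank 1 -> joint score covariance singular
    n = 12
    rng = np.random.default_rng(9)
    t = rng.normal(size=n)
    X = np.column_stack([t, t, t])
    Y = np.column_stack([t, t])
    X -= X.mean(0)
    Y -= Y.mean(0)
    with pytest.raises(np.linalg.LinAlgError, match="fewer components"):
        fit_o2pls(X, Y, 2, 0, 0)


# ---------------------------------------------------------------------------
# variance decomposition / top loadings


def test_variance_decomposition_matches_model_r2():
    X, Y = random_xy(2)
    m = fit_o2pls(X, Y, 2, 1, 1)
    r2 = variance_decomposition(m, X, Y)
    assert r2 == m.r2


def test_top_loadings_k1_order_and_edge_cases():
    X, Y = random_xy(4)
    Xdf = pd.DataFrame(X, columns=[f"L{i}" for i in range(X.shape[1])])
    Ydf = pd.DataFrame(Y, columns=[f"G{i}" for i in range(Y.shape[1])])
    m = fit_o2pls(Xdf, Ydf, 1, 0, 0)
    top = top_loadings(m, "lipid", 5)
    expected = np.argsort(-np.abs(m.W[:, 0]), kind="stable")[:5]
    assert top["feature"].tolist() == [f"L{i}" for i in expected]
    assert (top["loading_norm"].diff().dropna() <= 1e-12).all()
    assert len(top_loadings(m, "gene", 0)) == 0
    with pytest.warns(UserWarning, match="truncating"):
        over = top_loadings(m, "gene", 500)
    assert len(over) == Y.shape[1]
    with pytest.raises(ValueError, match="unknown side"):
        top_loadings(m, "metabolite", 3)


def test_planted_factor_recovery_on_simulated_study(small_study):
    """The joint component tracks the planted latent score and its top
    loadings concentrate on the planted lipid support."""
    from lipidlink.pipeline import RunConfig, preprocess_lipids

    merged, _ = preprocess_lipids(small_study.lipids, RunConfig(knn_k=5))
    X = scale_transform(merged)
    Y = scale_transform(small_study.genes)
    m = fit_o2pls(X, Y, 2, 2, 2)
    s = np.array(
        [small_study.truth["joint"]["latent_score"][i] for i in merged.sample_ids]
    )
    assert abs(np.corrcoef(m.T[:, 0], s)[0, 1]) >= 0.9
    planted = set(small_study.truth["joint"]["joint_lipids"])
    top = set(top_loadings(m, "lipid", 15)["feature"])
    assert len(top & planted) / len(planted) >= 0.8


def test_support_disjoint_from_tg_excludes_tg_candidates(small_design):
    """If the planted support is phosphatidylcholines (and there is no TG
    disease effect), the top integration candidates are not TGs."""
    cfg = ll.SimulationConfig(
        n_lipids=100, n_genes=200, disease_effect_size=0.0,
        n_joint_genes=10, missing_rate=0.0, dual_mode_fraction=0.0, seed=13,
    )
    lip, _ = ll.generate_lipidome(small_design, cfg)
    gen, _ = ll.generate_transcriptome(small_design, cfg)
    pc_ids = tuple(
        f for f in lip.feature_ids
        if lip.feature_meta.loc[f, "lipid_class"] == "PC"
    )[:8]
    import dataclasses

    cfg2 = dataclasses.replace(cfg, joint_lipid_ids=pc_ids)
    lip2, gen2, truth = ll.plant_joint_factor(lip, gen, cfg2)
    keep = [f for f in lip2.feature_ids if not lip2.feature_meta.loc[f, "is_standard"]]
    X = scale_transform(lip2.subset_features(keep))
    Y = scale_transform(gen2)
    m = fit_o2pls(X, Y, 1, 0, 0)
    top = top_loadings(m, "lipid", 8)["feature"]
    classes = {ll.parse_lipid_id(f.removesuffix("[+]").removesuffix("[-]")).lipid_class
               for f in top}
    assert "TG" not in classes


# ---------------------------------------------------------------------------
# component selection


def test_select_components_single_candidate():
    X, Y = random_xy(0)
    assert select_components(X, Y, [(2, 1, 1)]) == (2, 1, 1)


def test_select_components_empty_grid():
    X, Y = random_xy(0)
    with pytest.raises(ValueError, match="empty"):
        select_components(X, Y, [])


def test_select_components_noiseless_one_factor():
    rng = np.random.default_rng(3)
    n = 30
    t = rng.normal(size=(n, 1))
    X = t @ rng.normal(size=(1, 10))
    Y = t @ rng.normal(size=(1, 8))
    X -= X.mean(0)
    Y -= Y.mean(0)
    K, nx, ny = select_components(X, Y, [(1, 0, 0), (2, 0, 0), (3, 0, 0)], seed=0)
    assert K == 1


def test_select_components_recovers_planted_structure():
    """Low-noise data generated with 2 joint + 1/1 orthogonal components is
    assigned K=2 in most seeds."""
    hits = 0
    n_seeds = 5
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        n, p, q = 40, 12, 10
        T = rng.normal(size=(n, 2))
        X = T @ rng.normal(size=(2, p))
        Y = T @ rng.normal(size=(2, q))
        X += np.outer(rng.normal(size=n), rng.normal(size=p))  # X-only factor
        Y += np.outer(rng.normal(size=n), rng.normal(size=q))  # Y-only factor
        X += 0.05 * rng.normal(size=(n, p))
        Y += 0.05 * rng.normal(size=(n, q))
        X -= X.mean(0)
        Y -= Y.mean(0)
        grid = [(1, 1, 1), (2, 1, 1), (3, 1, 1)]
        K, _, _ = select_components(X, Y, grid, seed=seed)
        hits += K == 2
    assert hits >= 4
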