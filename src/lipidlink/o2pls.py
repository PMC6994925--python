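"""Two-way orthogonal partial least squares (O2PLS).

O2PLS decomposes two column-centred matrices X (n x p, lipids) and Y (n x q,
genes) sharing a sample axis into three parts each:

    X = T W' + T_Yo P_Yo' + E        Y = U C' + U_Xo P_Xo' + F

* a joint part (scores T, U; loadings W, C) capturing the covariation shared
  between the matrices — the K leading singular triplets of X'Y;
* an orthogonal part per matrix (nx / ny components) capturing systematic
  variation unique to that matrix, estimated from the residual covariance
  with the joint scores and removed by deflation;
* residual noise E, F.

The inner relations T ~ U B_U and U ~ T B_T link the two joint score sets,
and the squared-Frobenius-norm split of each matrix into joint / orthogonal /
noise gives the variance partition reported alongside the fit.  Features are
ranked for follow-up by the Euclidean norm of their joint-loading rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import OmicsMatrix


def scale_transform(
    matrix: OmicsMatrix | pd.DataFrame, pseudocount: float = 1.0, log: bool = True
) -> pd.DataFrame:
    """log2(x + pseudocount), then per-feature centring and unit-variance
    scaling (sample SD, ddof=1) — the standard preparation of both omics
    blocks before integration.  ``log=False`` re-centres/scales only.
    """
    vals = matrix.values if isinstance(matrix, OmicsMatrix) else matrix
    x = vals.to_numpy(dtype=float)
    if log:
        if (x < 0).any():
            raise ValueError("log transform requires non-negative input")
        x = np.log2(x + pseudocount)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    flat = sd <= 0
    if flat.any():
        bad = vals.columns[flat].tolist()
        raise ValueError(f"constant feature(s) after transform: {bad[:5]}")
    out = (x - mean) / sd
    return pd.DataFrame(out, index=vals.index, columns=vals.columns)


def filter_transcripts(
    counts: OmicsMatrix,
    de_results: list[pd.DataFrame],
    p_keep: float = 0.05,
    variance_floor: int = 0,
) -> OmicsMatrix:
    """Restrict the gene matrix to transcripts with potential differential
    signal: raw p < ``p_keep`` in any supplied contrast, union'd with the
    top-variance genes up to ``variance_floor``.  The retained count is
    recorded in ``result.values.attrs['n_retained']``.
    """
    keep: set[str] = set()
    for res in de_results:
        keep |= set(res.loc[res["raw_p"] < p_keep, "feature"])
    keep &= set(counts.feature_ids)
    if variance_floor > 0:
        var = counts.values.var(axis=0, ddof=1)
        top = var.sort_values(ascending=False, kind="stable").index[:variance_floor]
        keep |= set(top)
    if not keep:
        raise ValueError("transcript filter retained no genes")
    retained = [g for g in counts.feature_ids if g in keep]
    out = counts.subset_features(retained)
    out.values.attrs["n_retained"] = len(retained)
    return out


@dataclass
class O2PLSModel:
    """Fitted O2PLS decomposition (all arrays as described in the module doc)."""

    K: int
    nx: int
    ny: int
    W: np.ndarray            # p x K joint X loadings (orthonormal)
    C: np.ndarray            # q x K joint Y loadings (orthonormal)
    T: np.ndarray            # n x K joint X scores
    U: np.ndarray            # n x K joint Y scores
    W_Yo: np.ndarray         # p x nx orthogonal X weights
    P_Yo: np.ndarray         # p x nx orthogonal X loadings
    T_Yo: np.ndarray         # n x nx orthogonal X scores
    C_Xo: np.ndarray         # q x ny orthogonal Y weights
    P_Xo: np.ndarray         # q x ny orthogonal Y loadings
    U_Xo: np.ndarray         # n x ny orthogonal Y scores
    B_T: np.ndarray          # K x K regression of U on T
    B_U: np.ndarray          # K x K regression of T on U
    r2: dict = field(default_factory=dict)  # {"X": {...}, "Y": {...}}
    x_features: list[str] = field(default_factory=list)
    y_features: list[str] = field(default_factory=list)

    def predict_x_scores(self, X: np.ndarray) -> np.ndarray:
        """Joint X scores for new centred data, after removing the
        X-orthogonal part."""
        Xc = np.asarray(X, dtype=float)
        if self.nx:
            T_yo = Xc @ self.W_Yo
            Xc = Xc - T_yo @ self.P_Yo.T
        return Xc @ self.W

    def predict_y_scores(self, Y: np.ndarray) -> np.ndarray:
        Yc = np.asarray(Y, dtype=float)
        if self.ny:
            U_xo = Yc @ self.C_Xo
            Yc = Yc - U_xo @ self.P_Xo.T
        return Yc @ self.C

    def predict_x_from_y(self, Y: np.ndarray) -> np.ndarray:
        """X-hat = U(Y) B_U W' — the cross-block prediction used in CV."""
        return self.predict_y_scores(Y) @ self.B_U @ self.W.T

    def predict_y_from_x(self, X: np.ndarray) -> np.ndarray:
        return self.predict_x_scores(X) @ self.B_T @ self.C.T


def _fix_signs(W: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the per-component SVD sign ambiguity: the largest-magnitude
    entry of each W column is made positive; C flips with W to preserve the
    cross-covariance product."""
    signs = np.ones(W.shape[1])
    for k in range(W.shape[1]):
        j = int(np.argmax(np.abs(W[:, k])))
        if W[j, k] < 0:
            signs[k] = -1.0
    return W * signs, C * signs


def _svd_k(M: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Leading k left/right singular vectors of M."""
    left, _, right_t = np.linalg.svd(M, full_matrices=False)
    return left[:, :k], right_t[:k].T


def fit_o2pls(
    X: np.ndarray | pd.DataFrame,
    Y: np.ndarray | pd.DataFrame,
    K: int,
    nx: int = 0,
    ny: int = 0,
) -> O2PLSModel:
    """Fit an O2PLS model to centred/scaled matrices sharing a sample axis.

    Algorithm: (1) W, C from the K leading singular triplets of X'Y;
    (2) T = XW, U = YC; (3) X-side orthogonal block: nx leading left singular
    vectors of (X - TW')'T give W_Yo; T_Yo = X W_Yo; P_Yo by least squares;
    X is deflated and T recomputed; (4) the symmetric Y-side block;
    (5) inner regressions B_T, B_U; (6) variance partition of each original
    matrix into joint / orthogonal / noise fractions.

    Raises on rank deficiency that makes an inner inverse singular (use fewer
    components).
    """
    x_feat = list(X.columns) if isinstance(X, pd.DataFrame) else []
    y_feat = list(Y.columns) if isinstance(Y, pd.DataFrame) else []
    X0 = np.asarray(X, dtype=float)
    Y0 = np.asarray(Y, dtype=float)
    if X0.shape[0] != Y0.shape[0]:
        raise ValueError("X and Y must share the sample axis")
    n, p = X0.shape
    q = Y0.shape[1]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K + max(nx, ny) > min(n, p, q):
        raise ValueError(
            f"K + max(nx, ny) = {K + max(nx, ny)} exceeds min(n, p, q) = {min(n, p, q)}"
        )
    if nx > K or ny > K:
        # the orthogonal weights come from the p x K (q x K) residual
        # covariance with the joint scores, which has rank at most K
        raise ValueError("nx and ny cannot exceed K in this estimator")

    W, C = _svd_k(X0.T @ Y0, K)
    W, C = _fix_signs(W, C)
    Xd, Yd = X0.copy(), Y0.copy()
    T = Xd @ W
    U = Yd @ C

    def _solve_gram(S: np.ndarray, rhs: np.ndarray, what: str) -> np.ndarray:
        cond = np.linalg.cond(S)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"{what} score covariance is singular (cond={cond:.2e}); "
                "try fewer components"
            )
        return np.linalg.solve(S, rhs)

    if nx > 0:
        E = Xd - T @ W.T
        W_Yo, _ = _svd_k(E.T @ T, nx)
        T_Yo = Xd @ W_Yo
        P_Yo = Xd.T @ T_Yo @ _solve_gram(
            T_Yo.T @ T_Yo, np.eye(nx), "X-orthogonal"
        )
        Xd = Xd - T_Yo @ P_Yo.T
        T = Xd @ W
    else:
        W_Yo = np.zeros((p, 0))
        P_Yo = np.zeros((p, 0))
        T_Yo = np.zeros((n, 0))

    if ny > 0:
        F = Yd - U @ C.T
        C_Xo, _ = _svd_k(F.T @ U, ny)
        U_Xo = Yd @ C_Xo
        P_Xo = Yd.T @ U_Xo @ _solve_gram(
            U_Xo.T @ U_Xo, np.eye(ny), "Y-orthogonal"
        )
        Yd = Yd - U_Xo @ P_Xo.T
        U = Yd @ C
    else:
        C_Xo = np.zeros((q, 0))
        P_Xo = np.zeros((q, 0))
        U_Xo = np.zeros((n, 0))

    B_U = _solve_gram(U.T @ U, U.T @ T, "joint U")
    B_T = _solve_gram(T.T @ T, T.T @ U, "joint T")

    model = O2PLSModel(
        K=K, nx=nx, ny=ny, W=W, C=C, T=T, U=U,
        W_Yo=W_Yo, P_Yo=P_Yo, T_Yo=T_Yo,
        C_Xo=C_Xo, P_Xo=P_Xo, U_Xo=U_Xo,
        B_T=B_T, B_U=B_U,
        x_features=x_feat, y_features=y_feat,
    )
    model.r2 = variance_decomposition(model, X0, Y0)
    return model


def variance_decomposition(
    model: O2PLSModel, X_orig: np.ndarray, Y_orig: np.ndarray
) -> dict:
    """Joint / orthogonal / noise fractions of each matrix's total sum of
    squares; each triple sums to 1 (noise is the residual complement)."""
    X0 = np.asarray(X_orig, dtype=float)
    Y0 = np.asarray(Y_orig, dtype=float)

    def _split(total_mat, joint, ortho):
        total = float(np.sum(total_mat**2))
        j = float(np.sum(joint**2)) / total
        o = float(np.sum(ortho**2)) / total if ortho.size else 0.0
        resid = total_mat - joint - (ortho if ortho.size else 0.0)
        nz = float(np.sum(resid**2)) / total
        # renormalise tiny cross-term leakage so the triple sums to exactly 1
        s = j + o + nz
        return {"joint": j / s, "orthogonal": o / s, "noise": nz / s}

    x_joint = model.T @ model.W.T
    x_ortho = model.T_Yo @ model.P_Yo.T if model.nx else np.zeros(0)
    y_joint = model.U @ model.C.T
    y_ortho = model.U_Xo @ model.P_Xo.T if model.ny else np.zeros(0)
    return {"X": _split(X0, x_joint, x_ortho), "Y": _split(Y0, y_joint, y_ortho)}


def top_loadings(model: O2PLSModel, side: str, k: int) -> pd.DataFrame:
    """Rank features by the Euclidean norm of their joint-loading row.

    ``side`` is "lipid"/"x" or "gene"/"y"; returns the top ``k`` as a frame
    with columns (feature, loading_norm, rank), truncated with a warning if
    ``k`` exceeds the feature count.
    """
    side = side.lower()
    if side in ("lipid", "x"):
        L, names = model.W, model.x_features
    elif side in ("gene", "y"):
        L, names = model.C, model.y_features
    else:
        raise ValueError(f"unknown side {side!r}")
    if not names:
        names = [f"f{i}" for i in range(L.shape[0])]
    norms = np.linalg.norm(L, axis=1)
    if k > len(names):
        import warnings

        warnings.warn(
            f"requested top {k} but only {len(names)} features; truncating",
            stacklevel=2,
        )
        k = len(names)
    order = np.argsort(-norms, kind="stable")[:k]
    return pd.DataFrame(
        {
            "feature": [names[i] for i in order],
            "loading_norm": norms[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )


def select_components(
    X: np.ndarray | pd.DataFrame,
    Y: np.ndarray | pd.DataFrame,
    grid: list[tuple[int, int, int]],
    groups=None,
    n_folds: int = 5,
    seed: int = 0,
    parsimony_tol: float = 0.10,
) -> tuple[int, int, int]:
    """Pick (K, nx, ny) by cross-validated two-way prediction error.

    For each candidate triple the samples are split into ``n_folds`` folds
    (stratified by ``groups`` when given; fold assignment is a deterministic
    function of ``seed``) and the summed held-out error
    ``||X - X_hat(Y)||^2 + ||Y - Y_hat(X)||^2`` is computed.  Because the CV
    error of latent-variable models typically keeps creeping down slightly
    past the true dimensionality, the most parsimonious candidate (fewest
    total components, then smallest K) within ``parsimony_tol`` relative
    error of the minimum is returned — a one-standard-error-style rule.
    Candidates whose fit fails (rank deficiency) are skipped.
    """
    if not grid:
        raise ValueError("empty component grid")
    X0 = np.asarray(X, dtype=float)
    Y0 = np.asarray(Y, dtype=float)
    n = X0.shape[0]
    rng = np.random.default_rng(seed)

    # deterministic stratified fold assignment
    folds = np.zeros(n, dtype=int)
    if groups is not None:
        groups = np.asarray(groups)
        for g in np.unique(groups):
            idx = np.flatnonzero(groups == g)
            idx = rng.permutation(idx)
            folds[idx] = np.arange(len(idx)) % n_folds
    else:
        folds = rng.permutation(np.arange(n) % n_folds)

    scores: dict[tuple[int, int, int], float] = {}
    for cand in grid:
        K, nx, ny = cand
        err = 0.0
        ok = True
        for f in range(n_folds):
            test = folds == f
            if test.sum() == 0 or (~test).sum() <= K + max(nx, ny):
                continue
            try:
                m = fit_o2pls(X0[~test], Y0[~test], K, nx, ny)
            except (np.linalg.LinAlgError, ValueError):
                ok = False
                break
            err += float(np.sum((X0[test] - m.predict_x_from_y(Y0[test])) ** 2))
            err += float(np.sum((Y0[test] - m.predict_y_from_x(X0[test])) ** 2))
        if ok:
            scores[cand] = err
    if not scores:
        raise ValueError("no candidate in the grid could be fitted")
    min_err = min(scores.values())
    admissible = [c for c, e in scores.items() if e <= (1 + parsimony_tol) * min_err]
    admissible.sort(key=lambda c: (sum(c), c[0], c))
    return admissible[0]
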