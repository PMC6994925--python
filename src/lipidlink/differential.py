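"""Differential abundance / expression analysis and overlap bookkeeping.

Lipids: per-feature two-sample Student's t-test (pooled variance) with
Benjamini-Hochberg FDR control -> differentially altered lipids (DALs).
Genes: a simplified negative-binomial Wald test (median-of-ratios size
factors, method-of-moments dispersion, Wald statistic on the log2 group
ratio) -> differentially expressed genes (DEGs).  Disease vs reversal
overlaps and a hypergeometric gene-set enrichment complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OmicsMatrix


@dataclass
class Comparison:
    """A two-group contrast, optionally restricted to one timepoint."""

    group_a: str
    group_b: str
    timepoint: str | None = None

    @property
    def label(self) -> str:
        tp = f" @{self.timepoint}" if self.timepoint else ""
        return f"{self.group_a} vs {self.group_b}{tp}"


# -- primitives -------------------------------------------------------------


def t_test_feature(
    matrix: OmicsMatrix,
    feature: str,
    group_a: str,
    group_b: str,
    timepoint: str | None = None,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test on one feature; returns (t, p, log2FC).

    Pooled-variance (Student) by default; ``welch=True`` switches to the
    unequal-variance form.  log2FC is log2(mean_A / mean_B) and requires
    positive group means.
    """
    a = matrix.values.loc[matrix.samples_of(group_a, timepoint), feature].to_numpy()
    b = matrix.values.loc[matrix.samples_of(group_b, timepoint), feature].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    ma, mb = a.mean(), b.mean()
    if ma <= 0 or mb <= 0:
        raise ValueError("log2 fold change requires positive group means")
    if np.isnan(t):  # zero variance in both groups, equal means
        raise ValueError(f"feature {feature!r}: no variance in either group")
    return float(t), float(p), float(np.log2(ma / mb))


def bh_adjust(raw_p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_i = min over j >= i of (p_(j) * m / j) in ascending p order, clipped at
    1, returned in the original order; ties handled stably.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.ndim != 1:
        raise ValueError("raw_p must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# -- per-matrix analyses ----------------------------------------------------


def _group_blocks(matrix: OmicsMatrix, comparison: Comparison):
    ids_a = matrix.samples_of(comparison.group_a, comparison.timepoint)
    ids_b = matrix.samples_of(comparison.group_b, comparison.timepoint)
    for name, ids in (("A", ids_a), ("B", ids_b)):
        if len(ids) < 2:
            raise ValueError(
                f"comparison {comparison.label!r}: group {name} has {len(ids)} samples"
            )
    return matrix.values.loc[ids_a].to_numpy(), matrix.values.loc[ids_b].to_numpy()


def dal_analysis(
    matrix: OmicsMatrix,
    comparison: Comparison,
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Differentially altered lipids for one contrast.

    One row per lipid: t, log2FC, raw and BH-adjusted p, and a boolean
    ``significant`` flag at ``adjusted_p < alpha``.  Expects a merged,
    normalised matrix (positive abundances).
    """
    a, b = _group_blocks(matrix, comparison)
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(a.mean(axis=0) / b.mean(axis=0))
    # degenerate features (no variance anywhere): t is nan -> p = 1
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            "feature": matrix.feature_ids,
            "comparison": comparison.label,
            "log2_fold_change": lfc,
            "t": t,
            "raw_p": p,
            "adjusted_p": q,
            "significant": q < alpha,
        }
    )
    if "lipid_class" in matrix.feature_meta.columns:
        out["lipid_class"] = matrix.feature_meta["lipid_class"].to_numpy()
    return out


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors (samples x genes input).

    Ratios are taken to the per-gene geometric mean over genes expressed in
    every sample; the median ratio per sample is its size factor.
    """
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    usable = np.all(np.isfinite(log_counts), axis=0)
    if not usable.any():
        raise ValueError("no gene is expressed in every sample; cannot form ratios")
    log_geo = log_counts[:, usable].mean(axis=0)
    sf = np.exp(np.median(log_counts[:, usable] - log_geo, axis=1))
    return sf


def nb_wald_deg(
    matrix: OmicsMatrix,
    comparison: Comparison,
    alpha: float = 0.05,
    dispersion_floor: float = 1e-8,
) -> pd.DataFrame:
    """Simplified negative-binomial Wald differential expression.

    Counts are normalised by median-of-ratios size factors; per-gene
    dispersion is a pooled method-of-moments estimate
    ``alpha_g = (var - mu) / mu^2`` floored at ``dispersion_floor``; the Wald
    statistic tests the log2 ratio of group means with a delta-method
    standard error.  No shrinkage, no outlier filtering — a deliberate
    lightweight stand-in for a full DESeq2-style fit.  All-zero genes are
    dropped and flagged in ``result.attrs['dropped_genes']``.
    """
    ids_a = matrix.samples_of(comparison.group_a, comparison.timepoint)
    ids_b = matrix.samples_of(comparison.group_b, comparison.timepoint)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(f"comparison {comparison.label!r} needs >=2 samples per group")
    sub = matrix.values.loc[ids_a + ids_b]
    nonzero = sub.sum(axis=0) > 0
    dropped = sub.columns[~nonzero].tolist()
    sub = sub.loc[:, nonzero]

    counts = sub.to_numpy(dtype=float)
    sf = size_factors(counts)
    norm = counts / sf[:, None]
    na, nb = len(ids_a), len(ids_b)
    a, b = norm[:na], norm[na:]

    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    var_a, var_b = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    # pooled method-of-moments dispersion across the two groups
    mu_pool = (na * mu_a + nb * mu_b) / (na + nb)
    var_pool = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var_pool - mu_pool) / mu_pool**2
    disp = np.maximum(np.nan_to_num(disp, nan=dispersion_floor), dispersion_floor)

    eps = 0.5  # continuity floor against zero group means
    mu_a_s, mu_b_s = np.maximum(mu_a, eps), np.maximum(mu_b, eps)
    lfc = np.log2(mu_a_s / mu_b_s)
    # delta method: Var(log mu_hat) ~ (1/mu + disp) / n
    se = np.sqrt(
        (1.0 / mu_a_s + disp) / na + (1.0 / mu_b_s + disp) / nb
    ) / np.log(2)
    z = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            "feature": sub.columns,
            "comparison": comparison.label,
            "log2_fold_change": lfc,
            "wald_z": z,
            "raw_p": p,
            "adjusted_p": q,
            "significant": q < alpha,
        }
    ).reset_index(drop=True)
    out.attrs["dropped_genes"] = dropped
    out.attrs["size_factors"] = dict(zip(sub.index, sf.tolist()))
    return out


# -- overlap bookkeeping ----------------------------------------------------


@dataclass
class ComparisonOverlap:
    """Common significant features of a disease and a reversal contrast.

    ``direction`` labels each common feature by the contrast with the larger
    absolute log2FC: ``increased_with_disease`` when the disease contrast
    dominates with a positive fold change, ``decreased_with_reversal`` when
    the reversal contrast dominates with a negative fold change, otherwise
    ``discordant``.  Both raw fold changes are kept in ``table``.
    """

    disease_label: str
    reversal_label: str
    common: list[str]
    table: pd.DataFrame
    class_breakdown: dict[str, int] = field(default_factory=dict)

    @property
    def n_increased_with_disease(self) -> int:
        return int((self.table["direction"] == "increased_with_disease").sum())

    @property
    def n_decreased_with_reversal(self) -> int:
        return int((self.table["direction"] == "decreased_with_reversal").sum())


def overlap_analysis(
    disease: pd.DataFrame, reversal: pd.DataFrame
) -> ComparisonOverlap:
    """Intersect the significant sets of a disease and a reversal contrast."""
    if set(disease["feature"]) != set(reversal["feature"]):
        raise ValueError("disease and reversal results cover different feature universes")
    d = disease.set_index("feature")
    r = reversal.set_index("feature")
    common = sorted(
        set(d.index[d["significant"]]) & set(r.index[r["significant"]])
    )
    rows = []
    for f in common:
        lfc_d = float(d.loc[f, "log2_fold_change"])
        lfc_r = float(r.loc[f, "log2_fold_change"])
        if abs(lfc_d) >= abs(lfc_r):
            direction = (
                "increased_with_disease" if lfc_d > 0 else "discordant"
            )
        else:
            direction = (
                "decreased_with_reversal" if lfc_r < 0 else "discordant"
            )
        rows.append(
            {
                "feature": f,
                "disease_log2fc": lfc_d,
                "reversal_log2fc": lfc_r,
                "direction": direction,
            }
        )
    table = pd.DataFrame(
        rows, columns=["feature", "disease_log2fc", "reversal_log2fc", "direction"]
    )
    breakdown: dict[str, int] = {}
    if "lipid_class" in disease.columns and common:
        classes = d.loc[common, "lipid_class"]
        breakdown = classes.value_counts().to_dict()
        table["lipid_class"] = classes.to_numpy()
    return ComparisonOverlap(
        disease_label=str(disease["comparison"].iloc[0]) if len(disease) else "",
        reversal_label=str(reversal["comparison"].iloc[0]) if len(reversal) else "",
        common=common,
        table=table,
        class_breakdown=breakdown,
    )


def cross_model_common(
    overlap_a: ComparisonOverlap, overlap_b: ComparisonOverlap
) -> tuple[list[str], dict[str, int]]:
    """Features common to two model overlaps, with a lipid-class tally."""
    shared = sorted(set(overlap_a.common) & set(overlap_b.common))
    tally: dict[str, int] = {}
    if shared and "lipid_class" in overlap_a.table.columns:
        cls = overlap_a.table.set_index("feature").loc[shared, "lipid_class"]
        tally = cls.value_counts().to_dict()
    return shared, tally


def enrichment(
    gene_list, gene_sets: dict[str, list[str]], universe
) -> pd.DataFrame:
    """Hypergeometric (upper-tail) over-representation test per gene set.

    ``p = P(X >= k)`` for ``k`` overlap genes drawn ``len(gene_list)`` times
    without replacement from a universe containing ``len(set & universe)``
    set members; BH adjustment across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    genes = set(gene_list)
    if not genes <= universe:
        raise ValueError("gene_list must be a subset of the universe")
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe
        overlap = sorted(genes & in_universe)
        k, M, n, N = len(overlap), len(universe), len(in_universe), len(genes)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if k > 0 else 1.0
        rows.append(
            {
                "gene_set": name,
                "overlap_size": k,
                "set_size_in_universe": n,
                "list_size": N,
                "overlap_genes": ",".join(overlap),
                "raw_p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = bh_adjust(out["raw_p"].to_numpy())
    return out.sort_values("raw_p", kind="stable").reset_index(drop=True)
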