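"""Lipidomics preprocessing: imputation, normalisation, ion-mode merging,
z-scoring, and class / fatty-acyl summarisation.

The stage contract is raw -> imputed -> normalized -> merged -> zscored;
class and acyl summaries operate on merged matrices.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .containers import OmicsMatrix
from .lipids import format_chain, parse_lipid_id

logger = logging.getLogger(__name__)


def knn_impute(
    matrix: OmicsMatrix, k: int = 10, result_stage: str = "imputed"
) -> OmicsMatrix:
    """Fill missing lipid intensities by K-nearest-neighbour averaging.

    Neighbours are *features* (lipids): each missing entry is replaced by the
    mean value, in that sample, of the ``k`` lipids nearest in Euclidean
    distance computed over mutually observed samples and rescaled by
    sqrt(n_samples / n_observed) to stay comparable across missingness
    patterns.  Observed entries are never touched.  ``result_stage`` is
    "normalized" when imputation is deliberately run after internal-standard
    normalisation.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = matrix.values.to_numpy(dtype=float)
    all_missing = np.isnan(vals).all(axis=0)
    if all_missing.any():
        bad = matrix.values.columns[all_missing].tolist()
        raise ValueError(f"features missing in all samples: {bad[:5]}")
    if not np.isnan(vals).any():
        return matrix.copy().with_stage(result_stage)
    # features as rows so neighbours are lipids
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(vals.T).T
    out = matrix.copy()
    out.values = pd.DataFrame(
        filled, index=matrix.values.index, columns=matrix.values.columns
    )
    return out.with_stage(result_stage)


def normalize_internal_standard(
    matrix: OmicsMatrix,
    standards: dict[str, str],
    global_standard: str | None = None,
) -> OmicsMatrix:
    """Divide each lipid by its class's internal standard, per sample.

    ``standards`` maps lipid class -> standard feature id.  Classes without a
    mapped standard fall back to ``global_standard`` if given, otherwise an
    error is raised.  Standard features are removed from the output.
    """
    meta = matrix.feature_meta
    std_ids = set(standards.values()) | ({global_standard} if global_standard else set())
    std_ids &= set(matrix.feature_ids)
    out_vals = matrix.values.copy()

    for fid in matrix.feature_ids:
        if fid in std_ids:
            continue
        cls = meta.loc[fid, "lipid_class"]
        std = standards.get(cls, global_standard)
        if std is None:
            raise ValueError(f"no internal standard configured for class {cls!r}")
        if std not in matrix.values.columns:
            raise ValueError(f"standard feature {std!r} absent from matrix")
        denom = matrix.values[std]
        if (denom == 0).any() or denom.isna().any():
            raise ValueError(f"standard {std!r} has zero or missing intensity")
        out_vals[fid] = out_vals[fid] / denom

    keep = [f for f in matrix.feature_ids if f not in std_ids]
    out = matrix.copy()
    out.values = out_vals[keep]
    out.feature_meta = meta.loc[keep]
    # cannot advance past "raw" while missing values remain (impute-after order)
    stage = "raw" if out.values.isna().any().any() else "normalized"
    return out.with_stage(stage)


def merge_ion_modes(matrix: OmicsMatrix) -> OmicsMatrix:
    """Collapse species measured in both ion modes to their arithmetic mean.

    Features sharing the same species key (class + chains, ion-mode suffix
    stripped) are averaged; species seen in a single mode pass through
    unchanged.  More than two rows for one species is an error.  Output
    feature ids are the bare species keys.
    """
    if matrix.stage != "normalized":
        raise ValueError(f"merge_ion_modes expects stage 'normalized', got {matrix.stage!r}")
    groups: dict[str, list[str]] = {}
    for fid in matrix.feature_ids:
        groups.setdefault(parse_lipid_id(fid).species_key, []).append(fid)
    for key, members in groups.items():
        if len(members) > 2:
            raise ValueError(f"species {key!r} has {len(members)} ion-mode entries (max 2)")

    keys = list(groups)
    cols = {key: matrix.values[groups[key]].mean(axis=1) for key in keys}
    values = pd.DataFrame(cols, index=matrix.values.index)

    meta_rows = []
    for key in keys:
        first = matrix.feature_meta.loc[groups[key][0]].copy()
        first["ion_mode"] = "merged" if len(groups[key]) == 2 else parse_lipid_id(
            groups[key][0]
        ).ion_mode
        meta_rows.append(first)
    meta = pd.DataFrame(meta_rows, index=pd.Index(keys, name="feature"))

    out = matrix.copy()
    out.values = values
    out.feature_meta = meta
    return out.with_stage("merged")


def zscore_features(
    matrix: OmicsMatrix, within_timepoint: bool = True
) -> OmicsMatrix:
    """Centre and scale each lipid to mean 0, SD 1 (sample SD, ddof=1).

    With ``within_timepoint=True`` (the heat-map convention: one panel per
    timepoint) the transform is applied separately to each timepoint's
    samples; otherwise across all samples at once.
    """
    out = matrix.copy()
    vals = out.values

    def _z(block: pd.DataFrame) -> pd.DataFrame:
        sd = block.std(axis=0, ddof=1)
        flat = sd[(sd == 0) | sd.isna()]
        if len(flat):
            raise ValueError(
                f"constant feature(s) cannot be z-scored: {flat.index.tolist()[:5]}"
            )
        return (block - block.mean(axis=0)) / sd

    if within_timepoint:
        pieces = []
        for tp in out.sample_meta["timepoint"].unique():
            idx = out.sample_meta.index[out.sample_meta["timepoint"] == tp]
            pieces.append(_z(vals.loc[idx]))
        out.values = pd.concat(pieces).loc[vals.index]
    else:
        out.values = _z(vals)
    return out.with_stage("zscored")


def class_sum(
    matrix: OmicsMatrix, lipid_class: str
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample total abundance of one lipid class, with group summaries.

    Returns ``(per_sample_totals, summary)`` where the summary has one row
    per (group, timepoint) cell with the mean, SEM and n of the totals —
    the numbers behind a "sum of TG" bar chart.
    """
    members = matrix.feature_meta.index[
        matrix.feature_meta["lipid_class"] == lipid_class
    ].tolist()
    if not members:
        raise ValueError(f"no species of class {lipid_class!r} in matrix")
    totals = matrix.values[members].sum(axis=1)
    df = pd.DataFrame(
        {
            "total": totals,
            "group": matrix.sample_meta["group"],
            "timepoint": matrix.sample_meta["timepoint"],
        }
    )
    grouped = df.groupby(["group", "timepoint"], observed=True)["total"]
    summary = grouped.agg(
        mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="count"
    ).reset_index()
    return totals, summary


def fa_composition(matrix: OmicsMatrix, lipid_class: str) -> pd.DataFrame:
    """Per-sample fatty-acid totals for a class (samples x FA, e.g. C16:0).

    ``total(FA) = sum over species of abundance x multiplicity of that acyl
    chain in the species``; linear in abundance by construction.  Classes
    reported only as total compositions (unresolved chains) are an error —
    chain splits are never guessed.
    """
    meta = matrix.feature_meta
    members = meta.index[meta["lipid_class"] == lipid_class].tolist()
    if not members:
        raise ValueError(f"no species of class {lipid_class!r} in matrix")
    resolved = [m for m in members if len(meta.loc[m, "acyl_chains"]) > 0]
    if not resolved:
        raise ValueError(
            f"class {lipid_class!r} has only total-composition ids; "
            "fatty-acyl composition is undefined"
        )
    if len(resolved) < len(members):
        logger.warning(
            "%s: %d species without resolved chains excluded from FA composition",
            lipid_class, len(members) - len(resolved),
        )
    fa_totals: dict[str, pd.Series] = {}
    for m in resolved:
        for chain in meta.loc[m, "acyl_chains"]:
            name = format_chain(chain)
            contrib = matrix.values[m]
            fa_totals[name] = fa_totals.get(name, 0) + contrib
    out = pd.DataFrame(fa_totals, index=matrix.values.index)
    return out[sorted(out.columns, key=lambda c: (int(c[1:].split(":")[0]), int(c.split(":")[1])))]
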