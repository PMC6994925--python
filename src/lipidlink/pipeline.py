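"""End-to-end orchestration: preprocess -> differential -> O2PLS -> network.

A single :class:`RunConfig` drives the whole analysis; :func:`run_all`
executes the stages in order, persists intermediates under the output
directory and returns (and writes) a :class:`RunReport`-style dict whose
counts mirror the funnel a study of this design reports: lipids identified,
DAL/DEG grids per comparison, disease/reversal overlaps and their direction
splits, cross-model common features, the O2PLS variance partition and
candidate lists, and the network node/edge/subnetwork counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .containers import OmicsMatrix
from .differential import (
    Comparison,
    ComparisonOverlap,
    cross_model_common,
    dal_analysis,
    enrichment,
    nb_wald_deg,
    overlap_analysis,
)
from .io import (
    read_annotation,
    read_gmt,
    read_matrix,
    read_sample_sheet,
    write_annotation,
    write_gmt,
    write_json,
    write_matrix,
    write_sample_sheet,
)
from .lipids import parse_lipid_id
from .network import (
    annotate_reversal,
    build_network,
    detect_subnetworks,
    export_edge_list,
    export_graphml,
    filter_genes_by_annotation,
    pearson_edges,
)
from .o2pls import fit_o2pls, filter_transcripts, scale_transform, top_loadings
from .preprocess import knn_impute, merge_ion_modes, normalize_internal_standard
from .simulate import SimulationConfig, StudyDesign, simulate_study

logger = logging.getLogger(__name__)

#: Disease and reversal contrasts of the five-group design (24wk; reversal
#: groups do not exist at 16wk).
DISEASE_CONTRASTS_16 = [
    Comparison("HFD", "SD", "16wk"),
    Comparison("HFD-STZ", "SD", "16wk"),
]
DISEASE_CONTRASTS_24 = [
    Comparison("HFD", "SD", "24wk"),
    Comparison("HFD-STZ", "SD", "24wk"),
]
REVERSAL_CONTRASTS = [
    Comparison("HFD-DR", "HFD", "24wk"),
    Comparison("HFD-STZ-DR", "HFD-STZ", "24wk"),
]


@dataclass
class RunConfig:
    """Everything a full run needs; see the YAML schema in the README."""

    # inputs; leave None to simulate with `sim` below
    lipids_path: str | None = None
    genes_path: str | None = None
    samples_path: str | None = None
    annotation_path: str | None = None
    gmt_path: str | None = None
    sim: SimulationConfig | None = None
    n_per_group: int = 10

    # analysis parameters
    alpha: float = 0.05
    knn_k: int = 10
    impute_first: bool = True
    o2pls_K: int = 2
    o2pls_nx: int = 2
    o2pls_ny: int = 2
    transcript_p_keep: float = 0.05
    transcript_variance_floor: int = 0
    top_lipids: int = 50
    top_genes: int = 100
    corr_threshold: float = 0.6
    subnetwork_method: str = "modularity"
    large_subnetwork: int | None = None
    # which gene set intersects the annotation: retained transcripts (the
    # integration input) or only the top candidates
    annotation_filter_set: str = "retained"  # or "top"
    seed: int = 0
    outdir: str = "lipidlink_run"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.corr_threshold < 1:
            raise ValueError("corr_threshold must be in [0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.annotation_filter_set not in ("retained", "top"):
            raise ValueError("annotation_filter_set must be 'retained' or 'top'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimulationConfig(**sim)
        return cfg


def _load_inputs(config: RunConfig):
    """Read study inputs from disk, or simulate when no paths are given."""
    if config.lipids_path is None:
        sim = config.sim or SimulationConfig(seed=config.seed)
        design = StudyDesign(n_per_group=config.n_per_group)
        study = simulate_study(design, sim)
        return study.lipids, study.genes, study.annotation, study.gene_sets, study.truth
    sheet = read_sample_sheet(config.samples_path)
    lipids = read_matrix(config.lipids_path, sheet, lipid_meta=True)
    genes = read_matrix(config.genes_path, sheet)
    annotation = (
        read_annotation(config.annotation_path) if config.annotation_path else
        pd.DataFrame(columns=["gene", "lipid"])
    )
    gene_sets = read_gmt(config.gmt_path) if config.gmt_path else {}
    return lipids, genes, annotation, gene_sets, None


def _detect_standards(lipids: OmicsMatrix) -> dict[str, str]:
    """Class -> internal-standard id, from feature_meta['is_standard'] when
    present, else by recognising all-17:0 odd-chain identifiers."""
    meta = lipids.feature_meta
    from .simulate import internal_standard_id

    if "is_standard" in meta.columns:
        std = meta.index[meta["is_standard"].astype(bool)]
    else:
        std = [
            fid for fid in lipids.feature_ids
            if parse_lipid_id(fid).species_key
            == internal_standard_id(parse_lipid_id(fid).lipid_class)
        ]
    return {meta.loc[s, "lipid_class"]: s for s in std}


def preprocess_lipids(lipids: OmicsMatrix, config: RunConfig) -> tuple[OmicsMatrix, dict]:
    """Impute, normalise to internal standards, merge ion modes."""
    funnel = {"raw_features": lipids.n_features}
    standards = _detect_standards(lipids)
    if config.impute_first:
        m = knn_impute(lipids, k=config.knn_k)
        if standards:
            m = normalize_internal_standard(m, standards)
        else:
            logger.warning("no internal standards found; normalisation skipped")
            m = m.with_stage("normalized")
    else:
        m = lipids
        if standards:
            m = normalize_internal_standard(m, standards)
        m = knn_impute(m, k=config.knn_k, result_stage="normalized")
    merged = merge_ion_modes(m)
    funnel["merged_species"] = merged.n_features
    return merged, funnel


def run_all(config: RunConfig, write_outputs: bool = True) -> dict:
    """Execute the full pipeline and return the run report dict."""
    outdir = Path(config.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    lipids_raw, genes_raw, annotation, gene_sets, truth = _load_inputs(config)

    # ---- stage 1: lipid preprocessing
    lipids, funnel = preprocess_lipids(lipids_raw, config)
    logger.info("preprocess: %d raw features -> %d merged species",
                funnel["raw_features"], funnel["merged_species"])

    # ---- stage 2: differential analysis
    dal: dict[str, pd.DataFrame] = {}
    for comp in DISEASE_CONTRASTS_16 + DISEASE_CONTRASTS_24 + REVERSAL_CONTRASTS:
        dal[comp.label] = dal_analysis(lipids, comp, alpha=config.alpha)
    deg: dict[str, pd.DataFrame] = {}
    for comp in DISEASE_CONTRASTS_16 + DISEASE_CONTRASTS_24 + REVERSAL_CONTRASTS:
        deg[comp.label] = nb_wald_deg(genes_raw, comp, alpha=config.alpha)

    lipid_overlaps: list[ComparisonOverlap] = []
    gene_overlaps: list[ComparisonOverlap] = []
    for disease, reversal in zip(DISEASE_CONTRASTS_24, REVERSAL_CONTRASTS):
        lipid_overlaps.append(
            overlap_analysis(dal[disease.label], dal[reversal.label])
        )
        d, r = deg[disease.label], deg[reversal.label]
        shared = sorted(set(d["feature"]) & set(r["feature"]))
        gene_overlaps.append(
            overlap_analysis(
                d[d["feature"].isin(shared)], r[r["feature"].isin(shared)]
            )
        )
    cross_lipids, cross_classes = cross_model_common(*lipid_overlaps)
    cross_genes, _ = cross_model_common(*gene_overlaps)

    enrich = None
    if gene_sets:
        universe = deg[DISEASE_CONTRASTS_24[0].label]["feature"].tolist()
        common_genes = [g for g in gene_overlaps[0].common if g in set(universe)]
        enrich = enrichment(common_genes, gene_sets, universe)

    # ---- stage 3: O2PLS integration
    genes_kept = filter_transcripts(
        genes_raw, list(deg.values()),
        p_keep=config.transcript_p_keep,
        variance_floor=config.transcript_variance_floor,
    )
    funnel["retained_transcripts"] = genes_kept.n_features
    X = scale_transform(lipids)
    Y = scale_transform(genes_kept)
    model = fit_o2pls(X, Y, config.o2pls_K, config.o2pls_nx, config.o2pls_ny)
    top_lip = top_loadings(model, "lipid", config.top_lipids)
    top_gen = top_loadings(model, "gene", config.top_genes)

    # ---- stage 4: correlation network
    candidate_genes = (
        genes_kept.feature_ids
        if config.annotation_filter_set == "retained"
        else top_gen["feature"].tolist()
    )
    gene_set, filter_counts = filter_genes_by_annotation(
        annotation, candidate_genes, lipids.feature_ids
    )
    funnel.update(filter_counts)
    edges = pearson_edges(
        X, Y[[g for g in gene_set if g in Y.columns]] if gene_set else None,
        threshold=config.corr_threshold,
    )
    net = build_network(
        edges,
        top_o2pls=set(top_lip["feature"]) | set(top_gen["feature"]),
    )
    if net.graph.number_of_nodes():
        sub = detect_subnetworks(
            net, method=config.subnetwork_method,
            large_threshold=config.large_subnetwork,
        )
        annotate_reversal(net, lipid_overlaps + gene_overlaps)
    else:
        sub = pd.DataFrame(columns=["subnetwork", "size", "large"])

    # ---- report
    report = {
        "version": __version__,
        "config": _config_echo(config),
        "funnel": funnel,
        "dal_counts": {lbl: int(df["significant"].sum()) for lbl, df in dal.items()},
        "deg_counts": {lbl: int(df["significant"].sum()) for lbl, df in deg.items()},
        "lipid_overlaps": [_overlap_summary(o) for o in lipid_overlaps],
        "gene_overlaps": [_overlap_summary(o) for o in gene_overlaps],
        "cross_model_lipids": {
            "n_common": len(cross_lipids),
            "features": cross_lipids,
            "class_tally": {k: int(v) for k, v in cross_classes.items()},
        },
        "cross_model_genes": {"n_common": len(cross_genes), "features": cross_genes},
        "enrichment": enrich.to_dict(orient="records") if enrich is not None else [],
        "o2pls": {
            "K": model.K, "nx": model.nx, "ny": model.ny,
            "r2": model.r2,
            "top_lipids": top_lip["feature"].tolist(),
            "top_genes": top_gen["feature"].tolist(),
        },
        "network": {
            **net.summary(),
            "large_subnetworks": int(sub["large"].sum()) if len(sub) else 0,
        },
    }
    if truth is not None:
        report["ground_truth_available"] = True

    if write_outputs:
        write_matrix(lipids, outdir / "lipids_merged.tsv")
        write_matrix(genes_raw, outdir / "gene_counts.tsv")
        write_sample_sheet(lipids.sample_meta, outdir / "samples.tsv")
        if len(annotation):
            write_annotation(annotation, outdir / "annotation.tsv")
        if gene_sets:
            write_gmt(gene_sets, outdir / "gene_sets.gmt")
        pd.concat(dal.values()).to_csv(outdir / "dal_results.tsv", sep="\t", index=False)
        pd.concat(deg.values()).to_csv(outdir / "deg_results.tsv", sep="\t", index=False)
        top_lip.to_csv(outdir / "o2pls_top_lipids.tsv", sep="\t", index=False)
        top_gen.to_csv(outdir / "o2pls_top_genes.tsv", sep="\t", index=False)
        if net.graph.number_of_nodes():
            export_graphml(net, outdir / "network.graphml")
            export_edge_list(net, outdir / "network_edges.tsv")
        if truth is not None:
            write_json(truth, outdir / "ground_truth.json")
        write_json(report, outdir / "report.json")
        (outdir / "report.txt").write_text(format_report(report))
    return report


def _overlap_summary(ov: ComparisonOverlap) -> dict:
    return {
        "disease": ov.disease_label,
        "reversal": ov.reversal_label,
        "n_common": len(ov.common),
        "n_increased_with_disease": ov.n_increased_with_disease,
        "n_decreased_with_reversal": ov.n_decreased_with_reversal,
        "class_breakdown": {k: int(v) for k, v in ov.class_breakdown.items()},
        "features": ov.common,
    }


def _config_echo(config: RunConfig) -> dict:
    from dataclasses import asdict

    echo = asdict(config)
    return echo


def format_report(report: dict) -> str:
    """Human-readable run summary."""
    lines = [f"lipidlink v{report['version']} run report", ""]
    f = report["funnel"]
    lines.append(f"lipids: {f.get('raw_features', '?')} raw features -> "
                 f"{f.get('merged_species', '?')} merged species")
    if "retained_transcripts" in f:
        lines.append(f"transcripts retained for integration: {f['retained_transcripts']}")
    if "annotated_to_network_lipids" in f:
        lines.append(
            f"annotation filter: {f['annotated_to_network_lipids']} genes annotated "
            f"-> {f['after_o2pls_filter']} after integration filter"
        )
    lines.append("")
    lines.append("differentially altered lipids (BH < alpha):")
    for lbl, n in report["dal_counts"].items():
        lines.append(f"  {lbl}: {n}")
    lines.append("differentially expressed genes (BH < alpha):")
    for lbl, n in report["deg_counts"].items():
        lines.append(f"  {lbl}: {n}")
    lines.append("")
    for ov in report["lipid_overlaps"]:
        lines.append(
            f"common DALs {ov['disease']} / {ov['reversal']}: {ov['n_common']} "
            f"({ov['n_increased_with_disease']} up with disease, "
            f"{ov['n_decreased_with_reversal']} down with reversal)"
        )
    cm = report["cross_model_lipids"]
    lines.append(
        f"cross-model common DALs: {cm['n_common']} "
        f"(classes: {cm['class_tally']})"
    )
    o2 = report["o2pls"]
    lines.append("")
    lines.append(f"O2PLS (K={o2['K']}, nx={o2['nx']}, ny={o2['ny']}) variance partition:")
    for side in ("X", "Y"):
        r2 = o2["r2"][side]
        lines.append(
            f"  {side}: joint {r2['joint']:.3f}, orthogonal {r2['orthogonal']:.3f}, "
            f"noise {r2['noise']:.3f}"
        )
    netr = report["network"]
    lines.append("")
    lines.append(
        f"network: {netr['n_lipids']} lipids + {netr['n_genes']} genes, "
        f"{netr['n_edges']} edges, {netr['n_subnetworks']} subnetworks "
        f"({netr['large_subnetworks']} large)"
    )
    return "\n".join(lines) + "\n"
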