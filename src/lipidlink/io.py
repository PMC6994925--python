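"""Plain-text I/O: feature x sample TSVs with a sidecar stage tag, sample
sheets, GMT gene sets, annotation pair tables, and JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import OmicsMatrix
from .lipids import LipidParseError, parse_lipid_id


def write_matrix(matrix: OmicsMatrix, path) -> None:
    """Write features x samples TSV (first column = feature id) plus a
    ``<path>.meta.json`` sidecar recording the stage."""
    path = Path(path)
    df = matrix.values.T
    df.index.name = "feature"
    df.to_csv(path, sep="\t")
    sidecar = {"stage": matrix.stage, "n_samples": matrix.n_samples,
               "n_features": matrix.n_features}
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=1))


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample", "group", "timepoint"}
    if not required <= set(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    return sheet.set_index("sample")


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.reset_index().rename(columns={"index": "sample"}).to_csv(
        path, sep="\t", index=False
    )


def read_matrix(
    path,
    sample_sheet: pd.DataFrame,
    orientation: str = "auto",
    lipid_meta: bool = False,
) -> OmicsMatrix:
    """Read a TSV matrix against a sample sheet.

    ``orientation`` is "features" (features in rows, the write_matrix
    layout), "samples", or "auto": detected by matching the header against
    the sample-sheet ids.  Duplicate feature ids are an error.  With
    ``lipid_meta=True`` feature ids are parsed as lipid identifiers and the
    class/chain metadata attached.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = set(sample_sheet.index)
    if orientation == "auto":
        in_cols = len(samples & set(df.columns))
        in_rows = len(samples & set(df.index))
        orientation = "features" if in_cols >= in_rows else "samples"
    if orientation == "features":
        df = df.T
    elif orientation != "samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature id(s): {dup[:5]}")
    missing = samples - set(df.index)
    if missing:
        raise ValueError(f"samples in sheet but not in matrix: {sorted(missing)[:5]}")
    df = df.loc[sample_sheet.index]

    stage = "raw"
    sidecar = Path(str(path) + ".meta.json")
    if sidecar.exists():
        stage = json.loads(sidecar.read_text()).get("stage", "raw")

    feature_meta = None
    if lipid_meta:
        rows = {}
        for fid in df.columns:
            try:
                sp = parse_lipid_id(fid)
            except LipidParseError as err:
                raise ValueError(f"feature id {fid!r} is not a lipid id") from err
            rows[fid] = {
                "lipid_class": sp.lipid_class,
                "acyl_chains": sp.acyl_chains,
                "ion_mode": sp.ion_mode,
            }
        feature_meta = pd.DataFrame.from_dict(rows, orient="index")
        feature_meta.index.name = "feature"
    return OmicsMatrix(
        values=df, sample_meta=sample_sheet, feature_meta=feature_meta, stage=stage
    )


# -- GMT gene sets ----------------------------------------------------------


def read_gmt(path) -> dict[str, list[str]]:
    """Standard tab-delimited GMT: name, description, genes...."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# -- annotation pairs -------------------------------------------------------


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "lipid"} <= set(df.columns):
        raise ValueError("annotation table needs 'gene' and 'lipid' columns")
    return df.drop_duplicates(subset=["gene", "lipid"]).reset_index(drop=True)


def write_annotation(table: pd.DataFrame, path) -> None:
    table[["gene", "lipid"]].to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))
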