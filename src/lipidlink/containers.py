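"""In-memory containers shared by all pipeline stages.

The central object is :class:`OmicsMatrix`: a samples x features table backed
by a pandas DataFrame, with a per-sample metadata frame (experimental group and
timepoint) and a per-feature metadata frame (lipid class / acyl chains / ion
mode for lipids, nothing beyond the id for genes).  A ``stage`` tag tracks the
preprocessing state of a lipid matrix ("raw" -> "imputed" -> "normalized" ->
"merged" -> "zscored").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STAGES = ("raw", "imputed", "normalized", "merged", "zscored")

GROUPS = ("SD", "HFD", "HFD-STZ", "HFD-DR", "HFD-STZ-DR")
TIMEPOINTS = ("16wk", "24wk")


@dataclass
class OmicsMatrix:
    """Samples x features abundance (or count) matrix with metadata.

    Attributes
    ----------
    values : pd.DataFrame
        Rows indexed by sample id, columns by feature id.  May contain NaN
        only at stage "raw".
    sample_meta : pd.DataFrame
        Indexed like ``values``; columns ``group`` and ``timepoint``.
    feature_meta : pd.DataFrame
        Indexed by feature id.  For lipids carries ``lipid_class``,
        ``acyl_chains`` (tuple of (carbons, double_bonds)), ``ion_mode`` and
        ``is_standard``; for genes it may be empty.
    stage : str
        One of ``STAGES``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(index=self.values.columns)
        if not self.values.index.equals(self.sample_meta.index):
            raise ValueError("sample_meta index must match the sample axis")
        if not self.values.columns.equals(self.feature_meta.index):
            raise ValueError("feature_meta index must match the feature axis")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage != "raw" and self.values.isna().any().any():
            raise ValueError(f"missing values not allowed at stage {self.stage!r}")

    # -- convenience ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.index.tolist()

    def samples_of(self, group: str, timepoint: str | None = None) -> list[str]:
        """Sample ids belonging to one group (optionally at one timepoint)."""
        mask = self.sample_meta["group"] == group
        if timepoint is not None:
            mask &= self.sample_meta["timepoint"] == timepoint
        return self.sample_meta.index[mask].tolist()

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        return replace(
            self,
            values=self.values.loc[list(sample_ids)],
            sample_meta=self.sample_meta.loc[list(sample_ids)],
        )

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        return replace(
            self,
            values=self.values[list(feature_ids)],
            feature_meta=self.feature_meta.loc[list(feature_ids)],
        )

    def with_stage(self, stage: str) -> "OmicsMatrix":
        return replace(self, stage=stage)

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(
            values=self.values.copy(),
            sample_meta=self.sample_meta.copy(),
            feature_meta=self.feature_meta.copy(),
            stage=self.stage,
        )

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)
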