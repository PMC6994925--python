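import numpy as np
import pandas as pd
import pytest

import lipidlink as ll


@pytest.fixture(scope="session")
def small_design() -> ll.StudyDesign:
    return ll.StudyDesign(n_per_group=5)


@pytest.fixture(scope="session")
def small_config() -> ll.SimulationConfig:
    return ll.SimulationConfig(
        n_lipids=120,
        n_genes=300,
        n_affected_genes=40,
        n_joint_lipids=10,
        n_joint_genes=15,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_design, small_config) -> ll.SimulatedStudy:
    """One fully simulated small study, shared read-only across tests."""
    return ll.simulate_study(small_design, small_config)


def toy_matrix(values: np.ndarray, feature_ids, groups=None, timepoints=None,
               stage="merged", lipid_meta=True) -> ll.OmicsMatrix:
    """Hand-built OmicsMatrix for unit tests (samples x features)."""
    n = values.shape[0]
    samples = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "group": groups if groups is not None else ["SD"] * n,
            "timepoint": timepoints if timepoints is not None else ["24wk"] * n,
        },
        index=pd.Index(samples),
    )
    vals = pd.DataFrame(values, index=samples, columns=list(feature_ids))
    feature_meta = None
    if lipid_meta:
        rows = {}
        for fid in feature_ids:
            sp = ll.parse_lipid_id(fid)
            rows[fid] = {
                "lipid_class": sp.lipid_class,
                "acyl_chains": sp.acyl_chains,
                "ion_mode": sp.ion_mode,
            }
        feature_meta = pd.DataFrame.from_dict(rows, orient="index")
    return ll.OmicsMatrix(
        values=vals, sample_meta=meta, feature_meta=feature_meta, stage=stage
    )
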