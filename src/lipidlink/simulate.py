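"""Paired lipidome / transcriptome simulator.

Emulates a five-group, two-timepoint dietary study of peripheral-nerve
metabolic disease: a standard-diet control (SD), a high-fat-diet prediabetes
model (HFD), an HFD + streptozotocin type-2-diabetes model (HFD-STZ), and the
two disease models after dietary reversal (HFD-DR, HFD-STZ-DR; these exist
only at the later timepoint).  The generator plants three kinds of structure:

* a disease effect — a log2 shift on a fraction of triglyceride (TG) and
  diglyceride (DG) species and on a designated gene set, present in HFD and
  HFD-STZ at both timepoints and absent (restored to control level) in the
  reversal groups;
* a joint latent factor — a per-sample score correlated with disease status
  that loads sparsely on designated TG lipids and designated genes in both
  matrices, the structure an O2PLS integration should recover;
* nuisance realism — log-normal lipid intensities with MCAR missing values,
  per-class internal standards, duplicate rows for species measured in both
  ion modes, negative-binomial gene counts with varying library sizes.

Ground truth (affected features, latent support and scores) is returned
alongside every matrix so downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GROUPS, TIMEPOINTS, OmicsMatrix
from .lipids import CHAINS_PER_CLASS, LIPID_CLASSES, LipidSpecies, parse_lipid_id

DISEASE_GROUPS = ("HFD", "HFD-STZ")
REVERSAL_GROUPS = ("HFD-DR", "HFD-STZ-DR")

#: Default share of the lipidome per class (sums to 1); TG dominates, as in
#: shotgun lipidomics of lipid-rich nerve tissue.
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "TG": 0.26, "PC": 0.14, "PE": 0.10, "SM": 0.07, "DG": 0.06, "CE": 0.05,
    "FFA": 0.05, "PI": 0.04, "PS": 0.04, "PG": 0.03, "PA": 0.03, "CL": 0.03,
    "ME": 0.02, "LPC": 0.02, "LPE": 0.02, "pPC": 0.02, "pPE": 0.02,
}

#: Core acyl pool: the dominant dietary fatty acids (palmitate, palmitoleate,
#: stearate, oleate, linoleate).  Sampled with high weight; a wider pool adds
#: the diversity needed for unique species ids.
CORE_ACYLS = ((16, 0), (16, 1), (18, 0), (18, 1), (18, 2))
EXTENDED_ACYLS = (
    (12, 0), (13, 0), (14, 0), (14, 1), (14, 2), (15, 0), (15, 1),
    (16, 2), (16, 3), (17, 1), (17, 2), (18, 3), (19, 0), (19, 1),
    (20, 0), (20, 1), (20, 2), (20, 3), (20, 4), (20, 5), (21, 0),
    (22, 0), (22, 1), (22, 2), (22, 4), (22, 5), (22, 6),
    (23, 0), (24, 0), (24, 1), (24, 2), (26, 0), (26, 1),
)

#: Gene symbols always included among the planted disease/joint genes, echoing
#: the lipid-handling machinery (TG synthesis, lipolysis, FA uptake) this kind
#: of study implicates.
MARKER_GENES = ("Dgat2", "Lpl", "Cd36", "Lipf", "Pla2g2e", "Lpgat1", "Saa3", "Il1rn")

_STREAM_LIPID, _STREAM_GENE, _STREAM_JOINT, _STREAM_ANNOT = 11, 23, 37, 53


@dataclass(frozen=True)
class StudyDesign:
    """Sample layout: 5 diet groups x 2 timepoints, reversal groups only late.

    Reversal (DR) groups exist only at 24 weeks because reversal starts at the
    16-week baseline; with the default ``n_per_group=10`` the design yields
    3 x 10 samples at 16wk and 5 x 10 at 24wk.
    """

    groups: tuple[str, ...] = GROUPS
    timepoints: tuple[str, ...] = TIMEPOINTS
    n_per_group: int = 10

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be positive")

    def cells(self) -> list[tuple[str, str]]:
        """(group, timepoint) cells that actually contain samples."""
        out = []
        for tp in self.timepoints:
            for g in self.groups:
                if tp == "16wk" and g in REVERSAL_GROUPS:
                    continue
                out.append((g, tp))
        return out

    def sample_sheet(self) -> pd.DataFrame:
        """One row per sample: id, group, timepoint."""
        rows = []
        for g, tp in self.cells():
            for i in range(self.n_per_group):
                rows.append((f"{g}_{tp}_{i + 1:02d}", g, tp))
        sheet = pd.DataFrame(rows, columns=["sample", "group", "timepoint"])
        return sheet.set_index("sample")

    @property
    def n_samples(self) -> int:
        return len(self.cells()) * self.n_per_group


@dataclass
class SimulationConfig:
    """All knobs of the paired simulation; ``seed`` fully determines output."""

    n_lipids: int = 578
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    n_genes: int = 6000
    disease_effect_size: float = 1.0   # log2-fold shift in disease groups
    fraction_tg_affected: float = 0.5  # applied to TG and DG species
    n_affected_genes: int = 150
    affected_gene_ids: tuple[str, ...] | None = None
    joint_factor_strength: float = 3.0  # loading scale of the latent factor
    n_joint_lipids: int = 40
    n_joint_genes: int = 60
    joint_lipid_ids: tuple[str, ...] | None = None
    joint_gene_ids: tuple[str, ...] | None = None
    latent_noise_sd: float = 0.25      # noise on the disease-linked score
    missing_rate: float = 0.05         # MCAR fraction of lipid entries
    nb_dispersion: float = 0.05        # NB variance = mu + alpha * mu^2
    lipid_sigma: float = 0.5           # biological log2 SD of lipid intensity
    dual_mode_fraction: float = 0.15   # species measured in both ion modes
    dual_mode_noise_sd: float = 0.05   # log2 disagreement between modes
    library_size_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class_proportions must sum to 1 (got {total:.6f})")
        unknown = set(self.class_proportions) - set(LIPID_CLASSES)
        if unknown:
            raise ValueError(f"unknown lipid classes in proportions: {sorted(unknown)}")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValueError("class proportions must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        n_classes = sum(1 for p in self.class_proportions.values() if p > 0)
        if self.n_lipids < n_classes:
            raise ValueError("n_lipids must be at least the number of classes")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.lipid_sigma <= 0:
            raise ValueError("lipid_sigma must be positive")
        if not 0.0 <= self.fraction_tg_affected <= 1.0:
            raise ValueError("fraction_tg_affected must be in [0, 1]")
        if not 0.0 <= self.dual_mode_fraction <= 1.0:
            raise ValueError("dual_mode_fraction must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible substream for one generator stage."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


# ---------------------------------------------------------------------------
# lipid species sampling


def _class_counts(config: SimulationConfig) -> dict[str, int]:
    """Largest-remainder apportionment of n_lipids across classes."""
    props = {c: p for c, p in config.class_proportions.items() if p > 0}
    raw = {c: config.n_lipids * p for c, p in props.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    # every present class gets at least one species
    for c in counts:
        counts[c] = max(counts[c], 1)
    deficit = config.n_lipids - sum(counts.values())
    order = sorted(props, key=lambda c: raw[c] - np.floor(raw[c]), reverse=True)
    i = 0
    while deficit != 0:
        c = order[i % len(order)]
        if deficit > 0:
            counts[c] += 1
            deficit -= 1
        elif counts[c] > 1:
            counts[c] -= 1
            deficit += 1
        i += 1
    return counts


def _sample_acyl(rng: np.random.Generator) -> tuple[int, int]:
    if rng.random() < 0.8:
        return CORE_ACYLS[rng.integers(len(CORE_ACYLS))]
    return EXTENDED_ACYLS[rng.integers(len(EXTENDED_ACYLS))]


def generate_lipid_species(
    config: SimulationConfig, rng: np.random.Generator
) -> list[LipidSpecies]:
    """Draw ``n_lipids`` unique species ids following the class proportions.

    Multi-chain classes get resolved acyl chains drawn from the acyl pool
    (chains sorted, so ids are position-agnostic); cardiolipins (CL) are
    emitted as total-composition ids, as shotgun data typically reports them.
    """
    species: list[LipidSpecies] = []
    # reserve the internal-standard ids so no species can collide with them
    seen: set[str] = {internal_standard_id(c) for c in config.class_proportions}
    for cls, n in _class_counts(config).items():
        n_chains = CHAINS_PER_CLASS[cls]
        attempts = 0
        made = 0
        while made < n:
            attempts += 1
            if attempts > 200 * n + 1000:
                raise RuntimeError(f"cannot draw {n} unique {cls} species")
            if cls == "CL":
                # total composition only: 4 chains summed
                chains = sorted(_sample_acyl(rng) for _ in range(4))
                rid = f"CL({sum(c for c, _ in chains)}:{sum(d for _, d in chains)})"
            else:
                chains = sorted(_sample_acyl(rng) for _ in range(n_chains))
                body = "/".join(f"{c}:{d}" for c, d in chains)
                rid = f"{cls}({body})"
            if rid in seen:
                continue
            seen.add(rid)
            species.append(parse_lipid_id(rid))
            made += 1
    return species


def internal_standard_id(cls: str) -> str:
    """Odd-chain (17:0-based) internal standard identifier for a class."""
    n_chains = CHAINS_PER_CLASS[cls]
    if cls == "CL":
        return f"CL({17 * 4}:0)"
    body = "/".join(["17:0"] * n_chains)
    return f"{cls}({body})"


# ---------------------------------------------------------------------------
# matrix generators


def _feature_meta_from_species(ids: list[str]) -> pd.DataFrame:
    parsed = [parse_lipid_id(i) for i in ids]
    return pd.DataFrame(
        {
            "lipid_class": [s.lipid_class for s in parsed],
            "acyl_chains": [s.acyl_chains for s in parsed],
            "ion_mode": [s.ion_mode for s in parsed],
        },
        index=pd.Index(ids, name="feature"),
    )


def generate_lipidome(
    design: StudyDesign, config: SimulationConfig
) -> tuple[OmicsMatrix, dict]:
    """Simulate a raw lipid intensity matrix.

    Intensities are log-normal around class- and species-specific baselines.
    Disease groups carry a +``disease_effect_size`` log2 shift on the affected
    TG/DG subset at both timepoints; reversal groups sit at the control
    baseline.  A ``dual_mode_fraction`` of species is emitted twice (once per
    ion mode, with small inter-mode noise); one odd-chain internal standard
    per class is appended; missing entries are MCAR at ``missing_rate``.

    Returns the raw matrix (features carry ion-mode suffixes) and a ground
    truth dict with affected species, dual-mode species, the standards map and
    the noise-free log2 design means.
    """
    rng = config.rng(_STREAM_LIPID)
    sheet = design.sample_sheet()
    species = generate_lipid_species(config, rng)
    keys = [s.species_key for s in species]

    # class baselines and per-species offsets (log2 intensity scale)
    classes = sorted({s.lipid_class for s in species})
    class_base = {c: rng.normal(8.0, 1.5) for c in classes}
    offsets = rng.normal(0.0, 1.0, size=len(species))
    base_log2 = np.array(
        [class_base[s.lipid_class] + o for s, o in zip(species, offsets)]
    )

    # affected subset: fraction of TG and DG species
    affected: list[str] = []
    for cls in ("TG", "DG"):
        members = [k for s, k in zip(species, keys) if s.lipid_class == cls]
        n_aff = int(round(config.fraction_tg_affected * len(members)))
        if n_aff > 0:
            affected.extend(
                rng.choice(members, size=n_aff, replace=False).tolist()
            )
    affected_set = set(affected)

    # design means: samples x species, log2 scale
    is_disease = sheet["group"].isin(DISEASE_GROUPS).to_numpy()
    aff_mask = np.array([k in affected_set for k in keys])
    mean_log2 = np.tile(base_log2, (len(sheet), 1))
    mean_log2[np.ix_(is_disease, aff_mask)] += config.disease_effect_size

    # dual-mode duplication
    n_dual = int(round(config.dual_mode_fraction * len(species)))
    dual_idx = rng.choice(len(species), size=n_dual, replace=False) if n_dual else []
    dual_set = set(int(i) for i in np.atleast_1d(dual_idx))

    noise = rng.normal(0.0, config.lipid_sigma, size=mean_log2.shape)
    log2_vals = mean_log2 + noise

    cols: list[str] = []
    data: list[np.ndarray] = []
    for j, key in enumerate(keys):
        if j in dual_set:
            for suffix in ("[+]", "[-]"):
                mode_noise = rng.normal(0.0, config.dual_mode_noise_sd, len(sheet))
                cols.append(key + suffix)
                data.append(2.0 ** (log2_vals[:, j] + mode_noise))
        else:
            suffix = "[+]" if rng.random() < 0.7 else "[-]"
            cols.append(key + suffix)
            data.append(2.0 ** log2_vals[:, j])

    # internal standards: one per class, near-constant
    standards: dict[str, str] = {}
    for cls in classes:
        sid = internal_standard_id(cls) + "[+]"
        standards[cls] = sid
        cols.append(sid)
        data.append(2.0 ** (5.0 + rng.normal(0.0, 0.02, len(sheet))))

    values = pd.DataFrame(
        np.column_stack(data), index=sheet.index, columns=cols
    )

    # MCAR missingness on non-standard entries
    if config.missing_rate > 0:
        non_std = [c for c in cols if c not in standards.values()]
        mask = rng.random((len(sheet), len(non_std))) < config.missing_rate
        # keep each feature observed in at least 2 samples so imputation is defined
        for jj in range(mask.shape[1]):
            if mask[:, jj].sum() > len(sheet) - 2:
                keep = rng.choice(len(sheet), size=2, replace=False)
                mask[keep, jj] = False
        block = values[non_std].to_numpy()
        block[mask] = np.nan
        values[non_std] = block

    meta = _feature_meta_from_species(cols)
    meta["is_standard"] = meta.index.isin(set(standards.values()))
    matrix = OmicsMatrix(values=values, sample_meta=sheet, feature_meta=meta, stage="raw")

    truth = {
        "affected_lipids": sorted(affected_set),
        "dual_mode_species": sorted(keys[i] for i in dual_set),
        "standards": standards,
        "species": keys,
        "baseline_log2": dict(zip(keys, base_log2.tolist())),
    }
    return matrix, truth


def generate_transcriptome(
    design: StudyDesign, config: SimulationConfig
) -> tuple[OmicsMatrix, dict]:
    """Simulate a raw gene count matrix.

    Counts are negative binomial around gene-specific means with a common
    dispersion (``var = mu + alpha mu^2``; ``alpha == 0`` gives the Poisson
    limit).  Affected genes carry the disease log2 shift in HFD / HFD-STZ and
    are restored in the reversal groups; library sizes vary uniformly within
    ``library_size_range``.
    """
    rng = config.rng(_STREAM_GENE)
    sheet = design.sample_sheet()

    gene_ids = list(MARKER_GENES[: config.n_genes])
    gene_ids += [f"Gene{i:05d}" for i in range(1, config.n_genes - len(gene_ids) + 1)]

    if config.affected_gene_ids is not None:
        affected = [g for g in config.affected_gene_ids if g in set(gene_ids)]
    else:
        n_aff = min(config.n_affected_genes, config.n_genes)
        affected = list(gene_ids[: len(MARKER_GENES)])[:n_aff]
        pool = gene_ids[len(MARKER_GENES):]
        extra = n_aff - len(affected)
        if extra > 0:
            affected += rng.choice(pool, size=extra, replace=False).tolist()
    affected_set = set(affected)

    base_mu = np.maximum(2.0 ** rng.normal(5.0, 2.0, size=config.n_genes), 0.5)
    is_disease = sheet["group"].isin(DISEASE_GROUPS).to_numpy()
    aff_mask = np.array([g in affected_set for g in gene_ids])
    lib = rng.uniform(*config.library_size_range, size=len(sheet))

    mu = np.tile(base_mu, (len(sheet), 1))
    mu[np.ix_(is_disease, aff_mask)] *= 2.0 ** config.disease_effect_size
    mu *= lib[:, None]

    alpha = config.nb_dispersion
    if alpha <= 1e-12:
        counts = rng.poisson(mu)
    else:
        n_param = 1.0 / alpha
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param)

    values = pd.DataFrame(counts.astype(np.int64), index=sheet.index, columns=gene_ids)
    matrix = OmicsMatrix(
        values=values,
        sample_meta=sheet,
        feature_meta=pd.DataFrame(index=pd.Index(gene_ids, name="feature")),
        stage="raw",
    )
    truth = {
        "affected_genes": sorted(affected_set),
        "library_sizes": dict(zip(sheet.index, lib.tolist())),
        "base_mu": dict(zip(gene_ids, base_mu.tolist())),
    }
    return matrix, truth


def plant_joint_factor(
    lipid_matrix: OmicsMatrix,
    gene_matrix: OmicsMatrix,
    config: SimulationConfig,
    lipid_truth: dict | None = None,
    gene_truth: dict | None = None,
) -> tuple[OmicsMatrix, OmicsMatrix, dict]:
    """Overlay a shared latent factor on both matrices.

    A per-sample score ``s`` (standardised disease indicator plus Gaussian
    noise) multiplies sparse positive loading vectors: designated TG species
    in the lipid matrix and designated genes (always including the marker
    genes) in the count matrix.  The overlay is multiplicative
    (``value *= 2**(s * w)``), i.e. additive on the log2 scale the integration
    operates on; counts are re-rounded.  ``joint_factor_strength == 0`` leaves
    both matrices untouched.
    """
    if not lipid_matrix.values.index.equals(gene_matrix.values.index):
        raise ValueError("lipid and gene matrices must share the sample axis")
    rng = config.rng(_STREAM_JOINT)
    sheet = lipid_matrix.sample_meta

    # latent score: disease-linked, unit variance
    ind = sheet["group"].isin(DISEASE_GROUPS).to_numpy(dtype=float)
    s = ind - ind.mean() + rng.normal(0.0, config.latent_noise_sd, len(sheet))
    s = (s - s.mean()) / s.std(ddof=0)

    # lipid-side support: TG species (non-standard), unless overridden
    meta = lipid_matrix.feature_meta
    if config.joint_lipid_ids is not None:
        lip_support = list(config.joint_lipid_ids)
        missing = set(lip_support) - set(lipid_matrix.feature_ids)
        if missing:
            raise ValueError(f"joint lipid ids absent from matrix: {sorted(missing)[:5]}")
    else:
        is_std = meta.get("is_standard", pd.Series(False, index=meta.index))
        tg_ids = meta.index[(meta["lipid_class"] == "TG") & ~is_std].tolist()
        # pick species, then take every ion-mode row of each picked species
        tg_keys = sorted({parse_lipid_id(i).species_key for i in tg_ids})
        n_pick = min(config.n_joint_lipids, len(tg_keys))
        if n_pick < config.n_joint_lipids:
            raise ValueError(
                f"joint lipid support ({config.n_joint_lipids}) exceeds TG species ({len(tg_keys)})"
            )
        picked = set(rng.choice(tg_keys, size=n_pick, replace=False).tolist())
        lip_support = [i for i in tg_ids if parse_lipid_id(i).species_key in picked]

    if config.joint_gene_ids is not None:
        gene_support = list(config.joint_gene_ids)
        missing = set(gene_support) - set(gene_matrix.feature_ids)
        if missing:
            raise ValueError(f"joint gene ids absent from matrix: {sorted(missing)[:5]}")
    else:
        n_pick = min(config.n_joint_genes, gene_matrix.n_features)
        if n_pick < config.n_joint_genes:
            raise ValueError("joint gene support exceeds gene count")
        markers = [g for g in MARKER_GENES if g in set(gene_matrix.feature_ids)]
        gene_support = markers[:n_pick]
        pool = [g for g in gene_matrix.feature_ids if g not in set(gene_support)]
        extra = n_pick - len(gene_support)
        if extra > 0:
            gene_support += rng.choice(pool, size=extra, replace=False).tolist()

    w_x = config.joint_factor_strength * rng.uniform(0.5, 1.0, len(lip_support))
    w_y = config.joint_factor_strength * rng.uniform(0.5, 1.0, len(gene_support))

    lipid_out = lipid_matrix.copy()
    if len(lip_support):
        block = lipid_out.values[lip_support].to_numpy()
        lipid_out.values[lip_support] = block * 2.0 ** np.outer(s, w_x)

    gene_out = gene_matrix.copy()
    if len(gene_support):
        block = gene_out.values[gene_support].to_numpy(dtype=float)
        gene_out.values[gene_support] = np.rint(
            block * 2.0 ** np.outer(s, w_y)
        ).astype(np.int64)

    truth = {
        "latent_score": dict(zip(sheet.index, s.tolist())),
        "joint_lipids": sorted(
            {parse_lipid_id(i).species_key for i in lip_support}
        ),
        "joint_lipid_rows": list(lip_support),
        "joint_genes": sorted(gene_support),
        "w_x": dict(zip(lip_support, w_x.tolist())),
        "w_y": dict(zip(gene_support, w_y.tolist())),
    }
    return lipid_out, gene_out, truth


def generate_annotation(
    lipid_ids: Sequence[str],
    gene_ids: Sequence[str],
    config: SimulationConfig,
    joint_truth: dict | None = None,
    affected_genes: Sequence[str] | None = None,
    n_annotated_genes: int = 300,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Emit an HMDB-style gene-lipid pair table and GMT gene sets.

    The planted joint genes are always annotated to planted joint lipids, so
    the end-to-end annotation filter can retain them; background genes get
    1-3 random lipid partners.  Three gene sets are produced, one of which is
    the planted (affected/joint) gene set — the set an enrichment test should
    flag.
    """
    rng = config.rng(_STREAM_ANNOT)
    lipid_ids = list(dict.fromkeys(lipid_ids))
    gene_ids = list(dict.fromkeys(gene_ids))
    gene_set = set(gene_ids)

    planted_genes = list((joint_truth or {}).get("joint_genes", []))
    planted_genes = [g for g in planted_genes if g in gene_set]
    planted_lipids = [
        l for l in (joint_truth or {}).get("joint_lipids", []) if l in set(lipid_ids)
    ]

    n_annot = min(n_annotated_genes, len(gene_ids))
    annotated = list(planted_genes)
    pool = [g for g in gene_ids if g not in set(annotated)]
    extra = n_annot - len(annotated)
    if extra > 0:
        annotated += rng.choice(pool, size=extra, replace=False).tolist()

    pairs: set[tuple[str, str]] = set()
    for g in annotated:
        if g in set(planted_genes) and planted_lipids:
            partners = rng.choice(
                planted_lipids, size=min(3, len(planted_lipids)), replace=False
            )
        else:
            partners = rng.choice(
                lipid_ids, size=int(rng.integers(1, 4)), replace=False
            )
        for l in np.atleast_1d(partners):
            pairs.add((g, str(l)))

    table = pd.DataFrame(sorted(pairs), columns=["gene", "lipid"])

    planted_set = [g for g in (affected_genes or planted_genes) if g in gene_set]
    if not planted_set:
        planted_set = planted_genes or gene_ids[: min(20, len(gene_ids))]
    n_rand = min(40, len(gene_ids))
    gmt = {
        "PLANTED_LIPID_METABOLISM": sorted(planted_set),
        "RANDOM_SET_A": sorted(rng.choice(gene_ids, size=n_rand, replace=False)),
        "RANDOM_SET_B": sorted(rng.choice(gene_ids, size=n_rand, replace=False)),
    }
    return table, gmt


@dataclass
class SimulatedStudy:
    """Bundle of everything one simulation run produces."""

    design: StudyDesign
    config: SimulationConfig
    lipids: OmicsMatrix
    genes: OmicsMatrix
    annotation: pd.DataFrame
    gene_sets: dict[str, list[str]]
    truth: dict

    def config_dict(self) -> dict:
        d = asdict(self.config)
        d["design_n_per_group"] = self.design.n_per_group
        return d


def simulate_study(design: StudyDesign, config: SimulationConfig) -> SimulatedStudy:
    """Run all generator stages in order and collect ground truth."""
    lipids, lip_truth = generate_lipidome(design, config)
    genes, gene_truth = generate_transcriptome(design, config)
    lipids, genes, joint_truth = plant_joint_factor(lipids, genes, config)
    annotation, gmt = generate_annotation(
        [parse_lipid_id(i).species_key for i in lipids.feature_ids
         if not lipids.feature_meta.loc[i, "is_standard"]],
        genes.feature_ids,
        config,
        joint_truth=joint_truth,
        affected_genes=gene_truth["affected_genes"],
    )
    truth = {"lipidome": lip_truth, "transcriptome": gene_truth, "joint": joint_truth}
    return SimulatedStudy(
        design=design, config=config, lipids=lipids, genes=genes,
        annotation=annotation, gene_sets=gmt, truth=truth,
    )
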