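"""Synthetic morphometry cohorts with planted subtype structure.

The generator emulates the statistical situation the subtyping analysis is
built for: a case-control cohort in which only a *subset* of patients
(subtype 1) carries a regionally localized gray-matter-volume increase,
while the remaining patients (subtype 2) are distributionally identical to
controls.  Region volumes are confounded with age and total intracranial
volume (TIV) so the covariate-adjustment stage has real work to do.

Default cohort composition is 93 controls and 75 patients (38 subtype 1,
37 subtype 2) with the volume increase planted in 30 regions named after
pain-processing structures (caudate, putamen, thalamus, hippocampus,
amygdala, precuneus, parahippocampal gyrus).

Hidden truth labels are returned in a separate sidecar table and never
written into the main morphometry table, so they cannot leak into the
clustering stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from neurosubtype.io import MorphometryTable

# Bilateral subdivisions of seven pain-processing structures: 30 regions in
# total, used as the default location of the planted subtype-1 effect.
PAIN_STRUCTURES = {
    "caudate": ("dorsal", "ventral"),
    "putamen": ("dorsolateral", "ventromedial"),
    "thalamus": ("rostral_temporal", "sensory", "mediodorsal"),
    "hippocampus": ("rostral", "caudal"),
    "amygdala": ("lateral", "medial"),
    "precuneus": ("dorsomedial", "ventral"),
    "parahippocampal_gyrus": ("rostral", "caudal"),
}


def default_region_table(n_regions: int = 246) -> pd.DataFrame:
    """Region metadata: names and a pain-related flag for 30 default regions.

    The pain-related regions are placed at deterministic, evenly spread
    indices so the planted effect is not confined to one block of columns.
    """
    names = []
    for structure, parts in PAIN_STRUCTURES.items():
        for part in parts:
            for hemi in ("L", "R"):
                names.append(f"{hemi}_{part}_{structure}")
    n_pain = len(names)  # 30
    if n_regions < n_pain:
        raise ValueError(f"need at least {n_pain} regions, got {n_regions}")
    pain_idx = np.unique(np.linspace(0, n_regions - 1, n_pain).round().astype(int))
    region_id = [f"region_{i + 1:04d}" for i in range(n_regions)]
    region_name = [f"generic_region_{i + 1}" for i in range(n_regions)]
    pain_flag = np.zeros(n_regions, dtype=bool)
    for j, idx in enumerate(pain_idx):
        region_name[idx] = names[j]
        pain_flag[idx] = True
    return pd.DataFrame(
        {"region_id": region_id, "region_name": region_name, "pain_related": pain_flag}
    )


def default_affected_regions(n_regions: int = 246) -> np.ndarray:
    """1-based indices of the 30 default pain-related regions."""
    meta = default_region_table(n_regions)
    return np.flatnonzero(meta["pain_related"].to_numpy()) + 1


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Volumes (mL) for region r of subject i are generated as

        v_ir = b_r + beta_age * (age_i - age_mean) + beta_tiv * (tiv_i - tiv_mean)
               + delta_ir + eps_ir,   eps_ir ~ N(0, noise_sd^2)

    where b_r is a per-region baseline and delta_ir = effect_size * noise_sd
    for subtype-1 subjects in affected regions (zero otherwise), so the
    planted per-region effect is ``effect_size`` in Cohen's d units.
    Subtype-2 patients are drawn from the control model.
    """

    n_controls: int = 93
    n_subtype1: int = 38
    n_subtype2: int = 37
    n_regions: int = 246
    affected_regions: np.ndarray | None = None  # 1-based indices
    effect_size: float = 0.8
    age_mean: float = 46.0
    age_sd: float = 10.0
    tiv_mean: float = 1400.0
    tiv_sd: float = 120.0
    beta_age: float = -0.008  # mL per year: mild age-related atrophy
    beta_tiv: float = 0.0015  # mL per mL TIV: head-size scaling
    noise_sd: float = 0.25
    baseline_mean: float = 2.5
    baseline_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_subtype1", "n_subtype2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_controls + self.n_subtype1 + self.n_subtype2 == 0:
            raise ValueError("cohort has zero subjects")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.affected_regions is None:
            self.affected_regions = default_affected_regions(self.n_regions)
        self.affected_regions = np.asarray(self.affected_regions, dtype=int)
        if len(self.affected_regions) and (
            self.affected_regions.min() < 1 or self.affected_regions.max() > self.n_regions
        ):
            raise ValueError(
                f"affected region indices must lie in 1..{self.n_regions}"
            )


def generate_cohort(config: GeneratorConfig) -> tuple[MorphometryTable, pd.DataFrame]:
    """Generate a cohort and its hidden truth sidecar.

    Returns
    -------
    table
        MorphometryTable with ``n_controls + n_subtype1 + n_subtype2`` rows.
    truth
        Two-column sidecar (``subject_id``, ``true_subtype``) with
        ``control``, ``subtype1`` or ``subtype2`` per subject.  Kept out of
        the main table so the clustering stage cannot see it.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_controls + config.n_subtype1 + config.n_subtype2

    labels = (
        ["control"] * config.n_controls
        + ["subtype1"] * config.n_subtype1
        + ["subtype2"] * config.n_subtype2
    )
    group = ["control"] * config.n_controls + ["patient"] * (
        config.n_subtype1 + config.n_subtype2
    )
    subject_id = [f"sub-{i + 1:04d}" for i in range(n_total)]

    age = rng.normal(config.age_mean, config.age_sd, n_total)
    tiv = rng.normal(config.tiv_mean, config.tiv_sd, n_total)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_regions)
    baseline = np.clip(baseline, 0.5, None)  # volumes must stay positive

    vols = (
        baseline[None, :]
        + config.beta_age * (age - config.age_mean)[:, None]
        + config.beta_tiv * (tiv - config.tiv_mean)[:, None]
        + rng.normal(0.0, config.noise_sd, (n_total, config.n_regions))
    )
    affected0 = config.affected_regions - 1
    is_s1 = np.array([lab == "subtype1" for lab in labels])
    vols[np.ix_(is_s1, affected0)] += config.effect_size * config.noise_sd
    vols = np.clip(vols, 0.0, None)

    meta = default_region_table(config.n_regions)
    region_ids = meta["region_id"].tolist()
    data = pd.concat(
        [
            pd.DataFrame(
                {"subject_id": subject_id, "group": group, "age": age, "tiv": tiv}
            ),
            pd.DataFrame(vols, columns=region_ids),
        ],
        axis=1,
    )
    table = MorphometryTable(data=data, parcellation_name=f"synthetic-{config.n_regions}")
    truth = pd.DataFrame({"subject_id": subject_id, "true_subtype": labels})
    return table, truth


def pairwise_merge_grouping(region_ids: list[str]) -> dict[str, list[str]]:
    """Merge consecutive region pairs: a simple alternate parcellation with
    half (rounded up) as many regions."""
    grouping: dict[str, list[str]] = {}
    for i in range(0, len(region_ids), 2):
        members = region_ids[i : i + 2]
        grouping[f"merged_{i // 2 + 1:04d}"] = members
    return grouping


def generate_alternate_parcellation(
    table: MorphometryTable,
    grouping: dict[str, list[str]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    parcellation_name: str = "alternate",
) -> MorphometryTable:
    """Re-express a cohort in a coarser parcellation.

    Each new region's volume is the sum of its member regions' volumes plus
    optional remeasurement noise; subjects, groups and covariates are
    unchanged.  Emulates re-running the analysis with a different atlas.
    """
    if grouping is None:
        grouping = pairwise_merge_grouping(table.region_ids)
    if not grouping:
        raise ValueError("empty grouping")
    covered: set[str] = set()
    for new_region, members in grouping.items():
        unknown = [m for m in members if m not in table.region_ids]
        if unknown:
            raise ValueError(f"unknown region(s) in group '{new_region}': {unknown}")
        covered.update(members)
    missing = set(table.region_ids) - covered
    if missing:
        raise ValueError(f"grouping does not cover region(s): {sorted(missing)[:5]}")

    rng = np.random.default_rng(seed)
    new_cols = {}
    for new_region, members in grouping.items():
        vals = table.data[members].sum(axis=1).to_numpy(dtype=float)
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, len(vals))
        new_cols[new_region] = np.clip(vals, 0.0, None)
    data = pd.concat(
        [table.data[["subject_id", "group", "age", "tiv"]], pd.DataFrame(new_cols)],
        axis=1,
    )
    return MorphometryTable(data=data, parcellation_name=parcellation_name)


# --------------------------------------------------------------------------
# Voxel phantom


@dataclass
class VoxelPhantomConfig:
    """Small 3D phantom for exercising the voxel-wise comparison stage.

    A labeled grid of regions with per-region mean intensities; for regions
    listed in ``group_effects`` the mean is shifted for group-1 subjects.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    region_label_map: np.ndarray | None = None
    region_offsets: dict[int, float] = field(default_factory=dict)
    group_effects: dict[int, float] = field(default_factory=dict)
    voxel_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_label_map is None:
            self.region_label_map = default_phantom_labels(self.grid_shape)
        self.region_label_map = np.asarray(self.region_label_map)
        if self.region_label_map.shape != tuple(self.grid_shape):
            raise ValueError(
                f"label map shape {self.region_label_map.shape} does not match "
                f"grid shape {tuple(self.grid_shape)}"
            )
        if (self.region_label_map < 0).any():
            raise ValueError("labels must be nonnegative")
        if not (self.region_label_map > 0).any():
            raise ValueError("label map has no labeled regions")


def default_phantom_labels(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Two cubic regions (labels 1 and 2) inside the grid."""
    labels = np.zeros(grid_shape, dtype=np.int32)
    x, y, z = grid_shape
    labels[2 : x // 3, 2 : y // 3, 2 : z // 3] = 1
    labels[x // 2 : x - 2, y // 2 : y - 2, z // 2 : z - 2] = 2
    return labels


def generate_voxel_phantom(
    config: VoxelPhantomConfig, group_assignments: np.ndarray
) -> np.ndarray:
    """Per-subject intensity volumes: (n_subjects, x, y, z).

    ``group_assignments`` holds one 0/1 label per subject; regions listed in
    ``config.group_effects`` get that offset added for group-1 subjects.
    """
    groups = np.asarray(group_assignments)
    if groups.ndim != 1 or len(groups) == 0:
        raise ValueError("group_assignments must be a nonempty 1D array")
    rng = np.random.default_rng(config.seed)
    labels = config.region_label_map
    base = np.zeros(labels.shape)
    for lab, off in config.region_offsets.items():
        base[labels == lab] = off
    effect = np.zeros(labels.shape)
    for lab, off in config.group_effects.items():
        effect[labels == lab] = off

    n = len(groups)
    out = np.empty((n,) + labels.shape)
    for i in range(n):
        mean = base + effect if groups[i] == 1 else base
        if config.voxel_noise_sd > 0:
            out[i] = mean + rng.normal(0.0, config.voxel_noise_sd, labels.shape)
        else:
            out[i] = mean
    return out


# --------------------------------------------------------------------------
# Synthetic clinical scores


#: Per-measure (mean, sd) for subtype 1 and subtype 2 used as generator
#: defaults; magnitudes follow published fibromyalgia cohort summaries, with
#: a real separation planted only in age, symptom duration and perceived
#: stress (PSS).
CLINICAL_SCORE_MODEL = {
    "age": ((43.3, 10.5), (48.4, 10.1)),
    "symptom_duration": ((79.7, 69.5), (51.9, 48.9)),
    "education_years": ((14.0, 3.1), (14.0, 3.1)),
    "pain_vas": ((6.1, 1.5), (6.1, 1.5)),
    "wpi": ((11.2, 3.8), (11.2, 3.8)),
    "mfi20": ((67.5, 14.5), (67.5, 14.5)),
    "psqi": ((11.5, 3.3), (11.5, 3.3)),
    "bdi2": ((8.8, 7.0), (8.8, 7.0)),
    "pss": ((30.7, 9.0), (25.0, 9.3)),
    "fiqr": ((39.3, 18.7), (39.3, 18.7)),
}


def generate_clinical_scores(
    truth: pd.DataFrame, seed: int = 0, model: dict | None = None
) -> pd.DataFrame:
    """Synthetic clinical scores for the patients of a generated cohort.

    Scores are drawn per measure from Gaussians whose means/SDs differ
    between planted subtypes only where the model says so (by default: age,
    symptom duration and PSS).  Values with a natural floor are clipped at
    zero.
    """
    model = model or CLINICAL_SCORE_MODEL
    rng = np.random.default_rng(seed)
    patients = truth[truth["true_subtype"] != "control"].reset_index(drop=True)
    out = pd.DataFrame({"subject_id": patients["subject_id"]})
    is_s1 = (patients["true_subtype"] == "subtype1").to_numpy()
    for measure, ((m1, s1), (m2, s2)) in model.items():
        vals = np.where(
            is_s1,
            rng.normal(m1, s1, len(patients)),
            rng.normal(m2, s2, len(patients)),
        )
        out[measure] = np.clip(vals, 0.0, None)
    return out
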