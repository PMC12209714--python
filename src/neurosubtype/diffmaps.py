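"""Group-difference statistics at region and voxel level.

Subtype-vs-control (and whole-group-vs-control) comparisons with two-sample
t-tests, Benjamini-Hochberg FDR control, Cohen's d effect sizes, and — for
voxel maps — a cluster-extent filter that removes supra-threshold connected
components of 40 voxels or fewer (strict "> min_size" survival rule).  FDR
is applied voxel-wise *before* extent filtering (threshold-then-cluster).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from neurosubtype.io import MorphometryTable, write_stat_map

CONTRASTS = ("subtype1-vs-controls", "subtype2-vs-controls", "all-patients-vs-controls")


def two_sample_t(values_a, values_b, variant: str = "pooled") -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns (t, df, p).

    ``variant`` is "pooled" (equal-variance, df = nA+nB-2) or "welch"
    (Welch-Satterthwaite df).  Degenerate zero-variance inputs follow the
    conventions: equal means -> t = 0, p = 1; unequal means -> t = +/-inf,
    p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df_pooled = len(a) + len(b) - 2.0
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, df_pooled, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), df_pooled, 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    df = df_pooled if variant == "pooled" else float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (q_values, reject_mask)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def cohens_d(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> float:
    """Standardized mean difference with (n-1)-weighted pooled SD."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("SDs must be nonnegative")
    pooled = np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    if pooled == 0:
        raise ValueError("both groups have zero SD; d undefined")
    return float((mean_a - mean_b) / pooled)


def cohens_d_from_samples(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return cohens_d(a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))


# --------------------------------------------------------------------------
# Cluster-extent filtering


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def cluster_extent_filter(
    mask: np.ndarray,
    min_size: int = 40,
    connectivity: int = 26,
    stat: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Keep connected components strictly larger than ``min_size`` voxels.

    Returns the filtered boolean mask and a table of surviving clusters with
    (cluster_id, size, peak voxel) where the peak is the voxel of maximal
    ``stat`` (maximal |stat| when signed maps are passed) or, without a stat
    map, the first voxel in C order.  Voxel indices are 0-based.
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"mask must be 3D, got {mask.ndim}D")
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    labeled, n_comp = ndimage.label(mask.astype(bool), structure=_STRUCTURES[connectivity])
    out = np.zeros(mask.shape, dtype=bool)
    rows = []
    next_id = 1
    for comp in range(1, n_comp + 1):
        comp_mask = labeled == comp
        size = int(comp_mask.sum())
        if size <= min_size:
            continue
        out |= comp_mask
        voxels = np.argwhere(comp_mask)
        if stat is not None:
            vals = np.abs(np.asarray(stat)[comp_mask])
            peak = voxels[int(np.argmax(vals))]
        else:
            peak = voxels[0]
        rows.append(
            {
                "cluster_id": next_id,
                "size": size,
                "peak_x": int(peak[0]),
                "peak_y": int(peak[1]),
                "peak_z": int(peak[2]),
            }
        )
        next_id += 1
    table = pd.DataFrame(rows, columns=["cluster_id", "size", "peak_x", "peak_y", "peak_z"])
    return out, table


# --------------------------------------------------------------------------
# ROI-level group test


@dataclass
class StatResult:
    """Per-region (or per-voxel, flattened) group-difference statistics."""

    table: pd.DataFrame  # unit, t, df, p, q, d, significant
    contrast: str
    alpha: float
    n_group_a: int
    n_group_b: int
    metadata: dict = field(default_factory=dict)

    @property
    def significant_units(self) -> list:
        return self.table.loc[self.table["significant"], "unit"].tolist()

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def _contrast_masks(table: MorphometryTable, subtype_of: dict, contrast: str):
    groups = table.groups
    sids = table.subject_ids
    is_control = groups == "control"
    if contrast == "all-patients-vs-controls":
        mask_a = groups == "patient"
    elif contrast in ("subtype1-vs-controls", "subtype2-vs-controls"):
        want = int(contrast[7])
        mask_a = np.array(
            [groups[i] == "patient" and subtype_of.get(sids[i]) == want for i in range(len(sids))]
        )
    else:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    return mask_a, is_control


def roi_group_test(
    table: MorphometryTable,
    subset_labels: pd.DataFrame | None,
    contrast: str,
    alpha: float = 0.05,
    variant: str = "pooled",
) -> StatResult:
    """Per-region t-tests of one patient subset against all controls.

    ``subset_labels`` maps patients to integer subtypes (columns
    ``subject_id``, ``subtype``); it may be None for the whole-group
    contrast.  BH-FDR is applied across regions at level ``alpha``.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    subtype_of: dict = {}
    if subset_labels is not None:
        subtype_of = dict(
            zip(subset_labels["subject_id"].astype(str), subset_labels["subtype"].astype(int))
        )
    if contrast.startswith("subtype") and subtype_of:
        want = int(contrast[7])
        if want not in set(subtype_of.values()):
            raise ValueError(f"unknown subtype label {want} in contrast {contrast!r}")
    mask_a, mask_b = _contrast_masks(table, subtype_of, contrast)
    if not mask_a.any():
        raise ValueError(f"contrast {contrast!r}: no subjects in the patient subset")
    if not mask_b.any():
        raise ValueError("no controls in the table")
    V = table.volumes
    rows = []
    for j, region in enumerate(table.region_ids):
        t, df, p = two_sample_t(V[mask_a, j], V[mask_b, j], variant=variant)
        d = cohens_d_from_samples(V[mask_a, j], V[mask_b, j])
        rows.append({"unit": region, "t": t, "df": df, "p": p, "d": d})
    out = pd.DataFrame(rows)
    q, reject = bh_fdr(out["p"].to_numpy(), alpha=alpha)
    out["q"] = q
    out["significant"] = reject
    return StatResult(
        table=out,
        contrast=contrast,
        alpha=alpha,
        n_group_a=int(mask_a.sum()),
        n_group_b=int(mask_b.sum()),
        metadata={"variant": variant, "level": "roi"},
    )


# --------------------------------------------------------------------------
# Voxel-level group test


@dataclass
class StatMapResult:
    t_map: np.ndarray
    d_map: np.ndarray
    q_map: np.ndarray
    mask: np.ndarray  # surviving voxels after FDR + extent filter
    clusters: pd.DataFrame
    affine: np.ndarray
    alpha: float
    min_cluster: int
    connectivity: int

    @property
    def n_significant_voxels(self) -> int:
        return int(self.mask.sum())


def voxelwise_group_test(
    subject_volumes: np.ndarray,
    groups,
    alpha: float = 0.05,
    min_cluster: int = 40,
    connectivity: int = 26,
    analysis_mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
    variant: str = "pooled",
    out_dir: str | Path | None = None,
) -> StatMapResult:
    """Mass-univariate voxel-wise comparison of two groups of volumes.

    ``subject_volumes`` is (n_subjects, x, y, z); ``groups`` holds 1 for the
    test group and 0 for the reference group.  Per-voxel pooled t-tests,
    BH-FDR over in-mask voxels, then the strict > ``min_cluster`` extent
    filter.  If ``out_dir`` is given, t, d and q maps are written as NIfTI.
    """
    vols = np.asarray(subject_volumes, dtype=float)
    groups = np.asarray(groups)
    if vols.ndim != 4:
        raise ValueError(f"subject_volumes must be 4D, got shape {vols.shape}")
    if len(groups) != vols.shape[0]:
        raise ValueError("one group label per subject volume required")
    if affine is None:
        affine = np.eye(4)
    shape = vols.shape[1:]
    if analysis_mask is None:
        analysis_mask = np.ones(shape, dtype=bool)
    elif analysis_mask.shape != shape:
        raise ValueError(
            f"geometry mismatch: mask {analysis_mask.shape} vs volumes {shape}"
        )
    a = vols[groups == 1]
    b = vols[groups == 0]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two subjects")

    flat_mask = analysis_mask.reshape(-1)
    A = a.reshape(len(a), -1)[:, flat_mask]
    B = b.reshape(len(b), -1)[:, flat_mask]
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    var_a, var_b = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
    na, nb = len(a), len(b)
    if variant == "pooled":
        sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (mean_a - mean_b) / np.sqrt(sp2 * (1 / na + 1 / nb))
        df = np.full(t.shape, na + nb - 2.0)
    elif variant == "welch":
        se2 = var_a / na + var_b / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (mean_a - mean_b) / np.sqrt(se2)
            df = se2**2 / (
                (var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1)
            )
    else:
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    # zero-variance conventions
    both_const = (var_a == 0) & (var_b == 0)
    t = np.where(both_const & (mean_a == mean_b), 0.0, t)
    t = np.where(
        both_const & (mean_a != mean_b), np.sign(mean_a - mean_b) * np.inf, t
    )
    p = np.where(np.isinf(t), 0.0, 2 * stats.t.sf(np.abs(np.where(np.isinf(t), 0, t)), df))
    p = np.where(t == 0, np.where(both_const, 1.0, p), p)

    with np.errstate(divide="ignore", invalid="ignore"):
        pooled_sd = np.sqrt(((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2))
        d = np.where(pooled_sd > 0, (mean_a - mean_b) / pooled_sd, 0.0)

    q, reject = bh_fdr(p, alpha=alpha)

    t_map = np.zeros(shape)
    d_map = np.zeros(shape)
    q_map = np.ones(shape)
    sig = np.zeros(shape, dtype=bool)
    t_map.reshape(-1)[flat_mask] = t
    d_map.reshape(-1)[flat_mask] = d
    q_map.reshape(-1)[flat_mask] = q
    sig.reshape(-1)[flat_mask] = reject

    final_mask, clusters = cluster_extent_filter(
        sig, min_size=min_cluster, connectivity=connectivity, stat=t_map
    )
    result = StatMapResult(
        t_map=t_map, d_map=d_map, q_map=q_map, mask=final_mask, clusters=clusters,
        affine=affine, alpha=alpha, min_cluster=min_cluster, connectivity=connectivity,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_stat_map(t_map, affine, out_dir / "tmap.nii.gz")
        write_stat_map(d_map, affine, out_dir / "dmap.nii.gz")
        write_stat_map(q_map, affine, out_dir / "qmap.nii.gz")
        write_stat_map(final_mask.astype(np.float32), affine, out_dir / "sigmask.nii.gz")
        clusters.to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
    return result
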