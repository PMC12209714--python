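"""Robustness checks for a subtyping solution.

Two procedures: (1) cross-parcellation agreement — re-run the full
subtyping on the same subjects expressed in a different atlas and count how
many patients land in the same (aligned) subtype; (2) split-half
consistency — split the cohort into two stratified halves, subtype each
half independently, and compare each half's patient labels with the
full-data solution.  Agreement is computed over patients only, since
controls are never clustered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from neurosubtype.io import MorphometryTable, MorphometryTable as _Table
from neurosubtype.subtyping import (
    SubtypingConfig,
    adjusted_rand_index,
    align_labels,
    relabel,
    subtype_cohort,
)

__all__ = [
    "AgreementReport",
    "align_labels",
    "agreement",
    "agreement_permutation_p",
    "cross_parcellation_agreement",
    "split_half_consistency",
]


@dataclass
class AgreementReport:
    """Per-subject concordance between two (aligned) subtype labelings."""

    n_compared: int
    n_consistent: int
    permutation: dict[int, int]
    concordant: np.ndarray  # bool per compared subject
    subject_ids: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def fraction_consistent(self) -> float:
        return self.n_consistent / self.n_compared if self.n_compared else float("nan")

    def as_dict(self) -> dict:
        return {
            "n_compared": self.n_compared,
            "n_consistent": self.n_consistent,
            "fraction_consistent": self.fraction_consistent,
            "permutation": {str(k): v for k, v in sorted(self.permutation.items())},
        }


def agreement(labels_a, labels_b, subject_ids=None) -> AgreementReport:
    """Align b to a by the best label permutation and count exact matches."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    perm = align_labels(a, b)
    aligned = relabel(b, perm)
    flags = aligned == a
    if subject_ids is None:
        subject_ids = np.arange(len(a))
    return AgreementReport(
        n_compared=len(a),
        n_consistent=int(flags.sum()),
        permutation=perm,
        concordant=flags,
        subject_ids=np.asarray(subject_ids),
    )


def agreement_permutation_p(
    labels_a, labels_b, n_permutations: int = 999, seed: int = 0
) -> float:
    """Permutation p-value for aligned agreement exceeding chance.

    The observed best-permutation match fraction is compared with the null
    distribution obtained by shuffling one labeling.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(labels_a)
    b = np.asarray(labels_b).copy()
    observed = agreement(a, b).fraction_consistent
    hits = 0
    for _ in range(n_permutations):
        rng.shuffle(b)
        if agreement(a, b).fraction_consistent >= observed:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def cross_parcellation_agreement(
    table_a: MorphometryTable,
    table_b: MorphometryTable,
    config: SubtypingConfig | None = None,
) -> AgreementReport:
    """Subtype the same subjects under two parcellations and compare.

    Both tables get a complete, independent subtyping run (covariate
    adjustment, stability profiling, consensus labeling) with the same
    hyperparameters; the patient labelings are then aligned and per-subject
    concordance reported.
    """
    ids_a = set(table_a.subject_ids)
    ids_b = set(table_b.subject_ids)
    if ids_a != ids_b:
        raise ValueError(
            f"subject mismatch between tables: {len(ids_a ^ ids_b)} differing IDs"
        )
    config = config or SubtypingConfig()
    res_a = subtype_cohort(table_a, config)
    res_b = subtype_cohort(table_b, config)
    # align patient order of b to a
    order = {sid: i for i, sid in enumerate(res_b.patient_ids)}
    idx = np.array([order[sid] for sid in res_a.patient_ids])
    return agreement(
        res_a.consensus_labels,
        res_b.consensus_labels[idx],
        subject_ids=res_a.patient_ids,
    )


def _stratified_split(table: MorphometryTable, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random half-split stratified by group, sizes as equal as possible."""
    rng = np.random.default_rng(seed)
    half1 = []
    half2 = []
    groups = table.groups
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        rng.shuffle(idx)
        half1.extend(idx[: len(idx) // 2].tolist())
        half2.extend(idx[len(idx) // 2 :].tolist())
    return np.sort(np.asarray(half1)), np.sort(np.asarray(half2))


def split_half_consistency(
    table: MorphometryTable,
    config: SubtypingConfig | None = None,
    seed: int = 0,
) -> tuple[AgreementReport, AgreementReport]:
    """Subtype two stratified halves and compare each with the full run.

    Each half re-runs the entire subtyping with the main run's
    hyperparameters; its patient labels are aligned against the full-data
    consensus labels restricted to that half's patients.
    """
    config = config or SubtypingConfig()
    full = subtype_cohort(table, config)
    full_labels = dict(zip(full.patient_ids, full.consensus_labels))

    idx1, idx2 = _stratified_split(table, seed)
    reports = []
    for half_idx in (idx1, idx2):
        sub = _Table(
            data=table.data.iloc[half_idx].reset_index(drop=True),
            parcellation_name=table.parcellation_name,
        )
        if not sub.is_patient.any() or sub.is_patient.all():
            raise ValueError("a half-split lacks patients or controls")
        res = subtype_cohort(sub, config)
        ref = np.array([full_labels[sid] for sid in res.patient_ids])
        reports.append(agreement(ref, res.consensus_labels, subject_ids=res.patient_ids))
    return reports[0], reports[1]
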