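"""Semi-supervised max-margin polytope subtyping.

Patients are separated from controls by K linear max-margin classifiers
("faces") whose positive half-spaces jointly form a convex polytope around
the control distribution: each face is a soft-margin linear discriminant in
which every control enters with weight 1/K on the negative side and each
patient enters only the face it is currently assigned to on the positive
side.  Fitting alternates between (i) refitting the K faces given the
current patient assignments and (ii) reassigning every patient to the face
it is closest to — the face with maximal margin-normalized signed score
(w.x + b)/||w|| — until the assignment is stable.  The patient partition
induced by the faces is the subtyping.

The number of faces K is selected by clustering *stability*: for each K the
model is refit on the training portion of each cross-validation fold, the
full patient set is assigned with every fold's model, and the mean pairwise
adjusted Rand index (ARI) across folds is recorded; the K with the highest
mean ARI wins.

Before clustering, region volumes are adjusted for nuisance covariates
(age, total intracranial volume) by least squares fits estimated on
controls only, then standardized by the control mean and SD, so patient
deviations are expressed relative to the normative control distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import comb
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.svm import LinearSVC

from neurosubtype.io import MorphometryTable

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Covariate adjustment


@dataclass
class FeatureMatrix:
    """Covariate-adjusted, control-standardized region volumes.

    ``labels`` is +1 for patients, -1 for controls.  After adjustment the
    control rows of ``X`` have (approximately) zero mean and unit SD per
    feature.
    """

    X: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    region_ids: list[str]
    parcellation_name: str = "unnamed"
    betas: np.ndarray | None = None  # (n_covariates + 1, n_regions) incl. intercept
    covariate_names: tuple[str, ...] = ()

    @property
    def patient_mask(self) -> np.ndarray:
        return self.labels == 1

    @property
    def X_patients(self) -> np.ndarray:
        return self.X[self.patient_mask]

    @property
    def X_controls(self) -> np.ndarray:
        return self.X[~self.patient_mask]

    @property
    def patient_ids(self) -> np.ndarray:
        return self.subject_ids[self.patient_mask]

    def subset(self, row_mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X[row_mask],
            labels=self.labels[row_mask],
            subject_ids=self.subject_ids[row_mask],
            region_ids=self.region_ids,
            parcellation_name=self.parcellation_name,
            betas=self.betas,
            covariate_names=self.covariate_names,
        )


def residualize_covariates(
    table: MorphometryTable, covariate_names: tuple[str, ...] = ("age", "tiv")
) -> FeatureMatrix:
    """Remove covariate effects and standardize against controls.

    Per region, volume is regressed on the covariates (with intercept) using
    **controls only**, so that disease-related volume differences are not
    absorbed into the adjustment; the fitted effect is subtracted from all
    subjects and the residuals are scaled by the control residual SD.
    """
    is_control = ~table.is_patient
    n_controls = int(is_control.sum())
    if n_controls < len(covariate_names) + 2:
        raise ValueError(
            f"need at least {len(covariate_names) + 2} controls to fit "
            f"{len(covariate_names)} covariates, got {n_controls}"
        )
    C = table.covariate_matrix(covariate_names)
    for j, name in enumerate(covariate_names):
        if np.std(C[is_control, j]) == 0:
            raise ValueError(f"covariate '{name}' is constant among controls")
    V = table.volumes
    design = np.column_stack([np.ones(len(C)), C])
    betas, *_ = np.linalg.lstsq(design[is_control], V[is_control], rcond=None)
    resid = V - design @ betas
    mu = resid[is_control].mean(axis=0)
    sd = resid[is_control].std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    X = (resid - mu) / sd
    labels = np.where(table.is_patient, 1, -1)
    return FeatureMatrix(
        X=X,
        labels=labels,
        subject_ids=table.subject_ids,
        region_ids=table.region_ids,
        parcellation_name=table.parcellation_name,
        betas=betas,
        covariate_names=tuple(covariate_names),
    )


# --------------------------------------------------------------------------
# Polytope model


@dataclass
class PolytopeModel:
    """K face (weight, bias) pairs plus fitting metadata."""

    K: int
    W: np.ndarray  # (K, n_features)
    b: np.ndarray  # (K,)
    C: float
    seed: int
    n_restarts: int
    objective: float
    converged: bool
    n_iter: int
    objective_history: list[float] = field(default_factory=list)

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Margin-normalized signed score per face: (w.x + b)/||w||.

        Normalizing by the face norm makes the score a signed distance to
        the hyperplane, so "maximal score" means "closest face on the
        positive side"; faces with an all-zero weight vector (never produced
        by fitting) score at the raw offset.
        """
        if X.shape[1] != self.W.shape[1]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model "
                f"dimension {self.W.shape[1]}"
            )
        norms = np.linalg.norm(self.W, axis=1)
        norms = np.where(norms > 0, norms, 1.0)
        return (X @ self.W.T + self.b) / norms


@dataclass
class Assignment:
    """Patient-to-face assignment with per-face signed scores.

    Labels are 1-based face indices; ties in the maximal score are broken
    toward the lowest face index.
    """

    labels: np.ndarray  # (n_patients,), values in 1..K
    scores: np.ndarray  # (n_patients, K)
    subject_ids: np.ndarray


def assign(model: PolytopeModel, X: np.ndarray, subject_ids: np.ndarray | None = None) -> Assignment:
    """Assign each row of X to the face with maximal signed score."""
    S = model.scores(np.atleast_2d(X))
    labels = np.argmax(S, axis=1) + 1  # argmax takes the first (lowest) on ties
    if subject_ids is None:
        subject_ids = np.arange(len(labels))
    return Assignment(labels=labels, scores=S, subject_ids=np.asarray(subject_ids))


def _fit_face(X_pos, X_neg, C, K, random_state):
    """One face: weighted soft-margin linear discriminant (hinge loss).

    Patients on the positive side with weight 1, all controls on the
    negative side with weight 1/K each.
    """
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(len(X_pos)), -np.ones(len(X_neg))])
    w = np.concatenate([np.ones(len(X_pos)), np.full(len(X_neg), 1.0 / K)])
    clf = LinearSVC(
        C=C,
        loss="hinge",
        fit_intercept=True,
        intercept_scaling=10.0,
        tol=1e-4,
        max_iter=5000,
        random_state=random_state,
    )
    clf.fit(X, y, sample_weight=w)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def _objective(W, b, X_p, X_c, patient_labels, C, K):
    """0.5*sum ||w_k||^2 + C * weighted hinge losses over all faces."""
    obj = 0.5 * float(np.sum(W * W))
    S_p = X_p @ W.T + b
    S_c = X_c @ W.T + b
    for k in range(K):
        mine = patient_labels == k + 1
        obj += C * float(np.sum(np.maximum(0.0, 1.0 - S_p[mine, k])))
        obj += C / K * float(np.sum(np.maximum(0.0, 1.0 + S_c[:, k])))
    return obj


def _soft_threshold(diff: np.ndarray, n1: int, n2: int, factor: float = 1.5) -> np.ndarray:
    """Soft-threshold a mean-difference vector at ``factor`` standard errors.

    Features are control-standardized (unit SD), so the SE of a mean
    difference is sqrt(1/n1 + 1/n2) per feature.  Shrinking small entries
    to zero denoises the group-difference direction in the
    nearest-shrunken-centroid sense, which matters when the feature count
    exceeds the subject count.
    """
    tau = factor * np.sqrt(1.0 / n1 + 1.0 / n2)
    return np.sign(diff) * np.maximum(np.abs(diff) - tau, 0.0)


def _shrunken_discriminant_init(X_p, X_c, K, seed, factor=1.0, n_refine=6):
    """Patient split seeded by shrunken patient-vs-control directions.

    Start from a k-means split of the patients projected onto the
    soft-thresholded patient-minus-control mean direction, then refine:
    re-estimate one shrunken direction per current cluster, project every
    patient onto all K directions, and re-cluster; repeat until stable.
    A cluster member's projection onto its own cluster's direction is
    computed leave-one-out (the direction is re-estimated without that
    patient), which removes the self-bias that otherwise inflates the
    projections of exactly the patients that defined the direction.
    """
    n_p, n_c = len(X_p), len(X_c)
    mc = X_c.mean(0)
    w = _soft_threshold(X_p.mean(0) - mc, n_p, n_c, factor)
    if not np.linalg.norm(w):
        w = X_p.mean(0) - mc
    w = w / max(np.linalg.norm(w), 1e-12)
    labels = KMeans(K, n_init=10, random_state=seed).fit_predict((X_p @ w).reshape(-1, 1)) + 1
    for _ in range(n_refine):
        P = np.empty((n_p, K))
        for k in range(1, K + 1):
            mine = labels == k
            nk = int(mine.sum())
            if nk < 2:
                P[:, k - 1] = X_p @ w
                continue
            s = X_p[mine].sum(0)
            # shared direction for non-members
            d_all = _soft_threshold(s / nk - mc, nk, n_c, factor)
            if not np.linalg.norm(d_all):
                d_all = s / nk - mc
            d_all = d_all / max(np.linalg.norm(d_all), 1e-12)
            P[:, k - 1] = X_p @ d_all
            # leave-one-out directions for members
            MU = (s[None, :] - X_p[mine]) / (nk - 1)
            D = _soft_threshold(MU - mc, nk - 1, n_c, factor)
            zero = ~D.any(axis=1)
            D[zero] = (MU - mc)[zero]
            norms = np.maximum(np.linalg.norm(D, axis=1), 1e-12)
            P[mine, k - 1] = np.einsum("ij,ij->i", X_p[mine], D / norms[:, None])
        new = KMeans(K, n_init=10, random_state=seed).fit_predict(P) + 1
        if np.array_equal(new, labels):
            break
        labels = new
    return labels


def _initial_assignments(X_p, X_c, K, n_restarts, rng, kmeans_seed):
    """Initial patient splits for the restarts.

    The first restarts are informed: two shrunken-discriminant splits with
    different k-means seeds, a k-means split in a low-rank principal
    subspace of the patients, and a k-means split of the raw features.  Any
    remaining restarts are random assignments with every face nonempty.
    """
    if K == 1:
        return [np.ones(len(X_p), dtype=int) for _ in range(max(1, n_restarts))]
    inits = [_shrunken_discriminant_init(X_p, X_c, K, seed=kmeans_seed)]
    if n_restarts > 1:
        inits.append(_shrunken_discriminant_init(X_p, X_c, K, seed=kmeans_seed + 101))
    if n_restarts > 2:
        n_comp = min(max(K, 2), X_p.shape[0] - 1, X_p.shape[1])
        Z = PCA(n_components=n_comp, random_state=kmeans_seed).fit_transform(X_p)
        inits.append(KMeans(K, n_init=10, random_state=kmeans_seed).fit_predict(Z) + 1)
    if n_restarts > 3:
        inits.append(KMeans(K, n_init=10, random_state=kmeans_seed).fit_predict(X_p) + 1)
    for _ in range(n_restarts - len(inits)):
        lab = rng.integers(1, K + 1, len(X_p))
        # ensure every face starts nonempty
        for k in range(1, K + 1):
            if not (lab == k).any():
                lab[rng.integers(0, len(lab))] = k
        inits.append(lab)
    return inits


def fit_polytope(
    features: FeatureMatrix,
    K: int,
    C: float = 1.0,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 50,
) -> tuple[PolytopeModel, Assignment]:
    """Fit the K-face polytope by alternating optimization with restarts.

    Across ``n_restarts`` initializations (a k-means split of the patients
    plus random assignments) the solution with the lowest regularized-hinge
    objective is returned.  Deterministic given ``(seed, n_restarts)``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    X_p = features.X_patients
    X_c = features.X_controls
    if len(X_p) < K:
        raise ValueError(f"K={K} exceeds the number of patients ({len(X_p)})")
    if len(X_c) == 0:
        raise ValueError("no controls in the feature matrix")
    if not (np.isfinite(X_p).all() and np.isfinite(X_c).all()):
        raise ValueError("non-finite values in features")

    rng = np.random.default_rng(seed)
    inits = _initial_assignments(X_p, X_c, K, n_restarts, rng, kmeans_seed=seed)

    def _distance_scores(W, b):
        norms = np.linalg.norm(W, axis=1)
        norms = np.where(norms > 0, norms, 1.0)
        return (X_p @ W.T + b) / norms

    solutions = []
    for r, labels in enumerate(inits):
        labels = labels.copy()
        converged = False
        W = np.zeros((K, X_p.shape[1]))
        b = np.zeros(K)
        n_iter = 0
        history = []
        for n_iter in range(1, max_iter + 1):
            for k in range(K):
                mine = labels == k + 1
                if not mine.any():
                    # re-seed an empty face with the patient of lowest
                    # assigned-score margin so all K faces stay live
                    S = _distance_scores(W, b)
                    worst = int(np.argmin(S[np.arange(len(labels)), labels - 1]))
                    labels[worst] = k + 1
                    mine = labels == k + 1
                    logger.debug("restart %d iter %d: re-seeded empty face %d", r, n_iter, k + 1)
                W[k], b[k] = _fit_face(X_p[mine], X_c, C, K, random_state=seed)
            new_labels = np.argmax(_distance_scores(W, b), axis=1) + 1
            history.append(_objective(W, b, X_p, X_c, new_labels, C, K))
            if np.array_equal(new_labels, labels):
                converged = True
                break
            labels = new_labels
        obj = _objective(W, b, X_p, X_c, labels, C, K)
        solutions.append((obj, W, b, labels, converged, n_iter, history))

    # Restart selection by stability: the margin objective has spurious
    # optima when features outnumber subjects, so the solution agreeing most
    # with the other restarts (mean pairwise ARI) is kept; the objective
    # only breaks ties.
    if len(solutions) == 1:
        best = solutions[0]
    else:
        mean_agreement = [
            np.mean(
                [
                    adjusted_rand_index(solutions[i][3], solutions[j][3])
                    for j in range(len(solutions))
                    if j != i
                ]
            )
            for i in range(len(solutions))
        ]
        order = sorted(
            range(len(solutions)), key=lambda i: (-mean_agreement[i], solutions[i][0])
        )
        best = solutions[order[0]]

    obj, W, b, labels, converged, n_iter, history = best
    model = PolytopeModel(
        K=K, W=W, b=b, C=C, seed=seed, n_restarts=n_restarts,
        objective=obj, converged=converged, n_iter=n_iter,
        objective_history=history,
    )
    assignment = Assignment(
        labels=labels, scores=model.scores(X_p), subject_ids=features.patient_ids
    )
    return model, assignment


# --------------------------------------------------------------------------
# Adjusted Rand index


def adjusted_rand_index(partition_a, partition_b) -> float:
    """Chance-corrected partition agreement via the contingency-table form.

    Returns 1.0 for identical partitions, including the degenerate case of
    a single cluster on both sides (where the chance correction is 0/0).
    """
    a = np.asarray(partition_a)
    b = np.asarray(partition_b)
    if a.size == 0:
        raise ValueError("empty partitions")
    if a.shape != b.shape:
        raise ValueError(f"partition length mismatch: {a.shape} vs {b.shape}")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    n = a.size
    cont = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)
    sum_comb = comb(cont, 2).sum()
    sum_a = comb(cont.sum(axis=1), 2).sum()
    sum_b = comb(cont.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        # both partitions put everything in one cluster (or n == 1)
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


# --------------------------------------------------------------------------
# Label alignment and consensus


def align_labels(partition_a, partition_b) -> dict[int, int]:
    """Permutation of b's labels maximizing exact matches with a.

    Solved as an optimal assignment on the label contingency table.  Labels
    present in only one partition are mapped injectively but arbitrarily.
    Returns a mapping ``{label_in_b: aligned_label}``.
    """
    a = np.asarray(partition_a)
    b = np.asarray(partition_b)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same subjects")
    labs_a = np.unique(a)
    labs_b = np.unique(b)
    size = max(len(labs_a), len(labs_b))
    cont = np.zeros((size, size))
    for i, lb in enumerate(labs_b):
        for j, la in enumerate(labs_a):
            cont[i, j] = np.sum((b == lb) & (a == la))
    rows, cols = linear_sum_assignment(-cont)
    mapping = {}
    spare = [int(la) for la in labs_a] + list(
        range(int(labs_a.max(initial=0)) + 1, int(labs_a.max(initial=0)) + 1 + size)
    )
    for i, j in zip(rows, cols):
        if i < len(labs_b):
            mapping[int(labs_b[i])] = int(labs_a[j]) if j < len(labs_a) else spare[j]
    return mapping


def relabel(partition, mapping: dict[int, int]) -> np.ndarray:
    return np.asarray([mapping[int(v)] for v in partition])


def consensus_assignment(assignments: list[Assignment]) -> np.ndarray:
    """Majority-vote consensus of several assignments of the same patients.

    Every labeling is first aligned to the first one by its best label
    permutation; per-patient ties in the vote go to the lowest aligned
    label.
    """
    if not assignments:
        raise ValueError("need at least one assignment")
    ref = assignments[0]
    for a in assignments[1:]:
        if not np.array_equal(a.subject_ids, ref.subject_ids):
            raise ValueError("assignments cover inconsistent patient sets")
    aligned = [ref.labels]
    for a in assignments[1:]:
        aligned.append(relabel(a.labels, align_labels(ref.labels, a.labels)))
    stacked = np.stack(aligned)  # (n_assignments, n_patients)
    out = np.empty(stacked.shape[1], dtype=int)
    for j in range(stacked.shape[1]):
        vals, counts = np.unique(stacked[:, j], return_counts=True)
        out[j] = vals[np.argmax(counts)]  # ties -> lowest label (unique is sorted)
    return out


# --------------------------------------------------------------------------
# Stability profiling


@dataclass
class StabilityProfile:
    """Mean cross-validated pairwise ARI per candidate K, and the winner."""

    ks: list[int]
    mean_ari: list[float]
    n_folds: int
    selected_K: int
    fold_assignments: dict[int, list[Assignment]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "ks": self.ks,
            "mean_ari": self.mean_ari,
            "n_folds": self.n_folds,
            "selected_K": self.selected_K,
        }


def _stratified_folds(labels: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Group-stratified fold indices (list of test-index arrays)."""
    folds = [[] for _ in range(n_folds)]
    for value in np.unique(labels):
        idx = np.flatnonzero(labels == value)
        rng.shuffle(idx)
        for i, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[i].extend(chunk.tolist())
    return [np.sort(np.asarray(f)) for f in folds]


def stability_profile(
    features: FeatureMatrix,
    K_range=range(2, 11),
    n_folds: int = 5,
    C: float = 1.0,
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 30,
) -> StabilityProfile:
    """Cross-validated ARI stability over a range of cluster numbers.

    For each K the polytope is refit on the training portion of each fold
    (folds stratified by patient/control status), the *full* patient set is
    assigned with each fold's model, and the mean ARI over all fold pairs is
    recorded.  ``selected_K`` is the argmax of the mean ARI, with ties going
    to the smallest K.
    """
    ks = list(K_range)
    if not ks:
        raise ValueError("K_range is empty")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    test_folds = _stratified_folds(features.labels, n_folds, rng)
    n = len(features.labels)
    for f, test_idx in enumerate(test_folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        if not (features.labels[train_mask] == 1).any() or not (
            features.labels[train_mask] == -1
        ).any():
            raise ValueError(f"fold {f} training set lacks patients or controls")

    mean_ari = []
    fold_assignments: dict[int, list[Assignment]] = {}
    X_p_full = features.X_patients
    pids = features.patient_ids
    for K in ks:
        assignments = []
        for f, test_idx in enumerate(test_folds):
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            sub = features.subset(train_mask)
            model, _ = fit_polytope(
                sub, K, C=C, seed=seed + 1000 * f, n_restarts=n_restarts,
                max_iter=max_iter,
            )
            assignments.append(assign(model, X_p_full, subject_ids=pids))
        aris = [
            adjusted_rand_index(assignments[i].labels, assignments[j].labels)
            for i in range(n_folds)
            for j in range(i + 1, n_folds)
        ]
        mean_ari.append(float(np.mean(aris)))
        fold_assignments[K] = assignments
        logger.info("K=%d mean pairwise ARI = %.3f", K, mean_ari[-1])

    selected = ks[int(np.argmax(mean_ari))]  # argmax keeps the smallest K on ties
    return StabilityProfile(
        ks=ks, mean_ari=mean_ari, n_folds=n_folds, selected_K=selected,
        fold_assignments=fold_assignments,
    )


# --------------------------------------------------------------------------
# End-to-end subtyping of one table


@dataclass
class SubtypingConfig:
    """Hyperparameters of a full subtyping run."""

    covariates: tuple[str, ...] = ("age", "tiv")
    k_range: tuple[int, ...] = tuple(range(2, 11))
    n_folds: int = 5
    C: float = 1.0
    n_restarts: int = 10
    cv_restarts: int = 3
    max_iter: int = 50
    seed: int = 0


@dataclass
class SubtypingResult:
    profile: StabilityProfile
    model: PolytopeModel
    assignment: Assignment
    consensus_labels: np.ndarray
    features: FeatureMatrix

    @property
    def patient_ids(self) -> np.ndarray:
        return self.assignment.subject_ids


def subtype_cohort(table: MorphometryTable, config: SubtypingConfig | None = None) -> SubtypingResult:
    """Full subtyping of one cohort: adjust, profile K, fit, consensus.

    The final labeling is the majority-vote consensus of the selected-K
    fold-wise assignments together with a full-data fit (which also supplies
    the returned model).
    """
    config = config or SubtypingConfig()
    features = residualize_covariates(table, config.covariates)
    profile = stability_profile(
        features,
        K_range=config.k_range,
        n_folds=config.n_folds,
        C=config.C,
        seed=config.seed,
        n_restarts=config.cv_restarts,
        max_iter=config.max_iter,
    )
    K = profile.selected_K
    model, full_assignment = fit_polytope(
        features, K, C=config.C, seed=config.seed,
        n_restarts=config.n_restarts, max_iter=config.max_iter,
    )
    consensus = consensus_assignment(
        [full_assignment] + profile.fold_assignments[K]
    )
    return SubtypingResult(
        profile=profile,
        model=model,
        assignment=full_assignment,
        consensus_labels=consensus,
        features=features,
    )
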