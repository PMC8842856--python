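"""Unsupervised profile discovery.

Pipeline: z-score standardization of the 13 clinical variables, principal
component analysis on the correlation matrix, k-medoids (PAM, BUILD + SWAP)
on the retained component scores with Euclidean distance, gap-statistic
selection of the number of clusters, and a deterministic mapping from
arbitrary cluster ids to the canonical profile numbering 1-4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from copd_profiles.schema import CLUSTERING_VARIABLES


@dataclass(frozen=True)
class ScalingParams:
    """Column means and population standard deviations used for z-scoring."""

    columns: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.means) / self.sds


@dataclass(frozen=True)
class PCAModel:
    """Eigen-decomposition of the correlation matrix of standardized data."""

    scaling: ScalingParams
    eigenvalues: np.ndarray   # descending; sums to the number of variables
    eigenvectors: np.ndarray  # columns are components
    scores: np.ndarray        # standardized data projected on all components

    def transform(self, matrix: np.ndarray, n_components: int | None = None) -> np.ndarray:
        z = self.scaling.apply(matrix)
        v = self.eigenvectors if n_components is None else self.eigenvectors[:, :n_components]
        return z @ v


@dataclass(frozen=True)
class ClusterModel:
    """A PAM solution: medoid rows, assignments and the dissimilarity objective."""

    k: int
    medoid_indices: np.ndarray  # sorted row indices into the clustered matrix
    labels: np.ndarray          # cluster id = position in medoid_indices
    objective: float            # sum of distances of points to their medoid
    metric: str = "euclidean"


@dataclass(frozen=True)
class GapResult:
    """Gap curve and the one-standard-error choice of k."""

    k_values: tuple[int, ...]
    log_dispersion: np.ndarray       # log W_k, observed
    reference_log_dispersion: np.ndarray  # E*[log W_k] under the null
    gap: np.ndarray
    standard_error: np.ndarray       # s_k = sd_k * sqrt(1 + 1/B)
    selected_k: int
    rule: str = "tibshirani"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "log_w": self.log_dispersion,
                "ref_log_w": self.reference_log_dispersion,
                "gap": self.gap,
                "se": self.standard_error,
            }
        )


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def standardize(data) -> tuple[np.ndarray, ScalingParams]:
    """Z-score each column (population SD). Errors name the offending column
    for zero variance and the row/column for missing values."""
    matrix, columns = _as_matrix(data)
    if not np.isfinite(matrix).all():
        row, col = np.argwhere(~np.isfinite(matrix))[0]
        raise ValueError(
            f"missing/non-finite value at row {row}, column '{columns[col]}'"
        )
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0)  # ddof=0: matches the correlation-matrix PCA below
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise ValueError(f"zero-variance column '{columns[zero[0]]}'")
    params = ScalingParams(columns=tuple(columns), means=means, sds=sds)
    return (matrix - means) / sds, params


def pca(scaled: np.ndarray, scaling: ScalingParams | None = None) -> PCAModel:
    """PCA via eigen-decomposition of the correlation matrix of pre-scaled data.

    Components are ordered by descending eigenvalue; each eigenvector's sign is
    fixed so its largest-magnitude loading is positive.
    """
    z = np.asarray(scaled, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("non-finite values in input")
    n, p = z.shape
    if n < p:
        warnings.warn(
            f"fewer rows ({n}) than variables ({p}); trailing eigenvalues are zero",
            stacklevel=2,
        )
    corr = z.T @ z / n
    eigenvalues, eigenvectors = np.linalg.eigh(corr)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    eigenvectors = eigenvectors[:, order]
    for j in range(p):
        i = np.argmax(np.abs(eigenvectors[:, j]))
        if eigenvectors[i, j] < 0:
            eigenvectors[:, j] = -eigenvectors[:, j]
    if scaling is None:
        scaling = ScalingParams(
            columns=tuple(f"x{i}" for i in range(p)),
            means=np.zeros(p),
            sds=np.ones(p),
        )
    return PCAModel(
        scaling=scaling,
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        scores=z @ eigenvectors,
    )


def select_components(model: PCAModel, variance_threshold: float = 0.80) -> int:
    """Smallest component count whose cumulative explained variance reaches the
    threshold (default 80%)."""
    if not (0.0 < variance_threshold <= 1.0):
        raise ValueError("variance_threshold must be in (0, 1]")
    total = model.eigenvalues.sum()
    cumulative = np.cumsum(model.eigenvalues) / total
    if variance_threshold == 1.0:
        return int(np.count_nonzero(model.eigenvalues > 1e-12))
    return int(np.searchsorted(cumulative, variance_threshold - 1e-12) + 1)


def select_components_kaiser(model: PCAModel) -> int:
    """Kaiser rule: retain components whose eigenvalue exceeds 1 (i.e. that
    explain more than one original variable's worth of variance). The default
    retention rule of the discovery pipeline: on weakly correlated clinical
    variables a fixed cumulative-variance cut drags in near-noise components
    that demonstrably blur the cluster structure."""
    return max(int(np.count_nonzero(model.eigenvalues > 1.0)), 1)


# ---------------------------------------------------------------------------
# PAM k-medoids
# ---------------------------------------------------------------------------

def _pam_build(distance: np.ndarray, k: int) -> list[int]:
    n = distance.shape[0]
    medoids = [int(np.argmin(distance.sum(axis=0)))]
    dmin = distance[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dmin[:, None] - distance, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        h = int(np.argmax(gains))  # ties: lowest index
        medoids.append(h)
        np.minimum(dmin, distance[:, h], out=dmin)
    return medoids


def _pam_swap(distance: np.ndarray, medoids: list[int], max_iter: int = 200) -> list[int]:
    n = distance.shape[0]
    medoids = sorted(medoids)
    for _ in range(max_iter):
        dm = distance[:, medoids]                      # n x k
        order = np.argsort(dm, axis=1, kind="stable")
        nearest = order[:, 0]
        d1 = dm[np.arange(n), nearest]
        d2 = dm[np.arange(n), order[:, 1]] if len(medoids) > 1 else np.full(n, np.inf)
        current = d1.sum()
        best_cost, best_swap = current - 1e-10, None
        for j in range(len(medoids)):
            without_j = np.where(nearest == j, d2, d1)
            costs = np.minimum(without_j[:, None], distance).sum(axis=0)
            costs[medoids] = np.inf
            h = int(np.argmin(costs))
            if costs[h] < best_cost:
                best_cost, best_swap = costs[h], (j, h)
        if best_swap is None:
            break
        j, h = best_swap
        medoids[j] = h
        medoids.sort()
    return medoids


def pam_kmedoids(points, k: int, seed: int | None = None) -> ClusterModel:
    """Classic PAM: greedy BUILD seeding then best-improvement SWAP passes.

    Both phases are deterministic (ties broken by lowest row index), so
    ``seed`` is accepted for interface uniformity but unused. Assignment ties
    go to the lowest medoid index.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty input")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > np.unique(x, axis=0).shape[0]:
        raise ValueError(f"k={k} exceeds the number of distinct rows")
    distance = cdist(x, x)
    medoids = _pam_build(distance, k)
    medoids = _pam_swap(distance, medoids)
    medoid_indices = np.asarray(sorted(medoids))
    labels = np.argmin(distance[:, medoid_indices], axis=1)
    objective = float(distance[np.arange(n), medoid_indices[labels]].sum())
    return ClusterModel(k=k, medoid_indices=medoid_indices, labels=labels, objective=objective)


def within_cluster_dispersion(points, labels) -> float:
    """Pooled within-cluster dispersion W_k.

    W_k = sum over clusters of (1 / (2 n_r)) * sum of squared Euclidean
    distances over *ordered* point pairs in the cluster — computed here via
    the algebraically identical within-cluster sum of squares about the
    centroid.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(labels)
    total = 0.0
    for lab in np.unique(labels):
        members = x[labels == lab]
        if members.shape[0] == 0:
            warnings.warn(f"empty cluster {lab} contributes 0", stacklevel=2)
            continue
        centroid = members.mean(axis=0)
        total += float(((members - centroid) ** 2).sum())
    return total


def _log_dispersion_curve(x: np.ndarray, k_values) -> np.ndarray:
    out = np.empty(len(k_values))
    for i, k in enumerate(k_values):
        if k == 1:
            labels = np.zeros(x.shape[0], dtype=int)
        else:
            labels = pam_kmedoids(x, k).labels
        w = within_cluster_dispersion(x, labels)
        out[i] = np.log(w) if w > 0 else -np.inf
    return out


def _select_k(gap: np.ndarray, se: np.ndarray, rule: str) -> int:
    n = len(gap)
    if rule == "tibshirani":
        # one-standard-error rule: smallest k with gap(k) >= gap(k+1) - s_{k+1}
        for i in range(n - 1):
            if gap[i] >= gap[i + 1] - se[i + 1]:
                return i + 1
        return n
    if rule == "globalmax":
        return int(np.argmax(gap)) + 1
    if rule == "firstSEmax":
        decreasing = np.diff(gap) < 0
        peak = int(np.argmax(decreasing)) if decreasing.any() else n - 1
        for i in range(peak):
            if gap[i] >= gap[peak] - se[peak]:
                return i + 1
        return peak + 1
    raise ValueError(f"unknown selection rule '{rule}'")


def gap_statistic(
    points,
    k_max: int = 8,
    n_references: int = 100,
    seed: int | None = None,
    rule: str = "tibshirani",
) -> GapResult:
    """Gap statistic with a principal-axis-aligned uniform reference.

    Reference sets are drawn uniformly over the bounding box of the data in
    its principal-component basis and rotated back (the recommended
    rotation-invariant null). By default k is chosen by the one-standard-error
    rule: the smallest k with gap(k) >= gap(k+1) - s_{k+1}. This rule is
    deliberately conservative and known to undershoot when the gap curve is
    flat or dips before its peak; ``rule='firstSEmax'`` and
    ``rule='globalmax'`` expose the usual alternatives.
    """
    if n_references < 10:
        raise ValueError("at least 10 reference draws required")
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    k_values = tuple(range(1, k_max + 1))
    if np.unique(x, axis=0).shape[0] == 1:
        warnings.warn("degenerate data (single distinct point); k=1", stacklevel=2)
        z = np.zeros(len(k_values))
        return GapResult(k_values, z, z, z, z, selected_k=1, rule=rule)

    rng = np.random.default_rng(seed)
    centre = x.mean(axis=0)
    _, _, vt = np.linalg.svd(x - centre, full_matrices=False)
    rotated = (x - centre) @ vt.T
    lo, hi = rotated.min(axis=0), rotated.max(axis=0)

    log_w = _log_dispersion_curve(x, k_values)
    ref_log_w = np.empty((n_references, len(k_values)))
    for b in range(n_references):
        sample = rng.uniform(lo, hi, size=rotated.shape) @ vt + centre
        ref_log_w[b] = _log_dispersion_curve(sample, k_values)

    ref_mean = ref_log_w.mean(axis=0)
    gap = ref_mean - log_w
    sd = ref_log_w.std(axis=0)
    se = sd * np.sqrt(1.0 + 1.0 / n_references)

    return GapResult(
        k_values=k_values,
        log_dispersion=log_w,
        reference_log_dispersion=ref_mean,
        gap=gap,
        standard_error=se,
        selected_k=_select_k(gap, se, rule),
        rule=rule,
    )


# ---------------------------------------------------------------------------
# Canonical profile numbering
# ---------------------------------------------------------------------------

def canonical_profile_mapping(model: ClusterModel, cohort: pd.DataFrame) -> dict[int, int]:
    """Map arbitrary cluster ids to the canonical profile numbering 1-4.

    Rule (consistent with the published per-profile medians — CAT 15/23/9/9,
    age 71/66/72/59, FEV1 41/47/69/62):

    * highest median CAT → profile 2 (ties broken by higher median HADS-A);
    * of the rest, lowest median age → profile 4;
    * of the remaining two, lower median FEV1 %pred → profile 1, other → 3.
    """
    clusters = np.unique(model.labels)
    if len(clusters) != 4:
        warnings.warn(
            f"canonical mapping expects 4 clusters, got {len(clusters)}; identity mapping",
            stacklevel=2,
        )
        return {int(c): int(c) for c in clusters}
    med = {
        int(c): {
            v: float(cohort.loc[np.asarray(model.labels) == c, v].median())
            for v in ("cat", "age", "fev1_pct", "hads_a")
        }
        for c in clusters
    }
    remaining = sorted(med)
    profile2 = max(remaining, key=lambda c: (med[c]["cat"], med[c]["hads_a"], -c))
    remaining.remove(profile2)
    profile4 = min(remaining, key=lambda c: (med[c]["age"], c))
    remaining.remove(profile4)
    profile1 = min(remaining, key=lambda c: (med[c]["fev1_pct"], c))
    remaining.remove(profile1)
    profile3 = remaining[0]
    return {profile2: 2, profile4: 4, profile1: 1, profile3: 3}


@dataclass(frozen=True)
class DiscoveryResult:
    """Everything the unsupervised stage produces for one cohort."""

    pca_model: PCAModel
    n_components: int
    gap: GapResult | None
    cluster_model: ClusterModel
    mapping: dict[int, int]
    assignments: pd.DataFrame = field(repr=False)


def discover_profiles(
    cohort: pd.DataFrame,
    k: int | None = None,
    k_max: int = 8,
    n_references: int = 100,
    variance_threshold: float | None = None,
    seed: int | None = None,
) -> DiscoveryResult:
    """Run the full unsupervised pipeline on a baseline cohort table.

    Components are retained by the Kaiser rule (eigenvalue > 1) unless a
    cumulative ``variance_threshold`` is given. If ``k`` is None the gap
    statistic chooses it; the canonical 1-4 profile numbering is attached when
    four clusters are found.
    """
    baseline = cohort[cohort["timepoint"] == 0] if "timepoint" in cohort else cohort
    scaled, scaling = standardize(baseline[CLUSTERING_VARIABLES])
    model = pca(scaled, scaling)
    if variance_threshold is None:
        m = select_components_kaiser(model)
    else:
        m = select_components(model, variance_threshold)
    scores = model.scores[:, :m]
    gap = None
    if k is None:
        gap = gap_statistic(scores, k_max=k_max, n_references=n_references, seed=seed)
        k = gap.selected_k
    clusters = pam_kmedoids(scores, k)
    mapping = canonical_profile_mapping(clusters, baseline)
    assignments = pd.DataFrame(
        {
            "participant_id": baseline["participant_id"].to_numpy(),
            "cluster": clusters.labels,
            "profile": [mapping[int(c)] for c in clusters.labels],
        }
    )
    return DiscoveryResult(
        pca_model=model,
        n_components=m,
        gap=gap,
        cluster_model=clusters,
        mapping=mapping,
        assignments=assignments,
    )
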