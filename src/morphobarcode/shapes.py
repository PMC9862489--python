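"""Shape variables, allometry, and Mahalanobis-based group discrimination.

The analysis chain implemented here follows the classical landmark
workflow for congeneric wing discrimination:

1. aligned coordinates from GPA are projected into the tangent space of
   the consensus and re-expressed as partial-warp scores (the
   thin-plate-spline bending-energy eigenbasis of the consensus) plus the
   two uniform (affine) components — together an orthonormal rotation of
   the tangent space, so no shape variation is lost;
2. principal components of these scores, truncated at a retained-variance
   threshold, are the final shape variables;
3. canonical variate analysis maximizes between-group relative to pooled
   within-group variance; pairwise Mahalanobis distances D between group
   means (computed with the pooled within-group covariance) quantify
   shape divergence, with significance from a label-permutation test and
   Bonferroni correction;
4. group structure is summarized as a hierarchical clustering tree on the
   D matrix with within-group bootstrap supports, and identification
   performance as a leave-one-out reclassification confusion matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.linalg
from scipy.spatial.distance import squareform

from .gpa import ShapeAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "ShapeVariables",
    "DiscriminantResult",
    "PermutationTestResult",
    "ClassificationReport",
    "AllometryResult",
    "ClusteringTree",
    "tangent_basis",
    "compute_shape_variables",
    "allometry_regression",
    "discriminant_analysis",
    "permutation_test_mahalanobis",
    "hierarchical_tree",
    "loo_classification",
]

_COND_LIMIT = 1e8


# ---------------------------------------------------------------------------
# Partial warps / tangent-space basis
# ---------------------------------------------------------------------------

def _bending_energy_matrix(consensus: np.ndarray) -> np.ndarray:
    """Bending-energy matrix of the thin-plate spline on the consensus."""
    p = consensus.shape[0]
    d2 = np.sum((consensus[:, None, :] - consensus[None, :, :]) ** 2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(d2 > 0, d2 * np.log(d2), 0.0)
    Q = np.column_stack([np.ones(p), consensus])
    L = np.zeros((p + 3, p + 3))
    L[:p, :p] = K
    L[:p, p:] = Q
    L[p:, :p] = Q.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError:
        raise ValueError(
            "singular bending-energy system: consensus has coincident landmarks"
        ) from None
    Lk = Linv[:p, :p]
    return 0.5 * (Lk + Lk.T)


def tangent_basis(consensus: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal basis of the shape tangent space at the consensus.

    Returns ``(B, nonaffine, uniform)`` where ``B`` is (2p, 2p-4) with the
    2(p-3) partial-warp directions first and the 2 uniform (affine)
    directions last.  Rows of ``B`` are ordered x1, y1, x2, y2, ...
    The basis spans the orthogonal complement, within centred coordinate
    space, of the similarity directions (translation x/y, rotation,
    scaling) at the consensus.
    """
    c = np.asarray(consensus, float)
    c = c - c.mean(axis=0)
    c = c / np.sqrt(np.sum(c**2))
    p = c.shape[0]
    Lk = _bending_energy_matrix(c)
    evals, evecs = np.linalg.eigh(Lk)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-9
    principal_warps = evecs[:, evals > tol]  # (p, p-3), orthonormal
    n_pw = principal_warps.shape[1]
    if n_pw != p - 3:
        raise ValueError("unexpected bending-energy rank; degenerate consensus")

    def interleave(vx: np.ndarray, vy: np.ndarray) -> np.ndarray:
        out = np.zeros(2 * p)
        out[0::2] = vx
        out[1::2] = vy
        return out

    nonaffine = np.zeros((2 * p, 2 * n_pw))
    for j in range(n_pw):
        nonaffine[:, 2 * j] = interleave(principal_warps[:, j], np.zeros(p))
        nonaffine[:, 2 * j + 1] = interleave(np.zeros(p), principal_warps[:, j])

    # Affine candidates: linear maps of the consensus; remove the similarity
    # directions (scaling = consensus itself, rotation = consensus rotated 90deg).
    x, y = c[:, 0], c[:, 1]
    z = np.zeros(p)
    affine = np.column_stack(
        [interleave(x, z), interleave(y, z), interleave(z, x), interleave(z, y)]
    )
    scale_dir = interleave(x, y)
    rot_dir = interleave(-y, x)
    sim = np.column_stack([scale_dir, rot_dir])
    sim, _ = np.linalg.qr(sim)
    affine = affine - sim @ (sim.T @ affine)
    q, r = np.linalg.qr(affine)
    keep = np.abs(np.diag(r)) > 1e-9
    uniform = q[:, keep]
    if uniform.shape[1] != 2:
        raise ValueError("failed to extract 2 uniform components")
    B = np.hstack([nonaffine, uniform])
    return B, nonaffine, uniform


@dataclass
class ShapeVariables:
    """Final shape variables: PCs of partial-warp + uniform scores."""

    scores: np.ndarray  # (n, k)
    basis: np.ndarray  # (2p, k) loadings in coordinate space
    explained_variance: np.ndarray  # (k,) fractions of total shape variance
    k: int
    mean_scores: np.ndarray  # (2p-4,) mean partial-warp scores
    species_labels: list[str] = field(default_factory=list)
    specimen_ids: list[str] = field(default_factory=list)
    centroid_sizes: np.ndarray | None = None
    tangent_variance: float = 0.0


def compute_shape_variables(
    alignment: ShapeAlignment,
    variance_retained: float = 0.99,
) -> ShapeVariables:
    """Partial-warp scores of a GPA alignment, reduced by PCA.

    Residuals from the consensus are orthogonally projected into the
    tangent space, expressed in the partial-warp + uniform basis, and the
    principal components of those scores are truncated at the smallest
    dimension reaching ``variance_retained`` of the total shape variance.
    Because the basis is an orthonormal rotation of the tangent space, the
    retained space coincides with a PCA of the tangent residuals.
    """
    if alignment.n_specimens < 3:
        raise ValueError("shape variables need >= 3 specimens")
    if not (0 < variance_retained <= 1):
        raise ValueError("variance_retained must be in (0, 1]")
    n, p = alignment.n_specimens, alignment.n_landmarks
    B, _, _ = tangent_basis(alignment.mean_shape)
    resid = alignment.aligned - alignment.mean_shape  # (n, p, 2)
    flat = np.empty((n, 2 * p))
    flat[:, 0::2] = resid[:, :, 0]
    flat[:, 1::2] = resid[:, :, 1]
    pw_scores = flat @ B  # (n, 2p-4)

    centered = pw_scores - pw_scores.mean(axis=0)
    total_var = float(np.sum(centered**2)) / (n - 1)
    if total_var < 1e-24:
        warnings.warn("no shape variation among specimens; k = 0")
        return ShapeVariables(
            scores=np.zeros((n, 0)),
            basis=np.zeros((2 * p, 0)),
            explained_variance=np.zeros(0),
            k=0,
            mean_scores=pw_scores.mean(axis=0),
            species_labels=list(alignment.species_labels),
            specimen_ids=list(alignment.specimen_ids),
            centroid_sizes=alignment.centroid_sizes,
            tangent_variance=0.0,
        )
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2 / (n - 1)
    frac = var / var.sum()
    cum = np.cumsum(frac)
    k = int(np.searchsorted(cum, variance_retained - 1e-12) + 1)
    k = min(k, np.sum(s > s[0] * 1e-12))
    scores = centered @ vt[:k].T
    return ShapeVariables(
        scores=scores,
        basis=B @ vt[:k].T,
        explained_variance=frac[:k],
        k=k,
        mean_scores=pw_scores.mean(axis=0),
        species_labels=list(alignment.species_labels),
        specimen_ids=list(alignment.specimen_ids),
        centroid_sizes=alignment.centroid_sizes,
        tangent_variance=total_var,
    )


# ---------------------------------------------------------------------------
# Group statistics helpers
# ---------------------------------------------------------------------------

def _as_scores(shape: "ShapeVariables | np.ndarray") -> np.ndarray:
    if isinstance(shape, ShapeVariables):
        return shape.scores
    arr = np.asarray(shape, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def _group_indices(labels: list[str]) -> tuple[list[str], list[np.ndarray]]:
    uniq = sorted(set(labels))
    arr = np.asarray(labels)
    return uniq, [np.flatnonzero(arr == g) for g in uniq]


def _pooled_within(
    X: np.ndarray, idx: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Group means and pooled within-group covariance."""
    k = X.shape[1]
    means = np.stack([X[ix].mean(axis=0) for ix in idx])
    S = np.zeros((k, k))
    n = 0
    for g, ix in enumerate(idx):
        d = X[ix] - means[g]
        S += d.T @ d
        n += len(ix)
    return means, S / (n - len(idx))


def _condition_guard(
    X: np.ndarray, idx: list[np.ndarray], max_dim: int | None = None
) -> np.ndarray:
    """Truncate scores to the leading subspace where the pooled
    within-group covariance is well conditioned (condition number < 1e8).

    ``max_dim`` additionally caps the dimension (needed when a refit on
    n-1 specimens must stay full rank, as in leave-one-out)."""
    _, W = _pooled_within(X, idx)
    evals, evecs = np.linalg.eigh(W)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = np.flatnonzero(evals > evals[0] / _COND_LIMIT)
    if max_dim is not None:
        keep = keep[:max_dim]
    if len(keep) < X.shape[1]:
        logger.info(
            "pooled covariance ill-conditioned: truncating %d -> %d dimensions",
            X.shape[1],
            len(keep),
        )
        X = X @ evecs[:, keep]
    return X


# ---------------------------------------------------------------------------
# Discriminant analysis and Mahalanobis distances
# ---------------------------------------------------------------------------

@dataclass
class DiscriminantResult:
    """Canonical axes and pairwise Mahalanobis distances between groups."""

    canonical_scores: np.ndarray  # (n, g-1)
    canonical_axes: np.ndarray  # (k, g-1) in (possibly truncated) score space
    eigenvalues: np.ndarray
    mahalanobis: np.ndarray  # (g, g), distances D (not D^2)
    group_labels: list[str]
    group_sizes: np.ndarray
    group_means: np.ndarray


def discriminant_analysis(
    shape: ShapeVariables | np.ndarray,
    labels: list[str],
) -> DiscriminantResult:
    """Canonical variate analysis with pairwise Mahalanobis distances.

    Canonical axes maximize between-group relative to pooled within-group
    variance.  The Mahalanobis distance between group means i and j is
    ``D = sqrt((m_i - m_j)' W^-1 (m_i - m_j))`` with W the pooled
    within-group covariance; D (not D^2) is reported.  Axis signs follow
    the convention that the loading of largest magnitude on each axis is
    positive.
    """
    X = _as_scores(shape)
    uniq, idx = _group_indices(labels)
    if len(uniq) < 2:
        raise ValueError("discriminant analysis needs >= 2 groups")
    small = [g for g, ix in zip(uniq, idx) if len(ix) < 3]
    if small:
        raise ValueError(f"groups with < 3 members: {small}")
    X = _condition_guard(X, idx, max_dim=X.shape[0] - len(uniq) - 1)
    means, W = _pooled_within(X, idx)
    g = len(uniq)
    sizes = np.array([len(ix) for ix in idx])
    grand = X.mean(axis=0)
    Bmat = np.zeros_like(W)
    for a in range(g):
        d = (means[a] - grand)[:, None]
        Bmat += sizes[a] * (d @ d.T)
    Bmat /= X.shape[0] - 1

    evals, evecs = scipy.linalg.eigh(Bmat, W)
    order = np.argsort(evals)[::-1]
    n_axes = min(g - 1, X.shape[1])
    axes = evecs[:, order[:n_axes]]
    evals = np.maximum(evals[order[:n_axes]], 0.0)
    # deterministic sign convention
    for j in range(axes.shape[1]):
        jmax = np.argmax(np.abs(axes[:, j]))
        if axes[jmax, j] < 0:
            axes[:, j] = -axes[:, j]
    canonical_scores = (X - grand) @ axes

    Wc, low = scipy.linalg.cho_factor(W)
    D = np.zeros((g, g))
    for a in range(g):
        for b in range(a + 1, g):
            d = means[a] - means[b]
            D[a, b] = D[b, a] = float(
                np.sqrt(d @ scipy.linalg.cho_solve((Wc, low), d))
            )
    return DiscriminantResult(
        canonical_scores=canonical_scores,
        canonical_axes=axes,
        eigenvalues=evals,
        mahalanobis=D,
        group_labels=uniq,
        group_sizes=sizes,
        group_means=means,
    )


# ---------------------------------------------------------------------------
# Allometry
# ---------------------------------------------------------------------------

@dataclass
class AllometryResult:
    """Size-on-shape regression summary."""

    r_squared: float
    p_value: float
    slope_sign: str  # negative / zero / positive
    slope: float
    n: int


def allometry_regression(
    shape: ShapeVariables | np.ndarray,
    sizes: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AllometryResult:
    """Regress the first shape axis on centroid size.

    ``shape`` may be a :class:`ShapeVariables` (its first column is used)
    or an explicit score vector, typically the first canonical axis.  The
    coefficient of determination r^2 is reported with a permutation
    p-value obtained by shuffling the size vector ``n_perm`` times
    (add-one Monte-Carlo estimator, never exactly zero).
    """
    y = _as_scores(shape)[:, 0]
    sizes = np.asarray(sizes, float)
    if sizes.shape[0] != y.shape[0]:
        raise ValueError("sizes and scores have different lengths")
    if np.any(sizes <= 0):
        raise ValueError("centroid sizes must be positive")
    if np.var(sizes) == 0:
        raise ValueError("zero size variance")
    rng = np.random.default_rng(seed)

    def r2(yv: np.ndarray, xv: np.ndarray) -> float:
        c = np.corrcoef(yv, xv)[0, 1]
        return float(c * c) if np.isfinite(c) else 0.0

    obs = r2(y, sizes)
    slope = float(np.cov(y, sizes)[0, 1] / np.var(sizes, ddof=1))
    count = 0
    for _ in range(n_perm):
        if r2(y, rng.permutation(sizes)) >= obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    if obs < 1e-12:
        sign = "zero"
    else:
        sign = "negative" if slope < 0 else "positive"
    return AllometryResult(
        r_squared=obs, p_value=p, slope_sign=sign, slope=slope, n=len(y)
    )


# ---------------------------------------------------------------------------
# Permutation test on pairwise Mahalanobis distances
# ---------------------------------------------------------------------------

@dataclass
class PermutationTestResult:
    p_values: np.ndarray  # (g, g), upper triangle, NaN elsewhere
    significant: np.ndarray  # (g, g) bool after correction
    observed_D: np.ndarray
    group_labels: list[str]
    n_perm: int
    correction: str
    alpha: float
    n_pairs: int


def _pair_D2(X: np.ndarray, n1: int) -> float:
    """Two-group Mahalanobis D^2 with the first n1 rows as group 1."""
    m1 = X[:n1].mean(axis=0)
    m2 = X[n1:].mean(axis=0)
    d1 = X[:n1] - m1
    d2 = X[n1:] - m2
    W = (d1.T @ d1 + d2.T @ d2) / (X.shape[0] - 2)
    diff = m1 - m2
    return float(diff @ np.linalg.solve(W, diff))


def _pair_perm_D2(X: np.ndarray, n1: int, n_perm: int, rng) -> np.ndarray:
    """Vectorized permutation distribution of the two-group D^2."""
    n, k = X.shape
    n2 = n - n1
    S_tot = X.T @ X
    tsum = X.sum(axis=0)
    # random group-1 memberships as boolean indicators
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    Z = np.zeros((n_perm, n))
    np.put_along_axis(Z, order[:, :n1], 1.0, axis=1)
    sums1 = Z @ X  # (n_perm, k)
    m1 = sums1 / n1
    m2 = (tsum - sums1) / n2
    diff = m1 - m2
    Sw = (
        S_tot[None, :, :]
        - n1 * np.einsum("ij,il->ijl", m1, m1)
        - n2 * np.einsum("ij,il->ijl", m2, m2)
    ) / (n - 2)
    sol = np.linalg.solve(Sw, diff[..., None])[..., 0]
    return np.einsum("ij,ij->i", diff, sol)


def permutation_test_mahalanobis(
    shape: ShapeVariables | np.ndarray,
    labels: list[str],
    n_perm: int = 1000,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    seed: int | None = None,
) -> PermutationTestResult:
    """Label-permutation test of every pairwise Mahalanobis distance.

    For each unordered group pair the specimens of the two groups are
    pooled and labels permuted ``n_perm`` times; the p-value is
    ``(1 + #{D_perm >= D_obs}) / (n_perm + 1)``.  With Bonferroni
    correction, p is multiplied by the number of pairs before comparison
    with ``alpha``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution is coarse")
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    X = _as_scores(shape)
    uniq, idx = _group_indices(labels)
    g = len(uniq)
    if g < 2:
        raise ValueError("need >= 2 groups")
    min_pair_n = min(
        len(idx[a]) + len(idx[b]) for a in range(g) for b in range(a + 1, g)
    )
    X = _condition_guard(X, idx, max_dim=min_pair_n - 3)
    rng = np.random.default_rng(seed)
    n_pairs = g * (g - 1) // 2
    pvals = np.full((g, g), np.nan)
    obs_D = np.zeros((g, g))
    for a in range(g):
        for b in range(a + 1, g):
            Xab = np.vstack([X[idx[a]], X[idx[b]]])
            n1 = len(idx[a])
            d2_obs = _pair_D2(Xab, n1)
            d2_perm = _pair_perm_D2(Xab, n1, n_perm, rng)
            p = (1 + int(np.sum(d2_perm >= d2_obs))) / (n_perm + 1)
            pvals[a, b] = p
            obs_D[a, b] = obs_D[b, a] = np.sqrt(d2_obs)
    factor = n_pairs if correction == "bonferroni" else 1
    significant = np.zeros((g, g), dtype=bool)
    iu = np.triu_indices(g, 1)
    significant[iu] = np.minimum(pvals[iu] * factor, 1.0) < alpha
    significant |= significant.T
    return PermutationTestResult(
        p_values=pvals,
        significant=significant,
        observed_D=obs_D,
        group_labels=uniq,
        n_perm=n_perm,
        correction=correction,
        alpha=alpha,
        n_pairs=n_pairs,
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering tree with bootstrap supports
# ---------------------------------------------------------------------------

_LINKAGE_MAP = {"upgma": "average", "single": "single", "complete": "complete"}


@dataclass
class ClusteringTree:
    newick: str
    linkage_matrix: np.ndarray
    group_labels: list[str]
    supports: dict[frozenset, float] | None  # leaf-set -> support %
    n_boot: int


def _linkage_clusters(Z: np.ndarray, labels: list[str]) -> dict[int, frozenset]:
    """Leaf-label set of every node of a scipy linkage matrix."""
    n = len(labels)
    clusters = {i: frozenset([labels[i]]) for i in range(n)}
    for i, row in enumerate(Z):
        clusters[n + i] = clusters[int(row[0])] | clusters[int(row[1])]
    return clusters


def _internal_clusters(Z: np.ndarray, labels: list[str]) -> set[frozenset]:
    n = len(labels)
    cl = _linkage_clusters(Z, labels)
    return {cl[n + i] for i in range(len(Z)) if len(cl[n + i]) < n}


def _linkage_to_newick(
    Z: np.ndarray,
    labels: list[str],
    supports: dict[frozenset, float] | None = None,
) -> str:
    n = len(labels)
    clusters = _linkage_clusters(Z, labels)
    heights = {i: 0.0 for i in range(n)}

    def build(node: int) -> str:
        if node < n:
            return labels[node]
        row = Z[node - n]
        left, right = int(row[0]), int(row[1])
        h = row[2] / 2.0  # UPGMA ultrametric node height
        heights[node] = h
        parts = []
        for child in (left, right):
            bl = h - heights.get(child, 0.0)
            parts.append(f"{build(child)}:{bl:.6g}")
        label = ""
        if supports is not None and node != 2 * n - 2:
            sup = supports.get(clusters[node])
            if sup is not None:
                label = f"{sup:.0f}"
        return f"({','.join(parts)}){label}"

    # visit children before parents: build is recursive, heights filled on the way
    return build(2 * n - 2) + ";"


def hierarchical_tree(
    mahalanobis: np.ndarray,
    group_labels: list[str],
    shape: ShapeVariables | np.ndarray | None = None,
    labels: list[str] | None = None,
    linkage: str = "upgma",
    n_boot: int = 1000,
    seed: int | None = None,
) -> ClusteringTree:
    """Agglomerative clustering of groups on their Mahalanobis matrix.

    When raw scores and per-specimen labels are supplied, bootstrap
    supports are computed by resampling specimens with replacement within
    each group (preserving group sizes), recomputing the distance matrix
    and the tree, and counting the percentage of replicates reproducing
    each internal cluster of the full-data tree.
    """
    D = np.asarray(mahalanobis, float)
    g = D.shape[0]
    if g < 3:
        raise ValueError("clustering needs >= 3 groups")
    if D.shape != (g, g) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square symmetric")
    if linkage not in _LINKAGE_MAP:
        raise ValueError(f"linkage must be one of {sorted(_LINKAGE_MAP)}")
    method = _LINKAGE_MAP[linkage]
    Z = sch.linkage(squareform(D, checks=False), method=method)
    supports = None
    if shape is not None:
        if labels is None or seed is None:
            raise ValueError("bootstrap requires per-specimen labels and a seed")
        X = _as_scores(shape)
        uniq, idx = _group_indices(labels)
        if uniq != sorted(group_labels):
            raise ValueError("per-specimen labels do not match group_labels")
        rng = np.random.default_rng(seed)
        ref_clusters = _internal_clusters(Z, group_labels)
        counts = {c: 0 for c in ref_clusters}
        for _ in range(n_boot):
            rows = []
            labs = []
            for gl, ix in zip(uniq, idx):
                take = rng.integers(0, len(ix), size=len(ix))
                rows.append(X[ix[take]])
                labs.extend([gl] * len(ix))
            Xb = np.vstack(rows)
            try:
                res = discriminant_analysis(Xb, labs)
            except np.linalg.LinAlgError:
                continue
            Zb = sch.linkage(
                squareform(res.mahalanobis, checks=False), method=method
            )
            boot_clusters = _internal_clusters(Zb, res.group_labels)
            for c in ref_clusters:
                if c in boot_clusters:
                    counts[c] += 1
        supports = {c: 100.0 * counts[c] / n_boot for c in ref_clusters}
    newick = _linkage_to_newick(Z, list(group_labels), supports)
    return ClusteringTree(
        newick=newick,
        linkage_matrix=Z,
        group_labels=list(group_labels),
        supports=supports,
        n_boot=n_boot if supports is not None else 0,
    )


# ---------------------------------------------------------------------------
# Leave-one-out reclassification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    confusion: np.ndarray  # (g, g) ints, rows = true, cols = assigned
    group_labels: list[str]
    per_group_pct: np.ndarray
    total_pct: float

    def __post_init__(self) -> None:
        rows = self.confusion.sum(axis=1)
        assert np.all(rows > 0)


def loo_classification(
    shape: ShapeVariables | np.ndarray,
    labels: list[str],
) -> ClassificationReport:
    """Leave-one-out Mahalanobis reclassification.

    Each specimen is removed in turn; group means and the pooled
    within-group covariance are refit on the remainder, and the held-out
    specimen is assigned to the group with the smallest Mahalanobis
    distance.  Full refitting per fold gives honest error rates.
    """
    X = _as_scores(shape)
    uniq, idx = _group_indices(labels)
    g = len(uniq)
    if g == 1:
        warnings.warn("only one group: reclassification is trivially 100%")
        n = X.shape[0]
        return ClassificationReport(
            confusion=np.array([[n]]),
            group_labels=uniq,
            per_group_pct=np.array([100.0]),
            total_pct=100.0,
        )
    small = [gl for gl, ix in zip(uniq, idx) if len(ix) < 3]
    if small:
        raise ValueError(f"groups with < 3 members: {small}")
    X = _condition_guard(X, idx, max_dim=X.shape[0] - len(uniq) - 1)
    lab_arr = np.asarray(labels)
    lab_codes = np.array([uniq.index(l) for l in lab_arr])
    n = X.shape[0]
    confusion = np.zeros((g, g), dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        idx_i = [np.flatnonzero(lab_codes[mask] == a) for a in range(g)]
        if any(len(ix) == 0 for ix in idx_i):
            raise ValueError(
                f"removing specimen {i} empties a group; groups too small"
            )
        Xi = X[mask]
        means, W = _pooled_within(Xi, idx_i)
        diffs = means - X[i]
        sol = np.linalg.solve(W, diffs.T)
        d2 = np.einsum("ij,ji->i", diffs, sol)
        confusion[lab_codes[i], int(np.argmin(d2))] += 1
    rows = confusion.sum(axis=1)
    per_group = 100.0 * np.diag(confusion) / rows
    total = 100.0 * np.trace(confusion) / n
    return ClassificationReport(
        confusion=confusion,
        group_labels=uniq,
        per_group_pct=per_group,
        total_pct=total,
    )
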