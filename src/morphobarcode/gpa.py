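"""Generalized Procrustes Analysis and digitizing repeatability.

GPA iteratively removes translation (centering), scale (unit centroid
size) and rotation (orthogonal Procrustes fit to the consensus) from a
set of landmark configurations, leaving pure shape.  Full Procrustes
scaling is used, and reflections are disallowed (det +1 rotations only):
all wings come from the same body side.

Repeatability of landmark digitization is estimated by a one-way
Procrustes-ANOVA-style variance decomposition of jointly superimposed
repeat digitizations: the among-specimen variance component over the
total (among + within) variance, expressed in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import (
    DegenerateConfigurationError,
    LandmarkConfiguration,
    LandmarkDataset,
    centroid_size,
)

__all__ = [
    "ShapeAlignment",
    "RepeatabilityResult",
    "gpa_align",
    "procrustes_distance",
    "estimate_repeatability",
]


@dataclass
class ShapeAlignment:
    """Result of a Generalized Procrustes superimposition.

    ``aligned`` holds (n, n_landmarks, 2) unit-centroid-size, origin-centred,
    consensus-rotated coordinates; ``centroid_sizes`` are the pre-scaling
    sizes in the input units.
    """

    aligned: np.ndarray
    mean_shape: np.ndarray
    centroid_sizes: np.ndarray
    n_iterations: int
    converged: bool
    specimen_ids: list[str]
    species_labels: list[str]
    replicate_indices: list[int]

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]


@dataclass
class RepeatabilityResult:
    """Digitizing repeatability as percentages of total shape variance."""

    repeatability_pct: float
    measurement_error_pct: float
    n_specimens: int
    n_digitizations: int

    def __post_init__(self) -> None:
        assert abs(self.repeatability_pct + self.measurement_error_pct - 100.0) < 1e-6


def _center_scale(coords: np.ndarray, specimen: str = "<array>") -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    cs = np.sqrt(np.sum(centered**2))
    if cs == 0.0:
        raise DegenerateConfigurationError(
            f"all landmarks coincide in configuration {specimen}"
        )
    return centered / cs


def _optimal_rotation(ref: np.ndarray, mov: np.ndarray) -> np.ndarray:
    """Rotation matrix R (det +1) minimizing ||ref - mov @ R||."""
    u, _, vt = np.linalg.svd(mov.T @ ref)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def gpa_align(
    dataset: LandmarkDataset,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ShapeAlignment:
    """Generalized Procrustes superimposition of a landmark dataset.

    Each configuration is centred, scaled to unit centroid size and
    rotated to the running consensus; the consensus is then updated to the
    (renormalized) mean of the aligned configurations, until it changes by
    less than ``tol`` (Frobenius norm) or ``max_iter`` is reached.
    Non-convergence sets ``converged=False`` rather than raising.
    """
    if len(dataset) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    sizes = np.array([centroid_size(c) for c in dataset])
    shapes = np.stack(
        [_center_scale(c.coords, c.specimen_id) for c in dataset]
    )
    consensus = shapes[0].copy()
    n_it = 0
    converged = False
    for n_it in range(1, max_iter + 1):
        for i in range(shapes.shape[0]):
            shapes[i] = shapes[i] @ _optimal_rotation(consensus, shapes[i])
        new_consensus = shapes.mean(axis=0)
        new_consensus = _center_scale(new_consensus, "<consensus>")
        # keep the consensus orientation stable across iterations
        new_consensus = new_consensus @ _optimal_rotation(consensus, new_consensus)
        change = np.linalg.norm(new_consensus - consensus)
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    # final pass so every shape is optimally rotated to the final consensus
    for i in range(shapes.shape[0]):
        shapes[i] = shapes[i] @ _optimal_rotation(consensus, shapes[i])
    return ShapeAlignment(
        aligned=shapes,
        mean_shape=consensus,
        centroid_sizes=sizes,
        n_iterations=n_it,
        converged=converged,
        specimen_ids=dataset.specimen_ids,
        species_labels=dataset.species_labels,
        replicate_indices=dataset.replicate_indices,
    )


def procrustes_distance(
    a: LandmarkConfiguration | np.ndarray,
    b: LandmarkConfiguration | np.ndarray,
) -> float:
    """Procrustes distance between two configurations.

    Both configurations are centred and scaled to unit centroid size, the
    second is optimally rotated onto the first (no reflection), and the
    root summed squared coordinate difference is returned.  Zero iff the
    two shapes are identical up to a similarity transform.
    """
    ca = a.coords if isinstance(a, LandmarkConfiguration) else np.asarray(a, float)
    cb = b.coords if isinstance(b, LandmarkConfiguration) else np.asarray(b, float)
    if ca.shape != cb.shape:
        raise ValueError(f"landmark counts differ: {ca.shape} vs {cb.shape}")
    za = _center_scale(ca)
    zb = _center_scale(cb)
    zb = zb @ _optimal_rotation(za, zb)
    return float(np.linalg.norm(za - zb))


def estimate_repeatability(dataset: LandmarkDataset) -> RepeatabilityResult:
    """Partition shape variance into among-specimen vs. digitizing error.

    All digitizations of every specimen having >= 2 digitizations are
    jointly superimposed; aligned coordinates then enter a one-way
    variance decomposition with specimen as the grouping factor, pooled
    over all landmark coordinates.  The among-specimen variance component
    is extracted as (MS_among - MS_within) / r0 (r0 = the standard
    unbalanced-design replicate coefficient), clipped at zero.

    repeatability_pct = 100 * among / (among + within).
    """
    by_specimen: dict[str, list[LandmarkConfiguration]] = {}
    for cfg in dataset:
        by_specimen.setdefault(cfg.specimen_id, []).append(cfg)
    replicated = {k: v for k, v in by_specimen.items() if len(v) >= 2}
    if len(replicated) < 2:
        raise ValueError(
            "repeatability needs >= 2 specimens with >= 2 digitizations each; "
            "re-digitize a subset of specimens (replicate_index > 0) first"
        )
    configs = [c for v in replicated.values() for c in v]
    sub = LandmarkDataset.from_configurations(configs)
    alignment = gpa_align(sub)
    X = alignment.aligned.reshape(len(sub), -1)  # (N, 2p)

    groups = [alignment.specimen_ids[i] for i in range(len(sub))]
    uniq = sorted(set(groups))
    idx = {g: [] for g in uniq}
    for i, g in enumerate(groups):
        idx[g].append(i)
    N = X.shape[0]
    m = len(uniq)
    grand = X.mean(axis=0)
    ss_within = 0.0
    ss_among = 0.0
    r_sizes = []
    for g in uniq:
        rows = X[idx[g]]
        r_i = rows.shape[0]
        r_sizes.append(r_i)
        gm = rows.mean(axis=0)
        ss_within += float(np.sum((rows - gm) ** 2))
        ss_among += r_i * float(np.sum((gm - grand) ** 2))
    r_sizes = np.array(r_sizes, float)
    ms_within = ss_within / (N - m)
    ms_among = ss_among / (m - 1)
    r0 = (N - np.sum(r_sizes**2) / N) / (m - 1)
    s2_among = max(0.0, (ms_among - ms_within) / r0)
    s2_within = ms_within
    total = s2_among + s2_within
    rep = 100.0 * s2_among / total if total > 0 else 100.0
    return RepeatabilityResult(
        repeatability_pct=rep,
        measurement_error_pct=100.0 - rep,
        n_specimens=m,
        n_digitizations=N,
    )
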