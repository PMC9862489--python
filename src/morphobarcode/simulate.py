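"""Synthetic landmark and barcode datasets with controlled statistical structure.

The generators emulate the statistical design of a four-species mosquito
wing/barcode study: species groups of 25-50 specimens with 18 wing
landmarks whose mean shapes are displaced in tangent space relative to
isotropic within-species shape noise, an allometric size->shape
component, digitizing error as a small fraction of shape variance, and
~658 bp protein-coding barcodes with intraspecific divergence well below
1.5% and interspecific divergence up to ~5.6%, including one species
pair whose interspecific divergence sits inside the intraspecific range
(no barcoding gap).

Shape noise is drawn per coordinate of the tangent space of the template
and mapped back to landmark space, so specified variances read directly
as Procrustes (tangent) variances.  Sequence evolution uses the exact
closed-form Kimura 2-parameter transition probabilities per site, so a
branch of length d produces an expected K2P distance of exactly d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .barcodes import AlignedSequenceSet
from .landmarks import LandmarkConfiguration, LandmarkDataset
from .shapes import tangent_basis

__all__ = [
    "WING_TEMPLATE",
    "MorphoSimSpec",
    "SeqSimSpec",
    "generate_landmark_dataset",
    "generate_barcode_dataset",
    "study_mirror_morpho_spec",
    "study_mirror_barcode_spec",
    "STUDY_GROUP_SIZES",
    "STUDY_SPECIES",
]

# An 18-landmark configuration laid out like a culicid wing (vein
# intersections and termini along costal, radial, medial and cubital
# veins).  The exact coordinates are arbitrary; only the overall layout
# matters for generating realistic-looking datasets.
WING_TEMPLATE = np.array(
    [
        (0.20, 0.10),
        (0.80, 0.32),
        (1.60, 0.42),
        (2.30, 0.38),
        (2.80, 0.20),
        (3.00, 0.00),
        (2.80, -0.18),
        (2.40, -0.30),
        (1.90, -0.38),
        (1.30, -0.40),
        (0.70, -0.30),
        (0.30, -0.15),
        (1.00, 0.10),
        (1.50, 0.05),
        (1.95, 0.12),
        (2.10, -0.08),
        (1.70, -0.18),
        (1.20, -0.12),
    ]
)

STUDY_SPECIES = ["chiangmaiensis", "fuscana", "halifaxii", "vorax"]
STUDY_GROUP_SIZES = [40, 50, 42, 25]

# Exact 3-D classical-scaling embedding (whitened units) of the target
# between-group Mahalanobis distance matrix
#   cm-fu 4.55, cm-ha 5.34, cm-vo 8.45, fu-ha 4.05, fu-vo 10.25, ha-vo 9.99
_STUDY_D_EMBED = np.array(
    [
        [-0.83277913, -2.60417535, -1.14544464],
        [-3.20679118, -0.26774798, 1.95418016],
        [-2.83965295, 2.34429537, -1.11908180],
        [6.87922326, 0.52762796, 0.31034628],
    ]
)


# ---------------------------------------------------------------------------
# Landmark generator
# ---------------------------------------------------------------------------

@dataclass
class MorphoSimSpec:
    """Parameters of the landmark-dataset generator.

    ``per_species_displacement`` holds each species' mean-shape offset as
    coordinates (tangent units) along ``m`` fixed orthonormal tangent
    directions of the template (the lowest-bending-energy partial warps
    and the uniform components); with isotropic within-species noise of
    sd ``shape_noise_sd`` per tangent coordinate, the true Mahalanobis
    distance between species i and j is
    ``||disp_i - disp_j|| / shape_noise_sd`` (before allometric and
    digitizing inflation).

    ``size_mean_sd`` gives per-species (mean, sd) of log centroid size;
    ``allometry_coeff`` is the tangent displacement along
    ``allometry_direction`` per unit log size.  ``digitizing_error_sd``
    (tangent units per coordinate) is added independently to every
    digitization; the first ``n_redigitized_per_species`` specimens of
    each species receive ``n_replicates`` extra digitizations.
    """

    n_species: int
    per_species_displacement: np.ndarray  # (n_species, m)
    n_per_species: list[int]
    shape_noise_sd: float
    seed: int
    template: np.ndarray = field(default_factory=lambda: WING_TEMPLATE.copy())
    allometry_coeff: float = 0.0
    allometry_direction: int = 0
    size_mean_sd: np.ndarray | None = None  # (n_species, 2) mean/sd of log CS
    digitizing_error_sd: float = 0.0
    n_replicates: int = 1
    n_redigitized_per_species: int = 0
    species_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.per_species_displacement = np.atleast_2d(
            np.asarray(self.per_species_displacement, float)
        )
        if self.per_species_displacement.shape[0] != self.n_species:
            raise ValueError("per_species_displacement must have one row per species")
        if self.shape_noise_sd < 0 or self.digitizing_error_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if any(n < 3 for n in self.n_per_species):
            raise ValueError("n_per_species entries must be >= 3")
        if len(self.n_per_species) != self.n_species:
            raise ValueError("n_per_species must have one entry per species")
        if self.size_mean_sd is None:
            self.size_mean_sd = np.tile([np.log(3.0), 0.05], (self.n_species, 1))
        self.size_mean_sd = np.asarray(self.size_mean_sd, float)
        if self.species_labels is None:
            self.species_labels = [f"sp{i + 1}" for i in range(self.n_species)]


def _template_tangent_directions(template: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit template and ``m`` large-scale tangent directions (2p, m)."""
    c = template - template.mean(axis=0)
    c = c / np.sqrt(np.sum(c**2))
    B, _, _ = tangent_basis(c)
    if m > B.shape[1]:
        raise ValueError(f"at most {B.shape[1]} tangent directions available")
    # last columns = uniform components and lowest-bending partial warps:
    # smooth, large-scale deformations appropriate for species differences
    return c, B[:, B.shape[1] - m :][:, ::-1]


def _unflatten(v: np.ndarray, p: int) -> np.ndarray:
    out = np.empty((p, 2))
    out[:, 0] = v[0::2]
    out[:, 1] = v[1::2]
    return out


def generate_landmark_dataset(spec: MorphoSimSpec) -> LandmarkDataset:
    """Generate a labeled landmark dataset from a :class:`MorphoSimSpec`.

    Per specimen: species mean shape = template + species tangent offset;
    individual shape adds isotropic tangent noise and the allometric
    component; every digitization adds digitizing-error noise, a random
    rigid motion, and scaling by the specimen's centroid size.  Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.template.shape[0]
    m = spec.per_species_displacement.shape[1]
    unit_template, dirs = _template_tangent_directions(spec.template, m)
    B, _, _ = tangent_basis(unit_template)
    tdim = B.shape[1]
    u_allo = dirs[:, spec.allometry_direction]

    # population grand mean of log size, for the allometric reference point
    weights = np.asarray(spec.n_per_species, float)
    grand_log_cs = float(
        np.sum(weights * spec.size_mean_sd[:, 0]) / weights.sum()
    )

    species_offsets = spec.per_species_displacement @ dirs.T  # (s, 2p)
    off_diag = ~np.eye(p, dtype=bool)
    d2t = np.sum(
        (unit_template[:, None, :] - unit_template[None, :, :]) ** 2, axis=-1
    )
    min_template = np.sqrt(d2t[off_diag].min())
    for i, off in enumerate(species_offsets):
        mean_shape = unit_template + _unflatten(off, p)
        d2 = np.sum(
            (mean_shape[:, None, :] - mean_shape[None, :, :]) ** 2, axis=-1
        )
        # landmarks closer than a quarter of the template's tightest spacing
        # have lost their identity: refuse to generate such a species mean
        if np.sqrt(d2[off_diag].min()) < 0.25 * min_template:
            raise ValueError(
                f"species {spec.species_labels[i]!r} displacement collapses landmarks"
            )

    configs: list[LandmarkConfiguration] = []
    for i in range(spec.n_species):
        label = spec.species_labels[i]
        mu_log, sd_log = spec.size_mean_sd[i]
        for j in range(spec.n_per_species[i]):
            log_cs = rng.normal(mu_log, sd_log)
            tangent = (
                species_offsets[i]
                + spec.allometry_coeff * (log_cs - grand_log_cs) * u_allo
                + B @ rng.normal(0.0, spec.shape_noise_sd, size=tdim)
            )
            true_flat = unit_template.ravel().copy()
            true_flat[0::2] += _unflatten(tangent, p)[:, 0]
            true_flat[1::2] += _unflatten(tangent, p)[:, 1]
            true_shape = true_flat.reshape(p, 2)
            n_digs = 1
            if j < spec.n_redigitized_per_species:
                n_digs += spec.n_replicates
            for rep in range(n_digs):
                dig = true_shape
                if spec.digitizing_error_sd > 0:
                    dig = dig + _unflatten(
                        B @ rng.normal(0.0, spec.digitizing_error_sd, size=tdim), p
                    )
                theta = rng.uniform(0, 2 * np.pi)
                R = np.array(
                    [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
                )
                coords = dig @ R.T * np.exp(log_cs) + rng.uniform(-10, 10, size=2)
                configs.append(
                    LandmarkConfiguration(
                        specimen_id=f"{label}_s{j + 1:03d}",
                        species_label=label,
                        coords=coords,
                        replicate_index=rep,
                    )
                )
    return LandmarkDataset.from_configurations(configs)


# ---------------------------------------------------------------------------
# Barcode generator
# ---------------------------------------------------------------------------

_STOP_CODONS = {"TAA", "TAG"}  # invertebrate mitochondrial code
_BASES = "ACGT"
# COI-like base composition (A, C, G, T)
_BASE_PROBS = np.array([0.299, 0.159, 0.154, 0.388])


@dataclass
class SeqSimSpec:
    """Parameters of the barcode-dataset generator.

    ``intra_divergence`` is the target expected K2P distance between two
    individuals of one species (scalar or per-species).
    ``inter_divergence`` is the target between species: a scalar (all
    pairs equal) or a full (s, s) matrix whose UPGMA tree defines the
    species ancestry; ``overlap_pair`` optionally forces one species pair
    to a divergence (``overlap_divergence``, default = the intraspecific
    target) below the intraspecific maximum, producing a pair with no
    barcoding gap.  ``kappa`` is the transition/transversion rate ratio.
    """

    n_species: int = 4
    n_per_species: int | list[int] = 10
    seq_length: int = 658
    intra_divergence: float | list[float] = 0.005
    inter_divergence: float | np.ndarray = 0.045
    kappa: float = 4.0
    overlap_pair: tuple[int, int] | None = None
    overlap_divergence: float | None = None
    species_labels: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_per_species, int):
            self.n_per_species = [self.n_per_species] * self.n_species
        if isinstance(self.intra_divergence, (int, float)):
            self.intra_divergence = [float(self.intra_divergence)] * self.n_species
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        intra = np.asarray(self.intra_divergence, float)
        inter = np.asarray(self.inter_divergence, float)
        if np.any(intra < 0) or np.any(inter < 0):
            raise ValueError("divergence targets must be >= 0")
        if np.any(intra > 0.7) or np.any(inter > 0.7):
            raise ValueError("divergence targets beyond saturation (> 0.7)")
        if self.species_labels is None:
            self.species_labels = [f"sp{i + 1}" for i in range(self.n_species)]

    def inter_matrix(self) -> np.ndarray:
        inter = np.asarray(self.inter_divergence, float)
        s = self.n_species
        if inter.ndim == 0:
            M = np.full((s, s), float(inter))
            np.fill_diagonal(M, 0.0)
        else:
            if inter.shape != (s, s):
                raise ValueError("inter_divergence matrix must be (s, s)")
            M = inter.copy()
        if self.overlap_pair is not None:
            i, j = self.overlap_pair
            d = (
                self.overlap_divergence
                if self.overlap_divergence is not None
                else float(np.mean(self.intra_divergence))
            )
            M[i, j] = M[j, i] = d
        return M


def _k2p_site_probs(d: float, kappa: float) -> tuple[float, float]:
    """(P_transition, P_transversion_total) after expected distance d."""
    bt = d / (kappa + 2.0)
    at = kappa * bt
    e4b = np.exp(-4.0 * bt)
    e2ab = np.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv = 0.5 - 0.5 * e4b
    return float(p_ts), float(p_tv)


def _evolve(codes: np.ndarray, d: float, kappa: float, rng) -> np.ndarray:
    """Evolve encoded sequence (A0 C1 G2 T3) by expected K2P distance d."""
    if d <= 0:
        return codes.copy()
    p_ts, p_tv = _k2p_site_probs(d, kappa)
    u = rng.random(codes.shape[0])
    out = codes.copy()
    ts_partner = (codes + 2) % 4
    # transversion targets: the two bases of the opposite purine/pyrimidine class
    purine = (codes % 2) == 0  # A(0), G(2)
    tv1 = np.where(purine, 1, 0)  # C for purines, A for pyrimidines
    tv2 = np.where(purine, 3, 2)  # T for purines, G for pyrimidines
    out[u < p_ts] = ts_partner[u < p_ts]
    m1 = (u >= p_ts) & (u < p_ts + p_tv / 2)
    m2 = (u >= p_ts + p_tv / 2) & (u < p_ts + p_tv)
    out[m1] = tv1[m1]
    out[m2] = tv2[m2]
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def _site_transition_matrix(d: float, kappa: float) -> np.ndarray:
    """4x4 K2P site transition probability matrix after distance d."""
    bt = d / (kappa + 2.0)
    at = kappa * bt
    e4b = np.exp(-4.0 * bt)
    e2ab = np.exp(-2.0 * (at + bt))
    p_same = 0.25 + 0.25 * e4b + 0.5 * e2ab
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv = 0.25 - 0.25 * e4b  # each of the two transversion targets
    T = np.full((4, 4), p_tv)
    for i in range(4):
        T[i, i] = p_same
        T[i, (i + 2) % 4] = p_ts
    return T


_CODONS = np.array([[i // 16, (i // 4) % 4, i % 4] for i in range(64)])


def _codon_index(codon: str) -> int:
    return 16 * _BASES.index(codon[0]) + 4 * _BASES.index(codon[1]) + _BASES.index(codon[2])


_STOP_IDX = [_codon_index(c) for c in sorted(_STOP_CODONS)]
# per-site transition/transversion counts between every codon pair
_diff = _CODONS[:, None, :] != _CODONS[None, :, :]
_same_class = (_CODONS[:, None, :] % 2) == (_CODONS[None, :, :] % 2)
_N_TS = (_diff & _same_class).sum(axis=-1)
_N_TV = (_diff & ~_same_class).sum(axis=-1)


def _conditional_pq(d: float, kappa: float, codon_weights: np.ndarray) -> tuple[float, float]:
    """Expected per-site transition/transversion proportions of the
    stop-rejection sampler at branch length d."""
    T = _site_transition_matrix(d, kappa)
    probs = (
        T[_CODONS[:, None, 0], _CODONS[None, :, 0]]
        * T[_CODONS[:, None, 1], _CODONS[None, :, 1]]
        * T[_CODONS[:, None, 2], _CODONS[None, :, 2]]
    )  # (parent, child)
    probs[:, _STOP_IDX] = 0.0
    probs /= probs.sum(axis=1, keepdims=True)
    e_ts = codon_weights @ (probs * _N_TS).sum(axis=1)
    e_tv = codon_weights @ (probs * _N_TV).sum(axis=1)
    return float(e_ts / 3.0), float(e_tv / 3.0)


def _effective_branch_length(d_target: float, kappa: float, parent: np.ndarray) -> float:
    """Branch length whose stop-conditioned expected K2P distance is d_target.

    Rejecting codons that mutate into stops slightly suppresses observed
    substitutions; this inverts that suppression exactly (64x64 codon
    enumeration weighted by the parent's codon usage)."""
    if d_target <= 0:
        return d_target
    n_codons = parent.shape[0] // 3
    idx = (
        16 * parent[: 3 * n_codons : 3]
        + 4 * parent[1 : 3 * n_codons : 3]
        + parent[2 : 3 * n_codons : 3]
    )
    weights = np.bincount(idx, minlength=64).astype(float)
    weights /= weights.sum()

    def realized(d: float) -> float:
        P, Q = _conditional_pq(d, kappa, weights)
        return -0.5 * np.log(1 - 2 * P - Q) - 0.25 * np.log(1 - 2 * Q)

    lo, hi = d_target, d_target * 1.5 + 1e-4
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if realized(mid) < d_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _fix_stops(child: np.ndarray, parent: np.ndarray, d: float, kappa: float, rng) -> np.ndarray:
    """Re-evolve frame-0 codons of ``child`` that became stop codons."""
    n_codons = child.shape[0] // 3
    for _ in range(200):
        view = child[: 3 * n_codons].reshape(n_codons, 3)
        codons = ["".join(_BASES[c] for c in row) for row in view]
        bad = [k for k, cd in enumerate(codons) if cd in _STOP_CODONS]
        if not bad:
            return child
        for k in bad:
            child[3 * k : 3 * k + 3] = _evolve(
                parent[3 * k : 3 * k + 3], d if d > 0 else 1e-4, kappa, rng
            )
    raise RuntimeError("could not produce a stop-free sequence")


def _random_orf(length: int, rng) -> np.ndarray:
    codes = rng.choice(4, size=length, p=_BASE_PROBS)
    n_codons = length // 3
    for _ in range(200):
        view = codes[: 3 * n_codons].reshape(n_codons, 3)
        bad = [
            k
            for k in range(n_codons)
            if "".join(_BASES[c] for c in view[k]) in _STOP_CODONS
        ]
        if not bad:
            return codes
        for k in bad:
            codes[3 * k : 3 * k + 3] = rng.choice(4, size=3, p=_BASE_PROBS)
    raise RuntimeError("could not generate a stop-free ancestral sequence")


def generate_barcode_dataset(spec: SeqSimSpec) -> AlignedSequenceSet:
    """Generate aligned, stop-free barcode sequences from a :class:`SeqSimSpec`.

    A random ancestral in-frame sequence evolves down the species tree
    implied by the interspecific target matrix (each branch under the
    exact K2P substitution process), then each individual evolves a
    further half of its species' intraspecific target.  Codons that
    mutate into stop codons are re-rolled, keeping all sequences clean
    ORFs in frame 0.
    """
    rng = np.random.default_rng(spec.seed)
    ancestral = _random_orf(spec.seq_length, rng)
    M = spec.inter_matrix()
    s = spec.n_species
    # the interspecific target is the expected distance between
    # *individuals*, which includes both intraspecific half-branches;
    # place species ancestors correspondingly closer (never below zero)
    intra = np.asarray(spec.intra_divergence, float)
    M = M - 0.5 * (intra[:, None] + intra[None, :])
    np.fill_diagonal(M, 0.0)
    M = np.maximum(M, 0.0)
    if s == 1:
        species_seqs = [ancestral]
    else:
        Z = sch.linkage(squareform(M, checks=False), method="average")
        seqs_by_node: dict[int, np.ndarray] = {}
        root = 2 * s - 2
        node_height = {i: 0.0 for i in range(s)}
        for k, row in enumerate(Z):
            node_height[s + k] = row[2] / 2.0
        seqs_by_node[root] = ancestral

        def descend(node: int) -> None:
            if node < s:
                return
            row = Z[node - s]
            for child in (int(row[0]), int(row[1])):
                d = node_height[node] - node_height[child]
                d_eff = _effective_branch_length(d, spec.kappa, seqs_by_node[node])
                child_seq = _evolve(seqs_by_node[node], d_eff, spec.kappa, rng)
                child_seq = _fix_stops(child_seq, seqs_by_node[node], d_eff, spec.kappa, rng)
                seqs_by_node[child] = child_seq
                descend(child)

        descend(root)
        species_seqs = [seqs_by_node[i] for i in range(s)]

    ids, species, seqs = [], [], []
    for i in range(s):
        label = spec.species_labels[i]
        half_intra = _effective_branch_length(
            spec.intra_divergence[i] / 2.0, spec.kappa, species_seqs[i]
        )
        for j in range(spec.n_per_species[i]):
            ind = _evolve(species_seqs[i], half_intra, spec.kappa, rng)
            ind = _fix_stops(ind, species_seqs[i], half_intra, spec.kappa, rng)
            ids.append(f"{label}_{j + 1:02d}")
            species.append(label)
            seqs.append(_decode(ind))
    return AlignedSequenceSet(ids, species, seqs)


# ---------------------------------------------------------------------------
# Study-mirror specifications
# ---------------------------------------------------------------------------

def study_mirror_morpho_spec(
    seed: int,
    measurement_error_fraction: float = 0.04,
    target_r2: float = 0.22,
) -> MorphoSimSpec:
    """Landmark-generator spec mirroring the study's morphometric design.

    Four species with group sizes 40/50/42/25, species mean shapes placed
    (in the tangent space of the wing template) at the exact embedding of
    the reported between-group Mahalanobis distance matrix, isotropic
    within-species tangent noise, log-normal centroid sizes whose species
    means follow the leading separation axis, an allometric shape
    component calibrated so that the regression of the first discriminant
    axis on centroid size explains ``target_r2`` of its variance, and
    digitizing error amounting to ``measurement_error_fraction`` of the
    among-specimen shape variance.  Ten specimens per species carry one
    re-digitization, as in a repeatability protocol.
    """
    sigma = 0.004  # within-species tangent sd per coordinate
    sd_log_within = 0.06  # within-species sd of log centroid size
    # within-species allometric shape sd along the leading axis = sigma / 2
    a_coeff = 0.5 * sigma / sd_log_within

    W = _STUDY_D_EMBED
    weights = np.asarray(STUDY_GROUP_SIZES, float)
    wfrac = weights / weights.sum()
    wmean0 = float(wfrac @ W[:, 0])
    v_between0 = float(wfrac @ (W[:, 0] - wmean0) ** 2)

    # digitizing error inflates every axis; solve by fixed point
    sigma_d = 0.0
    tdim = 2 * WING_TEMPLATE.shape[0] - 4
    for _ in range(8):
        s0_eff = np.sqrt(sigma**2 + sigma_d**2 + (a_coeff * sd_log_within) ** 2)
        s_eff = np.sqrt(sigma**2 + sigma_d**2)
        scale = np.array([s0_eff, s_eff, s_eff])
        positions = W * scale
        # among-specimen shape variance for the re-digitized subset
        # (equal species weights): between-species + within-species parts
        v_between = float(np.mean(np.sum((positions - positions.mean(0)) ** 2, axis=1)))
        v_within = tdim * sigma**2 + (a_coeff * sd_log_within) ** 2
        v_among = v_between + v_within
        frac = measurement_error_fraction
        sigma_d = np.sqrt(frac / (1 - frac) * v_among / tdim)

    # species mean log sizes follow the leading axis; the slope b is set so
    # the expected r^2 of (first canonical axis ~ size) equals target_r2
    v_b = v_between0
    c_within = (a_coeff / s0_eff) * sd_log_within**2

    def r2_of(b: float) -> float:
        num = (v_b * b + c_within) ** 2
        den = (v_b + 1.0) * (v_b * b**2 + sd_log_within**2)
        return num / den

    lo, hi = 0.0, 0.5
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if r2_of(mid) < target_r2:
            lo = mid
        else:
            hi = mid
    b = 0.5 * (lo + hi)

    mu0 = np.log(3.0)  # ~3 mm wings
    mean_logs = mu0 + b * (W[:, 0] - wmean0)
    size_mean_sd = np.column_stack([mean_logs, np.full(4, sd_log_within)])

    # remove the allometric between-species shift from the displacement so
    # the effective species positions land exactly on the embedding
    positions = W * np.array([s0_eff, s_eff, s_eff])
    positions[:, 0] -= a_coeff * (mean_logs - float(wfrac @ mean_logs))

    return MorphoSimSpec(
        n_species=4,
        per_species_displacement=positions,
        n_per_species=list(STUDY_GROUP_SIZES),
        shape_noise_sd=sigma,
        allometry_coeff=a_coeff,
        allometry_direction=0,
        size_mean_sd=size_mean_sd,
        digitizing_error_sd=float(sigma_d),
        n_replicates=1,
        n_redigitized_per_species=10,
        species_labels=list(STUDY_SPECIES),
        seed=seed,
    )


def study_mirror_barcode_spec(seed: int) -> SeqSimSpec:
    """Barcode-generator spec mirroring the study's divergence structure.

    Four species, ten 658 bp barcodes each; per-species intraspecific
    targets at the reported means, and an ultrametric interspecific
    target matrix in which two species ("fuscana"/"halifaxii"-like) sit
    closer together than the intraspecific maximum — the pair with no
    barcoding gap — while the most divergent species is ~5% from all
    others.
    """
    inter = np.array(
        [
            [0.000, 0.0350, 0.0350, 0.0494],
            [0.0350, 0.000, 0.0048, 0.0494],
            [0.0350, 0.0048, 0.000, 0.0494],
            [0.0494, 0.0494, 0.0494, 0.000],
        ]
    )
    return SeqSimSpec(
        n_species=4,
        n_per_species=10,
        seq_length=658,
        intra_divergence=[0.0019, 0.0060, 0.0035, 0.0076],
        inter_divergence=inter,
        kappa=4.0,
        species_labels=list(STUDY_SPECIES),
        seed=seed,
    )
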