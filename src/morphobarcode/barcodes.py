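"""COI DNA-barcode analytics.

Composition, pseudogene screening (stop-codon check under the
invertebrate mitochondrial code), Kimura 2-parameter distances,
intra-/interspecific divergence summaries, barcoding-gap detection, and
neighbor-joining trees with site-resampling bootstrap supports.

Sequences must arrive aligned (equal length); COI barcodes are
indel-free in-frame in culicids, so a strict length check replaces a
bundled aligner.  Distances are raw substitutions/site in matrices and
percent (x100) in summaries; gap and N sites are removed per sequence
pair (pairwise deletion) by default, with complete deletion available.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

__all__ = [
    "AlignedSequenceSet",
    "DivergenceSummary",
    "GapReport",
    "SaturationError",
    "read_fasta",
    "write_fasta",
    "nucleotide_composition",
    "check_stop_codons",
    "k2p_distance",
    "k2p_matrix",
    "divergence_summary",
    "barcoding_gap",
    "nj_tree",
    "bootstrap_nj",
]

INVERTEBRATE_MITO_TABLE = 5

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 255, "N": 255}
_PURINE = np.array([True, False, True, False])  # A, C, G, T


class SaturationError(ValueError):
    """K2P log argument non-positive: sequences too divergent."""


@dataclass
class AlignedSequenceSet:
    """Labeled, aligned DNA sequences over {A, C, G, T, -, N}."""

    ids: list[str]
    species: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len({len(self.ids), len(self.species), len(self.sequences)}) != 1:
            raise ValueError("ids, species and sequences must have equal length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(
                f"aligned sequences must share one length, got {sorted(lengths)}; "
                "align them externally (e.g. mafft) first"
            )
        self.sequences = [s.upper() for s in self.sequences]
        for sid, s in zip(self.ids, self.sequences):
            bad = set(s) - set("ACGTN-")
            if bad:
                raise ValueError(
                    f"sequence {sid!r} has unsupported characters {sorted(bad)}; "
                    "IUPAC ambiguity codes beyond N are rejected"
                )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def encoded(self) -> np.ndarray:
        """(n, L) uint8 matrix: A=0 C=1 G=2 T=3, gap/N = 255."""
        lut = np.full(256, 255, dtype=np.uint8)
        for ch, v in _CODE.items():
            lut[ord(ch)] = v
        raw = np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(len(self), self.length)
        return lut[raw]

    def subset_sites(self, cols: np.ndarray) -> "AlignedSequenceSet":
        seqs = []
        for s in self.sequences:
            arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)[cols]
            seqs.append(arr.tobytes().decode("ascii"))
        return AlignedSequenceSet(list(self.ids), list(self.species), seqs)


def _load_label_map(label_map: "dict[str, str] | str | Path | None") -> dict[str, str] | None:
    if label_map is None or isinstance(label_map, dict):
        return label_map
    mapping = {}
    with open(label_map, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            if row[0].strip().lower() in ("sequence_id", "id"):
                continue
            mapping[row[0].strip()] = row[1].strip()
    return mapping


def read_fasta(
    path: str | Path,
    label_map: "dict[str, str] | str | Path | None" = None,
) -> AlignedSequenceSet:
    """Read aligned barcodes from FASTA.

    Species labels come from ``label_map`` (a dict or a two-column
    id,species CSV); without a map the token before the first underscore
    of each record id is used.
    """
    mapping = _load_label_map(label_map)
    ids, species, seqs = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
        if mapping is not None:
            try:
                species.append(mapping[rec.id])
            except KeyError:
                raise ValueError(f"no species label for record {rec.id!r}") from None
        else:
            species.append(rec.id.split("_")[0])
    if not ids:
        raise ValueError(f"{path}: no FASTA records")
    return AlignedSequenceSet(ids, species, seqs)


def write_fasta(seqs: AlignedSequenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(seqs.ids, seqs.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Composition and pseudogene screen
# ---------------------------------------------------------------------------

def nucleotide_composition(seqs: AlignedSequenceSet) -> dict[str, float]:
    """Mean per-sequence base percentages (gaps and N excluded)."""
    if len(seqs) == 0:
        raise ValueError("empty sequence set")
    fracs = []
    for sid, s in zip(seqs.ids, seqs.sequences):
        counts = {b: s.count(b) for b in "ACGT"}
        tot = sum(counts.values())
        if tot == 0:
            warnings.warn(f"sequence {sid!r} has no unambiguous bases; excluded")
            continue
        fracs.append([counts[b] / tot for b in "ACGT"])
    if not fracs:
        raise ValueError("no sequence with unambiguous bases")
    mean = 100.0 * np.mean(fracs, axis=0)
    return dict(zip("ACGT", map(float, mean)))


@dataclass
class StopCodonResult:
    passed: bool
    frame: int | None  # first passing frame, or None
    peptide: str | None
    frames_checked: dict[int, bool]


def check_stop_codons(
    seq: str,
    table: int = INVERTEBRATE_MITO_TABLE,
    frame: "int | str" = "auto",
) -> StopCodonResult:
    """Screen a barcode for internal stop codons (pseudogene check).

    Under ``frame='auto'`` the sequence passes iff at least one forward
    reading frame translates without a stop codon; the first passing
    frame and its peptide are reported.  Gaps are removed before
    translation; the trailing incomplete codon is ignored.
    """
    clean = seq.upper().replace("-", "")
    if len(clean) < 3:
        raise ValueError("ungapped sequence shorter than one codon")
    bad = set(clean) - set("ACGTN")
    if bad:
        raise ValueError(f"non-DNA characters: {sorted(bad)}")
    frames = [0, 1, 2] if frame == "auto" else [int(frame)]
    results: dict[int, bool] = {}
    first_frame = None
    peptide = None
    for f in frames:
        sub = clean[f:]
        sub = sub[: len(sub) - len(sub) % 3]
        pep = str(Seq(sub).translate(table=table))
        ok = "*" not in pep
        results[f] = ok
        if ok and first_frame is None:
            first_frame = f
            peptide = pep
    return StopCodonResult(
        passed=first_frame is not None,
        frame=first_frame,
        peptide=peptide,
        frames_checked=results,
    )


# ---------------------------------------------------------------------------
# K2P distances
# ---------------------------------------------------------------------------

def _k2p_from_counts(n_sites: int, n_ts: int, n_tv: int, pair: str = "") -> float:
    if n_sites == 0:
        raise ValueError(f"zero comparable sites{pair}")
    P = n_ts / n_sites
    Q = n_tv / n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P distance saturated{pair} (P={P:.3f}, Q={Q:.3f})")
    return float(-0.5 * np.log(w1) - 0.25 * np.log(w2))


def k2p_distance(a: str, b: str, deletion: str = "pairwise") -> float:
    """Kimura 2-parameter distance between two aligned sequences.

    With P and Q the transition and transversion proportions over
    comparable sites, ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)``
    substitutions/site.  ``deletion`` controls gap handling: 'pairwise'
    drops sites missing in either sequence of this pair; 'complete' is
    equivalent for a single pair.
    """
    if len(a) != len(b):
        raise ValueError("aligned lengths differ")
    if deletion not in ("pairwise", "complete"):
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    sub = AlignedSequenceSet(["a", "b"], ["x", "x"], [a, b])
    enc = sub.encoded()
    valid = (enc[0] != 255) & (enc[1] != 255)
    ea, eb = enc[0][valid], enc[1][valid]
    diff = ea != eb
    ts = diff & (_PURINE[ea] == _PURINE[eb])
    return _k2p_from_counts(int(valid.sum()), int(ts.sum()), int((diff & ~ts).sum()))


def k2p_matrix(
    seqs: AlignedSequenceSet,
    deletion: str = "pairwise",
    saturation: str = "raise",
) -> np.ndarray:
    """All pairwise K2P distances (substitutions/site).

    ``saturation='raise'`` raises :class:`SaturationError` naming the
    offending pair; ``'nan'`` records NaN instead so summaries can
    proceed.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    if saturation not in ("raise", "nan"):
        raise ValueError("saturation must be 'raise' or 'nan'")
    enc = seqs.encoded()
    if deletion == "complete":
        keep = np.all(enc != 255, axis=0)
        enc = enc[:, keep]
    n = len(seqs)
    valid = enc != 255
    purine = np.zeros_like(enc, dtype=bool)
    ok = valid
    purine[ok] = _PURINE[enc[ok]]
    D = np.zeros((n, n))
    for i in range(n - 1):
        v = valid[i] & valid[i + 1 :]
        diff = (enc[i] != enc[i + 1 :]) & v
        ts = diff & (purine[i] == purine[i + 1 :])
        n_sites = v.sum(axis=1)
        n_ts = ts.sum(axis=1)
        n_tv = (diff & ~ts).sum(axis=1)
        for off, (ns, nt, nv) in enumerate(zip(n_sites, n_ts, n_tv)):
            j = i + 1 + off
            try:
                d = _k2p_from_counts(
                    int(ns), int(nt), int(nv),
                    pair=f" for pair ({seqs.ids[i]}, {seqs.ids[j]})",
                )
            except (SaturationError, ValueError):
                if saturation == "raise":
                    raise
                d = np.nan
            D[i, j] = D[j, i] = d
    return D


# ---------------------------------------------------------------------------
# Divergence summary and barcoding gap
# ---------------------------------------------------------------------------

@dataclass
class DivergenceSummary:
    """Per-species and per-pair K2P statistics, in percent."""

    table: pd.DataFrame  # species_a, species_b, kind, mean/min/max %, n
    overall_intra_mean: float
    overall_inter_mean: float
    species: list[str]
    distance_matrix: np.ndarray  # raw substitutions/site, specimen level
    sequence_species: list[str]

    def cell(self, a: str, b: str) -> pd.Series:
        t = self.table
        key = tuple(sorted((a, b)))
        row = t[(t.species_a == key[0]) & (t.species_b == key[1])]
        if row.empty:
            raise KeyError(f"no cell for pair {key}")
        return row.iloc[0]


def divergence_summary(
    seqs: AlignedSequenceSet,
    deletion: str = "pairwise",
    saturation: str = "raise",
) -> DivergenceSummary:
    """Table-style intra-/interspecific K2P divergence summary.

    Diagonal cells (species_a == species_b) hold intraspecific
    statistics over unordered distinct sequence pairs; species with a
    single sequence get an undefined (NaN) intraspecific cell, never
    zero.  Off-diagonal cells hold interspecific statistics.  All values
    are percent (x100).
    """
    species = sorted(set(seqs.species))
    if len(species) < 2:
        raise ValueError("divergence summary needs >= 2 species")
    D = k2p_matrix(seqs, deletion=deletion, saturation=saturation)
    sp = np.asarray(seqs.species)
    rows = []
    intra_all, inter_all = [], []
    for ia, a in enumerate(species):
        for b in species[ia:]:
            ix_a = np.flatnonzero(sp == a)
            ix_b = np.flatnonzero(sp == b)
            if a == b:
                if len(ix_a) < 2:
                    vals = np.array([])
                else:
                    iu = np.triu_indices(len(ix_a), 1)
                    vals = D[np.ix_(ix_a, ix_a)][iu]
                kind = "intra"
                if vals.size:
                    intra_all.append(vals)
            else:
                vals = D[np.ix_(ix_a, ix_b)].ravel()
                kind = "inter"
                inter_all.append(vals)
            vals = vals * 100.0
            ok = vals[~np.isnan(vals)] if vals.size else vals
            rows.append(
                {
                    "species_a": a,
                    "species_b": b,
                    "kind": kind,
                    "mean_pct": float(np.mean(ok)) if ok.size else np.nan,
                    "min_pct": float(np.min(ok)) if ok.size else np.nan,
                    "max_pct": float(np.max(ok)) if ok.size else np.nan,
                    "n_comparisons": int(vals.size),
                }
            )
    table = pd.DataFrame(rows)
    intra = np.concatenate(intra_all) if intra_all else np.array([])
    inter = np.concatenate(inter_all) if inter_all else np.array([])
    return DivergenceSummary(
        table=table,
        overall_intra_mean=float(np.nanmean(intra) * 100) if intra.size else np.nan,
        overall_inter_mean=float(np.nanmean(inter) * 100) if inter.size else np.nan,
        species=species,
        distance_matrix=D,
        sequence_species=list(seqs.species),
    )


@dataclass
class GapReport:
    """Barcoding-gap assessment for every species pair.

    A pair shows a barcoding gap when its smallest interspecific distance
    strictly exceeds the larger of the two species' intraspecific maxima.
    """

    table: pd.DataFrame  # species_a, species_b, max_intra_pct, min_inter_pct, gap_present

    @property
    def gapless_pairs(self) -> list[tuple[str, str]]:
        t = self.table
        sel = t[t.gap_present == False]  # noqa: E712  (NaN-safe)
        return [
            (r.species_a, r.species_b)
            for r in sel.itertuples()
            if r.gap_present is False or r.gap_present == False  # noqa: E712
        ]


def barcoding_gap(summary: DivergenceSummary) -> GapReport:
    """Detect presence/absence of the barcoding gap per species pair.

    ``gap_present`` is True iff min_inter > max_intra (strict); a pair
    with an undefined intraspecific cell on either side is reported
    indeterminate (``gap_present`` = None).
    """
    rows = []
    species = summary.species
    for ia, a in enumerate(species):
        for b in species[ia + 1 :]:
            inter = summary.cell(a, b)
            max_intra = np.nanmax(
                [summary.cell(a, a)["max_pct"], summary.cell(b, b)["max_pct"]]
            ) if not (
                np.isnan(summary.cell(a, a)["max_pct"])
                and np.isnan(summary.cell(b, b)["max_pct"])
            ) else np.nan
            indeterminate = np.isnan(summary.cell(a, a)["max_pct"]) or np.isnan(
                summary.cell(b, b)["max_pct"]
            )
            min_inter = inter["min_pct"]
            gap = None if indeterminate else bool(min_inter > max_intra)
            rows.append(
                {
                    "species_a": a,
                    "species_b": b,
                    "max_intra_pct": max_intra,
                    "min_inter_pct": min_inter,
                    "gap_present": gap,
                }
            )
    df = pd.DataFrame(rows)
    # keep plain Python bool / None (object dtype) so identity checks work
    df["gap_present"] = pd.Series(
        [g if g is None else bool(g) for g in df["gap_present"]], dtype=object
    )
    return GapReport(table=df)


# ---------------------------------------------------------------------------
# Neighbor joining and bootstrap
# ---------------------------------------------------------------------------

def nj_tree(dist: np.ndarray, taxa: list[str]) -> TreeNode:
    """Saitou–Nei neighbor joining on a distance matrix.

    Negative branch lengths are clamped to zero; on additive matrices the
    tree reproduces all input path lengths exactly.
    """
    D = np.asarray(dist, float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be square symmetric with zero diagonal")
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    dm = DistanceMatrix(D, ids=list(taxa))
    return nj(dm)


def _bipartitions(tree: TreeNode, all_tips: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, canonicalized as the
    side not containing the alphabetically first tip."""
    anchor = min(all_tips)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(all_tips - side) < 2:
            continue
        if anchor in side:
            side = all_tips - side
        if len(side) >= 2:
            parts.add(side)
    return parts


@dataclass
class BootstrapTree:
    tree: TreeNode  # full-data NJ topology, internal nodes labeled with support %
    newick: str
    supports: dict[frozenset, float]
    n_boot: int
    n_skipped: int
    tip_names: frozenset = frozenset()

    def support_for(self, tips) -> float | None:
        """Bootstrap support (%) of the bipartition separating ``tips``
        from the rest, or None if it is not in the full-data tree."""
        side = frozenset(tips)
        if min(self.tip_names) in side:
            side = self.tip_names - side
        return self.supports.get(side)


def bootstrap_nj(
    seqs: AlignedSequenceSet,
    n_boot: int = 1000,
    outgroup: str | None = None,
    seed: int | None = None,
    deletion: str = "pairwise",
) -> BootstrapTree:
    """NJ tree of K2P distances with site-resampling bootstrap supports.

    Sites are resampled with replacement ``n_boot`` times; the K2P matrix
    and NJ tree are recomputed per replicate, and each bipartition of the
    full-data tree is annotated with the percentage of replicates
    containing it.  Replicates with saturated distances are skipped and
    counted (warning if more than 1% skipped).  If ``outgroup`` is given
    the returned tree is rooted on it for display.
    """
    if len(seqs) < 4:
        raise ValueError("bootstrap NJ needs >= 4 sequences")
    rng = np.random.default_rng(seed)
    full_D = k2p_matrix(seqs, deletion=deletion)
    tree = nj_tree(full_D, seqs.ids)
    all_tips = frozenset(seqs.ids)
    ref_parts = _bipartitions(tree, all_tips)
    counts = {p: 0 for p in ref_parts}
    L = seqs.length
    n_skipped = 0
    n_used = 0
    for _ in range(n_boot):
        cols = rng.integers(0, L, size=L)
        rep = seqs.subset_sites(cols)
        try:
            Db = k2p_matrix(rep, deletion=deletion)
        except (SaturationError, ValueError):
            n_skipped += 1
            continue
        tb = nj_tree(Db, rep.ids)
        parts_b = _bipartitions(tb, all_tips)
        for p in ref_parts:
            if p in parts_b:
                counts[p] += 1
        n_used += 1
    if n_used == 0:
        raise SaturationError("every bootstrap replicate was saturated")
    if n_skipped > 0.01 * n_boot:
        warnings.warn(f"{n_skipped}/{n_boot} bootstrap replicates skipped (saturation)")
    supports = {p: 100.0 * counts[p] / n_used for p in ref_parts}

    display = tree
    if outgroup is not None:
        og = display.find(outgroup)
        display = display.root_at(og.parent if og.is_tip() else og)
    for node in display.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = side if min(all_tips) not in side else all_tips - side
        if canon in supports:
            node.name = f"{supports[canon]:.0f}"
    return BootstrapTree(
        tree=display,
        newick=str(display).strip(),
        supports=supports,
        n_boot=n_boot,
        n_skipped=n_skipped,
        tip_names=all_tips,
    )
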