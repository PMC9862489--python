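"""Labeled 2-D landmark configurations and file I/O.

A *landmark* is a homologous anatomical point (here a wing-vein
intersection or terminus) digitized as an (x, y) coordinate pair.  A
:class:`LandmarkDataset` holds one :class:`LandmarkConfiguration` per
digitization of a specimen's wing; re-digitizations of the same wing are
distinguished by ``replicate_index`` (0 = the original digitization).

Landmark indices are 1-based in files and reports and 0-based internally.
Coordinates are stored in native digitizing units; the optional ``scale``
(units per mm) is carried as metadata and only applied on explicit request,
because Procrustes superimposition discards scale anyway.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkConfiguration",
    "LandmarkDataset",
    "centroid_size",
    "read_tps",
    "write_tps",
    "read_landmarks_csv",
    "write_landmarks_csv",
]


class LandmarkFormatError(ValueError):
    """Raised for malformed landmark files."""


class DegenerateConfigurationError(ValueError):
    """Raised when all landmarks of a configuration coincide."""


@dataclass
class LandmarkConfiguration:
    """One digitization of one specimen.

    Parameters
    ----------
    specimen_id : str
        Unique specimen identifier.
    species_label : str
        Free-text species label, compared case-sensitively after
        whitespace trimming.
    coords : (n_landmarks, 2) float array
        Landmark coordinates in digitizing units.
    scale : float, optional
        Digitizing units per millimetre, if recorded.
    replicate_index : int
        0 for the original digitization, >0 for re-digitizations.
    """

    specimen_id: str
    species_label: str
    coords: np.ndarray
    scale: float | None = None
    replicate_index: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"coords must be (n_landmarks, 2), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(
                f"non-finite coordinate in specimen {self.specimen_id!r}"
            )
        if self.replicate_index < 0:
            raise ValueError("replicate_index must be >= 0")
        self.species_label = self.species_label.strip()

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass
class LandmarkDataset:
    """A collection of landmark configurations sharing one landmark scheme."""

    configurations: list[LandmarkConfiguration]
    n_landmarks: int
    dimension: int = 2

    def __post_init__(self) -> None:
        for cfg in self.configurations:
            if cfg.n_landmarks != self.n_landmarks:
                raise ValueError(
                    f"specimen {cfg.specimen_id!r} has {cfg.n_landmarks} "
                    f"landmarks, dataset declares {self.n_landmarks}"
                )

    @classmethod
    def from_configurations(
        cls, configurations: list[LandmarkConfiguration]
    ) -> "LandmarkDataset":
        if not configurations:
            raise ValueError("cannot build a dataset from zero configurations")
        return cls(configurations, configurations[0].n_landmarks)

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    def coords_array(self) -> np.ndarray:
        """Stack all configurations into an (n, n_landmarks, 2) array."""
        return np.stack([c.coords for c in self.configurations])

    @property
    def species_labels(self) -> list[str]:
        return [c.species_label for c in self.configurations]

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    @property
    def replicate_indices(self) -> list[int]:
        return [c.replicate_index for c in self.configurations]


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: root summed squared landmark distances to the centroid.

    The standard geometric-morphometric size measure; invariant under
    translation and rotation and linear in coordinate scaling.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if coords.shape[0] < 2:
        raise ValueError("centroid size needs at least 2 landmarks")
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs == 0.0:
        name = config.specimen_id if isinstance(config, LandmarkConfiguration) else "<array>"
        raise DegenerateConfigurationError(
            f"all landmarks coincide in configuration {name}"
        )
    return cs


# ---------------------------------------------------------------------------
# TPS dialect
#
# Recognized keys: LM= (landmark count, begins a block), ID=, IMAGE=, SCALE=.
# Unknown keys are skipped with a logged warning.  The species label is taken
# from a sidecar id->species mapping when given; otherwise it is parsed from
# the ID as the token before the first underscore.  A trailing "_r<k>" token
# in the ID marks re-digitization k of the same specimen.
# ---------------------------------------------------------------------------

_REPLICATE_RE = re.compile(r"^(?P<base>.+)_r(?P<rep>\d+)$")
_KNOWN_KEYS = {"LM", "ID", "IMAGE", "SCALE"}


def _split_id(raw_id: str, species_map: dict[str, str] | None) -> tuple[str, str, int]:
    m = _REPLICATE_RE.match(raw_id)
    if m:
        base, rep = m.group("base"), int(m.group("rep"))
    else:
        base, rep = raw_id, 0
    if species_map is not None:
        try:
            species = species_map[base]
        except KeyError:
            raise LandmarkFormatError(
                f"specimen id {base!r} missing from species map"
            ) from None
    else:
        species = base.split("_")[0]
    return base, species, rep


def read_tps(
    path: str | Path,
    species_map: dict[str, str] | None = None,
) -> LandmarkDataset:
    """Read a TPS landmark file into a :class:`LandmarkDataset`.

    Every ``LM=`` record starts one configuration block and must be followed
    by exactly that many coordinate lines.  ``SCALE=`` is stored as metadata
    and never multiplied into the coordinates.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    block_no = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise LandmarkFormatError(
                f"{path}: expected LM= at line {i + 1}, found {line!r}"
            )
        block_no += 1
        try:
            n_lm = int(line.split("=", 1)[1])
        except ValueError:
            raise LandmarkFormatError(
                f"{path}: bad landmark count at line {i + 1}"
            ) from None
        i += 1
        coords = []
        while len(coords) < n_lm and i < len(lines):
            row = lines[i].strip()
            if "=" in row:
                break
            if row:
                parts = row.split()
                try:
                    coords.append((float(parts[0]), float(parts[1])))
                except (ValueError, IndexError):
                    raise LandmarkFormatError(
                        f"{path}: non-numeric coordinate at line {i + 1}"
                    ) from None
            i += 1
        if len(coords) != n_lm:
            raise LandmarkFormatError(
                f"{path}: block {block_no} declares LM={n_lm} but has "
                f"{len(coords)} coordinate lines"
            )
        raw_id = f"block{block_no}"
        scale = None
        while i < len(lines):
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if row.upper().startswith("LM="):
                break
            key = row.split("=", 1)[0].upper()
            if key == "ID":
                raw_id = row.split("=", 1)[1].strip()
            elif key == "SCALE":
                scale = float(row.split("=", 1)[1])
            elif key == "IMAGE":
                pass
            else:
                logger.warning("%s: ignoring unknown TPS key %r", path, key)
            i += 1
        base, species, rep = _split_id(raw_id, species_map)
        configs.append(
            LandmarkConfiguration(base, species, np.array(coords), scale, rep)
        )
    if not configs:
        raise LandmarkFormatError(f"{path}: no LM blocks found")
    return LandmarkDataset.from_configurations(configs)


def write_tps(dataset: LandmarkDataset, path: str | Path) -> None:
    """Write a dataset in TPS format (LM=, coordinate lines, ID=, SCALE=)."""
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    out = []
    for cfg in dataset:
        out.append(f"LM={cfg.n_landmarks}")
        for x, y in cfg.coords:
            out.append(f"{x:.10f} {y:.10f}")
        raw_id = cfg.specimen_id
        if cfg.replicate_index > 0:
            raw_id = f"{raw_id}_r{cfg.replicate_index}"
        out.append(f"ID={raw_id}")
        if cfg.scale is not None:
            out.append(f"SCALE={cfg.scale:.10f}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Long-format CSV
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["specimen_id", "species_label", "replicate_index", "landmark_index", "x", "y"]


def write_landmarks_csv(dataset: LandmarkDataset, path: str | Path) -> None:
    """Write a long-format landmark table (one row per landmark).

    Columns: specimen_id, species_label, replicate_index,
    landmark_index (1-based), x, y.
    """
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    rows = []
    for cfg in dataset:
        for j, (x, y) in enumerate(cfg.coords, start=1):
            rows.append(
                (cfg.specimen_id, cfg.species_label, cfg.replicate_index, j, x, y)
            )
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_landmarks_csv(path: str | Path) -> LandmarkDataset:
    """Read the long-format landmark table written by :func:`write_landmarks_csv`."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise LandmarkFormatError(f"{path}: missing columns {sorted(missing)}")
    configs = []
    for (sid, rep), grp in df.groupby(["specimen_id", "replicate_index"], sort=False):
        grp = grp.sort_values("landmark_index")
        if not np.array_equal(grp["landmark_index"].to_numpy(), np.arange(1, len(grp) + 1)):
            raise LandmarkFormatError(
                f"{path}: landmark indices for specimen {sid!r} are not 1..n"
            )
        configs.append(
            LandmarkConfiguration(
                str(sid),
                str(grp["species_label"].iloc[0]),
                grp[["x", "y"]].to_numpy(float),
                None,
                int(rep),
            )
        )
    return LandmarkDataset.from_configurations(configs)
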