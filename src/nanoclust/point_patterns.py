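"""Data model and I/O for immunogold point patterns.

Patterns are gold-particle (x, y) coordinates in nanometres, digitised from
TEM images of intact plasma-membrane sheets.  The coordinate system has its
origin at the lower-left corner of the observation window, y increasing
upward.  Coordinates are continuous floats; duplicate coordinates are
permitted by the estimator but flagged during validation because physical
gold particles exclude each other.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Window",
    "PointPattern",
    "ConditionGroup",
    "ProximityWarning",
    "read_point_pattern",
    "write_point_pattern",
    "read_manifest",
    "validate_pattern",
]


@dataclass(frozen=True)
class Window:
    """Rectangular observation window, dimensions in nm.

    The default study area is a 1 um^2 membrane sheet, i.e. 1000 x 1000 nm.
    """

    width: float = 1000.0
    height: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("window dimensions must be positive")

    @property
    def area(self) -> float:
        """Window area in nm^2 (the symbol A of the K-function)."""
        return self.width * self.height

    def contains(self, coords: np.ndarray, atol: float = 0.0) -> np.ndarray:
        """Boolean mask of points inside [0, width] x [0, height] (+/- atol)."""
        coords = np.asarray(coords, dtype=float).reshape(-1, 2)
        return (
            (coords[:, 0] >= -atol)
            & (coords[:, 0] <= self.width + atol)
            & (coords[:, 1] >= -atol)
            & (coords[:, 1] <= self.height + atol)
        )


@dataclass
class PointPattern:
    """A finite point pattern inside a bounded rectangular window.

    Parameters
    ----------
    coords : (n, 2) float array
        Particle positions in nm, order preserved from the source file.
    window : Window
        Observation window; every point must lie inside it.
    image_id : str
        Label of the membrane sheet / micrograph this pattern came from.
    condition : str
        Experimental condition label used for grouping.
    """

    coords: np.ndarray
    window: Window = field(default_factory=Window)
    image_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.size == 0:
            coords = np.empty((0, 2), dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords contain non-finite values")
        if not np.all(self.window.contains(coords)):
            bad = np.flatnonzero(~self.window.contains(coords))
            raise ValueError(
                f"{bad.size} point(s) outside the window (first at row {bad[0]})"
            )
        self.coords = coords

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n


@dataclass
class ConditionGroup:
    """Patterns sharing one condition label, for replicated-pattern analysis.

    The study design images at least 15 membrane sheets per condition; group
    analysis refuses smaller groups unless ``minimum_images`` is lowered.
    """

    patterns: list[PointPattern]
    minimum_images: int = 15

    def __post_init__(self) -> None:
        labels = {p.condition for p in self.patterns}
        if len(labels) > 1:
            raise ValueError(f"patterns mix condition labels: {sorted(labels)}")

    @property
    def condition(self) -> str:
        return self.patterns[0].condition if self.patterns else ""

    def require_minimum(self) -> None:
        if len(self.patterns) < self.minimum_images:
            raise ValueError(
                f"group '{self.condition}' has {len(self.patterns)} patterns; "
                f"at least {self.minimum_images} required"
            )


@dataclass(frozen=True)
class ProximityWarning:
    """A pair of points closer than the physical minimum separation."""

    i: int
    j: int
    distance: float


def read_point_pattern(
    path: str | Path,
    window: Window | None = None,
    image_id: str = "",
    condition: str = "",
    *,
    delimiter: str | None = None,
    out_of_window: str = "reject",
    clip_tolerance: float = 1.0,
) -> PointPattern:
    """Read a two-column x,y coordinate table (nm) into a PointPattern.

    The file is a delimited numeric table with an optional header row.  An
    empty file yields an empty pattern.  Points outside the window are an
    error under ``out_of_window='reject'`` (the default: they violate the
    study-area premise of the K-function); ``'clip'`` snaps digitisation
    slop within ``clip_tolerance`` nm back onto the boundary and still
    rejects anything further out.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    window = window or Window()
    if out_of_window not in ("reject", "clip"):
        raise ValueError(f"unknown out_of_window mode: {out_of_window!r}")

    sep = delimiter if delimiter is not None else r"[,\t;\s]+"
    try:
        df = pd.read_csv(path, sep=sep, header=None, comment="#", engine="python")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=[0, 1])
    if df.shape[0] and not _is_numeric_row(df.iloc[0]):
        df = df.iloc[1:]  # header row
    if df.shape[1] < 2 and df.shape[0] > 0:
        raise ValueError(f"{path}: expected two coordinate columns")
    if df.shape[0] == 0:
        coords = np.empty((0, 2))
    else:
        try:
            coords = df.iloc[:, :2].to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric coordinate rows") from exc

    if out_of_window == "clip":
        inside_loose = window.contains(coords, atol=clip_tolerance)
        if not np.all(inside_loose):
            bad = np.flatnonzero(~inside_loose)
            raise ValueError(
                f"{path}: point at row {bad[0]} more than {clip_tolerance} nm "
                "outside the window"
            )
        coords[:, 0] = np.clip(coords[:, 0], 0.0, window.width)
        coords[:, 1] = np.clip(coords[:, 1], 0.0, window.height)
    return PointPattern(coords, window, image_id=image_id, condition=condition)


def write_point_pattern(pattern: PointPattern, path: str | Path) -> Path:
    """Write a pattern as a two-column CSV with an x,y header (nm, full float precision)."""
    path = Path(path)
    df = pd.DataFrame(pattern.coords, columns=["x", "y"])
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_manifest(
    manifest_path: str | Path,
    *,
    base_dir: str | Path | None = None,
    out_of_window: str = "reject",
) -> list[PointPattern]:
    """Load patterns listed in a manifest CSV.

    Columns: ``file, image_id, condition`` and optional ``width, height`` (nm,
    default 1000 x 1000).  Relative file paths resolve against the manifest's
    directory unless ``base_dir`` is given.
    """
    manifest_path = Path(manifest_path)
    base = Path(base_dir) if base_dir is not None else manifest_path.parent
    df = pd.read_csv(manifest_path)
    required = {"file", "image_id", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest missing columns: {sorted(required - set(df.columns))}")
    patterns = []
    for row in df.itertuples(index=False):
        w = Window(float(getattr(row, "width", 1000.0) or 1000.0),
                   float(getattr(row, "height", 1000.0) or 1000.0))
        fp = Path(row.file)
        if not fp.is_absolute():
            fp = base / fp
        patterns.append(
            read_point_pattern(fp, w, image_id=str(row.image_id),
                               condition=str(row.condition),
                               out_of_window=out_of_window)
        )
    return patterns


def validate_pattern(
    pattern: PointPattern, min_separation: float = 0.0
) -> tuple[PointPattern, list[ProximityWarning]]:
    """Check physical plausibility of a pattern without mutating it.

    Gold particles are ~4.5 nm solid spheres, so genuine labels cannot sit
    closer than one particle diameter.  Pairs closer than ``min_separation``
    (nm) are returned as warning records; ``min_separation=0`` disables the
    check.  The pattern itself is returned unchanged.
    """
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    warnings: list[ProximityWarning] = []
    if min_separation > 0 and pattern.n >= 2:
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pattern.coords))
        iu = np.triu_indices(pattern.n, k=1)
        close = d[iu] < min_separation
        for i, j, dist in zip(iu[0][close], iu[1][close], d[iu][close]):
            warnings.append(ProximityWarning(int(i), int(j), float(dist)))
    return pattern, warnings


def file_sha256(path: str | Path) -> str:
    """Hex digest of a file's contents, for run-record logging."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _is_numeric_row(row: pd.Series) -> bool:
    try:
        row.astype(float)
        return True
    except (TypeError, ValueError):
        return False
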