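"""Molecular geometries and XYZ file I/O.

A :class:`Geometry` is a minimal container for one molecular species or
fragment: element symbols plus Cartesian coordinates in Ångström.  Multi-frame
XYZ files (trajectory pools) are read into lists of geometries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Geometry", "read_xyz", "write_xyz", "place_atom"]


@dataclass(frozen=True)
class Geometry:
    """Element symbols and Cartesian coordinates (Å) of one species.

    Parameters
    ----------
    symbols : tuple of str
        Element symbols, e.g. ``("S", "C", "H")``.
    coords : ndarray, shape (n_atoms, 3)
        Cartesian coordinates in Ångström.
    label : str
        Free-text species label (e.g. ``"DT"``, ``"biradical"``).
    """

    symbols: tuple[str, ...]
    coords: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must have shape (n, 3), got {coords.shape}")
        if len(self.symbols) != coords.shape[0]:
            raise ValueError(
                f"{len(self.symbols)} symbols but {coords.shape[0]} coordinate rows"
            )
        if coords.shape[0] < 1:
            raise ValueError("geometry needs at least one atom")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "symbols", tuple(str(s) for s in self.symbols))
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def distances(self) -> np.ndarray:
        """Pairwise distance matrix (Å)."""
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((d**2).sum(axis=-1))

    def composition(self) -> dict[str, int]:
        comp: dict[str, int] = {}
        for s in self.symbols:
            comp[s] = comp.get(s, 0) + 1
        return comp

    def translated(self, shift: Sequence[float]) -> "Geometry":
        return Geometry(self.symbols, self.coords + np.asarray(shift, float), self.label)

    def rotated(self, matrix: np.ndarray) -> "Geometry":
        """Rigidly rotate by a 3x3 rotation matrix."""
        matrix = np.asarray(matrix, float)
        return Geometry(self.symbols, self.coords @ matrix.T, self.label)


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle: float, dihedral: float,
) -> np.ndarray:
    """Position a new atom from internal coordinates (Z-matrix step).

    The new atom is placed at distance ``bond`` from ``c``, forming
    ``angle`` (degrees) with ``b--c`` and dihedral ``dihedral`` (degrees)
    about the ``b--c`` axis relative to ``a``.
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    ang = np.deg2rad(angle)
    dih = np.deg2rad(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("reference atoms are collinear; dihedral undefined")
    n /= nn
    m = np.cross(n, bc)
    d = -bond * np.cos(ang) * bc + bond * np.sin(ang) * (np.cos(dih) * m + np.sin(dih) * n)
    return c + d


# ---------------------------------------------------------------------------
# XYZ I/O


def _parse_frames(lines: list[str], label_default: str) -> list[Geometry]:
    frames: list[Geometry] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(f"expected atom count at line {i + 1}") from exc
        if i + 2 + natoms > n_lines:
            raise ValueError("truncated XYZ frame")
        comment = lines[i + 1].strip()
        symbols = []
        coords = np.empty((natoms, 3))
        for j in range(natoms):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ValueError(f"malformed atom line {i + 3 + j}")
            symbols.append(parts[0])
            coords[j] = [float(x) for x in parts[1:4]]
        frames.append(Geometry(tuple(symbols), coords, comment or label_default))
        i += 2 + natoms
    return frames


def read_xyz(path: str | Path) -> list[Geometry]:
    """Read a (possibly multi-frame) XYZ file; returns a list of geometries."""
    path = Path(path)
    lines = path.read_text().splitlines()
    frames = _parse_frames(lines, label_default=path.stem)
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return frames


def write_xyz(path: str | Path, geometries: Geometry | Iterable[Geometry]) -> None:
    """Write one geometry or a trajectory of geometries to an XYZ file."""
    if isinstance(geometries, Geometry):
        geometries = [geometries]
    out = []
    for g in geometries:
        out.append(f"{g.n_atoms}")
        out.append(g.label)
        for s, (x, y, z) in zip(g.symbols, g.coords):
            out.append(f"{s:<2s} {x:15.8f} {y:15.8f} {z:15.8f}")
    Path(path).write_text("\n".join(out) + "\n")
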