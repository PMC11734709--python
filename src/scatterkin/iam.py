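"""Independent-atom-model (IAM) scattering patterns and percent differences.

Under the IAM the molecular electron density is a superposition of spherical
atomic densities, and the rotationally averaged elastic scattering intensity
follows the Debye equation

    I(q) = sum_ij f_i(q) f_j(q) sinc(q r_ij),

with f_i the tabulated atomic form factors and r_ij the interatomic
distances.  Pump-probe observables are expressed as percent differences
100 (I_on - I_off) / I_off, which cancels static backgrounds to first order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .formfactors import FormFactorModel
from .geometry import Geometry

__all__ = [
    "Pattern",
    "DiffPattern",
    "validate_qgrid",
    "debye_pattern",
    "mixture_pattern",
    "percent_difference",
]


def validate_qgrid(q: np.ndarray) -> np.ndarray:
    """Validate and return a momentum-transfer grid (1/Å, strictly increasing, >= 0)."""
    q = np.asarray(q, dtype=float)
    if q.ndim != 1 or q.size < 1:
        raise ValueError("q grid must be a non-empty 1-D array")
    if not np.all(np.isfinite(q)):
        raise ValueError("q grid contains non-finite values")
    if np.any(q < 0):
        raise ValueError("q values must be >= 0")
    if q.size > 1 and np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be strictly increasing")
    return q


@dataclass(frozen=True)
class Pattern:
    """Rotationally averaged scattering intensity on a q grid (electron units)."""

    q: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        q = validate_qgrid(self.q)
        inten = np.asarray(self.intensity, dtype=float)
        if inten.shape != q.shape:
            raise ValueError("intensity and q grids differ in length")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", inten)

    def __add__(self, other: "Pattern") -> "Pattern":
        if not np.array_equal(self.q, other.q):
            raise ValueError("cannot add patterns on different q grids")
        return Pattern(self.q, self.intensity + other.intensity,
                       label=f"{self.label}+{other.label}")

    def save(self, path: str | Path) -> None:
        header = f"label: {self.label}\nq [1/A]    I [electron units]"
        np.savetxt(path, np.column_stack([self.q, self.intensity]), header=header)

    @classmethod
    def load(cls, path: str | Path, label: str = "") -> "Pattern":
        arr = np.loadtxt(path)
        return cls(arr[:, 0], arr[:, 1], label=label or Path(path).stem)


@dataclass(frozen=True)
class DiffPattern:
    """Percent-difference pattern 100 (I_on - I_off)/I_off against a reference."""

    q: np.ndarray
    values: np.ndarray
    reference: str = "DT"
    label: str = ""
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        q = validate_qgrid(self.q)
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != q.shape:
            raise ValueError("values and q grids differ in length")
        if not np.all(np.isfinite(vals)):
            raise ValueError("percent-difference values must be finite")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "values", vals)
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            if s.shape != q.shape:
                raise ValueError("sigma and q grids differ in length")
            object.__setattr__(self, "sigma", s)

    def save(self, path: str | Path) -> None:
        cols = [self.q, self.values]
        names = "q [1/A]    dI/I [%]"
        if self.sigma is not None:
            cols.append(self.sigma)
            names += "    sigma [%]"
        header = f"label: {self.label}\nreference: {self.reference}\n{names}"
        np.savetxt(path, np.column_stack(cols), header=header)

    @classmethod
    def load(cls, path: str | Path, label: str = "", reference: str = "DT") -> "DiffPattern":
        arr = np.loadtxt(path)
        sigma = arr[:, 2] if arr.shape[1] > 2 else None
        return cls(arr[:, 0], arr[:, 1], reference=reference,
                   label=label or Path(path).stem, sigma=sigma)


def debye_pattern(geometry: Geometry, q: np.ndarray,
                  ff: FormFactorModel | None = None) -> Pattern:
    """Rotationally averaged IAM intensity of one rigid structure.

    Evaluates the Debye double sum; the self terms (i = j) and the q = 0
    limit use sinc -> 1.  Intensity is in electron units, so
    I(0) = (sum_i Z_i)^2.
    """
    ff = ff if ff is not None else FormFactorModel()
    q = validate_qgrid(q)
    f = np.stack([ff.evaluate(s, q) for s in geometry.symbols])  # (n_atoms, nq)
    r = geometry.distances()
    qr = q[None, None, :] * r[:, :, None]  # (n, n, nq)
    # np.sinc(x) = sin(pi x)/(pi x); handles qr = 0 exactly
    sinc = np.sinc(qr / np.pi)
    inten = np.einsum("iq,jq,ijq->q", f, f, sinc)
    return Pattern(q, inten, label=geometry.label)


def mixture_pattern(geometries: Sequence[Geometry], q: np.ndarray,
                    ff: FormFactorModel | None = None) -> Pattern:
    """Incoherent sum of the IAM patterns of well-separated fragments.

    Dissociation co-fragments fly apart; beyond a few tens of Å their
    interference term oscillates faster than any practical q bin, so the
    observed intensity is the plain sum of the fragment intensities.
    """
    if len(geometries) == 0:
        raise ValueError("mixture requires at least one geometry")
    ff = ff if ff is not None else FormFactorModel()
    q = validate_qgrid(q)
    total = np.zeros_like(q)
    labels = []
    for g in geometries:
        total = total + debye_pattern(g, q, ff).intensity
        labels.append(g.label or "?")
    return Pattern(q, total, label="+".join(labels))


def percent_difference(on: Pattern, off: Pattern) -> DiffPattern:
    """Percent difference 100 (I_on - I_off) / I_off of two patterns."""
    if not np.array_equal(on.q, off.q):
        raise ValueError("patterns are on different q grids")
    if np.any(off.intensity <= 0):
        raise ValueError("reference (off) intensity must be strictly positive")
    vals = 100.0 * (on.intensity - off.intensity) / off.intensity
    return DiffPattern(on.q, vals, reference=off.label or "off", label=on.label)
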