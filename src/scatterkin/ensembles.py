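"""Ensemble-averaged scattering for vibrationally hot species.

A vibrationally hot molecule explores a distribution of geometries; its
rotationally averaged scattering is the (weighted) mean of the single-frame
IAM patterns over a geometry pool.  Averaging damps the interference
oscillations relative to the equilibrium structure while leaving I(0)
pinned at the squared electron count.  Pools can be loaded from multi-frame
XYZ files (e.g. molecular-dynamics snapshots) or generated with a toy
Gaussian-displacement sampler.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .formfactors import FormFactorModel
from .geometry import Geometry, read_xyz
from .iam import Pattern, debye_pattern, validate_qgrid

__all__ = ["GeometryPool", "ensemble_pattern", "toy_thermal_pool", "load_pool"]


@dataclass(frozen=True)
class GeometryPool:
    """A pool of geometry frames with optional per-frame weights."""

    frames: tuple[Geometry, ...]
    weights: np.ndarray | None = None
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("pool needs at least one frame")
        comp0 = self.frames[0].composition()
        for i, g in enumerate(self.frames):
            if g.composition() != comp0:
                raise ValueError(
                    f"frame {i} composition {g.composition()} differs from frame 0 {comp0}"
                )
        if self.weights is not None:
            w = np.asarray(self.weights, float)
            if w.shape != (len(self.frames),):
                raise ValueError("one weight per frame required")
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError("weights must be >= 0 with positive sum")
            object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.frames)

    def normalized_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.full(len(self.frames), 1.0 / len(self.frames))
        return self.weights / self.weights.sum()


def ensemble_pattern(pool: GeometryPool, q: np.ndarray,
                     ff: FormFactorModel | None = None) -> Pattern:
    """Weighted mean IAM pattern over the frames of a pool."""
    q = validate_qgrid(q)
    ff = ff if ff is not None else FormFactorModel()
    w = pool.normalized_weights()
    total = np.zeros_like(q)
    for wi, frame in zip(w, pool.frames):
        if wi > 0:
            total += wi * debye_pattern(frame, q, ff).intensity
    label = pool.frames[0].label or "ensemble"
    return Pattern(q, total, label=f"<{label}> n={len(pool)}")


def toy_thermal_pool(seed_geometry: Geometry, amplitude: float, n: int,
                     seed: int | None = None) -> GeometryPool:
    """Gaussian-displacement stand-in for a hot-molecule geometry pool.

    Each of ``n`` frames displaces every Cartesian coordinate independently
    by a zero-mean Gaussian of standard deviation ``amplitude`` (Å).  This
    emulates the pattern-damping effect of thermal structural disorder; it
    carries no dynamics, mode structure or anharmonicity.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n):
        disp = rng.normal(0.0, amplitude, size=seed_geometry.coords.shape) if amplitude > 0 \
            else np.zeros_like(seed_geometry.coords)
        frames.append(Geometry(seed_geometry.symbols,
                               seed_geometry.coords + disp,
                               label=f"{seed_geometry.label}-hot{i}"))
    return GeometryPool(tuple(frames),
                        provenance=f"toy-sampler(amplitude={amplitude}, n={n}, seed={seed})")


def load_pool(path: str | Path, weights: np.ndarray | None = None) -> GeometryPool:
    """Load a multi-frame XYZ trajectory as a geometry pool."""
    frames = read_xyz(path)
    return GeometryPool(tuple(frames), weights=weights,
                        provenance=f"file:{path} ({len(frames)} frames)")
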