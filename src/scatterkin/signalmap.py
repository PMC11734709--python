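"""The central observable: a percent-difference scattering map on (q, t).

``SignalMap`` stores %dI(q, t) with per-point standard deviations and an
optional mask for missing pixels; this is the quantity the global kinetic
fit consumes.  Maps serialize to a single plain-text file with labelled
sections so runs remain diff-able and portable.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .iam import validate_qgrid

__all__ = ["SignalMap"]


@dataclass
class SignalMap:
    """Percent-difference scattering signal %dI(q, t).

    Parameters
    ----------
    q : ndarray, shape (nq,)
        Momentum transfer grid in 1/Å (strictly increasing).
    t : ndarray, shape (nt,)
        Pump-probe delays in fs.
    values : ndarray, shape (nq, nt)
        Percent-difference values.
    sigma : ndarray, shape (nq, nt)
        Per-point standard deviations (same units); must be > 0 where data
        are present.
    mask : ndarray of bool, optional
        True marks missing/invalid points, excluded from all fits.
    meta : dict
        Provenance (source "experiment" | "synthetic", seed, ...).
    """

    q: np.ndarray
    t: np.ndarray
    values: np.ndarray
    sigma: np.ndarray
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = validate_qgrid(self.q)
        self.t = np.asarray(self.t, float)
        self.values = np.asarray(self.values, float)
        self.sigma = np.asarray(self.sigma, float)
        shape = (self.q.size, self.t.size)
        if self.values.shape != shape:
            raise ValueError(f"values shape {self.values.shape} != {shape}")
        if self.sigma.shape != shape:
            raise ValueError(f"sigma shape {self.sigma.shape} != {shape}")
        if self.mask is None:
            self.mask = np.zeros(shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != shape:
                raise ValueError(f"mask shape {self.mask.shape} != {shape}")
        ok = ~self.mask
        if not np.all(np.isfinite(self.values[ok])):
            raise ValueError("non-finite values outside the mask")
        if np.any(self.sigma[ok] <= 0):
            raise ValueError("sigma must be > 0 where data are present")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def weights(self) -> np.ndarray:
        """Inverse-variance weights, 0 on masked points."""
        w = np.zeros_like(self.sigma)
        ok = ~self.mask
        w[ok] = 1.0 / self.sigma[ok] ** 2
        return w

    # ------------------------------------------------------------------
    # plain-text serialization

    def save(self, path: str | Path) -> None:
        buf = io.StringIO()
        buf.write("# scatterkin signal map v1\n")
        buf.write("# meta: " + json.dumps(self.meta, default=str) + "\n")
        for name, arr in (("q", self.q), ("t", self.t)):
            buf.write(f"# section: {name}\n")
            np.savetxt(buf, arr[None, :], fmt="%.10g")
        for name, arr in (("values", self.values), ("sigma", self.sigma),
                          ("mask", self.mask.astype(int))):
            buf.write(f"# section: {name}\n")
            np.savetxt(buf, arr, fmt="%.10g")
        Path(path).write_text(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "SignalMap":
        lines = Path(path).read_text().splitlines()
        meta: dict = {}
        sections: dict[str, list[str]] = {}
        current: str | None = None
        for line in lines:
            if line.startswith("# meta:"):
                meta = json.loads(line.split(":", 1)[1])
            elif line.startswith("# section:"):
                current = line.split(":", 1)[1].strip()
                sections[current] = []
            elif line.startswith("#") or not line.strip():
                continue
            elif current is not None:
                sections[current].append(line)
        def arr(name: str) -> np.ndarray:
            return np.loadtxt(io.StringIO("\n".join(sections[name])))
        q = np.atleast_1d(arr("q"))
        t = np.atleast_1d(arr("t"))
        values = arr("values").reshape(q.size, t.size)
        sigma = arr("sigma").reshape(q.size, t.size)
        mask = arr("mask").reshape(q.size, t.size).astype(bool)
        return cls(q, t, values, sigma, mask=mask, meta=meta)
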