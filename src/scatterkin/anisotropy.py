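"""Detector-plane simulation and isotropic/anisotropic decomposition.

A linearly polarized pump pulse photoselects molecules by the cosine-squared
overlap of their transition dipole with the polarization axis, imprinting a
second-Legendre angular modulation on the difference scattering signal:

    I(q, theta_q) = S0(q) + S2(q) P2(cos theta_q),

with theta_q the angle between the scattering vector and the pump
polarization.  This module renders simplified flat-detector images of that
model (with the Thomson polarization factor of the x-ray probe) and inverts
them by per-bin weighted linear regression, recovering S0 and S2 with
per-bin uncertainties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .iam import DiffPattern

__all__ = [
    "DetectorGeometry",
    "Image2D",
    "IsoAnisoPair",
    "pixel_to_q_theta",
    "decompose_iso_aniso",
    "render_detector_image",
    "photon_energy_ev",
    "wavelength_angstrom",
]

_HC_EV_NM = 1239.8419843320026  # h*c in eV nm


def photon_energy_ev(wavelength_nm: float) -> float:
    """Photon energy (eV) of light with the given vacuum wavelength (nm)."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be > 0")
    return _HC_EV_NM / wavelength_nm


def wavelength_angstrom(energy_kev: float) -> float:
    """X-ray wavelength (Å) at the given photon energy (keV)."""
    if energy_kev <= 0:
        raise ValueError("photon energy must be > 0")
    return _HC_EV_NM / (energy_kev * 1000.0) * 10.0


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat square detector downstream of the interaction point.

    The beam travels along +z and hits the detector centre region; the pump
    polarization lies in the detector (x, y) plane.  The x-ray probe is
    taken linearly polarized along x (horizontal), giving the Thomson
    factor 1 - (e_out . x)^2.
    """

    distance_mm: float = 80.0
    pixel_mm: float = 0.4
    shape: tuple[int, int] = (128, 128)
    center: tuple[float, float] | None = None  # pixels; default: image centre
    energy_kev: float = 9.5
    polarization: tuple[float, float] = (1.0, 0.0)  # pump axis, detector plane

    def __post_init__(self) -> None:
        if self.distance_mm <= 0 or self.pixel_mm <= 0 or self.energy_kev <= 0:
            raise ValueError("distance, pixel pitch and photon energy must be > 0")
        p = np.asarray(self.polarization, float)
        n = np.linalg.norm(p)
        if n == 0:
            raise ValueError("polarization axis must be non-zero")
        object.__setattr__(self, "polarization", tuple(p / n))
        if self.center is None:
            object.__setattr__(self, "center",
                               ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0))

    @property
    def wavelength(self) -> float:
        return wavelength_angstrom(self.energy_kev)


@dataclass
class Image2D:
    """Pixel intensities plus a mask (True = excluded)."""

    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("image must be 2-D")
        if self.mask is None:
            self.mask = np.zeros_like(self.values, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape mismatch")


@dataclass(frozen=True)
class IsoAnisoPair:
    """Radially binned isotropic (S0) and anisotropic (S2) components."""

    q: np.ndarray
    s0: np.ndarray
    s2: np.ndarray
    s0_sigma: np.ndarray
    s2_sigma: np.ndarray
    flagged: np.ndarray  # True where the bin was unfit (degenerate coverage)

    def __post_init__(self) -> None:
        n = np.asarray(self.q).size
        for name in ("s0", "s2", "s0_sigma", "s2_sigma", "flagged"):
            if np.asarray(getattr(self, name)).size != n:
                raise ValueError(f"{name} length mismatch")


def _legendre2(x: np.ndarray) -> np.ndarray:
    return 0.5 * (3.0 * x**2 - 1.0)


def pixel_to_q_theta(geom: DetectorGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel momentum transfer, q-polarization angle, and Thomson factor.

    Returns ``(q, theta_q, thomson)``: q in 1/Å from the exact flat-detector
    geometry q = (4 pi / lambda) sin(Theta / 2); theta_q from the full 3-D
    scattering-vector direction against the pump polarization axis; and the
    Thomson polarization factor for the x-polarized probe.  The beam-centre
    pixel has q = 0 and undefined theta_q (flagged NaN; callers mask it).
    """
    ny, nx = geom.shape
    iy, ix = np.mgrid[0:ny, 0:nx]
    x_mm = (ix - geom.center[1]) * geom.pixel_mm
    y_mm = (iy - geom.center[0]) * geom.pixel_mm
    r = np.sqrt(x_mm**2 + y_mm**2)
    theta_scat = np.arctan2(r, geom.distance_mm)  # scattering angle Theta
    lam = geom.wavelength
    q = (4.0 * math.pi / lam) * np.sin(theta_scat / 2.0)
    # unit outgoing direction
    norm = np.sqrt(x_mm**2 + y_mm**2 + geom.distance_mm**2)
    ex, ey, ez = x_mm / norm, y_mm / norm, geom.distance_mm / norm
    # q vector = k_out - k_in, with k_in along +z
    qx, qy, qz = ex, ey, ez - 1.0
    qnorm = np.sqrt(qx**2 + qy**2 + qz**2)
    px, py = geom.polarization
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = (qx * px + qy * py) / qnorm  # polarization has no z component
    theta_q = np.arccos(np.clip(cos_t, -1.0, 1.0))
    theta_q[qnorm == 0] = np.nan
    thomson = 1.0 - ex**2  # probe polarization along x
    return q, theta_q, thomson


def render_detector_image(
    iso: DiffPattern,
    aniso: DiffPattern | None,
    geom: DetectorGeometry,
    noise: float = 0.0,
    seed: int | None = None,
    apply_thomson: bool = True,
    qbins: np.ndarray | None = None,
) -> Image2D:
    """Synthesize a detector image from S0(q) and S2(q).

    Pixelwise ``[S0(q) + S2(q) P2(cos theta_q)] * thomson`` plus seeded
    Gaussian noise.  Pixels outside the patterns' q support (and the beam
    centre) are masked.  With ``qbins`` (bin edges), pattern values are
    evaluated at the bin centre of each pixel's bin — the forward model on
    the same discretization :func:`decompose_iso_aniso` inverts, making the
    zero-noise round trip exact rather than limited by bin-width bias.
    """
    q, theta_q, thomson = pixel_to_q_theta(geom)
    if qbins is not None:
        qbins = np.asarray(qbins, float)
        centers = 0.5 * (qbins[:-1] + qbins[1:])
        idx = np.clip(np.digitize(q, qbins) - 1, 0, centers.size - 1)
        q = centers[idx]
    qlo, qhi = iso.q[0], iso.q[-1]
    if aniso is not None:
        if not np.array_equal(aniso.q, iso.q):
            raise ValueError("iso and aniso patterns must share a q grid")
    if q[~np.isnan(theta_q)].max() < qlo:
        raise ValueError("patterns' q range does not cover the detector")
    mask = np.isnan(theta_q) | (q < qlo) | (q > qhi)
    s0 = np.interp(q, iso.q, iso.values)
    s2 = np.interp(q, aniso.q, aniso.values) if aniso is not None else np.zeros_like(q)
    vals = s0 + s2 * _legendre2(np.cos(np.where(mask, 0.0, theta_q)))
    if apply_thomson:
        vals = vals * thomson
    if noise > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise, vals.shape)
    vals = np.where(mask, 0.0, vals)
    return Image2D(vals, mask)


def decompose_iso_aniso(
    image: Image2D,
    geom: DetectorGeometry,
    qbins: np.ndarray,
    noise_sigma: float | np.ndarray = 1.0,
    apply_thomson: bool = True,
    min_pixels: int = 4,
) -> IsoAnisoPair:
    """Per-bin regression I = S0 + S2 P2(cos theta_q) over detector pixels.

    Pixels are grouped into q bins (``qbins`` are bin edges); within each
    bin a weighted linear regression on [1, P2] recovers S0 and S2 with
    standard errors from the normal-equation covariance.  Bins with too few
    pixels or degenerate angular coverage are flagged (NaN components).
    The Thomson factor applied at render time is divided out first.
    """
    q, theta_q, thomson = pixel_to_q_theta(geom)
    qbins = np.asarray(qbins, float)
    if qbins.ndim != 1 or qbins.size < 2:
        raise ValueError("qbins must be an array of bin edges")
    ok = ~image.mask & ~np.isnan(theta_q)
    vals = image.values.copy()
    sig = np.broadcast_to(np.asarray(noise_sigma, float), vals.shape).copy()
    if apply_thomson:
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = vals / thomson
            sig = sig / thomson  # detector noise rescales with the correction
        ok &= thomson > 0.05
    centers = 0.5 * (qbins[:-1] + qbins[1:])
    nb = centers.size
    s0 = np.full(nb, np.nan)
    s2 = np.full(nb, np.nan)
    s0e = np.full(nb, np.nan)
    s2e = np.full(nb, np.nan)
    flagged = np.ones(nb, dtype=bool)
    idx = np.digitize(q, qbins) - 1
    p2 = _legendre2(np.cos(theta_q))
    for b in range(nb):
        sel = ok & (idx == b)
        if sel.sum() < min_pixels:
            continue
        x = p2[sel]
        if np.ptp(x) < 1e-6:  # no angular contrast: S2 inseparable from S0
            continue
        y = vals[sel]
        w = 1.0 / sig[sel] ** 2
        design = np.column_stack([np.ones_like(x), x])
        a = design.T @ (design * w[:, None])
        b_vec = design.T @ (w * y)
        try:
            cov = np.linalg.inv(a)
        except np.linalg.LinAlgError:
            continue
        coef = cov @ b_vec
        s0[b], s2[b] = coef
        s0e[b], s2e[b] = np.sqrt(np.diag(cov))
        flagged[b] = False
    return IsoAnisoPair(centers, s0, s2, s0e, s2e, flagged)
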