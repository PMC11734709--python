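"""Tabulated atomic x-ray form factors.

The elastic scattering amplitude of an isolated, spherically averaged atom is
parameterized by the standard four-Gaussian-plus-constant fit

    f(q) = sum_i a_i exp(-b_i s^2) + c,   s = q / (4 pi) = sin(theta) / lambda

with coefficients from the International Tables for Crystallography
(Cromer–Mann parameterization).  At q = 0 the form factor equals the atomic
number Z (the electron count), which is what makes difference-scattering
analysis quantitatively interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FormFactorModel", "atomic_form_factor", "CROMER_MANN"]

# element -> (a1..a4, b1..b4, c); International Tables vol. C, table 6.1.1.4
CROMER_MANN: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]] = {
    "H": ((0.489918, 0.262003, 0.196767, 0.049879),
          (20.6593, 7.74039, 49.5519, 2.20159), 0.001305),
    "C": ((2.31000, 1.02000, 1.58860, 0.865000),
          (20.8439, 10.2075, 0.568700, 51.6512), 0.215600),
    "N": ((12.2126, 3.13220, 2.01250, 1.16630),
          (0.005700, 9.89330, 28.9975, 0.582600), -11.529),
    "O": ((3.04850, 2.28680, 1.54630, 0.867000),
          (13.2771, 5.70110, 0.323900, 32.9089), 0.250800),
    "S": ((6.90530, 5.20340, 1.43790, 1.58630),
          (1.46790, 22.2151, 0.253600, 56.1720), 0.866900),
}

ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16}


@dataclass(frozen=True)
class FormFactorModel:
    """Per-element four-Gaussian form-factor coefficient sets.

    The default table covers the elements of the dithiane system (H, C, S)
    plus N and O.  ``source`` records the provenance of the coefficients.
    """

    coefficients: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]] = field(
        default_factory=lambda: dict(CROMER_MANN)
    )
    source: str = "International Tables C, 6.1.1.4 (Cromer-Mann)"

    def supported(self) -> frozenset[str]:
        return frozenset(self.coefficients)

    def __call__(self, element: str, q: np.ndarray) -> np.ndarray:
        return self.evaluate(element, q)

    def evaluate(self, element: str, q: np.ndarray) -> np.ndarray:
        """Evaluate f(q) for one element on a grid of q (1/Å)."""
        if element not in self.coefficients:
            raise KeyError(
                f"no form-factor coefficients for element {element!r}; "
                f"supported: {sorted(self.coefficients)}"
            )
        a, b, c = self.coefficients[element]
        q = np.atleast_1d(np.asarray(q, dtype=float))
        s2 = (q / (4.0 * np.pi)) ** 2
        f = np.full_like(q, c, dtype=float)
        for ai, bi in zip(a, b):
            f += ai * np.exp(-bi * s2)
        return f

    def f_zero(self, element: str) -> float:
        """f(0), which equals Z to the accuracy of the tabulation."""
        return float(self.evaluate(element, np.array([0.0]))[0])


def atomic_form_factor(element: str, q: np.ndarray,
                       model: FormFactorModel | None = None) -> np.ndarray:
    """Atomic form factor f(q) of ``element`` on the grid ``q`` (1/Å)."""
    model = model if model is not None else FormFactorModel()
    return model.evaluate(element, q)
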