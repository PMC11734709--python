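"""Built-in approximate structures for the dithiane photofragmentation network.

1,2-dithiane (DT, C4H8S2) photolysis at 200 nm proceeds through ring opening
(S–S rupture to an open-chain biradical), re-closure to vibrationally hot DT,
and fragmentation into one-sulfur (FA) and two-sulfur (FB) channels.  The
builders here assemble self-consistent heavy-atom skeletons from standard
covalent parameters (C–C 1.53 Å, C–S 1.82 Å, S–S 2.06 Å, S=S 1.89 Å,
tetrahedral carbons); they are geometric stand-ins, not quantum-chemical
optimizations.  X-ray scattering is nearly blind to hydrogen, so the exact H
placement matters little; the number of hydrogens transferred to the sulfur
fragments (x, y, z, each 0 or 1) is configurable.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from .geometry import Geometry, place_atom

__all__ = ["reference_structures", "build_dithiane", "build_biradical"]

# standard covalent parameters, Å / degrees
R_CC = 1.53
R_CS = 1.82
R_SS = 2.06
R_S2 = 1.89  # S=S in free S2
R_CH = 1.09
R_SH = 1.34
ANG_TET = 109.47


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return np.degrees(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))


@lru_cache(maxsize=8)
def _dithiane_ring(ss_distance: float = R_SS) -> np.ndarray:
    """Six-membered S-S-C-C-C-C chair ring with standard bond lengths.

    Starts from a Z-matrix chair guess (alternating ±60° ring torsions) and
    refines all six ring atoms so every ring bond takes its standard length
    while the chair torsion pattern is retained.
    """
    bonds = [ss_distance, R_CS, R_CC, R_CC, R_CC, R_CS]  # bond i: atom i -> i+1 (mod 6)
    # Z-matrix chair guess
    p = np.zeros((6, 3))
    p[1] = [ss_distance, 0.0, 0.0]
    ang = np.deg2rad(100.0)
    p[2] = p[1] + R_CS * np.array([-np.cos(ang), np.sin(ang), 0.0])
    p[3] = place_atom(p[0], p[1], p[2], R_CC, 112.0, 60.0)
    p[4] = place_atom(p[1], p[2], p[3], R_CC, 112.0, -60.0)
    p[5] = place_atom(p[2], p[3], p[4], R_CC, 112.0, 60.0)

    # alternating-sign ring torsions (chair); signs taken from the guess
    guess_tors = [_dihedral(p[i], p[(i + 1) % 6], p[(i + 2) % 6], p[(i + 3) % 6])
                  for i in range(6)]
    signs = [60.0 * np.sign(t) for t in guess_tors]
    # interior bond-angle targets at S0, S1, C2..C5
    angle_targets = [100.0, 100.0, 112.0, 112.0, 112.0, 112.0]

    def _angle(a, b, c):
        u = (a - b) / np.linalg.norm(a - b)
        v = (c - b) / np.linalg.norm(c - b)
        return np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0)))

    def resid(x: np.ndarray) -> np.ndarray:
        q = x.reshape(6, 3)
        out = []
        for i in range(6):
            j = (i + 1) % 6
            out.append(np.linalg.norm(q[j] - q[i]) - bonds[i])
        for i in range(6):
            ang_i = _angle(q[(i - 1) % 6], q[i], q[(i + 1) % 6])
            out.append(0.02 * (ang_i - angle_targets[i]))
            tor = _dihedral(q[i], q[(i + 1) % 6], q[(i + 2) % 6], q[(i + 3) % 6])
            out.append(0.02 * (tor - signs[i]))  # soft chair-shape restraint
        return np.asarray(out)

    sol = least_squares(resid, p.ravel(), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    ring = sol.x.reshape(6, 3)
    ring -= ring.mean(axis=0)
    return ring


def _methylene_hydrogens(c: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> list[np.ndarray]:
    """Two H atoms completing a tetrahedral CH2 between heavy neighbours."""
    d1 = (n1 - c) / np.linalg.norm(n1 - c)
    d2 = (n2 - c) / np.linalg.norm(n2 - c)
    bis = -(d1 + d2)
    bis /= np.linalg.norm(bis)
    perp = np.cross(d1, d2)
    perp /= np.linalg.norm(perp)
    half = np.deg2rad(ANG_TET / 2.0)
    return [
        c + R_CH * (np.cos(half) * bis + np.sin(half) * perp),
        c + R_CH * (np.cos(half) * bis - np.sin(half) * perp),
    ]


def build_dithiane(label: str = "DT") -> Geometry:
    """Chair 1,2-dithiane, C4H8S2 (16 atoms)."""
    ring = _dithiane_ring()
    symbols = ["S", "S", "C", "C", "C", "C"]
    coords = [ring[i] for i in range(6)]
    for i in range(2, 6):
        prev = ring[(i - 1) % 6]
        nxt = ring[(i + 1) % 6]
        for h in _methylene_hydrogens(ring[i], prev, nxt):
            symbols.append("H")
            coords.append(h)
    return Geometry(tuple(symbols), np.array(coords), label)


def build_ring_opened(ss_distance: float = 3.3, label: str = "ring-opened") -> Geometry:
    """Compact ring-opened biradical: the chair with the S–S contact broken.

    After S–S rupture the two sulfur radicals remain confined by the carbon
    backbone, so the ring opens only partially (``ss_distance`` replaces the
    2.06 Å bond; covalent bonds keep their standard lengths).  This is the
    effective structure used for the rapidly equilibrating biradical/hot-DT
    pair, whose difference pattern against cold DT is weak — the pair stays
    structurally close to the reactant.
    """
    ring = _dithiane_ring(ss_distance)
    symbols = ["S", "S", "C", "C", "C", "C"]
    coords = [ring[i] for i in range(6)]
    for i in range(2, 6):
        prev = ring[(i - 1) % 6]
        nxt = ring[(i + 1) % 6]
        for h in _methylene_hydrogens(ring[i], prev, nxt):
            symbols.append("H")
            coords.append(h)
    return Geometry(tuple(symbols), np.array(coords), label)


def build_dt_star(stretch: float = 0.35, label: str = "DT-star") -> Geometry:
    """Electronically excited DT proxy: the chair with the S–S bond extended.

    Early excited-state motion drives the sulfurs apart; displacing each S by
    ``stretch`` Å along the S–S axis gives a compact stand-in whose difference
    pattern against cold DT is small but non-zero.
    """
    g = build_dithiane(label)
    coords = g.coords.copy()
    axis = coords[1] - coords[0]
    axis /= np.linalg.norm(axis)
    coords[0] -= stretch * axis
    coords[1] += stretch * axis
    return Geometry(g.symbols, coords, label)


def _chain(bond_pattern: list[tuple[str, float]], label: str) -> tuple[list[str], list[np.ndarray]]:
    """All-anti heavy-atom chain from (symbol, bond-to-previous) entries."""
    symbols = [bond_pattern[0][0]]
    coords = [np.zeros(3)]
    if len(bond_pattern) > 1:
        coords.append(np.array([bond_pattern[1][1], 0.0, 0.0]))
        symbols.append(bond_pattern[1][0])
    for i in range(2, len(bond_pattern)):
        sym, r = bond_pattern[i]
        if i == 2:
            # dummy reference off-axis defines the (planar) dihedral frame
            coords.append(place_atom(coords[0] + np.array([0.0, 1.0, 0.0]),
                                     coords[0], coords[1], r, 112.0, 0.0))
        else:
            coords.append(place_atom(coords[i - 3], coords[i - 2], coords[i - 1],
                                     r, 112.0, 180.0))
        symbols.append(sym)
    return symbols, coords


def _hydrogenate_chain(symbols: list[str], coords: list[np.ndarray],
                       h_per_atom: dict[int, int]) -> tuple[list[str], list[np.ndarray]]:
    """Append hydrogens to chain atoms.  Supports 1 or 2 H per heavy atom."""
    out_sym = list(symbols)
    out_xyz = list(coords)
    n = len(symbols)
    for i, nh in h_per_atom.items():
        c = coords[i]
        neighbours = [coords[j] for j in (i - 1, i + 1) if 0 <= j < n]
        r_xh = R_CH if symbols[i] == "C" else R_SH
        if len(neighbours) == 2:
            hs = _methylene_hydrogens(c, neighbours[0], neighbours[1])
        else:
            # terminal atom: build H frame off the single neighbour
            d = (neighbours[0] - c) / np.linalg.norm(neighbours[0] - c)
            ref = np.array([0.0, 0.0, 1.0])
            if abs(np.dot(ref, d)) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            perp = np.cross(d, ref)
            perp /= np.linalg.norm(perp)
            a = np.deg2rad(ANG_TET)
            h1 = c + 1.0 * (np.cos(a) * d + np.sin(a) * perp)
            h2 = c + 1.0 * (np.cos(a) * d - np.sin(a) * perp)
            hs = [h1, h2]
        for k in range(nh):
            out_sym.append("H")
            h = hs[k]
            out_xyz.append(c + r_xh * (h - c) / np.linalg.norm(h - c))
    return out_sym, out_xyz


def build_biradical(label: str = "biradical") -> Geometry:
    """Ring-opened S–C4–S chain biradical, C4H8S2."""
    symbols, coords = _chain(
        [("S", 0.0), ("C", R_CS), ("C", R_CC), ("C", R_CC), ("C", R_CC), ("S", R_CS)],
        label,
    )
    symbols, coords = _hydrogenate_chain(symbols, coords, {1: 2, 2: 2, 3: 2, 4: 2})
    return Geometry(tuple(symbols), np.array(coords), label)


def _build_c4_chain(n_h: int, label: str) -> Geometry:
    """Tetramethylene chain C4 with ``n_h`` hydrogens (8 = all CH2)."""
    symbols, coords = _chain([("C", 0.0), ("C", R_CC), ("C", R_CC), ("C", R_CC)], label)
    per_atom = {0: 2, 1: 2, 2: 2, 3: 2}
    # drop hydrogens from terminal carbons first when fewer than 8
    order = [0, 3, 1, 2]
    deficit = 8 - n_h
    for i in order:
        while deficit > 0 and per_atom[i] > 0:
            per_atom[i] -= 1
            deficit -= 1
            break
    symbols, coords = _hydrogenate_chain(symbols, coords, per_atom)
    return Geometry(tuple(symbols), np.array(coords), label)


def _build_c4s_chain(n_h: int, label: str) -> Geometry:
    """Thio-tetramethylene chain S–C4 with ``n_h`` hydrogens on carbon."""
    symbols, coords = _chain(
        [("S", 0.0), ("C", R_CS), ("C", R_CC), ("C", R_CC), ("C", R_CC)], label
    )
    per_atom = {1: 2, 2: 2, 3: 2, 4: 2}
    deficit = 8 - n_h
    for i in [4, 1, 2, 3]:
        while deficit > 0 and per_atom[i] > 0:
            per_atom[i] -= 1
            deficit -= 1
            break
    symbols, coords = _hydrogenate_chain(symbols, coords, per_atom)
    return Geometry(tuple(symbols), np.array(coords), label)


def _build_sh(n_h: int, label: str) -> Geometry:
    if n_h == 0:
        return Geometry(("S",), np.zeros((1, 3)), label)
    return Geometry(("S", "H"), np.array([[0.0, 0.0, 0.0], [R_SH, 0.0, 0.0]]), label)


def _build_s2h(n_h: int, label: str) -> Geometry:
    sym = ["S", "S"]
    xyz = [[0.0, 0.0, 0.0], [R_S2, 0.0, 0.0]]
    if n_h:
        sym.append("H")
        a = np.deg2rad(100.0)
        xyz.append([R_S2 + R_SH * np.cos(np.pi - a), R_SH * np.sin(np.pi - a), 0.0])
    return Geometry(tuple(sym), np.array(xyz), label)


def reference_structures(x: int = 0, y: int = 0, z: int = 0) -> dict[str, list[Geometry]]:
    """Built-in structures for every species of the reaction network.

    Parameters
    ----------
    x, y, z : int (0 or 1)
        Hydrogens transferred to the sulfur co-fragments: FA-1 is
        C4H(8-x)S + SHx, FA-2 is C4H(8-x-y) + SHx + SHy, FB is
        C4H(8-z) + S2Hz.  Scattering is nearly H-insensitive, so all
        placements yield near-identical patterns; default is no transfer.

    Returns
    -------
    dict mapping species name to a list of fragment geometries
    (single-fragment species are one-element lists).  Besides the network
    species the set carries "DT" (the ground-state reference) and
    "biradical-extended" (the fully unfolded chain, a comparison candidate).
    """
    for name, v in (("x", x), ("y", y), ("z", z)):
        if v not in (0, 1):
            raise ValueError(f"{name} must be 0 or 1, got {v}")
    return {
        "DT": [build_dithiane()],
        # vertical excitation leaves the nuclear frame unchanged: under the
        # IAM the excited reactant scatters exactly like cold DT
        "DT*": [build_dithiane("DT*")],
        # confinement keeps the sulfur radicals close: the biradical is a
        # partially opened ring, structurally near the reactant
        "biradical": [build_ring_opened(label="biradical")],
        # vibrationally hot cyclic DT; pattern damping comes from ensemble
        # averaging over a thermal geometry pool at simulation time
        "DT_hot": [build_dithiane("DT_hot")],
        # fully extended S-C4-S chain, kept as a candidate for comparisons
        "biradical-extended": [build_biradical("biradical-extended")],
        "FA-1": [_build_c4s_chain(8 - x, "FA1-C4S"), _build_sh(x, "FA1-S")],
        "FA-2": [
            _build_c4_chain(8 - x - y, "FA2-C4"),
            _build_sh(x, "FA2-S"),
            _build_sh(y, "FA2-S'"),
        ],
        "FB": [_build_c4_chain(8 - z, "FB-C4"), _build_s2h(z, "FB-S2")],
    }
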