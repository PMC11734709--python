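"""First-order photochemical reaction networks and their population dynamics.

The photolysis of 1,2-dithiane is modelled as a linear first-order network:
the pump promotes a fraction of molecules to an effective excited state DT*,
which branches into a ring-opened biradical, a one-sulfur fragment channel
(FA-1 -> FA-2) and a two-sulfur channel (FB).  The biradical equilibrates
with vibrationally hot cyclic dithiane (DT_hot), and both drain slowly into
the terminal products.  Populations follow dP/dt = A P with A assembled from
the rate constants; the finite pump-probe cross-correlation is included by
convolving the delta-excitation response with a Gaussian instrument response
function (IRF), which for exponential modes has the closed
exponentially-modified-Gaussian form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import erfcx

__all__ = [
    "Species",
    "RateSet",
    "ReactionNetwork",
    "InstrumentResponse",
    "PopulationSet",
    "default_dt_network",
    "solve_populations",
    "equilibrium_ratio",
    "asymptotic_fractions",
    "DT_RATES",
]

FS = 1e-15  # seconds per femtosecond
_SIGMA_PER_FWHM = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

RATE_SYMBOLS = ("k1", "k2", "km2", "k3", "k4", "k5", "k6", "k7")


@dataclass(frozen=True)
class Species:
    """One node of the reaction network.

    ``group`` is the pattern-group id used by the global fit; it defaults to
    the species name.  ``group=None`` marks a species whose difference
    pattern is pinned to zero and never extracted (the convention for the
    vertically excited reactant, whose nuclear geometry — all the IAM sees —
    is still that of the ground state).
    """

    name: str
    role: str = "intermediate"  # excited | intermediate | product
    group: str | None = "__auto__"

    def __post_init__(self) -> None:
        if self.role not in ("excited", "intermediate", "product"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.group == "__auto__":
            object.__setattr__(self, "group", self.name)


@dataclass(frozen=True)
class RateSet:
    """First-order rate constants in s^-1.

    ``km2`` is the reverse rate of the biradical <-> DT_hot equilibrium
    (often written k-2).  Time constants are the reciprocals.
    """

    k1: float = 0.0
    k2: float = 0.0
    km2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0
    k5: float = 0.0
    k6: float = 0.0
    k7: float = 0.0

    def __post_init__(self) -> None:
        for sym in RATE_SYMBOLS:
            v = getattr(self, sym)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {sym} must be finite and >= 0, got {v}")

    def __getitem__(self, sym: str) -> float:
        if sym not in RATE_SYMBOLS:
            raise KeyError(sym)
        return getattr(self, sym)

    def as_dict(self) -> dict[str, float]:
        return {s: getattr(self, s) for s in RATE_SYMBOLS}

    def time_constants_fs(self) -> dict[str, float]:
        """Reciprocal rates in femtoseconds (inf for zero rates)."""
        out = {}
        for s in RATE_SYMBOLS:
            k = getattr(self, s)
            out[s] = math.inf if k == 0 else 1.0 / (k * FS)
        return out

    def replace(self, **kw: float) -> "RateSet":
        return replace(self, **kw)


#: Reference rate constants (s^-1) for the 200-nm photofragmentation of
#: 1,2-dithiane: k1 240 fs (ring opening), k2/km2 the biradical<->DT_hot
#: equilibrium (1.05 ps / 3.2 ps), k3/k4 350 fs (prompt FA-1/FB channels),
#: k5-k7 the slow drains (63 ps, 400 ps, 455 ps).
DT_RATES = RateSet(
    k1=4.23e12, k2=0.95e12, km2=0.31e12, k3=2.86e12,
    k4=2.85e12, k5=0.0158e12, k6=0.0025e12, k7=0.0022e12,
)


@dataclass(frozen=True)
class ReactionNetwork:
    """Species and directed first-order edges labelled by rate symbols."""

    species: tuple[Species, ...]
    edges: tuple[tuple[str, str, str], ...]  # (source, target, rate symbol)
    initial: str = "DT*"

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        byname = {s.name: s for s in self.species}
        if self.initial not in byname:
            raise ValueError(f"initial species {self.initial!r} not in network")
        for src, dst, sym in self.edges:
            for n in (src, dst):
                if n not in byname:
                    raise ValueError(f"edge endpoint {n!r} not a species")
            if sym not in RATE_SYMBOLS:
                raise ValueError(f"unknown rate symbol {sym!r}")
            if byname[src].role == "product":
                raise ValueError(f"product species {src!r} cannot have outgoing edges")
        # connectivity from the initial species
        reach = {self.initial}
        frontier = [self.initial]
        adjacency: dict[str, list[str]] = {}
        for src, dst, _ in self.edges:
            adjacency.setdefault(src, []).append(dst)
        while frontier:
            cur = frontier.pop()
            for nxt in adjacency.get(cur, ()):
                if nxt not in reach:
                    reach.add(nxt)
                    frontier.append(nxt)
        missing = set(names) - reach
        if missing:
            raise ValueError(f"species unreachable from {self.initial}: {sorted(missing)}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def species_by_name(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def products(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species if s.role == "product")

    def rate_matrix(self, rates: RateSet, unit: float = FS) -> np.ndarray:
        """Generator matrix A (dP/dt = A P), rates scaled to ``unit`` seconds."""
        idx = {n: i for i, n in enumerate(self.names)}
        n = len(idx)
        a = np.zeros((n, n))
        for src, dst, sym in self.edges:
            k = rates[sym] * unit
            a[idx[dst], idx[src]] += k
            a[idx[src], idx[src]] -= k
        return a

    def groups(self) -> dict[str, list[str]]:
        """Pattern-group id -> member species names (zero-pattern species omitted)."""
        out: dict[str, list[str]] = {}
        for s in self.species:
            if s.group is not None:
                out.setdefault(s.group, []).append(s.name)
        return out


@dataclass(frozen=True)
class InstrumentResponse:
    """Gaussian pump-probe cross-correlation: FWHM and time-zero, both fs."""

    fwhm: float = 238.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise ValueError("IRF FWHM must be > 0")

    @property
    def sigma(self) -> float:
        return self.fwhm * _SIGMA_PER_FWHM


@dataclass(frozen=True)
class PopulationSet:
    """Relative populations F_alpha(t) on a delay grid (fs)."""

    t: np.ndarray
    populations: np.ndarray  # (n_t, n_species)
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.t, float)
        p = np.asarray(self.populations, float)
        if p.shape != (t.size, len(self.names)):
            raise ValueError("population matrix shape mismatch")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "populations", p)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.populations[:, self.names.index(name)]

    def group_courses(self, groups: Mapping[str, Sequence[str]]) -> np.ndarray:
        """Summed time courses, one column per group (order of ``groups``)."""
        cols = []
        for members in groups.values():
            cols.append(sum(self[m] for m in members))
        return np.stack(cols, axis=1)

    def save(self, path) -> None:
        header = "t [fs]  " + "  ".join(self.names)
        np.savetxt(path, np.column_stack([self.t, self.populations]), header=header)


def default_dt_network(
    edge_assignment: Mapping[str, str] | None = None,
    merge_hot_group: bool = False,
    fit_dt_star_pattern: bool = False,
) -> ReactionNetwork:
    """The dithiane photofragmentation scheme.

    Fast edges: DT* -> biradical (k1), DT* -> FA-1 (k3), DT* -> FB (k4);
    the reversible pair biradical <-> DT_hot (k2 / km2); and three slow
    drains whose symbol-to-edge mapping is configurable via
    ``edge_assignment``, a bijection from the edges
    ``{"FA-1->FA-2", "DT_hot->FB", "biradical->FA-2"}`` onto
    ``{"k5", "k6", "k7"}``.  Default: k5 drains FA-1, k6 drains DT_hot,
    k7 drains the biradical.

    DT* carries no extracted pattern by default: vertical excitation leaves
    the nuclear frame — all the IAM sees — unchanged, and the network has
    one fewer temporal mode than species, so a free DT* pattern would make
    the branching ratios unidentifiable.  ``merge_hot_group=True`` instead
    assigns the rapidly equilibrating biradical/DT_hot pair one shared
    pattern group (useful for presentation; their separate time-courses
    become proportional once the equilibrium is established, which is also
    why the pair's patterns need prior information to separate).
    """
    default = {"FA-1->FA-2": "k5", "DT_hot->FB": "k6", "biradical->FA-2": "k7"}
    assignment = dict(default if edge_assignment is None else edge_assignment)
    if set(assignment) != set(default) or set(assignment.values()) != {"k5", "k6", "k7"}:
        raise ValueError(
            "edge_assignment must map {'FA-1->FA-2', 'DT_hot->FB', "
            "'biradical->FA-2'} bijectively onto {'k5', 'k6', 'k7'}"
        )
    hot_group = "biradical+DT_hot" if merge_hot_group else "__auto__"
    species = (
        Species("DT*", "excited", group="__auto__" if fit_dt_star_pattern else None),
        Species("biradical", "intermediate", group=hot_group),
        Species("DT_hot", "intermediate", group=hot_group),
        Species("FA-1", "intermediate"),
        Species("FA-2", "product"),
        Species("FB", "product"),
    )
    edges = (
        ("DT*", "biradical", "k1"),
        ("DT*", "FA-1", "k3"),
        ("DT*", "FB", "k4"),
        ("biradical", "DT_hot", "k2"),
        ("DT_hot", "biradical", "km2"),
        ("FA-1", "FA-2", assignment["FA-1->FA-2"]),
        ("DT_hot", "FB", assignment["DT_hot->FB"]),
        ("biradical", "FA-2", assignment["biradical->FA-2"]),
    )
    return ReactionNetwork(species, edges)


def _emg(lam: np.ndarray, tau: np.ndarray, sigma: float) -> np.ndarray:
    """(exp(lam*t) * step(t)) convolved with a unit Gaussian of width sigma.

    Evaluated at tau = t - t0 for each eigenvalue lam (columns).  Uses the
    scaled complementary error function for numerical stability; supports
    complex eigenvalues (conjugate pairs recombine to a real result).
    """
    lam = np.asarray(lam)
    tau = np.asarray(tau, float)[:, None]
    if sigma == 0.0:
        return np.where(tau >= 0, np.exp(lam[None, :] * tau), 0.0)
    b = (-lam[None, :] * sigma - tau / sigma) / math.sqrt(2.0)
    # exp(a) * erfc(b) with a = lam*tau + lam^2 sigma^2 / 2;  a - b^2 = -tau^2/(2 sigma^2)
    out = np.empty(np.broadcast_shapes(tau.shape, b.shape), dtype=complex)
    use_x = np.real(b) >= 0
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        a = lam[None, :] * tau + 0.5 * (lam[None, :] * sigma) ** 2
        direct = 0.5 * np.exp(a) * _erfc_complex(b)
        stable = 0.5 * np.exp(-(tau**2) / (2.0 * sigma**2)) * _erfcx_complex(b)
    out[use_x] = np.broadcast_to(stable, out.shape)[use_x]
    out[~use_x] = np.broadcast_to(direct, out.shape)[~use_x]
    return out


def _erfc_complex(z: np.ndarray) -> np.ndarray:
    from scipy.special import erfc
    if np.iscomplexobj(z):
        from scipy.special import wofz
        return np.exp(-z * z) * wofz(1j * z)
    return erfc(z)


def _erfcx_complex(z: np.ndarray) -> np.ndarray:
    if np.iscomplexobj(z):
        from scipy.special import wofz
        return wofz(1j * z)
    return erfcx(z)


def solve_populations(
    network: ReactionNetwork,
    rates: RateSet,
    irf: InstrumentResponse | None = None,
    tgrid: np.ndarray | Sequence[float] | None = None,
) -> PopulationSet:
    """Populations of every species on ``tgrid`` (fs), IRF-convolved.

    Solves dP/dt = A P for delta excitation at t0 by eigen-decomposition,
    then convolves each exponential mode with the Gaussian IRF analytically.
    Falls back to dense numerical integration when the eigenvector matrix is
    ill-conditioned (degenerate eigenvalues).

    The populations are normalized to the eventually-excited subpopulation:
    after the IRF has fully passed, they sum to 1.
    """
    if tgrid is None:
        tgrid = default_delay_grid()
    t = np.asarray(tgrid, float)
    a = network.rate_matrix(rates)  # per fs
    idx0 = network.names.index(network.initial)
    p0 = np.zeros(len(network.names))
    p0[idx0] = 1.0
    sigma = irf.sigma if irf is not None else 0.0
    t0 = irf.t0 if irf is not None else 0.0

    lam, vec = np.linalg.eig(a)
    cond = np.linalg.cond(vec)
    if cond < 1e8:
        coef = np.linalg.solve(vec, p0)  # modal amplitudes
        modes = _emg(lam, t - t0, sigma)  # (n_t, n_modes)
        pops = np.real(modes * coef[None, :] @ vec.T)
    else:  # pragma: no cover - degenerate spectra are exotic for these networks
        pops = _solve_numerical(a, p0, t, t0, sigma)
    pops = np.clip(pops, 0.0, None)
    return PopulationSet(t, pops, network.names)


def _solve_numerical(a: np.ndarray, p0: np.ndarray, t: np.ndarray,
                     t0: float, sigma: float) -> np.ndarray:
    """Matrix-exponential delta response + Gaussian quadrature convolution.

    Fallback for (near-)defective rate matrices where the eigen route is
    unreliable.  The delta response is exact (expm per evaluation point);
    the IRF integral over the Gaussian support uses Gauss-Legendre nodes.
    """
    from scipy.linalg import expm

    def delta_response(times: np.ndarray) -> np.ndarray:
        out = np.zeros((times.size, p0.size))
        for i, ti in enumerate(times):
            if ti >= 0.0:
                out[i] = expm(a * ti) @ p0
        return out

    if sigma == 0.0:
        return delta_response(t - t0)
    nodes, weights = np.polynomial.legendre.leggauss(48)
    gauss_norm = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    out = np.zeros((t.size, p0.size))
    lo = t0 - 6.0 * sigma
    for i, ti in enumerate(t):
        hi = min(ti, t0 + 6.0 * sigma)  # response vanishes for u > ti
        if hi <= lo:
            continue
        half = 0.5 * (hi - lo)
        u = 0.5 * (hi + lo) + half * nodes
        wu = half * weights * gauss_norm * np.exp(-((u - t0) ** 2) / (2 * sigma**2))
        out[i] = wu @ delta_response(ti - u)
    return out


def default_delay_grid(n_linear: int = 40, n_log: int = 40,
                       t_min: float = -500.0, t_switch: float = 1000.0,
                       t_max: float = 3.0e6) -> np.ndarray:
    """Pump-probe delay grid in fs: linear to 1 ps, log-spaced to 3 ns."""
    lin = np.linspace(t_min, t_switch, n_linear, endpoint=False)
    log = np.geomspace(t_switch, t_max, n_log)
    return np.concatenate([lin, log])


def equilibrium_ratio(rates: RateSet) -> float:
    """DT_hot / biradical population ratio of the fast equilibrium, k2 / km2."""
    if rates.km2 == 0:
        raise ValueError("km2 = 0: no biradical <-> DT_hot equilibrium")
    return rates.k2 / rates.km2


def asymptotic_fractions(network: ReactionNetwork, rates: RateSet) -> dict[str, float]:
    """Long-time product fractions by first-step absorption analysis.

    For a linear first-order network every transient's branching is governed
    by its outgoing rates; the probability b_ip of ending in product p solves
    the linear system b_ip = sum_j (k_ij / k_i) b_jp with b_pp = 1.  The
    returned fractions are those of the initial species and sum to 1.
    """
    names = list(network.names)
    products = list(network.products())
    if not products:
        raise ValueError("network has no product species")
    transients = [n for n in names if n not in products]
    out_rates: dict[str, float] = {n: 0.0 for n in transients}
    edges_from: dict[str, list[tuple[str, float]]] = {n: [] for n in transients}
    for src, dst, sym in network.edges:
        k = rates[sym]
        if k > 0:
            out_rates[src] += k
            edges_from[src].append((dst, k))
    trapped = [n for n in transients if out_rates[n] == 0.0]
    if trapped:
        raise ValueError(f"trapped species with no decay path to products: {trapped}")

    ti = {n: i for i, n in enumerate(transients)}
    nt = len(transients)
    m = np.eye(nt)
    rhs = np.zeros((nt, len(products)))
    for n in transients:
        for dst, k in edges_from[n]:
            p = k / out_rates[n]
            if dst in ti:
                m[ti[n], ti[dst]] -= p
            else:
                rhs[ti[n], products.index(dst)] += p
    try:
        b = np.linalg.solve(m, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("absorption system singular: some species cannot reach a product") from exc
    absorbed = b[ti[network.initial]]
    total = absorbed.sum()
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"absorption probabilities sum to {total}, not 1")
    return {p: float(f) for p, f in zip(products, absorbed)}
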