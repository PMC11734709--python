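"""Global kinetic analysis of percent-difference scattering maps.

The observable separates into kinetics and structure,

    dI(q, t) = gamma * sum_alpha S_alpha(q) F_alpha(t),

with F_alpha(t) the network populations and S_alpha(q) the species-associated
difference patterns.  Because the model is linear in the patterns, fitting
uses variable projection: an outer nonlinear search over the shared rate
constants (optionally time zero and IRF width) with the patterns solved
exactly by weighted linear least squares at every step.  Multi-start restarts
from random initial rates characterize the optimization landscape; reported
parameters are the mean +- SD over converged restarts.

Only the product gamma * S_alpha(q) is identifiable from the map alone
(scaling gamma by c and all patterns by 1/c leaves the model unchanged); the
excitation fraction gamma is fixed afterwards by anchoring extracted product
patterns to their IAM simulations, whose absolute scale is set by electron
counting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .iam import DiffPattern
from .kinetics import (
    RATE_SYMBOLS,
    DT_RATES,
    InstrumentResponse,
    PopulationSet,
    RateSet,
    ReactionNetwork,
    solve_populations,
)
from .signalmap import SignalMap

__all__ = [
    "CollinearityWarning",
    "FitConfig",
    "FitResult",
    "KineticGlobalFit",
    "model_signal",
    "solve_patterns_linear",
    "global_fit",
    "estimate_gamma",
    "residual_map",
    "compare_patterns",
    "rank_candidates",
]


class CollinearityWarning(UserWarning):
    """Raised when group population time-courses are nearly collinear."""


def _check_groups(groups: Mapping[str, Sequence[str]], species: Sequence[str]) -> dict[str, list[str]]:
    """Groups must cover a subset of the species, each species at most once.

    Species left out of every group carry a zero difference pattern and are
    excluded from extraction (the convention for the vertically excited
    reactant, indistinguishable from the ground state under the IAM).
    """
    if not groups:
        raise ValueError("at least one pattern group is required")
    flat = [m for members in groups.values() for m in members]
    if len(set(flat)) != len(flat):
        raise ValueError("a species may belong to at most one pattern group")
    unknown = set(flat) - set(species)
    if unknown:
        raise ValueError(f"groups reference unknown species {sorted(unknown)}")
    return {g: list(m) for g, m in groups.items()}


def model_signal(
    gamma: float,
    patterns: Mapping[str, np.ndarray],
    populations: PopulationSet,
    groups: Mapping[str, Sequence[str]],
    q: np.ndarray | None = None,
    sigma: float | np.ndarray = 1.0,
) -> SignalMap:
    """Exact forward model: gamma * sum_g S_g(q) (sum_{a in g} F_a(t)).

    ``patterns`` maps group id -> S_g values (percent-difference units) on
    the q grid; ``groups`` maps group id -> member species and must
    partition the population species.
    """
    groups = _check_groups(groups, populations.names)
    missing = set(groups) - set(patterns)
    if missing:
        raise ValueError(f"no pattern provided for groups {sorted(missing)}")
    courses = populations.group_courses(groups)  # (nt, ng)
    s = np.stack([np.asarray(patterns[g], float) for g in groups])  # (ng, nq)
    values = gamma * (s.T @ courses.T)  # (nq, nt)
    nq = s.shape[1]
    if q is None:
        q = np.arange(nq, dtype=float)
    sig = np.broadcast_to(np.asarray(sigma, float), values.shape).copy()
    return SignalMap(q, populations.t, values, sig, meta={"source": "model"})


def solve_patterns_linear(
    data: SignalMap,
    populations: PopulationSet,
    groups: Mapping[str, Sequence[str]],
    condition_threshold: float = 1e6,
    warn: bool = True,
    prior_targets: Mapping[str, np.ndarray] | None = None,
    prior_weight: float = 0.0,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-q weighted linear solve for the (gamma-folded) group patterns.

    For each q independently, regress data(q, :) on the group population
    time-courses with weights 1 / sigma^2.  Returns the coefficient table
    {group: gamma*S_g(q)} and the per-q coefficient covariance array of
    shape (nq, ng, ng).  Near-collinear groups (condition number of the
    whitened design above ``condition_threshold``) trigger a
    :class:`CollinearityWarning` naming the worst-correlated pair.

    ``prior_targets``/``prior_weight`` add one pseudo-measurement per group
    and q pulling the coefficient toward the target with inverse variance
    ``prior_weight`` — the theory-informed regularization used by the
    global fit to resolve the gauge freedoms of the separable model.
    """
    groups = _check_groups(groups, populations.names)
    if not np.array_equal(data.t, populations.t):
        raise ValueError("data and populations are on different delay grids")
    x = populations.group_courses(groups)  # (nt, ng)
    ng = x.shape[1]
    n_informative = int(np.any(~data.mask, axis=0).sum())
    if ng > n_informative:
        raise ValueError(f"{ng} pattern groups but only {n_informative} informative delays")
    w = data.weights()  # (nq, nt)
    y = np.where(data.mask, 0.0, data.values)
    a = np.einsum("tg,qt,th->qgh", x, w, x)
    b = np.einsum("tg,qt->qg", x, w * y)
    if prior_targets is not None and prior_weight > 0:
        a += prior_weight * np.eye(ng)[None, :, :]
        for j, g in enumerate(groups):
            b[:, j] += prior_weight * np.asarray(prior_targets[g], float)
    if warn:
        _warn_collinear(x, w, list(groups), condition_threshold)
    try:
        coef = np.linalg.solve(a, b[..., None])[..., 0]
        cov = np.linalg.inv(a)
    except np.linalg.LinAlgError:
        coef = np.stack([np.linalg.pinv(ai) @ bi for ai, bi in zip(a, b)])
        cov = np.stack([np.linalg.pinv(ai) for ai in a])
    out = {g: coef[:, j] for j, g in enumerate(groups)}
    return out, cov


def _warn_collinear(x: np.ndarray, w: np.ndarray, names: list[str],
                    threshold: float) -> None:
    xw = x * np.sqrt(np.maximum(w.mean(axis=0), 0.0))[:, None]
    norms = np.linalg.norm(xw, axis=0)
    live = norms > 0
    if live.sum() < 2:
        return
    cond = np.linalg.cond(xw[:, live] / norms[live])
    if cond > threshold:
        g = xw[:, live].T @ xw[:, live]
        corr = g / np.outer(norms[live], norms[live])
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        live_names = [n for n, ok in zip(names, live) if ok]
        warnings.warn(
            f"group time-courses nearly collinear (condition number {cond:.3g}); "
            f"worst pair: {live_names[i]!r} and {live_names[j]!r} "
            f"(|correlation| = {abs(corr[i, j]):.6f})",
            CollinearityWarning,
            stacklevel=3,
        )


#: Default per-rate search windows (s^-1).  They encode the timescale
#: hierarchy the kinetic scheme itself postulates — sub-picosecond
#: photophysics out of the excited state, picosecond equilibration of the
#: ring-opened pair, and slow (10 ps - 10 ns) ground-state drains — and are
#: part of the model specification: without them the eigenvalue-to-edge
#: assignment of the network is permutation-degenerate.
DEFAULT_RATE_BOUNDS: dict[str, tuple[float, float]] = {
    "k1": (5e11, 5e13), "k3": (5e11, 5e13), "k4": (5e11, 5e13),
    "k2": (5e10, 1e13), "km2": (5e10, 1e13),
    "k5": (1e8, 1e11), "k6": (1e8, 1e11), "k7": (1e8, 1e11),
}


@dataclass
class FitConfig:
    """Configuration of the multi-start variable-projection fit."""

    free: tuple[str, ...] = RATE_SYMBOLS
    rates0: RateSet = field(default_factory=lambda: DT_RATES)
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATE_BOUNDS))
    init_range: dict[str, tuple[float, float]] | None = None  # default: bounds
    n_restarts: int = 20
    seed: int | None = None
    fit_t0: bool = False
    fit_irf: bool = False
    t0_bounds: tuple[float, float] = (-300.0, 300.0)  # fs
    irf_bounds: tuple[float, float] = (50.0, 1000.0)  # fs FWHM
    groups: dict[str, list[str]] | None = None
    condition_threshold: float = 1e6
    cost_trim: float = 1e-4  # restarts above best*(1+cost_trim) are local minima
    # gamma and the theory-informed pattern prior (see KineticGlobalFit)
    fit_gamma: bool = True
    gamma_bounds: tuple[float, float] = (1e-3, 0.5)
    gamma_init: tuple[float, float] = (5e-3, 0.2)
    prior_strength: float = 10.0  # pseudo-measurements per (group, q), in units
    #                               of the mean data weight

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        for sym in self.free:
            if sym not in RATE_SYMBOLS:
                raise ValueError(f"unknown rate symbol {sym!r}")
            lo, hi = self.rate_bounds(sym)
            if not (0 < lo < hi and math.isfinite(hi)):
                raise ValueError(f"bounds for {sym} must be finite, positive, ordered")

    def rate_bounds(self, sym: str) -> tuple[float, float]:
        return self.bounds.get(sym, (1e8, 1e14))

    def rate_init_range(self, sym: str) -> tuple[float, float]:
        if self.init_range is not None and sym in self.init_range:
            return self.init_range[sym]
        return self.rate_bounds(sym)


@dataclass
class FitResult:
    """Outcome of a multi-start global fit."""

    rates: RateSet  # best restart
    rates_mean: dict[str, float]
    rates_sd: dict[str, float]
    gamma: float | None
    gamma_sd: float | None
    coeffs: dict[str, np.ndarray]  # gamma-folded patterns, best restart
    coeffs_sd: dict[str, np.ndarray]  # SD over restarts
    patterns: dict[str, DiffPattern] | None  # anchored S_alpha, if gamma known
    residual: SignalMap
    chi2: float  # weighted chi^2 per degree of freedom, best restart
    t0: float
    irf_fwhm: float
    t0_sd: float = 0.0
    irf_fwhm_sd: float = 0.0
    n_converged: int = 0
    restarts: list[dict] = field(default_factory=list)

    def time_constants_fs(self) -> dict[str, float]:
        """Best-fit reciprocal rates in fs."""
        return self.rates.time_constants_fs()

    def summary(self) -> str:
        lines = ["global kinetic fit"]
        for sym in RATE_SYMBOLS:
            mu, sd = self.rates_mean[sym], self.rates_sd[sym]
            tc = math.inf if mu == 0 else 1.0 / (mu * 1e-15)
            lines.append(f"  {sym:>4s} = ({mu:.4g} +- {sd:.2g}) /s   (1/k = {tc:.4g} fs)")
        if self.gamma is not None:
            lines.append(f"  gamma = {100 * self.gamma:.3f} %"
                         + (f" +- {100 * self.gamma_sd:.3f} %" if self.gamma_sd else ""))
        lines.append(f"  chi2/dof = {self.chi2:.4g}  ({self.n_converged} converged restarts)")
        return "\n".join(lines)


class KineticGlobalFit(BaseEstimator):
    """Variable-projection global fit of a percent-difference map.

    Scikit-learn style estimator: construct with hyperparameters, call
    :meth:`fit` with a :class:`SignalMap`, read fitted attributes
    (``rates_``, ``gamma_``, ``coeffs_``, ``residual_`` ...).

    Parameters
    ----------
    network : ReactionNetwork
        The kinetic scheme; species groups provide the default pattern
        grouping.
    irf : InstrumentResponse
        Gaussian cross-correlation (frozen unless ``fit_t0``/``fit_irf``).
    config : FitConfig, optional
        Multi-start and bound settings.
    theory_patterns : mapping group -> array, optional
        IAM percent-difference patterns used to anchor gamma on
        ``anchor_groups``; without them only gamma-folded patterns are
        reported.
    anchor_groups : tuple of str
        Groups used for the gamma anchor (default: terminal products).
    """

    def __init__(
        self,
        network: ReactionNetwork | None = None,
        irf: InstrumentResponse | None = None,
        config: FitConfig | None = None,
        theory_patterns: Mapping[str, np.ndarray] | None = None,
        anchor_groups: tuple[str, ...] = ("FB", "FA-2"),
    ) -> None:
        self.network = network
        self.irf = irf
        self.config = config
        self.theory_patterns = theory_patterns
        self.anchor_groups = anchor_groups

    # ------------------------------------------------------------------

    def _residual_factory(self, data: SignalMap, groups: dict[str, list[str]],
                          cfg: FitConfig):
        sqrtw = np.sqrt(data.weights())
        names = list(cfg.free)
        fixed = cfg.rates0.as_dict()
        use_prior = self.theory_patterns is not None and cfg.prior_strength > 0
        fit_gamma = cfg.fit_gamma and use_prior
        w_prior = cfg.prior_strength * float(data.weights().mean()) if use_prior else 0.0
        sqrt_wp = math.sqrt(w_prior) if w_prior > 0 else 0.0
        theory = None
        if use_prior:
            missing = set(groups) - set(self.theory_patterns)
            if missing:
                raise ValueError(f"theory patterns missing for groups {sorted(missing)}")
            theory = {g: np.asarray(self.theory_patterns[g], float) for g in groups}

        def unpack(x: np.ndarray) -> tuple[RateSet, InstrumentResponse, float | None]:
            vals = dict(fixed)
            for i, sym in enumerate(names):
                vals[sym] = math.exp(x[i])
            j = len(names)
            t0 = self.irf.t0
            fwhm = self.irf.fwhm
            if cfg.fit_t0:
                t0 = x[j]
                j += 1
            if cfg.fit_irf:
                fwhm = math.exp(x[j])
                j += 1
            gamma = math.exp(x[j]) if fit_gamma else None
            return RateSet(**vals), InstrumentResponse(fwhm, t0), gamma

        def inner(x: np.ndarray):
            rates, irf, gamma = unpack(x)
            pops = solve_populations(self.network, rates, irf, data.t)
            if use_prior:
                g0 = gamma if gamma is not None else 1.0
                targets = {g: g0 * theory[g] for g in groups}
                coeffs, _ = solve_patterns_linear(
                    data, pops, groups, warn=False,
                    prior_targets=targets, prior_weight=w_prior)
            else:
                targets = None
                coeffs, _ = solve_patterns_linear(data, pops, groups, warn=False)
            return rates, irf, gamma, pops, coeffs, targets

        def resid(x: np.ndarray) -> np.ndarray:
            _, _, _, pops, coeffs, targets = inner(x)
            model = _compose(coeffs, pops, groups)
            parts = [((data.values - model) * sqrtw).ravel()]
            if targets is not None:
                parts.append(np.concatenate(
                    [sqrt_wp * (coeffs[g] - targets[g]) for g in groups]))
            return np.concatenate(parts)

        return resid, unpack, inner, fit_gamma, w_prior

    def fit(self, data: SignalMap, y: None = None) -> "KineticGlobalFit":
        if self.network is None or self.irf is None:
            raise ValueError("network and irf are required to fit")
        if not np.all(np.isfinite(data.values[~data.mask])):
            raise ValueError("data contain non-finite values")
        if data.t.size < 2:
            raise ValueError("need at least two delay points")
        cfg = self.config if self.config is not None else FitConfig()
        groups = _check_groups(
            cfg.groups if cfg.groups is not None else self.network.groups(),
            self.network.names,
        )
        rng = np.random.default_rng(cfg.seed)
        resid, unpack, inner, fit_gamma, w_prior = self._residual_factory(data, groups, cfg)

        nfree = len(cfg.free)
        lo = [math.log(cfg.rate_bounds(s)[0]) for s in cfg.free]
        hi = [math.log(cfg.rate_bounds(s)[1]) for s in cfg.free]
        if cfg.fit_t0:
            lo.append(cfg.t0_bounds[0])
            hi.append(cfg.t0_bounds[1])
        if cfg.fit_irf:
            lo.append(math.log(cfg.irf_bounds[0]))
            hi.append(math.log(cfg.irf_bounds[1]))
        if fit_gamma:
            lo.append(math.log(cfg.gamma_bounds[0]))
            hi.append(math.log(cfg.gamma_bounds[1]))

        restarts: list[dict] = []
        for i in range(cfg.n_restarts):
            # log-uniform initial rates: uniform draws in log space
            x0 = [rng.uniform(math.log(cfg.rate_init_range(s)[0]),
                              math.log(cfg.rate_init_range(s)[1]))
                  for s in cfg.free]
            if cfg.fit_t0:
                x0.append(rng.uniform(*cfg.t0_bounds))
            if cfg.fit_irf:
                x0.append(rng.uniform(math.log(cfg.irf_bounds[0]),
                                      math.log(cfg.irf_bounds[1])))
            if fit_gamma:
                x0.append(rng.uniform(math.log(cfg.gamma_init[0]),
                                      math.log(cfg.gamma_init[1])))
            try:
                sol = least_squares(
                    resid, np.asarray(x0), bounds=(lo, hi), method="trf",
                    xtol=1e-12, ftol=1e-12, gtol=1e-12, x_scale="jac",
                )
                rates, irf, gamma = unpack(sol.x)
                entry = {
                    "x": sol.x, "cost": sol.cost, "status": sol.status,
                    "nfev": sol.nfev, "rates": rates, "irf": irf, "gamma": gamma,
                    "converged": sol.status > 0 and np.isfinite(sol.cost),
                    "reason": "",
                }
                # bound-hugging restarts did not find an interior optimum
                at_bound = np.any(
                    (sol.x[:nfree] < np.asarray(lo[:nfree]) + 1e-6)
                    | (sol.x[:nfree] > np.asarray(hi[:nfree]) - 1e-6)
                )
                if at_bound:
                    entry["converged"] = False
                    entry["reason"] = "rate at bound"
            except Exception as exc:  # noqa: BLE001 - diagnostics per restart
                entry = {"x": None, "cost": math.inf, "status": -99,
                         "nfev": 0, "rates": None, "irf": None, "gamma": None,
                         "converged": False, "reason": repr(exc)}
            restarts.append(entry)

        converged = [r for r in restarts if r["converged"]]
        if not converged:
            details = "; ".join(f"restart {i}: status={r['status']} {r['reason']}"
                                for i, r in enumerate(restarts))
            raise RuntimeError(f"no restart converged: {details}")

        best = min(converged, key=lambda r: r["cost"])
        # restarts stuck in distinctly worse local minima are excluded from
        # the aggregate (exclusion reason recorded per restart)
        cut = best["cost"] * (1.0 + cfg.cost_trim) + 1e-9
        good = []
        for r in converged:
            if r["cost"] <= cut:
                good.append(r)
            else:
                r["converged"] = False
                r["reason"] = "local minimum (cost above best)"
        _, _, _, pops, coeffs, best_targets = inner(best["x"])
        coeffs, cov = solve_patterns_linear(
            data, pops, groups, cfg.condition_threshold, warn=True,
            prior_targets=best_targets, prior_weight=w_prior)
        model_vals = _compose(coeffs, pops, groups)
        w = data.weights()
        dof = max(int((~data.mask).sum()) - (len(groups) * data.q.size + nfree), 1)
        chi2 = float((((data.values - model_vals) ** 2) * w).sum() / dof)

        # aggregate over restarts that reached the global cost level
        per_sym = {s: np.array([r["rates"][s] for r in good]) for s in RATE_SYMBOLS}
        all_coeffs = []
        gammas = []
        for r in good:
            _, _, gam_r, _, c, _ = inner(r["x"])
            all_coeffs.append(c)
            if gam_r is not None:
                gammas.append(gam_r)
            elif self.theory_patterns is not None:
                gammas.append(estimate_gamma(c, self.theory_patterns,
                                             anchor_groups=self.anchor_groups))
        coeffs_sd = {
            g: np.std([c[g] for c in all_coeffs], axis=0) for g in groups
        }

        self.groups_ = groups
        self.rates_ = best["rates"]
        self.rates_mean_ = {s: float(per_sym[s].mean()) for s in RATE_SYMBOLS}
        self.rates_sd_ = {s: float(per_sym[s].std()) for s in RATE_SYMBOLS}
        self.t0_ = best["irf"].t0
        self.irf_fwhm_ = best["irf"].fwhm
        self.t0_sd_ = float(np.std([r["irf"].t0 for r in good]))
        self.irf_fwhm_sd_ = float(np.std([r["irf"].fwhm for r in good]))
        self.coeffs_ = coeffs
        self.coeffs_sd_ = coeffs_sd
        self.coeffs_cov_ = cov
        if gammas:
            self.gamma_ = float(np.mean(gammas))
            self.gamma_sd_ = float(np.std(gammas))
            self.patterns_ = {
                g: DiffPattern(data.q, coeffs[g] / self.gamma_, label=g,
                               sigma=coeffs_sd[g] / self.gamma_)
                for g in groups
            }
        else:
            self.gamma_ = None
            self.gamma_sd_ = None
            self.patterns_ = None
        self.populations_ = pops
        self.residual_ = residual_map(
            data, SignalMap(data.q, data.t, model_vals, data.sigma, meta={"source": "model"})
        )
        self.chi2_ = chi2
        self.n_converged_ = len(good)
        self.restarts_ = restarts
        return self

    def result(self) -> FitResult:
        """Bundle fitted attributes into a :class:`FitResult`."""
        if not hasattr(self, "rates_"):
            raise RuntimeError("call fit() first")
        return FitResult(
            rates=self.rates_, rates_mean=self.rates_mean_, rates_sd=self.rates_sd_,
            gamma=self.gamma_, gamma_sd=self.gamma_sd_,
            coeffs=self.coeffs_, coeffs_sd=self.coeffs_sd_, patterns=self.patterns_,
            residual=self.residual_, chi2=self.chi2_,
            t0=self.t0_, irf_fwhm=self.irf_fwhm_,
            t0_sd=self.t0_sd_, irf_fwhm_sd=self.irf_fwhm_sd_,
            n_converged=self.n_converged_, restarts=self.restarts_,
        )


def _compose(coeffs: Mapping[str, np.ndarray], pops: PopulationSet,
             groups: Mapping[str, Sequence[str]]) -> np.ndarray:
    courses = pops.group_courses(groups)  # (nt, ng)
    s = np.stack([coeffs[g] for g in groups])  # (ng, nq)
    return s.T @ courses.T


def global_fit(
    data: SignalMap,
    network: ReactionNetwork,
    config: FitConfig | None = None,
    irf: InstrumentResponse | None = None,
    theory_patterns: Mapping[str, np.ndarray] | None = None,
    anchor_groups: tuple[str, ...] = ("FB", "FA-2"),
) -> FitResult:
    """Functional wrapper around :class:`KineticGlobalFit`."""
    est = KineticGlobalFit(network=network,
                           irf=irf if irf is not None else InstrumentResponse(),
                           config=config, theory_patterns=theory_patterns,
                           anchor_groups=anchor_groups)
    est.fit(data)
    return est.result()


def estimate_gamma(
    extracted: Mapping[str, np.ndarray],
    theory: Mapping[str, np.ndarray],
    anchor_groups: Sequence[str] | None = None,
    sigma: Mapping[str, np.ndarray] | None = None,
    full_output: bool = False,
):
    """Excitation fraction from gamma-folded patterns vs IAM theory.

    The fit determines only gamma * S_alpha(q); the absolute scale comes
    from anchoring one or more groups to theoretical IAM patterns:
    gamma = argmin sum_g sum_q w (extracted - gamma * theory)^2, i.e. the
    weighted least-squares scale factor pooled over anchor groups.
    """
    anchors = list(anchor_groups) if anchor_groups is not None else sorted(set(extracted) & set(theory))
    if not anchors:
        raise ValueError("no anchor groups in common between extracted and theory")
    num = 0.0
    den = 0.0
    per_group: dict[str, float] = {}
    for g in anchors:
        e = np.asarray(extracted[g], float)
        th = np.asarray(theory[g], float)
        if e.shape != th.shape:
            raise ValueError(f"shape mismatch for group {g!r}")
        w = 1.0 / np.asarray(sigma[g], float) ** 2 if sigma is not None else np.ones_like(e)
        tt = float((w * th * th).sum())
        if tt == 0.0:
            raise ValueError(f"theory pattern for group {g!r} has zero norm")
        per_group[g] = float((w * e * th).sum() / tt)
        num += float((w * e * th).sum())
        den += tt
    gamma = num / den
    if full_output:
        mismatch = {g: per_group[g] - gamma for g in anchors}
        return gamma, per_group, mismatch
    return gamma


def residual_map(data: SignalMap, model: SignalMap) -> SignalMap:
    """data - model with propagated sigma and simple whiteness statistics."""
    if not (np.array_equal(data.q, model.q) and np.array_equal(data.t, model.t)):
        raise ValueError("data and model are on different grids")
    res = data.values - model.values
    stats = {
        "mean": float(res[~data.mask].mean()),
        "lag1_autocorr_t": _mean_lag1_autocorr(res, data.mask),
    }
    return SignalMap(data.q, data.t, res, data.sigma, mask=data.mask,
                     meta={"source": "residual", "stats": stats})


def _mean_lag1_autocorr(res: np.ndarray, mask: np.ndarray) -> float:
    vals = []
    for row, m in zip(res, mask):
        r = row[~m]
        if r.size > 2 and r.std() > 0:
            c = np.corrcoef(r[:-1], r[1:])[0, 1]
            if np.isfinite(c):
                vals.append(c)
    return float(np.mean(vals)) if vals else float("nan")


def compare_patterns(extracted: DiffPattern, simulated: DiffPattern) -> float:
    """Error-weighted chi^2 per point between an extraction and a simulation.

    The simulated pattern is linearly resampled onto the extracted q grid if
    the grids differ; q points outside the common support are dropped.
    """
    qe = extracted.q
    qs = simulated.q
    losup, hisup = max(qe[0], qs[0]), min(qe[-1], qs[-1])
    keep = (qe >= losup) & (qe <= hisup)
    if not np.any(keep):
        raise ValueError("no overlapping q support")
    sim = np.interp(qe[keep], qs, simulated.values)
    err = extracted.sigma[keep] if extracted.sigma is not None else np.ones(keep.sum())
    return float((((extracted.values[keep] - sim) / err) ** 2).mean())


def rank_candidates(extracted: DiffPattern,
                    candidates: Mapping[str, DiffPattern]) -> list[tuple[str, float]]:
    """Candidate structures ordered by chi^2 agreement with an extraction."""
    scored = [(name, compare_patterns(extracted, sim)) for name, sim in candidates.items()]
    return sorted(scored, key=lambda kv: kv[1])
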