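"""Multi-start nonlinear least squares and profile-likelihood confidence intervals.

The objective everywhere is a sum of squared (optionally variance-scaled)
residuals F.  The 95% confidence interval of a parameter is the set where the
log-increase

    phi(p) = n * [log(F(p)/n) - log(F_min/n)] = n * log(F(p)/F_min)

stays below the chi-square 95% quantile with one degree of freedom (3.84),
with all other parameters re-optimized at every scan point.  Intervals that
run into a parameter bound without crossing the threshold are reported open
on that side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .config import CHI2_1_95

__all__ = ["ParamSpec", "FitResult", "multistart_fit", "profile_ci", "ConfidenceInterval"]

log = logging.getLogger("npckinetics.fitting")


@dataclass(frozen=True)
class ParamSpec:
    """One free parameter: bounds and scan/optimization scale."""

    name: str
    lo: float
    hi: float
    log_scale: bool = False

    def to_internal(self, value: float) -> float:
        return math.log(value) if self.log_scale else value

    def from_internal(self, x: float) -> float:
        return math.exp(x) if self.log_scale else x


@dataclass(frozen=True)
class ConfidenceInterval:
    lo: float
    hi: float
    open_lo: bool = False  # True when the scan hit the bound before phi crossed
    open_hi: bool = False

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi


@dataclass
class FitResult:
    """Best-fit parameters, objective value and per-parameter 95% CIs."""

    params: dict[str, float]
    F: float  # objective at the optimum (sum of squared scaled residuals)
    n: int  # number of residuals
    ci_95: dict[str, ConfidenceInterval] = field(default_factory=dict)
    profiles: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    #: per scan point, the full parameter dict with nuisances re-optimized
    profile_params: dict[str, list[dict]] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


def _internal_bounds(specs: list[ParamSpec]):
    lo = np.array([s.to_internal(s.lo) for s in specs])
    hi = np.array([s.to_internal(s.hi) for s in specs])
    return lo, hi


def _wrap(residual_fn, specs: list[ParamSpec], fixed: dict | None = None):
    names = [s.name for s in specs]

    def fn(x):
        params = {n: s.from_internal(v) for n, s, v in zip(names, specs, x)}
        if fixed:
            params.update(fixed)
        return np.asarray(residual_fn(params), dtype=float)

    return fn


def multistart_fit(
    residual_fn,
    specs: list[ParamSpec],
    n_starts: int = 20,
    seed: int = 0,
    x0_list: list[dict] | None = None,
    fixed: dict | None = None,
    xtol: float = 1e-10,
) -> FitResult:
    """Bounded least squares from multiple seeded random starts.

    ``residual_fn`` maps a parameter dict to a residual vector.  Starts are
    drawn uniformly in internal (log where requested) coordinates; explicit
    ``x0_list`` dicts are tried in addition.  Returns the best solution.
    """
    lo, hi = _internal_bounds(specs)
    fn = _wrap(residual_fn, specs, fixed)
    rng = np.random.default_rng(seed)
    starts = [lo + (hi - lo) * rng.random(len(specs)) for _ in range(n_starts)]
    for x0 in x0_list or []:
        starts.append(np.array([s.to_internal(x0[s.name]) for s in specs]))
    best = None
    n_fail = 0
    for x0 in starts:
        try:
            sol = least_squares(fn, x0, bounds=(lo, hi), xtol=xtol, method="trf")
        except Exception as err:  # singular model at this start: try the next
            n_fail += 1
            log.debug("start failed: %s", err)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(
            f"optimizer failed to converge from all {len(starts)} starts "
            f"({n_fail} raised)"
        )
    params = {s.name: s.from_internal(v) for s, v in zip(specs, best.x)}
    res = fn(best.x)
    F = float(np.sum(res**2))
    log.info("fit converged: F=%.6g, params=%s", F, params)
    return FitResult(params=params, F=F, n=res.size)


def _reoptimize(residual_fn, specs, free_specs, params, fixed_name, fixed_value, x0):
    fixed = {fixed_name: fixed_value}
    fn = _wrap(residual_fn, free_specs, fixed)
    if not free_specs:
        r = fn(np.empty(0))
        return float(np.sum(r**2)), np.empty(0)
    lo, hi = _internal_bounds(free_specs)
    x0 = np.clip(x0, lo, hi)
    sol = least_squares(fn, x0, bounds=(lo, hi), method="trf", xtol=1e-9)
    return 2.0 * float(sol.cost), sol.x


def profile_ci(
    residual_fn,
    specs: list[ParamSpec],
    fit: FitResult,
    name: str,
    n_grid: int = 60,
    threshold: float = CHI2_1_95,
) -> ConfidenceInterval:
    """Profile-likelihood 95% CI for one named parameter.

    The parameter is scanned from its estimate out to each bound on a
    monotone grid (log-spaced for log-scale parameters); at every point the
    remaining parameters are re-optimized, warm-started from the previous
    point.  Endpoints are located by linear interpolation of phi on the scan;
    a scan that exhausts its bound without crossing the threshold yields an
    open boundary flag rather than an error.  The scan (values, phi) is
    stored in ``fit.profiles[name]``.
    """
    spec = {s.name: s for s in specs}[name]
    free_specs = [s for s in specs if s.name != name]
    p_hat = fit.params[name]
    x_hat = np.array([s.to_internal(fit.params[s.name]) for s in free_specs])
    F_min, n = fit.F, fit.n

    def scan(direction: int):
        lim = spec.hi if direction > 0 else spec.lo
        a, b = spec.to_internal(p_hat), spec.to_internal(lim)
        grid = np.linspace(a, b, n_grid + 1)[1:]
        values, phis, plist = [], [], []
        x0 = x_hat.copy()
        for g in grid:
            v = spec.from_internal(g)
            F, x0 = _reoptimize(residual_fn, specs, free_specs, fit.params, name, v, x0)
            phi = n * math.log(max(F, 1e-300) / max(F_min, 1e-300))
            values.append(v)
            phis.append(phi)
            full = {s.name: s.from_internal(x) for s, x in zip(free_specs, x0)}
            full[name] = v
            plist.append(full)
            if phi > threshold * 1.5:
                break
        return np.array(values), np.array(phis), plist

    vals_up, phi_up, params_up = scan(+1)
    vals_dn, phi_dn, params_dn = scan(-1)

    def endpoint(values, phis, plist, bound):
        above = np.nonzero(phis > threshold)[0]
        if above.size == 0:
            return bound, True
        i = above[0]
        lo_v = p_hat if i == 0 else values[i - 1]
        hi_v = values[i]
        # refine the crossing by root finding on phi, re-optimizing the
        # nuisance parameters at each trial point (warm started)
        x_state = [np.array([spec_f.to_internal(plist[i][spec_f.name])
                             for spec_f in free_specs])]

        def phi_at(v):
            F, x_state[0] = _reoptimize(
                residual_fn, specs, free_specs, fit.params, name, v, x_state[0]
            )
            return n * math.log(max(F, 1e-300) / max(F_min, 1e-300)) - threshold

        try:
            from scipy.optimize import brentq

            root = brentq(phi_at, min(lo_v, hi_v), max(lo_v, hi_v),
                          rtol=1e-5, maxiter=30)
        except ValueError:  # no sign change at the refined ends: fall back
            lo_phi = 0.0 if i == 0 else phis[i - 1]
            frac = (threshold - lo_phi) / (phis[i] - lo_phi)
            root = lo_v + frac * (hi_v - lo_v)
        return root, False

    hi_val, open_hi = endpoint(vals_up, phi_up, params_up, spec.hi)
    lo_val, open_lo = endpoint(vals_dn, phi_dn, params_dn, spec.lo)
    ci = ConfidenceInterval(min(lo_val, p_hat), max(hi_val, p_hat), open_lo, open_hi)
    all_v = np.concatenate([vals_dn, [p_hat], vals_up])
    all_phi = np.concatenate([phi_dn, [0.0], phi_up])
    all_params = list(params_dn) + [dict(fit.params)] + list(params_up)
    order = np.argsort(all_v)
    fit.ci_95[name] = ci
    fit.profiles[name] = (all_v[order], all_phi[order])
    fit.profile_params[name] = [all_params[i] for i in order]
    return ci
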