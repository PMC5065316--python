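"""Delay-equation model of nuclear pore maturation.

Assembly intermediates are produced at a rate V(t) (counts/min over the whole
region surface), enter maturation with rate constant kM, become mature pores
a fixed delay tauM later, and mature pores are degraded with rate constant
kd:

    dI/dt  = V(t) - kM * I(t)
    dIm/dt = kM * I(t) - kM * I(t - tauM)
    dM/dt  = kM * I(t - tauM) - kd * M(t)

with history I(t) = 0 for t < 0.  Model time t runs from NE sealing,
t = tAO - tauS.  The measurable quantity is the total intermediate count
IT = I + Im; surface densities are iT = IT/A and m = M/A with A(t) the
growing nuclear-region area.

Production variants:

* ``constant_rate`` (Variant 1):  V = v * A(t)
* ``decaying_rate`` (Variant 2):  V = (v1 * exp(-kv t) + v0) * A(t)
* ``burst`` (Variant 3):          V = v0 * A(t), plus a delta-function
  initiation at sealing implemented as the initial condition
  I(0) = i0 * A(0) (per region).

The overall maturation time is TM = 1/kM + tauM.  Alternatives with the same
interface: an N-step chain with equal per-step rate kM (TM = (N-1)/kM,
Erlang-distributed maturation) and a distributed-delay model where the fixed
tauM is replaced by a uniform distribution tauM +/- w.

Integration uses an exponential integrator on a uniform grid: each linear
compartment is advanced with the exact decay factor and a piecewise-linear
quadrature of its forcing (second-order accurate, unconditionally stable),
with delayed terms looked up by monotone interpolation of the stored I
history and an internal step that also resolves the 1/kM initial transient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import lsq_linear
from scipy.signal import lfilter

from .config import RunConfig
from .fitting import FitResult, ParamSpec, multistart_fit, profile_ci
from .growth import GrowthParams, area_at
from .table_io import CORE_REGIONS, RegionLabel, TomogramSample

__all__ = [
    "MaturationParams",
    "MultiStepParams",
    "DelayDistribution",
    "SimulationResult",
    "simulate",
    "simulate_multistep",
    "simulate_distributed",
    "densities_from_samples",
    "objective",
    "fit",
    "maturation_time",
    "VARIANTS",
]

log = logging.getLogger("npckinetics.maturation")

VARIANTS = ("constant_rate", "decaying_rate", "burst")

#: default integrator step, min
DEFAULT_STEP = 0.25


@dataclass(frozen=True)
class MaturationParams:
    """All rate constants and initial densities of the delay model."""

    variant: str = "burst"
    kM: float = 1.0  # per min, maturation initiation rate constant
    tauM: float = 40.0  # min, maturation delay
    kd: float = 0.00042  # per min, mature-pore degradation
    tauS: float = 10.0  # min, NE sealing time after anaphase onset
    v: float = 0.0  # intermediates/um^2/min (constant_rate)
    v1: float = 0.0  # intermediates/um^2/min (decaying_rate amplitude)
    kv: float = 0.0  # per min (decaying_rate decay)
    v0: float = 0.015  # intermediates/um^2/min (basal, decaying_rate/burst)
    i0_by_region: dict = field(default_factory=dict)  # intermediates/um^2 at tS
    m0_by_region: dict = field(default_factory=dict)  # pores/um^2 at tS

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        for name in ("kM", "kd", "v", "v1", "kv", "v0", "tauM", "tauS"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def i0(self, region: str) -> float:
        if self.variant != "burst":
            return 0.0
        return self.i0_by_region.get(region, self.i0_by_region.get("default", 0.0))

    def m0(self, region: str) -> float:
        return self.m0_by_region.get(region, self.m0_by_region.get("default", 0.0))


@dataclass(frozen=True)
class MultiStepParams:
    """Maturation as an (N-1)-intermediate chain with equal step rate kM."""

    n_steps: int  # N >= 2; N-1 sequential intermediate compartments
    kM: float
    kd: float = 0.00042
    tauS: float = 10.0
    v0: float = 0.015
    i0_by_region: dict = field(default_factory=dict)
    m0_by_region: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.kM < 0 or self.kd < 0:
            raise ValueError("rates must be >= 0")


@dataclass(frozen=True)
class DelayDistribution:
    """Uniform maturation-time distribution tauM +/- w (finite support)."""

    center: float  # tauM, min
    half_width: float  # w, min
    form: str = "uniform"

    def __post_init__(self) -> None:
        if self.form != "uniform":
            raise ValueError(f"unsupported distribution form {self.form!r}")
        if not 0 <= self.half_width <= self.center:
            raise ValueError("need 0 <= w <= tauM for positive support")


@dataclass
class SimulationResult:
    """Trajectories in model time t = tAO - tauS (counts and densities)."""

    times: np.ndarray  # min, model time
    I: np.ndarray  # intermediates not yet maturing
    Im: np.ndarray  # intermediates inside the maturation delay
    IT: np.ndarray  # I + Im, the measurable intermediate count
    M: np.ndarray  # mature pores
    iT: np.ndarray  # IT / A, per um^2
    m: np.ndarray  # M / A, per um^2

    def at(self, t) -> "SimulationResult":
        """Linear interpolation of all trajectories at the given times."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        interp = lambda y: np.interp(t, self.times, y)
        return SimulationResult(
            t, *(interp(getattr(self, f)) for f in ("I", "Im", "IT", "M", "iT", "m"))
        )


def _phi_coeffs(k: float, h: float):
    """Exact step response of y' = f(t) - k y for piecewise-linear f."""
    if k * h < 1e-12:
        return 1.0, h, h * h / 2.0
    alpha = math.exp(-k * h)
    phi1 = -math.expm1(-k * h) / k
    phi2 = (h - phi1) / k
    return alpha, phi1, phi2


def _linear_decay(y0: float, forcing: np.ndarray, k: float, h: float) -> np.ndarray:
    """Advance y' = f(t) - k y on a uniform grid; f linear between nodes."""
    alpha, phi1, phi2 = _phi_coeffs(k, h)
    f = np.asarray(forcing, dtype=float)
    beta = f[:-1] * phi1 + np.diff(f) * (phi2 / h)
    y_rest, _ = lfilter([1.0], [1.0, -alpha], beta, zi=[alpha * y0])
    return np.concatenate([[y0], y_rest])


def _grid(t_grid: np.ndarray, step: float, kM: float = 0.0):
    """Uniform internal grid; the step also resolves the 1/kM transient."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be 1-D and strictly increasing")
    if t_grid[0] < 0:
        raise ValueError("t_grid must start at or after sealing (model time 0)")
    if kM > 0:
        # resolve the 1/kM transient, but keep the grid bounded: the exact
        # per-step decay factor stays stable for under-resolved stiff decay
        step = min(step, max(0.2 / kM, 1e-3))
    t_end = t_grid[-1]
    n = max(int(math.ceil(t_end / step)), 2)
    return np.linspace(0.0, t_end, n + 1)


def _cumulative(values: np.ndarray, h: float) -> np.ndarray:
    """Trapezoidal cumulative integral from 0 on a uniform grid."""
    return np.concatenate([[0.0], np.cumsum((values[1:] + values[:-1]) * 0.5 * h)])


def _im_from_identity(t, I, V, I0, kM, tau, h):
    """Im(t) = kM * (C(t) - C(t - tau)) with C = int_0^t I ds obtained from
    the exact balance I(t) - I(0) = int V - kM int I, which carries no
    quadrature error on the sharp homogeneous transient of burst runs."""
    if kM <= 0 or tau == 0.0:
        return np.zeros_like(t)
    C = (I0 - I + _cumulative(V, h)) / kM
    ts = t - tau
    C_del = np.zeros_like(C)
    inside = ts >= 0
    if inside.any():
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            C_del[inside] = PchipInterpolator(t, C)(ts[inside])
    return kM * (C - C_del)


def _production(p, A: np.ndarray, t: np.ndarray) -> np.ndarray:
    if isinstance(p, MultiStepParams) or p.variant == "burst":
        return p.v0 * A
    if p.variant == "constant_rate":
        return p.v * A
    return (p.v1 * np.exp(-p.kv * t) + p.v0) * A


def _mh_burst(t: np.ndarray, I0: float, kM: float, kd: float, tau: float) -> np.ndarray:
    """Mature pores produced by the delayed homogeneous (burst) component.

    M_h solves M_h' = kM * I0 * exp(-kM (t - tau)) - kd * M_h with
    M_h(tau) = 0 — closed form, so the forcing discontinuity at t = tau
    costs no quadrature error.
    """
    out = np.zeros_like(t)
    if I0 == 0.0 or kM == 0.0:
        return out
    dt = t - tau
    mask = dt >= 0
    d = dt[mask]
    with np.errstate(over="ignore", under="ignore"):
        if abs(kM - kd) < 1e-12 * max(kM, kd):
            out[mask] = kM * I0 * d * np.exp(-kM * d)
        else:
            out[mask] = kM * I0 * (np.exp(-kd * d) - np.exp(-kM * d)) / (kM - kd)
    return out


def _delayed(t: np.ndarray, I: np.ndarray, tau: float) -> np.ndarray:
    """I(t - tau) with zero history for t < 0.

    Monotone (PCHIP) interpolation is overshoot-free on the sharp initial
    transient of burst runs and smooth in tau, so the fitting objective has
    neither spline ringing nor derivative kinks at grid nodes.
    """
    if tau == 0.0:
        return I.copy()
    ts = t - tau
    out = np.zeros_like(I)
    inside = ts >= 0
    if inside.any():
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            out[inside] = PchipInterpolator(t, I)(ts[inside])
    return out


def _pack(t_grid, t, I, Im, M, A):
    IT = I + Im
    out = SimulationResult(t, I, Im, IT, M, IT / A, M / A)
    return out.at(t_grid) if (t.size != t_grid.size or not np.allclose(t, t_grid)) else out


def simulate(
    params: MaturationParams,
    growth: GrowthParams,
    t_grid,
    region: str = "default",
    step: float = DEFAULT_STEP,
) -> SimulationResult:
    """Simulate the fixed-delay model on ``t_grid`` (model time, from 0).

    The burst variant's delta-function initiation enters as the initial
    condition I(0) = i0 * A(0); there is no delta inside the integrator.
    """
    t = _grid(t_grid, step, params.kM)
    h = t[1] - t[0]
    A = area_at(t + params.tauS, growth)
    V = _production(params, A, t)
    I0 = params.i0(region) * A[0]
    M0 = params.m0(region) * A[0]
    if params.tauM > 0 and I0 > 0:
        # the burst component I0*exp(-kM t) makes the delayed forcing jump at
        # t = tauM; superpose its mature-pore response in closed form and
        # integrate only the continuous production-driven part numerically
        with np.errstate(under="ignore"):
            I_h = I0 * np.exp(-params.kM * t)
        I_p = _linear_decay(0.0, V, params.kM, h)
        I = I_p + I_h
        M = (
            _linear_decay(M0, params.kM * _delayed(t, I_p, params.tauM), params.kd, h)
            + _mh_burst(t, I0, params.kM, params.kd, params.tauM)
        )
    else:
        I = _linear_decay(I0, V, params.kM, h)
        I_del = _delayed(t, I, params.tauM)
        M = _linear_decay(M0, params.kM * I_del, params.kd, h)
    Im = _im_from_identity(t, I, V, I0, params.kM, params.tauM, h)
    return _pack(np.asarray(t_grid, float), t, I, Im, M, A)


def simulate_multistep(
    params: MultiStepParams,
    growth: GrowthParams,
    t_grid,
    region: str = "default",
    step: float = DEFAULT_STEP,
) -> SimulationResult:
    """Simulate the N-step chain; measured intermediates are sum_{j<N} I_j.

    The first compartment carries the burst initial condition; downstream
    compartments start empty.  With N = 2 the chain is exactly the delay
    model with tauM = 0.  ``Im`` holds the downstream compartments (j >= 2).
    """
    t = _grid(t_grid, step, params.kM)
    h = t[1] - t[0]
    A = area_at(t + params.tauS, growth)
    V = _production(params, A, t)
    i0 = params.i0_by_region.get(region, params.i0_by_region.get("default", 0.0))
    m0 = params.m0_by_region.get(region, params.m0_by_region.get("default", 0.0))
    I1 = _linear_decay(i0 * A[0], V, params.kM, h)
    chain = [I1]
    for _ in range(2, params.n_steps):
        chain.append(_linear_decay(0.0, params.kM * chain[-1], params.kM, h))
    M = _linear_decay(m0 * A[0], params.kM * chain[-1], params.kd, h)
    Im = np.sum(chain[1:], axis=0) if len(chain) > 1 else np.zeros_like(I1)
    return _pack(np.asarray(t_grid, float), t, I1, Im, M, A)


def simulate_distributed(
    params: MaturationParams,
    delay: DelayDistribution,
    growth: GrowthParams,
    t_grid,
    region: str = "default",
    step: float = DEFAULT_STEP,
    n_quad: int = 33,
) -> SimulationResult:
    """Simulate with maturation times drawn from a uniform tauM +/- w.

    The delayed flux kM * integral P(tau) I(t - tau) dtau is evaluated by
    composite Simpson quadrature over the distribution's support; w = 0
    reduces to :func:`simulate`.
    """
    if delay.half_width == 0:
        return simulate(
            replace(params, tauM=delay.center), growth, t_grid, region, step
        )
    t = _grid(t_grid, step, params.kM)
    h = t[1] - t[0]
    A = area_at(t + params.tauS, growth)
    V = _production(params, A, t)
    I0 = params.i0(region) * A[0]
    M0 = params.m0(region) * A[0]
    with np.errstate(under="ignore"):
        I_h = I0 * np.exp(-params.kM * t)
    I_p = _linear_decay(0.0, V, params.kM, h)
    I = I_p + I_h
    taus = np.linspace(delay.center - delay.half_width, delay.center + delay.half_width,
                       n_quad if n_quad % 2 == 1 else n_quad + 1)
    w_simp = np.ones(taus.size)
    w_simp[1:-1:2], w_simp[2:-1:2] = 4.0, 2.0
    w_simp *= (taus[1] - taus[0]) / 3.0 / (2.0 * delay.half_width)
    I_del_p = np.einsum("q,qn->n", w_simp,
                        np.stack([_delayed(t, I_p, tau) for tau in taus]))
    M = _linear_decay(M0, params.kM * I_del_p, params.kd, h)
    M += np.einsum("q,qn->n", w_simp,
                   np.stack([_mh_burst(t, I0, params.kM, params.kd, tau)
                             for tau in taus]))
    Im = np.einsum(
        "q,qn->n", w_simp,
        np.stack([_im_from_identity(t, I, V, I0, params.kM, tau, h)
                  for tau in taus]),
    )
    return _pack(np.asarray(t_grid, float), t, I, Im, M, A)


def maturation_time(params) -> float:
    """Overall maturation time TM in minutes.

    TM = 1/kM + tauM for the delay model, (N-1)/kM for the N-step chain.
    kM = 0 has no finite maturation time and returns inf.
    """
    if params.kM == 0:
        return math.inf
    if isinstance(params, MultiStepParams):
        return (params.n_steps - 1) / params.kM
    return 1.0 / params.kM + params.tauM


# ---------------------------------------------------------------------------
# fitting to density time courses


def densities_from_samples(
    samples: list[TomogramSample],
    regions=CORE_REGIONS,
    time_window: tuple[float, float] = (0.0, 130.0),
):
    """Per-region density time courses for fitting.

    Returns ``{region_value: (t_ao, d_intermediate, d_mature)}`` with one
    point per tomogram sample inside the window, sorted by time.
    """
    out = {}
    for region in regions:
        rows = sorted(
            (s for s in samples
             if s.region == region and time_window[0] <= s.time_ao <= time_window[1]),
            key=lambda s: s.time_ao,
        )
        if rows:
            out[region.value] = (
                np.array([s.time_ao for s in rows]),
                np.array([s.n_intermediate / s.area for s in rows]),
                np.array([s.n_mature / s.area for s in rows]),
            )
    return out


def _scaled_residuals(params, data, growth, config, step):
    res = []
    sigma = math.sqrt(config.sigma2)
    for region, (t_ao, d_int, d_mat) in data.items():
        t_model = t_ao - params.tauS
        sim = (
            simulate_multistep(params, growth, t_model, region=region, step=step)
            if isinstance(params, MultiStepParams)
            else simulate(params, growth, t_model, region=region, step=step)
        )
        res.append((sim.iT - d_int) / sigma)
        res.append((sim.m - d_mat) / sigma)
    return np.concatenate(res)


def objective(params, data, growth: GrowthParams, config: RunConfig | None = None,
              step: float = DEFAULT_STEP) -> float:
    """Variance-scaled sum of squared residuals F over both regions and both
    observables (intermediate and mature densities)."""
    config = config or RunConfig()
    if config.sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    r = _scaled_residuals(params, data, growth, config, step)
    return float(np.sum(r**2))


def _param_specs(variant: str, regions: list[str], n_steps: int | None = None):
    """Full free-parameter list (nonlinear rates plus linear amplitudes)."""
    specs = []
    if variant == "constant_rate":
        specs.append(ParamSpec("v", 1e-7, 1.0, log_scale=True))
    elif variant == "decaying_rate":
        specs.append(ParamSpec("v1", 1e-7, 10.0, log_scale=True))
        specs.append(ParamSpec("kv", 1e-5, 2.0, log_scale=True))
    specs.append(ParamSpec("kM", 1e-3, 20.0, log_scale=True))
    if n_steps is None:
        specs.append(ParamSpec("tauM", 0.0, 120.0))
    if variant == "burst":
        for r in regions:
            specs.append(ParamSpec(f"i0_{r}", 0.0, 30.0))
    for r in regions:
        specs.append(ParamSpec(f"m0_{r}", 0.0, 30.0))
    return specs


def _outer_specs(variant: str, n_steps: int | None = None):
    """The nonlinear parameters; everything else is solved by projection."""
    specs = []
    if variant == "decaying_rate":
        specs.append(ParamSpec("kv", 1e-5, 2.0, log_scale=True))
    specs.append(ParamSpec("kM", 1e-3, 20.0, log_scale=True))
    if n_steps is None:
        specs.append(ParamSpec("tauM", 0.0, 120.0))
    return specs


def _basis_sims(variant, outer, config, growth, t_model, region, step, n_steps):
    """Model response split into unit-amplitude components.

    At fixed nonlinear rates the trajectories are linear in the initial
    densities and production amplitudes, so the model is
    fixed_part + sum_j coef_j * basis_j.  Returns (fixed, bases) where each
    entry is a (iT_density, m_density) pair on ``t_model`` and ``bases`` maps
    coefficient name -> pair.
    """
    kM = outer["kM"]
    tauM = outer.get("tauM", 0.0)

    def run(**kw):
        if n_steps is not None:
            p = MultiStepParams(n_steps=n_steps, kM=kM, kd=config.kd,
                                tauS=config.sealing_time, **kw)
            s = simulate_multistep(p, growth, t_model, region=region, step=step)
        else:
            p = MaturationParams(kd=config.kd, tauS=config.sealing_time,
                                 kM=kM, tauM=tauM, **kw)
            s = simulate(p, growth, t_model, region=region, step=step)
        return s.iT, s.m

    bases = {}
    if variant == "burst" or n_steps is not None:
        fixed = run(variant="burst", v0=config.v0) if n_steps is None else run(v0=config.v0)
        if n_steps is None:
            bases[f"i0_{region}"] = run(variant="burst", v0=0.0,
                                        i0_by_region={region: 1.0})
        else:
            bases[f"i0_{region}"] = run(v0=0.0, i0_by_region={region: 1.0})
    elif variant == "constant_rate":
        fixed = (np.zeros_like(t_model, dtype=float),) * 2
        bases["v"] = run(variant="constant_rate", v=1.0, v0=0.0)
    else:  # decaying_rate
        fixed = run(variant="decaying_rate", v1=0.0, kv=outer["kv"], v0=config.v0)
        b = run(variant="decaying_rate", v1=1.0, kv=outer["kv"], v0=0.0)
        fixed_iT, fixed_m = fixed
        bases["v1"] = b
        fixed = (fixed_iT, fixed_m)
    if n_steps is None:
        bases[f"m0_{region}"] = run(variant="burst", v0=0.0,
                                    m0_by_region={region: 1.0})
    else:
        bases[f"m0_{region}"] = run(v0=0.0, m0_by_region={region: 1.0})
    return fixed, bases


def _project(variant, outer, data, growth, config, step, n_steps):
    """Solve the bounded linear subproblem at fixed nonlinear rates.

    Returns (residual_vector, coefficient_dict).  Shared amplitudes (v, v1)
    get one column across regions; initial densities one column per region.
    """
    sigma = math.sqrt(config.sigma2)
    cols: dict[str, list] = {}
    fixed_parts, rhs = [], []
    blocks = []
    for region, (t_ao, d_int, d_mat) in data.items():
        t_model = t_ao - config.sealing_time
        fixed, bases = _basis_sims(variant, outer, config, growth, t_model,
                                   region, step, n_steps)
        blocks.append((region, fixed, bases, d_int, d_mat))
    names = []
    for _, _, bases, _, _ in blocks:
        for name in bases:
            if name not in names:
                names.append(name)
    rows_A, rows_b = [], []
    for region, fixed, bases, d_int, d_mat in blocks:
        npts = d_int.size
        for obs_i, (fx, dat) in enumerate(((fixed[0], d_int), (fixed[1], d_mat))):
            A = np.zeros((npts, len(names)))
            for j, name in enumerate(names):
                if name in bases:
                    A[:, j] = bases[name][obs_i]
            rows_A.append(A / sigma)
            rows_b.append((dat - fx) / sigma)
    A = np.vstack(rows_A)
    b = np.concatenate(rows_b)
    lo = np.zeros(len(names))
    hi = np.array([30.0 if name.startswith(("i0_", "m0_")) else np.inf
                   for name in names])
    sol = lsq_linear(A, b, bounds=(lo, hi), method="bvls")
    coefs = dict(zip(names, sol.x))
    return A @ sol.x - b, coefs


def _build_params(variant, values, config, regions, n_steps=None):
    i0 = {r: values.get(f"i0_{r}", 0.0) for r in regions}
    m0 = {r: values.get(f"m0_{r}", 0.0) for r in regions}
    if n_steps is not None:
        return MultiStepParams(
            n_steps=n_steps, kM=values["kM"], kd=config.kd, tauS=config.sealing_time,
            v0=config.v0, i0_by_region=i0, m0_by_region=m0,
        )
    return MaturationParams(
        variant=variant,
        kM=values["kM"],
        tauM=values.get("tauM", 0.0),
        kd=config.kd,
        tauS=config.sealing_time,
        v=values.get("v", 0.0),
        v1=values.get("v1", 0.0),
        kv=values.get("kv", 0.0),
        v0=config.v0 if variant in ("decaying_rate", "burst") else 0.0,
        i0_by_region=i0,
        m0_by_region=m0,
    )


def fit(
    variant: str,
    data: dict,
    growth: GrowthParams,
    config: RunConfig | None = None,
    n_starts: int = 20,
    seed: int = 0,
    step: float = DEFAULT_STEP,
    n_steps: int | None = None,
    profile: tuple[str, ...] = (),
    profile_grid: int = 60,
) -> FitResult:
    """Fit a production variant (or, with ``n_steps``, the multi-step chain)
    to per-region density time courses.

    ``data`` is the mapping produced by :func:`densities_from_samples`.  kd,
    v0 and tauS are fixed from the run configuration; the free parameters are
    the variant's rates plus per-region initial densities.  Multi-start
    bounded optimization in log/linear coordinates; 95% profile-likelihood
    CIs are computed for the parameters named in ``profile``.  The result's
    ``extra`` carries the built parameter object and TM (with a CI whenever
    kM and tauM were both profiled).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    config = config or RunConfig()
    regions = list(data.keys())
    outer = _outer_specs(variant, n_steps)
    coef_cache: dict = {}

    def residuals(values):
        res, coefs = _project(variant, values, data, growth, config, step, n_steps)
        coef_cache.update(coefs)
        return res

    x0_list = [{"kv": 0.05, "kM": km, "tauM": tm}
               for km in (0.08, 1.5) for tm in (15.0, 45.0)]
    x0_list = [{s.name: x0[s.name] for s in outer} for x0 in x0_list]
    fitres = multistart_fit(residuals, outer, n_starts=n_starts, seed=seed,
                            x0_list=x0_list)
    residuals(fitres.params)  # refresh the projected coefficients at the optimum
    fitres.params.update(coef_cache)
    want_tm_ci = "TM" in profile
    profile = tuple(p for p in profile if p != "TM")
    for name in profile:
        if name in {s.name for s in outer}:
            profile_ci(residuals, outer, fitres, name, n_grid=profile_grid)
        else:
            full_specs = _param_specs(variant, regions, n_steps)

            def full_residuals(values):
                p = _build_params(variant, values, config, regions, n_steps)
                return _scaled_residuals(p, data, growth, config, step)

            profile_ci(full_residuals, full_specs, fitres, name,
                       n_grid=profile_grid)
    best = _build_params(variant, fitres.params, config, regions, n_steps)
    fitres.extra["params_obj"] = best
    fitres.extra["TM"] = maturation_time(best)
    fitres.extra["sigma2"] = config.sigma2
    if want_tm_ci:
        if n_steps is not None:
            # TM = (N-1)/kM is monotone in kM: transform its profile CI
            if "kM" not in fitres.ci_95:
                profile_ci(residuals, outer, fitres, "kM", n_grid=profile_grid)
            ci = fitres.ci_95["kM"]
            fitres.extra["TM_ci"] = ((n_steps - 1) / ci.hi, (n_steps - 1) / ci.lo)
        else:
            fitres.extra["TM_ci"] = _profile_tm(
                variant, data, growth, config, step, fitres, profile_grid)
    return fitres


def _profile_tm(variant, data, growth, config, step, fitres, n_grid):
    """Direct profile-likelihood CI for TM = 1/kM + tauM.

    Reparametrize (kM, tauM) -> (TM, s) with tauM = TM*s and
    kM = 1/(TM*(1-s)): every admissible point keeps 1/kM + tauM = TM
    exactly, so scanning TM while re-optimizing s (and the projected
    amplitudes) profiles the quantity itself rather than tracing the
    per-parameter profile paths, which would under-cover.
    """
    tm_hat = fitres.extra["TM"]
    kM_hat = fitres.params["kM"]
    s_hat = min(max(fitres.params.get("tauM", 0.0) / tm_hat, 0.0), 0.999)
    specs = [ParamSpec("TM", 0.5, 200.0, log_scale=True),
             ParamSpec("s", 0.0, 0.999)]
    if variant == "decaying_rate":
        specs.append(ParamSpec("kv", 1e-5, 2.0, log_scale=True))

    def residual_tm(values):
        tm, s = values["TM"], values["s"]
        kM = min(max(1.0 / (tm * (1.0 - s)), 1e-3), 20.0)
        outer = {"kM": kM, "tauM": tm * s}
        if variant == "decaying_rate":
            outer["kv"] = values["kv"]
        res, _ = _project(variant, outer, data, growth, config, step, None)
        return res

    pseudo = FitResult(params={"TM": tm_hat, "s": s_hat}, F=fitres.F, n=fitres.n)
    if variant == "decaying_rate":
        pseudo.params["kv"] = fitres.params["kv"]
    ci = profile_ci(residual_tm, specs, pseudo, "TM", n_grid=n_grid)
    fitres.ci_95["TM"] = ci
    fitres.profiles["TM"] = pseudo.profiles["TM"]
    return (ci.lo, ci.hi)
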