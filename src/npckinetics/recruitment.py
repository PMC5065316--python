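"""Sequential Nup107 -> Nup358 recruitment kinetics.

Each NPC passes irreversibly through three states: no marker (N0), Nup107
only (N1), Nup107 + Nup358 (N2):

    dN0/dt = -k N0,   dN1/dt = k N0 - l N1,   dN2/dt = l N1

with separate rate constants for the postmitotic pool (pm, active from
t = 4 min after anaphase onset) and the interphase pool (ip, active from
NE sealing at t = 10 min).  Degradation and new production are neglected on
the 0-125 min window.  Measured total intensities mix the pools by the
postmitotic fraction f_pm of the region (0.92 in non-core, 0.5 in
inner-core):

    T_Nup107 = (N1 + N2)_pm f_pm + (N1 + N2)_ip (1 - f_pm)
    T_Nup358 = N2_pm f_pm + N2_ip (1 - f_pm)

The linear chain has a closed-form solution, used directly for simulation,
fitting and half-time root-finding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .fitting import FitResult, ParamSpec, multistart_fit, profile_ci
from .growth import GrowthParams, area_at
from .table_io import IntensityTrack, RegionLabel

__all__ = [
    "RecruitmentParams",
    "RecruitmentState",
    "PRINTED_RATES",
    "pool_fractions",
    "simulate_recruitment",
    "fit_recruitment",
    "half_time",
    "density_normalize",
    "DEFAULT_F_PM",
]

log = logging.getLogger("npckinetics.recruitment")

#: postmitotic NPC fraction per region (measured from density data)
DEFAULT_F_PM = {RegionLabel.NON_CORE: 0.92, RegionLabel.INNER_CORE: 0.5}


@dataclass(frozen=True)
class RecruitmentParams:
    k_pm: float = 0.355  # per min, Nup107 recruitment, postmitotic pool
    k_ip: float = 0.0374  # per min, Nup107 recruitment, interphase pool
    l_pm: float = 0.0437  # per min, Nup358 recruitment, postmitotic pool
    l_ip: float = 0.0276  # per min, Nup358 recruitment, interphase pool
    f_pm: float = 0.5  # postmitotic NPC fraction of the region
    t_pm_start: float = 4.0  # min after anaphase onset
    t_ip_start: float = 10.0  # min after anaphase onset (NE sealing)

    def __post_init__(self) -> None:
        for name in ("k_pm", "k_ip", "l_pm", "l_ip"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.f_pm <= 1:
            raise ValueError("f_pm must be in [0, 1]")


#: the four rate constants estimated from the live-imaging intensity data
PRINTED_RATES = RecruitmentParams()


@dataclass
class RecruitmentState:
    """Pool occupancies and mixed totals on a time grid (tAO, min)."""

    times: np.ndarray
    N0_pm: np.ndarray
    N1_pm: np.ndarray
    N2_pm: np.ndarray
    N0_ip: np.ndarray
    N1_ip: np.ndarray
    N2_ip: np.ndarray
    T_Nup107: np.ndarray
    T_Nup358: np.ndarray


def pool_fractions(t, k: float, l: float, t_start: float):
    """Closed-form (N0, N1, N2) of one pool; pool inactive before t_start.

    Handles the degenerate k == l case with the t*k*exp(-kt) limit.
    """
    t = np.asarray(t, dtype=float)
    dt = np.clip(t - t_start, 0.0, None)
    active = t >= t_start
    N0 = np.where(active, np.exp(-k * dt), 1.0)
    if k == 0:
        N1 = np.zeros_like(dt)
    elif abs(k - l) < 1e-12 * max(k, l):
        N1 = np.where(active, k * dt * np.exp(-k * dt), 0.0)
    else:
        N1 = np.where(
            active, k / (l - k) * (np.exp(-k * dt) - np.exp(-l * dt)), 0.0
        )
    N2 = 1.0 - N0 - N1
    return N0, N1, np.clip(N2, 0.0, None)


def simulate_recruitment(params: RecruitmentParams, t_grid) -> RecruitmentState:
    """Evaluate the closed-form model on a tAO grid covering both starts."""
    t = np.asarray(t_grid, dtype=float)
    N0p, N1p, N2p = pool_fractions(t, params.k_pm, params.l_pm, params.t_pm_start)
    N0i, N1i, N2i = pool_fractions(t, params.k_ip, params.l_ip, params.t_ip_start)
    f = params.f_pm
    T107 = (N1p + N2p) * f + (N1i + N2i) * (1.0 - f)
    T358 = N2p * f + N2i * (1.0 - f)
    return RecruitmentState(t, N0p, N1p, N2p, N0i, N1i, N2i, T107, T358)


_RATE_SPECS = [
    ParamSpec("k_pm", 1e-4, 5.0, log_scale=True),
    ParamSpec("k_ip", 1e-4, 5.0, log_scale=True),
    ParamSpec("l_pm", 1e-4, 5.0, log_scale=True),
    ParamSpec("l_ip", 1e-4, 5.0, log_scale=True),
]


def _model_curve(values: dict, track: IntensityTrack, f_pm: dict) -> np.ndarray:
    p = RecruitmentParams(
        k_pm=values["k_pm"], k_ip=values["k_ip"],
        l_pm=values["l_pm"], l_ip=values["l_ip"],
        f_pm=f_pm[track.region],
    )
    state = simulate_recruitment(p, track.times)
    return state.T_Nup107 if track.species == "Nup107" else state.T_Nup358


def fit_recruitment(
    tracks: list[IntensityTrack],
    f_pm: dict | None = None,
    t_window: tuple[float, float] = (4.0, 125.0),
    n_starts: int = 15,
    seed: int = 0,
    profile: tuple[str, ...] = (),
) -> FitResult:
    """Joint fit of the four rate constants to the four intensity tracks.

    Requires one track per (species, region) for Nup107/Nup358 in non-core
    and inner-core; f_pm is fixed per region.  Each model curve is multiplied
    by a fitted per-track normalization coefficient constrained to [1, 1.1]
    before comparison with the data (the experimental normalization sets the
    observed plateau to ~1 but the model plateau is exactly 1).
    """
    f_pm = dict(DEFAULT_F_PM) if f_pm is None else f_pm
    want = {(sp, rg) for sp in ("Nup107", "Nup358")
            for rg in (RegionLabel.NON_CORE, RegionLabel.INNER_CORE)}
    have = {(tr.species, tr.region) for tr in tracks}
    if not want <= have:
        raise ValueError(f"missing track(s): {sorted(want - have)}")
    use = [tr for tr in tracks if (tr.species, tr.region) in want]
    clipped = []
    for tr in use:
        keep = (tr.times >= t_window[0]) & (tr.times <= t_window[1])
        clipped.append(
            IntensityTrack(tr.species, tr.region, tr.times[keep], tr.values[keep])
        )
    specs = list(_RATE_SPECS)
    coef_names = []
    for i, tr in enumerate(clipped):
        name = f"c_{tr.species}_{tr.region.value}"
        coef_names.append(name)
        specs.append(ParamSpec(name, 1.0, 1.1))

    def residuals(values):
        res = []
        for tr, cname in zip(clipped, coef_names):
            res.append(values[cname] * _model_curve(values, tr, f_pm) - tr.values)
        return np.concatenate(res)

    x0 = {"k_pm": 0.3, "k_ip": 0.03, "l_pm": 0.05, "l_ip": 0.03}
    x0.update({c: 1.02 for c in coef_names})
    fit = multistart_fit(residuals, specs, n_starts=n_starts, seed=seed, x0_list=[x0])
    for name in profile:
        profile_ci(residuals, specs, fit, name, n_grid=40)
    fit.extra["params_obj"] = RecruitmentParams(
        k_pm=fit.params["k_pm"], k_ip=fit.params["k_ip"],
        l_pm=fit.params["l_pm"], l_ip=fit.params["l_ip"],
    )
    return fit


def half_time(
    params: RecruitmentParams,
    species: str = "Nup107",
    pool: str = "ip",
    reference: str = "pool_start",
) -> float:
    """Time for a species' accumulation in one pool to reach half its asymptote.

    For Nup107 the accumulation is N1 + N2 = 1 - N0 (single exponential,
    half-time ln2/k from pool start); for Nup358 it is N2 (two-step form,
    solved by bracketed root finding).  ``reference`` selects the zero point:
    ``pool_start`` or ``anaphase_onset``.
    """
    if pool not in ("pm", "ip"):
        raise ValueError("pool must be 'pm' or 'ip'")
    k = params.k_pm if pool == "pm" else params.k_ip
    l = params.l_pm if pool == "pm" else params.l_ip
    t0 = params.t_pm_start if pool == "pm" else params.t_ip_start
    if species == "Nup107":
        if k == 0:
            return math.inf
        t_half = math.log(2.0) / k
    elif species == "Nup358":
        if k == 0 or l == 0:
            return math.inf

        def n2(dt):
            _, _, N2 = pool_fractions(np.array([t0 + dt]), k, l, t0)
            return float(N2[0]) - 0.5

        hi = 10.0
        while n2(hi) < 0 and hi < 1e7:
            hi *= 2.0
        t_half = brentq(n2, 0.0, hi)
    else:
        raise ValueError(f"unknown species {species!r}")
    return t_half if reference == "pool_start" else t_half + t0


def density_normalize(track: IntensityTrack, growth: GrowthParams) -> IntensityTrack:
    """Convert a normalized total-intensity track to a normalized density track.

    The normalized total is divided by the nuclear surface area (scaled by
    the maximal area on the track so the units stay normalized) and the
    result rescaled to peak 1: a constant total on a growing nucleus gives a
    monotonically decreasing density.
    """
    A = area_at(track.times, growth)
    if np.any(A <= 0):
        raise ValueError("surface area must be positive on the track times")
    dens = track.values / A * A.max()
    peak = np.abs(dens).max()
    if peak == 0:
        raise ValueError("track is identically zero")
    return IntensityTrack(
        species=track.species, region=track.region,
        times=track.times.copy(), values=dens / peak,
    )
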