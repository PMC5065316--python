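"""Nuclear surface-area growth during interphase.

The nucleus expands isotropically after anaphase; its surface area follows a
saturating-exponential-plus-linear law

    A(tAO) = a0 + a1 * (1 - exp(-kg1 * tAO)) + kg2 * tAO     [um^2]

with tAO in minutes after anaphase onset: a fast G1 expansion phase (a1, kg1)
on top of the post-anaphase baseline a0 and a slow linear growth kg2 that
continues until the next mitosis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .fitting import FitResult, ParamSpec, multistart_fit, profile_ci

__all__ = ["GrowthParams", "area_at", "fit_growth", "PRINTED_GROWTH"]

log = logging.getLogger("npckinetics.growth")


@dataclass(frozen=True)
class GrowthParams:
    a0: float  # um^2, area at anaphase onset
    a1: float  # um^2, amplitude of the fast G1 expansion
    kg1: float  # per min, rate of the fast expansion
    kg2: float  # um^2/min, slow linear growth

    def __post_init__(self) -> None:
        if self.a0 < 0 or self.a1 < 0 or self.kg2 < 0:
            raise ValueError("a0, a1, kg2 must be non-negative")
        if self.kg1 <= 0:
            raise ValueError("kg1 must be positive")


#: parameters of the fit to the 9-cell averaged surface-area time course
#: (a0 = 424 um^2, a1 = 161 um^2, kg1 = 0.0722/min, kg2 = 0.397 um^2/min)
PRINTED_GROWTH = GrowthParams(a0=424.0, a1=161.0, kg1=0.0722, kg2=0.397)

_SPECS = [
    ParamSpec("a0", 1.0, 2000.0),
    ParamSpec("a1", 1e-2, 2000.0, log_scale=True),
    ParamSpec("kg1", 1e-4, 1.0, log_scale=True),
    ParamSpec("kg2", 1e-6, 10.0, log_scale=True),
]


def area_at(t_ao, p: GrowthParams):
    """Evaluate A(tAO) in um^2; tAO in minutes after anaphase onset (>= 0)."""
    t = np.asarray(t_ao, dtype=float)
    if np.any(t < 0):
        raise ValueError("time after anaphase onset must be non-negative")
    out = p.a0 + p.a1 * (1.0 - np.exp(-p.kg1 * t)) + p.kg2 * t
    return out if out.ndim else float(out)


def fit_growth(
    times_ao,
    areas,
    n_starts: int = 10,
    seed: int = 0,
    max_time_hr: float = 17.0,
    compute_ci: bool = True,
) -> tuple[GrowthParams, FitResult]:
    """Nonlinear least-squares fit of the growth law to an area time series.

    Data beyond ``max_time_hr`` are excluded before fitting (the second
    mitosis distorts late points).  Multi-start optimization over bounded
    log-scaled parameters avoids the kg1/a1 trade-off local minima; 95% CIs
    come from the profile likelihood.
    """
    t = np.asarray(times_ao, dtype=float)
    a = np.asarray(areas, dtype=float)
    keep = t <= max_time_hr * 60.0
    t, a = t[keep], a[keep]
    if t.size < 5:
        raise ValueError("need at least 5 time points within the fit window")
    if np.ptp(a) < 1e-9 * max(abs(a).max(), 1.0):
        warnings.warn(
            "constant area series: growth parameters are not identifiable "
            "(flat likelihood)",
            stacklevel=2,
        )

    def residuals(params):
        p = GrowthParams(**params)
        return area_at(t, p) - a

    x0 = {"a0": float(a[t.argmin()]), "a1": max(float(np.ptp(a)), 1.0) * 0.5,
          "kg1": 0.05, "kg2": max(float(np.ptp(a)) / max(float(np.ptp(t)), 1.0), 1e-4)}
    fit = multistart_fit(residuals, _SPECS, n_starts=n_starts, seed=seed, x0_list=[x0])
    if compute_ci:
        for name in ("a0", "a1", "kg1", "kg2"):
            profile_ci(residuals, _SPECS, fit, name, n_grid=40)
    return GrowthParams(**fit.params), fit
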