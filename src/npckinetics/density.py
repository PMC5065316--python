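"""Surface densities and descriptive statistics from tomogram counts.

Pooling follows a ratio-of-sums convention: counts and areas are summed over
the selection before division, and the across-cell standard deviation of the
per-cell densities is reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .table_io import RegionLabel, TomogramSample

__all__ = [
    "DensityPoint",
    "ShrinkageEstimate",
    "compute_density",
    "pool_density",
    "intermediate_fraction",
    "estimate_shrinkage",
    "apply_shrinkage",
    "EnrichmentTest",
    "gold_enrichment_test",
    "ttest_unpaired",
]


@dataclass(frozen=True)
class DensityPoint:
    """Mature-pore and intermediate surface densities at one time/region."""

    time_ao: float  # min
    region: RegionLabel | None  # None for pooled multi-region selections
    d_mature: float  # pores/um^2
    d_intermediate: float  # intermediates/um^2
    n_cells: int = 1
    sd_mature: float | None = None
    sd_intermediate: float | None = None


@dataclass(frozen=True)
class ShrinkageEstimate:
    """Plastic-section shrinkage fraction relative to cryo reference."""

    fraction: float  # in [0, 1)
    sd: float
    n_sections: int

    def __post_init__(self) -> None:
        if not 0 <= self.fraction < 1:
            raise ValueError("shrinkage fraction must be in [0, 1)")


def compute_density(sample: TomogramSample) -> DensityPoint:
    """Per-tomogram densities: counts divided by analyzed surface area."""
    if sample.area <= 0:
        raise ValueError("area must be positive")
    return DensityPoint(
        time_ao=sample.time_ao,
        region=sample.region,
        d_mature=sample.n_mature / sample.area,
        d_intermediate=sample.n_intermediate / sample.area,
    )


def _select(
    samples: Iterable[TomogramSample],
    regions: Sequence[RegionLabel] | None,
    time_window: tuple[float, float] | None,
) -> list[TomogramSample]:
    out = []
    for s in samples:
        if regions is not None and s.region not in regions:
            continue
        if time_window is not None and not (time_window[0] <= s.time_ao <= time_window[1]):
            continue
        out.append(s)
    return out


def pool_density(
    samples: Iterable[TomogramSample],
    regions: Sequence[RegionLabel] | None = None,
    time_window: tuple[float, float] | None = None,
) -> DensityPoint:
    """Pooled density over a selection of samples.

    Counts and areas are summed before division (ratio of sums).  The s.d. is
    computed across per-cell densities, where each cell's samples in the
    selection (e.g. inner + outer core) are first pooled; it is reported as
    ``None`` when only one cell is selected.
    """
    sel = _select(samples, regions, time_window)
    if not sel:
        raise ValueError("empty selection")
    area = sum(s.area for s in sel)
    d_m = sum(s.n_mature for s in sel) / area
    d_i = sum(s.n_intermediate for s in sel) / area
    by_cell: dict[str, list[TomogramSample]] = {}
    for s in sel:
        by_cell.setdefault(s.cell_id, []).append(s)
    cell_dm = []
    cell_di = []
    for group in by_cell.values():
        a = sum(s.area for s in group)
        cell_dm.append(sum(s.n_mature for s in group) / a)
        cell_di.append(sum(s.n_intermediate for s in group) / a)
    n_cells = len(by_cell)
    sd_m = float(np.std(cell_dm, ddof=1)) if n_cells > 1 else None
    sd_i = float(np.std(cell_di, ddof=1)) if n_cells > 1 else None
    t_mid = float(np.mean([s.time_ao for s in sel]))
    region = sel[0].region if len({s.region for s in sel}) == 1 else None
    return DensityPoint(t_mid, region, d_m, d_i, n_cells, sd_m, sd_i)


def intermediate_fraction(
    samples: Iterable[TomogramSample],
    regions: Sequence[RegionLabel] | None = None,
    time_window: tuple[float, float] | None = (0.0, 60.0),
    per_cell_mean: bool = False,
) -> float:
    """Fraction of assembly intermediates among all pores in a selection.

    Default window is "early G1" (the first hour post anaphase); with the
    bundled table this selects the six cells at 19.2-53.2 min.
    The default is the ratio of summed counts; ``per_cell_mean=True`` instead
    averages per-cell fractions (the two conventions agree to within rounding
    on the bundled table).
    """
    sel = _select(samples, regions, time_window)
    if not sel:
        raise ValueError("empty selection")
    if per_cell_mean:
        by_cell: dict[str, list[TomogramSample]] = {}
        for s in sel:
            by_cell.setdefault(s.cell_id, []).append(s)
        fracs = []
        for group in by_cell.values():
            n_i = sum(s.n_intermediate for s in group)
            n_m = sum(s.n_mature for s in group)
            if n_i + n_m > 0:
                fracs.append(n_i / (n_i + n_m))
        return float(np.mean(fracs))
    n_i = sum(s.n_intermediate for s in sel)
    n_m = sum(s.n_mature for s in sel)
    if n_i + n_m == 0:
        raise ValueError("selection contains no pores")
    return n_i / (n_i + n_m)


def estimate_shrinkage(
    plastic_diameters: Sequence[float], cryo_diameters: Sequence[float]
) -> ShrinkageEstimate:
    """Shrinkage of plastic sections from mature-pore diameters vs cryo.

    fraction = 1 - mean(plastic)/mean(cryo).  The s.d. is propagated from the
    two group standard errors by the delta method.
    """
    p = np.asarray(plastic_diameters, float)
    c = np.asarray(cryo_diameters, float)
    if p.size == 0 or c.size == 0:
        raise ValueError("both diameter lists must be non-empty")
    if np.any(p <= 0) or np.any(c <= 0):
        raise ValueError("diameters must be positive")
    ratio = p.mean() / c.mean()
    se_p = p.std(ddof=1) / math.sqrt(p.size) if p.size > 1 else 0.0
    se_c = c.std(ddof=1) / math.sqrt(c.size) if c.size > 1 else 0.0
    sd = ratio * math.sqrt((se_p / p.mean()) ** 2 + (se_c / c.mean()) ** 2)
    return ShrinkageEstimate(fraction=1.0 - ratio, sd=sd, n_sections=p.size)


def apply_shrinkage(length_nm: float, s: ShrinkageEstimate | float) -> float:
    """Correct a measured length by the shrinkage fraction.

    Lengths divide by (1 - fraction); areas should be corrected by
    (1 - fraction)^2 by applying this twice or squaring the factor.
    """
    frac = s.fraction if isinstance(s, ShrinkageEstimate) else float(s)
    if not 0 <= frac < 1:
        raise ValueError("shrinkage fraction must be in [0, 1)")
    return length_nm / (1.0 - frac)


class EnrichmentTest(NamedTuple):
    """Chi-square enrichment statistic with an optional exact cross-check."""

    chi2: float
    p: float
    p_binomial: float | None = None


def gold_enrichment_test(
    observed_on_intermediates: int,
    expected_on_intermediates: float,
    total_particles: int,
) -> EnrichmentTest:
    """Chi-square goodness of fit for immunogold enrichment on intermediates.

    Tests the observed split (on intermediates vs elsewhere) against the
    split expected under a spatially random particle distribution.  When the
    expected on-intermediate count is <5 (where the chi-square approximation
    is weak) an exact binomial two-sided p-value is also reported as a
    robustness check in ``p_binomial``.
    """
    if expected_on_intermediates <= 0:
        raise ValueError("expected count must be positive")
    if not 0 <= observed_on_intermediates <= total_particles:
        raise ValueError("observed must be between 0 and total")
    f_obs = [observed_on_intermediates, total_particles - observed_on_intermediates]
    f_exp = [expected_on_intermediates, total_particles - expected_on_intermediates]
    chi2, p = stats.chisquare(f_obs, f_exp)
    p_binom = None
    if expected_on_intermediates < 5:
        p_binom = float(
            stats.binomtest(
                observed_on_intermediates,
                total_particles,
                expected_on_intermediates / total_particles,
            ).pvalue
        )
    return EnrichmentTest(float(chi2), float(p), p_binom)


def ttest_unpaired(group_a: Sequence[float], group_b: Sequence[float]):
    """Classic two-sample equal-variance t-test (two-sided).

    Degenerate input (zero pooled variance) returns t = 0, p = 1 when the
    group means are equal.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
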