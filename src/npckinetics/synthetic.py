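"""Synthetic data with the statistical structure the analysis assumes.

Every input the pipeline consumes can be generated here, so all stages are
testable without microscopy data: Poisson tomogram counts from a ground-truth
maturation model on a growing nuclear surface, two-step recruitment intensity
curves with Gaussian noise, circular-arc dome profiles with clicked-point
jitter, punctate two-channel line scans, and noisy surface-area growth
series.  One RNG stream per generator, fully deterministic per seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .growth import GrowthParams, PRINTED_GROWTH, area_at
from .maturation import MaturationParams, simulate
from .recruitment import DEFAULT_F_PM, RecruitmentParams, simulate_recruitment
from .ne_ratio import DEFAULT_PIXEL_NM, LineScanTrack
from .morphometry import ProfileTrace
from .table_io import IntensityTrack, RegionLabel, TomogramSample

__all__ = [
    "CountDesign",
    "GroundTruth",
    "TABLE1_LIKE_DESIGN",
    "DEFAULT_TRUTH",
    "gen_counts",
    "gen_intensity",
    "gen_profiles",
    "gen_linescan",
    "gen_growth_series",
]

log = logging.getLogger("npckinetics.synthetic")


@dataclass(frozen=True)
class CountDesign:
    """Sampling design of a tomogram count experiment."""

    times: tuple = (19.2, 24.4, 28.4, 36.3, 42.0, 53.2, 61.0, 65.6, 73.6, 82.9, 100.0, 116.0)
    regions: tuple = ("inner_core", "outer_core")
    area_range: tuple = (2.5, 7.0)  # um^2 per tomogram set
    tomograms_per_region: int = 1
    fusion_rate: float = 0.005  # events/um^2 (rare)

    def __post_init__(self) -> None:
        if self.area_range[0] <= 0:
            raise ValueError("areas must be positive")


#: the sampling design of the bundled EM count table
TABLE1_LIKE_DESIGN = CountDesign()


@dataclass(frozen=True)
class GroundTruth:
    """Parameters generating a synthetic experiment.

    The maturation defaults are the burst-variant model fitted to the
    bundled count table (kM = 1.357/min, tauM = 43.03 min, kd = 0.00042/min,
    v0 = 0.015/um^2/min, with per-region initial densities at sealing close
    to the fitted values); growth and recruitment defaults are the published
    estimates for the same data.
    """

    maturation: MaturationParams = field(
        default_factory=lambda: MaturationParams(
            variant="burst",
            kM=1.357,
            tauM=43.03,
            kd=0.00042,
            tauS=10.0,
            v0=0.015,
            i0_by_region={"inner_core": 4.5, "outer_core": 3.4},
            m0_by_region={"inner_core": 4.6, "outer_core": 8.8},
        )
    )
    growth: GrowthParams = PRINTED_GROWTH
    recruitment: RecruitmentParams = field(default_factory=RecruitmentParams)
    #: depth (nm) of intermediates at 19/28 min post anaphase and of fusion events
    depth_schedule: dict = field(
        default_factory=lambda: {19.0: 16.0, 28.0: 22.0, "fusion": 28.0}
    )
    #: diameter (nm) at 19/53 min and of fusion events
    diameter_schedule: dict = field(
        default_factory=lambda: {19.0: 51.0, 53.0: 58.0, "fusion": 61.0}
    )
    onm_inm_distance: float = 28.0  # nm
    intensity_noise_sd: float = 0.02  # multiplicative
    profile_jitter_nm: float = 1.0
    area_noise_sd: float = 0.05  # multiplicative, growth series


DEFAULT_TRUTH = GroundTruth()


def gen_counts(
    truth: GroundTruth = DEFAULT_TRUTH,
    design: CountDesign = TABLE1_LIKE_DESIGN,
    seed: int = 0,
) -> list[TomogramSample]:
    """Poisson tomogram counts from the ground-truth maturation model.

    Per tomogram set, n_mature ~ Poisson(m(t) * area) and
    n_intermediate ~ Poisson(iT(t) * area) independently; fusion counts are
    Poisson with a rare area-proportional rate.  Areas are drawn uniformly
    from the design's range.
    """
    rng = np.random.default_rng(seed)
    p = truth.maturation
    t_model = np.array(design.times) - p.tauS
    if np.any(t_model < 0):
        raise ValueError("design times must lie after sealing")
    samples = []
    for region in design.regions:
        sim = simulate(p, truth.growth, t_model, region=region)
        for j, t_ao in enumerate(design.times):
            for rep in range(design.tomograms_per_region):
                area = rng.uniform(*design.area_range)
                samples.append(
                    TomogramSample(
                        cell_id=f"s{j:02d}" if design.tomograms_per_region == 1
                        else f"s{j:02d}r{rep}",
                        time_ao=t_ao,
                        region=RegionLabel(region),
                        area=area,
                        n_mature=int(rng.poisson(sim.m[j] * area)),
                        n_intermediate=int(rng.poisson(sim.iT[j] * area)),
                        n_fusion=int(rng.poisson(design.fusion_rate * area)),
                    )
                )
    return samples


def gen_intensity(
    truth: GroundTruth = DEFAULT_TRUTH,
    regions=(RegionLabel.NON_CORE, RegionLabel.INNER_CORE),
    noise_sd: float | None = None,
    seed: int = 0,
    t_grid=None,
) -> list[IntensityTrack]:
    """Sequential-model intensity tracks with multiplicative Gaussian noise.

    tracks = model * (1 + eps), eps ~ N(0, noise_sd), for Nup107 and Nup358
    in each requested region, mixing pools with the region's f_pm.
    """
    rng = np.random.default_rng(seed)
    noise_sd = truth.intensity_noise_sd if noise_sd is None else noise_sd
    t = np.arange(4.0, 126.0, 1.0) if t_grid is None else np.asarray(t_grid, float)
    tracks = []
    for region in regions:
        p = replace(truth.recruitment, f_pm=DEFAULT_F_PM[region])
        state = simulate_recruitment(p, t)
        for species, curve in (("Nup107", state.T_Nup107), ("Nup358", state.T_Nup358)):
            values = curve * (1.0 + rng.normal(0.0, noise_sd, size=t.size))
            tracks.append(IntensityTrack(species, region, t.copy(), values))
    return tracks


def _dome_arc(depth: float, diameter: float, n_arc: int) -> np.ndarray:
    """Circular-arc cap of the given chord diameter and apex height."""
    r = diameter / 2.0
    R = (r * r + depth * depth) / (2.0 * depth)  # circumradius
    yc = depth - R  # center below baseline
    theta_max = np.arcsin(r / R) if depth <= R else np.pi - np.arcsin(r / R)
    th = np.linspace(-theta_max, theta_max, n_arc)
    return np.c_[R * np.sin(th), R * np.cos(th) + yc]


def gen_profiles(
    depth: float,
    diameter: float,
    n_points: int = 21,
    jitter_nm: float = 1.0,
    seed: int = 0,
    onm_separation: float = 28.0,
    flank_nm: float = 50.0,
    event_id: str = "synthetic",
) -> tuple[ProfileTrace, ProfileTrace]:
    """One synthetic INM dome (circular-arc cap on a flat baseline) plus a
    flat ONM at the stated separation, sampled as sparse clicked-like points
    with isotropic Gaussian jitter.  Requires depth < diameter.
    """
    if not 0 < depth < diameter:
        raise ValueError("need 0 < depth < diameter")
    rng = np.random.default_rng(seed)
    half = diameter / 2.0 + flank_nm
    n_flank = max(n_points // 4, 3)
    n_arc = max(n_points - 2 * n_flank, 5)
    left = np.c_[np.linspace(-half, -diameter / 2.0, n_flank, endpoint=False),
                 np.zeros(n_flank)]
    right = np.c_[np.linspace(diameter / 2.0, half, n_flank + 1)[1:],
                  np.zeros(n_flank)]
    arc = _dome_arc(depth, diameter, n_arc)
    inm_pts = np.vstack([left, arc, right])
    inm_pts = inm_pts + rng.normal(0.0, jitter_nm, size=inm_pts.shape)
    onm_x = np.linspace(-half, half, n_points)
    onm_pts = np.c_[onm_x, np.full(n_points, onm_separation)]
    onm_pts = onm_pts + rng.normal(0.0, jitter_nm, size=onm_pts.shape)
    inm = ProfileTrace("INM", inm_pts, event_id=event_id, event_type="intermediate")
    onm = ProfileTrace("ONM", onm_pts, event_id=event_id, event_type="intermediate")
    return inm, onm


def gen_linescan(
    pore_density_per_um: float = 6.0,
    fraction_intermediate: float = 0.08,
    gains: tuple[float, float] = (1.0, 1.0),
    seed: int = 0,
    length_um: float = 15.0,
    pixel_nm: float = DEFAULT_PIXEL_NM,
    psf_sigma_nm: float = 60.0,
    noise_sd: float = 0.02,
    region: RegionLabel = RegionLabel.NON_CORE,
    cell_id: str = "synthetic",
) -> LineScanTrack:
    """Punctate two-channel NE line scan at 20 nm/pixel.

    Pores are a 1-D Poisson process; each punctum is a Gaussian spot of the
    microscope's effective PSF width in both channels, except assembly
    intermediates (a Bernoulli fraction) which are dark in the Nup358
    channel.  Channel-specific gains emulate detection differences.
    """
    if pore_density_per_um < 0 or not 0 <= fraction_intermediate <= 1:
        raise ValueError("invalid density or fraction")
    rng = np.random.default_rng(seed)
    length_nm = length_um * 1e3
    pos = np.arange(0.0, length_nm, pixel_nm)
    n_pores = rng.poisson(pore_density_per_um * length_um)
    centers = rng.uniform(0.0, length_nm, size=n_pores)
    is_intermediate = rng.random(n_pores) < fraction_intermediate
    amp = rng.lognormal(0.0, 0.2, size=n_pores)
    ch1 = np.zeros_like(pos)
    ch2 = np.zeros_like(pos)
    for c, inter, a in zip(centers, is_intermediate, amp):
        spot = a * np.exp(-0.5 * ((pos - c) / psf_sigma_nm) ** 2)
        ch1 += spot
        if not inter:
            ch2 += spot
    ch1 = gains[0] * ch1 + rng.normal(0.0, noise_sd, size=pos.size)
    ch2 = gains[1] * ch2 + rng.normal(0.0, noise_sd, size=pos.size)
    return LineScanTrack(
        positions=pos,
        ch_nup107=np.clip(ch1, 0.0, None),
        ch_nup358=np.clip(ch2, 0.0, None),
        region=region,
        cell_id=cell_id,
    )


def gen_growth_series(
    growth: GrowthParams = PRINTED_GROWTH,
    noise_sd: float = 0.05,
    seed: int = 0,
    t_max_hr: float = 17.0,
    dt_min: float = 10.0,
):
    """Noisy nuclear surface-area time series (multiplicative noise), on the
    live-imaging acquisition grid (every 10 min out to 17 hr)."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max_hr * 60.0 + dt_min / 2, dt_min)
    a = area_at(t, growth) * (1.0 + rng.normal(0.0, noise_sd, size=t.size))
    return t, a
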