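"""Two-channel NE line-scan segment analysis (STED-style).

Flattened nuclear-envelope line scans carry a Nup107 and a Nup358 channel at
20 nm/pixel.  Intensities are summed in 15-pixel (300 nm) segments, the
Nup358 channel is rescaled so the typical (median) Nup107/Nup358 ratio in
non-core reference segments - which contain almost only mature, double-
labelled pores - equals 1, and the frequency of segments whose ratio exceeds
2.0 estimates the local fraction of assembly intermediates (Nup107-positive,
Nup358-free).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .table_io import RegionLabel

__all__ = [
    "LineScanTrack",
    "bin_segments",
    "normalize_channels",
    "high_ratio_frequency",
    "DEFAULT_PIXEL_NM",
    "DEFAULT_BIN_PX",
]

log = logging.getLogger("npckinetics.ne_ratio")

DEFAULT_PIXEL_NM = 20.0
DEFAULT_BIN_PX = 15  # 300 nm segments


@dataclass
class LineScanTrack:
    """One flattened NE line scan: two channels on a regular position grid."""

    positions: np.ndarray  # nm along the NE, strictly increasing, regular
    ch_nup107: np.ndarray
    ch_nup358: np.ndarray
    region: RegionLabel = RegionLabel.NON_CORE
    cell_id: str = ""
    time_ao: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.ch_nup107 = np.asarray(self.ch_nup107, float)
        self.ch_nup358 = np.asarray(self.ch_nup358, float)
        d = np.diff(self.positions)
        if self.positions.ndim != 1 or np.any(d <= 0):
            raise ValueError("positions must be 1-D and strictly increasing")
        if d.size and not np.allclose(d, d[0], rtol=1e-6):
            raise ValueError("positions must be regularly spaced")
        if not (self.positions.size == self.ch_nup107.size == self.ch_nup358.size):
            raise ValueError("channels must match positions in length")


def bin_segments(
    track: LineScanTrack,
    bin_px: int = DEFAULT_BIN_PX,
    background: str = "none",
) -> pd.DataFrame:
    """Per-segment summed intensities; the trailing partial bin is dropped.

    ``background="percentile"`` subtracts the 5th percentile of each channel
    over the whole track before summation (default off; clipped at zero).
    Returns a DataFrame with columns segment, position_nm, nup107, nup358,
    region, cell_id.
    """
    n = track.positions.size
    if n < bin_px:
        raise ValueError("track shorter than one segment")
    c1, c2 = track.ch_nup107, track.ch_nup358
    if background == "percentile":
        c1 = np.clip(c1 - np.percentile(c1, 5), 0, None)
        c2 = np.clip(c2 - np.percentile(c2, 5), 0, None)
    elif background != "none":
        raise ValueError(f"unknown background mode {background!r}")
    n_seg = n // bin_px
    used = n_seg * bin_px
    seg1 = c1[:used].reshape(n_seg, bin_px).sum(axis=1)
    seg2 = c2[:used].reshape(n_seg, bin_px).sum(axis=1)
    pos = track.positions[:used].reshape(n_seg, bin_px).mean(axis=1)
    return pd.DataFrame(
        {
            "segment": np.arange(n_seg),
            "position_nm": pos,
            "nup107": seg1,
            "nup358": seg2,
            "region": track.region.value,
            "cell_id": track.cell_id,
        }
    )


def normalize_channels(
    segments: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    statistic: str = "median",
) -> pd.DataFrame:
    """Equalize the two channels using non-core reference segments.

    The Nup358 channel is multiplied by the reference's typical
    nup107/nup358 ratio so that ratio becomes 1 in the reference (median by
    default; ``statistic="mean"`` supported).  ``reference`` defaults to the
    non-core rows of ``segments``.
    """
    if reference is None:
        reference = segments[segments["region"] == RegionLabel.NON_CORE.value]
    if len(reference) == 0:
        raise ValueError("empty non-core reference")
    ratios = reference["nup107"].to_numpy() / np.where(
        reference["nup358"].to_numpy() > 0, reference["nup358"].to_numpy(), np.nan
    )
    scale = np.nanmedian(ratios) if statistic == "median" else np.nanmean(ratios)
    if not np.isfinite(scale) or scale == 0:
        raise ValueError("reference ratio is zero or undefined")
    out = segments.copy()
    out["nup358"] = out["nup358"] * scale
    out["ratio"] = out["nup107"] / out["nup358"].replace(0, np.nan)
    return out


def high_ratio_frequency(segments: pd.DataFrame, threshold: float = 2.0) -> float:
    """Fraction of segments with Nup107/Nup358 ratio strictly above threshold.

    Segments with zero Nup358 count as high-ratio (with a warning); requires
    normalized segments (a ``ratio`` column, or nup107/nup358 present).
    """
    if len(segments) == 0:
        raise ValueError("no segments")
    n107 = segments["nup107"].to_numpy(float)
    n358 = segments["nup358"].to_numpy(float)
    zero = n358 == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} segment(s) with zero Nup358 counted as high-ratio",
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        ratio = np.where(zero, np.inf, n107 / np.where(zero, 1.0, n358))
    return float(np.mean(ratio > threshold))
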