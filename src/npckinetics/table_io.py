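"""Tabular I/O for tomogram counts, intensity tracks and membrane profiles.

All tables are tab-separated UTF-8 with a fixed header; lines starting with
``#`` are comments.  Times are minutes after anaphase onset (tAO) throughout;
the kinetic model's internal clock t = tAO - tau_S is computed downstream and
never stored.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionLabel",
    "TomogramSample",
    "IntensityTrack",
    "SchemaError",
    "ValidationError",
    "read_counts",
    "write_counts",
    "load_table1_fixture",
    "read_intensity_tracks",
    "write_intensity_tracks",
    "read_profiles",
    "write_profiles",
]


class SchemaError(ValueError):
    """A table is missing required columns."""


class ValidationError(ValueError):
    """A table row violates a type invariant."""


class RegionLabel(str, enum.Enum):
    """Nuclear-envelope region of a measurement.

    ``non_core`` is the NE populated by postmitotic assembly; ``inner_core``
    and ``outer_core`` are the NPC-poor islands over the anaphase chromatin
    core (facing the spindle midzone and poles, respectively); ``mature_ne``
    marks fully grown nuclei (>180 min post anaphase) where core and non-core
    can no longer be distinguished.
    """

    NON_CORE = "non_core"
    INNER_CORE = "inner_core"
    OUTER_CORE = "outer_core"
    MATURE_NE = "mature_ne"


#: regions entering the interphase-assembly kinetic fits
CORE_REGIONS = (RegionLabel.INNER_CORE, RegionLabel.OUTER_CORE)

_COUNT_COLUMNS = [
    "cell_id",
    "time_ao",
    "region",
    "area_um2",
    "n_mature",
    "n_intermediate",
    "n_fusion",
]


@dataclass(frozen=True)
class TomogramSample:
    """Counts and analyzed surface area of one tomogram set (cell x region)."""

    cell_id: str
    time_ao: float  # min after anaphase onset
    region: RegionLabel
    area: float  # um^2, shrinkage-corrected
    n_mature: int
    n_intermediate: int
    n_fusion: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.time_ao) or self.time_ao <= 0:
            raise ValidationError(f"{self.cell_id}: time_ao must be finite and >0")
        if not self.area > 0:
            raise ValidationError(f"{self.cell_id}: area must be >0, got {self.area}")
        for name in ("n_mature", "n_intermediate", "n_fusion"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(
                    f"{self.cell_id}: {name} must be a non-negative integer, got {v}"
                )
        if self.region is RegionLabel.MATURE_NE and self.time_ao <= 180:
            raise ValidationError(
                f"{self.cell_id}: mature_ne label requires time_ao > 180 min"
            )


@dataclass
class IntensityTrack:
    """Normalized total-intensity time course of one nucleoporin in one region.

    ``values`` are unitless total intensities normalized so the plateau is
    close to 1; ``sd`` is the optional across-cell standard deviation.
    """

    species: str  # "Nup107" or "Nup358"
    region: RegionLabel
    times: np.ndarray  # min after anaphase onset, strictly increasing
    values: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.species not in ("Nup107", "Nup358"):
            raise ValidationError(f"unknown species {self.species!r}")
        if self.times.ndim != 1 or self.times.size != self.values.size:
            raise ValidationError("times and values must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("intensity values must be finite")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.size != self.times.size:
                raise ValidationError("sd must match times in length")


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def read_counts(path: str | Path) -> list[TomogramSample]:
    """Read a tomogram count table, validating every row.

    Returns samples sorted by (time_ao, region).
    """
    df = _read_tsv(path, _COUNT_COLUMNS)
    samples = []
    for idx, row in df.iterrows():
        try:
            samples.append(
                TomogramSample(
                    cell_id=str(row["cell_id"]),
                    time_ao=float(row["time_ao"]),
                    region=RegionLabel(row["region"]),
                    area=float(row["area_um2"]),
                    n_mature=int(row["n_mature"]),
                    n_intermediate=int(row["n_intermediate"]),
                    n_fusion=int(row["n_fusion"]),
                )
            )
        except ValueError as err:
            raise ValidationError(f"{path}, row {idx}: {err}") from err
    order = {r: i for i, r in enumerate(RegionLabel)}
    samples.sort(key=lambda s: (s.time_ao, order[s.region]))
    return samples


def write_counts(samples: Iterable[TomogramSample], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "cell_id": s.cell_id,
                "time_ao": s.time_ao,
                "region": s.region.value,
                "area_um2": s.area,
                "n_mature": s.n_mature,
                "n_intermediate": s.n_intermediate,
                "n_fusion": s.n_fusion,
            }
            for s in samples
        ],
        columns=_COUNT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def load_table1_fixture() -> list[TomogramSample]:
    """Load the bundled EM-tomography count table (38 samples, 14 cells).

    Row/column sums satisfy the published caption totals: 153.66 um^2 analyzed
    area (printed as 154), 1322 mature pores, 279 intermediates, 5 ONM/INM
    fusion events.  See the fixture header for transcription notes.
    """
    ref = importlib.resources.files("npckinetics.data") / "table1_counts.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_counts(path)


_INTENSITY_COLUMNS = ["species", "region", "time_ao", "value"]


def read_intensity_tracks(path: str | Path) -> list[IntensityTrack]:
    """Read normalized intensity time courses; one track per (species, region)."""
    df = _read_tsv(path, _INTENSITY_COLUMNS)
    has_sd = "sd" in df.columns
    tracks = []
    for (species, region), grp in df.groupby(["species", "region"], sort=True):
        grp = grp.sort_values("time_ao")
        tracks.append(
            IntensityTrack(
                species=str(species),
                region=RegionLabel(region),
                times=grp["time_ao"].to_numpy(float),
                values=grp["value"].to_numpy(float),
                sd=grp["sd"].to_numpy(float) if has_sd else None,
            )
        )
    return tracks


def write_intensity_tracks(tracks: Iterable[IntensityTrack], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        for i, t in enumerate(tr.times):
            row = {
                "species": tr.species,
                "region": tr.region.value,
                "time_ao": t,
                "value": tr.values[i],
            }
            if tr.sd is not None:
                row["sd"] = tr.sd[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_PROFILE_COLUMNS = ["event_id", "structure", "point_index", "x_nm", "y_nm"]


def read_profiles(path: str | Path):
    """Read membrane-profile point traces.

    Returns a dict mapping (event_id, structure) -> (n, 2) float array of
    ordered points in nm.  Construction of :class:`morphometry.ProfileTrace`
    objects (which carry event metadata) is left to the caller.
    """
    df = _read_tsv(path, _PROFILE_COLUMNS)
    out = {}
    for (event_id, structure), grp in df.groupby(["event_id", "structure"], sort=True):
        grp = grp.sort_values("point_index")
        out[(str(event_id), str(structure))] = grp[["x_nm", "y_nm"]].to_numpy(float)
    return out


def write_profiles(profiles: dict, path: str | Path) -> None:
    """Write a dict as produced by :func:`read_profiles`."""
    rows = []
    for (event_id, structure), pts in sorted(profiles.items()):
        for i, (x, y) in enumerate(np.asarray(pts, dtype=float)):
            rows.append(
                {
                    "event_id": event_id,
                    "structure": structure,
                    "point_index": i,
                    "x_nm": x,
                    "y_nm": y,
                }
            )
    pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)
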