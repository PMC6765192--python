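"""Readers and writers for trajectories, well geometry, traces, image stacks and feature tables.

Trajectories live in well-centred millimetre coordinates with *y* increasing
upward; tracker exports in top-left pixel coordinates are converted on read via
the column mapping / unit scale in :class:`TrajectoryFormat`.  Image stacks are
plain multi-channel TIFFs with physical voxel size attached (µm, z/y/x order).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "TreatmentGroup",
    "WellGeometry",
    "Trajectory",
    "ZoneFeatures",
    "FeatureSet",
    "LarvaFeatureRecord",
    "ImageStack",
    "TrajectoryFormat",
    "read_trajectory",
    "write_trajectory",
    "write_features",
    "read_features",
    "read_stack",
    "write_stack",
    "load_well_config",
]

#: µm per voxel along (z, y, x) for the lightsheet acquisition used throughout
#: (0.6 µm pixels in x-y, 1 µm slice spacing).
DEFAULT_VOXEL_SIZE = (1.0, 0.6, 0.6)

OSMOLYTES = ("mannitol", "glucose")


@dataclass(frozen=True)
class TreatmentGroup:
    """One cell of the 2x2 design: osmolyte (20 mM mannitol or glucose) x SNP (0.1 mM)."""

    osmolyte: str
    snp: bool

    def __post_init__(self) -> None:
        if self.osmolyte not in OSMOLYTES:
            raise ValueError(f"osmolyte must be one of {OSMOLYTES}, got {self.osmolyte!r}")

    @property
    def label(self) -> str:
        return f"{self.osmolyte}+SNP" if self.snp else self.osmolyte

    @classmethod
    def from_label(cls, label: str) -> "TreatmentGroup":
        osmolyte, _, suffix = label.partition("+")
        return cls(osmolyte=osmolyte, snp=suffix.upper() == "SNP")


@dataclass(frozen=True)
class WellGeometry:
    """Circular well with a diameter divider separating light and dark halves.

    ``divider_normal`` is the unit normal of the divider line through the well
    centre; it points into the dark half, so a point p is dark iff
    ``(p - centre) . divider_normal > 0`` (points exactly on the divider count
    as light).
    """

    centre: tuple[float, float] = (0.0, 0.0)
    radius: float = 11.0  # mm; 12-well plate well
    divider_normal: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("well radius must be positive")
        norm = math.hypot(*self.divider_normal)
        if not math.isclose(norm, 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("divider_normal must have unit length")

    def signed_dark_distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Signed distance to the divider, positive on the dark side (mm)."""
        nx, ny = self.divider_normal
        return (np.asarray(x) - self.centre[0]) * nx + (np.asarray(y) - self.centre[1]) * ny


@dataclass
class Trajectory:
    """Timestamped 2-D positions of one larva in one well (seconds / mm)."""

    larva_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    group: TreatmentGroup | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise ValueError("a trajectory needs at least 2 points")
        bad = np.nonzero(np.diff(self.t) <= 0)[0]
        if bad.size:
            raise ValueError(f"non-increasing time at row {bad[0] + 2}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class ZoneFeatures:
    """Per-zone behavioural endpoints for one larva (percentages are of zone time)."""

    pct_inactive: float
    pct_low: float
    pct_high: float
    mean_eccentricity: float | None = None
    mean_mpde: float | None = None
    mean_mpdc: float | None = None
    n_segments_kept: int = 0
    n_segments_removed: int = 0


@dataclass
class FeatureSet:
    """Whole-recording (or one time block's) endpoints: light preference, transitions, zones."""

    pct_time_light: float
    transitions: int
    zones: dict[str, ZoneFeatures | None] = field(default_factory=dict)


@dataclass
class LarvaFeatureRecord:
    larva_id: str
    group: TreatmentGroup
    overall: FeatureSet
    blocks: dict[str, FeatureSet] = field(default_factory=dict)


@dataclass
class ImageStack:
    """Named multi-channel 3-D voxel array with physical voxel size (µm, z/y/x)."""

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape


@dataclass(frozen=True)
class TrajectoryFormat:
    """Column mapping and unit conversion for delimited tracker exports."""

    time_col: str = "time"
    x_col: str = "x"
    y_col: str = "y"
    larva_col: str | None = None
    #: multiply raw coordinates by this to obtain mm (e.g. mm per pixel)
    coord_scale: float = 1.0
    #: multiply raw time stamps by this to obtain seconds
    time_scale: float = 1.0
    #: raw-coordinate origin, subtracted before scaling (top-left pixel origin)
    origin: tuple[float, float] = (0.0, 0.0)
    #: flip y after scaling (pixel rows grow downward)
    flip_y: bool = False


def read_trajectory(
    path: str | Path,
    well: WellGeometry,
    fmt: TrajectoryFormat = TrajectoryFormat(),
    larva_id: str | None = None,
    group: TreatmentGroup | None = None,
    tolerance: float = 0.5,
) -> Trajectory:
    """Read one larva's trajectory from a delimited text table.

    Raw coordinates are converted to well-centred mm via ``fmt``; every point
    must lie within ``well.radius + tolerance`` mm of the well centre.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in (fmt.time_col, fmt.x_col, fmt.y_col) if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path}: {missing}")
    if fmt.larva_col is not None and fmt.larva_col in df.columns:
        ids = df[fmt.larva_col].unique()
        if larva_id is None:
            if len(ids) > 1:
                raise ValueError(f"multiple larvae in {path}; pass larva_id")
            larva_id = str(ids[0])
        df = df[df[fmt.larva_col].astype(str) == str(larva_id)]
    t = df[fmt.time_col].to_numpy(dtype=float) * fmt.time_scale
    x = (df[fmt.x_col].to_numpy(dtype=float) - fmt.origin[0]) * fmt.coord_scale
    y = (df[fmt.y_col].to_numpy(dtype=float) - fmt.origin[1]) * fmt.coord_scale
    if fmt.flip_y:
        y = -y
    traj = Trajectory(
        larva_id=larva_id or Path(path).stem, t=t, x=x, y=y, group=group
    )
    r = np.hypot(traj.x - well.centre[0], traj.y - well.centre[1])
    outside = np.nonzero(r > well.radius + tolerance)[0]
    if outside.size:
        raise ValueError(
            f"point beyond well radius at row {outside[0] + 2} "
            f"(r={r[outside[0]]:.3f} mm > {well.radius + tolerance:.3f} mm)"
        )
    return traj


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as a CSV in mm/seconds (inverse of :func:`read_trajectory`)."""
    path = Path(path)
    df = pd.DataFrame({"time": traj.t, "x": traj.x, "y": traj.y})
    df.to_csv(path, index=False, float_format="%.17g")
    return path


# --- feature tables --------------------------------------------------------

_ZONE_COLS = [
    "pct_inactive",
    "pct_low",
    "pct_high",
    "mean_eccentricity",
    "mean_mpde",
    "mean_mpdc",
    "n_segments_kept",
    "n_segments_removed",
]


def _feature_rows(rec: LarvaFeatureRecord, block: str, fs: FeatureSet) -> list[dict]:
    rows = []
    for zone in ("light", "dark"):
        zf = fs.zones.get(zone)
        row: dict = {
            "larva_id": rec.larva_id,
            "osmolyte": rec.group.osmolyte,
            "snp": rec.group.snp,
            "group": rec.group.label,
            "block": block,
            "zone": zone,
            "pct_time_light": fs.pct_time_light,
            "transitions": fs.transitions,
        }
        for col in _ZONE_COLS:
            row[col] = getattr(zf, col) if zf is not None else None
        rows.append(row)
    return rows


def write_features(records: Sequence[LarvaFeatureRecord], path: str | Path) -> Path:
    """Write per-larva endpoints as a tidy CSV: one row per larva x zone (x block)."""
    if not records:
        raise ValueError("no records to write")
    rows: list[dict] = []
    for rec in records:
        rows.extend(_feature_rows(rec, "all", rec.overall))
        for block, fs in rec.blocks.items():
            rows.extend(_feature_rows(rec, block, fs))
    df = pd.DataFrame(rows)
    df.to_csv(Path(path), index=False, float_format="%.17g")
    return Path(path)


def read_features(path: str | Path) -> list[LarvaFeatureRecord]:
    """Parse a feature CSV written by :func:`write_features` back into records."""
    df = pd.read_csv(path, float_precision="round_trip")
    records: list[LarvaFeatureRecord] = []
    for (larva_id, group_label), sub in df.groupby(["larva_id", "group"], sort=False):
        group = TreatmentGroup.from_label(group_label)
        overall: FeatureSet | None = None
        blocks: dict[str, FeatureSet] = {}
        for block, bsub in sub.groupby("block", sort=False):
            zones: dict[str, ZoneFeatures | None] = {}
            for _, row in bsub.iterrows():
                if pd.isna(row["pct_inactive"]):
                    zones[row["zone"]] = None
                else:
                    zones[row["zone"]] = ZoneFeatures(
                        pct_inactive=float(row["pct_inactive"]),
                        pct_low=float(row["pct_low"]),
                        pct_high=float(row["pct_high"]),
                        mean_eccentricity=None
                        if pd.isna(row["mean_eccentricity"])
                        else float(row["mean_eccentricity"]),
                        mean_mpde=None if pd.isna(row["mean_mpde"]) else float(row["mean_mpde"]),
                        mean_mpdc=None if pd.isna(row["mean_mpdc"]) else float(row["mean_mpdc"]),
                        n_segments_kept=int(row["n_segments_kept"]),
                        n_segments_removed=int(row["n_segments_removed"]),
                    )
            fs = FeatureSet(
                pct_time_light=float(bsub["pct_time_light"].iloc[0]),
                transitions=int(bsub["transitions"].iloc[0]),
                zones=zones,
            )
            if block == "all":
                overall = fs
            else:
                blocks[str(block)] = fs
        if overall is None:
            raise ValueError(f"no 'all' block for larva {larva_id}")
        records.append(
            LarvaFeatureRecord(larva_id=str(larva_id), group=group, overall=overall, blocks=blocks)
        )
    return records


# --- image stacks ----------------------------------------------------------


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an :class:`ImageStack` as a (C, Z, Y, X) TIFF with a JSON description tag."""
    path = Path(path)
    data = np.stack(list(stack.channels.values()), axis=0)
    meta = {
        "channel_names": list(stack.channels.keys()),
        "voxel_size_um_zyx": list(stack.voxel_size),
    }
    tifffile.imwrite(path, data, description=json.dumps(meta), photometric="minisblack")
    return path


def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a TIFF stack; voxel size comes from the embedded metadata or ``voxel_size``.

    Accepts (C, Z, Y, X) or single-channel (Z, Y, X) arrays.  Stacks written by
    :func:`write_stack` round-trip exactly, including channel names.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    meta: dict = {}
    if desc:
        try:
            parsed = json.loads(desc)
            if isinstance(parsed, dict):
                meta = parsed
        except (json.JSONDecodeError, TypeError):
            pass
    if voxel_size is None:
        if "voxel_size_um_zyx" in meta:
            voxel_size = tuple(float(v) for v in meta["voxel_size_um_zyx"])
        else:
            voxel_size = DEFAULT_VOXEL_SIZE
    if data.ndim == 3:
        data = data[None]
    if data.ndim != 4:
        raise ValueError(f"expected a 3-D or 4-D TIFF, got shape {data.shape}")
    if channel_names is None:
        channel_names = meta.get(
            "channel_names", [f"ch{i}" for i in range(data.shape[0])]
        )
    if len(channel_names) != data.shape[0]:
        raise ValueError("channel_names length does not match channel axis")
    return ImageStack(
        channels={name: data[i] for i, name in enumerate(channel_names)},
        voxel_size=tuple(voxel_size),
    )


# --- configuration ---------------------------------------------------------


def load_well_config(path: str | Path) -> dict:
    """Load a YAML analysis config (well geometry, format, thresholds).

    Returns a dict with keys ``well`` (:class:`WellGeometry`), ``fmt``
    (:class:`TrajectoryFormat`) and any remaining scalar settings.  The tracker
    frame rate, when needed, must be stated in the file; there is no default.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    wellspec = raw.pop("well", {})
    angle = wellspec.pop("divider_angle_deg", None)
    if angle is not None:
        a = math.radians(float(angle))
        wellspec["divider_normal"] = (math.cos(a), math.sin(a))
    if "centre" in wellspec:
        wellspec["centre"] = tuple(float(v) for v in wellspec["centre"])
    if "divider_normal" in wellspec:
        wellspec["divider_normal"] = tuple(float(v) for v in wellspec["divider_normal"])
    well = WellGeometry(**wellspec)
    fmtspec = raw.pop("format", {})
    if "origin" in fmtspec:
        fmtspec["origin"] = tuple(float(v) for v in fmtspec["origin"])
    fmt = TrajectoryFormat(**fmtspec)
    return {"well": well, "fmt": fmt, **raw}
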