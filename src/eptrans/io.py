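"""Readers and writers for the pipeline's CSV/TIFF/YAML dialects.

Units are mandatory metadata in every file: the long-format series CSV
carries ``time_unit`` and ``reading_unit`` columns, TEER CSVs name their
units in the column headers (``time_day``, ``resistance_ohm``,
``baseline_ohm``, ``area_cm2``), protocol and geometry YAML keys embed
units (``channel_volume_ul``, ``width_mm``, ...). Readers reject rather
than silently coerce; malformed rows are reported with their line
numbers. Assay time is converted to minutes at this boundary.

Z-stacks travel as multi-page TIFF with planes ordered z-major,
channel-minor, plus a sidecar YAML naming the channels and stating the
pitch and apical direction.

Every CLI run writes a YAML manifest (tool version, subcommand, full
parameter set, SHA-256 input checksums, seeds, timestamp) next to its
outputs so any output file can be traced to the invocation that produced
it.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .errors import ValidationError
from .types import (
    ChannelGeometry,
    SamplingProtocol,
    SampleSeries,
    TEERTrace,
    ZStack,
)

__all__ = [
    "SERIES_COLUMNS",
    "read_series_csv",
    "write_series_csv",
    "read_calibration_csv",
    "read_teer_csv",
    "read_protocol_yaml",
    "read_geometry_yaml",
    "write_zstack_tiff",
    "read_zstack_tiff",
    "read_morphometry_csv",
    "RunManifest",
    "write_manifest",
]

SERIES_COLUMNS = (
    "chip_id",
    "condition",
    "substrate",
    "direction",
    "time",
    "time_unit",
    "reading",
    "reading_unit",
)

_MINUTES_PER = {"s": 1 / 60.0, "sec": 1 / 60.0, "min": 1.0, "h": 60.0, "hour": 60.0}


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def read_series_csv(path, to_minutes: bool = True) -> List[SampleSeries]:
    """Read a long-format assay CSV into validated series.

    Rows are grouped by chip × condition × substrate × direction; times
    are converted to minutes when ``to_minutes`` (the internal assay-time
    convention). Non-monotone times or undeclared units are rejected with
    the offending chip and line numbers named.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, SERIES_COLUMNS, path)
    bad_unit = df[~df["time_unit"].isin(_MINUTES_PER)]
    if not bad_unit.empty:
        lines = (bad_unit.index + 2).tolist()
        raise ValidationError(
            f"{path}: undeclared/unknown time_unit at line(s) {lines[:5]}"
        )
    if df["reading"].isna().any():
        lines = (df.index[df["reading"].isna()] + 2).tolist()
        raise ValidationError(f"{path}: missing reading at line(s) {lines[:5]}")
    series: List[SampleSeries] = []
    keys = ["chip_id", "condition", "substrate", "direction"]
    for (chip, condition, substrate, direction), grp in df.groupby(
        keys, sort=False
    ):
        units = grp["reading_unit"].unique()
        if len(units) != 1:
            raise ValidationError(
                f"{path}: chip {chip!r} mixes reading units {list(units)}"
            )
        t = grp["time"].to_numpy(dtype=float)
        if to_minutes:
            t = t * grp["time_unit"].map(_MINUTES_PER).to_numpy(dtype=float)
        order_ok = np.all(np.diff(t) > 0) if t.size > 1 else True
        if not order_ok:
            raise ValidationError(
                f"{path}: non-monotone times for chip {chip!r} "
                f"(lines {(grp.index + 2).tolist()})"
            )
        series.append(
            SampleSeries(
                times=t,
                readings=grp["reading"].to_numpy(dtype=float),
                substrate=str(substrate),
                condition=str(condition),
                chip_id=str(chip),
                direction=str(direction),
                time_unit="min" if to_minutes else str(grp["time_unit"].iloc[0]),
                reading_unit=str(units[0]),
            )
        )
    if not series:
        raise ValidationError(f"{path}: no data rows")
    return series


def write_series_csv(path, series: Sequence[SampleSeries]) -> None:
    """Write series back to the long-format dialect (round-trip safe)."""
    rows = []
    for s in series:
        for t, r in zip(s.times, s.readings):
            rows.append(
                {
                    "chip_id": s.chip_id,
                    "condition": s.condition,
                    "substrate": s.substrate,
                    "direction": s.direction,
                    "time": t,
                    "time_unit": s.time_unit,
                    "reading": r,
                    "reading_unit": s.reading_unit,
                }
            )
    pd.DataFrame(rows, columns=list(SERIES_COLUMNS)).to_csv(path, index=False)


def read_calibration_csv(path) -> Dict[str, List[tuple]]:
    """Read a standards table (substrate, concentration, signal) by substrate."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("substrate", "concentration", "signal"), path)
    out: Dict[str, List[tuple]] = {}
    for substrate, grp in df.groupby("substrate", sort=False):
        out[str(substrate)] = list(
            zip(grp["concentration"].astype(float), grp["signal"].astype(float))
        )
    return out


def read_teer_csv(path) -> List[TEERTrace]:
    """Read TEER traces (time_day, resistance_ohm, chip_id, baseline_ohm, area_cm2)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(
        df, ("time_day", "resistance_ohm", "chip_id", "baseline_ohm", "area_cm2"), path
    )
    traces = []
    for chip, grp in df.groupby("chip_id", sort=False):
        baselines = grp["baseline_ohm"].unique()
        areas = grp["area_cm2"].unique()
        if len(baselines) != 1 or len(areas) != 1:
            raise ValidationError(
                f"{path}: chip {chip!r} has inconsistent baseline/area"
            )
        traces.append(
            TEERTrace(
                times_day=grp["time_day"].to_numpy(dtype=float),
                resistance_ohm=grp["resistance_ohm"].to_numpy(dtype=float),
                baseline_ohm=float(baselines[0]),
                area_cm2=float(areas[0]),
                label=str(chip),
            )
        )
    if not traces:
        raise ValidationError(f"{path}: no data rows")
    return traces


def read_protocol_yaml(path) -> SamplingProtocol:
    """Load a sampling protocol; YAML keys mirror SamplingProtocol fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = {
        "channel_volume_ul",
        "sample_volume_ul",
        "normalization_volume_ul",
        "interval_min",
        "direction",
        "replacement",
        "source_volume_ul",
    }
    unknown = set(raw) - allowed
    if unknown:
        raise ValidationError(
            f"{path}: unknown protocol key(s) {sorted(unknown)}; "
            "units must be embedded in key names"
        )
    return SamplingProtocol(**raw)


def read_geometry_yaml(path) -> ChannelGeometry:
    """Load channel geometry; YAML keys mirror ChannelGeometry fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = {"width_mm", "height_mm", "length_mm", "membrane_area_cm2", "porosity"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValidationError(f"{path}: unknown geometry key(s) {sorted(unknown)}")
    return ChannelGeometry(**raw)


def write_zstack_tiff(path, stack: ZStack, sidecar_path=None) -> None:
    """Write a stack as multi-page TIFF (z-major, channel-minor) + sidecar YAML."""
    path = Path(path)
    names = list(stack.channels)
    data = np.stack([stack.channels[n] for n in names], axis=1)  # (z, c, y, x)
    tifffile.imwrite(path, data.astype(np.float32), photometric="minisblack")
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(".yaml")
    meta = {
        "channels": names,
        "pitch_nm": float(stack.z_pitch_nm),
        "apical_direction": stack.apical_direction,
        "scan_area_cm2": stack.scan_area_cm2,
    }
    with open(sidecar, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_zstack_tiff(
    path,
    sidecar_path=None,
    channels: Optional[Sequence[str]] = None,
    pitch_nm: Optional[float] = None,
    apical_direction: Optional[str] = None,
) -> ZStack:
    """Read a multi-channel TIFF stack; metadata from sidecar YAML or kwargs."""
    path = Path(path)
    meta = {}
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(".yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    names = list(channels) if channels else meta.get("channels")
    pitch = pitch_nm if pitch_nm is not None else meta.get("pitch_nm")
    apical = apical_direction or meta.get("apical_direction")
    if not names or pitch is None or not apical:
        raise ValidationError(
            f"{path}: channel names, pitch_nm and apical_direction must be "
            "supplied via sidecar YAML or arguments"
        )
    data = tifffile.imread(path)
    if data.ndim == 3:  # single channel written without channel axis
        data = data[:, None, :, :]
    if data.ndim != 4 or data.shape[1] != len(names):
        raise ValidationError(
            f"{path}: expected (z, {len(names)}, y, x) pages, got {data.shape}"
        )
    return ZStack(
        channels={name: data[:, i] for i, name in enumerate(names)},
        z_pitch_nm=float(pitch),
        apical_direction=str(apical),
        scan_area_cm2=meta.get("scan_area_cm2"),
    )


def read_morphometry_csv(path) -> pd.DataFrame:
    """Read a TEM annotation table (condition, count, periphery_um, ...)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("condition", "count", "periphery_um"), path)
    return df


def sha256_of(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    subcommand: str
    parameters: dict
    input_checksums: Dict[str, str] = field(default_factory=dict)
    seed: Optional[int] = None
    tool_version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()


def write_manifest(path, manifest: RunManifest) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(manifest), fh, sort_keys=False)
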