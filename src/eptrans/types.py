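"""Domain containers for chip transport assays, TEER traces and z-stacks.

All containers are plain dataclasses with eager ``__post_init__``
validation: every physically impossible field combination (negative
volumes, non-increasing sample times, a sampling volume exceeding the
channel volume, ...) raises :class:`~eptrans.errors.ValidationError` at
construction time, so downstream numerics never see malformed input.

Unit conventions
----------------
* assay time: minutes internally (``SampleSeries.time_unit`` records what
  the caller supplied; I/O converts at the boundary),
* TEER time: days; resistance: Ω; areal TEER: Ω·cm²,
* concentrations: μM unless relabelled via ``reading_unit``,
* lengths: channel dimensions in mm, membrane area in cm², confocal z in
  μm with the pitch given in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "ChannelGeometry",
    "SamplingProtocol",
    "CalibrationCurve",
    "SampleSeries",
    "ReconstructedSeries",
    "TransferRate",
    "PappResult",
    "EffluxSummary",
    "DepletionCheck",
    "TEERTrace",
    "FilterSpec",
    "Plateau",
    "ZStack",
    "ZProfile",
    "DeltaD",
    "MorphometryRecord",
    "CompareResult",
    "TransportParams",
    "SimTruth",
]


def _as_float_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if np.any(~np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular microchannel geometry above a porous membrane.

    Parameters
    ----------
    width_mm, height_mm, length_mm : float
        Channel cross-section width ``W`` and height ``h`` and its length,
        in millimetres.
    membrane_area_cm2 : float
        Area of the porous membrane shared between the two channels, cm².
    porosity : float, optional
        Open-area fraction of the membrane, in (0, 1].
    """

    width_mm: float
    height_mm: float
    length_mm: float
    membrane_area_cm2: float
    porosity: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("width_mm", "height_mm", "length_mm", "membrane_area_cm2"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"ChannelGeometry.{name} must be > 0")
        if self.porosity is not None and not (0.0 < self.porosity <= 1.0):
            raise ValidationError("ChannelGeometry.porosity must lie in (0, 1]")


@dataclass(frozen=True)
class SamplingProtocol:
    """Removal-and-replacement sampling scheme for a two-channel assay.

    At every ``interval_min`` a volume ``sample_volume_ul`` is withdrawn
    from the receiver channel (total volume ``channel_volume_ul``),
    measured, and — when ``replacement='fresh_buffer'`` — replaced with
    analyte-free buffer. ``normalization_volume_ul`` is the divisor used by
    the literal concentration-reconstruction recursion.
    ``source_volume_ul`` is set for circulating-reservoir assays where
    aliquots are drawn from a large external jar instead.
    """

    channel_volume_ul: float = 200.0
    sample_volume_ul: float = 100.0
    normalization_volume_ul: float = 1000.0
    interval_min: float = 60.0
    direction: str = "a_to_b"
    replacement: str = "fresh_buffer"
    source_volume_ul: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.sample_volume_ul <= self.channel_volume_ul:
            raise ValidationError(
                "sample_volume_ul must satisfy 0 < V_s <= channel volume "
                f"(got V_s={self.sample_volume_ul}, V_c={self.channel_volume_ul})"
            )
        if not self.normalization_volume_ul > 0:
            raise ValidationError("normalization_volume_ul must be > 0")
        if not self.interval_min > 0:
            raise ValidationError("interval_min must be > 0")
        if self.direction not in ("a_to_b", "b_to_a"):
            raise ValidationError("direction must be 'a_to_b' or 'b_to_a'")
        if self.replacement not in ("fresh_buffer", "none"):
            raise ValidationError("replacement must be 'fresh_buffer' or 'none'")
        if self.source_volume_ul is not None and not self.source_volume_ul > 0:
            raise ValidationError("source_volume_ul must be > 0 when given")


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS standard line mapping fluorescence signal to concentration."""

    slope: float
    intercept: float
    r_squared: float
    standard_points: tuple = ()
    warning: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValidationError("calibration slope must be > 0")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValidationError("r_squared must lie in [0, 1]")
        if len(self.standard_points) < 3:
            raise ValidationError("calibration needs at least 3 standard points")

    def signal_to_concentration(self, signal):
        return self.slope * np.asarray(signal, dtype=float) + self.intercept


@dataclass
class SampleSeries:
    """Timestamped receiver-side readings for one chip/direction/condition."""

    times: np.ndarray
    readings: np.ndarray
    substrate: str = ""
    condition: str = ""
    chip_id: str = ""
    direction: str = "a_to_b"
    time_unit: str = "min"
    reading_unit: str = "uM"

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.readings = _as_float_array(self.readings, "readings")
        if self.times.size != self.readings.size:
            raise ValidationError("times and readings must have equal length")
        if self.times.size == 0:
            raise ValidationError("SampleSeries must contain at least one point")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError(
                f"times must be strictly increasing (chip '{self.chip_id}')"
            )
        if self.times.size and self.times[0] < 0:
            raise ValidationError("times must be >= 0")
        if np.any(self.readings < 0):
            raise ValidationError("readings must be non-negative")
        if self.direction not in ("a_to_b", "b_to_a"):
            raise ValidationError("direction must be 'a_to_b' or 'b_to_a'")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class ReconstructedSeries:
    """Depletion-corrected concentration time course in the receiver channel.

    ``method`` records which correction produced it: ``'literal_eq2'`` (the
    published recursion with its fixed 200/100/1000 μL constants as
    defaults) or ``'mass_balance'`` (exact cumulative ledger of analyte
    removed in aliquots).
    """

    times: np.ndarray
    concentrations: np.ndarray
    method: str
    protocol: SamplingProtocol
    source: Optional[SampleSeries] = None

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.concentrations = _as_float_array(self.concentrations, "concentrations")
        if self.times.size != self.concentrations.size:
            raise ValidationError("times and concentrations must match in length")
        if self.method not in ("literal_eq2", "mass_balance"):
            raise ValidationError("method must be 'literal_eq2' or 'mass_balance'")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class TransferRate:
    """Initial-rate OLS fit of a concentration time course.

    ``slope`` is in concentration units per ``time_unit``; ``fit_window``
    is the (closed) time interval actually used.
    """

    slope: float
    intercept: float
    standard_error: float
    r_squared: float
    fit_window: tuple
    n_points: int
    time_unit: str = "min"
    warning: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValidationError("a rate fit requires at least 2 points")


@dataclass(frozen=True)
class PappResult:
    """Apparent permeability under sink conditions, in cm s⁻¹."""

    value_cm_s: float
    donor_concentration_uM: float
    receiver_volume_ul: float
    membrane_area_cm2: float

    def __post_init__(self) -> None:
        if not self.donor_concentration_uM > 0:
            raise ValidationError("donor concentration must be > 0")
        if not self.membrane_area_cm2 > 0:
            raise ValidationError("membrane area must be > 0")


@dataclass(frozen=True)
class EffluxSummary:
    """Excretion/absorption rate pair and their ratio.

    ``efflux_ratio`` is NaN (with a flag) when the absorptive slope is not
    positive — never silently infinite.
    """

    rate_ba: float
    rate_ab: float
    efflux_ratio: float
    inhibition_percent: Optional[float] = None
    flags: tuple = ()


@dataclass(frozen=True)
class DepletionCheck:
    """Cumulative reservoir-depletion bookkeeping for repeated aliquots."""

    depleted_fraction: float
    threshold: float
    flagged: bool
    message: Optional[str] = None


@dataclass
class TEERTrace:
    """Raw four-probe resistance series with its pre-seeding baseline."""

    times_day: np.ndarray
    resistance_ohm: np.ndarray
    baseline_ohm: float
    area_cm2: float
    label: str = ""

    def __post_init__(self) -> None:
        self.times_day = _as_float_array(self.times_day, "times_day")
        self.resistance_ohm = _as_float_array(self.resistance_ohm, "resistance_ohm")
        if self.times_day.size != self.resistance_ohm.size:
            raise ValidationError("times and resistances must match in length")
        if self.times_day.size > 1 and np.any(np.diff(self.times_day) < 0):
            raise ValidationError("times_day must be non-decreasing")
        if not self.area_cm2 > 0:
            raise ValidationError("area_cm2 must be > 0")
        if self.baseline_ohm is None or self.baseline_ohm < 0:
            raise ValidationError("baseline_ohm must be recorded and >= 0")

    def __len__(self) -> int:
        return int(self.times_day.size)


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass specification ``f3dB = 1 / (2 n Δt)``.

    ``n`` is the points-of-window count and ``dt_day`` the sampling
    interval in days; the derived cutoff is in day⁻¹.
    """

    n: int = 6
    dt_day: float = 0.5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("FilterSpec.n must be >= 1")
        if not self.dt_day > 0:
            raise ValidationError("FilterSpec.dt_day must be > 0")

    @property
    def f3db_per_day(self) -> float:
        return 1.0 / (2.0 * self.n * self.dt_day)


@dataclass(frozen=True)
class Plateau:
    """A low-slope interval of a smoothed TEER trace."""

    t_start_day: float
    t_end_day: float
    level: float

    @property
    def duration_day(self) -> float:
        return self.t_end_day - self.t_start_day


@dataclass
class ZStack:
    """Multi-channel confocal intensity volume indexed (z, y, x).

    ``apical_direction`` states which end of the z axis faces the lumen;
    it cannot be inferred from the data and must always be supplied.
    """

    channels: dict
    z_pitch_nm: float
    apical_direction: str
    scan_area_cm2: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("ZStack needs at least one channel")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise ValidationError(f"all channels must share one shape, got {shapes}")
        if len(first) != 3:
            raise ValidationError("channel volumes must be indexed (z, y, x)")
        if first[0] < 5:
            raise ValidationError("a z-stack needs at least 5 z-planes")
        if not self.z_pitch_nm > 0:
            raise ValidationError("z_pitch_nm must be > 0")
        if self.apical_direction not in ("increasing_z", "decreasing_z"):
            raise ValidationError(
                "apical_direction must be 'increasing_z' or 'decreasing_z'"
            )
        self.channels = {
            name: np.asarray(arr, dtype=float) for name, arr in self.channels.items()
        }

    @property
    def n_planes(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def z_um(self) -> np.ndarray:
        return np.arange(self.n_planes) * self.z_pitch_nm * 1e-3


@dataclass
class ZProfile:
    """Per-channel mean intensity against z (μm from the first plane)."""

    z_um: np.ndarray
    intensities: dict
    z_pitch_nm: float
    apical_direction: str = "increasing_z"

    def __post_init__(self) -> None:
        self.z_um = _as_float_array(self.z_um, "z_um")
        for name, arr in self.intensities.items():
            arr = _as_float_array(arr, f"intensity[{name}]")
            if arr.size != self.z_um.size:
                raise ValidationError(f"profile length mismatch for channel {name!r}")
            if np.any(arr < 0):
                raise ValidationError(f"intensities must be >= 0 (channel {name!r})")
            self.intensities[name] = arr


@dataclass(frozen=True)
class DeltaD:
    """Signed marker-to-nucleus peak distance along z.

    Positive values mean the marker peaks apical of the DAPI peak. The
    magnitude is what figure-style summaries report; the sign is kept for
    orientation-aware analyses.
    """

    value_um: float
    marker: str
    smoothing_sigma_um: float


@dataclass(frozen=True)
class MorphometryRecord:
    """Manual TEM annotation for one micrograph."""

    protrusion_count: int
    periphery_length_um: float
    villi_lengths_um: tuple = ()
    cell_height_um: Optional[float] = None
    condition: str = ""

    def __post_init__(self) -> None:
        if self.protrusion_count < 0:
            raise ValidationError("protrusion_count must be >= 0")
        if not self.periphery_length_um > 0:
            raise ValidationError("periphery_length_um must be > 0")
        if any(v <= 0 for v in self.villi_lengths_um):
            raise ValidationError("villi lengths must be > 0")
        if self.cell_height_um is not None and not self.cell_height_um > 0:
            raise ValidationError("cell_height_um must be > 0 when given")


@dataclass(frozen=True)
class CompareResult:
    """Welch two-sample comparison with figure-style significance stars."""

    t_statistic: float
    p_value: float
    stars: str
    significant: bool
    alpha: float = 0.05
    warning: Optional[str] = None


@dataclass(frozen=True)
class TransportParams:
    """Ground-truth parameters of the two-compartment transport simulator.

    Passive leak is linear in the transmembrane concentration difference
    with permeability ``passive_P_cm_s``; the active (transporter) term is
    saturable with ``vmax_umol_min`` and ``km_uM`` and is competitively
    inhibited: Km is scaled by ``1 + I/Ki``. ``noise_cv`` is the
    multiplicative coefficient of variation applied to recorded readings.
    """

    passive_P_cm_s: float = 3e-6
    vmax_umol_min: float = 0.0
    km_uM: float = 5.0
    active_direction: str = "b_to_a"
    inhibitor_uM: float = 0.0
    ki_uM: Optional[float] = None
    donor_c0_uM: float = 2.5
    volume_a_ul: float = 200.0
    volume_b_ul: float = 200.0
    membrane_area_cm2: float = 0.1
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.passive_P_cm_s < 0 or self.vmax_umol_min < 0 or self.km_uM < 0:
            raise ValidationError("P, Vmax and Km must be >= 0")
        if not self.donor_c0_uM > 0:
            raise ValidationError("donor_c0_uM must be > 0")
        if not (self.volume_a_ul > 0 and self.volume_b_ul > 0):
            raise ValidationError("channel volumes must be > 0")
        if not self.membrane_area_cm2 > 0:
            raise ValidationError("membrane_area_cm2 must be > 0")
        if self.active_direction not in ("a_to_b", "b_to_a"):
            raise ValidationError("active_direction must be 'a_to_b' or 'b_to_a'")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.inhibitor_uM < 0:
            raise ValidationError("inhibitor_uM must be >= 0")
        if self.ki_uM is not None and not self.ki_uM > 0:
            raise ValidationError("ki_uM must be > 0 when given")


@dataclass(frozen=True)
class SimTruth:
    """Generator parameters plus derived analytic quantities.

    Together with the seed (inside ``params``) this fully determines the
    generated dataset; recovery tests compare pipeline estimates against
    the ``derived`` entries (initial flux, expected efflux ratio, plateau
    asymptotes, peak centres, ...).
    """

    params: object
    derived: dict = field(default_factory=dict)
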