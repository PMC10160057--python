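"""Transepithelial transport quantification.

Turns raw receiver-channel readings from removal-and-replacement sampling
assays into calibrated, depletion-corrected concentration time courses,
and derives initial transfer rates, apparent permeabilities (P_app),
efflux ratios, inhibition percentages, reservoir-depletion diagnostics and
the wall shear stress of the perfused channel.

The fit/transform-shaped steps are scikit-learn estimators
(:class:`CalibrationRegression`, :class:`ConcentrationReconstructor`,
:class:`TransferRateRegression`) so they compose with sklearn pipelines
and model selection; the module-level functions are thin wrappers that
speak the domain containers of :mod:`eptrans.types`.

Depletion correction
--------------------
Each sampling event removes an aliquot of receiver fluid, so raw sample
concentrations under-report the transported mass. Two corrections are
provided:

``literal_eq2``
    the published recursion
    ``C_t = C_{t-1} + (R_t·V_c − R_{t-1}·V_s) / V_n``
    with the published constants V_c = 200 μL, V_s = 100 μL and
    V_n = 1000 μL as defaults. The 1000 μL divisor is not derivable from
    the channel and sample volumes and does not close an exact mass
    balance; it is reproduced verbatim because published rates were
    computed with it. Slopes differ from the exact correction only by a
    constant factor, so relative comparisons are preserved.

``mass_balance``
    the exact cumulative ledger under fresh-buffer replacement,
    ``C_t = R_t + (V_s/V_c)·Σ_{i<t} R_i``:
    each earlier aliquot carried off ``R_i·V_s`` of analyte which is added
    back as an equivalent channel concentration.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ComputationError, ValidationError
from .types import (
    CalibrationCurve,
    ChannelGeometry,
    DepletionCheck,
    EffluxSummary,
    PappResult,
    ReconstructedSeries,
    SamplingProtocol,
    SampleSeries,
    TransferRate,
)

__all__ = [
    "CalibrationRegression",
    "ConcentrationReconstructor",
    "TransferRateRegression",
    "fit_calibration",
    "reconstruct_concentrations",
    "fit_transfer_rate",
    "apparent_permeability",
    "efflux_summary",
    "shear_stress",
    "reservoir_depletion_check",
    "DEFAULT_GLUCOSE_WINDOW_MIN",
]

#: Default regression window for interval-sampled (glucose-style) assays:
#: 0–3 h, expressed in minutes (the internal assay-time unit).
DEFAULT_GLUCOSE_WINDOW_MIN: Tuple[float, float] = (0.0, 180.0)

_SECONDS_PER = {"s": 1.0, "sec": 1.0, "min": 60.0, "h": 3600.0, "hour": 3600.0}


def _seconds_per(time_unit: str) -> float:
    try:
        return _SECONDS_PER[time_unit]
    except KeyError:
        raise ValidationError(
            f"unknown time unit {time_unit!r}; use one of {sorted(_SECONDS_PER)}"
        ) from None


class CalibrationRegression(RegressorMixin, BaseEstimator):
    """OLS standard line mapping instrument signal to concentration.

    Fit on known standards (signal ``X``, concentration ``y``); ``predict``
    converts raw fluorescence readings to concentration. The intercept is
    free (blank subtraction is the caller's responsibility).

    Parameters
    ----------
    min_r_squared : float, default 0.99
        Fits below this r² are kept but carry a quality warning.

    Attributes
    ----------
    slope_ : float
        Concentration per signal unit (> 0 required).
    intercept_ : float
    r_squared_ : float
    curve_ : CalibrationCurve
    """

    def __init__(self, min_r_squared: float = 0.99):
        self.min_r_squared = min_r_squared

    def fit(self, X, y):
        signal = np.asarray(X, dtype=float).reshape(-1)
        conc = np.asarray(y, dtype=float).reshape(-1)
        if signal.size != conc.size:
            raise ValidationError("signal and concentration lengths differ")
        if np.unique(conc).size < 3:
            raise ValidationError("calibration needs >= 3 distinct concentrations")
        if np.any(signal < 0):
            raise ValidationError("calibration signals must be >= 0")
        if np.ptp(signal) == 0:
            raise ValidationError("calibration signals have zero variance")
        res = stats.linregress(signal, conc)
        if res.slope <= 0:
            raise ValidationError(
                "calibration slope is not positive; check standard ordering"
            )
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        warning = None
        if self.r_squared_ < self.min_r_squared:
            warning = (
                f"calibration r²={self.r_squared_:.4f} below "
                f"{self.min_r_squared:.2f}"
            )
            warnings.warn(warning, stacklevel=2)
        self.curve_ = CalibrationCurve(
            slope=self.slope_,
            intercept=self.intercept_,
            r_squared=min(self.r_squared_, 1.0),
            standard_points=tuple(zip(conc.tolist(), signal.tolist())),
            warning=warning,
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        signal = np.asarray(X, dtype=float)
        return self.slope_ * signal + self.intercept_


class ConcentrationReconstructor(TransformerMixin, BaseEstimator):
    """Depletion correction of aliquot readings (stateless transformer).

    ``transform`` maps a 1-D array of sample readings ``R_t`` (one per
    sampling event, R_0 = 0 and C_0 = 0 by convention — no analyte in the
    receiver at assay start) to corrected channel concentrations ``C_t``
    using either the literal published recursion or the exact mass-balance
    ledger; see the module docstring.
    """

    def __init__(
        self,
        method: str = "literal_eq2",
        protocol: Optional[SamplingProtocol] = None,
    ):
        self.method = method
        self.protocol = protocol

    def fit(self, X=None, y=None):
        if self.method not in ("literal_eq2", "mass_balance"):
            raise ValidationError(
                "method must be 'literal_eq2' or 'mass_balance', "
                f"got {self.method!r}"
            )
        self.protocol_ = self.protocol if self.protocol is not None else SamplingProtocol()
        return self

    def transform(self, X):
        if not hasattr(self, "protocol_"):
            self.fit()
        readings = np.asarray(X, dtype=float).reshape(-1)
        if readings.size == 0:
            raise ValidationError("no readings to reconstruct")
        if np.any(readings < 0):
            raise ValidationError("readings must be non-negative")
        p = self.protocol_
        if self.method == "literal_eq2":
            increments = (
                readings * p.channel_volume_ul
                - np.concatenate(([0.0], readings[:-1])) * p.sample_volume_ul
            ) / p.normalization_volume_ul
            return np.cumsum(increments)
        # mass_balance: add back the concentration-equivalent of every
        # aliquot removed before the current event.
        removed_prefix = np.concatenate(([0.0], np.cumsum(readings[:-1])))
        return readings + (p.sample_volume_ul / p.channel_volume_ul) * removed_prefix


class TransferRateRegression(RegressorMixin, BaseEstimator):
    """Initial-rate OLS on a (time, concentration) course.

    Parameters
    ----------
    window : (float, float) or None
        Closed time interval to fit over, in the units of the supplied
        times. ``None`` uses the full series. Interval-sampled
        glucose-style assays conventionally use 0–3 h
        (:data:`DEFAULT_GLUCOSE_WINDOW_MIN`).
    min_r_squared : float, default 0.8
        Below this the fitted rate carries a quality warning (the fit is
        reported, never suppressed).

    Attributes
    ----------
    slope_, intercept_, standard_error_, r_squared_ : float
    n_points_ : int
    """

    def __init__(
        self,
        window: Optional[Tuple[float, float]] = None,
        min_r_squared: float = 0.8,
    ):
        self.window = window
        self.min_r_squared = min_r_squared

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        c = np.asarray(y, dtype=float).reshape(-1)
        if t.size != c.size:
            raise ValidationError("time and concentration lengths differ")
        if self.window is not None:
            lo, hi = self.window
            if lo > hi:
                raise ValidationError("window start must not exceed window end")
            mask = (t >= lo) & (t <= hi)
        else:
            mask = np.ones_like(t, dtype=bool)
        t_fit, c_fit = t[mask], c[mask]
        if t_fit.size < 2:
            raise ValidationError(
                f"rate fit needs >= 2 points inside the window, got {t_fit.size}"
            )
        if np.ptp(t_fit) == 0:
            raise ValidationError("fit window collapses to a single time point")
        res = stats.linregress(t_fit, c_fit)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.standard_error_ = float(res.stderr) if np.isfinite(res.stderr) else 0.0
        # rvalue is nan for an exactly constant c; a flat series is a
        # perfect zero-slope line, so report r²=1 there.
        self.r_squared_ = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
        self.n_points_ = int(t_fit.size)
        self.window_ = (float(t_fit.min()), float(t_fit.max()))
        self.warning_ = None
        if self.r_squared_ < self.min_r_squared:
            self.warning_ = (
                f"rate fit r²={self.r_squared_:.3f} below {self.min_r_squared:.2f}"
            )
            warnings.warn(self.warning_, stacklevel=2)
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        return self.slope_ * np.asarray(X, dtype=float) + self.intercept_


# ---------------------------------------------------------------------------
# functional wrappers


def fit_calibration(
    standards: Sequence[Tuple[float, float]], min_r_squared: float = 0.99
) -> CalibrationCurve:
    """Fit an OLS standard line from (concentration, signal) pairs."""
    pairs = list(standards)
    if len(pairs) < 3:
        raise ValidationError("calibration needs at least 3 standard points")
    conc = np.array([p[0] for p in pairs], dtype=float)
    signal = np.array([p[1] for p in pairs], dtype=float)
    est = CalibrationRegression(min_r_squared=min_r_squared).fit(signal, conc)
    return est.curve_


def reconstruct_concentrations(
    series: SampleSeries,
    protocol: Optional[SamplingProtocol] = None,
    method: str = "literal_eq2",
) -> ReconstructedSeries:
    """Correct a sampled receiver series for aliquot depletion.

    Returns a :class:`ReconstructedSeries` of the same length, tagged with
    the correction method. ``C_0 = 0`` and ``R_0 = 0`` by convention: the
    receiver channel contains no analyte when the assay starts.
    """
    protocol = protocol if protocol is not None else SamplingProtocol()
    rec = ConcentrationReconstructor(method=method, protocol=protocol).fit()
    conc = rec.transform(series.readings)
    return ReconstructedSeries(
        times=series.times.copy(),
        concentrations=conc,
        method=method,
        protocol=protocol,
        source=series,
    )


def fit_transfer_rate(
    series,
    window: Optional[Tuple[float, float]] = None,
    time_unit: Optional[str] = None,
) -> TransferRate:
    """OLS transfer rate of a (reconstructed) concentration time course.

    Parameters
    ----------
    series : ReconstructedSeries or SampleSeries
        Uses ``concentrations`` when present, else raw ``readings``.
    window : (lo, hi), optional
        Fit window in the series' own time units; ``None`` fits the whole
        course (reservoir-style 24 h assays), glucose-style assays pass
        the 0–3 h window.
    """
    times = series.times
    values = getattr(series, "concentrations", None)
    if values is None:
        values = series.readings
    if time_unit is None:
        src = getattr(series, "source", None)
        time_unit = getattr(series, "time_unit", None) or getattr(
            src, "time_unit", None
        ) or "min"
    est = TransferRateRegression(window=window).fit(times, values)
    return TransferRate(
        slope=est.slope_,
        intercept=est.intercept_,
        standard_error=est.standard_error_,
        r_squared=min(est.r_squared_, 1.0),
        fit_window=est.window_,
        n_points=est.n_points_,
        time_unit=time_unit,
        warning=est.warning_,
    )


def apparent_permeability(
    rate,
    c0_uM: float,
    receiver_volume_ul: float,
    membrane_area_cm2: Optional[float] = None,
    geometry: Optional[ChannelGeometry] = None,
    time_unit: Optional[str] = None,
) -> PappResult:
    """Apparent permeability ``P_app = (dC_r/dt)·V_r / (A·C_0)`` in cm s⁻¹.

    Standard sink-condition form: receiver accumulation rate times
    receiver volume, normalized by membrane area and donor concentration.

    Parameters
    ----------
    rate : TransferRate or float
        Receiver concentration slope, in μM per ``time_unit`` (taken from
        the :class:`TransferRate` when one is passed).
    c0_uM : float
        Donor (source) concentration, μM.
    receiver_volume_ul : float
    membrane_area_cm2 : float, optional
        Either this or ``geometry`` must be given.
    """
    if isinstance(rate, TransferRate):
        slope = rate.slope
        time_unit = time_unit or rate.time_unit
    else:
        slope = float(rate)
        time_unit = time_unit or "h"
    if membrane_area_cm2 is None:
        if geometry is None:
            raise ValidationError("membrane_area_cm2 or geometry is required")
        membrane_area_cm2 = geometry.membrane_area_cm2
    if c0_uM <= 0:
        raise ValidationError("donor concentration must be > 0")
    if receiver_volume_ul <= 0 or membrane_area_cm2 <= 0:
        raise ValidationError("receiver volume and membrane area must be > 0")
    # (μM/unit · μL) / (cm² · μM) = μL cm⁻² per unit = 1e-3 cm per unit
    slope_per_s = slope / _seconds_per(time_unit)
    value = slope_per_s * receiver_volume_ul * 1e-3 / (membrane_area_cm2 * c0_uM)
    return PappResult(
        value_cm_s=value,
        donor_concentration_uM=c0_uM,
        receiver_volume_ul=receiver_volume_ul,
        membrane_area_cm2=membrane_area_cm2,
    )


def efflux_summary(
    rate_ba,
    rate_ab,
    rate_inhibited=None,
) -> EffluxSummary:
    """Efflux ratio (excretion/absorption) and optional inhibition percent.

    ``efflux_ratio = slope_ba / slope_ab``; a non-positive absorptive
    slope yields NaN plus an explanatory flag rather than an infinity.
    ``inhibition_percent = 100·(1 − slope_inhibited/slope_ba)`` compares an
    inhibited excretion rate against the uninhibited control.
    """

    def _slope(r):
        return r.slope if isinstance(r, TransferRate) else float(r)

    slope_ba, slope_ab = _slope(rate_ba), _slope(rate_ab)
    flags = []
    if slope_ab > 0:
        ratio = slope_ba / slope_ab
    else:
        ratio = float("nan")
        flags.append("absorptive (a->b) slope <= 0: efflux ratio undefined")
    inhibition = None
    if rate_inhibited is not None:
        slope_inh = _slope(rate_inhibited)
        if slope_ba > 0:
            inhibition = 100.0 * (1.0 - slope_inh / slope_ba)
        else:
            flags.append("control slope <= 0: inhibition percent undefined")
    return EffluxSummary(
        rate_ba=slope_ba,
        rate_ab=slope_ab,
        efflux_ratio=ratio,
        inhibition_percent=inhibition,
        flags=tuple(flags),
    )


def shear_stress(
    geometry: ChannelGeometry,
    flow_ul_min: float,
    viscosity_mPa_s: float = 0.7,
) -> float:
    """Wall shear stress ``τ = 6 η Q / (W h²)`` in dyn cm⁻².

    Shallow-rectangular-channel estimate of the tangential stress the
    perfusate exerts on the apical cell membrane. Inputs are in working
    units (μL min⁻¹, mPa·s, mm) and converted to CGS internally; 0.7 mPa·s
    approximates culture-medium viscosity at 37 °C.
    """
    if flow_ul_min < 0:
        raise ValidationError("flow rate must be >= 0")
    if viscosity_mPa_s <= 0:
        raise ValidationError("viscosity must be > 0")
    eta_poise = viscosity_mPa_s * 1e-2  # 1 mPa·s = 0.01 dyn·s·cm⁻²
    q_cm3_s = flow_ul_min * 1e-3 / 60.0
    w_cm = geometry.width_mm * 0.1
    h_cm = geometry.height_mm * 0.1
    return 6.0 * eta_poise * q_cm3_s / (w_cm * h_cm**2)


def reservoir_depletion_check(
    protocol: SamplingProtocol,
    n_samples: int,
    threshold: float = 0.05,
) -> DepletionCheck:
    """Cumulative removed fraction ``n·V_s / V_source`` of a reservoir.

    Circulating-reservoir assays assume repeated small aliquots leave the
    diffusion equilibrium undisturbed; the check flags protocols whose
    cumulative withdrawal exceeds ``threshold`` (default 5%).
    """
    if protocol.source_volume_ul is None:
        raise ValidationError(
            "protocol.source_volume_ul must be set for a reservoir assay"
        )
    if n_samples < 0:
        raise ValidationError("n_samples must be >= 0")
    fraction = n_samples * protocol.sample_volume_ul / protocol.source_volume_ul
    flagged = fraction > threshold
    message = (
        "equilibrium assumption violated: cumulative withdrawal "
        f"{fraction:.1%} exceeds {threshold:.1%}"
        if flagged
        else None
    )
    return DepletionCheck(
        depleted_fraction=fraction,
        threshold=threshold,
        flagged=flagged,
        message=message,
    )
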