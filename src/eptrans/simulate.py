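"""Synthetic chip assays with recorded ground truth.

Every generator is a pure function of its parameters and an integer seed,
and returns the simulated dataset together with a :class:`SimTruth`
carrying the generating parameters and the analytic quantities a recovery
test compares against (initial flux, expected efflux ratio, plateau
asymptotes, peak centres).

Transport model
---------------
Two well-mixed compartments (apical channel a, basolateral channel b)
exchange solute across the membrane:

``dM_b/dt = P·A·(C_a − C_b) + s·Vmax·C_src / (Km·(1 + I/Ki) + C_src)``

a linear passive leak of permeability ``P`` (membrane hindrance folded
into an effective P) plus a saturable carrier of capacity ``Vmax`` and
affinity ``Km`` under competitive inhibition (Km scaled by ``1 + I/Ki``).
The carrier draws from the channel on its *source* side (``C_src``; a for
apical-to-basal pumps such as SGLT2-mediated reabsorption, b for
basal-to-apical efflux such as P-glycoprotein), so in the against-pump
assay direction the active term starts at zero and grows only as the
receiver fills. The chip itself fits no kinetic model — this functional
form is a deliberately simple stand-in consistent with the use of
competitive inhibitors (phlorizin, verapamil, cimetidine) and with linear
initial-rate analysis.

Integration is fixed-step RK4 with at least 100 steps per sampling
interval; on any negative excursion the interval is re-integrated at 10×
resolution. At each sampling event the receiver concentration is recorded
with multiplicative Gaussian noise (CV ``noise_cv``), an aliquot ``V_s``
is withdrawn, and — under the fresh-buffer protocol — replaced with
analyte-free buffer. Mass (both channels plus all withdrawn aliquots) is
conserved to float precision; the running audit is reported in the truth
record.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import ValidationError
from .types import (
    MorphometryRecord,
    SamplingProtocol,
    SampleSeries,
    SimTruth,
    TEERTrace,
    TransportParams,
    ZStack,
)

__all__ = [
    "simulate_transport",
    "simulate_teer",
    "simulate_zstack",
    "simulate_morphometry",
]

# P[cm/s]·A[cm²]·C[μM] → pmol/min  (cm³/s · μmol/L = 1e-3 μmol/s)
_PA_TO_PMOL_MIN = 6.0e4


def _km_effective(params: TransportParams) -> float:
    if params.inhibitor_uM > 0:
        if params.ki_uM is None:
            raise ValidationError("ki_uM is required when an inhibitor is present")
        return params.km_uM * (1.0 + params.inhibitor_uM / params.ki_uM)
    return params.km_uM


def _active_flux_into_b(c_a: float, c_b: float, params: TransportParams,
                        km_eff: float, vmax_pmol: float) -> float:
    """Carrier flux into channel b, pmol/min (negative = toward a)."""
    if vmax_pmol == 0.0:
        return 0.0
    if not np.isfinite(km_eff):  # I → ∞ limit: fully inhibited
        return 0.0
    if params.active_direction == "a_to_b":
        src, sign = c_a, 1.0
    else:
        src, sign = c_b, -1.0
    if src <= 0.0:
        return 0.0
    return sign * vmax_pmol * src / (km_eff + src)


def simulate_transport(
    params: TransportParams,
    protocol: Optional[SamplingProtocol] = None,
    n_intervals: int = 6,
    steps_per_interval: int = 100,
) -> Tuple[SampleSeries, SimTruth]:
    """Simulate a removal-and-replacement transport assay.

    The donor channel is set by ``protocol.direction`` (``a_to_b``: donor
    a, receiver b) and starts at ``params.donor_c0_uM``; the receiver
    starts empty. Returns the noisy receiver readings as a
    :class:`SampleSeries` (with a leading (t=0, 0) point) and the truth
    record with the analytic initial flux, the expected initial-flux
    efflux ratio, the withdrawn aliquot masses and a mass-conservation
    audit.
    """
    protocol = protocol if protocol is not None else SamplingProtocol()
    if n_intervals < 2:
        raise ValidationError("n_intervals must be >= 2")
    steps_per_interval = max(int(steps_per_interval), 100)
    rng = np.random.default_rng(params.seed)

    km_eff = _km_effective(params)
    vmax_pmol = params.vmax_umol_min * 1e6
    pa = params.passive_P_cm_s * params.membrane_area_cm2 * _PA_TO_PMOL_MIN

    donor_is_a = protocol.direction == "a_to_b"
    c_a = params.donor_c0_uM if donor_is_a else 0.0
    c_b = 0.0 if donor_is_a else params.donor_c0_uM
    v_a, v_b = params.volume_a_ul, params.volume_b_ul
    v_receiver = v_b if donor_is_a else v_a

    def deriv(y: np.ndarray) -> np.ndarray:
        flux_b = pa * (y[0] - y[1]) + _active_flux_into_b(
            y[0], y[1], params, km_eff, vmax_pmol
        )
        return np.array([-flux_b / v_a, flux_b / v_b])

    def rk4_span(y: np.ndarray, dt_total: float, n_steps: int) -> np.ndarray:
        h = dt_total / n_steps
        for _ in range(n_steps):
            k1 = deriv(y)
            k2 = deriv(y + 0.5 * h * k1)
            k3 = deriv(y + 0.5 * h * k2)
            k4 = deriv(y + h * k3)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        return y

    initial_mass = c_a * v_a + c_b * v_b
    removed_masses: List[float] = []
    times = [0.0]
    readings = [0.0]
    state = np.array([c_a, c_b])
    mass_rel_err = 0.0
    for _ in range(n_intervals):
        new_state = rk4_span(state, protocol.interval_min, steps_per_interval)
        if np.any(new_state < 0):
            new_state = rk4_span(state, protocol.interval_min, steps_per_interval * 10)
            new_state = np.clip(new_state, 0.0, None)
        state = new_state
        c_rec = state[1] if donor_is_a else state[0]
        reading = c_rec * (1.0 + params.noise_cv * rng.standard_normal())
        readings.append(max(reading, 0.0))
        times.append(times[-1] + protocol.interval_min)
        # withdraw the aliquot; fresh-buffer replacement dilutes the
        # receiver, 'none' shrinks its working volume instead
        removed_masses.append(c_rec * protocol.sample_volume_ul)
        if protocol.replacement == "fresh_buffer":
            c_rec *= (v_receiver - protocol.sample_volume_ul) / v_receiver
        else:
            v_receiver -= protocol.sample_volume_ul
            if v_receiver <= 0:
                raise ValidationError("receiver volume exhausted by sampling")
        if donor_is_a:
            state[1] = c_rec
            v_b = v_receiver
        else:
            state[0] = c_rec
            v_a = v_receiver
        total = state[0] * v_a + state[1] * v_b + sum(removed_masses)
        if initial_mass > 0:
            mass_rel_err = max(mass_rel_err, abs(total - initial_mass) / initial_mass)

    c0 = params.donor_c0_uM
    passive_flux0 = pa * c0
    active_at_c0 = (
        vmax_pmol * c0 / (km_eff + c0)
        if vmax_pmol > 0 and np.isfinite(km_eff)
        else 0.0
    )
    # active term only contributes at t=0 when its source side is the donor
    active_source_is_donor = params.active_direction == protocol.direction
    initial_flux = passive_flux0 + (active_at_c0 if active_source_is_donor else 0.0)
    if passive_flux0 > 0:
        if params.active_direction == "b_to_a":
            analytic_efflux_ratio = 1.0 + active_at_c0 / passive_flux0
        else:
            analytic_efflux_ratio = passive_flux0 / (passive_flux0 + active_at_c0)
    else:
        analytic_efflux_ratio = float("nan")

    series = SampleSeries(
        times=np.array(times),
        readings=np.array(readings),
        substrate="synthetic",
        condition="simulated",
        chip_id=f"sim-{params.seed}",
        direction=protocol.direction,
        time_unit="min",
        reading_unit="uM",
    )
    truth = SimTruth(
        params=params,
        derived={
            "km_effective_uM": km_eff,
            "initial_flux_pmol_min": initial_flux,
            "initial_receiver_rate_uM_min": initial_flux
            / (params.volume_b_ul if donor_is_a else params.volume_a_ul),
            "analytic_efflux_ratio": analytic_efflux_ratio,
            "removed_masses_pmol": tuple(removed_masses),
            "final_c_a_uM": float(state[0]),
            "final_c_b_uM": float(state[1]),
            "final_volume_a_ul": v_a,
            "final_volume_b_ul": v_b,
            "initial_mass_pmol": initial_mass,
            "mass_rel_error": mass_rel_err,
        },
    )
    return series, truth


def simulate_teer(
    asymptotes: Sequence[float] = (40.0, 20.0),
    rise_times_day: Sequence[float] = (3.0, 12.0),
    rise_widths_day: Union[float, Sequence[float]] = 0.5,
    noise_sigma: float = 1.0,
    dt_day: float = 0.5,
    duration_day: float = 20.0,
    baseline_ohm: float = 100.0,
    area_cm2: float = 0.1,
    label: str = "simulated",
    seed: int = 0,
) -> Tuple[TEERTrace, SimTruth]:
    """Logistic TEER growth with one or two plateaus plus Gaussian noise.

    The areal TEER is a sum of one or two logistic components,
    ``S(t) = Σ_i L_i / (1 + exp(−(t − t_i)/w_i))``; the plateau levels are
    the cumulative sums of the component amplitudes ``L_i`` (Ω·cm²). The
    defaults mimic a coculture-style trace: a first plateau near 40 Ω·cm²
    followed by saturation at 60 Ω·cm². ``noise_sigma`` is in Ω·cm²; the
    raw trace is returned in Ω against the recorded baseline and area.
    """
    asymptotes = tuple(float(a) for a in asymptotes)
    if len(asymptotes) not in (1, 2):
        raise ValidationError("asymptotes must list one or two levels")
    if len(rise_times_day) != len(asymptotes):
        raise ValidationError("one rise time per asymptote is required")
    if np.isscalar(rise_widths_day):
        widths = (float(rise_widths_day),) * len(asymptotes)
    else:
        widths = tuple(float(w) for w in rise_widths_day)
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_day + 0.5 * dt_day, dt_day)
    s = np.zeros_like(t)
    for level, t0, w in zip(asymptotes, rise_times_day, widths):
        s += level / (1.0 + np.exp(-(t - t0) / w))
    noisy = s + noise_sigma * rng.standard_normal(t.size)
    resistance = baseline_ohm + noisy / area_cm2
    trace = TEERTrace(
        times_day=t,
        resistance_ohm=resistance,
        baseline_ohm=baseline_ohm,
        area_cm2=area_cm2,
        label=label,
    )
    truth = SimTruth(
        params={
            "asymptotes": asymptotes,
            "rise_times_day": tuple(rise_times_day),
            "rise_widths_day": widths,
            "noise_sigma": noise_sigma,
            "dt_day": dt_day,
            "duration_day": duration_day,
            "baseline_ohm": baseline_ohm,
            "area_cm2": area_cm2,
            "seed": seed,
        },
        derived={
            "plateau_levels": tuple(np.cumsum(asymptotes)),
            "clean_teer": s,
        },
    )
    return trace, truth


def simulate_zstack(
    centers_um: Dict[str, float],
    sigmas_um: Union[float, Dict[str, float]] = 1.0,
    amplitudes: Union[float, Dict[str, float]] = 100.0,
    pitch_nm: float = 200.0,
    shape: Tuple[int, int, int] = (51, 24, 24),
    snr: float = 20.0,
    apical_direction: str = "increasing_z",
    scan_area_cm2: float = 0.1,
    seed: int = 0,
) -> Tuple[ZStack, SimTruth]:
    """Gaussian-slab confocal stack with Poisson-like shot noise.

    Each channel's intensity is a Gaussian profile along z (centre and σ
    in μm) constant across (y, x), sampled at the stated pitch. Noise is
    Poisson with a per-channel gain chosen so the signal-to-noise ratio at
    the profile peak equals ``snr`` per voxel. A DAPI channel plus at
    least one marker is required; the truth records the generating centres
    and the true marker-to-DAPI separations (signed apically).
    """
    if "DAPI" not in centers_um or len(centers_um) < 2:
        raise ValidationError("centers_um must include 'DAPI' and >= 1 marker")
    if snr <= 0:
        raise ValidationError("snr must be > 0")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    z = np.arange(nz) * pitch_nm * 1e-3

    def _lookup(value, channel):
        return float(value[channel]) if isinstance(value, dict) else float(value)

    channels = {}
    for name, centre in centers_um.items():
        sigma = _lookup(sigmas_um, name)
        amp = _lookup(amplitudes, name)
        profile = amp * np.exp(-0.5 * ((z - centre) / sigma) ** 2)
        clean = np.broadcast_to(profile[:, None, None], (nz, ny, nx))
        gain = snr**2 / amp  # Poisson: SNR at peak = sqrt(amp·gain)
        channels[name] = rng.poisson(clean * gain).astype(float) / gain
    stack = ZStack(
        channels=channels,
        z_pitch_nm=pitch_nm,
        apical_direction=apical_direction,
        scan_area_cm2=scan_area_cm2,
    )
    sign = 1.0 if apical_direction == "increasing_z" else -1.0
    truth = SimTruth(
        params={
            "centers_um": dict(centers_um),
            "sigmas_um": sigmas_um,
            "amplitudes": amplitudes,
            "pitch_nm": pitch_nm,
            "shape": shape,
            "snr": snr,
            "apical_direction": apical_direction,
            "seed": seed,
        },
        derived={
            "delta_d_true_um": {
                name: sign * (centre - centers_um["DAPI"])
                for name, centre in centers_um.items()
                if name != "DAPI"
            }
        },
    )
    return stack, truth


def simulate_morphometry(
    group_specs: Dict[str, Dict[str, float]],
    n_per_group: Union[int, Dict[str, int]] = 5,
    villi_per_record: int = 3,
    seed: int = 0,
) -> Tuple[List[MorphometryRecord], SimTruth]:
    """Truncated-normal TEM morphometry cohorts.

    ``group_specs`` maps a condition label to generating means/SDs with
    keys ``count_mean``, ``count_sd``, ``periphery_mean``,
    ``periphery_sd``, ``villus_mean``, ``villus_sd``, ``height_mean``,
    ``height_sd``. Draws are normal, truncated below at a small positive
    floor (counts are additionally rounded to integers ≥ 0).
    """
    if not group_specs:
        raise ValidationError("no group specifications supplied")
    rng = np.random.default_rng(seed)
    records: List[MorphometryRecord] = []
    for condition, spec in group_specs.items():
        n = n_per_group[condition] if isinstance(n_per_group, dict) else n_per_group
        if n < 1:
            raise ValidationError(f"group {condition!r} needs n >= 1")
        for _ in range(n):
            count = int(round(max(
                rng.normal(spec["count_mean"], spec.get("count_sd", 0.0)), 0.0
            )))
            periphery = max(
                rng.normal(spec["periphery_mean"], spec.get("periphery_sd", 0.0)),
                1e-3,
            )
            villi = tuple(
                max(rng.normal(spec["villus_mean"], spec.get("villus_sd", 0.0)), 1e-3)
                for _ in range(villi_per_record)
            )
            height = max(
                rng.normal(spec["height_mean"], spec.get("height_sd", 0.0)), 1e-3
            )
            records.append(
                MorphometryRecord(
                    protrusion_count=count,
                    periphery_length_um=periphery,
                    villi_lengths_um=villi,
                    cell_height_um=height,
                    condition=condition,
                )
            )
    truth = SimTruth(
        params={
            "group_specs": {k: dict(v) for k, v in group_specs.items()},
            "n_per_group": n_per_group,
            "villi_per_record": villi_per_record,
            "seed": seed,
        },
        derived={
            "group_means": {
                cond: {
                    "villi_density_per_um": spec["count_mean"]
                    / spec["periphery_mean"],
                    "villus_um": spec["villus_mean"],
                    "height_um": spec["height_mean"],
                }
                for cond, spec in group_specs.items()
            }
        },
    )
    return records, truth
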