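"""Synthetic msRMR tables and raw respirometry traces.

The generator reproduces the statistical structure the analysis assumes:

* a piecewise-linear Scholander-Irving thermal curve — a flat plateau of
  mass-specific resting metabolism between the lower and upper critical
  temperature, rising linearly outside it;
* per-animal additive random intercepts (shared across repeated
  measurements) and multiplicative Gamma measurement noise;
* the study design of the mole-rat colony: 14 non-reproductive animals
  measured at 13 temperatures (n = 11 at 40 deg C), 12 reproductive animals
  measured densely only at 28-33 deg C (n = 4 at peripheral temperatures);
* raw 1 Hz analyzer traces built by inverting the open-flow mass balance,
  with first-order chamber washout (tau = volume / flow), sensor noise,
  linear drift and Poisson activity bouts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .respirometry import (
    O2_SPAN_FRACTION,
    CalibrationPair,
    RespirometryTrace,
    stp_correct,
)

# ---------------------------------------------------------------------------
# Thermal curve


@dataclass(frozen=True)
class ThermalCurveParams:
    """Piecewise-linear thermal curve plus noise structure.

    plateau : msRMR inside the TNZ, ml O2 g^-1 h^-1
    lct_c, uct_c : true critical temperatures, deg C
    slope_low, slope_high : rise per deg C below/above the TNZ (>= 0)
    sigma_u : SD of the additive per-animal random intercept
    gamma_shape : Gamma shape k of the measurement noise (CV = k^-0.5)
    """

    plateau: float
    lct_c: float
    uct_c: float
    slope_low: float = 0.05
    slope_high: float = 0.08
    sigma_u: float = 0.05
    gamma_shape: float = 25.0

    def __post_init__(self) -> None:
        if not self.plateau > 0:
            raise ValueError("plateau must be positive")
        if not self.lct_c < self.uct_c:
            raise ValueError("lct_c must be below uct_c")
        if self.slope_low < 0 or self.slope_high < 0:
            raise ValueError("slopes must be >= 0")
        if not self.gamma_shape > 0:
            raise ValueError("gamma_shape must be positive")


#: Plateau levels anchored to the fitted status means (0.89 / 1.17) and the
#: status-specific TNZ boundaries (26-30 and 28-33 deg C).
NONREPRODUCTIVE_CURVE = ThermalCurveParams(plateau=0.89, lct_c=26.0, uct_c=30.0)
REPRODUCTIVE_CURVE = ThermalCurveParams(plateau=1.17, lct_c=28.0, uct_c=33.0)


def scholander_mean(ta_c, params: ThermalCurveParams):
    """Expected msRMR at ambient temperature(s) ``ta_c``."""
    ta = np.asarray(ta_c, dtype=float)
    out = np.full_like(ta, params.plateau, dtype=float)
    below = ta < params.lct_c
    above = ta > params.uct_c
    out = np.where(below, params.plateau + params.slope_low * (params.lct_c - ta), out)
    out = np.where(above, params.plateau + params.slope_high * (ta - params.uct_c), out)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Study design

#: Measurement schedule of the colony: (temperature, sample size).
NONREPRODUCTIVE_SCHEDULE = [(t, 14) for t in (10, 15, 20, 25, 26, 28, 30, 32,
                                              33, 34, 35, 37)] + [(40, 11)]
REPRODUCTIVE_SCHEDULE = [(t, 4) for t in (20, 25, 26)] + \
    [(t, 12) for t in (28, 30, 32, 33)] + [(t, 4) for t in (34, 35, 37)]

#: Roster moments per (status, sex): (n, mass mean, mass SD, age mean, age SD).
ROSTER_MOMENTS = {
    ("R", "M"): (6, 83.9, 10.5, 6.9, 2.4),
    ("NR", "M"): (6, 108.8, 21.4, 4.8, 2.8),
    ("R", "F"): (6, 87.2, 21.8, 8.9, 3.1),
    ("NR", "F"): (8, 68.2, 8.9, 2.4, 1.2),
}


@dataclass
class StudyDesign:
    """Measurement schedule plus the animal roster it draws on."""

    status: str                       # "NR" | "R"
    schedule: list[tuple[float, int]]
    n_animals: int

    def roster(self, rng: np.random.Generator) -> pd.DataFrame:
        rows = []
        idx = 0
        for (status, sex), (n, mm, ms, am, asd) in ROSTER_MOMENTS.items():
            if status != self.status:
                continue
            for _ in range(n):
                mass = max(float(rng.normal(mm, ms)), 20.0)
                age = max(float(rng.normal(am, asd)), 0.5)
                rows.append({
                    "animal_id": f"{status}{idx:02d}",
                    "sex": sex,
                    "status": status,
                    "body_mass_g": round(mass, 1),
                    "age_y": round(age, 1),
                })
                idx += 1
        df = pd.DataFrame(rows)
        assert len(df) == self.n_animals
        return df


def nonreproductive_design(within_tnz: bool = False,
                           curve: ThermalCurveParams = NONREPRODUCTIVE_CURVE
                           ) -> StudyDesign:
    sched = NONREPRODUCTIVE_SCHEDULE
    if within_tnz:
        sched = [(t, 14) for t, _ in sched if curve.lct_c <= t <= curve.uct_c]
    return StudyDesign("NR", [(float(t), n) for t, n in sched], 14)


def reproductive_design(within_tnz: bool = False,
                        curve: ThermalCurveParams = REPRODUCTIVE_CURVE
                        ) -> StudyDesign:
    sched = REPRODUCTIVE_SCHEDULE
    if within_tnz:
        sched = [(t, 12) for t, n in sched if curve.lct_c <= t <= curve.uct_c]
    return StudyDesign("R", [(float(t), n) for t, n in sched], 12)


def simulate_msrmr_table(design: StudyDesign, params: ThermalCurveParams,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Tidy msRMR table for one study design.

    Per animal i a random intercept u_i ~ N(0, sigma_u) is drawn once and
    shared across its repeated measurements; each measurement at temperature
    T has mean mu = scholander_mean(T) + u_i and is Gamma(k, mu/k)
    distributed. Should u_i push any scheduled mean non-positive (possible
    only for extreme parameter choices), u_i is redrawn.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    roster = design.roster(rng)
    temps = np.array([t for t, _ in design.schedule])
    base = scholander_mean(temps, params)
    u = np.empty(len(roster))
    for i in range(len(roster)):
        for _ in range(1000):
            ui = rng.normal(0.0, params.sigma_u)
            if np.all(base + ui > 0):
                u[i] = ui
                break
        else:  # pragma: no cover - requires pathological parameters
            raise RuntimeError("could not draw a valid random intercept")
    rows = []
    for (ta, n), mu_base in zip(design.schedule, base):
        if n > len(roster):
            raise ValueError(f"schedule asks for {n} animals, roster has "
                             f"{len(roster)}")
        chosen = np.sort(rng.choice(len(roster), size=n, replace=False))
        for i in chosen:
            mu = mu_base + u[i]
            value = rng.gamma(shape=params.gamma_shape,
                              scale=mu / params.gamma_shape)
            rows.append({
                **roster.iloc[i].to_dict(),
                "ta_c": float(ta),
                "msrmr": float(value),
            })
    return pd.DataFrame(rows)


def simulate_study(seed: int | None = None,
                   nr_curve: ThermalCurveParams = NONREPRODUCTIVE_CURVE,
                   r_curve: ThermalCurveParams = REPRODUCTIVE_CURVE,
                   within_tnz: bool = False) -> pd.DataFrame:
    """Both statuses' tables stacked (the full colony experiment)."""
    rng = np.random.default_rng(seed)
    nr = simulate_msrmr_table(nonreproductive_design(within_tnz, nr_curve),
                              nr_curve, rng=rng)
    r = simulate_msrmr_table(reproductive_design(within_tnz, r_curve),
                             r_curve, rng=rng)
    return pd.concat([nr, r], ignore_index=True)


# ---------------------------------------------------------------------------
# Raw trace simulation


@dataclass(frozen=True)
class TraceParams:
    """Chamber, sensor and behaviour parameters for trace simulation."""

    chamber_volume_ml: float = 896.0
    flow_ml_min: float = 350.0
    fi_o2: float = O2_SPAN_FRACTION
    sensor_noise_sd: float = 2e-4      # raw sensor units per sample
    drift_per_hour: float = -5e-4      # raw-unit baseline drift
    zero_raw: float = 0.05             # sensor reading on the zero gas at t=0
    span_raw: float = 0.95             # sensor reading on the span gas at t=0
    bout_rate_per_h: float = 2.0       # Poisson activity-bout arrivals
    bout_multiplier: float = 2.5       # VO2 elevation during a bout
    bout_duration_s: float = 120.0
    sample_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        if self.chamber_volume_ml <= 0 or self.flow_ml_min <= 0:
            raise ValueError("volume and flow must be positive")

    @property
    def washout_tau_s(self) -> float:
        """First-order washout time constant: volume / flow."""
        return 60.0 * self.chamber_volume_ml / self.flow_ml_min


def lighton_inverse_fe(vo2_ml_min, flow_ml_min, fi_o2=O2_SPAN_FRACTION):
    """Steady-state excurrent fraction for a given oxygen consumption:
    fe = (F_ri * FiO2 - VO2) / (F_ri - VO2), the exact inverse of the
    open-flow mass balance."""
    vo2 = np.asarray(vo2_ml_min, dtype=float)
    if np.any(vo2 >= flow_ml_min):
        raise ValueError("VO2 >= flow is nonphysical in an open-flow system")
    out = (flow_ml_min * fi_o2 - vo2) / (flow_ml_min - vo2)
    return out if out.ndim else float(out)


def simulate_trace(resting_vo2_stp_ml_min: float,
                   params: TraceParams = TraceParams(),
                   duration_s: float = 4800.0,
                   ta_c: float = 28.0,
                   pressure_kpa: float = 101.325,
                   body_mass_g: float = 85.0,
                   animal_id: str = "SYN",
                   trial_id: str = "SYN-T1",
                   seed: int | None = None,
                   rng: np.random.Generator | None = None):
    """Simulate one trial's raw trace from a known resting VO2 (at STP).

    The true instantaneous VO2 is the resting level times the bout
    multiplier during Poisson-arriving activity bouts. The excurrent
    fraction relaxes toward the Lighton-inverse steady state with the
    chamber washout time constant; sensor noise and linear drift are added
    on the raw scale and the matching start/end calibration pairs are
    returned.

    Returns ``(trace, start_cal, end_cal, truth)`` where ``truth`` holds the
    generator's resting VO2 (STP, ml min^-1), RMR (ml h^-1) and msRMR.
    """
    if resting_vo2_stp_ml_min < 0:
        raise ValueError("resting VO2 must be >= 0")
    if duration_s < 2400:
        raise ValueError("duration must be >= 2400 s (acclimation + window)")
    if rng is None:
        rng = np.random.default_rng(seed)

    dt = 1.0 / params.sample_rate_hz
    t = np.arange(0.0, duration_s, dt)
    n = t.size

    # ambient-condition VO2 whose STP correction returns the requested value
    stp_factor = stp_correct(1.0, ta_c, pressure_kpa)
    vo2_amb = resting_vo2_stp_ml_min / stp_factor

    active = np.zeros(n, dtype=bool)
    n_bouts = rng.poisson(params.bout_rate_per_h * duration_s / 3600.0)
    for start in np.sort(rng.uniform(0.0, duration_s, size=n_bouts)):
        i0 = int(start / dt)
        i1 = min(n, i0 + int(params.bout_duration_s / dt))
        active[i0:i1] = True
    vo2_true = np.where(active, vo2_amb * params.bout_multiplier, vo2_amb)

    fe_ss = lighton_inverse_fe(vo2_true, params.flow_ml_min, params.fi_o2)
    alpha = np.exp(-dt / params.washout_tau_s)
    fe = np.empty(n)
    prev = params.fi_o2               # chamber starts flushed with fresh air
    for i in range(n):
        prev = fe_ss[i] + (prev - fe_ss[i]) * alpha
        fe[i] = prev

    gain = (params.span_raw - params.zero_raw) / O2_SPAN_FRACTION
    drift = params.drift_per_hour * t / 3600.0
    raw = params.zero_raw + fe * gain + drift \
        + rng.normal(0.0, params.sensor_noise_sd, size=n)

    end_drift = params.drift_per_hour * duration_s / 3600.0
    start_cal = CalibrationPair(params.zero_raw, params.span_raw, time_s=0.0)
    end_cal = CalibrationPair(params.zero_raw + end_drift,
                              params.span_raw + end_drift, time_s=duration_s)

    trace = RespirometryTrace(
        timestamps=t,
        raw_o2=raw,
        chamber_temp_c=np.full(n, ta_c),
        flow_ml_min=params.flow_ml_min,
        pressure_kpa=pressure_kpa,
        incurrent_o2_fraction=params.fi_o2,
        animal_id=animal_id,
        trial_id=trial_id,
        body_mass_g=body_mass_g,
    )
    truth = {
        "resting_vo2_stp_ml_min": resting_vo2_stp_ml_min,
        "rmr_ml_h": resting_vo2_stp_ml_min * 60.0,
        "msrmr": resting_vo2_stp_ml_min * 60.0 / body_mass_g,
        "tau_s": params.washout_tau_s,
    }
    return trace, start_cal, end_cal, truth


def quiet_trace_params(params: TraceParams = TraceParams()) -> TraceParams:
    """The same chamber/sensor but no activity bouts (calm animal)."""
    return replace(params, bout_rate_per_h=0.0)
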