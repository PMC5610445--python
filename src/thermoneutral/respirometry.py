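"""Open-flow respirometry processing.

Converts raw oxygen-analyzer traces into calibrated excurrent O2 fractions,
instantaneous oxygen consumption (VO2, Lighton mass-balance equation with
CO2 and water scrubbed upstream of the sensor), STP-corrected rates, and a
resting metabolic rate (RMR) defined as the lowest stable 10-minute mean of
VO2 after an acclimation period.

Units convention: flow and instantaneous VO2 in ml O2 min^-1; RMR is
reported in ml O2 h^-1 and mass-specific RMR (msRMR) in ml O2 g^-1 h^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fractional O2 content of the span gas (dry outdoor air).
O2_SPAN_FRACTION = 0.2095
STANDARD_TEMP_K = 273.15
STANDARD_PRESSURE_KPA = 101.325

#: Calibrated fractions outside this interval are flagged out-of-calibration.
FRACTION_BOUNDS = (-0.01, 0.25)


class CalibrationError(ValueError):
    """Raised when a two-point calibration is unusable (span <= zero)."""


class TraceTooShortError(ValueError):
    """Raised when a VO2 series cannot hold a single analysis window."""


@dataclass(frozen=True)
class CalibrationPair:
    """Raw sensor readings against the zero gas (pure N2, 0% O2) and the
    span gas (outdoor air, 20.95% O2) taken at one point in time."""

    zero_reading: float
    span_reading: float
    time_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.span_reading > self.zero_reading:
            raise CalibrationError(
                f"span reading ({self.span_reading}) must exceed zero reading "
                f"({self.zero_reading})"
            )


@dataclass
class RespirometryTrace:
    """One trial's raw 1 Hz time series plus the per-trial conditions."""

    timestamps: np.ndarray          # seconds from trial start
    raw_o2: np.ndarray              # uncalibrated sensor values
    chamber_temp_c: np.ndarray      # deg C, per sample
    flow_ml_min: float = 350.0      # incurrent flow, constant per trial
    pressure_kpa: float = STANDARD_PRESSURE_KPA
    incurrent_o2_fraction: float = O2_SPAN_FRACTION
    animal_id: str = ""
    trial_id: str = ""
    body_mass_g: float = float("nan")

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.raw_o2 = np.asarray(self.raw_o2, dtype=float)
        self.chamber_temp_c = np.broadcast_to(
            np.asarray(self.chamber_temp_c, dtype=float), self.timestamps.shape
        ).copy()
        if self.timestamps.size == 0:
            raise ValueError("empty trace")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.flow_ml_min > 0:
            raise ValueError("flow_ml_min must be positive")
        if not 0 < self.incurrent_o2_fraction < 1:
            raise ValueError("incurrent_o2_fraction must lie in (0, 1)")

    @property
    def duration_s(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class VO2Series:
    """Calibrated, STP-corrected oxygen consumption with per-sample flags.

    ``negative_drawdown`` marks samples where the excurrent fraction exceeds
    the incurrent one (VO2 < 0); ``out_of_calibration`` marks samples whose
    calibrated fraction left the physically plausible band. Flagged samples
    are excluded from RMR windows.
    """

    timestamps: np.ndarray
    vo2_ml_min: np.ndarray
    negative_drawdown: np.ndarray = field(default=None)  # type: ignore[assignment]
    out_of_calibration: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.vo2_ml_min = np.asarray(self.vo2_ml_min, dtype=float)
        n = self.timestamps.size
        if self.negative_drawdown is None:
            self.negative_drawdown = np.zeros(n, dtype=bool)
        if self.out_of_calibration is None:
            self.out_of_calibration = np.zeros(n, dtype=bool)
        self.negative_drawdown = np.asarray(self.negative_drawdown, dtype=bool)
        self.out_of_calibration = np.asarray(self.out_of_calibration, dtype=bool)

    @property
    def flagged(self) -> np.ndarray:
        return self.negative_drawdown | self.out_of_calibration


@dataclass
class RmrResult:
    """Lowest stable window summary for one trial."""

    rmr_ml_h: float
    msrmr: float
    window_start_s: float
    window_end_s: float
    window_cv: float
    valid: bool
    reason: str = ""


def calibrate_trace(
    trace: RespirometryTrace,
    start_cal: CalibrationPair,
    end_cal: CalibrationPair | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Map raw sensor values to fractional O2 by a drifting two-point line.

    Zero and span readings are linearly interpolated in time between the
    start and end calibration pairs, correcting linear sensor drift. With no
    end pair the start calibration is used throughout (with a warning).

    Returns ``(fraction, out_of_calibration)`` where the boolean array flags
    samples outside ``FRACTION_BOUNDS``.
    """
    t = trace.timestamps
    if end_cal is None:
        warnings.warn(
            f"trial {trace.trial_id or '<unnamed>'}: no end calibration; "
            "using start calibration without drift correction",
            stacklevel=2,
        )
        zero = np.full_like(t, start_cal.zero_reading)
        span = np.full_like(t, start_cal.span_reading)
    else:
        tp = [start_cal.time_s, end_cal.time_s]
        zero = np.interp(t, tp, [start_cal.zero_reading, end_cal.zero_reading])
        span = np.interp(t, tp, [start_cal.span_reading, end_cal.span_reading])
    fraction = O2_SPAN_FRACTION * (trace.raw_o2 - zero) / (span - zero)
    lo, hi = FRACTION_BOUNDS
    out = (fraction < lo) | (fraction > hi) | ~np.isfinite(fraction)
    return fraction, out


def compute_vo2(fi_o2, fe_o2, flow_ml_min):
    """Oxygen consumption from the open-flow mass balance (Lighton):

        VO2 = F_ri * (FiO2 - FeO2) / (1 - FeO2)

    valid when CO2 and water are scrubbed before the analyzer. Accepts
    scalars or arrays; negative results (excurrent above incurrent) are
    returned as-is so the caller can flag them.
    """
    fe = np.asarray(fe_o2, dtype=float)
    if np.any(fe >= 1.0):
        raise ValueError("excurrent O2 fraction must be < 1")
    if np.any(np.asarray(flow_ml_min) <= 0):
        raise ValueError("flow must be positive")
    out = np.asarray(flow_ml_min, dtype=float) * (np.asarray(fi_o2, float) - fe) / (1.0 - fe)
    return out if out.ndim else float(out)


def stp_correct(vo2, temp_c, pressure_kpa=STANDARD_PRESSURE_KPA):
    """Convert a volumetric rate at ambient conditions to STP
    (273.15 K, 101.325 kPa) by the ideal-gas factor."""
    temp_c = np.asarray(temp_c, dtype=float)
    if np.any(temp_c <= -STANDARD_TEMP_K):
        raise ValueError("temperature below absolute zero")
    if np.any(np.asarray(pressure_kpa) <= 0):
        raise ValueError("pressure must be positive")
    out = (
        np.asarray(vo2, dtype=float)
        * (STANDARD_TEMP_K / (temp_c + STANDARD_TEMP_K))
        * (np.asarray(pressure_kpa, dtype=float) / STANDARD_PRESSURE_KPA)
    )
    return out if out.ndim else float(out)


def trace_to_vo2(
    trace: RespirometryTrace,
    start_cal: CalibrationPair,
    end_cal: CalibrationPair | None = None,
) -> VO2Series:
    """Full per-sample chain: calibrate, Lighton equation, STP correction."""
    fraction, out_of_cal = calibrate_trace(trace, start_cal, end_cal)
    safe = np.clip(fraction, None, 0.999)
    vo2 = compute_vo2(trace.incurrent_o2_fraction, safe, trace.flow_ml_min)
    vo2 = stp_correct(vo2, trace.chamber_temp_c, trace.pressure_kpa)
    return VO2Series(
        timestamps=trace.timestamps,
        vo2_ml_min=vo2,
        negative_drawdown=np.asarray(vo2) < 0,
        out_of_calibration=out_of_cal,
    )


def extract_rmr(
    series: VO2Series,
    body_mass_g: float,
    window_s: float = 600.0,
    acclimation_s: float = 1800.0,
    stability_cv: float = 0.10,
) -> RmrResult:
    """Lowest stable mean VO2 over a sliding window after acclimation.

    Scans every contiguous window of ``window_s`` starting at or after
    ``acclimation_s`` (set 0 to disable for short protocols). Windows
    containing flagged samples are excluded; remaining windows must satisfy
    the stability criterion CV <= ``stability_cv``. The admissible window
    with the smallest mean defines RMR (in ml h^-1) and msRMR = RMR / mass.
    """
    if not body_mass_g > 0:
        raise ValueError("body_mass_g must be positive")
    t = series.timestamps
    n = t.size
    if n < 2:
        raise TraceTooShortError("series has fewer than two samples")
    dt = float(np.median(np.diff(t)))
    if not np.allclose(np.diff(t), dt, atol=1e-6):
        raise ValueError("extract_rmr requires a uniformly sampled series")
    w = int(round(window_s / dt))
    if w < 2 or w > n:
        raise TraceTooShortError(
            f"series ({n} samples) shorter than one {window_s} s window"
        )
    first = int(np.searchsorted(t, t[0] + acclimation_s))
    if first > n - w:
        raise TraceTooShortError(
            "series shorter than acclimation period plus one window"
        )

    x = series.vo2_ml_min
    bad = series.flagged.astype(float)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    csum2 = np.concatenate(([0.0], np.cumsum(x * x)))
    cbad = np.concatenate(([0.0], np.cumsum(bad)))
    starts = np.arange(first, n - w + 1)
    means = (csum[starts + w] - csum[starts]) / w
    var = (csum2[starts + w] - csum2[starts]) / w - means**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    clean = (cbad[starts + w] - cbad[starts]) == 0

    if not np.any(clean):
        return RmrResult(np.nan, np.nan, np.nan, np.nan, np.nan, False, "no-clean-window")
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means > 0, sd / means, np.inf)
    admissible = clean & (cv <= stability_cv) & (means > 0)
    if not np.any(admissible):
        return RmrResult(np.nan, np.nan, np.nan, np.nan, np.nan, False, "no-stable-window")
    idx = np.flatnonzero(admissible)
    best = idx[np.argmin(means[idx])]
    mean_vo2 = float(means[best])
    rmr = mean_vo2 * 60.0
    return RmrResult(
        rmr_ml_h=rmr,
        msrmr=rmr / body_mass_g,
        window_start_s=float(t[starts[best]]),
        window_end_s=float(t[starts[best]] + window_s),
        window_cv=float(cv[best]),
        valid=True,
    )


# ---------------------------------------------------------------------------
# File I/O (plain CSV/TSV, schemas documented in the README)

def read_trace_csv(
    path,
    animal_id: str = "",
    trial_id: str = "",
    body_mass_g: float = float("nan"),
) -> RespirometryTrace:
    """Read a raw trace CSV with columns
    ``time_s,raw_o2,chamber_temp_c,flow_ml_min,pressure_kpa``."""
    df = pd.read_csv(path)
    required = {"time_s", "raw_o2", "chamber_temp_c", "flow_ml_min", "pressure_kpa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return RespirometryTrace(
        timestamps=df["time_s"].to_numpy(),
        raw_o2=df["raw_o2"].to_numpy(),
        chamber_temp_c=df["chamber_temp_c"].to_numpy(),
        flow_ml_min=float(df["flow_ml_min"].iloc[0]),
        pressure_kpa=float(df["pressure_kpa"].iloc[0]),
        animal_id=animal_id,
        trial_id=trial_id,
        body_mass_g=body_mass_g,
    )


def read_calibration_csv(path) -> dict[str, dict[str, CalibrationPair]]:
    """Read calibration CSV ``trial_id,when,zero_reading,span_reading[,time_s]``
    into ``{trial_id: {"start": pair, "end": pair}}``."""
    df = pd.read_csv(path)
    out: dict[str, dict[str, CalibrationPair]] = {}
    for _, row in df.iterrows():
        when = str(row["when"]).lower()
        if when not in ("start", "end"):
            raise ValueError(f"{path}: 'when' must be start or end, got {when!r}")
        pair = CalibrationPair(
            zero_reading=float(row["zero_reading"]),
            span_reading=float(row["span_reading"]),
            time_s=float(row.get("time_s", 0.0) if "time_s" in df.columns else 0.0),
        )
        out.setdefault(str(row["trial_id"]), {})[when] = pair
    return out
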