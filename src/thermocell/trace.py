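"""Device trace logs and trace-level statistics.

A :class:`TemperatureTrace` is the (time, temperature, setpoint, PWM) series
the controller logs every sample (0.5 s by default), in the same shape the
device's visualization tool saves to CSV.  This module reads/writes that CSV
dialect and computes the statistics used to characterize a run: 1-min
binning, post-equilibration stability, time-to-band equilibration, and
exponential heating/cooling time constants fitted to normalized transitions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

CSV_COLUMNS = ["time_s", "temp_C", "setpoint_C", "pwm"]


class TraceValidationError(ValueError):
    """Trace violates its invariants (non-monotone time, PWM out of range)."""


class TraceParseError(ValueError):
    """Trace CSV is malformed; message names the offending line."""


@dataclass(frozen=True)
class TemperatureTrace:
    """Logged controller run: time (s), measured T, setpoint, PWM per sample."""

    time_s: np.ndarray
    temp_c: np.ndarray
    setpoint_c: np.ndarray
    pwm: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if n == 0:
            raise TraceValidationError("trace is empty")
        for name in ("temp_c", "setpoint_c", "pwm"):
            if len(getattr(self, name)) != n:
                raise TraceValidationError("trace columns have unequal lengths")
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            raise TraceValidationError("time must be strictly increasing")
        if np.any(self.pwm < 0) or np.any(self.pwm > 255):
            raise TraceValidationError("pwm out of [0, 255]")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def slice(self, t_start: float, t_end: float) -> "TemperatureTrace":
        """Sub-trace with t_start <= time < t_end."""
        sel = (self.time_s >= t_start) & (self.time_s < t_end)
        if not np.any(sel):
            raise TraceValidationError(
                f"no samples in [{t_start}, {t_end}) s"
            )
        return TemperatureTrace(
            self.time_s[sel], self.temp_c[sel], self.setpoint_c[sel], self.pwm[sel]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "temp_C": self.temp_c,
                "setpoint_C": self.setpoint_c,
                "pwm": self.pwm,
            }
        )

    @staticmethod
    def from_dataframe(df: pd.DataFrame) -> "TemperatureTrace":
        return TemperatureTrace(
            np.asarray(df["time_s"], dtype=float),
            np.asarray(df["temp_C"], dtype=float),
            np.asarray(df["setpoint_C"], dtype=float),
            np.asarray(df["pwm"], dtype=float),
        )


def write_trace_csv(trace: TemperatureTrace, path: str | Path) -> None:
    trace.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def read_trace_csv(path: str | Path) -> TemperatureTrace:
    """Read a trace CSV (header ``time_s,temp_C,setpoint_C,pwm``).

    Malformed rows raise :class:`TraceParseError` naming the 1-based line
    number (header = line 1).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TraceParseError(f"{path}: empty file") from exc
    if list(df.columns) != CSV_COLUMNS:
        raise TraceParseError(
            f"{path}: line 1: expected header {','.join(CSV_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    for col in CSV_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & ~df[col].isna()
        bad |= df[col].isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise TraceParseError(f"{path}: line {line}: non-numeric value in '{col}'")
        df[col] = coerced
    return TemperatureTrace.from_dataframe(df)


def bin_trace(trace: TemperatureTrace, window_s: float = 60.0) -> pd.DataFrame:
    """Tile the trace into fixed windows; mean and sd of temperature per bin.

    Returns a DataFrame (bin_center_s, mean_C, sd_C, n).  Windows are
    non-overlapping, anchored at the first sample; a partial final window is
    included.  The sd is the population standard deviation.
    """
    if not window_s > 0:
        raise ValueError("window must be positive")
    t0 = trace.time_s[0]
    idx = np.floor((trace.time_s - t0) / window_s).astype(int)
    rows = []
    for k in np.unique(idx):
        vals = trace.temp_c[idx == k]
        rows.append(
            (t0 + (k + 0.5) * window_s, float(vals.mean()), float(vals.std()), len(vals))
        )
    return pd.DataFrame(rows, columns=["bin_center_s", "mean_C", "sd_C", "n"])


@dataclass(frozen=True)
class StabilityStats:
    mean_c: float
    sd_c: float
    max_abs_error_c: float
    max_windowed_sd_c: float


def stability_stats(
    trace: TemperatureTrace, after_s: float, window_s: float = 180.0
) -> StabilityStats:
    """Stability of the controlled temperature for samples with t >= after_s.

    Reports the mean and sd of the measured temperature, the maximum
    |T - setpoint| deviation, and the largest per-window sd over tiled
    windows (3 min by default) — the same windowed-error summary used to
    characterize maintenance runs.
    """
    sel = trace.time_s >= after_s
    if not np.any(sel):
        raise TraceValidationError(f"no samples at or after t = {after_s} s")
    temps = trace.temp_c[sel]
    errs = np.abs(temps - trace.setpoint_c[sel])
    sub = TemperatureTrace(
        trace.time_s[sel], temps, trace.setpoint_c[sel], trace.pwm[sel]
    )
    binned = bin_trace(sub, window_s)
    return StabilityStats(
        mean_c=float(temps.mean()),
        sd_c=float(temps.std()),
        max_abs_error_c=float(errs.max()),
        max_windowed_sd_c=float(binned["sd_C"].max()),
    )


def equilibration_time(
    trace: TemperatureTrace, target_c: float, band_c: float = 0.3
) -> float | None:
    """Minutes (from trace start) until |T - target| enters and holds a band.

    Returns the first time after which every remaining sample satisfies
    |T - target| <= band; 0.0 if the whole trace is inside the band; ``None``
    if the trace never settles (the final sample is outside the band or the
    band is never entered for good).
    """
    outside = np.abs(trace.temp_c - target_c) > band_c
    if not outside.any():
        return 0.0
    last_out = int(np.flatnonzero(outside)[-1])
    if last_out == len(trace) - 1:
        return None
    t_settle = trace.time_s[last_out + 1] - trace.time_s[0]
    return float(t_settle) / 60.0


@dataclass(frozen=True)
class FitResult:
    """Fitted exponential time constant with 95% CI and residual scale."""

    tau_min: float
    ci95_min: tuple[float, float]
    rmse_c: float

    def __post_init__(self) -> None:
        if not self.tau_min > 0:
            raise ValueError("tau must be positive")
        lo, hi = self.ci95_min
        if not (lo <= self.tau_min <= hi):
            raise ValueError("tau must lie inside its confidence interval")


def _normalize_segment(
    trace: TemperatureTrace,
    t_start: float,
    t_end: float,
    baseline_window_s: float,
    plateau_window_s: float,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Times (s, from t_start) and normalized response in [0, 1].

    baseline = mean over the window just before t_start (or the first sample
    if the trace starts at t_start); plateau = mean over the final window of
    the segment.
    """
    seg_sel = (trace.time_s >= t_start) & (trace.time_s <= t_end)
    if not np.any(seg_sel):
        raise TraceValidationError("segment contains no samples")
    t = trace.time_s[seg_sel] - t_start
    y = trace.temp_c[seg_sel]
    pre_sel = (trace.time_s >= t_start - baseline_window_s) & (trace.time_s < t_start)
    baseline = float(trace.temp_c[pre_sel].mean()) if np.any(pre_sel) else float(y[0])
    plat_sel = t >= (t[-1] - plateau_window_s)
    plateau = float(y[plat_sel].mean())
    span = plateau - baseline
    if abs(span) < 1e-9:
        raise TraceValidationError(
            "degenerate segment: baseline and plateau coincide (no transition)"
        )
    return t, (y - baseline) / span, baseline, plateau


def _fit_exponential(
    t_s: np.ndarray,
    y_norm: np.ndarray,
    rising: bool,
    span_c: float,
) -> FitResult:
    if rising:
        model = lambda t, a, b, tau: a + b * (1.0 - np.exp(-t / tau))  # noqa: E731
    else:
        model = lambda t, a, b, tau: a + b * np.exp(-t / tau)  # noqa: E731
        y_norm = 1.0 - y_norm  # normalized decay: 1 at t_start, 0 at plateau
    resid_span = np.ptp(y_norm)
    if resid_span < 0.1:
        raise TraceValidationError("segment shows no usable transition")
    # crude monotonicity check (beyond-noise wiggles flag a poor segment)
    smooth = np.convolve(y_norm, np.ones(5) / 5.0, mode="valid")
    backstep = np.min(np.diff(smooth)) if rising else -np.max(np.diff(smooth))
    if backstep < -0.05:
        warnings.warn(
            "transition segment is non-monotone beyond noise; fit may be poor",
            stacklevel=3,
        )
    # amplitude/offset are nuisance parameters: the normalization anchors
    # them near (0, 1), but letting them float propagates baseline/plateau
    # estimation noise into the tau confidence interval
    p0 = [0.0, 1.0, max(t_s[-1] / 5.0, 1e-3)]
    popt, pcov = curve_fit(model, t_s, y_norm, p0=p0, maxfev=10000)
    tau = float(popt[2])
    if not tau > 0:
        raise TraceValidationError(f"fit produced nonpositive tau {tau}")
    stderr = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else 0.0
    resid = y_norm - model(t_s, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)) * abs(span_c))
    lo, hi = tau - 1.96 * stderr, tau + 1.96 * stderr
    return FitResult(
        tau_min=tau / 60.0,
        ci95_min=(max(lo, 0.0) / 60.0, hi / 60.0),
        rmse_c=rmse,
    )


def fit_heating_constant(
    trace: TemperatureTrace,
    t_start: float,
    t_end: float,
    baseline_window_s: float = 60.0,
    plateau_window_s: float = 60.0,
) -> FitResult:
    """Fit ``1 - exp(-t/tau_h)`` to a normalized heating transition.

    The segment [t_start, t_end] is normalized to [0, 1] using the pre-shift
    baseline (mean of the minute before t_start) and the post-shift plateau
    (mean of the final minute); tau and its 95% CI come from a scalar
    least-squares fit.
    """
    t, y, baseline, plateau = _normalize_segment(
        trace, t_start, t_end, baseline_window_s, plateau_window_s
    )
    return _fit_exponential(t, y, rising=True, span_c=plateau - baseline)


def fit_cooling_constant(
    trace: TemperatureTrace,
    t_start: float,
    t_end: float,
    baseline_window_s: float = 60.0,
    plateau_window_s: float = 60.0,
) -> FitResult:
    """Fit ``exp(-t/tau_c)`` to a normalized passive-cooling transition."""
    t, y, baseline, plateau = _normalize_segment(
        trace, t_start, t_end, baseline_window_s, plateau_window_s
    )
    return _fit_exponential(t, y, rising=False, span_c=plateau - baseline)


def setpoint_transitions(trace: TemperatureTrace) -> list[tuple[float, float, float]]:
    """Times at which the logged setpoint changes.

    Returns a list of (time_s, old_setpoint, new_setpoint).
    """
    changes = np.flatnonzero(np.diff(trace.setpoint_c) != 0)
    return [
        (
            float(trace.time_s[i + 1]),
            float(trace.setpoint_c[i]),
            float(trace.setpoint_c[i + 1]),
        )
        for i in changes
    ]
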