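"""Fast-inactivation statistics from whole-cell current traces.

Currents recorded during a hyperpolarizing voltage step (0 to -160 mV,
60 ms, digitized at 10 kHz) are summarized by two numbers: the residual
current — the ratio of the mean current over the last 5 ms of the pulse to
the mean over the first 5 ms (1 = no inactivation) — and the time constant
tau of a single-exponential decay

    i(t) = i_inf + (i0 - i_inf) * exp(-(t - t_pulse) / tau)

fitted over the pulse window.  tau is reported only for traces that actually
decay; flat traces return ``converged=False`` with tau absent.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Sequence, TextIO

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import TraceError, UnstableRatioError

logger = logging.getLogger(__name__)


@dataclass
class CurrentTrace:
    """One uniformly sampled whole-cell current trace.

    ``t`` in ms, ``i`` in pA; the pulse window [pulse_start,
    pulse_start + pulse_duration) must lie inside the trace.  Holding and
    step potentials are carried as metadata only.
    """

    t: np.ndarray
    i: np.ndarray
    sampling_rate: float = 10000.0  # Hz
    pulse_start: float = 0.0  # ms
    pulse_duration: float = 60.0  # ms
    holding_mV: float = 0.0
    step_mV: float = -160.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.t.shape != self.i.shape or self.t.ndim != 1 or self.t.size < 2:
            raise TraceError("t and i must be equal-length 1-D arrays with >= 2 samples")
        step = np.diff(self.t)
        expected = 1000.0 / self.sampling_rate
        if np.any(step <= 0) or not np.allclose(step, expected, rtol=1e-6, atol=1e-9):
            raise TraceError(
                f"t must increase in constant steps of {expected} ms "
                f"(1000 / sampling_rate)"
            )
        if self.pulse_start < self.t[0] - 1e-9 or self.pulse_end > self.t[-1] + expected:
            raise TraceError("pulse window extends outside the trace")

    @property
    def pulse_end(self) -> float:
        return self.pulse_start + self.pulse_duration

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Current samples with t0 <= t < t1."""
        mask = (self.t >= t0 - 1e-9) & (self.t < t1 - 1e-9)
        return self.i[mask]


@dataclass
class InactivationMetrics:
    """Residual-current and exponential-fit summary of one trace."""

    residual: float | None = None
    i_start_mean: float | None = None
    i_end_mean: float | None = None
    tau: float | None = None
    fit: tuple[float, float, float, float] | None = None  # (i0, i_inf, tau, rss)
    converged: bool = False


def read_trace(
    csv: str | TextIO,
    *,
    sampling_rate: float = 10000.0,
    pulse_start: float | None = None,
    pulse_duration: float = 60.0,
) -> CurrentTrace:
    """Two-column CSV (time_ms, current_pA) -> CurrentTrace.

    Lines starting with '#' are metadata comments (the synthetic generator
    records its seed there).  When ``pulse_start`` is None the pulse is
    assumed to start at the first sample.
    """
    handle = io.StringIO(csv) if isinstance(csv, str) else csv
    df = pd.read_csv(handle, comment="#")
    if not {"time_ms", "current_pA"} <= set(df.columns):
        raise TraceError("trace CSV needs columns time_ms, current_pA")
    t = df["time_ms"].to_numpy(dtype=float)
    return CurrentTrace(
        t=t,
        i=df["current_pA"].to_numpy(dtype=float),
        sampling_rate=sampling_rate,
        pulse_start=float(t[0]) if pulse_start is None else pulse_start,
        pulse_duration=pulse_duration,
    )


def residual_current(
    tr: CurrentTrace, edge_ms: float = 5.0, *, denominator_floor: float = 1.0
) -> InactivationMetrics:
    """Ratio of the end-window mean to the start-window mean of the pulse.

    Start window is the first ``edge_ms`` of the pulse, end window the last
    ``edge_ms``; the windows must not overlap.  Currents are signed, so a
    trace of constant sign yields a positive ratio.
    """
    if tr.pulse_duration < 2 * edge_ms:
        raise TraceError(
            f"pulse of {tr.pulse_duration} ms cannot hold two disjoint {edge_ms} ms windows"
        )
    start = tr.window(tr.pulse_start, tr.pulse_start + edge_ms)
    end = tr.window(tr.pulse_end - edge_ms, tr.pulse_end)
    if start.size == 0 or end.size == 0:
        raise TraceError("no samples in a residual-current window")
    i_start = float(start.mean())
    i_end = float(end.mean())
    if abs(i_start) < denominator_floor:
        raise UnstableRatioError(
            f"|start-window mean| = {abs(i_start):.3g} pA below floor {denominator_floor} pA"
        )
    return InactivationMetrics(
        residual=i_end / i_start, i_start_mean=i_start, i_end_mean=i_end
    )


def _exp_model(t: np.ndarray, i0: float, i_inf: float, tau: float) -> np.ndarray:
    return i_inf + (i0 - i_inf) * np.exp(-t / tau)


def _initial_tau(t_rel: np.ndarray, i: np.ndarray, i_inf0: float, pulse_duration: float) -> float:
    # log-linear regression of |i - i_inf| over the samples still above noise
    dev = np.abs(i - i_inf0)
    mask = dev > 1e-12
    if mask.sum() < 2:
        return pulse_duration / 5.0
    slope = np.polyfit(t_rel[mask], np.log(dev[mask]), 1)[0]
    if slope >= 0:
        return pulse_duration / 5.0
    return float(np.clip(-1.0 / slope, 1e-3, 100.0 * pulse_duration))


def fit_inactivation_tau(
    tr: CurrentTrace, *, edge_ms: float = 5.0, blank_ms: float = 0.0
) -> InactivationMetrics:
    """Single-exponential fit of the pulse-window current.

    ``blank_ms`` optionally drops the start of the pulse before fitting
    (capacitive transient; unnecessary for synthetic traces).  A trace whose
    decay amplitude does not exceed three times a first-difference noise
    estimate is declared non-decaying: ``converged=False``, tau absent.
    """
    t0 = tr.pulse_start + blank_ms
    mask = (tr.t >= t0 - 1e-9) & (tr.t < tr.pulse_end - 1e-9)
    t_win = tr.t[mask] - tr.pulse_start
    i_win = tr.i[mask]
    if t_win.size < 20:
        raise TraceError(f"pulse window holds {t_win.size} samples; need >= 20 to fit")

    start = tr.window(tr.pulse_start, tr.pulse_start + edge_ms)
    end = tr.window(tr.pulse_end - edge_ms, tr.pulse_end)
    i0_init = float(start.mean())
    i_inf_init = float(end.mean())

    # noise scale from first differences (decay contributes ~0 at 10 kHz)
    noise_sd = float(np.diff(i_win).std() / np.sqrt(2)) if i_win.size > 2 else 0.0
    amplitude = abs(i0_init - i_inf_init)
    if amplitude <= max(3.0 * noise_sd, 1e-12) or abs(i_inf_init) >= abs(i0_init):
        logger.info("trace does not decay (amplitude %.3g pA, noise %.3g pA)", amplitude, noise_sd)
        return InactivationMetrics(
            i_start_mean=i0_init, i_end_mean=i_inf_init, converged=False
        )

    tau_init = _initial_tau(t_win, i_win, i_inf_init, tr.pulse_duration)
    try:
        popt, _ = curve_fit(
            _exp_model,
            t_win,
            i_win,
            p0=(i0_init, i_inf_init, tau_init),
            bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        success = True
    except RuntimeError:
        popt, success = (i0_init, i_inf_init, tau_init), False
    i0, i_inf, tau = (float(v) for v in popt)
    rss = float(((i_win - _exp_model(t_win, i0, i_inf, tau)) ** 2).sum())
    converged = success and 0.1 < tau < 10.0 * tr.pulse_duration
    return InactivationMetrics(
        i_start_mean=i0_init,
        i_end_mean=i_inf_init,
        tau=tau if converged else None,
        fit=(i0, i_inf, tau, rss),
        converged=converged,
    )


def analyze_trace(tr: CurrentTrace, *, edge_ms: float = 5.0, blank_ms: float = 0.0) -> InactivationMetrics:
    """Residual current plus exponential fit in one metrics record."""
    res = residual_current(tr, edge_ms)
    fit = fit_inactivation_tau(tr, edge_ms=edge_ms, blank_ms=blank_ms)
    return InactivationMetrics(
        residual=res.residual,
        i_start_mean=res.i_start_mean,
        i_end_mean=res.i_end_mean,
        tau=fit.tau,
        fit=fit.fit,
        converged=fit.converged,
    )


def summarize_metrics(metrics: Sequence[InactivationMetrics]) -> pd.DataFrame:
    """Group summary (mean +/- standard error) of residuals and taus."""
    residuals = np.array([m.residual for m in metrics if m.residual is not None])
    taus = np.array([m.tau for m in metrics if m.tau is not None])
    rows = []
    for name, vals in (("residual", residuals), ("tau_ms", taus)):
        if vals.size:
            sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            rows.append({"metric": name, "mean": float(vals.mean()), "sem": sem, "n": int(vals.size)})
    return pd.DataFrame(rows, columns=["metric", "mean", "sem", "n"])
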