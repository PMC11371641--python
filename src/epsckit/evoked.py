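"""Evoked-release analysis: single-EPSC metrics, bi-exponential decay
decomposition into synchronous and asynchronous charge, paired-pulse ratio,
stimulus-train analysis with tail kinetics, and readily-releasable-pool
(RRP) estimation by cumulative-charge back-extrapolation or hypertonic
sucrose application.

All operations expect a preprocessed trace (see :func:`preprocess`):
baseline-subtracted, positive-up magnitude currents with stimulus artifacts
blanked.  Charges are reported in pC, time constants in ms.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import optimize, stats

from .traceio import (
    AnalysisConfig,
    MetadataError,
    ParameterError,
    Polarity,
    Trace,
    WindowError,
)

__all__ = [
    "EPSCMetrics",
    "EPSCDecayFit",
    "TrainResult",
    "RRPEstimate",
    "FitError",
    "preprocess",
    "epsc_metrics",
    "fit_biexp_decay",
    "decompose_sync_async",
    "paired_pulse_ratio",
    "analyze_epsc",
    "analyze_train",
    "backextrapolate_rrp",
    "estimate_rrp_sucrose",
]


class FitError(ValueError):
    """Too few samples (or otherwise unusable data) for a requested fit."""


@dataclasses.dataclass
class EPSCMetrics:
    amplitude: float      # pA, rectified
    charge: float         # pC
    time_to_peak: float   # ms from stimulus onset
    baseline: float       # pA, holding current removed during preprocessing


@dataclasses.dataclass
class EPSCDecayFit:
    """Bi-exponential decay fit A_f·exp(-t/tau_f) + A_s·exp(-t/tau_s),
    components ordered so tau_fast < tau_slow, with the derived
    synchronous/asynchronous charge decomposition."""

    A_fast: float            # pA
    tau_fast: float          # ms
    A_slow: float            # pA
    tau_slow: float          # ms
    fit_rmse: float          # pA
    converged: bool
    relative_slow_amplitude: float = float("nan")  # A_slow/(A_fast+A_slow)
    rise_charge: float = float("nan")   # pC
    sync_charge: float = float("nan")   # pC
    async_charge: float = float("nan")  # pC
    async_fraction: float = float("nan")

    def __post_init__(self):
        if self.converged and not (self.tau_slow > self.tau_fast > 0):
            raise ParameterError("decay components must satisfy "
                                 "tau_slow > tau_fast > 0")
        if math.isnan(self.relative_slow_amplitude):
            tot = self.A_fast + self.A_slow
            self.relative_slow_amplitude = self.A_slow / tot if tot > 0 else 0.0

    def model(self, t_ms: np.ndarray) -> np.ndarray:
        """Fitted decay evaluated at ``t_ms`` (ms after the peak)."""
        return (self.A_fast * np.exp(-t_ms / self.tau_fast)
                + self.A_slow * np.exp(-t_ms / self.tau_slow))


@dataclasses.dataclass
class TrainResult:
    pulse_amplitudes: np.ndarray       # pA, phasic (above asynchronous envelope)
    normalized_amplitudes: np.ndarray  # first pulse = 1
    per_pulse_charges: np.ndarray      # pC per inter-stimulus interval
    total_charge: float                # pC over the train window
    train_async_fraction: float
    tail_tau: float                    # ms
    tail_charge: float                 # pC
    envelope_clipped: bool = False


@dataclasses.dataclass
class RRPEstimate:
    rrp_charge: float         # pC
    recruitment_rate: float   # pC/s
    method: str               # {back_extrapolation, sucrose}
    fit_r2: float = float("nan")
    flags: tuple = ()


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(trace: Trace, config: AnalysisConfig | None = None) -> Trace:
    """Baseline-subtract, rectify to positive-up, and blank stimulus windows.

    The baseline is the mean over ``baseline_window`` immediately preceding
    the first stimulus (or from the sweep start when there are no stimuli).
    The ``blank_window`` after each stimulus onset is replaced by linear
    interpolation to remove stimulation artifacts.
    """
    config = config or AnalysisConfig()
    sr = trace.sampling_rate
    win = int(round(config.baseline_window / 1000.0 * sr))
    if trace.stimulus_times.size:
        i1 = trace.index_of(trace.stimulus_times[0])
        i0 = i1 - win
        if i0 < 0:
            raise WindowError("baseline window extends before the sweep start")
    else:
        i0, i1 = 0, min(win, trace.samples.size)
    baseline = float(np.mean(trace.samples[i0:i1]))

    x = trace.samples - baseline
    if trace.polarity is Polarity.INWARD_NEGATIVE:
        x = -x

    blank = max(int(round(config.blank_window / 1000.0 * sr)), 1)
    for t in trace.stimulus_times:
        j0 = max(trace.index_of(t), 0)
        j1 = min(j0 + blank, x.size)
        if j1 <= j0:
            continue
        left = x[j0 - 1] if j0 > 0 else 0.0
        right = x[j1] if j1 < x.size else left
        x[j0:j1] = np.linspace(left, right, j1 - j0 + 2)[1:-1]

    ann = dict(trace.annotations)
    ann["baseline_pA"] = f"{baseline:.6g}"
    return Trace(
        samples=x,
        sampling_rate=sr,
        start_time=trace.start_time,
        polarity=Polarity.POSITIVE_UP,
        stimulus_times=trace.stimulus_times.copy(),
        annotations=ann,
    )


def _segment(trace: Trace, t0: float, t1: float):
    i0 = max(trace.index_of(t0), 0)
    i1 = min(trace.index_of(t1), trace.samples.size)
    if i1 <= i0:
        raise WindowError(f"no samples in window [{t0:g}, {t1:g}] s")
    return i0, i1


# ---------------------------------------------------------------------------
# single EPSC
# ---------------------------------------------------------------------------

def epsc_metrics(trace: Trace, stim_time: float,
                 config: AnalysisConfig | None = None,
                 window_end: float | None = None) -> EPSCMetrics:
    """Amplitude, charge and time-to-peak of the response to one stimulus.

    The response window runs from the stimulus to the next stimulus, or to
    ``stim_time + fit_window`` when none follows; ``window_end`` overrides.
    """
    config = config or AnalysisConfig()
    if window_end is None:
        later = trace.stimulus_times[trace.stimulus_times > stim_time]
        window_end = (float(later[0]) if later.size
                      else stim_time + config.fit_window / 1000.0)
    i0, i1 = _segment(trace, stim_time, window_end)
    seg = trace.samples[i0:i1]
    ipk = int(np.argmax(seg))
    amplitude = float(seg[ipk])
    ttp = ipk / trace.sampling_rate * 1000.0
    charge = float(np.trapezoid(seg, dx=1.0 / trace.sampling_rate))
    baseline = float(trace.annotations.get("baseline_pA", "nan"))
    return EPSCMetrics(amplitude=amplitude, charge=charge,
                       time_to_peak=ttp, baseline=baseline)


def _mono_fit(t_ms, y):
    """Least-squares mono-exponential fit; returns (A, tau_ms, rmse, ok)."""
    y0 = max(float(y[0]), 1e-12)
    tau0 = _tau_from_decay(t_ms, y)

    def resid(theta):
        return theta[0] * np.exp(-t_ms / math.exp(theta[1])) - y

    res = optimize.least_squares(
        resid, x0=[y0, math.log(tau0)], method="lm", max_nfev=2000)
    A, tau = res.x[0], math.exp(res.x[1])
    rmse = float(np.sqrt(np.mean(res.fun ** 2)))
    return A, tau, rmse, bool(res.success)


def _tau_from_decay(t_ms, y):
    """Crude time constant from the 80 % -> 20 % decay time."""
    y0 = float(y[0])
    if y0 <= 0:
        return max((t_ms[-1] - t_ms[0]) / 3.0, 1e-3)
    below80 = np.nonzero(y <= 0.8 * y0)[0]
    below20 = np.nonzero(y <= 0.2 * y0)[0]
    if below80.size and below20.size and below20[0] > below80[0]:
        dt = t_ms[below20[0]] - t_ms[below80[0]]
        return max(dt / math.log(4.0), 1e-3)
    return max((t_ms[-1] - t_ms[0]) / 3.0, 1e-3)


def _grid_init(t_ms, y, tau0):
    """Variable-projection initialization: scan (tau_fast, tau_slow) pairs
    on log grids, solve the two amplitudes linearly (clipped at zero), and
    seed the nonlinear refinement from the best pair.  This avoids the
    local minimum in which a small slow component collapses onto the fast
    one."""
    t_span = max(t_ms[-1], 10.0 * tau0)
    tf_grid = tau0 * np.logspace(-0.5, 0.5, 7)
    ts_grid = np.geomspace(2.0 * tau0, max(3.0 * t_span, 20.0 * tau0), 10)
    best = None
    for tf in tf_grid:
        ef = np.exp(-t_ms / tf)
        for ts in ts_grid:
            if ts <= 1.5 * tf:
                continue
            es = np.exp(-t_ms / ts)
            design = np.column_stack([ef, es])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            coef = np.clip(coef, 0.0, None)
            sse = float(np.sum((design @ coef - y) ** 2))
            if best is None or sse < best[0]:
                best = (sse, tf, ts, coef[0], coef[1])
    _, tf, ts, a_f, a_s = best
    return [math.log(tf), math.log(ts - tf), max(a_f, 1e-9), max(a_s, 0.0)]


def _peel_init(t_ms, y, tau0):
    """Exponential-peeling initialization: fit the late tail with a
    mono-exponential, subtract its extrapolation, fit the early remainder,
    and seed the joint fit from the two components.  Returns None when
    there is no usable tail (then only the grid seed is tried)."""
    y0 = max(float(y[0]), 1e-12)
    late = np.nonzero(y < 0.05 * y0)[0]
    i_split = int(late[0]) if late.size else 0
    i_split = max(i_split, int(np.searchsorted(t_ms, 5.0 * tau0)))
    if y.size - i_split < 20 or i_split < 10:
        return None
    tail = y[i_split:]
    if float(np.max(tail)) <= 0:
        return None
    a_t, tau_s, _, ok = _mono_fit(t_ms[i_split:] - t_ms[i_split], tail)
    if not ok or a_t <= 0 or tau_s <= tau0:
        return None
    a_s = a_t * math.exp(t_ms[i_split] / tau_s)
    early = y[:i_split] - a_s * np.exp(-t_ms[:i_split] / tau_s)
    a_f, tau_f, _, ok = _mono_fit(t_ms[:i_split], np.maximum(early, 0.0))
    if not ok or a_f <= 0 or tau_s <= 1.5 * tau_f:
        return None
    return [math.log(tau_f), math.log(tau_s - tau_f), a_f, max(a_s, 0.0)]


def fit_biexp_decay(trace: Trace, peak_time: float,
                    config: AnalysisConfig | None = None,
                    window_end: float | None = None) -> EPSCDecayFit:
    """Fit the decay phase from the peak with a bi-exponential.

    The fit is performed in log-tau with the slow component parameterized as
    ``tau_slow = tau_fast + exp(theta)``, which enforces the ordering by
    construction; amplitudes are bounded below by zero.  The fast time
    constant is seeded from the 80->20 % decay time and the slow one at ten
    times that.  When the slow component collapses (contributing < 1 % of
    the fitted charge, or with a time constant within 20 % of the fast one)
    the result is reported as mono-exponential with ``A_slow = 0``.
    Non-convergence is reported through ``converged=False``, not raised.
    """
    config = config or AnalysisConfig()
    if window_end is None:
        window_end = peak_time + config.fit_window / 1000.0
    i0, i1 = _segment(trace, peak_time, window_end)
    y = trace.samples[i0:i1]
    if y.size < 10:
        raise FitError("fewer than 10 samples in the decay segment")
    t_ms = np.arange(y.size) / trace.sampling_rate * 1000.0

    tau0 = _tau_from_decay(t_ms, y)

    def resid(theta):
        a_f, a_s = theta[2], theta[3]
        tau_f = math.exp(theta[0])
        tau_s = tau_f + math.exp(theta[1])
        return (a_f * np.exp(-t_ms / tau_f)
                + a_s * np.exp(-t_ms / tau_s) - y)

    lo = [math.log(1e-2), math.log(1e-2), 0.0, 0.0]
    hi = [math.log(5e3), math.log(5e3), np.inf, np.inf]
    res = None
    for x0 in filter(None, (_peel_init(t_ms, y, tau0),
                            _grid_init(t_ms, y, tau0))):
        x0[0] = min(max(x0[0], lo[0]), hi[0])
        x0[1] = min(max(x0[1], lo[1]), hi[1])
        cand = optimize.least_squares(resid, x0=x0, bounds=(lo, hi),
                                      max_nfev=5000)
        if res is None or cand.cost < res.cost:
            res = cand
    tau_f = math.exp(res.x[0])
    tau_s = tau_f + math.exp(res.x[1])
    a_f, a_s = float(res.x[2]), float(res.x[3])
    rmse = float(np.sqrt(np.mean(res.fun ** 2)))
    converged = bool(res.success)

    slow_share = (a_s * tau_s) / max(a_f * tau_f + a_s * tau_s, 1e-300)
    if converged and (slow_share < 0.01 or tau_s < 1.2 * tau_f):
        a, tau, rmse_m, ok = _mono_fit(t_ms, y)
        if ok:
            return EPSCDecayFit(A_fast=max(a, 0.0), tau_fast=tau, A_slow=0.0,
                                tau_slow=10.0 * tau, fit_rmse=rmse_m,
                                converged=True)
    if not converged:
        # degenerate fit: keep ordering legal for reporting
        tau_s = max(tau_s, 1.01 * tau_f)
    return EPSCDecayFit(A_fast=a_f, tau_fast=tau_f, A_slow=a_s,
                        tau_slow=tau_s, fit_rmse=rmse, converged=converged)


def decompose_sync_async(fit: EPSCDecayFit, rise_charge: float):
    """Split one EPSC into synchronous and asynchronous charge.

    Synchronous charge is the rise-phase integral plus the analytic
    integral of the fast decay component (``A_f * tau_f``); asynchronous
    charge is the integral of the slow component (``A_s * tau_s``).  The
    analytic integrals run from the peak to infinity, making the split
    independent of the fit window.

    Returns ``(sync_charge, async_charge, async_fraction)`` in pC; the
    fraction is NaN when both charges vanish.
    """
    sync = rise_charge + fit.A_fast * fit.tau_fast / 1000.0
    async_ = fit.A_slow * fit.tau_slow / 1000.0
    total = sync + async_
    frac = async_ / total if total > 0 else float("nan")
    return sync, async_, frac


def analyze_epsc(trace: Trace, config: AnalysisConfig | None = None):
    """Full single-EPSC pipeline on a preprocessed single-stimulus trace.

    Returns ``(EPSCMetrics, EPSCDecayFit)`` with the decomposition fields of
    the fit populated.
    """
    config = config or AnalysisConfig()
    if trace.stimulus_times.size != 1:
        raise ParameterError("analyze_epsc expects exactly one stimulus")
    stim = float(trace.stimulus_times[0])
    metrics = epsc_metrics(trace, stim, config)
    peak_time = stim + metrics.time_to_peak / 1000.0
    fit = fit_biexp_decay(trace, peak_time, config,
                          window_end=stim + config.fit_window / 1000.0)
    i0, i1 = _segment(trace, stim, peak_time + 0.5 / trace.sampling_rate)
    rise = float(np.trapezoid(trace.samples[i0:i1],
                              dx=1.0 / trace.sampling_rate))
    sync, async_, frac = decompose_sync_async(fit, rise)
    fit.rise_charge = rise
    fit.sync_charge = sync
    fit.async_charge = async_
    fit.async_fraction = frac
    return metrics, fit


# ---------------------------------------------------------------------------
# paired pulses
# ---------------------------------------------------------------------------

def paired_pulse_ratio(trace: Trace, stim_times=None,
                       config: AnalysisConfig | None = None) -> float:
    """Second/first EPSC amplitude for two closely spaced stimuli.

    The second amplitude is measured after subtracting the extrapolated
    bi-exponential decay of the first response.  NaN when the first
    response is absent.
    """
    config = config or AnalysisConfig()
    if stim_times is None:
        stim_times = trace.stimulus_times
    stim_times = np.asarray(stim_times, dtype=float)
    if stim_times.size != 2:
        raise ParameterError("paired_pulse_ratio requires exactly 2 stimuli")
    s1, s2 = stim_times
    interval = s2 - s1

    m1 = epsc_metrics(trace, s1, config, window_end=s2)
    if m1.amplitude <= 0:
        return float("nan")
    peak1 = s1 + m1.time_to_peak / 1000.0
    fit1 = fit_biexp_decay(trace, peak1, config, window_end=s2)

    i0, i1 = _segment(trace, s2, min(s2 + interval, trace.start_time
                                     + trace.duration))
    t_ms = ((trace.start_time + np.arange(i0, i1) / trace.sampling_rate)
            - peak1) * 1000.0
    corrected = trace.samples[i0:i1] - fit1.model(t_ms)
    amp2 = float(np.max(corrected))
    return max(amp2, 0.0) / m1.amplitude


# ---------------------------------------------------------------------------
# trains
# ---------------------------------------------------------------------------

def _noise_sd(trace: Trace, config: AnalysisConfig) -> float:
    """Noise SD from the pre-stimulus baseline segment."""
    sr = trace.sampling_rate
    win = int(round(config.baseline_window / 1000.0 * sr))
    if trace.stimulus_times.size:
        i1 = max(trace.index_of(trace.stimulus_times[0]), 1)
        i0 = max(i1 - win, 0)
    else:
        i0, i1 = 0, min(win, trace.samples.size)
    return float(np.std(trace.samples[i0:i1]))


def analyze_train(trace: Trace, stim_times=None,
                  config: AnalysisConfig | None = None) -> TrainResult:
    """Synchronous/asynchronous division of a uniform stimulus train.

    The asynchronous envelope is the piecewise-linear interpolation of the
    mean current over the 2 ms preceding each stimulus (and one
    inter-stimulus interval after the last); its integral over the train
    window is the asynchronous charge, the remainder of the total charge is
    synchronous.  Phasic amplitudes are measured above the local envelope
    and normalized to the first pulse.  The tail current, from one
    inter-stimulus interval after the final stimulus until it returns to
    within twice the baseline noise SD, is fitted with a mono-exponential
    (``tail_tau``); its charge is reported separately and excluded from
    ``train_async_fraction``.
    """
    config = config or AnalysisConfig()
    if stim_times is None:
        stim_times = trace.stimulus_times
    stims = np.asarray(stim_times, dtype=float)
    if stims.size < 5:
        raise ParameterError("analyze_train requires at least 5 stimuli")
    isi = np.diff(stims)
    if not np.allclose(isi, isi[0], rtol=1e-6, atol=1e-9):
        raise ParameterError("stimuli must be uniformly spaced")
    delta = float(isi[0])
    sr = trace.sampling_rate
    x = trace.samples
    pre = max(int(round(0.002 * sr)), 1)
    window_end = stims[-1] + delta

    # asynchronous envelope through the pre-pulse baselines
    anchor_t = np.append(stims, window_end)
    b = np.empty(anchor_t.size)
    for j, t in enumerate(anchor_t):
        i1 = trace.index_of(t)
        i0 = max(i1 - pre, 0)
        b[j] = np.mean(x[i0:i1]) if i1 > i0 else 0.0
    b = np.maximum(b, 0.0)

    i0, i1 = _segment(trace, stims[0], window_end)
    t_win = trace.start_time + np.arange(i0, i1) / sr
    envelope = np.interp(t_win, anchor_t, b)
    dt = 1.0 / sr
    async_charge = float(np.trapezoid(envelope, dx=dt))
    total_charge = float(np.trapezoid(x[i0:i1], dx=dt))

    clipped = False
    if async_charge > total_charge:
        async_charge, clipped = total_charge, True
    sync_charge = total_charge - async_charge
    frac = (async_charge / total_charge) if total_charge > 0 else float("nan")

    amps = np.empty(stims.size)
    charges = np.empty(stims.size)
    for k, tk in enumerate(stims):
        j0, j1 = _segment(trace, tk, tk + delta)
        seg = x[j0:j1]
        amps[k] = max(float(np.max(seg)) - b[k], 0.0)
        charges[k] = float(np.trapezoid(seg, dx=dt))
    norm = amps / amps[0] if amps[0] > 0 else np.full_like(amps, np.nan)

    tail_tau, tail_charge = _fit_tail(trace, window_end, config,
                                      smooth_s=delta / 2.0)

    return TrainResult(
        pulse_amplitudes=amps,
        normalized_amplitudes=norm,
        per_pulse_charges=charges,
        total_charge=total_charge,
        train_async_fraction=frac,
        tail_tau=tail_tau,
        tail_charge=tail_charge,
        envelope_clipped=clipped,
    )


def _fit_tail(trace: Trace, t_start: float, config: AnalysisConfig,
              smooth_s: float = 0.025):
    """Mono-exponential fit to the post-train tail current.

    The tail is carried by discrete asynchronous quanta, so the current is
    first smoothed with a boxcar (half an inter-stimulus interval) to
    estimate its rate envelope — a boxcar preserves an exponential's time
    constant exactly — and fitted from ``t_start`` until the envelope
    returns to within twice the (smoothed) baseline noise SD.
    """
    sr = trace.sampling_rate
    noise = _noise_sd(trace, config)
    i0 = trace.index_of(t_start)
    if i0 >= trace.samples.size - 10:
        return float("nan"), 0.0
    y = trace.samples[i0:]
    w = max(int(round(smooth_s * sr)), 1)
    smooth = np.convolve(y, np.ones(w) / w, mode="same")
    sigma_sm = noise / math.sqrt(w)
    start = float(np.max(smooth[: max(w, 1)])) if smooth.size else 0.0
    floor = max(2.0 * sigma_sm, 0.01 * max(start, 1e-12))
    below = np.nonzero(smooth < floor)[0]
    i_end = int(below[0]) if below.size else y.size
    tail_charge = float(np.trapezoid(y[:max(i_end, 1)], dx=1.0 / sr))
    # trim the edge-distorted first half-window from the fitted segment
    j0 = min(w // 2, max(i_end - 10, 0))
    seg = smooth[j0:i_end]
    if seg.size < 10 or start <= floor:
        return float("nan"), tail_charge
    t_ms = np.arange(seg.size) / sr * 1000.0
    a, tau, _, ok = _mono_fit(t_ms, seg)
    return (tau if ok and a > 0 else float("nan")), tail_charge


def backextrapolate_rrp(train_result: TrainResult, stim_times,
                        config: AnalysisConfig | None = None) -> RRPEstimate:
    """RRP charge and recruitment rate from cumulative train charge.

    The cumulative per-pulse charge is fitted with an ordinary
    least-squares line over the final ``steady_state_fraction`` of pulses
    (default last 25 %); the y-axis intercept at the first stimulus is the
    RRP charge and the slope the recruitment rate (pC/s).
    """
    config = config or AnalysisConfig()
    stims = np.asarray(stim_times, dtype=float)
    charges = np.asarray(train_result.per_pulse_charges, dtype=float)
    if charges.size < 20 or stims.size != charges.size:
        raise ParameterError("back-extrapolation requires >= 20 per-pulse "
                             "charges matching the stimulus count")
    y = np.cumsum(charges)
    t = stims - stims[0]
    n_fit = max(int(math.ceil(config.steady_state_fraction * charges.size)), 2)
    ts, ys = t[-n_fit:], y[-n_fit:]
    if np.allclose(ys, 0.0):
        return RRPEstimate(0.0, 0.0, "back_extrapolation", fit_r2=float("nan"))
    reg = stats.linregress(ts, ys)
    flags = ("negative_slope",) if reg.slope < 0 else ()
    return RRPEstimate(
        rrp_charge=float(reg.intercept),
        recruitment_rate=float(max(reg.slope, 0.0)),
        method="back_extrapolation",
        fit_r2=float(reg.rvalue ** 2),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# sucrose
# ---------------------------------------------------------------------------

def estimate_rrp_sucrose(trace: Trace, application_window=None,
                         config: AnalysisConfig | None = None) -> RRPEstimate:
    """RRP charge from the transient of a hypertonic-sucrose response.

    The steady-state current is the mean over the final 20 % of the
    application; the RRP charge is the integral of (current - steady state)
    over the application window, clipped below at zero.  Clipping the
    integral rather than individual samples keeps the estimate unbiased in
    the presence of recording and shot noise around the steady state.
    """
    config = config or AnalysisConfig()
    if application_window is None:
        raw = trace.annotations.get("application_window")
        if not raw:
            raise MetadataError("sucrose application window not annotated")
        t0, t1 = (float(v) for v in str(raw).split(","))
    else:
        t0, t1 = float(application_window[0]), float(application_window[1])
    i0, i1 = _segment(trace, t0, t1)
    seg = trace.samples[i0:i1]
    n_ss = max(int(round(0.2 * seg.size)), 1)
    steady = float(np.mean(seg[-n_ss:]))
    charge = float(np.trapezoid(seg - steady, dx=1.0 / trace.sampling_rate))
    return RRPEstimate(rrp_charge=max(charge, 0.0),
                       recruitment_rate=float("nan"), method="sucrose")
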