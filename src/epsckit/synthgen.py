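"""Ground-truthed synthetic voltage-clamp recordings.

This module generates every recording type the analysis stages consume —
single evoked EPSCs, paired pulses, 20/40 Hz stimulus trains, hypertonic
sucrose pool discharge and spontaneous miniature-EPSC sweeps — from an
explicit quantal-release model, and returns the exact event list produced
so each analysis can be validated by parameter recovery.

Generative model
----------------
* A quantal (single-vesicle) EPSC is a difference of exponentials
  ``k(t) = c * (exp(-t/tau_decay) - exp(-t/tau_rise))`` with ``c`` chosen so
  the peak equals ``quantal_amplitude``; event amplitudes are lognormal with
  coefficient of variation ``quantal_cv``.
* Spontaneous minis are a homogeneous Poisson process at ``mini_rate``.
* An action potential releases ``n_sync`` synchronous vesicles with tightly
  Gaussian latencies, plus ``Poisson(async_count_mean)`` asynchronous
  vesicles with ``Exponential(tau_async)`` latencies.
* During trains a readily releasable pool of ``pool_size`` vesicles is
  depleted binomially with release fraction ``p`` per pulse and refilled at
  a constant recruitment rate ``rho`` (capped at the resting pool size);
  asynchronous release at each pulse scales with the synchronous release at
  that pulse.
* Hypertonic sucrose discharges every pooled vesicle with an exponential
  fusion latency (time constant ``sucrose_discharge_tau``), followed by a
  steady-state release rate set by recruitment.
* Recording noise is additive Gaussian; traces are emitted inward-negative,
  as in conventional voltage-clamp EPSC recordings.

A deterministic *expected-value mode* propagates means instead of sampling
(synchronous release as one aggregate quantum per pulse, asynchronous
release as its expected current), which gives exact closed-form oracles for
the train and paired-pulse analyses.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .traceio import ParameterError, Polarity, Trace

__all__ = [
    "MiniKernel",
    "SimulationConfig",
    "GroundTruth",
    "make_mini_kernel",
    "simulate_minis",
    "simulate_evoked_epsc",
    "simulate_train",
    "simulate_sucrose",
    "make_preset",
    "protocol_stimulus_times",
    "preset_config",
    "PROTOCOLS",
]

SYNC, ASYNC, SPONT = "synchronous", "asynchronous", "spontaneous"


# ---------------------------------------------------------------------------
# quantal waveform
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MiniKernel:
    """Quantal EPSC waveform sampled on the acquisition grid.

    ``samples`` hold the positive-going magnitude waveform; polarity is
    applied when a trace is assembled.
    """

    quantal_amplitude: float  # pA
    tau_rise: float           # ms
    tau_decay: float          # ms
    sampling_rate: float      # Hz
    samples: np.ndarray       # pA

    @property
    def peak_time(self) -> float:
        """Analytic time-to-peak in ms."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * math.log(td / tr)

    @property
    def unit_charge(self) -> float:
        """Charge (pC) delivered per pA of peak amplitude."""
        return float(
            np.trapezoid(self.samples, dx=1.0 / self.sampling_rate)
            / self.quantal_amplitude
        )


def make_mini_kernel(
    quantal_amplitude: float,
    tau_rise: float,
    tau_decay: float,
    sampling_rate: float,
    n_tau: float = 8.0,
) -> MiniKernel:
    """Build the difference-of-exponentials quantal waveform.

    The kernel is truncated at ``n_tau`` decay time constants (default 8,
    leaving < 0.04 % of the charge outside the support).
    """
    if quantal_amplitude <= 0 or tau_rise <= 0 or tau_decay <= 0:
        raise ParameterError("kernel amplitude and time constants must be positive")
    if tau_decay <= tau_rise:
        raise ParameterError("tau_decay must exceed tau_rise")
    if sampling_rate < 2.0 / (tau_rise / 1000.0):
        raise ParameterError("sampling_rate must resolve the rise phase "
                             "(>= 2 samples per tau_rise)")
    tr, td = tau_rise / 1000.0, tau_decay / 1000.0  # s
    t_star = tr * td / (td - tr) * math.log(td / tr)
    peak = math.exp(-t_star / td) - math.exp(-t_star / tr)
    c = quantal_amplitude / peak
    n = int(math.ceil(n_tau * td * sampling_rate)) + 1
    t = np.arange(n) / sampling_rate
    samples = c * (np.exp(-t / td) - np.exp(-t / tr))
    return MiniKernel(quantal_amplitude, tau_rise, tau_decay, sampling_rate, samples)


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Full generative parameter set; the seed fully determines the output.

    Durations (``tau_*``, latencies, ``sucrose_discharge_tau``) are in ms,
    rates in Hz or vesicles/s, currents in pA, times in seconds.
    ``n_synapses`` is bookkeeping metadata used for per-synapse
    normalization; the simulated quantities are per cell.
    """

    seed: int = 0
    sampling_rate: float = 10_000.0
    noise_sd: float = 2.0                 # pA
    quantal_amplitude: float = 20.0       # pA
    quantal_cv: float = 0.25
    tau_rise: float = 0.5                 # ms
    tau_decay: float = 3.0                # ms
    mini_rate: float = 1.5                # Hz, per cell
    n_sync: int = 150                     # vesicles per AP
    sync_latency_mean: float = 1.0        # ms
    sync_latency_sd: float = 0.2          # ms
    async_count_mean: float = 10.0        # vesicles per AP
    tau_async: float = 50.0               # ms
    pool_size: int = 500                  # vesicles
    release_fraction: float = 0.3         # p, per pulse
    recruitment_rate: float = 800.0       # vesicles/s
    sucrose_discharge_tau: float = 250.0  # ms
    stimulus_times: tuple = ()            # s
    n_synapses: int = 100
    genotype: str = ""
    expected_value_mode: bool = False

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        for name in ("noise_sd", "quantal_cv", "mini_rate", "n_sync",
                     "sync_latency_sd", "async_count_mean", "pool_size",
                     "recruitment_rate"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        for name in ("tau_rise", "tau_decay", "tau_async",
                     "sucrose_discharge_tau"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 <= self.release_fraction <= 1:
            raise ParameterError("release_fraction must lie in [0, 1]")
        st = np.asarray(self.stimulus_times, dtype=float)
        if st.size > 1 and np.any(np.diff(st) <= 0):
            raise ParameterError("stimulus_times must be strictly increasing")
        object.__setattr__(self, "stimulus_times", tuple(float(t) for t in st))

    def kernel(self) -> MiniKernel:
        return make_mini_kernel(
            self.quantal_amplitude, self.tau_rise, self.tau_decay,
            self.sampling_rate,
        )

    @property
    def mean_quantal_charge(self) -> float:
        """Mean charge per released vesicle in pC."""
        return self.quantal_amplitude * self.kernel().unit_charge

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass
class GroundTruth:
    """Exact event list and derived truths for one simulated sweep.

    ``true_async_fraction`` is the asynchronous share of the released charge
    over the analysis window of the corresponding protocol (for trains: the
    window from the first stimulus to one inter-stimulus interval after the
    last; the tail beyond that window is excluded).  NaN when undefined.
    """

    event_times: np.ndarray        # s
    event_amplitudes: np.ndarray   # pA
    event_class: np.ndarray        # {synchronous, asynchronous, spontaneous}
    per_pulse_released_charge: np.ndarray = dataclasses.field(
        default_factory=lambda: np.empty(0)
    )  # pC
    true_async_fraction: float = float("nan")
    true_rrp_charge: float = float("nan")  # pC

    def __post_init__(self):
        n = len(self.event_times)
        if not (len(self.event_amplitudes) == n == len(self.event_class)):
            raise ParameterError("ground-truth sequences must be parallel")


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------

def _quantal_amplitudes(rng, cfg: SimulationConfig, n: int) -> np.ndarray:
    """Lognormal amplitudes with mean ``quantal_amplitude`` and CV ``quantal_cv``."""
    if n == 0:
        return np.empty(0)
    q, cv = cfg.quantal_amplitude, cfg.quantal_cv
    if cv == 0:
        return np.full(n, q)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(math.log(q) - 0.5 * sigma * sigma, sigma, n)


def _render(times, amps, n_samples, kernel, sampling_rate, start_time=0.0):
    """Superpose kernel copies at the given event times (nearest-sample grid)."""
    signal = np.zeros(n_samples)
    k = kernel.samples / kernel.quantal_amplitude  # unit-peak waveform
    klen = k.size
    idx = np.round((np.asarray(times) - start_time) * sampling_rate).astype(int)
    for i, a in zip(idx, np.asarray(amps, dtype=float)):
        if i >= n_samples:
            continue
        i0 = max(i, 0)
        seg = min(klen, n_samples - i0)
        signal[i0:i0 + seg] += a * k[i0 - i:i0 - i + seg]
    return signal


def _async_current(charges_pC, onsets, tau_async_ms, n_samples, kernel,
                   sampling_rate):
    """Expected asynchronous current: exponential release-rate densities
    convolved with the unit-charge kernel (expected-value mode)."""
    dt = 1.0 / sampling_rate
    tau = tau_async_ms / 1000.0
    t = np.arange(n_samples) * dt
    lam = np.zeros(n_samples)  # pC/s = pA
    for q_pC, t0 in zip(charges_pC, onsets):
        m = t >= t0
        lam[m] += q_pC / tau * np.exp(-(t[m] - t0) / tau)
    k_unit = kernel.samples / (np.sum(kernel.samples) / sampling_rate)  # 1/s
    return np.convolve(lam, k_unit)[:n_samples] * dt


def _finish(cfg, rng, signal, n_samples, stimulus_times, annotations):
    noise = rng.normal(0.0, cfg.noise_sd, n_samples) if cfg.noise_sd > 0 else 0.0
    samples = -(signal) + noise
    ann = {"genotype": cfg.genotype, **annotations}
    return Trace(
        samples=samples,
        sampling_rate=cfg.sampling_rate,
        start_time=0.0,
        polarity=Polarity.INWARD_NEGATIVE,
        stimulus_times=np.asarray(stimulus_times, dtype=float),
        annotations=ann,
    )


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def simulate_minis(cfg: SimulationConfig, duration: float):
    """Spontaneous miniature-EPSC sweep.

    Event times are a homogeneous Poisson process at ``cfg.mini_rate``:
    the event count is a single Poisson draw, times are sorted uniforms,
    amplitudes are lognormal, and Gaussian noise is added last (this RNG
    order is part of the reproducibility contract).
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(duration * cfg.sampling_rate))
    n = rng.poisson(cfg.mini_rate * duration)
    times = np.sort(rng.uniform(0.0, duration, n))
    amps = _quantal_amplitudes(rng, cfg, n)
    kernel = cfg.kernel()
    signal = _render(times, amps, n_samples, kernel, cfg.sampling_rate)
    trace = _finish(cfg, rng, signal, n_samples, [], {"protocol": "minis"})
    gt = GroundTruth(
        event_times=times,
        event_amplitudes=amps,
        event_class=np.full(n, SPONT, dtype=object),
    )
    return trace, gt


def simulate_evoked_epsc(cfg: SimulationConfig, duration: float | None = None):
    """Single AP-evoked EPSC: tight Gaussian synchronous latencies plus an
    exponential asynchronous tail."""
    if len(cfg.stimulus_times) != 1:
        raise ParameterError("simulate_evoked_epsc requires exactly one stimulus")
    t0 = cfg.stimulus_times[0]
    if duration is None:
        duration = t0 + 0.7
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(duration * cfg.sampling_rate))
    kernel = cfg.kernel()

    if cfg.expected_value_mode:
        sync_t = np.array([t0 + cfg.sync_latency_mean / 1000.0])
        sync_a = np.array([cfg.n_sync * cfg.quantal_amplitude])
        async_q = cfg.async_count_mean * cfg.mean_quantal_charge
        signal = _render(sync_t, sync_a, n_samples, kernel, cfg.sampling_rate)
        if async_q > 0:
            signal += _async_current(
                [async_q], [t0 + cfg.sync_latency_mean / 1000.0],
                cfg.tau_async, n_samples, kernel, cfg.sampling_rate)
        times = sync_t
        amps = sync_a
        classes = np.array([SYNC], dtype=object)
        sync_charge = cfg.n_sync * cfg.mean_quantal_charge
        async_charge = async_q
    else:
        sync_lat = np.maximum(
            rng.normal(cfg.sync_latency_mean, cfg.sync_latency_sd, cfg.n_sync),
            0.0) / 1000.0
        n_async = rng.poisson(cfg.async_count_mean)
        async_lat = rng.exponential(cfg.tau_async, n_async) / 1000.0
        amps = _quantal_amplitudes(rng, cfg, cfg.n_sync + n_async)
        times = t0 + np.concatenate([sync_lat, async_lat])
        classes = np.array([SYNC] * cfg.n_sync + [ASYNC] * n_async, dtype=object)
        order = np.argsort(times, kind="stable")
        times, amps, classes = times[order], amps[order], classes[order]
        signal = _render(times, amps, n_samples, kernel, cfg.sampling_rate)
        uc = kernel.unit_charge
        sync_charge = float(np.sum(amps[classes == SYNC])) * uc
        async_charge = float(np.sum(amps[classes == ASYNC])) * uc

    total = sync_charge + async_charge
    frac = async_charge / total if total > 0 else float("nan")
    trace = _finish(cfg, rng, signal, n_samples, [t0], {"protocol": "epsc"})
    gt = GroundTruth(
        event_times=times,
        event_amplitudes=amps,
        event_class=classes,
        per_pulse_released_charge=np.array([total]),
        true_async_fraction=frac,
        true_rrp_charge=cfg.pool_size * cfg.mean_quantal_charge,
    )
    return trace, gt


def simulate_train(cfg: SimulationConfig, duration: float | None = None):
    """Uniform stimulus train with binomial pool depletion and constant
    recruitment.

    At pulse k the pool of P_k vesicles releases Binomial(P_k, p)
    synchronously plus Poisson asynchronous events scaled by that release
    (ratio ``async_count_mean / n_sync``); the pool is then refilled by
    ``rho * dt`` vesicles, capped at the resting pool size.  In
    expected-value mode the means are propagated deterministically, so
    per-pulse release follows the closed-form geometric depletion curve.
    """
    stims = np.asarray(cfg.stimulus_times, dtype=float)
    if stims.size < 2:
        raise ParameterError("simulate_train requires at least two stimuli")
    isi = np.diff(stims)
    if not np.allclose(isi, isi[0], rtol=1e-9, atol=1e-12):
        raise ParameterError("stimulus_times must be uniformly spaced")
    dt_pulse = float(isi[0])
    if duration is None:
        duration = stims[-1] + max(1.0, 6.0 * cfg.tau_async / 1000.0)
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(duration * cfg.sampling_rate))
    kernel = cfg.kernel()
    uc = kernel.unit_charge
    r_async = (cfg.async_count_mean / cfg.n_sync) if cfg.n_sync > 0 else 0.0
    lat_mean = cfg.sync_latency_mean / 1000.0
    window_end = stims[-1] + dt_pulse

    times, amps, classes, pulse_of = [], [], [], []
    sync_counts, async_counts = [], []
    pool = float(cfg.pool_size)
    for k, tk in enumerate(stims):
        if cfg.expected_value_mode:
            n_s = pool * cfg.release_fraction
            n_a = min(r_async * n_s, max(pool - n_s, 0.0))
            released = n_s + n_a
            pool = min(pool - released + cfg.recruitment_rate * dt_pulse,
                       float(cfg.pool_size))
            times.append(tk + lat_mean)
            amps.append(n_s * cfg.quantal_amplitude)
            classes.append(SYNC)
            pulse_of.append(k)
            if n_a > 0:
                times.append(tk + lat_mean)
                amps.append(n_a * cfg.quantal_amplitude)
                classes.append(ASYNC)
                pulse_of.append(k)
        else:
            p_int = int(round(pool))
            n_s = rng.binomial(p_int, cfg.release_fraction) if p_int > 0 else 0
            n_a = rng.poisson(r_async * n_s) if r_async > 0 else 0
            n_a = min(n_a, max(p_int - n_s, 0))
            released = n_s + n_a
            pool = min(pool - released + round(cfg.recruitment_rate * dt_pulse),
                       float(cfg.pool_size))
            s_lat = np.maximum(
                rng.normal(cfg.sync_latency_mean, cfg.sync_latency_sd, n_s),
                0.0) / 1000.0
            a_lat = rng.exponential(cfg.tau_async, n_a) / 1000.0
            ev_amps = _quantal_amplitudes(rng, cfg, n_s + n_a)
            times.extend(tk + np.concatenate([s_lat, a_lat]))
            amps.extend(ev_amps)
            classes.extend([SYNC] * n_s + [ASYNC] * n_a)
            pulse_of.extend([k] * (n_s + n_a))
        sync_counts.append(n_s)
        async_counts.append(n_a)

    times = np.asarray(times)
    amps = np.asarray(amps)
    classes = np.asarray(classes, dtype=object)
    pulse_of = np.asarray(pulse_of, dtype=int)

    if cfg.expected_value_mode:
        signal = _render(times[classes == SYNC], amps[classes == SYNC],
                         n_samples, kernel, cfg.sampling_rate)
        a_mask = classes == ASYNC
        if np.any(a_mask):
            signal += _async_current(amps[a_mask] * uc, times[a_mask],
                                     cfg.tau_async, n_samples, kernel,
                                     cfg.sampling_rate)
        # asynchronous charge actually delivered inside the train window
        tau_s = cfg.tau_async / 1000.0
        in_win = amps[a_mask] * uc * (
            1.0 - np.exp(-(window_end - times[a_mask]) / tau_s))
        async_in_window = float(np.sum(in_win))
        sync_in_window = float(np.sum(amps[classes == SYNC])) * uc
    else:
        order = np.argsort(times, kind="stable")
        times, amps, classes, pulse_of = (
            times[order], amps[order], classes[order], pulse_of[order])
        signal = _render(times, amps, n_samples, kernel, cfg.sampling_rate)
        in_win = times <= window_end
        async_in_window = float(np.sum(amps[(classes == ASYNC) & in_win])) * uc
        sync_in_window = float(np.sum(amps[(classes == SYNC) & in_win])) * uc

    per_pulse = np.array([
        float(np.sum(amps[pulse_of == k])) * uc for k in range(stims.size)
    ])
    total_win = sync_in_window + async_in_window
    frac = async_in_window / total_win if total_win > 0 else float("nan")

    trace = _finish(cfg, rng, signal, n_samples, stims,
                    {"protocol": "train",
                     "train_hz": f"{1.0 / dt_pulse:g}"})
    gt = GroundTruth(
        event_times=times,
        event_amplitudes=amps,
        event_class=classes,
        per_pulse_released_charge=per_pulse,
        true_async_fraction=frac,
        true_rrp_charge=cfg.pool_size * cfg.mean_quantal_charge,
    )
    return trace, gt


def simulate_sucrose(cfg: SimulationConfig, application_window,
                     duration: float | None = None):
    """Hypertonic sucrose (500 mM) pool discharge.

    Each pooled vesicle fuses with an exponential latency
    (``sucrose_discharge_tau``) from application onset; vesicles recruited
    during the application (rate ``rho``) release immediately, forming the
    steady-state component.  ``true_rrp_charge`` is the resting pool size
    times the mean quantal charge.
    """
    t0, t1 = float(application_window[0]), float(application_window[1])
    if not 0 <= t0 < t1:
        raise ParameterError("application_window must be an increasing pair "
                             "within the sweep")
    if duration is None:
        duration = t1 + 1.0
    if t1 > duration:
        raise ParameterError("application_window must lie within the sweep")
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(duration * cfg.sampling_rate))
    kernel = cfg.kernel()
    tau_s = cfg.sucrose_discharge_tau / 1000.0
    app_len = t1 - t0

    if cfg.expected_value_mode:
        pool_q = cfg.pool_size * cfg.mean_quantal_charge
        signal = _async_current([pool_q], [t0], cfg.sucrose_discharge_tau,
                                n_samples, kernel, cfg.sampling_rate)
        if cfg.recruitment_rate > 0:
            t = np.arange(n_samples) / cfg.sampling_rate
            lam = np.where((t >= t0) & (t < t1),
                           cfg.recruitment_rate * cfg.mean_quantal_charge, 0.0)
            k_unit = kernel.samples / (np.sum(kernel.samples)
                                       / cfg.sampling_rate)
            signal += (np.convolve(lam, k_unit)[:n_samples]
                       / cfg.sampling_rate)
        times = np.array([t0])
        amps = np.array([pool_q / kernel.unit_charge])
        classes = np.array([SPONT], dtype=object)
    else:
        lat = rng.exponential(tau_s, cfg.pool_size)
        pool_times = t0 + lat[lat < app_len]
        n_ss = rng.poisson(cfg.recruitment_rate * app_len)
        ss_times = rng.uniform(t0, t1, n_ss)
        times = np.sort(np.concatenate([pool_times, ss_times]))
        amps = _quantal_amplitudes(rng, cfg, times.size)
        classes = np.full(times.size, SPONT, dtype=object)
        signal = _render(times, amps, n_samples, kernel, cfg.sampling_rate)

    trace = _finish(cfg, rng, signal, n_samples, [],
                    {"protocol": "sucrose",
                     "sucrose_concentration": "500 mM",
                     "application_window": f"{t0:g},{t1:g}"})
    gt = GroundTruth(
        event_times=times,
        event_amplitudes=amps,
        event_class=classes,
        true_rrp_charge=cfg.pool_size * cfg.mean_quantal_charge,
    )
    return trace, gt


# ---------------------------------------------------------------------------
# presets and protocols
# ---------------------------------------------------------------------------

PROTOCOLS = ("minis", "epsc", "paired", "train20", "train40", "sucrose")

#: Defaults encode the reported effect directions: the PL variant leaves
#: synchronous kinetics, release probability and the total readily
#: releasable charge unchanged, but releases a several-fold larger
#: asynchronous component, a 6-fold higher spontaneous rate, and carries
#: a ~30 % smaller synapse count (hence a larger pool per synapse).
_PRESETS = {
    "WT": dict(mini_rate=1.5, n_sync=150, async_count_mean=10.0,
               tau_async=50.0, n_synapses=100, genotype="WT"),
    "PL": dict(mini_rate=9.0, n_sync=130, async_count_mean=30.0,
               tau_async=80.0, n_synapses=70, genotype="PL"),
}


def make_preset(genotype: str) -> SimulationConfig:
    """Generative parameter set for a wild-type-rescue ("WT") or P400L-rescue
    ("PL") neuron."""
    if genotype not in _PRESETS:
        raise ParameterError(
            f"unknown genotype {genotype!r}; expected one of {sorted(_PRESETS)}")
    return SimulationConfig(**_PRESETS[genotype])


def protocol_stimulus_times(protocol: str) -> tuple:
    """Stimulus onsets for the standard protocols (first stimulus at 0.2 s).

    20 Hz trains use 50 pulses, 40 Hz trains 100 pulses — long enough to
    reach the steady-state release needed for back-extrapolation.
    """
    if protocol in ("minis", "sucrose"):
        return ()
    if protocol == "epsc":
        return (0.2,)
    if protocol == "paired":
        return (0.2, 0.25)
    if protocol == "train20":
        return tuple(0.2 + 0.05 * np.arange(50))
    if protocol == "train40":
        return tuple(0.2 + 0.025 * np.arange(100))
    raise ParameterError(f"unknown protocol {protocol!r}")


def preset_config(genotype: str, protocol: str, seed: int = 0,
                  **overrides) -> SimulationConfig:
    """Preset configuration with the stimulus pattern of ``protocol`` attached."""
    cfg = make_preset(genotype).replace(
        seed=seed, stimulus_times=protocol_stimulus_times(protocol))
    return cfg.replace(**overrides) if overrides else cfg
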