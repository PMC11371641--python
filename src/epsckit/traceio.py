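"""Trace container, on-disk formats, analysis configuration and logging.

Conventions used throughout the package:

* time is stored in seconds, current in pA, charge in pC (1 pA * 1 s = 1 pC);
* sample indexing is 0-based and ``stimulus_times`` refer to stimulus onset;
* acquired traces carry an explicit polarity flag; conventional voltage-clamp
  EPSC recordings are inward-negative, and all analysis operates on
  baseline-subtracted, polarity-rectified magnitude traces.

Two interchange formats are supported: an HDF5 layout (datasets ``/samples``
float32 and ``/stimulus_times`` float64, attributes ``sampling_rate``,
``start_time``, ``polarity`` and ``annotations`` as JSON text) and a
two-column CSV (``time_s,current_pA``) with a JSON sidecar carrying the same
metadata.  Vendor acquisition formats are out of scope.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import time
from contextlib import contextmanager
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("epsckit")

__all__ = [
    "Trace",
    "AnalysisConfig",
    "Polarity",
    "ParameterError",
    "FormatError",
    "WindowError",
    "MetadataError",
    "read_trace",
    "write_trace",
    "timed",
]


class ParameterError(ValueError):
    """A simulation or analysis parameter violates its documented constraint."""


class FormatError(ValueError):
    """An on-disk file does not follow the declared trace layout."""


class WindowError(ValueError):
    """A requested analysis window falls outside the available samples."""


class MetadataError(ValueError):
    """Required trace metadata (e.g. an application window) is missing."""


class Polarity(str, enum.Enum):
    INWARD_NEGATIVE = "inward_negative"
    POSITIVE_UP = "positive_up"


@contextmanager
def timed(stage: str):
    """Log wall-clock duration of an analysis stage at INFO level."""
    t0 = time.perf_counter()
    yield
    log.info("%s: %.3f s", stage, time.perf_counter() - t0)


@dataclasses.dataclass
class Trace:
    """One sweep of sampled membrane current with stimulus metadata.

    Parameters
    ----------
    samples : array of current values in pA.
    sampling_rate : sampling frequency in Hz.
    start_time : time of the first sample in seconds.
    polarity : whether EPSC deflections are negative-going (raw recordings)
        or positive-up (rectified, analysis-ready).
    stimulus_times : ordered stimulus onsets in seconds.
    annotations : free-form string metadata (protocol, genotype, TTX flag,
        sucrose concentration, application window, ...).
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    polarity: Polarity = Polarity.INWARD_NEGATIVE
    stimulus_times: np.ndarray = dataclasses.field(
        default_factory=lambda: np.empty(0, dtype=float)
    )
    annotations: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        self.polarity = Polarity(self.polarity)
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise FormatError("trace must contain a non-empty 1-D sample array")
        if not self.sampling_rate > 0:
            raise FormatError("sampling_rate must be positive")
        if self.stimulus_times.size:
            if np.any(np.diff(self.stimulus_times) <= 0):
                raise FormatError("stimulus_times must be strictly increasing")
            end = self.start_time + self.samples.size / self.sampling_rate
            if (
                self.stimulus_times[0] < self.start_time
                or self.stimulus_times[-1] > end
            ):
                raise FormatError("stimulus_times fall outside the recorded sweep")

    # -- convenience ----------------------------------------------------
    @property
    def duration(self) -> float:
        """Sweep duration in seconds."""
        return self.samples.size / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate

    def index_of(self, t: float) -> int:
        """Nearest sample index for time ``t`` (seconds)."""
        return int(round((t - self.start_time) * self.sampling_rate))


@dataclasses.dataclass
class AnalysisConfig:
    """Tunable analysis parameters shared by all stages.

    All windows are durations in ms.

    Attributes
    ----------
    baseline_window : pre-stimulus segment used for baseline estimation.
    blank_window : post-stimulus segment replaced by linear interpolation
        (stimulus-artifact blanking).
    fit_window : decay-fit / response window after a stimulus.
    detection_threshold_k : mEPSC detection threshold in multiples of the
        robust noise SD.
    min_event_interval : minimum spacing between detected mEPSCs.
    steady_state_fraction : trailing fraction of train pulses used for the
        cumulative-charge linear fit.
    alpha : significance level for the statistics module.
    """

    baseline_window: float = 50.0
    blank_window: float = 1.0
    fit_window: float = 500.0
    detection_threshold_k: float = 4.0
    min_event_interval: float = 3.0
    steady_state_fraction: float = 0.25
    alpha: float = 0.05

    def __post_init__(self):
        for name in ("baseline_window", "blank_window", "fit_window",
                     "min_event_interval"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 < self.steady_state_fraction <= 1:
            raise ParameterError("steady_state_fraction must be in (0, 1]")
        if not 0 < self.alpha < 0.5:
            raise ParameterError("alpha must be in (0, 0.5)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_trace(trace: Trace, path, format: str | None = None):
    """Write ``trace`` to ``path`` in HDF5 or CSV format.

    Samples are stored as float32 in HDF5 (ample for pA-scale currents) and
    with 9 significant digits in CSV; metadata round-trips exactly.
    """
    trace.validate()
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=trace.samples.astype(np.float32))
            f.create_dataset(
                "stimulus_times", data=trace.stimulus_times.astype(np.float64)
            )
            f.attrs["sampling_rate"] = float(trace.sampling_rate)
            f.attrs["start_time"] = float(trace.start_time)
            f.attrs["polarity"] = trace.polarity.value
            f.attrs["annotations"] = json.dumps(trace.annotations)
    else:
        df = pd.DataFrame(
            {"time_s": trace.times(), "current_pA": trace.samples}
        )
        df.to_csv(path, index=False, float_format="%.9g")
        meta = {
            "sampling_rate": float(trace.sampling_rate),
            "start_time": float(trace.start_time),
            "polarity": trace.polarity.value,
            "stimulus_times": [float(t) for t in trace.stimulus_times],
            "annotations": trace.annotations,
        }
        _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_trace(path, format: str | None = None) -> Trace:
    """Read a trace written by :func:`write_trace`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            for key in ("samples", "stimulus_times"):
                if key not in f:
                    raise FormatError(f"HDF5 trace is missing dataset /{key}")
            for key in ("sampling_rate", "polarity"):
                if key not in f.attrs:
                    raise FormatError(f"HDF5 trace is missing attribute {key!r}")
            return Trace(
                samples=f["samples"][...].astype(float),
                sampling_rate=float(f.attrs["sampling_rate"]),
                start_time=float(f.attrs.get("start_time", 0.0)),
                polarity=Polarity(str(f.attrs["polarity"])),
                stimulus_times=f["stimulus_times"][...],
                annotations=json.loads(f.attrs.get("annotations", "{}")),
            )
    # CSV
    df = pd.read_csv(path)
    for col in ("time_s", "current_pA"):
        if col not in df.columns:
            raise FormatError(f"CSV trace is missing required column {col!r}")
    t = df["time_s"].to_numpy(float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise FormatError("CSV time column must be strictly increasing")
    side = _sidecar(path)
    if not side.exists():
        raise FormatError(
            f"CSV trace requires a metadata sidecar {side.name} "
            "(sampling_rate, polarity)"
        )
    meta = json.loads(side.read_text())
    for key in ("sampling_rate", "polarity"):
        if key not in meta:
            raise FormatError(f"CSV sidecar is missing required field {key!r}")
    return Trace(
        samples=df["current_pA"].to_numpy(float),
        sampling_rate=float(meta["sampling_rate"]),
        start_time=float(meta.get("start_time", t[0])),
        polarity=Polarity(meta["polarity"]),
        stimulus_times=np.asarray(meta.get("stimulus_times", []), dtype=float),
        annotations=dict(meta.get("annotations", {})),
    )


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
        if fmt in ("h5", "hdf5"):
            return "hdf5"
        if fmt == "csv":
            return "csv"
        raise FormatError(f"unknown trace format {format!r}")
    if path.suffix.lower() in (".h5", ".hdf5"):
        return "hdf5"
    if path.suffix.lower() == ".csv":
        return "csv"
    raise FormatError(f"cannot infer trace format from suffix {path.suffix!r}")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")
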