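"""In-memory containers for epoched MEG-style data and derived quantities.

All time-series containers share the layout ``trials x channels/regions x
samples`` with an explicit sampling rate ``fs`` (Hz) and epoch start time
``t0`` (seconds relative to stimulus onset).  Containers are lightweight
dataclasses around numpy arrays; they validate their invariants on
construction and round-trip to HDF5 via :func:`save_h5` / :func:`load_h5`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

#: canonical six regions of the emotional dual-pathway model:
#: bilateral amygdala, thalamus and orbitofrontal cortex.
DEFAULT_ROI_LABELS = ("lAMG", "rAMG", "lTHA", "rTHA", "lOFC", "rOFC")


def _check_series(data: np.ndarray, fs: float, labels: Sequence[str]) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected 3-D (trials x channels x samples), got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite values")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if len(labels) != data.shape[1]:
        raise ValueError(f"{len(labels)} labels for {data.shape[1]} channels")
    if len(set(labels)) != len(labels):
        raise ValueError("channel labels must be unique")


@dataclass
class EpochedSeries:
    """Sensor-level epoched time series (trials x channels x samples)."""

    data: np.ndarray
    fs: float
    t0: float = 0.0
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not self.channel_labels:
            self.channel_labels = tuple(f"ch{i}" for i in range(self.data.shape[1]))
        self.channel_labels = tuple(self.channel_labels)
        _check_series(self.data, self.fs, self.channel_labels)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy_with(self, data: np.ndarray, channel_labels: Sequence[str] | None = None) -> "EpochedSeries":
        labels = tuple(channel_labels) if channel_labels is not None else self.channel_labels
        return replace(self, data=np.asarray(data, dtype=float), channel_labels=labels)


@dataclass
class RoiSeries:
    """Source-level epoched time series for a set of regions of interest."""

    data: np.ndarray
    fs: float
    t0: float = 0.0
    region_labels: tuple[str, ...] = DEFAULT_ROI_LABELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.region_labels = tuple(self.region_labels)
        _check_series(self.data, self.fs, self.region_labels)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def region_index(self, label: str) -> int:
        try:
            return self.region_labels.index(label)
        except ValueError:
            raise KeyError(f"region {label!r} not in {self.region_labels}") from None

    def region(self, label: str) -> np.ndarray:
        """Return the (trials x samples) series of one region."""
        return self.data[:, self.region_index(label), :]


@dataclass
class TimeFreqPower:
    """Trial-averaged time-frequency power, regions x frequencies x time bins.

    Bins whose analysis window does not fit inside the epoch are NaN
    ("missing"), never zero.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    region_labels: tuple[str, ...]
    method: str = "hanning"

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.region_labels = tuple(self.region_labels)
        if self.power.ndim != 3:
            raise ValueError("power must be regions x freqs x times")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.power) < -1e-12 if self.power.size else False:
                raise ValueError("power must be non-negative")

    def region_index(self, label: str) -> int:
        return self.region_labels.index(label)


@dataclass
class Comodulogram:
    """Phase-amplitude coupling matrix for one (phase region, amplitude
    region, time window) triple.

    ``values[i, j]`` is the coupling between the phase of
    ``phase_freqs[i]`` in ``phase_region`` and the envelope of
    ``amp_freqs[j]`` in ``amp_region`` within ``window`` seconds.
    """

    values: np.ndarray
    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    window: tuple[float, float]
    phase_region: str
    amp_region: str
    n_trials_used: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.phase_freqs = np.asarray(self.phase_freqs, dtype=float)
        self.amp_freqs = np.asarray(self.amp_freqs, dtype=float)
        if self.values.shape != (self.phase_freqs.size, self.amp_freqs.size):
            raise ValueError("values shape must be (n phase freqs, n amp freqs)")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("coupling values must lie in [0, 1]")
        if np.any(np.diff(self.phase_freqs) <= 0) or np.any(np.diff(self.amp_freqs) <= 0):
            raise ValueError("frequency grids must be strictly increasing")


# ---------------------------------------------------------------------------
# HDF5 round-trip


def save_h5(path: str | Path, series: EpochedSeries | RoiSeries) -> None:
    """Write an epoched container to an HDF5 file with fs/t0/labels as attrs."""
    labels = (
        series.channel_labels if isinstance(series, EpochedSeries) else series.region_labels
    )
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=series.data)
        d.attrs["fs"] = series.fs
        d.attrs["t0"] = series.t0
        d.attrs["labels"] = [s.encode() for s in labels]
        d.attrs["kind"] = "epoched" if isinstance(series, EpochedSeries) else "roi"


def load_h5(path: str | Path) -> EpochedSeries | RoiSeries:
    with h5py.File(path, "r") as f:
        d = f["data"]
        labels = tuple(s.decode() if isinstance(s, bytes) else str(s) for s in d.attrs["labels"])
        kind = d.attrs.get("kind", "roi")
        cls = EpochedSeries if kind == "epoched" else RoiSeries
        if cls is EpochedSeries:
            return EpochedSeries(d[()], fs=float(d.attrs["fs"]), t0=float(d.attrs["t0"]), channel_labels=labels)
        return RoiSeries(d[()], fs=float(d.attrs["fs"]), t0=float(d.attrs["t0"]), region_labels=labels)
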