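"""Filtering and variance-based trial/channel rejection for epoched data.

The filter chain mirrors standard MEG practice: a band-stop (notch) filter
at the power-line frequency followed by a 1-100 Hz band-pass, both applied
forward-backward (zero phase) so stimulus-locked latencies are not shifted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import EpochedSeries, RoiSeries

Series = EpochedSeries | RoiSeries


def _design_filters(fs: float, notch_hz: float, band: tuple[float, float]):
    lo, hi = band
    nyq = fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} must lie inside (0, {nyq}) Hz")
    if not lo < notch_hz < hi:
        raise ValueError(f"notch {notch_hz} Hz must lie inside the pass band {band}")
    sos_band = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    sos_notch = signal.butter(
        2, [notch_hz - 2.0, notch_hz + 2.0], btype="bandstop", fs=fs, output="sos"
    )
    return np.vstack([sos_notch, sos_band])


def notch_and_bandpass(
    x: Series,
    notch_hz: float = 50.0,
    band: tuple[float, float] = (1.0, 100.0),
    on_short_epoch: str = "error",
) -> Series:
    """Zero-phase notch + band-pass filter of every trial and channel.

    A 2nd-order Butterworth band-stop around ``notch_hz`` and a 4th-order
    Butterworth band-pass over ``band`` are applied forward-backward
    (``sosfiltfilt``), doubling the effective order and cancelling phase
    delay. Epochs shorter than three filter time-constants of the low band
    edge raise (or warn, if ``on_short_epoch='warn'``).
    """
    sos = _design_filters(x.fs, notch_hz, band)
    # the slowest transient is set by the high-pass edge
    n_tc = 3 * x.fs / band[0]
    if x.n_samples < n_tc:
        msg = (
            f"epoch of {x.n_samples} samples is shorter than 3 filter "
            f"time-constants ({n_tc:.0f} samples) of the {band[0]} Hz edge"
        )
        if on_short_epoch == "error":
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    filtered = signal.sosfiltfilt(sos, x.data, axis=-1)
    return x.copy_with(filtered) if isinstance(x, EpochedSeries) else RoiSeries(
        filtered, fs=x.fs, t0=x.t0, region_labels=x.region_labels
    )


@dataclass
class RejectionReport:
    """Indices removed by :func:`reject_high_variance` with their robust z."""

    trials: list[tuple[int, float]] = field(default_factory=list)
    channels: list[tuple[int, float]] = field(default_factory=list)

    @property
    def n_trials_removed(self) -> int:
        return len(self.trials)

    @property
    def n_channels_removed(self) -> int:
        return len(self.channels)


def _robust_z(values: np.ndarray) -> np.ndarray:
    """Two-sided robust z-score: (x - median) / (1.4826 * MAD)."""
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    scale = 1.4826 * mad
    if scale == 0:
        # degenerate spread: anything off the median is infinitely outlying
        z = np.zeros_like(values)
        z[values != med] = np.inf
        return z
    return (values - med) / scale


def reject_high_variance(
    x: Series, z_thresh: float = 3.0
) -> tuple[Series, RejectionReport]:
    """Iteratively drop the worst high/low-variance trial or channel.

    Log-variance is computed per trial (pooled over channels) and per
    channel (pooled over trials); the single entity with the largest robust
    |z| (median/MAD) above ``z_thresh`` is removed, and the statistics are
    recomputed, until nothing exceeds the threshold. Values are never
    modified, only rows/columns dropped.
    """
    n_ch = x.data.shape[1]
    if x.n_trials < 3 or n_ch < 3:
        raise ValueError("need at least 3 trials and 3 channels for robust rejection")

    keep_tr = list(range(x.n_trials))
    keep_ch = list(range(n_ch))
    report = RejectionReport()
    eps = np.finfo(float).tiny
    while True:
        sub = x.data[np.ix_(keep_tr, keep_ch)]
        z_tr = _robust_z(np.log(sub.var(axis=(1, 2)) + eps))
        z_ch = _robust_z(np.log(sub.var(axis=(0, 2)) + eps))
        worst_tr = int(np.argmax(np.abs(z_tr)))
        worst_ch = int(np.argmax(np.abs(z_ch)))
        zt, zc = abs(z_tr[worst_tr]), abs(z_ch[worst_ch])
        if max(zt, zc) <= z_thresh:
            break
        if zt >= zc:
            report.trials.append((keep_tr[worst_tr], float(z_tr[worst_tr])))
            del keep_tr[worst_tr]
        else:
            report.channels.append((keep_ch[worst_ch], float(z_ch[worst_ch])))
            del keep_ch[worst_ch]
        if len(keep_tr) == 0:
            raise ValueError("all trials rejected: subject unusable")
        if len(keep_tr) < 3 or len(keep_ch) < 3:
            break

    clean = x.data[np.ix_(keep_tr, keep_ch)]
    if isinstance(x, EpochedSeries):
        labels = tuple(x.channel_labels[i] for i in keep_ch)
        out: Series = EpochedSeries(clean, fs=x.fs, t0=x.t0, channel_labels=labels)
    else:
        labels = tuple(x.region_labels[i] for i in keep_ch)
        out = RoiSeries(clean, fs=x.fs, t0=x.t0, region_labels=labels)
    return out, report
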