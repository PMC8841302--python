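"""Synthetic cohort generator for the dual-pathway alpha-gamma coupling study.

The generative model is the minimal one whose analysis ground truth is known
in closed form:

* every region carries additive 1/f ("pink") background noise;
* the right thalamus (rTHA) and right orbitofrontal cortex (rOFC) each carry
  an alpha-band sinusoidal driver with trial-random phase;
* the right amygdala (rAMG) carries a gamma carrier whose instantaneous
  envelope inside each coupling window equals
  ``A0 * (1 + kappa * cos(phi_driver(t) - phi0))`` and ``A0`` elsewhere,
  where ``phi_driver`` is the alpha phase of the window's driver region
  (rTHA for the early 0-50 ms window, rOFC for the 100-200 ms window);
* non-responders have their modulation depth ``kappa`` attenuated and their
  driver alpha power reduced in short post-stimulus sub-windows;
* each patient's HAM-D-6 reduction ratio is drawn from a linear-Gaussian
  model of the subject's realized kappa, so coupling strength and clinical
  improvement are statistically linked by construction.

Group sizes default to the study cohort: 32 responders, 33 non-responders,
29 healthy controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import DEFAULT_ROI_LABELS, EpochedSeries, RoiSeries

GROUPS = ("responder", "non_responder", "HC")


@dataclass
class CouplingWindow:
    """One cross-regional coupling pathway: the phase of ``phase_region``
    modulates the gamma envelope of ``amp_region`` in [t_start_s, t_end_s)."""

    phase_region: str
    amp_region: str
    t_start_s: float
    t_end_s: float


@dataclass
class ClinicalModel:
    """Linear-Gaussian map from realized modulation depth kappa to the
    HAM-D-6 reduction ratio: ratio = intercept + slope * kappa + N(0, sd),
    truncated to <= 1."""

    intercept: float = 0.1
    slope: float = 1.0
    noise_sd: float = 0.12


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the study conditions: 40 three-second epochs, six
    dual-pathway ROIs, alpha drivers at 10 Hz, an amygdala gamma carrier at
    60 Hz, coupling windows at 0-50 ms (thalamic route) and 100-200 ms
    (orbitofrontal route), and attenuated coupling in non-responders.
    Sampling rate defaults to 600 Hz for desk-scale speed (the recording
    hardware's 1200 Hz remains available by config); the Nyquist margin for
    the 1-100 Hz analysis band is retained.
    """

    n_responder: int = 32
    n_nonresponder: int = 33
    n_hc: int = 29
    n_trials: int = 40
    epoch_len_s: float = 3.0
    pre_stim_s: float = 0.5
    fs: float = 600.0
    roi_labels: tuple[str, ...] = DEFAULT_ROI_LABELS
    alpha_freq: float = 10.0
    gamma_freq: float = 60.0
    coupling_windows: tuple[CouplingWindow, ...] = (
        CouplingWindow("rTHA", "rAMG", 0.000, 0.050),
        CouplingWindow("rOFC", "rAMG", 0.100, 0.200),
    )
    kappa_by_group: dict = field(
        default_factory=lambda: {"responder": 0.6, "non_responder": 0.2, "HC": 0.6}
    )
    kappa_sd: float = 0.1
    alpha_power_attenuation: float = 0.5
    attenuation_windows: dict = field(
        default_factory=lambda: {"rTHA": (0.020, 0.050), "rOFC": (0.110, 0.145)}
    )
    noise_exponent: float = 1.0
    noise_sd: float = 1.0
    alpha_amplitude: float = 1.0
    gamma_amplitude: float = 0.5
    coupling_phase_offset: float = 0.0
    snr_db: float = 10.0
    clinical_model: ClinicalModel = field(default_factory=ClinicalModel)
    hamd6_baseline_mean: float = 12.0
    hamd6_baseline_sd: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_responder", "n_nonresponder", "n_hc", "n_trials"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pre_stim_s < 0:
            raise ValueError("pre_stim_s must be non-negative")
        for g, k in self.kappa_by_group.items():
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"kappa for group {g!r} must lie in [0, 1], got {k}")
        for w in self.coupling_windows:
            if not (0.0 <= w.t_start_s < w.t_end_s <= self.epoch_len_s):
                raise ValueError(
                    f"coupling window [{w.t_start_s}, {w.t_end_s}] outside epoch "
                    f"[0, {self.epoch_len_s}]"
                )
            if w.phase_region not in self.roi_labels or w.amp_region not in self.roi_labels:
                raise ValueError("coupling window references unknown region")
        # need headroom above the gamma carrier for envelope side-bands
        if self.fs <= 2 * (self.gamma_freq + 2 * self.alpha_freq):
            raise ValueError(
                f"fs={self.fs} too low for gamma at {self.gamma_freq} Hz with "
                f"alpha side-bands"
            )

    @property
    def n_samples(self) -> int:
        return int(round((self.pre_stim_s + self.epoch_len_s) * self.fs))

    @property
    def t0(self) -> float:
        return -self.pre_stim_s

    @property
    def group_sizes(self) -> dict:
        return {
            "responder": self.n_responder,
            "non_responder": self.n_nonresponder,
            "HC": self.n_hc,
        }


@dataclass
class SubjectRecord:
    """Clinical bookkeeping for one (real or simulated) participant."""

    id: str
    group: str
    hamd6_baseline: float = math.nan
    hamd6_endpoint: float = math.nan
    hamd17_baseline: float = math.nan
    reduction_ratio: float = math.nan
    age: float = math.nan
    sex: str = ""
    education: float = math.nan
    true_kappa: float = math.nan

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if math.isfinite(self.hamd6_baseline) and self.hamd6_baseline > 0:
            implied = (self.hamd6_baseline - self.hamd6_endpoint) / self.hamd6_baseline
            if math.isfinite(self.reduction_ratio) and abs(implied - self.reduction_ratio) > 1e-9:
                raise ValueError("reduction_ratio inconsistent with HAM-D-6 scores")


@dataclass
class ToyLeadField:
    """Fixed-orientation linear forward model on a toy source grid."""

    gain: np.ndarray                    # sensors x sources
    roi_map: dict                       # label -> list of source indices
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise ValueError("gain must be 2-D (sensors x sources)")
        if np.linalg.matrix_rank(self.gain) < self.gain.shape[1]:
            raise ValueError("gain must have full column rank")
        covered = sorted(i for idx in self.roi_map.values() for i in idx)
        if any(len(v) == 0 for v in self.roi_map.values()):
            raise ValueError("every ROI must own at least one source")
        if max(covered, default=-1) >= self.gain.shape[1]:
            raise ValueError("roi_map references source beyond gain columns")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


def make_toy_leadfield(
    roi_labels: Sequence[str] = DEFAULT_ROI_LABELS,
    n_sensors: int = 30,
    sources_per_roi: int = 1,
    rng: np.random.Generator | int | None = 0,
) -> ToyLeadField:
    """Random full-rank lead field with ``sources_per_roi`` sources per ROI."""
    rng = np.random.default_rng(rng)
    n_sources = len(roi_labels) * sources_per_roi
    if n_sensors < n_sources:
        raise ValueError("toy grid requires at least as many sensors as sources")
    gain = rng.standard_normal((n_sensors, n_sources))
    gain /= np.linalg.norm(gain, axis=0, keepdims=True)
    roi_map = {
        lab: list(range(i * sources_per_roi, (i + 1) * sources_per_roi))
        for i, lab in enumerate(roi_labels)
    }
    return ToyLeadField(gain=gain, roi_map=roi_map)


# ---------------------------------------------------------------------------
# signal building blocks


def one_over_f_noise(
    rng: np.random.Generator, shape: tuple[int, ...], fs: float, exponent: float = 1.0, sd: float = 1.0
) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent.

    Generated by shaping white Gaussian noise in the frequency domain; the
    output is rescaled to standard deviation ``sd`` per trace.
    """
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC drift
    out = np.fft.irfft(spec * scale, n=n, axis=-1)
    std = out.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return sd * out / std


def _window_mask(times: np.ndarray, t_start: float, t_end: float) -> np.ndarray:
    return (times >= t_start) & (times < t_end)


# ---------------------------------------------------------------------------
# subject- and cohort-level simulation


def simulate_subject(
    config: SimulationConfig,
    group: str,
    rng: np.random.Generator | int | None = None,
    kappa: float | None = None,
) -> tuple[RoiSeries, SubjectRecord]:
    """Simulate one subject's ROI time series and clinical record.

    Parameters
    ----------
    config : SimulationConfig
    group : one of ``responder``, ``non_responder``, ``HC``
    rng : numpy Generator or seed; defaults to ``config.seed``
    kappa : override the realized modulation depth (otherwise drawn around
        the group mean with spread ``config.kappa_sd``, clipped to [0, 1])
    """
    if group not in config.kappa_by_group:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(config.seed if rng is None else rng)

    n_tr, n_sm = config.n_trials, config.n_samples
    times = config.t0 + np.arange(n_sm) / config.fs
    labels = config.roi_labels
    data = one_over_f_noise(
        rng, (n_tr, len(labels), n_sm), config.fs, config.noise_exponent, config.noise_sd
    )

    if kappa is None:
        kappa = float(
            np.clip(
                config.kappa_by_group[group] + config.kappa_sd * rng.standard_normal(),
                0.0,
                1.0,
            )
        )
    if not 0.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [0, 1], got {kappa}")

    # alpha drivers with trial-random phase; keep each driver's phase handy.
    # iterate in first-appearance order: set order is process-dependent and
    # would break cross-run determinism of the RNG stream assignment
    driver_phase: dict[str, np.ndarray] = {}
    driver_regions = list(dict.fromkeys(w.phase_region for w in config.coupling_windows))
    for region in driver_regions:
        phi_trial = rng.uniform(0, 2 * np.pi, size=(n_tr, 1))
        phase = 2 * np.pi * config.alpha_freq * times[None, :] + phi_trial
        driver_phase[region] = phase
        alpha = config.alpha_amplitude * np.cos(phase)
        if group == "non_responder" and region in config.attenuation_windows:
            t0a, t1a = config.attenuation_windows[region]
            mask = _window_mask(times, t0a, t1a)
            alpha[:, mask] *= config.alpha_power_attenuation
        data[:, labels.index(region), :] += alpha

    # gamma carriers with phase-locked envelope inside each coupling window
    for amp_region in dict.fromkeys(w.amp_region for w in config.coupling_windows):
        psi_trial = rng.uniform(0, 2 * np.pi, size=(n_tr, 1))
        carrier = np.cos(2 * np.pi * config.gamma_freq * times[None, :] + psi_trial)
        envelope = np.ones((n_tr, n_sm))
        for w in config.coupling_windows:
            if w.amp_region != amp_region:
                continue
            mask = _window_mask(times, w.t_start_s, w.t_end_s)
            envelope[:, mask] = 1.0 + kappa * np.cos(
                driver_phase[w.phase_region][:, mask] - config.coupling_phase_offset
            )
        data[:, labels.index(amp_region), :] += config.gamma_amplitude * envelope * carrier

    roi = RoiSeries(data=data, fs=config.fs, t0=config.t0, region_labels=labels)
    record = _draw_clinical_record(config, group, kappa, rng)
    return roi, record


def _draw_clinical_record(
    config: SimulationConfig, group: str, kappa: float, rng: np.random.Generator
) -> SubjectRecord:
    """Draw HAM-D-6 scores consistent with the subject's group label.

    The reduction ratio comes from the linear-Gaussian clinical model of
    kappa; for patients the draw is conditioned on the side of the 50%
    responder boundary matching the intended group (bounded resampling),
    and the integer endpoint is nudged by one point if rounding crosses the
    boundary, so label-ratio consistency is exact.
    """
    age = float(np.clip(rng.normal(31.6, 8.5), 18, 60))
    sex = "F" if rng.random() < 0.46 else "M"
    education = float(np.clip(rng.normal(13.6, 2.9), 6, 22))
    sid = f"S{rng.integers(0, 10**9):09d}"
    if group == "HC":
        return SubjectRecord(
            id=sid, group=group, age=age, sex=sex, education=education, true_kappa=kappa
        )

    cm = config.clinical_model
    want_responder = group == "responder"
    ratio = cm.intercept + cm.slope * kappa + cm.noise_sd * rng.standard_normal()
    for _ in range(200):
        if min(ratio, 1.0) >= 0.5 if want_responder else min(ratio, 1.0) < 0.5:
            break
        ratio = cm.intercept + cm.slope * kappa + cm.noise_sd * rng.standard_normal()
    else:  # pragma: no cover - pathological clinical model
        ratio = 0.5 if want_responder else 0.49
    ratio = min(ratio, 1.0)

    baseline = int(np.clip(round(rng.normal(config.hamd6_baseline_mean, config.hamd6_baseline_sd)), 6, 22))
    endpoint = int(np.clip(round(baseline * (1.0 - ratio)), 0, baseline))
    # integer rounding may cross the 50% boundary; one-point nudge restores it
    if want_responder and (baseline - endpoint) / baseline < 0.5:
        endpoint -= 1
    elif not want_responder and (baseline - endpoint) / baseline >= 0.5:
        endpoint += 1
    endpoint = int(np.clip(endpoint, 0, baseline))
    exact_ratio = (baseline - endpoint) / baseline
    hamd17 = int(np.clip(round(baseline * 1.95 + rng.normal(0, 2.0)), baseline, 52))
    return SubjectRecord(
        id=sid,
        group=group,
        hamd6_baseline=float(baseline),
        hamd6_endpoint=float(endpoint),
        hamd17_baseline=float(hamd17),
        reduction_ratio=float(exact_ratio),
        age=age,
        sex=sex,
        education=education,
        true_kappa=kappa,
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[RoiSeries], list[SubjectRecord]]:
    """Simulate a full cohort with per-subject RNG substreams.

    Substreams are spawned deterministically from the master seed by subject
    index, so any subject's data is reproducible independently of cohort
    size. Patient group labels are re-derived from the simulated reduction
    ratios via the >= 50% rule; by construction they agree with the intended
    group, so the configured group sizes are exact.
    """
    roi_list: list[RoiSeries] = []
    records: list[SubjectRecord] = []
    idx = 0
    for group in ("non_responder", "responder", "HC"):
        for _ in range(config.group_sizes[group]):
            rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(idx,)))
            roi, rec = simulate_subject(config, group, rng)
            rec.id = f"S{idx:03d}"
            if group != "HC":
                derived = "responder" if rec.reduction_ratio >= 0.5 else "non_responder"
                rec.group = derived
            roi_list.append(roi)
            records.append(rec)
            idx += 1
    return roi_list, records


def project_to_sensors(
    roi: RoiSeries,
    lf: ToyLeadField,
    snr_db: float = np.inf,
    rng: np.random.Generator | int | None = 0,
) -> EpochedSeries:
    """Forward-project ROI series through the toy lead field.

    Every source belonging to an ROI carries that ROI's time series; white
    sensor noise is added so the sensor-level signal-to-noise power ratio is
    ``10^(snr_db/10)``; ``snr_db = inf`` gives the noiseless projection.
    """
    missing = [r for r in roi.region_labels if r not in lf.roi_map]
    if missing:
        raise ValueError(f"regions {missing} not present in lead-field roi_map")
    rng = np.random.default_rng(rng)
    n_tr, _, n_sm = roi.data.shape
    sources = np.zeros((n_tr, lf.n_sources, n_sm))
    for ri, label in enumerate(roi.region_labels):
        for s in lf.roi_map[label]:
            sources[:, s, :] = roi.data[:, ri, :]
    sensors = np.einsum("cs,tsn->tcn", lf.gain, sources)
    if np.isfinite(snr_db):
        sig_power = np.mean(sensors**2)
        noise_power = sig_power / (10.0 ** (snr_db / 10.0))
        sensors = sensors + rng.standard_normal(sensors.shape) * np.sqrt(noise_power)
    return EpochedSeries(
        data=sensors, fs=roi.fs, t0=roi.t0, channel_labels=tuple(f"MEG{i:03d}" for i in range(lf.n_sensors))
    )
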