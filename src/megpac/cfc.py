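"""Cross-regional phase-amplitude coupling (PAC) comodulograms.

Coupling is quantified as the coherence between the unit phasor of a slow
oscillation's phase in one region and the amplitude envelope of a fast
oscillation in another region, over pooled trial samples inside a short
post-stimulus window:

    PAC = |sum env * exp(-i phi)| / sqrt(N * sum env^2)

which is bounded in [0, 1] by Cauchy-Schwarz, invariant to envelope
rescaling and to global phase rotation. Phase and envelope are extracted by
band-pass filtering the *full* epoch and taking the analytic signal, and
only then restricted to the analysis window — the windows here (0-50 ms is
half an alpha cycle) are far too short to filter within.

The amplitude band-pass half-width must exceed the highest phase frequency,
or the modulation side-bands at f_amp +- f_phase are filtered out and the
coupling is undetectable by construction; the default is
max(2 Hz, 1.2 x max phase frequency).
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import Comodulogram, RoiSeries

DEFAULT_PHASE_FREQS = np.arange(8.0, 14.0)          # 8..13 Hz step 1
DEFAULT_AMP_FREQS = np.arange(30.0, 101.0)          # 30..100 Hz step 1


def amp_halfwidth(phase_freqs: np.ndarray = DEFAULT_PHASE_FREQS) -> float:
    """Default amplitude-band half-width: max(2 Hz, 1.2 x max phase freq)."""
    return float(max(2.0, 1.2 * np.max(phase_freqs)))


def phase_and_envelope(
    roi: RoiSeries,
    region: str,
    f_centre: float,
    kind: str,
    half_width: float | None = None,
) -> np.ndarray:
    """Instantaneous phase or envelope at ``f_centre`` for one region.

    Band-passes the full epoch (4th-order Butterworth, zero phase) around
    ``f_centre`` — half-width 1 Hz for phase bands, :func:`amp_halfwidth`
    for envelope bands — then takes the Hilbert analytic signal over the
    full epoch to avoid window-edge distortion. Returns trials x samples.
    """
    if kind not in ("phase", "envelope"):
        raise ValueError("kind must be 'phase' or 'envelope'")
    if half_width is None:
        half_width = 1.0 if kind == "phase" else amp_halfwidth()
    lo, hi = f_centre - half_width, f_centre + half_width
    if lo <= 0:
        raise ValueError(f"band [{lo}, {hi}] collapses below 0 Hz")
    if hi >= roi.fs / 2:
        raise ValueError(f"band [{lo}, {hi}] exceeds Nyquist {roi.fs / 2} Hz")
    x = roi.region(region)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=roi.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, x, axis=-1)
    analytic = signal.hilbert(filtered, axis=-1)
    return np.angle(analytic) if kind == "phase" else np.abs(analytic)


def pac_coherence(phase: np.ndarray, env: np.ndarray) -> float:
    """Phasor-envelope coherence over pooled samples (and trials).

    ``phase`` and ``env`` must have identical shapes; all samples are
    pooled. Returns 0 for an identically-zero envelope by convention.
    """
    phase = np.asarray(phase, dtype=float)
    env = np.asarray(env, dtype=float)
    if phase.shape != env.shape:
        raise ValueError(f"shape mismatch: {phase.shape} vs {env.shape}")
    n = env.size
    if n == 0:
        raise ValueError("empty window")
    denom_sq = n * np.sum(env**2)
    if denom_sq == 0:
        return 0.0
    num = np.abs(np.sum(env * np.exp(-1j * phase)))
    return float(num / np.sqrt(denom_sq))


def comodulogram(
    roi: RoiSeries,
    phase_region: str,
    amp_region: str,
    window: tuple[float, float],
    phase_freqs: np.ndarray = DEFAULT_PHASE_FREQS,
    amp_freqs: np.ndarray = DEFAULT_AMP_FREQS,
    amp_half_width: float | None = None,
    *,
    _env_cache: dict | None = None,
) -> Comodulogram:
    """PAC over a (phase frequency x amplitude frequency) grid.

    Phase comes from ``phase_region``, envelope from ``amp_region``; both
    are extracted on the full epoch and restricted to ``window`` seconds.
    ``_env_cache`` may be shared between calls on the same subject to reuse
    envelope extractions across windows/pairs.
    """
    phase_freqs = np.asarray(phase_freqs, dtype=float)
    amp_freqs = np.asarray(amp_freqs, dtype=float)
    t = roi.times
    mask = (t >= window[0]) & (t < window[1])
    if mask.sum() < 2:
        raise ValueError(f"window {window} spans fewer than 2 samples")
    if amp_half_width is None:
        amp_half_width = amp_halfwidth(phase_freqs)

    values = np.empty((phase_freqs.size, amp_freqs.size))
    envs = []
    for fa in amp_freqs:
        key = (amp_region, float(fa), amp_half_width)
        if _env_cache is not None and key in _env_cache:
            env = _env_cache[key]
        else:
            env = phase_and_envelope(roi, amp_region, fa, "envelope", amp_half_width)
            if _env_cache is not None:
                _env_cache[key] = env
        envs.append(env[:, mask])
    for pi, fp in enumerate(phase_freqs):
        key = (phase_region, float(fp), "phase")
        if _env_cache is not None and key in _env_cache:
            ph = _env_cache[key]
        else:
            ph = phase_and_envelope(roi, phase_region, fp, "phase")
            if _env_cache is not None:
                _env_cache[key] = ph
        ph_w = ph[:, mask]
        for ai in range(amp_freqs.size):
            values[pi, ai] = pac_coherence(ph_w, envs[ai])
    return Comodulogram(
        values=values,
        phase_freqs=phase_freqs,
        amp_freqs=amp_freqs,
        window=tuple(window),
        phase_region=phase_region,
        amp_region=amp_region,
        n_trials_used=roi.n_trials,
    )


def mean_vector_length(phase: np.ndarray, env: np.ndarray) -> float:
    """Alternative PAC estimator |mean(env e^{-i phi})| / mean(env).

    Kept as an independent cross-check of :func:`pac_coherence`; both rise
    monotonically with modulation depth under the generative model.
    """
    phase = np.asarray(phase, dtype=float)
    env = np.asarray(env, dtype=float)
    if phase.shape != env.shape:
        raise ValueError("shape mismatch")
    m = env.mean()
    if m == 0:
        return 0.0
    return float(np.abs(np.mean(env * np.exp(-1j * phase))) / m)


def shuffled_null(
    roi: RoiSeries,
    phase_region: str,
    amp_region: str,
    window: tuple[float, float],
    f_phase: float,
    f_amp: float,
    n_shuffles: int = 200,
    rng: np.random.Generator | int | None = 0,
    amp_half_width: float | None = None,
) -> np.ndarray:
    """Within-subject trial-shuffled PAC null at one (f_phase, f_amp) pair.

    Pairs each trial's phase with a circularly different trial's envelope,
    destroying phase-envelope alignment while preserving marginals.
    """
    rng = np.random.default_rng(rng)
    t = roi.times
    mask = (t >= window[0]) & (t < window[1])
    ph = phase_and_envelope(roi, phase_region, f_phase, "phase")[:, mask]
    env = phase_and_envelope(roi, amp_region, f_amp, "envelope", amp_half_width)[:, mask]
    n_tr = ph.shape[0]
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(n_tr)
        if n_tr > 1:
            while np.all(perm == np.arange(n_tr)):  # avoid identity pairing
                perm = rng.permutation(n_tr)
        null[i] = pac_coherence(ph, env[perm])
    return null
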