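"""Phase/envelope extraction and the phasor-envelope coherence statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from megpac import (
    RoiSeries,
    SimulationConfig,
    amp_halfwidth,
    comodulogram,
    pac_coherence,
    phase_and_envelope,
    shuffled_null,
    simulate_subject,
)

FS = 600.0


def _roi(data, labels=("A", "B"), fs=FS, t0=0.0):
    return RoiSeries(data, fs=fs, t0=t0, region_labels=labels)


class TestPhaseEnvelope:
    def _sine(self, f, dur=4.0, amp=1.0):
        t = np.arange(int(dur * FS)) / FS
        sig = amp * np.cos(2 * np.pi * f * t)
        return _roi(np.tile(sig, (2, 2, 1)))

    def test_pure_sine_envelope_constant(self):
        roi = self._sine(40.0)
        env = phase_and_envelope(roi, "A", 40.0, "envelope")
        interior = env[:, 600:-600]
        assert np.max(np.abs(interior - 1.0)) < 0.02

    def test_pure_sine_phase_slope(self):
        roi = self._sine(10.0)
        ph = phase_and_envelope(roi, "A", 10.0, "phase")
        unwrapped = np.unwrap(ph[0, 600:-600])
        slope = np.polyfit(np.arange(unwrapped.size) / FS, unwrapped, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10.0, rel=0.01)

    def test_am_carrier_envelope_recovered(self):
        t = np.arange(int(4 * FS)) / FS
        a_t = 1 + 0.5 * np.cos(2 * np.pi * 10 * t)
        sig = a_t * np.cos(2 * np.pi * 60 * t)
        roi = _roi(np.tile(sig, (1, 2, 1)))
        env = phase_and_envelope(roi, "A", 60.0, "envelope")
        r = np.corrcoef(env[0, 600:-600], a_t[600:-600])[0, 1]
        assert r > 0.99

    def test_collapsing_band_rejected(self):
        roi = self._sine(10.0)
        with pytest.raises(ValueError):
            phase_and_envelope(roi, "A", 0.5, "phase")
        with pytest.raises(ValueError):
            phase_and_envelope(roi, "A", 295.0, "envelope")


class TestPacCoherence:
    def test_closed_form_modulated_envelope(self):
        """env = 1 + cos(phi), phi uniform over whole cycles.

        Closed form of |<env e^{-i phi}>| / sqrt(<env^2>):
        numerator 1/2, denominator sqrt(3/2), so the value is
        1/sqrt(6) ~ 0.4082 (oracle: direct numerical integration).
        """
        phi = np.linspace(0, 2 * np.pi * 60, 60 * 500, endpoint=False)  # 60 cycles
        env = 1.0 + np.cos(phi)
        val = pac_coherence(phi, env)
        assert val == pytest.approx(1.0 / np.sqrt(6.0), abs=0.01)

    def test_constant_envelope_uniform_phase_vanishes(self):
        phi = np.linspace(0, 2 * np.pi * 25, 25 * 400, endpoint=False)
        val = pac_coherence(phi, np.ones_like(phi))
        assert val <= 0.05

    def test_zero_envelope_convention(self):
        phi = np.linspace(0, 2 * np.pi, 100)
        assert pac_coherence(phi, np.zeros_like(phi)) == 0.0

    def test_independent_processes_below_shuffled_null(self, rng):
        hits = 0
        n_sim = 40
        for _ in range(n_sim):
            phi = rng.uniform(-np.pi, np.pi, (20, 50))
            env = rng.random((20, 50)) + 0.5
            obs = pac_coherence(phi, env)
            null = np.array([
                pac_coherence(phi, env[rng.permutation(20)]) for _ in range(99)
            ])
            hits += obs < np.percentile(null, 95)
        assert hits >= 0.9 * n_sim * 0.9  # ≥ ~90% below the 95th percentile

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_and_invariances(self, seed):
        r = np.random.default_rng(seed)
        phi = r.uniform(-np.pi, np.pi, (3, 40))
        env = r.random((3, 40)) * r.uniform(0.1, 10)
        v = pac_coherence(phi, env)
        assert 0.0 <= v <= 1.0
        assert pac_coherence(phi + 1.234, env) == pytest.approx(v, abs=1e-12)
        assert pac_coherence(phi, 5.0 * env) == pytest.approx(v, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pac_coherence(np.zeros((2, 10)), np.zeros((2, 11)))


class TestComodulogram:
    def test_recovers_injected_coupling(self):
        cfg = SimulationConfig()
        roi, _ = simulate_subject(cfg, "responder", rng=42, kappa=0.8)
        c = comodulogram(roi, "rOFC", "rAMG", (0.1, 0.2),
                         amp_freqs=np.arange(30.0, 101.0, 2.0))
        i, j = np.unravel_index(np.argmax(c.values), c.values.shape)
        assert abs(c.phase_freqs[i] - cfg.alpha_freq) <= 1.0
        assert abs(c.amp_freqs[j] - cfg.gamma_freq) <= amp_halfwidth()

    def test_no_coupling_stays_below_shuffled_99th(self):
        """Without injected coupling, no comodulogram bin should exceed the
        99th percentile of the subject's trial-shuffled max-statistic null
        (the max over bins per shuffle, so the comparison is family-wise)."""
        cfg = SimulationConfig(n_trials=20, epoch_len_s=0.5, pre_stim_s=0.3, fs=300.0)
        phase_freqs = np.arange(8.0, 14.0)
        amp_freqs = np.arange(30.0, 81.0, 10.0)
        exceed = 0
        n_sub = 10
        for s in range(n_sub):
            roi, _ = simulate_subject(cfg, "HC", rng=200 + s, kappa=0.0)
            t = roi.times
            m = (t >= 0.1) & (t < 0.2)
            phases = [
                phase_and_envelope(roi, "rOFC", f, "phase")[:, m] for f in phase_freqs
            ]
            envs = [
                phase_and_envelope(roi, "rAMG", f, "envelope")[:, m] for f in amp_freqs
            ]
            obs = np.max([[pac_coherence(p, e) for e in envs] for p in phases])
            r = np.random.default_rng(300 + s)
            null = []
            for _ in range(100):
                perm = r.permutation(roi.n_trials)
                null.append(
                    np.max([[pac_coherence(p, e[perm]) for e in envs] for p in phases])
                )
            exceed += obs > np.percentile(null, 99)
        assert exceed <= 0.1 * n_sub

    def test_mean_value_monotone_in_kappa(self):
        cfg = SimulationConfig(n_trials=20, epoch_len_s=0.5, pre_stim_s=0.3, fs=300.0)
        means = []
        for k in (0.2, 0.4, 0.6, 0.8):
            vals = [
                comodulogram(
                    simulate_subject(cfg, "responder", rng=400 + rep, kappa=k)[0],
                    "rOFC", "rAMG", (0.1, 0.2),
                    phase_freqs=np.array([9.0, 10.0, 11.0]),
                    amp_freqs=np.arange(50.0, 71.0, 5.0),
                ).values.mean()
                for rep in range(6)
            ]
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_region_pair_asymmetry(self):
        """Coupling is directional: phase from A with envelope from B is a
        different statistic from phase from B with envelope from A."""
        cfg = SimulationConfig(n_trials=20, epoch_len_s=0.5, pre_stim_s=0.3, fs=300.0)
        roi, _ = simulate_subject(cfg, "responder", rng=77, kappa=0.9)
        grids = dict(phase_freqs=np.array([10.0]), amp_freqs=np.array([60.0]))
        fwd = comodulogram(roi, "rOFC", "rAMG", (0.1, 0.2), **grids)
        rev = comodulogram(roi, "rAMG", "rOFC", (0.1, 0.2), **grids)
        assert fwd.values[0, 0] > 2 * rev.values[0, 0]

    def test_short_window_rejected(self, coupled_subject):
        roi, _ = coupled_subject
        with pytest.raises(ValueError):
            comodulogram(roi, "rOFC", "rAMG", (0.1, 0.1 + 1e-4))
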