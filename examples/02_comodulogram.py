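"""Compute a cross-regional phase-amplitude comodulogram for one subject.

A strongly coupled subject is simulated (alpha driver in right OFC
modulating right amygdala gamma in the 100-200 ms window); the
comodulogram should peak near the injected (10 Hz, 60 Hz) pair.
"""

import numpy as np

from megpac import SimulationConfig, amp_halfwidth, comodulogram, simulate_subject

config = SimulationConfig()          # study conditions: 40 trials, 3 s epochs
roi, _ = simulate_subject(config, "responder", rng=42, kappa=0.8)

c = comodulogram(
    roi, phase_region="rOFC", amp_region="rAMG", window=(0.1, 0.2),
    amp_freqs=np.arange(30.0, 101.0, 2.0),
)
i, j = np.unravel_index(np.argmax(c.values), c.values.shape)
print(f"comodulogram shape: {c.values.shape} (phase 8-13 Hz x amplitude 30-100 Hz)")
print(f"global argmax: phase {c.phase_freqs[i]:.0f} Hz, amplitude {c.amp_freqs[j]:.0f} Hz, "
      f"PAC = {c.values[i, j]:.3f}")
print(f"injected coupling: ({config.alpha_freq:.0f} Hz, {config.gamma_freq:.0f} Hz); "
      f"amplitude half-width {amp_halfwidth():.1f} Hz")
print(f"map mean away from the coupled band: "
      f"{c.values[:, np.abs(c.amp_freqs - 60) > 20].mean():.3f}")
print("-> the argmax sits on the injected pair; off-band values hover near the")
print("   trial-shuffled chance level (a few percent at these pooled counts).")
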