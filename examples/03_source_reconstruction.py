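"""Beamform sensor data back to ROI series and remove leakage.

The subject's ROI series are forward-projected through a toy lead field to
30 sensors at 10 dB SNR, filtered, then reconstructed with an LCMV
beamformer; symmetric orthogonalization removes the zero-lag correlations
the projection/reconstruction introduces.
"""

import numpy as np

from megpac import (
    SimulationConfig,
    lcmv_filters,
    make_toy_leadfield,
    notch_and_bandpass,
    apply_filters,
    project_to_sensors,
    sensor_covariance,
    simulate_subject,
    symmetric_orthogonalize,
)

config = SimulationConfig(n_trials=20, epoch_len_s=3.0, fs=600.0)
roi, _ = simulate_subject(config, "responder", rng=3, kappa=0.8)

lf = make_toy_leadfield(roi.region_labels, n_sensors=30, sources_per_roi=1, rng=4)
sensors = project_to_sensors(roi, lf, snr_db=10.0, rng=5)
sensors = notch_and_bandpass(sensors)

filters = lcmv_filters(lf, sensor_covariance(sensors), reg=0.05)
recon = apply_filters(sensors, filters, lf)

print("unit-gain check: max |w.l - 1| =",
      f"{np.max(np.abs(np.einsum('sc,cs->s', filters.weights, lf.gain) - 1)):.2e}")
for region in ("rTHA", "rAMG", "rOFC"):
    r = np.corrcoef(roi.region(region).ravel(), recon.region(region).ravel())[0, 1]
    print(f"reconstruction correlation with ground truth, {region}: {abs(r):.3f}")

def max_off_diag_corr(x):
    c = np.corrcoef(x.data.transpose(1, 0, 2).reshape(x.n_regions, -1))
    return np.max(np.abs(c[~np.eye(x.n_regions, dtype=bool)]))

print(f"max |cross-ROI correlation| before orthogonalization: {max_off_diag_corr(recon):.3f}")
ortho = symmetric_orthogonalize(recon)
print(f"max |cross-ROI correlation| after orthogonalization:  {max_off_diag_corr(ortho):.2e}")
print("-> beamformed series track the true sources; orthogonalization drives")
print("   residual zero-lag leakage to numerical zero.")
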