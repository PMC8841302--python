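"""Cluster-based permutation test between responder groups.

Comodulograms are computed for simulated non-responders (attenuated
coupling, kappa 0.2) and responders (kappa 0.6); the test should find a
significant negative cluster (non-responder minus responder) around the
injected coupling bins.
"""

import numpy as np

from megpac import SimulationConfig, comodulogram, cluster_permutation, simulate_subject

config = SimulationConfig(n_trials=20, epoch_len_s=0.5, pre_stim_s=0.3, fs=300.0)
amp_freqs = np.arange(30.0, 81.0, 5.0)

def group_maps(group, n, seed0):
    maps = []
    for s in range(n):
        roi, _ = simulate_subject(config, group, rng=seed0 + s)
        c = comodulogram(roi, "rOFC", "rAMG", (0.1, 0.2), amp_freqs=amp_freqs)
        maps.append(c.values)
    return np.stack(maps)

nr = group_maps("non_responder", 15, 100)
r = group_maps("responder", 15, 200)

res = cluster_permutation(nr, r, n_permutations=500, rng=0)
print(f"{len(res.p_values)} cluster(s) found "
      f"(cluster-forming threshold |t| at alpha={res.cluster_alpha})")
for i, (mass, sign, p) in enumerate(zip(res.cluster_masses, res.cluster_signs, res.p_values)):
    bins = res.cluster_masks[i].sum()
    print(f"  cluster {i}: sign={sign:+d}, {bins} bins, mass={mass:8.1f}, p={p:.4f}")
sig = res.significant(0.05, sign=-1)
print("significant negative cluster(s):", sig if sig else "none")
print("-> the attenuated-coupling group shows a negative cluster over the")
print("   coupled (alpha phase, gamma amplitude) bins; its mass is referred to")
print("   the max-cluster permutation null, controlling family-wise error.")
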