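"""Boltzmann-inversion free-energy profile of DNA unwrapping.

For a zipper process with per-bp detachment cost epsilon the stationary
occupancy of i unwrapped bp is geometric, so dG(i) = -RT ln(f_i/f_max) is a
straight line of slope epsilon — the analysis should read the generator
parameter back off the profile.
"""

import numpy as np

import nucdyn as nd

params = nd.SyntheticParams(epsilon=0.5, n_frames=50_000, seed=3)
entry, exit_ = nd.simulate_unwrap_counts(params)

profile = nd.free_energy_1d(np.concatenate([entry, exit_]), temperature=310.0)
slope = nd.fit_profile_slope(profile)

print("  i   dG (kcal/mol)   frames")
for i in profile.i[:8]:
    print(f"{i:3d}   {profile.delta_g[i]:12.3f}   {profile.n_samples[i]:6d}")
print(f"fitted slope: {slope:.3f} kcal/mol/bp  (generator epsilon = 0.5)")
# dG grows ~0.5 kcal/mol per unwrapped bp: the Boltzmann inversion of the
# occupancy histogram recovers the per-bp unwrapping cost.
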