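"""Generate a synthetic nucleosome trajectory and recover DNA unwrapping.

The generator peels base pairs off the DNA ends with a per-bp free-energy
cost epsilon; the analysis counts unwrapped bp per frame (center displaced
> 7 A from the reference after core superposition) and should match the
generator's exact labels frame by frame.
"""

import numpy as np

import nucdyn as nd

params = nd.SyntheticParams(n_frames=2000, seed=12, noise_sigma=0.5)
system, ensemble, truth = nd.simulate_trajectory(params)

ensemble = nd.superpose(ensemble, system)
uw = nd.unwrap_series(ensemble, system)

agree = np.mean((uw.entry == truth.entry_unwrapped)
                & (uw.exit == truth.exit_unwrapped))
print(f"frames analysed:            {len(uw)}")
print(f"max total unwrapped bp:     {int(uw.total.max())}")
print(f"label agreement vs truth:   {100 * agree:.2f} %")
# agreement is the fraction of frames where both DNA sides' counts match the
# generator's pre-noise labels; near 100% because the 12.5 A peel clears the
# 7 A detection threshold with a wide margin.
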