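"""Histone-core flexibility via RMSF.

Each annotated histone-fold element fluctuates with its own amplitude in
the generator (loops twice as soft as helices).  RMSF about the ensemble
mean, aggregated over the two chain copies, should reproduce that ordering.
"""

import numpy as np

import nucdyn as nd

params = nd.SyntheticParams(n_frames=2000, seed=21, noise_sigma=0.0)
system, ensemble, _ = nd.simulate_trajectory(params)

results = [nd.chain_core_rmsf(ensemble, system, "H2A.Z", c) for c in (1, 2)]
agg = nd.aggregate_rmsf(results)

ch = system.chains[system.chain_index("H2A.Z", 1)]
for name, (lo, hi) in sorted(ch.core_annotations.items()):
    mask = (agg.positions >= lo) & (agg.positions <= hi)
    print(f"{name:7s} residues {lo:3d}-{hi:3d}  "
          f"RMSF = {agg.values[mask].mean():.2f} +/- "
          f"{agg.se[mask].mean():.3f} A")
# loops (L1, L2) show ~2x the RMSF of the helices, matching the generator's
# per-element sigmas; errors are SE over the n = 2 chain copies.
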