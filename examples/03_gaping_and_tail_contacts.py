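"""Nucleosome gaping and tail-DNA contact coupling.

Gaping separates the two DNA gyres along the superhelix axis; it is
measured as the distance between the SHL -4 and SHL +4 segment centroids.
The generator also programs the H2A.Z C-tail to unbind as its DNA side
unwraps, so the contact series anti-correlates with the unwrapped count.
"""

import numpy as np

import nucdyn as nd

params = nd.SyntheticParams(n_frames=4000, seed=8, gaping_mean=27.0)
system, ensemble, truth = nd.simulate_trajectory(params)

gaping = nd.gaping_series(ensemble, system)
h, edges = np.histogram(gaping.distance, bins=np.arange(15.0, 45.0, 0.5))
mode = 0.5 * (edges[np.argmax(h)] + edges[np.argmax(h) + 1])

contacts = nd.tail_dna_contact_series(ensemble, system, ("H2A.Z", 1, "C"),
                                      "total")
unwrap = nd.unwrap_series(ensemble, system)
r = nd.series_correlation(unwrap.entry, contacts.counts)
smoothed = nd.smooth_series(contacts.counts, window_ns=10,
                            sampling_interval=ensemble.sampling_interval)

print(f"gaping histogram mode:        {mode:.2f} A (programmed 27.0 A)")
print(f"unwrap vs C-tail contacts r:  {r:+.3f}")
print(f"raw/smoothed contact sd:      {contacts.counts.std():.2f} / "
      f"{smoothed.std():.2f}")
# the mode recovers the programmed gyre separation; the negative r is the
# programmed anti-coupling between unwrapping and tail binding; smoothing
# (Savitzky-Golay, 10 ns, degree 1) suppresses frame-to-frame noise.
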