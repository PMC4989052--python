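"""Tuning curves in the population rate, with significant-extremum detection.

A neuron's tuning curve is its spike probability conditioned on the summed
activity of all *other* neurons, p(sigma_i = 1 | K_other).  Curves are
estimated on random half-splits of the data; a local maximum is declared
significant when it exceeds its neighbours by at least 5 cross-split SDs.
The complete-coupling model reproduces these curves by construction; the
linear model generally cannot.
"""

import numpy as np

from popcoupling import make_synthetic_dataset
from popcoupling.evaluation import detect_extrema, tuning_replicates

# a shared multiplicative gain produces population-rate tuning
ds = make_synthetic_dataset("independent-with-gain", n_neurons=10, n_bins=40_000,
                            seed=1, gain_sd=1.2)

reps = tuning_replicates(ds.raster, n_splits=20, source="data", seed=2)
print("tuning-curve replicates:", reps.shape, "(splits x neurons x K_other)")

for i in range(ds.raster.n_neurons):
    extrema = detect_extrema(reps[:, i, :], sd_threshold=5.0)
    mean_curve = np.nanmean(reps[:, i, :], axis=0)
    peak = "none"
    if extrema:
        e = extrema[0]
        peak = f"{e.kind} at K_other={e.location:.0f}"
    print(f"neuron {i}: curve rises {mean_curve[0]:.3f} -> {np.nanmax(mean_curve):.3f}, "
          f"significant extremum: {peak}")

# With a positive shared gain every neuron's spike probability increases with
# the others' activity, so curves are increasing and interior maxima are rare;
# a neuron tuned to a *preferred* population rate would instead show a
# significant interior maximum.
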