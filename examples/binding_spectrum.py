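"""Recover a dissociation-rate spectrum from time-lapse binding durations.

Generates binding events from a two-cluster state spectrum (half the bound
molecules in a long-lived 16.2 s state, half in a 1 s state), observes them
through four time-lapse illumination conditions with 10% photobleaching per
illuminated frame, and inverts the survival-time distributions into a
photobleaching-corrected rate spectrum.  The slow cluster's residence time
and state fraction are the headline numbers.
"""

import numpy as np

from morphotrack import kinetics, synthetic

rates_true = np.array([1 / 16.2, 1.0])  # 1/s
state_true = np.array([0.5, 0.5])

data, truth = synthetic.generate_survival(
    rates_true, state_true, n_events=10_000, bleach_per_frame=0.1, seed=3
)
print(f"events observed: {data.n_events} "
      f"(censored fraction {data.censored_fraction():.1%})")

spectrum = kinetics.invert_spectrum(data)
print(f"estimated bleaching per illuminated frame: "
      f"{spectrum.bleaching_per_frame:.3f} (truth 0.100)")

clusters = kinetics.cluster_spectrum(spectrum, boundaries=[0.15])
t_slow = clusters.residence_times[0]
f_slow = clusters.state_fractions[0]
print(f"slow cluster: residence time = {t_slow:.1f} s (truth 16.2 s), "
      f"state fraction = {100 * f_slow:.1f}% (truth 50.0%)")

envelope, summary = kinetics.resample_spectrum(
    data, n_reps=20, seed=4, boundaries=[0.15]
)
print(f"resampling s.d.: residence +/- {summary.sd_residence[0]:.1f} s, "
      f"fraction +/- {100 * summary.sd_fraction[0]:.1f} points")
print(
    "a single 10,000-event experiment carries ~25% uncertainty on the slow "
    "residence time; scripts/acceptance.py medians over replicates."
)
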