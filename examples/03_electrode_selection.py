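"""Per-participant electrode selection and the condition contrast at 14 Hz.

The intermodulation response sits at different scalp sites in different
people, so each participant contributes the mean percent power change
over their own best cluster of electrodes (largest neighboring subset of
their top-6 at 14 Hz, conditions averaged before selection). The group
test asks whether that percent change differs between the related and
unrelated conditions.
"""

from rifteeg import (SimConfig, percent_change, selection_contrast,
                     neighbor_frequency_validation, simulate_dataset,
                     windowed_power)

cfg = SimConfig(n_participants=12, n_trials_per_condition=20, seed=5)
dataset = simulate_dataset(cfg)
pc = percent_change(windowed_power(dataset, "tagging"),
                    windowed_power(dataset, "baseline"))

res = selection_contrast(pc, cfg.montage, freq=14.0, k=6)
print(f"t({res.df}) = {res.t:.2f}, p = {res.p:.4f}, d = {res.cohens_d:.2f}")
print("sub-01 selected cluster:", ", ".join(res.clusters["sub-01"]))
print(res.mean_pc.round(1).head())
# A negative t means the related condition shows the weaker 14 Hz
# response: the generative model gives the unrelated condition the larger
# interaction gain, and the contrast recovers that direction.

print(neighbor_frequency_validation(pc, cfg.montage).round(1))
# The group-mean selected percent change should peak at 14 Hz, not at the
# neighboring frequencies: the effect is an intermodulation line, not a
# broadband power shift.
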