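"""Simulate a randomized trial with high-dimensional biomarkers.

Draws one replicate of the ten-predictive-marker scenario, prints the
cohort's censoring fraction and arm balance, and writes the training half
to CSV.  The censoring fraction should sit near 0.20: with ten strong
treatment-modifying markers the event hazard varies widely across patients,
and more of them outlive the 2-5 year uniform censoring window.
"""

import numpy as np

from hierlasso import generate_replicate, scenario_presets, write_survival_csv

config = scenario_presets(seed=7)["s3"]
replicate = generate_replicate(config, replicate_id=0)
train = replicate.training

print(f"scenario {config.name}: n={train.n} patients, p={train.p} biomarkers")
print(f"true predictive markers (gamma=ln 0.5): {config.predictive_indices}")
print(f"censoring fraction  : {1 - train.event.mean():.3f}")
print(f"experimental arm    : {(train.treatment == 0.5).mean():.3f}")
print(f"median observed time: {np.median(train.time):.2f} years")

write_survival_csv(train, "scratch_training.csv")
print("training half written to scratch_training.csv "
      "(columns time,event,treatment,X0001..X0500)")
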