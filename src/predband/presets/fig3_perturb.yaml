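name: fig3_perturb
description: After K4-only training, predict responses with single parameters multiplied or divided by 10.
scenario: cascade_train
model: nominal
train_on: [K4]
protocols: [pulse_train]
perturbations:
  - {parameter: f1, factor: 10}
  - {parameter: f1, factor: 0.1}
  - {parameter: a1, factor: 10}
  - {parameter: a1, factor: 0.1}
seed: 205
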