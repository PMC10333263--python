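name: figS2_short_on
description: Train on data from an inadequate 1-h 'on' protocol; prediction bands stay broad.
scenario: cascade_train_short_on
model: nominal
train_on: [K4]
protocols: [pulse_train]
seed: 208
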