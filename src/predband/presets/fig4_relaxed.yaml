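name: fig4_relaxed
description: Train the relaxed cascade (all three feedbacks free) on K4-only data from the nominal model.
scenario: cascade_train
model: relaxed
train_on: [K4]
protocols: [pulse_train, staircase]
seed: 206
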