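name: fig2_K4
description: Train the nominal cascade on the K4 trajectory only; predict responses to test protocols and report the deviation spectrum.
scenario: cascade_train
model: nominal
train_on: [K4]
protocols: [pulse_train, staircase]
seed: 202
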