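name: fig2_all
description: Train the nominal cascade on all four variables; predictions and deviation spectrum.
scenario: cascade_train
model: nominal
train_on: [K1, K2, K3, K4]
protocols: [pulse_train, staircase]
seed: 204
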