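name: fig2_K2K4
description: Train the nominal cascade on K2 and K4 trajectories; predictions and deviation spectrum.
scenario: cascade_train
model: nominal
train_on: [K2, K4]
protocols: [pulse_train, staircase]
seed: 203
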