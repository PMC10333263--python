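name: fig5_simplified
description: Train the oversimplified two-step cascade on nominal K4 data; its narrow bands miss the nominal trajectory.
scenario: cascade_train
model: simplified
train_on: [K4]
protocols: [pulse_train]
seed: 207
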