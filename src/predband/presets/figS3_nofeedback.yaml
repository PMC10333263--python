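name: figS3_nofeedback
description: Train a wrong model with no negative feedback on nominal K4 data; wrong predictions with narrow bands.
scenario: cascade_train
model: nofeedback
train_on: [K4]
protocols: [pulse_train]
seed: 209
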