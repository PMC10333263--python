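name: fig1d
description: Generate the cascade training dataset (nominal model, on-off protocol, 3 noisy replicates); no training stage.
scenario: cascade_train
model: nominal
train_on: []
protocols: []
seed: 201
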