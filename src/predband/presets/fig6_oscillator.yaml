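name: fig6_oscillator
description: Train the three-mass oscillator on the displacement of the mass opposite to the forcing; predict the sinusoidal-forcing response.
scenario: oscillator_train
model: oscillator
train_on: [x3]
protocols: [f_test_sine]
seed: 210
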