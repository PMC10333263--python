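"""Posterior prediction bands under a new stimulation protocol.

After K4-only training, every retained parameter set is simulated under a
pulse-train protocol the model never saw.  The 80% band for K4 is narrow and
covers the true (nominal) trajectory, while the bands for the unmeasured
K1-K3 stay wide: the non-identifiable model predicts exactly what it was
trained on, and honestly reports ignorance about the rest.
"""

import numpy as np

from predband import (
    MCMCConfig,
    make_training_scenario,
    predict_band,
    run_training,
    simulate,
    softlog,
)
from predband.models import CASCADE_T_GRID, get_protocol

model, protocol, measurements = make_training_scenario("cascade_train")
posterior = run_training(
    model, measurements, ["K4"], config=MCMCConfig(scale_factor=0.01, seed=2),
    protocol=protocol,
)

test_protocol = get_protocol("pulse_train")
band = predict_band(posterior, model, test_protocol, CASCADE_T_GRID)
truth = simulate(model, model.nominal, test_protocol, CASCADE_T_GRID)

print(f"80% prediction bands under {test_protocol.name!r}:")
print(f"{'variable':>9} {'median width':>13} {'coverage of nominal':>20}")
for var in model.state_names:
    cov = band.coverage(CASCADE_T_GRID, softlog(truth.state(var)), var)
    print(f"{var:>9} {band.median_width(var):13.2f} {cov:20.0%}")
print("\nwidths are in softlog units (decades); K4's band is several times")
print("narrower than the others and still contains the true trajectory.")
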