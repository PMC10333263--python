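"""Generate the in-silico training dataset.

Measurements emulate an experiment: the deterministic trajectory is read out
hourly, softlog-transformed (log10(0.001 + x)), and perturbed with Gaussian
noise of SD 0.3, independently for 3 replicates.  Prints the first records
and verifies the empirical noise level.
"""

import numpy as np

from predband import make_training_scenario, simulate, softlog

model, protocol, measurements = make_training_scenario("cascade_train")
print(measurements.records.head(10).to_string(index=False))
print(f"...\n{len(measurements.records)} records "
      f"({len(measurements.variables)} variables x {len(measurements.times)} times "
      f"x {measurements.n_replicates} replicates)")

from predband.models import CASCADE_T_GRID

traj = simulate(model, model.nominal, protocol, CASCADE_T_GRID)
truth = {
    (v, t): softlog(x)
    for v in model.state_names
    for t, x in zip(traj.times, traj.state(v))
}
resid = [
    m - truth[(v, t)]
    for v, t, m in zip(
        measurements.records.variable, measurements.records.time, measurements.records.value
    )
]
print(f"empirical residual SD: {np.std(resid):.3f} (error model: sigma = 0.3)")
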