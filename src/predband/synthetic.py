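"""In-silico measurement generation.

Measurements emulate noisy experimental readouts of the deterministic model:
the trajectory is evaluated on a regular grid (full hours for the cascade,
full seconds for the oscillator), cascade values are softlog-transformed,
and independent Gaussian noise with sigma_error = 0.3 is added to each of
3 replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models as _models
from .models import ModelSpec, Protocol, Trajectory, simulate

__all__ = [
    "SIGMA_ERROR",
    "SOFTLOG_OFFSET",
    "SOFTLOG_BASE",
    "softlog",
    "MeasurementSet",
    "generate_measurements",
    "make_training_scenario",
    "SCENARIO_NAMES",
]

#: Measurement-error SD shared by all models.
SIGMA_ERROR = 0.3

#: softlog(x) = log_base(offset + x).  Base 10 by default; base e can be
#: toggled for sensitivity checks.
SOFTLOG_OFFSET = 1e-3
SOFTLOG_BASE = 10.0


def softlog(x):
    """softlog(x) = log10(0.001 + x); strictly increasing on x >= 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("softlog requires x >= 0")
    out = np.log(SOFTLOG_OFFSET + x) / np.log(SOFTLOG_BASE)
    return out if out.ndim else float(out)


@dataclass
class MeasurementSet:
    """Noisy observations indexed by (variable, time, replicate).

    ``records`` has columns variable, time, replicate, value; the value is on
    the transformed scale (softlog for the cascade, raw displacement for the
    oscillator).
    """

    records: pd.DataFrame
    sigma_error: float = SIGMA_ERROR
    transform: str = "softlog"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"variable", "time", "replicate", "value"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(required)}")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.records["variable"]))

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.records["time"].to_numpy(dtype=float))

    @property
    def n_replicates(self) -> int:
        return int(self.records["replicate"].nunique())

    def subset(self, variables) -> "MeasurementSet":
        """Measurements of the given variables only (training selection)."""
        variables = list(variables)
        unknown = set(variables) - set(self.variables)
        if unknown:
            raise KeyError(f"variables not in measurement set: {sorted(unknown)}")
        rec = self.records[self.records["variable"].isin(variables)].reset_index(drop=True)
        return MeasurementSet(rec, self.sigma_error, self.transform, dict(self.provenance))

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            meta = " ".join(f"{k}={v}" for k, v in sorted(self.provenance.items()))
            fh.write(f"# sigma_error={self.sigma_error} transform={self.transform} {meta}\n")
            self.records.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "MeasurementSet":
        with open(path) as fh:
            header = fh.readline()
            df = pd.read_csv(fh)
        meta = dict(
            tok.split("=", 1) for tok in header.lstrip("# ").split() if "=" in tok
        )
        return cls(
            df,
            sigma_error=float(meta.get("sigma_error", SIGMA_ERROR)),
            transform=meta.get("transform", "softlog"),
            provenance={k: v for k, v in meta.items() if k not in ("sigma_error", "transform")},
        )

    def kernel_arrays(self, model: ModelSpec, variables=None):
        """Flatten records into (state_index, time_index, value) arrays against
        the model's state layout and the measurement time grid."""
        rec = self.records if variables is None else self.subset(variables).records
        times = self.times
        t_index = {t: i for i, t in enumerate(times)}
        var_idx = np.array(
            [model.state_names.index(v) for v in rec["variable"]], dtype=np.int64
        )
        tidx = np.array([t_index[float(t)] for t in rec["time"]], dtype=np.int64)
        vals = rec["value"].to_numpy(dtype=float)
        return var_idx, tidx, vals, times


def generate_measurements(
    traj: Trajectory,
    times=None,
    sigma_error: float = SIGMA_ERROR,
    n_replicates: int = 3,
    transform: str = "softlog",
    seed: int | None = None,
    variables=None,
) -> MeasurementSet:
    """Draw ``m_{k,t,r} = transform(x_k(t)) + Normal(0, sigma_error)`` with
    independent noise across variables, times and replicates.

    ``times`` must lie on the trajectory grid — measurements are never
    interpolated.
    """
    if times is None:
        times = traj.times
    times = np.asarray(times, dtype=float)
    pos = []
    for t in times:
        hits = np.nonzero(np.isclose(traj.times, t, rtol=0.0, atol=1e-9))[0]
        if hits.size == 0:
            raise ValueError(f"measurement time {t} not on the trajectory grid")
        pos.append(hits[0])
    pos = np.asarray(pos)
    if variables is None:
        variables = traj.state_names
    rng = np.random.default_rng(seed)
    rows = []
    for var in variables:
        x = traj.values[pos, traj.state_names.index(var)]
        y = softlog(x) if transform == "softlog" else np.asarray(x, dtype=float)
        for r in range(1, n_replicates + 1):
            noise = rng.normal(0.0, sigma_error, size=y.shape) if sigma_error > 0 else 0.0
            vals = y + noise
            for t, m in zip(times, np.atleast_1d(vals)):
                rows.append((var, float(t), r, float(m)))
    records = pd.DataFrame(rows, columns=["variable", "time", "replicate", "value"])
    return MeasurementSet(
        records,
        sigma_error=sigma_error,
        transform=transform,
        provenance={
            "model": traj.model_name,
            "protocol": traj.protocol_name,
            "seed": seed,
        },
    )


#: Frozen scenario fixtures: (model variant, protocol, generator seed).
_SCENARIOS = {
    "cascade_train": ("nominal", "s_train", 101),
    "cascade_train_short_on": ("nominal", "s_train_short", 102),
    "oscillator_train": ("oscillator", "f_train", 103),
}

SCENARIO_NAMES = tuple(_SCENARIOS)


def make_training_scenario(name: str):
    """Return the frozen training fixture ``(model, protocol, measurements)``.

    Each scenario simulates the generating model at its nominal parameters
    under the training protocol and adds 3 replicates of Gaussian noise with
    a fixed, recorded seed.
    """
    try:
        variant, protocol_name, seed = _SCENARIOS[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(_SCENARIOS)}") from None
    model = _models.get_model(variant)
    protocol = _models.get_protocol(protocol_name)
    t_grid = _models.default_t_grid(model)
    traj = simulate(model, model.nominal, protocol, t_grid)
    measurements = generate_measurements(
        traj,
        times=t_grid,
        sigma_error=SIGMA_ERROR,
        n_replicates=3,
        transform=model.transform,
        seed=seed,
        variables=model.observed_names,
    )
    measurements.provenance["scenario"] = name
    return model, protocol, measurements
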