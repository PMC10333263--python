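"""ODE models, stimulation protocols and deterministic simulation.

Two model families are provided:

* a four-step signalling cascade ``S -> K1 -> K2 -> K3 -> K4`` with a
  negative feedback from K4 onto the activation of step 1 (and optionally
  steps 2 and 3), in four variants — *nominal* (f2 = f3 = 0 fixed),
  *relaxed* (all three feedback strengths free), *simplified* (two steps,
  K1 drives K4 directly) and *no-feedback* (f1 = f2 = f3 = 0);
* a damped harmonic oscillator of three masses in a chain connected by two
  springs, driven by a force on the first mass.

Cascade activities are fractions of active protein, so each activation term
saturates as K_i -> 1; the K4 feedback divides the activation rate of the
regulated step by (1 + f_j * K4).  Rate constants are per hour; the
oscillator uses seconds.

Nominal parameter values are package defaults chosen to give a multi-hour
cascade response (rise during a 4-h 'on' phase, relaxation afterwards) and
order-one oscillator displacements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _ode

__all__ = [
    "Protocol",
    "CascadeParams",
    "OscillatorParams",
    "ModelSpec",
    "Trajectory",
    "cascade_rhs",
    "simplified_rhs",
    "oscillator_rhs",
    "simulate",
    "get_model",
    "get_protocol",
    "MODEL_VARIANTS",
    "CASCADE_PROTOCOLS",
    "OSCILLATOR_PROTOCOLS",
    "NOMINAL_CASCADE",
    "NOMINAL_OSCILLATOR",
]

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-9


# --------------------------------------------------------------------------
# protocols


@dataclass(frozen=True)
class Protocol:
    """Time-dependent scalar input: piecewise-constant segments plus an
    optional sinusoid ``A * sin(omega * (t - t_start) + phase)``.

    Outside all segments (and before the sinusoid's start) the input is 0.
    Segments must not overlap; this is checked at construction.
    """

    name: str = "custom"
    segments: tuple[tuple[float, float, float], ...] = ()
    sinusoid: tuple[float, float, float, float] | None = None  # (A, omega, phase, t_start)

    def __post_init__(self):
        segs = sorted(self.segments)
        for (t0, t1, _v) in segs:
            if not t0 < t1:
                raise ValueError(f"protocol segment with t_start >= t_end: ({t0}, {t1})")
        for (_, t1a, _), (t0b, _, _) in zip(segs, segs[1:]):
            if t0b < t1a:
                raise ValueError("overlapping protocol segments")
        object.__setattr__(self, "segments", tuple(segs))

    def value(self, t: float) -> float:
        """Input value at time ``t``."""
        if not np.isfinite(t):
            raise ValueError("protocol evaluation requires finite t")
        u = 0.0
        for (t0, t1, v) in self.segments:
            if t0 <= t < t1:
                u += v
                break
        if self.sinusoid is not None:
            a, omega, phase, t_start = self.sinusoid
            if t >= t_start:
                u += a * math.sin(omega * (t - t_start) + phase)
        return u

    __call__ = value

    def _arrays(self):
        if self.segments:
            seg = np.asarray(self.segments, dtype=float)
            t0, t1, v = seg[:, 0].copy(), seg[:, 1].copy(), seg[:, 2].copy()
        else:
            t0 = t1 = v = np.empty(0, dtype=float)
        sin_par = np.zeros(4)
        if self.sinusoid is not None:
            sin_par[:] = self.sinusoid
        return t0, t1, v, sin_par


def evaluate_protocol(protocol: Protocol, t: float) -> float:
    return protocol.value(t)


#: Training and test protocols for the cascade (times in hours).
CASCADE_PROTOCOLS: dict[str, Protocol] = {
    "s_train": Protocol("s_train", segments=((0.0, 4.0, 1.0),)),
    "s_train_short": Protocol("s_train_short", segments=((0.0, 1.0, 1.0),)),
    "single_pulse": Protocol("single_pulse", segments=((2.0, 6.0, 1.0),)),
    "pulse_train": Protocol(
        "pulse_train", segments=((0.0, 2.0, 1.0), (8.0, 10.0, 1.0), (16.0, 18.0, 1.0))
    ),
    "long_step": Protocol("long_step", segments=((0.0, 20.0, 0.5),)),
    "staircase": Protocol(
        "staircase", segments=((0.0, 6.0, 0.25), (6.0, 12.0, 0.5), (12.0, 18.0, 1.0))
    ),
}

#: Training and test protocols for the oscillator (times in seconds).
OSCILLATOR_PROTOCOLS: dict[str, Protocol] = {
    "f_train": Protocol("f_train", segments=((0.0, 10.0, 1.0),)),
    "f_test_sine": Protocol("f_test_sine", sinusoid=(1.0, 1.0, 0.0, 0.0)),
}


def get_protocol(name: str) -> Protocol:
    for lib in (CASCADE_PROTOCOLS, OSCILLATOR_PROTOCOLS):
        if name in lib:
            return lib[name]
    raise KeyError(f"unknown protocol {name!r}")


# --------------------------------------------------------------------------
# parameters

CASCADE_PARAM_NAMES = ("a1", "a2", "a3", "a4", "d1", "d2", "d3", "d4", "f1", "f2", "f3")
SIMPLIFIED_PARAM_NAMES = ("a1", "d1", "a4", "d4", "f1")
OSCILLATOR_PARAM_NAMES = ("m1", "m2", "m3", "b1", "b2", "b3", "k1", "k2")

#: Package-default parameter values used to generate training data.
NOMINAL_CASCADE: dict[str, float] = {
    "a1": 0.4, "a2": 0.5, "a3": 0.4, "a4": 0.6,
    "d1": 0.3, "d2": 0.3, "d3": 0.4, "d4": 0.3,
    "f1": 5.0, "f2": 0.0, "f3": 0.0,
}

NOMINAL_OSCILLATOR: dict[str, float] = {
    "m1": 1.0, "m2": 2.0, "m3": 1.0,
    "b1": 0.5, "b2": 0.2, "b3": 0.3,
    "k1": 2.0, "k2": 1.0,
}


@dataclass(frozen=True)
class CascadeParams:
    """Activation (a_i, 1/h), deactivation (d_i, 1/h) and feedback-strength
    (f_j, dimensionless) parameters of the cascade."""

    a1: float; a2: float; a3: float; a4: float
    d1: float; d2: float; d3: float; d4: float
    f1: float = 0.0; f2: float = 0.0; f3: float = 0.0

    def __post_init__(self):
        for name in CASCADE_PARAM_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"cascade parameter {name} must be >= 0")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in CASCADE_PARAM_NAMES], dtype=float)


@dataclass(frozen=True)
class OscillatorParams:
    """Masses m_i, damping coefficients b_i and spring constants k_j."""

    m1: float; m2: float; m3: float
    b1: float; b2: float; b3: float
    k1: float; k2: float

    def __post_init__(self):
        for name in ("m1", "m2", "m3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"mass {name} must be > 0")
        for name in ("b1", "b2", "b3", "k1", "k2"):
            if getattr(self, name) < 0:
                raise ValueError(f"oscillator parameter {name} must be >= 0")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in OSCILLATOR_PARAM_NAMES], dtype=float)


def _as_array(params, names) -> np.ndarray:
    if isinstance(params, (CascadeParams, OscillatorParams)):
        arr = params.to_array()
    elif isinstance(params, dict):
        arr = np.array([params[n] for n in names], dtype=float)
    else:
        arr = np.asarray(params, dtype=float)
    if arr.shape != (len(names),):
        raise ValueError(f"expected {len(names)} parameters, got shape {arr.shape}")
    return arr


# --------------------------------------------------------------------------
# model specs


@dataclass(frozen=True)
class ModelSpec:
    """A model variant: state layout, parameter layout, fixed-parameter mask,
    initial condition and observation transform."""

    name: str
    model_id: int
    state_names: tuple[str, ...]
    param_names: tuple[str, ...]
    fixed: dict[str, float]  # parameters held at a constant value
    initial_state: np.ndarray
    transform: str  # "softlog" | "identity"
    nominal: dict[str, float]
    observed_names: tuple[str, ...] = ()  # states reported as measurements

    def __post_init__(self):
        if not self.observed_names:
            object.__setattr__(self, "observed_names", self.state_names)

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.param_names if n not in self.fixed)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def full_params(self, free_values: dict[str, float] | np.ndarray) -> np.ndarray:
        """Assemble the full parameter vector from free values + fixed mask."""
        if isinstance(free_values, dict):
            vals = dict(self.fixed)
            vals.update(free_values)
            return np.array([vals[n] for n in self.param_names], dtype=float)
        free_values = np.asarray(free_values, dtype=float)
        out = np.empty(len(self.param_names))
        j = 0
        for i, n in enumerate(self.param_names):
            if n in self.fixed:
                out[i] = self.fixed[n]
            else:
                out[i] = free_values[j]
                j += 1
        return out

    @property
    def nominal_array(self) -> np.ndarray:
        return np.array([self.nominal[n] for n in self.param_names], dtype=float)

    @property
    def nominal_free(self) -> np.ndarray:
        return np.array([self.nominal[n] for n in self.free_names], dtype=float)


def _cascade_spec(name: str, fixed: dict[str, float]) -> ModelSpec:
    return ModelSpec(
        name=name,
        model_id=_ode.MODEL_CASCADE,
        state_names=("K1", "K2", "K3", "K4"),
        param_names=CASCADE_PARAM_NAMES,
        fixed=fixed,
        initial_state=np.zeros(4),
        transform="softlog",
        nominal=dict(NOMINAL_CASCADE),
    )


MODEL_VARIANTS: dict[str, ModelSpec] = {
    "nominal": _cascade_spec("nominal", {"f2": 0.0, "f3": 0.0}),
    "relaxed": _cascade_spec("relaxed", {}),
    "nofeedback": _cascade_spec("nofeedback", {"f1": 0.0, "f2": 0.0, "f3": 0.0}),
    "simplified": ModelSpec(
        name="simplified",
        model_id=_ode.MODEL_SIMPLIFIED,
        state_names=("K1", "K4"),
        param_names=SIMPLIFIED_PARAM_NAMES,
        fixed={},
        initial_state=np.zeros(2),
        transform="softlog",
        nominal={n: NOMINAL_CASCADE[n] for n in SIMPLIFIED_PARAM_NAMES},
    ),
    "oscillator": ModelSpec(
        name="oscillator",
        model_id=_ode.MODEL_OSCILLATOR,
        state_names=("x1", "v1", "x2", "v2", "x3", "v3"),
        param_names=OSCILLATOR_PARAM_NAMES,
        fixed={},
        initial_state=np.zeros(6),
        transform="identity",
        nominal=dict(NOMINAL_OSCILLATOR),
        observed_names=("x1", "x2", "x3"),
    ),
}


def get_model(name: str) -> ModelSpec:
    try:
        return MODEL_VARIANTS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODEL_VARIANTS)}"
        ) from None


# --------------------------------------------------------------------------
# right-hand sides (thin wrappers over the compiled kernel)


def _rhs_dispatch(model_id, state, t, params_arr, protocol):
    state = np.asarray(state, dtype=float)
    out = np.empty_like(state)
    t0, t1, v, sin_par = protocol._arrays()
    _ode.rhs(model_id, float(t), state, params_arr, t0, t1, v, sin_par, out)
    return out


def cascade_rhs(state, t, params, protocol: Protocol) -> np.ndarray:
    """dK/dt of the 4-step cascade at ``(state, t)``."""
    arr = _as_array(params, CASCADE_PARAM_NAMES)
    if np.any(arr < 0):
        raise ValueError("cascade parameters must be >= 0")
    return _rhs_dispatch(_ode.MODEL_CASCADE, state, t, arr, protocol)


def simplified_rhs(state, t, params, protocol: Protocol) -> np.ndarray:
    """d(K1, K4)/dt of the simplified two-step cascade."""
    arr = _as_array(params, SIMPLIFIED_PARAM_NAMES)
    if np.any(arr < 0):
        raise ValueError("cascade parameters must be >= 0")
    return _rhs_dispatch(_ode.MODEL_SIMPLIFIED, state, t, arr, protocol)


def oscillator_rhs(state, t, params, protocol: Protocol) -> np.ndarray:
    """d(x, v)/dt of the three-mass damped oscillator."""
    arr = _as_array(params, OSCILLATOR_PARAM_NAMES)
    if np.any(arr[:3] <= 0):
        raise ValueError("masses must be > 0")
    return _rhs_dispatch(_ode.MODEL_OSCILLATOR, state, t, arr, protocol)


# --------------------------------------------------------------------------
# simulation


class SolverError(RuntimeError):
    """ODE integration failed; carries the offending parameter vector."""

    def __init__(self, message: str, params: np.ndarray):
        super().__init__(message)
        self.params = np.asarray(params)


@dataclass
class Trajectory:
    """Deterministic solution sampled on a time grid (untransformed state)."""

    times: np.ndarray
    values: np.ndarray  # [time, state]
    state_names: tuple[str, ...]
    model_name: str = ""
    protocol_name: str = ""

    def state(self, name: str) -> np.ndarray:
        return self.values[:, self.state_names.index(name)]

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values, columns=list(self.state_names))
        df.insert(0, "time", self.times)
        with open(path, "w") as fh:
            fh.write(f"# model={self.model_name} protocol={self.protocol_name}\n")
            df.to_csv(fh, index=False)


def simulate(
    model: ModelSpec,
    params,
    protocol: Protocol,
    t_grid,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_steps: int = 2_000_000,
) -> Trajectory:
    """Integrate ``model`` with Dormand-Prince 5(4) and report the state at
    the requested times.

    ``t_grid`` must be increasing and start at 0 (the initial condition is
    fixed and not estimated).  Raises :class:`SolverError` if the integrator
    fails; inference layers treat that as zero likelihood.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise ValueError("t_grid must be a 1-D array with at least two points")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    arr = _as_array(params, model.param_names)
    t0, t1, v, sin_par = protocol._arrays()
    values, status = _ode.integrate(
        model.model_id, arr, model.initial_state, t_grid, t0, t1, v, sin_par, rtol, atol,
        max_steps,
    )
    if status != _ode.STATUS_OK:
        raise SolverError(f"ODE solver failed with status {status}", arr)
    return Trajectory(
        times=t_grid,
        values=values,
        state_names=model.state_names,
        model_name=model.name,
        protocol_name=protocol.name,
    )


#: Default measurement grids: hourly over 24 h (cascade), each second over
#: 30 s (oscillator).
CASCADE_T_GRID = np.arange(0.0, 24.0 + 1e-9, 1.0)
OSCILLATOR_T_GRID = np.arange(0.0, 30.0 + 1e-9, 1.0)


def default_t_grid(model: ModelSpec) -> np.ndarray:
    if model.model_id == _ode.MODEL_OSCILLATOR:
        return OSCILLATOR_T_GRID.copy()
    return CASCADE_T_GRID.copy()
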