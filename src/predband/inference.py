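"""Bayesian training: priors, likelihood, Metropolis-Hastings, diagnostics.

The posterior over model parameters theta given measurements m_{k,t,r} is

    f(theta) = P(theta) * prod_k prod_{t,r} N(m_{k,t,r} | y_k(t), sigma_error)

where y_k(t) is the (softlog-transformed, for the cascade) model trajectory
and the outer product runs over only the variables selected for training.
Sampling uses plain Metropolis-Hastings with a symmetric Gaussian proposal:
spherical with sigma = 0.2 in log-parameter space for the cascades,
elliptical in natural space for the oscillator (sigma 1.0 / 0.2 / 0.4 for
masses / damping / stiffness).

At full scale: 8 chains of 1.5 million steps, the first 0.25 million
discarded as burn-in, every 1000th step retained — 10,000 posterior samples.
``MCMCConfig.scale_factor`` shrinks steps, burn-in and thinning
proportionally so the retained-sample count is preserved at desk scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _mcmc, _ode
from .models import ModelSpec, Protocol, SolverError, default_t_grid, simulate
from .synthetic import MeasurementSet, softlog

__all__ = [
    "PriorSpec",
    "default_prior",
    "MCMCConfig",
    "PosteriorSamples",
    "log_prior",
    "log_likelihood",
    "metropolis_hastings",
    "run_training",
    "r_hat",
    "effective_sample_size",
    "RHAT_THRESHOLD",
    "ESS_FULL_SCALE_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Convergence criterion on the rank-normalised split R-hat.
RHAT_THRESHOLD = 1.01
#: Minimum effective sample size asserted for full-scale runs.
ESS_FULL_SCALE_THRESHOLD = 1000

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


# --------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class PriorSpec:
    """Independent per-parameter priors.

    ``entries`` maps a parameter name to either
    ``("lognormal", mu, sigma, clip)`` — LogNormal(mu, sigma) on the
    natural-log scale, clipped to (0, clip] — or ``("uniform", lo, hi)``.
    ``log_scale_sampling`` selects whether MH proposals act on
    log-parameters (cascades) or natural parameters (oscillator).
    """

    entries: dict[str, tuple]
    log_scale_sampling: bool = True

    def names(self):
        return tuple(self.entries)

    def logpdf(self, name: str, value: float) -> float:
        """Log density of one parameter in natural space (integrates to 1)."""
        from scipy import stats

        entry = self.entries[name]
        if entry[0] == "lognormal":
            _, mu, sigma, clip = entry
            if value <= 0 or value > clip:
                return -np.inf
            z_clip = (np.log(clip) - mu) / sigma
            log_norm = stats.norm.logcdf(z_clip)
            return stats.norm.logpdf(np.log(value), mu, sigma) - np.log(value) - log_norm
        _, lo, hi = entry
        if not (lo <= value <= hi):
            return -np.inf
        return -np.log(hi - lo)

    def sample(self, rng: np.random.Generator, names=None) -> np.ndarray:
        """Draw one parameter vector (natural space) from the prior."""
        names = self.names() if names is None else tuple(names)
        out = np.empty(len(names))
        for i, n in enumerate(names):
            entry = self.entries[n]
            if entry[0] == "lognormal":
                _, mu, sigma, clip = entry
                while True:
                    x = np.exp(rng.normal(mu, sigma))
                    if x <= clip:
                        break
                out[i] = x
            else:
                _, lo, hi = entry
                out[i] = rng.uniform(lo, hi)
        return out

    def kernel_arrays(self, names):
        """Per-parameter (kind, a, b, lo, hi) arrays in the sampling space."""
        k = len(names)
        kind = np.empty(k, dtype=np.int64)
        a = np.zeros(k)
        b = np.ones(k)
        lo = np.full(k, -np.inf)
        hi = np.full(k, np.inf)
        for i, n in enumerate(names):
            entry = self.entries[n]
            if entry[0] == "lognormal":
                if not self.log_scale_sampling:
                    raise ValueError("lognormal priors require log-scale sampling")
                kind[i] = _mcmc.PRIOR_TRUNC_NORMAL
                a[i], b[i] = entry[1], entry[2]
                hi[i] = np.log(entry[3])
            else:
                if self.log_scale_sampling:
                    raise ValueError("uniform priors require natural-scale sampling")
                kind[i] = _mcmc.PRIOR_UNIFORM
                lo[i], hi[i] = entry[1], entry[2]
        return kind, a, b, lo, hi


#: Cascade default: LogNormal(mu=1, sigma=3) on the natural-log scale,
#: clipped to (0, 1e4].
CASCADE_PRIOR_MU = 1.0
CASCADE_PRIOR_SIGMA = 3.0
CASCADE_PRIOR_CLIP = 1e4

#: Oscillator default: Uniform over [0.1, 10] x nominal per parameter
#: (bounds are a package choice; the study states only that the priors are
#: uniform).
OSCILLATOR_PRIOR_SPAN = (0.1, 10.0)


def default_prior(model: ModelSpec) -> PriorSpec:
    """The default prior for a model variant over its free parameters."""
    if model.model_id == _ode.MODEL_OSCILLATOR:
        entries = {
            n: ("uniform", OSCILLATOR_PRIOR_SPAN[0] * model.nominal[n],
                OSCILLATOR_PRIOR_SPAN[1] * model.nominal[n])
            for n in model.free_names
        }
        return PriorSpec(entries, log_scale_sampling=False)
    entries = {
        n: ("lognormal", CASCADE_PRIOR_MU, CASCADE_PRIOR_SIGMA, CASCADE_PRIOR_CLIP)
        for n in model.free_names
    }
    return PriorSpec(entries, log_scale_sampling=True)


def log_prior(params, prior: PriorSpec, names=None) -> float:
    """Sum of per-parameter natural-space log prior densities; -inf outside
    support (above the lognormal clip or outside uniform bounds)."""
    if isinstance(params, dict):
        items = params.items()
    else:
        names = prior.names() if names is None else tuple(names)
        params = np.asarray(params, dtype=float)
        if params.shape != (len(names),):
            raise ValueError("parameter vector does not match prior dimension")
        items = zip(names, params)
    return float(sum(prior.logpdf(n, v) for n, v in items))


# --------------------------------------------------------------------------
# likelihood


def _measurement_grid(model: ModelSpec, times: np.ndarray) -> np.ndarray:
    if times[0] != 0.0:
        return np.concatenate(([0.0], times))
    return times


def log_likelihood(
    params,
    measurements: MeasurementSet,
    model: ModelSpec,
    protocol: Protocol | None = None,
    trained_variables=None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> float:
    """Gaussian measurement log-likelihood of the full parameter vector.

    Simulates the model once on the measurement grid and sums
    ``log N(m_{k,t,r} | y_k(t), sigma_error)`` over all records of the
    variables selected for training.  A solver failure yields -inf.
    """
    if protocol is None:
        from .models import get_protocol

        protocol = get_protocol(measurements.provenance.get("protocol", "s_train"))
    ms = measurements if trained_variables is None else measurements.subset(trained_variables)
    unknown = set(ms.variables) - set(model.state_names)
    if unknown:
        raise KeyError(f"measured variables not in model: {sorted(unknown)}")
    times = ms.times
    grid = _measurement_grid(model, times)
    try:
        traj = simulate(model, params, protocol, grid, rtol=rtol, atol=atol)
    except SolverError:
        return -np.inf
    sigma = ms.sigma_error
    ll = 0.0
    rec = ms.records
    t_to_row = {t: np.searchsorted(grid, t) for t in times}
    for var, t, m in zip(rec["variable"], rec["time"], rec["value"]):
        x = traj.values[t_to_row[float(t)], model.state_names.index(var)]
        y = softlog(x) if ms.transform == "softlog" else x
        ll += -0.5 * ((y - m) / sigma) ** 2 - np.log(sigma) - _LOG_SQRT_2PI
    return float(ll)


# --------------------------------------------------------------------------
# configuration and samples


@dataclass(frozen=True)
class MCMCConfig:
    """Metropolis-Hastings settings.

    Defaults are the full-scale settings (8 x 1.5M steps, 0.25M burn-in,
    thin 1000).  ``scale_factor`` < 1 shrinks steps, burn-in and thinning
    proportionally, preserving the retained-sample count.  ``step_sd`` is a
    scalar (spherical proposal) or a per-free-parameter array.
    """

    n_chains: int = 8
    n_steps: int = 1_500_000
    burn_in: int = 250_000
    thin: int = 1000
    step_sd: float | np.ndarray = 0.2
    seed: int = 0
    scale_factor: float = 1.0

    def __post_init__(self):
        if not (0 < self.scale_factor <= 1):
            raise ValueError("scale_factor must be in (0, 1]")
        if self.burn_in >= self.n_steps:
            raise ValueError("burn_in must be smaller than n_steps")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_steps_eff(self) -> int:
        return max(2, int(round(self.n_steps * self.scale_factor)))

    @property
    def burn_in_eff(self) -> int:
        return int(round(self.burn_in * self.scale_factor))

    @property
    def thin_eff(self) -> int:
        return max(1, int(round(self.thin * self.scale_factor)))

    @property
    def n_retained(self) -> int:
        return self.n_chains * ((self.n_steps_eff - self.burn_in_eff) // self.thin_eff)

    def step_sd_array(self, n_free: int) -> np.ndarray:
        sd = np.asarray(self.step_sd, dtype=float)
        if sd.ndim == 0:
            return np.full(n_free, float(sd))
        if sd.shape != (n_free,):
            raise ValueError("step_sd length does not match free-parameter count")
        return sd.copy()


def oscillator_step_sd(model: ModelSpec, all_masses: bool = False) -> np.ndarray:
    """Per-parameter proposal SDs for the oscillator: 1.0 for masses, 0.2 for
    damping, 0.4 for stiffness; divided by 4 for the all-masses fit."""
    base = {"m": 1.0, "b": 0.2, "k": 0.4}
    sd = np.array([base[n[0]] for n in model.free_names])
    return sd / 4.0 if all_masses else sd


@dataclass
class PosteriorSamples:
    """Retained posterior draws plus chain/step provenance and diagnostics.

    ``df`` has columns chain, step, one per free parameter (natural scale)
    and log_posterior (the log target density in sampling coordinates).
    """

    df: pd.DataFrame
    param_names: tuple[str, ...]
    model_name: str = ""
    config: MCMCConfig | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.df[list(self.param_names)].to_numpy(dtype=float)

    @property
    def n_chains(self) -> int:
        return int(self.df["chain"].nunique())

    def per_chain(self) -> np.ndarray:
        """Samples as an (n_chains, n_draws, n_params) array."""
        chains = []
        for _, grp in self.df.groupby("chain", sort=True):
            chains.append(grp[list(self.param_names)].to_numpy(dtype=float))
        n = min(c.shape[0] for c in chains)
        return np.stack([c[:n] for c in chains])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            cfg = self.config
            meta = ""
            if cfg is not None:
                meta = (
                    f" n_chains={cfg.n_chains} n_steps={cfg.n_steps} burn_in={cfg.burn_in}"
                    f" thin={cfg.thin} scale_factor={cfg.scale_factor} seed={cfg.seed}"
                )
            fh.write(f"# model={self.model_name}{meta}\n")
            self.df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "PosteriorSamples":
        with open(path) as fh:
            header = fh.readline()
            df = pd.read_csv(fh)
        meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split() if "=" in tok)
        params = tuple(c for c in df.columns if c not in ("chain", "step", "log_posterior"))
        cfg = None
        if "n_chains" in meta:
            cfg = MCMCConfig(
                n_chains=int(meta["n_chains"]),
                n_steps=int(meta["n_steps"]),
                burn_in=int(meta["burn_in"]),
                thin=int(meta["thin"]),
                scale_factor=float(meta["scale_factor"]),
                seed=int(meta["seed"]),
            )
        return cls(df, params, model_name=meta.get("model", ""), config=cfg)


# --------------------------------------------------------------------------
# samplers


def metropolis_hastings(
    log_target,
    init,
    step_sd,
    n_steps: int,
    seed: int = 0,
    burn_in: int = 0,
    thin: int = 1,
):
    """Plain Metropolis-Hastings with a symmetric Gaussian proposal.

    Returns ``(samples, acceptance_rate)`` where samples holds every
    ``thin``-th post-burn-in state.  ``log_target`` must be finite at
    ``init``.
    """
    x = np.atleast_1d(np.asarray(init, dtype=float)).copy()
    d = x.size
    sd = np.broadcast_to(np.asarray(step_sd, dtype=float), (d,))
    lp = float(log_target(x))
    if not np.isfinite(lp):
        raise ValueError("log_target must be finite at init")
    rng = np.random.default_rng(seed)
    kept = []
    n_acc = 0
    window_acc = 0
    for step in range(n_steps):
        prop = x + sd * rng.standard_normal(d)
        lp_new = float(log_target(prop))
        if lp_new - lp > np.log(rng.random()):
            x = prop
            lp = lp_new
            n_acc += 1
            window_acc += 1
        if step >= burn_in and (step - burn_in) % thin == thin - 1:
            kept.append(x.copy())
        if (step + 1) % 10_000 == 0:
            if window_acc == 0:
                logger.warning("MH chain accepted nothing in the last 10000 steps")
            window_acc = 0
    return np.asarray(kept), n_acc / n_steps


def _chain_inputs(model, protocol, measurements, trained_variables, prior):
    ms = measurements.subset(trained_variables)
    var_idx, tidx, vals, times = ms.kernel_arrays(model)
    grid = _measurement_grid(model, times)
    if grid.shape != times.shape:  # t=0 prepended; shift time indices
        tidx = tidx + 1
    seg_t0, seg_t1, seg_v, sin_par = protocol._arrays()
    transform_id = (
        _mcmc.TRANSFORM_SOFTLOG if ms.transform == "softlog" else _mcmc.TRANSFORM_IDENTITY
    )
    kind, a, b, lo, hi = prior.kernel_arrays(model.free_names)
    template = np.array(
        [model.fixed.get(n, np.nan) for n in model.param_names], dtype=float
    )
    free_idx = np.array(
        [i for i, n in enumerate(model.param_names) if n not in model.fixed], dtype=np.int64
    )
    return dict(
        model_id=model.model_id,
        y0=model.initial_state,
        t_out=grid,
        seg_t0=seg_t0,
        seg_t1=seg_t1,
        seg_v=seg_v,
        sin_par=sin_par,
        transform_id=transform_id,
        meas_var=var_idx,
        meas_tidx=tidx,
        meas_val=vals,
        sigma_err=ms.sigma_error,
        free_idx=free_idx,
        template=template,
        log_scale=prior.log_scale_sampling,
        prior_kind=kind,
        prior_a=a,
        prior_b=b,
        lo=lo,
        hi=hi,
    )


def run_training(
    model: ModelSpec,
    measurements: MeasurementSet,
    trained_variables,
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    protocol: Protocol | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> PosteriorSamples:
    """Train the model: run independent MH chains against the selected
    variables' measurements, drop burn-in, thin and concatenate.

    Chains start from prior draws, retried up to 100 times until the log
    posterior is finite.  Diagnostics (split R-hat, ESS, per-chain
    acceptance rates) are recorded on the retained per-chain samples.
    """
    trained_variables = list(trained_variables)
    if not trained_variables:
        raise ValueError("trained_variables must be non-empty")
    if prior is None:
        prior = default_prior(model)
    if config is None:
        config = MCMCConfig()
    if protocol is None:
        from .models import get_protocol

        protocol = get_protocol(measurements.provenance.get("protocol", "s_train"))
    inputs = _chain_inputs(model, protocol, measurements, trained_variables, prior)
    n_free = len(model.free_names)
    sd = config.step_sd_array(n_free)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_chains + 1)
    init_rng = np.random.default_rng(children[-1])
    n_steps, burn_in, thin = config.n_steps_eff, config.burn_in_eff, config.thin_eff

    def _logpost_at(x):
        lp = _mcmc._log_prior_kernel(
            x, inputs["prior_kind"], inputs["prior_a"], inputs["prior_b"],
            inputs["lo"], inputs["hi"],
        )
        if lp == -np.inf:
            return -np.inf
        full_p = _mcmc._build_full(
            x, inputs["free_idx"], inputs["template"], inputs["log_scale"]
        )
        ll = _mcmc._log_likelihood_kernel(
            inputs["model_id"], full_p, inputs["y0"], inputs["t_out"],
            inputs["seg_t0"], inputs["seg_t1"], inputs["seg_v"], inputs["sin_par"],
            rtol, atol, inputs["transform_id"], inputs["meas_var"],
            inputs["meas_tidx"], inputs["meas_val"], inputs["sigma_err"],
        )
        return lp + ll

    chains, logposts, acc_rates = [], [], []
    for c in range(config.n_chains):
        chain_seed = int(children[c].generate_state(1, dtype=np.uint32)[0] % (2**31))
        init = None
        for _ in range(100):
            draw = prior.sample(init_rng, model.free_names)
            x0 = np.log(draw) if prior.log_scale_sampling else draw
            if np.isfinite(_logpost_at(x0)):
                init = x0
                break
        if init is None:
            raise RuntimeError(
                f"chain {c}: no finite-posterior initial point in 100 prior draws"
            )
        kept, kept_lp, acc = _mcmc.run_chain(
            inputs["model_id"], inputs["y0"], inputs["t_out"],
            inputs["seg_t0"], inputs["seg_t1"], inputs["seg_v"], inputs["sin_par"],
            rtol, atol, inputs["transform_id"],
            inputs["meas_var"], inputs["meas_tidx"], inputs["meas_val"],
            inputs["sigma_err"], inputs["free_idx"], inputs["template"],
            inputs["log_scale"], inputs["prior_kind"], inputs["prior_a"],
            inputs["prior_b"], inputs["lo"], inputs["hi"],
            sd, init, n_steps, burn_in, thin, chain_seed,
        )
        if acc == 0.0:
            logger.warning("chain %d accepted no proposals", c)
        chains.append(kept)
        logposts.append(kept_lp)
        acc_rates.append(acc)
        logger.info("chain %d done, acceptance %.3f", c, acc)

    sampling = np.stack(chains)  # (n_chains, n_keep, d)
    natural = np.exp(sampling) if prior.log_scale_sampling else sampling
    rhat = r_hat(sampling)
    ess = effective_sample_size(sampling)
    n_keep = sampling.shape[1]
    steps = burn_in + thin * (np.arange(n_keep) + 1)
    rows = []
    for c in range(config.n_chains):
        block = pd.DataFrame(natural[c], columns=list(model.free_names))
        block.insert(0, "step", steps)
        block.insert(0, "chain", c)
        block["log_posterior"] = logposts[c]
        rows.append(block)
    df = pd.concat(rows, ignore_index=True)
    diagnostics = {
        "rhat": dict(zip(model.free_names, np.atleast_1d(rhat))),
        "ess": dict(zip(model.free_names, np.atleast_1d(ess))),
        "acceptance": acc_rates,
        "trained_variables": trained_variables,
    }
    return PosteriorSamples(
        df=df,
        param_names=model.free_names,
        model_name=model.name,
        config=config,
        diagnostics=diagnostics,
    )


# --------------------------------------------------------------------------
# convergence diagnostics (arviz-backed)


def _to_chain_array(chains) -> np.ndarray:
    arr = np.asarray(chains, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError("expected (n_chains, n_draws) or (n_chains, n_draws, n_params)")
    if arr.shape[0] < 2:
        raise ValueError("r_hat requires at least 2 chains")
    return arr


def r_hat(chains) -> np.ndarray:
    """Rank-normalised split R-hat per parameter; ~1 at convergence.

    Degenerate inputs (zero within-chain variance) yield NaN with a warning.
    """
    import arviz as az

    arr = _to_chain_array(chains)
    out = np.empty(arr.shape[2])
    for j in range(arr.shape[2]):
        col = arr[:, :, j]
        if np.allclose(col.var(axis=1), 0.0):
            warnings.warn(f"zero within-chain variance for parameter {j}; R-hat is NaN")
            out[j] = np.nan
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[j] = float(az.rhat(az.convert_to_dataset(col))["x"].values)
    return out if out.size > 1 else out[0]


def effective_sample_size(samples) -> np.ndarray:
    """Autocorrelation-based effective sample size per parameter.

    Accepts (n_draws,), (n_draws, n_params) single-chain input or
    (n_chains, n_draws, n_params).
    """
    import arviz as az

    arr = np.asarray(samples, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :, None]
    elif arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.shape[1] < 100:
        raise ValueError("effective_sample_size requires at least 100 draws")
    out = np.empty(arr.shape[2])
    for j in range(arr.shape[2]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[j] = float(az.ess(az.convert_to_dataset(arr[:, :, j]))["x"].values)
    return out if out.size > 1 else out[0]
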