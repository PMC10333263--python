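"""Posterior analysis: prediction bands, parameter perturbations, and
PCA-based dimensionality of the plausible parameter set.

Prediction bands simulate every retained posterior sample under a test
protocol and report point-wise medians and quantiles (80% by default) in the
measurement space — softlog for the cascade, raw displacement for the
oscillator.

Dimensionality is quantified by PCA on natural logarithms of the plausible
parameters: principal values lambda_i (variances along the principal
directions) translate into principal multiplicative deviations
delta_i = exp(sqrt(lambda_i)), the fold-change spread along each direction.
delta_i = 1 means no variation; directions with delta below a stiffness
threshold (1.5 by default) count as stiff, i.e. constrained by the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _ode
from .models import ModelSpec, Protocol
from .synthetic import softlog

__all__ = [
    "PredictionBand",
    "DeviationSpectrum",
    "predict_band",
    "perturb_and_predict",
    "deviation_spectrum",
    "count_stiff",
    "stiff_basis_rotation",
    "local_pca_check",
    "marginal_summaries",
    "STIFF_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Default delta threshold below which a principal direction counts as stiff.
STIFF_THRESHOLD = 1.5


# --------------------------------------------------------------------------
# prediction bands


@dataclass
class PredictionBand:
    """Point-wise median and quantile envelope of posterior trajectories."""

    times: np.ndarray
    variables: tuple[str, ...]
    median: np.ndarray  # [time, variable]
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.8
    n_failed: int = 0

    def width(self, variable: str | None = None) -> np.ndarray:
        """Point-wise band width, for one variable or all (columns)."""
        w = self.upper - self.lower
        if variable is None:
            return w
        return w[:, self.variables.index(variable)]

    def median_width(self, variable: str) -> float:
        return float(np.median(self.width(variable)))

    def coverage(self, times, values, variable: str) -> float:
        """Fraction of the given reference points inside the band."""
        j = self.variables.index(variable)
        pos = np.searchsorted(self.times, np.asarray(times, dtype=float))
        inside = (values >= self.lower[pos, j]) & (values <= self.upper[pos, j])
        return float(np.mean(inside))

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.times}
        for i, v in enumerate(self.variables):
            cols[f"{v}_median"] = self.median[:, i]
            cols[f"{v}_lower"] = self.lower[:, i]
            cols[f"{v}_upper"] = self.upper[:, i]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# level={self.level} n_failed={self.n_failed}\n")
            self.to_frame().to_csv(fh, index=False)


def _sample_matrix(samples) -> tuple[np.ndarray, tuple[str, ...]]:
    """Accept PosteriorSamples, DataFrame or array; return (N x P, names)."""
    from .inference import PosteriorSamples

    if isinstance(samples, PosteriorSamples):
        return samples.values, samples.param_names
    if isinstance(samples, pd.DataFrame):
        names = tuple(c for c in samples.columns if c not in ("chain", "step", "log_posterior"))
        return samples[list(names)].to_numpy(dtype=float), names
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D sample matrix")
    return arr, tuple(f"p{i}" for i in range(arr.shape[1]))


def predict_band(
    samples,
    model: ModelSpec,
    protocol: Protocol,
    t_grid=None,
    level: float = 0.8,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> PredictionBand:
    """Simulate every posterior sample under ``protocol`` and report the
    point-wise median and the (1 +/- level)/2 quantiles per variable.

    Cascade trajectories are softlog-transformed first, matching the
    measurement space.  Samples whose solve fails are dropped (counted in
    ``n_failed``).
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    from .models import default_t_grid

    if t_grid is None:
        t_grid = default_t_grid(model)
    t_grid = np.asarray(t_grid, dtype=float)
    X, names = _sample_matrix(samples)
    if X.shape[0] == 0:
        raise ValueError("empty sample set")
    if names != model.free_names and len(names) != len(model.free_names):
        raise ValueError("sample parameters do not match the model's free parameters")
    full = np.stack([model.full_params(x) for x in X])
    seg_t0, seg_t1, seg_v, sin_par = protocol._arrays()
    trajs, status = _ode.integrate_batch(
        model.model_id, full, model.initial_state, t_grid, seg_t0, seg_t1, seg_v,
        sin_par, rtol, atol,
    )
    ok = status == 0
    n_failed = int((~ok).sum())
    if n_failed:
        logger.info("predict_band: dropped %d/%d failed solves", n_failed, len(status))
    if not ok.any():
        raise RuntimeError("all posterior solves failed")
    obs_idx = [model.state_names.index(v) for v in model.observed_names]
    Y = trajs[ok][:, :, obs_idx]
    if model.transform == "softlog":
        Y = softlog(np.clip(Y, 0.0, None))
    alpha = (1.0 - level) / 2.0
    lower, med, upper = np.quantile(Y, [alpha, 0.5, 1.0 - alpha], axis=0)
    return PredictionBand(
        times=t_grid,
        variables=tuple(model.observed_names),
        median=med,
        lower=lower,
        upper=upper,
        level=level,
        n_failed=n_failed,
    )


def perturb_and_predict(
    samples,
    model: ModelSpec,
    protocol: Protocol,
    parameter_name: str,
    factor: float,
    t_grid=None,
    level: float = 0.8,
) -> PredictionBand:
    """Multiply one free parameter by ``factor`` in every posterior sample,
    then compute the prediction band — the predicted response to a x10 (or
    /10) perturbation such as overexpression or knockdown."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    if parameter_name in model.fixed:
        raise ValueError(f"cannot perturb fixed parameter {parameter_name!r}")
    X, names = _sample_matrix(samples)
    if parameter_name not in names and len(names) == len(model.free_names):
        names = model.free_names  # bare arrays follow the model's layout
    if parameter_name not in names:
        raise ValueError(f"unknown parameter {parameter_name!r}")
    X = X.copy()
    X[:, names.index(parameter_name)] *= factor
    return predict_band(X, model, protocol, t_grid=t_grid, level=level)


# --------------------------------------------------------------------------
# PCA dimensionality


@dataclass
class DeviationSpectrum:
    """PCA of log-parameters: principal values (descending), principal
    multiplicative deviations delta_i = exp(sqrt(lambda_i)), and loadings."""

    principal_values: np.ndarray  # lambda_i, descending
    deviations: np.ndarray  # delta_i = exp(sqrt(lambda_i))
    eigenvectors: np.ndarray  # [parameter, component]
    param_names: tuple[str, ...] = ()

    @property
    def n_components(self) -> int:
        return len(self.principal_values)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.eigenvectors,
            index=list(self.param_names) or None,
            columns=[f"pc{i + 1}" for i in range(self.n_components)],
        )
        df.loc["lambda"] = self.principal_values
        df.loc["delta"] = self.deviations
        return df


def deviation_spectrum(samples) -> DeviationSpectrum:
    """PCA on natural logarithms of the plausible parameter set.

    All sampled values must be positive.  Principal values are the
    eigenvalues of the covariance of log-parameters, in descending order;
    deviations delta_i = exp(sqrt(lambda_i)) >= 1.
    """
    X, names = _sample_matrix(samples)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if np.any(X <= 0):
        raise ValueError("deviation_spectrum requires positive parameter values")
    L = np.log(X)
    cov = np.cov(L, rowvar=False)
    cov = np.atleast_2d(cov)
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    vec = vec[:, order]
    return DeviationSpectrum(
        principal_values=lam,
        deviations=np.exp(np.sqrt(lam)),
        eigenvectors=vec,
        param_names=names,
    )


def count_stiff(spectrum: DeviationSpectrum, threshold: float = STIFF_THRESHOLD) -> int:
    """Number of principal directions with delta below the threshold."""
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    return int(np.sum(spectrum.deviations < threshold))


def stiff_basis_rotation(spectrum: DeviationSpectrum, n_stiff: int) -> np.ndarray:
    """Varimax-rotate the ``n_stiff`` stiffest eigenvectors (the components
    with the smallest principal values) to minimise the number of dominant
    coordinates per vector; the spanned subspace is unchanged.

    Returns a [parameter, n_stiff] matrix of orthonormal loading vectors.
    """
    if n_stiff > spectrum.n_components:
        raise ValueError("n_stiff exceeds the number of components")
    if n_stiff == 0:
        return np.empty((spectrum.eigenvectors.shape[0], 0))
    V = spectrum.eigenvectors[:, -n_stiff:]  # stiffest = smallest lambda
    if n_stiff == 1:
        return V
    from statsmodels.multivariate.factor_rotation import rotate_factors

    R, _ = rotate_factors(V, "varimax")
    return R


def local_pca_check(
    samples,
    n_neighbors: int,
    n_anchors: int = 20,
    seed: int = 0,
) -> list[DeviationSpectrum]:
    """PCA on k-nearest-neighbour subsets in log-parameter space around
    random anchor samples.

    If the point cloud is flat (well described by global PCA), local spectra
    resemble the global one; curvature shows up as locally smaller principal
    values at small scales.
    """
    X, names = _sample_matrix(samples)
    dim = X.shape[1]
    if n_neighbors < dim + 1:
        raise ValueError("n_neighbors must be at least dimension + 1")
    if X.shape[0] < n_neighbors:
        raise ValueError("not enough samples for the requested neighbourhood size")
    L = np.log(X)
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(L)
    rng = np.random.default_rng(seed)
    anchors = rng.choice(X.shape[0], size=min(n_anchors, X.shape[0]), replace=False)
    _, idx = nn.kneighbors(L[anchors])
    spectra = []
    for row in idx:
        spectra.append(deviation_spectrum(X[row]))
    return spectra


def marginal_summaries(samples, prior, n_bins: int = 40) -> dict[str, dict]:
    """Per-parameter log10-scale histogram plus the prior density overlay.

    Returns ``{name: {"bin_edges", "density", "prior_grid", "prior_density"}}``
    with densities per unit log10-parameter; fixed parameters never appear
    (samples only carry free parameters).
    """
    X, names = _sample_matrix(samples)
    prior_names = prior.names()
    if any(n not in prior_names for n in names) and len(names) == len(prior_names):
        names = prior_names  # bare arrays follow the prior's layout
    out = {}
    for j, name in enumerate(names):
        x = X[:, j]
        lx = np.log10(x[x > 0])
        hist, edges = np.histogram(lx, bins=n_bins, density=True)
        grid = np.linspace(edges[0], edges[-1], 200)
        # prior density transformed to the log10 axis
        vals = 10.0 ** grid
        pdens = np.array([np.exp(prior.logpdf(name, v)) for v in vals]) * vals * np.log(10)
        out[name] = {
            "bin_edges": edges,
            "density": hist,
            "prior_grid": grid,
            "prior_density": pdens,
        }
    return out
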