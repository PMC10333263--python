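"""Compiled Metropolis-Hastings chain for ODE-model posteriors.

One call runs a single chain entirely inside compiled code: propose a
Gaussian step (in log-parameter space for the cascades, natural space for
the oscillator), integrate the model, score the Gaussian measurement
likelihood over the selected variables, and accept or reject.

Prior kinds per free parameter (in the sampling coordinate):
  0 -> Normal(mu, sd) truncated above at ``hi`` (log of a clipped lognormal),
  1 -> Uniform(lo, hi).
Normalisation constants are dropped here; the Python-level ``log_prior``
carries the full densities.
"""

import numpy as np
from numba import njit

from ._ode import integrate

TRANSFORM_IDENTITY = 0
TRANSFORM_SOFTLOG = 1

PRIOR_TRUNC_NORMAL = 0
PRIOR_UNIFORM = 1


@njit(cache=True)
def _log_prior_kernel(x, prior_kind, prior_a, prior_b, lo, hi):
    lp = 0.0
    for i in range(x.shape[0]):
        if x[i] < lo[i] or x[i] > hi[i]:
            return -np.inf
        if prior_kind[i] == PRIOR_TRUNC_NORMAL:
            z = (x[i] - prior_a[i]) / prior_b[i]
            lp += -0.5 * z * z
        # uniform contributes a constant
    return lp


@njit(cache=True)
def _log_likelihood_kernel(
    model_id,
    full_p,
    y0,
    t_out,
    seg_t0,
    seg_t1,
    seg_v,
    sin_par,
    rtol,
    atol,
    transform_id,
    meas_var,
    meas_tidx,
    meas_val,
    sigma_err,
):
    traj, status = integrate(
        model_id, full_p, y0, t_out, seg_t0, seg_t1, seg_v, sin_par, rtol, atol
    )
    if status != 0:
        return -np.inf
    inv2s2 = 1.0 / (2.0 * sigma_err * sigma_err)
    ll = 0.0
    for i in range(meas_val.shape[0]):
        x = traj[meas_tidx[i], meas_var[i]]
        if transform_id == TRANSFORM_SOFTLOG:
            y = np.log10(0.001 + x) if x > -0.001 else -np.inf
        else:
            y = x
        if not np.isfinite(y):
            return -np.inf
        r = y - meas_val[i]
        ll += -inv2s2 * r * r
    return ll


@njit(cache=True)
def _build_full(free_val, free_idx, template, log_scale):
    full_p = template.copy()
    for i in range(free_idx.shape[0]):
        full_p[free_idx[i]] = np.exp(free_val[i]) if log_scale else free_val[i]
    return full_p


@njit(cache=True)
def run_chain(
    model_id,
    y0,
    t_out,
    seg_t0,
    seg_t1,
    seg_v,
    sin_par,
    rtol,
    atol,
    transform_id,
    meas_var,
    meas_tidx,
    meas_val,
    sigma_err,
    free_idx,
    template,
    log_scale,
    prior_kind,
    prior_a,
    prior_b,
    lo,
    hi,
    prop_sd,
    init,
    n_steps,
    burn_in,
    thin,
    seed,
):
    """Run one MH chain; returns (kept_samples, kept_logpost, acceptance_rate).

    ``kept_samples`` holds the sampling-space coordinates (log-parameters for
    the cascades) at every ``thin``-th post-burn-in step.
    """
    np.random.seed(seed)
    d = init.shape[0]
    n_keep = (n_steps - burn_in) // thin
    kept = np.empty((n_keep, d))
    kept_lp = np.empty(n_keep)
    x = init.copy()
    lp = _log_prior_kernel(x, prior_kind, prior_a, prior_b, lo, hi)
    full_p = _build_full(x, free_idx, template, log_scale)
    ll = _log_likelihood_kernel(
        model_id, full_p, y0, t_out, seg_t0, seg_t1, seg_v, sin_par,
        rtol, atol, transform_id, meas_var, meas_tidx, meas_val, sigma_err,
    )
    logpost = lp + ll
    n_acc = 0
    k = 0
    prop = np.empty(d)
    for step in range(n_steps):
        for i in range(d):
            prop[i] = x[i] + prop_sd[i] * np.random.normal()
        lp_new = _log_prior_kernel(prop, prior_kind, prior_a, prior_b, lo, hi)
        if lp_new > -np.inf:
            full_p = _build_full(prop, free_idx, template, log_scale)
            ll_new = _log_likelihood_kernel(
                model_id, full_p, y0, t_out, seg_t0, seg_t1, seg_v, sin_par,
                rtol, atol, transform_id, meas_var, meas_tidx, meas_val, sigma_err,
            )
            logpost_new = lp_new + ll_new
            if logpost_new - logpost > np.log(np.random.random()):
                x[:] = prop
                logpost = logpost_new
                n_acc += 1
        if step >= burn_in and (step - burn_in) % thin == thin - 1 and k < n_keep:
            kept[k] = x
            kept_lp[k] = logpost
            k += 1
    return kept, kept_lp, n_acc / n_steps
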