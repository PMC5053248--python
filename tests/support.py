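"""Shared helpers for the test suite: random consistent model states and a
brute-force, loop-level oracle for the joint log-posterior.

The oracle deliberately shares no code with the package's vectorized
implementation: every term is an explicit scipy.stats call inside explicit
loops over cells.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from odast import LatentState, ParameterState, ReportedFlowData
from odast.dims import RECEIVING, SENDING


def random_model_state(
    data: ReportedFlowData, rng: np.random.Generator
) -> tuple[LatentState, ParameterState]:
    """A random finite state consistent with the data masks (constraints
    satisfied, precisions positive)."""
    d = data.dims
    F, T, A, U = d.n_flows, d.n_years, d.n_ages, d.n_units
    latent = LatentState(
        log_m=rng.normal(2.0, 1.0, size=(F, T, A, 2)),
        log_nu_agesex=rng.normal(2.0, 1.0, size=(2, F, T, A, 2)),
        log_nu_sexonly=rng.normal(3.0, 1.0, size=(2, F, T, 2)),
        report_effect=rng.normal(0.0, 0.5, size=(2, F, T)),
        report_mask=data.report_mask.copy(),
    )
    age_effect = rng.normal(size=A)
    age_effect[0] = 0.0
    sex_effect = rng.normal(size=2)
    sex_effect[0] = 0.0
    params = ParameterState(
        age_effect=age_effect,
        sex_effect=sex_effect,
        dest_age=rng.normal(size=(U, A)),
        dest_sex=rng.normal(size=(U, 2)),
        orig_age=rng.normal(size=(U, A)),
        orig_sex=rng.normal(size=(U, 2)),
        **{name: float(rng.gamma(4.0, 0.5)) for name in (
            "tau_level", "tau_send", "tau_recv", "tau_send_sexonly",
            "tau_recv_sexonly", "tau_dest_age", "tau_dest_sex",
            "tau_orig_age", "tau_orig_sex",
        )},
    )
    return latent, params


def oracle_log_prior(latent: LatentState, params: ParameterState, dims) -> float:
    """Term-by-term prior: global profiles, country effects, precisions and
    the reporter interactions that exist."""
    A, U = dims.n_ages, dims.n_units
    sd = lambda tau: 1.0 / np.sqrt(tau)
    total = 0.0
    for a in range(1, A):
        total += stats.norm.logpdf(params.age_effect[a], 0.0, 1.0)
    total += stats.norm.logpdf(params.sex_effect[1], 0.0, 1.0)
    for u in range(U):
        for a in range(A):
            total += stats.norm.logpdf(
                params.dest_age[u, a], params.age_effect[a], sd(params.tau_dest_age)
            )
            total += stats.norm.logpdf(
                params.orig_age[u, a], params.age_effect[a], sd(params.tau_orig_age)
            )
        for s in range(2):
            total += stats.norm.logpdf(
                params.dest_sex[u, s], params.sex_effect[s], sd(params.tau_dest_sex)
            )
            total += stats.norm.logpdf(
                params.orig_sex[u, s], params.sex_effect[s], sd(params.tau_orig_sex)
            )
    for name in ("tau_level", "tau_send", "tau_recv", "tau_send_sexonly",
                 "tau_recv_sexonly"):
        total += stats.gamma.logpdf(getattr(params, name), 1e-3, scale=1.0 / 1e-3)
    for name in ("tau_dest_age", "tau_dest_sex", "tau_orig_age", "tau_orig_sex"):
        total += stats.gamma.logpdf(getattr(params, name), 1e-2, scale=1.0 / 1e-2)
    for k in (SENDING, RECEIVING):
        for f in range(dims.n_flows):
            for t in range(dims.n_years):
                if latent.report_mask[k, f, t]:
                    total += stats.norm.logpdf(
                        latent.report_effect[k, f, t], 0.0, 10.0
                    )
    return float(total)


def oracle_log_level(latent: LatentState, params: ParameterState, dims) -> float:
    """Cellwise level-model density of log m around the four-effect sum."""
    o_idx, d_idx = dims.flow_arrays()
    sd = lambda tau: 1.0 / np.sqrt(tau)
    F, T, A = dims.n_flows, dims.n_years, dims.n_ages
    total = 0.0
    for f in range(F):
        o, dst = o_idx[f], d_idx[f]
        for t in range(T):
            for a in range(A):
                for s in range(2):
                    mean = (
                        params.dest_age[dst, a] + params.dest_sex[dst, s]
                        + params.orig_age[o, a] + params.orig_sex[o, s]
                    )
                    total += stats.norm.logpdf(
                        latent.log_m[f, t, a, s], mean, sd(params.tau_level)
                    )
    return float(total)


def oracle_log_likelihood(
    data: ReportedFlowData, latent: LatentState, params: ParameterState
) -> float:
    """Measurement and Poisson terms for every observed cell."""
    d = data.dims
    F, T, A = d.n_flows, d.n_years, d.n_ages
    sd = lambda tau: 1.0 / np.sqrt(tau)
    total = 0.0
    tau_as = {SENDING: params.tau_send, RECEIVING: params.tau_recv}
    tau_sx = {SENDING: params.tau_send_sexonly, RECEIVING: params.tau_recv_sexonly}
    for k in (SENDING, RECEIVING):
        for f in range(F):
            for t in range(T):
                alpha = latent.report_effect[k, f, t]
                if data.mask_agesex[k, f, t]:
                    for a in range(A):
                        for s in range(2):
                            ln = latent.log_nu_agesex[k, f, t, a, s]
                            total += stats.norm.logpdf(
                                ln, latent.log_m[f, t, a, s] + alpha, sd(tau_as[k])
                            )
                            total += stats.poisson.logpmf(
                                data.z_agesex[k, f, t, a, s], np.exp(ln)
                            )
                if data.mask_sexonly[k, f, t]:
                    for s in range(2):
                        ln = latent.log_nu_sexonly[k, f, t, s]
                        ref = np.log(np.exp(latent.log_m[f, t, :, s]).sum())
                        total += stats.norm.logpdf(ln, ref + alpha, sd(tau_sx[k]))
                        total += stats.poisson.logpmf(
                            data.z_sexonly[k, f, t, s], np.exp(ln)
                        )
    return float(total)


def oracle_log_posterior(
    data: ReportedFlowData, latent: LatentState, params: ParameterState
) -> float:
    """Direct term-by-term summation of the joint log-posterior."""
    return (
        oracle_log_prior(latent, params, data.dims)
        + oracle_log_level(latent, params, data.dims)
        + oracle_log_likelihood(data, latent, params)
    )
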