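"""Model unknowns and every log-density entering the joint posterior.

The model observes counts ``z`` for flow blocks reported by the sending (S)
and/or receiving (R) country.  Within a block the counts are Poisson with
means ``nu`` whose logs scatter, with reporter-specific precision, around the
log of the latent true flow ``m`` shifted by a reporter-by-block interaction
(the shift makes reported totals uninformative about compositions, so the
Poisson formulation is a valid respecification of a multinomial model for the
age–sex split).  The true flows follow a multiplicative (log-additive) model
with destination-age, destination-sex, origin-age and origin-sex effects, each
shrunk towards global age and sex profiles.  All normal densities are
parameterized by precision (inverse variance).

This module is the single source of truth for the posterior: the Gibbs
sampler's conditionals and the test oracles both reduce to sums of the terms
defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln

from .data import ReportedFlowData
from .dims import RECEIVING, SENDING, StudyDimensions
from .errors import ConfigError, DataError, ModelAssemblyError

LOG_2PI = float(np.log(2.0 * np.pi))

# Hyperprior constants: Gamma(shape, rate) for precisions, normal precision
# for the reporter-by-block interaction terms.
GAMMA_OBS_SHAPE = GAMMA_OBS_RATE = 1e-3  # level + measurement precisions
GAMMA_HIER_SHAPE = GAMMA_HIER_RATE = 1e-2  # country-effect precisions
REPORT_EFFECT_PRECISION = 1e-2  # weakly informative N(0, prec 1e-2)

OBS_PRECISION_NAMES = (
    "tau_level",
    "tau_send",
    "tau_recv",
    "tau_send_sexonly",
    "tau_recv_sexonly",
)
HIER_PRECISION_NAMES = ("tau_dest_age", "tau_dest_sex", "tau_orig_age", "tau_orig_sex")
PRECISION_NAMES = OBS_PRECISION_NAMES + HIER_PRECISION_NAMES


@dataclass
class ParameterState:
    """Hierarchical effects and precisions.

    ``age_effect[0]`` (youngest age group) and ``sex_effect[0]`` (females) are
    constrained to zero for identifiability; everything else is free.
    Country-level effect matrices include the rest-of-world unit as an
    ordinary row.
    """

    age_effect: np.ndarray  # (A,), [0] == 0
    sex_effect: np.ndarray  # (2,), [0] == 0
    dest_age: np.ndarray  # (U, A)
    dest_sex: np.ndarray  # (U, 2)
    orig_age: np.ndarray  # (U, A)
    orig_sex: np.ndarray  # (U, 2)
    tau_level: float = 1.0  # precision of log m around its predictor
    tau_send: float = 1.0  # measurement precision, sending age-sex reports
    tau_recv: float = 1.0
    tau_send_sexonly: float = 1.0
    tau_recv_sexonly: float = 1.0
    tau_dest_age: float = 1.0
    tau_dest_sex: float = 1.0
    tau_orig_age: float = 1.0
    tau_orig_sex: float = 1.0

    @classmethod
    def zeros(cls, dims: StudyDimensions, **precisions: float) -> "ParameterState":
        U, A = dims.n_units, dims.n_ages
        return cls(
            age_effect=np.zeros(A),
            sex_effect=np.zeros(2),
            dest_age=np.zeros((U, A)),
            dest_sex=np.zeros((U, 2)),
            orig_age=np.zeros((U, A)),
            orig_sex=np.zeros((U, 2)),
            **precisions,
        )

    def copy(self) -> "ParameterState":
        return replace(
            self,
            age_effect=self.age_effect.copy(),
            sex_effect=self.sex_effect.copy(),
            dest_age=self.dest_age.copy(),
            dest_sex=self.dest_sex.copy(),
            orig_age=self.orig_age.copy(),
            orig_sex=self.orig_sex.copy(),
        )

    def precisions(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PRECISION_NAMES}

    def check(self) -> None:
        if self.age_effect[0] != 0.0:
            raise ModelAssemblyError("identifiability: age_effect[0] must be 0")
        if self.sex_effect[0] != 0.0:
            raise ModelAssemblyError("identifiability: sex_effect[0] (F) must be 0")
        for name, value in self.precisions().items():
            if not np.isfinite(value) or value <= 0:
                raise ConfigError(f"precision {name} must be positive, got {value}")

    def measurement_precision(self, reporter: int, sexonly: bool) -> float:
        if reporter == SENDING:
            return self.tau_send_sexonly if sexonly else self.tau_send
        if reporter == RECEIVING:
            return self.tau_recv_sexonly if sexonly else self.tau_recv
        raise ConfigError(f"unknown reporter index {reporter}")


@dataclass
class LatentState:
    """Latent quantities tied to one data set: log true flows, log Poisson
    means per observed report cell, and one reporter-by-block interaction per
    observed (origin, destination, year, reporter) combination (regardless of
    whether that block is age–sex or sex-only).
    """

    log_m: np.ndarray  # (F, T, A, 2)
    log_nu_agesex: np.ndarray  # (2, F, T, A, 2); valid under mask
    log_nu_sexonly: np.ndarray  # (2, F, T, 2); valid under mask
    report_effect: np.ndarray  # (2, F, T); valid under report_mask
    report_mask: np.ndarray  # (2, F, T) bool — which blocks carry a report

    def copy(self) -> "LatentState":
        return LatentState(
            log_m=self.log_m.copy(),
            log_nu_agesex=self.log_nu_agesex.copy(),
            log_nu_sexonly=self.log_nu_sexonly.copy(),
            report_effect=self.report_effect.copy(),
            report_mask=self.report_mask.copy(),
        )


# ---------------------------------------------------------------------------
# Elementary densities
# ---------------------------------------------------------------------------


def log_poisson_obs(z, log_nu):
    """Poisson log-pmf ``z log nu - nu - log z!`` evaluated stably from log nu.

    Accepts scalars or arrays; ``z`` must be non-negative integers.
    """
    z = np.asarray(z)
    log_nu = np.asarray(log_nu, dtype=float)
    if not np.issubdtype(z.dtype, np.integer):
        zf = np.asarray(z, dtype=float)
        if not np.allclose(zf, np.round(zf)):
            raise DataError("counts must be integers")
        z = np.round(zf).astype(np.int64)
    if (z < 0).any():
        raise DataError("counts must be non-negative")
    out = z * log_nu - np.exp(log_nu) - gammaln(z + 1.0)
    return out if out.ndim else float(out)


def log_normal_prec(x, mean, tau):
    """Normal log-density with precision parameterization."""
    x = np.asarray(x, dtype=float)
    out = 0.5 * (np.log(tau) - LOG_2PI) - 0.5 * tau * (x - mean) ** 2
    return out if out.ndim else float(out)


def log_measurement(log_nu, log_m_ref, alpha_odt, tau):
    """Measurement term: log nu ~ N(log m_ref + alpha_odt, tau).

    ``log_m_ref`` is log m for an age–sex cell, or log of the age-summed true
    flow for a sex-only cell.
    """
    if np.any(np.asarray(tau) <= 0):
        raise ConfigError("measurement precision must be positive")
    return log_normal_prec(log_nu, np.asarray(log_m_ref) + np.asarray(alpha_odt), tau)


def log_gamma_prior(tau: float, shape: float, rate: float) -> float:
    """Gamma(shape, rate) log-density (shape–rate parameterization)."""
    if tau <= 0:
        raise ConfigError("precision must be positive")
    return float(
        shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(tau) - rate * tau
    )


# ---------------------------------------------------------------------------
# Structured terms
# ---------------------------------------------------------------------------


def predictor(params: ParameterState, dims: StudyDimensions) -> np.ndarray:
    """Four-effect linear predictor of log m, shape ``(F, 1, A, 2)``.

    The predictor has no time dimension (broadcast over years).
    """
    o_idx, d_idx = dims.flow_arrays()
    p = (
        params.dest_age[d_idx][:, None, :, None]
        + params.dest_sex[d_idx][:, None, None, :]
        + params.orig_age[o_idx][:, None, :, None]
        + params.orig_sex[o_idx][:, None, None, :]
    )
    return p


def log_level_model(log_m: np.ndarray, params: ParameterState, dims: StudyDimensions) -> float:
    """Sum over all cells of the level-model density of log m."""
    params.check()
    p = predictor(params, dims)
    expected = (dims.n_flows, dims.n_years, dims.n_ages, 2)
    if log_m.shape != expected:
        raise ModelAssemblyError(f"log_m has shape {log_m.shape}, expected {expected}")
    return float(log_normal_prec(log_m, p, params.tau_level).sum())


def log_prior(params: ParameterState, latent: LatentState) -> float:
    """Joint log-prior of all parameters and the reporter interactions.

    Standard normal on free global age/sex effects; hierarchical normal terms
    for the country effects; Gamma hyperpriors on precisions; weakly
    informative normal on each reporter-by-block interaction that exists.
    """
    params.check()
    total = 0.0
    # global profiles: free elements standard normal, constrained ones fixed
    total += float(log_normal_prec(params.age_effect[1:], 0.0, 1.0).sum())
    total += float(log_normal_prec(params.sex_effect[1:], 0.0, 1.0).sum())
    # country effects shrunk towards the global profiles
    total += float(
        log_normal_prec(params.dest_age, params.age_effect[None, :], params.tau_dest_age).sum()
    )
    total += float(
        log_normal_prec(params.dest_sex, params.sex_effect[None, :], params.tau_dest_sex).sum()
    )
    total += float(
        log_normal_prec(params.orig_age, params.age_effect[None, :], params.tau_orig_age).sum()
    )
    total += float(
        log_normal_prec(params.orig_sex, params.sex_effect[None, :], params.tau_orig_sex).sum()
    )
    for name in OBS_PRECISION_NAMES:
        total += log_gamma_prior(getattr(params, name), GAMMA_OBS_SHAPE, GAMMA_OBS_RATE)
    for name in HIER_PRECISION_NAMES:
        total += log_gamma_prior(getattr(params, name), GAMMA_HIER_SHAPE, GAMMA_HIER_RATE)
    # one interaction per reporting combination
    alphas = latent.report_effect[latent.report_mask]
    total += float(log_normal_prec(alphas, 0.0, REPORT_EFFECT_PRECISION).sum())
    return total


def log_posterior(
    data: ReportedFlowData, latent: LatentState, params: ParameterState
) -> float:
    """Unnormalized joint log-posterior: prior + level model + measurement and
    Poisson terms over every observed age–sex and sex-only cell.

    Rest-of-world flows contribute single-sided terms only, enforced by the
    data masks.
    """
    if latent.report_mask.shape != data.report_mask.shape or not np.array_equal(
        latent.report_mask, data.report_mask
    ):
        raise ModelAssemblyError("latent report mask does not match the data masks")
    d = data.dims
    total = log_prior(params, latent) + log_level_model(latent.log_m, params, d)
    tau_as = (params.tau_send, params.tau_recv)
    tau_sx = (params.tau_send_sexonly, params.tau_recv_sexonly)
    log_m_sum_a = _log_sum_over_age(latent.log_m)  # (F, T, 2)
    for k in (SENDING, RECEIVING):
        bm = data.mask_agesex[k]  # (F, T)
        if bm.any():
            cells = np.broadcast_to(bm[:, :, None, None], latent.log_m.shape)
            ln = latent.log_nu_agesex[k][cells]
            ref = latent.log_m[cells]
            alpha = np.broadcast_to(
                latent.report_effect[k][:, :, None, None], latent.log_m.shape
            )[cells]
            total += float(log_measurement(ln, ref, alpha, tau_as[k]).sum())
            total += float(log_poisson_obs(data.z_agesex[k][cells], ln).sum())
        bm1 = data.mask_sexonly[k]
        if bm1.any():
            cells = np.broadcast_to(bm1[:, :, None], (d.n_flows, d.n_years, 2))
            ln = latent.log_nu_sexonly[k][cells]
            ref = log_m_sum_a[cells]
            alpha = np.broadcast_to(
                latent.report_effect[k][:, :, None], (d.n_flows, d.n_years, 2)
            )[cells]
            total += float(log_measurement(ln, ref, alpha, tau_sx[k]).sum())
            total += float(log_poisson_obs(data.z_sexonly[k][cells], ln).sum())
    return total


def _log_sum_over_age(log_m: np.ndarray) -> np.ndarray:
    """log of the age-summed true flow, per (flow, year, sex)."""
    from scipy.special import logsumexp

    return logsumexp(log_m, axis=2)


# ---------------------------------------------------------------------------
# Compositions
# ---------------------------------------------------------------------------


def rho_from_nu(nu_block: np.ndarray) -> np.ndarray:
    """Reported age–sex composition: entries of a positive block divided by
    the block total."""
    nu_block = np.asarray(nu_block, dtype=float)
    if not (nu_block > 0).all():
        raise DataError("composition requires strictly positive entries")
    return nu_block / nu_block.sum()


def pi_from_m(m_block: np.ndarray) -> np.ndarray:
    """True age–sex composition of one (origin, destination, year) block; the
    same normalization as :func:`rho_from_nu`."""
    return rho_from_nu(m_block)


def pi_from_log_m(log_m: np.ndarray) -> np.ndarray:
    """Compositions for every (flow, year) block of a full log m array.

    Input ``(F, T, A, 2)``; output the same shape with each (a, s) block
    summing to one.  Computed with max-subtraction for stability.
    """
    shift = log_m - log_m.max(axis=(2, 3), keepdims=True)
    w = np.exp(shift)
    return w / w.sum(axis=(2, 3), keepdims=True)
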