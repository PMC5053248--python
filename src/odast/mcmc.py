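"""Slice-within-Gibbs sampler for the joint posterior.

One sweep updates, in a fixed documented order:

1. every observed log Poisson mean (age–sex cells, then sex-only cells) by
   vectorized univariate slice sampling — the cells are conditionally
   independent given the rest of the state;
2. every log true flow, age group by age group (cells within an age group are
   conditionally independent across blocks and sexes; the age loop respects
   the coupling introduced by sex-only log-sum terms);
3. every reporter-by-block interaction (slice on its quadratic conditional);
4. the four country-effect families and then the free global age/sex profile
   elements (slice on their normal conditionals);
5. all precisions by exact conjugate Gamma draws.

A randomized-scan variant permutes the order of these step groups.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data import ReportedFlowData
from .dims import RECEIVING, SENDING, StudyDimensions
from .errors import ConfigError, DiagnosticError
from .model import (
    GAMMA_HIER_RATE,
    GAMMA_HIER_SHAPE,
    GAMMA_OBS_RATE,
    GAMMA_OBS_SHAPE,
    REPORT_EFFECT_PRECISION,
    LatentState,
    ParameterState,
    pi_from_log_m,
    predictor,
)
from .samplers import slice_sample_vec

_EXP_CLIP = 700.0  # exp() overflow guard on proposals far in the tail


@dataclass
class McmcConfig:
    """Chain-length, tuning and monitoring settings.

    ``burn_in`` defaults to half of ``n_iterations``; retained draws are the
    every-``thinning``-th sweeps after burn-in.
    """

    n_iterations: int = 5000
    burn_in: int | None = None
    thinning: int = 10
    slice_width: float = 1.0
    max_stepouts: int = 50
    seed: int = 0
    store_m: bool = True
    store_report_effect: bool = True
    randomized_scan: bool = False
    progress_every: int = 0  # sweeps between progress lines; 0 silences

    @property
    def resolved_burn_in(self) -> int:
        return self.n_iterations // 2 if self.burn_in is None else self.burn_in

    def validate(self) -> None:
        if self.n_iterations <= self.resolved_burn_in or self.resolved_burn_in < 0:
            raise ConfigError(
                f"need n_iterations > burn_in >= 0, got "
                f"{self.n_iterations} and {self.resolved_burn_in}"
            )
        if self.thinning < 1:
            raise ConfigError("thinning must be >= 1")
        if not self.slice_width > 0:
            raise ConfigError("slice width must be positive")
        if self.max_stepouts < 1:
            raise ConfigError("max_stepouts must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.resolved_burn_in) // self.thinning


@dataclass
class PosteriorDraws:
    """Retained draws with provenance.

    ``pi`` holds the composition draws (each (flow, year) block sums to one);
    ``log_m`` and ``report_effect`` are kept when monitoring is configured so
    the posterior-predictive machinery can re-simulate reports.
    """

    dims: StudyDimensions
    pi: np.ndarray  # (n, F, T, A, 2)
    age_effect: np.ndarray  # (n, A)
    sex_effect: np.ndarray  # (n, 2)
    scalars: dict[str, np.ndarray]  # precision name -> (n,)
    report_mask: np.ndarray  # (2, F, T)
    config: McmcConfig
    seed: int
    log_m: np.ndarray | None = None  # (n, F, T, A, 2)
    report_effect: np.ndarray | None = None  # (n, 2, F, T)

    @property
    def n_draws(self) -> int:
        return self.pi.shape[0]

    def scalar_series(self, name: str) -> np.ndarray:
        """Monitored scalar chain by name: a precision (e.g. ``tau_level``)
        or an indexed effect such as ``age_effect[3]`` / ``sex_effect[1]``."""
        if name in self.scalars:
            return self.scalars[name]
        m = re.fullmatch(r"(age_effect|sex_effect)\[(\d+)\]", name)
        if m:
            arr = getattr(self, m.group(1))
            idx = int(m.group(2))
            if idx >= arr.shape[1]:
                raise KeyError(f"index {idx} out of range for {m.group(1)}")
            return arr[:, idx]
        raise KeyError(f"unknown monitored quantity {name!r}")


def update_precision(
    residuals: np.ndarray,
    prior_shape: float,
    prior_rate: float,
    rng: np.random.Generator,
) -> float:
    """Exact conjugate draw of a normal precision given its centred residuals.

    With a Gamma(shape, rate) prior and residuals ``r`` the full conditional
    is Gamma(shape + n/2, rate + sum(r^2)/2); an empty residual vector returns
    a prior draw.
    """
    if prior_shape <= 0 or prior_rate <= 0:
        raise ConfigError("Gamma prior shape and rate must be positive")
    r = np.asarray(residuals, dtype=float).ravel()
    shape = prior_shape + 0.5 * r.size
    rate = prior_rate + 0.5 * float(r @ r)
    draw = float(rng.gamma(shape, 1.0 / rate))
    # a near-noninformative shape can underflow to exactly 0; keep positivity
    return draw if draw > 0.0 else float(np.finfo(float).tiny)


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def initial_state(data: ReportedFlowData) -> tuple[LatentState, ParameterState]:
    """Data-driven starting point.

    Log true flows start at smoothed log observed counts (averaged across the
    reporters that saw the block; sex-only counts are split evenly over age),
    with unobserved cells at the mean of the initialized ones; log Poisson
    means start at smoothed log counts; interactions and effects start at 0
    and precisions at 1.
    """
    d = data.dims
    F, T, A = d.n_flows, d.n_years, d.n_ages
    log_m = np.full((F, T, A, 2), np.nan)

    n_as = data.mask_agesex.sum(axis=0)  # (F, T) number of age-sex reporters
    if (n_as > 0).any():
        zsum = (data.z_agesex * data.mask_agesex[:, :, :, None, None]).sum(axis=0)
        zbar = zsum[n_as > 0] / n_as[n_as > 0, None, None]
        log_m[n_as > 0] = np.log(zbar + 0.5)

    n_sx = data.mask_sexonly.sum(axis=0)
    sx_only = (n_sx > 0) & (n_as == 0)
    if sx_only.any():
        z1sum = (data.z_sexonly * data.mask_sexonly[:, :, :, None]).sum(axis=0)
        z1bar = z1sum[sx_only] / n_sx[sx_only, None]
        log_m[sx_only] = np.log(z1bar[:, None, :] / A + 0.5)

    seen = np.isfinite(log_m)
    fill = float(log_m[seen].mean()) if seen.any() else 0.0
    log_m[~seen] = fill

    log_nu_as = np.zeros((2, F, T, A, 2))
    cells = np.broadcast_to(data.mask_agesex[:, :, :, None, None], log_nu_as.shape)
    log_nu_as[cells] = np.log(data.z_agesex[cells] + 0.5)
    log_nu_sx = np.zeros((2, F, T, 2))
    cells1 = np.broadcast_to(data.mask_sexonly[:, :, :, None], log_nu_sx.shape)
    log_nu_sx[cells1] = np.log(data.z_sexonly[cells1] + 0.5)

    latent = LatentState(
        log_m=log_m,
        log_nu_agesex=log_nu_as,
        log_nu_sexonly=log_nu_sx,
        report_effect=np.zeros((2, F, T)),
        report_mask=data.report_mask.copy(),
    )
    params = ParameterState.zeros(d)
    return latent, params


# ---------------------------------------------------------------------------
# The sweep
# ---------------------------------------------------------------------------


class GibbsSampler:
    """Caches data-dependent index structures and performs sweeps in place."""

    def __init__(self, data: ReportedFlowData, cfg: McmcConfig):
        data.validate()
        cfg.validate()
        self.data = data
        self.cfg = cfg
        d = data.dims
        self.dims = d
        self.o_idx, self.d_idx = d.flow_arrays()
        A, T = d.n_ages, d.n_years
        cell_shape = (2, d.n_flows, T, A, 2)
        self.cells_as = np.where(
            np.broadcast_to(data.mask_agesex[:, :, :, None, None], cell_shape)
        )
        self.z_as = data.z_agesex[self.cells_as].astype(float)
        sx_shape = (2, d.n_flows, T, 2)
        self.cells_sx = np.where(
            np.broadcast_to(data.mask_sexonly[:, :, :, None], sx_shape)
        )
        self.z_sx = data.z_sexonly[self.cells_sx].astype(float)
        self.blocks = np.where(data.report_mask)
        # each unit is origin (and destination) of n_units - 1 flows
        self.n_cells_age_family = float((d.n_units - 1) * T * 2)
        self.n_cells_sex_family = float((d.n_units - 1) * T * A)

    # -- step 1: log Poisson means -------------------------------------
    def _update_log_nu(self, latent: LatentState, params: ParameterState, rng) -> None:
        w, ms = self.cfg.slice_width, self.cfg.max_stepouts
        if self.z_as.size:
            K, Fi, Ti, Ai, Si = self.cells_as
            z = self.z_as
            tau = np.where(K == SENDING, params.tau_send, params.tau_recv)
            mean = latent.log_m[Fi, Ti, Ai, Si] + latent.report_effect[K, Fi, Ti]

            def logf(x):
                return z * x - np.exp(np.minimum(x, _EXP_CLIP)) - 0.5 * tau * (x - mean) ** 2

            latent.log_nu_agesex[self.cells_as] = slice_sample_vec(
                logf, latent.log_nu_agesex[self.cells_as], w, ms, rng
            )
        if self.z_sx.size:
            K, Fi, Ti, Si = self.cells_sx
            z = self.z_sx
            tau = np.where(K == SENDING, params.tau_send_sexonly, params.tau_recv_sexonly)
            log_sum_m = logsumexp(latent.log_m, axis=2)  # (F, T, 2)
            mean = log_sum_m[Fi, Ti, Si] + latent.report_effect[K, Fi, Ti]

            def logf1(x):
                return z * x - np.exp(np.minimum(x, _EXP_CLIP)) - 0.5 * tau * (x - mean) ** 2

            latent.log_nu_sexonly[self.cells_sx] = slice_sample_vec(
                logf1, latent.log_nu_sexonly[self.cells_sx], w, ms, rng
            )

    # -- step 2: log true flows ----------------------------------------
    def _update_log_m(self, latent: LatentState, params: ParameterState, rng) -> None:
        d = self.dims
        w, ms = self.cfg.slice_width, self.cfg.max_stepouts
        data = self.data
        m = np.exp(latent.log_m)
        S = m.sum(axis=2)  # (F, T, 2) age-summed true flows
        pred = predictor(params, d)  # (F, 1, A, 2)
        tau_as = np.array([params.tau_send, params.tau_recv])
        tau_sx = np.array([params.tau_send_sexonly, params.tau_recv_sexonly])
        # quadratic coefficient of the age-sex measurement terms per (f, t)
        qn = (data.mask_agesex * tau_as[:, None, None]).sum(axis=0)[:, :, None]
        mask_sx = data.mask_sexonly  # (2, F, T)
        any_sx = bool(mask_sx.any())
        if any_sx:
            r_sx = latent.log_nu_sexonly - latent.report_effect[:, :, :, None]  # (2,F,T,2)
            wt_sx = mask_sx[:, :, :, None] * tau_sx[:, None, None, None]

        for a in range(d.n_ages):
            x0 = latent.log_m[:, :, a, :]  # (F, T, 2)
            mu0 = pred[:, :, a, :]  # (F, 1, 2) broadcasts over T
            qlin = np.zeros_like(x0)
            for k in (SENDING, RECEIVING):
                qlin += (
                    tau_as[k]
                    * data.mask_agesex[k][:, :, None]
                    * (latent.log_nu_agesex[k, :, :, a, :] - latent.report_effect[k][:, :, None])
                )
            S_other = S - m[:, :, a, :]
            if any_sx:
                log_S_other = np.log(S_other)

            def logf(x):
                val = (
                    -0.5 * params.tau_level * (x - mu0) ** 2
                    - 0.5 * qn * x * x
                    + qlin * x
                )
                if any_sx:
                    ls = np.logaddexp(np.minimum(x, _EXP_CLIP), log_S_other)
                    val = val - 0.5 * (wt_sx * (r_sx - ls[None]) ** 2).sum(axis=0)
                return val

            x = slice_sample_vec(logf, x0, w, ms, rng)
            latent.log_m[:, :, a, :] = x
            m[:, :, a, :] = np.exp(x)
            S = S_other + m[:, :, a, :]

    # -- step 3: reporter-by-block interactions ------------------------
    def _update_report_effect(self, latent: LatentState, params: ParameterState, rng) -> None:
        if not self.blocks[0].size:
            return
        data = self.data
        d = self.dims
        A = d.n_ages
        tau_as = np.array([params.tau_send, params.tau_recv])
        tau_sx = np.array([params.tau_send_sexonly, params.tau_recv_sexonly])
        res_as = (
            (latent.log_nu_agesex - latent.log_m[None]).sum(axis=(3, 4))
            * data.mask_agesex
        )  # (2, F, T)
        log_sum_m = logsumexp(latent.log_m, axis=2)
        res_sx = (
            (latent.log_nu_sexonly - log_sum_m[None]).sum(axis=3) * data.mask_sexonly
        )
        K, Fi, Ti = self.blocks
        n_as = data.mask_agesex[self.blocks] * (A * 2)
        n_sx = data.mask_sexonly[self.blocks] * 2
        P = REPORT_EFFECT_PRECISION + tau_as[K] * n_as + tau_sx[K] * n_sx
        L = tau_as[K] * res_as[self.blocks] + tau_sx[K] * res_sx[self.blocks]

        def logf(x):
            return -0.5 * P * x * x + L * x

        latent.report_effect[self.blocks] = slice_sample_vec(
            logf,
            latent.report_effect[self.blocks],
            self.cfg.slice_width,
            self.cfg.max_stepouts,
            rng,
        )

    # -- step 4: hierarchical effects ----------------------------------
    def _update_effects(self, latent: LatentState, params: ParameterState, rng) -> None:
        d = self.dims
        U = d.n_units
        lm = latent.log_m
        w, ms = self.cfg.slice_width, self.cfg.max_stepouts
        o_idx, d_idx = self.o_idx, self.d_idx

        def contribution(family: str) -> np.ndarray:
            if family == "dest_age":
                return params.dest_age[d_idx][:, None, :, None]
            if family == "dest_sex":
                return params.dest_sex[d_idx][:, None, None, :]
            if family == "orig_age":
                return params.orig_age[o_idx][:, None, :, None]
            return params.orig_sex[o_idx][:, None, None, :]

        specs = [
            ("dest_age", d_idx, (1, 3), params.age_effect, params.tau_dest_age,
             self.n_cells_age_family),
            ("dest_sex", d_idx, (1, 2), params.sex_effect, params.tau_dest_sex,
             self.n_cells_sex_family),
            ("orig_age", o_idx, (1, 3), params.age_effect, params.tau_orig_age,
             self.n_cells_age_family),
            ("orig_sex", o_idx, (1, 2), params.sex_effect, params.tau_orig_sex,
             self.n_cells_sex_family),
        ]
        families = ("dest_age", "dest_sex", "orig_age", "orig_sex")
        for family, scatter_idx, sum_axes, prior_mean, prior_tau, n_cells in specs:
            others = sum(contribution(f) for f in families if f != family)
            resid = (lm - others).sum(axis=sum_axes)  # (F, A) or (F, 2)
            current = getattr(params, family)
            Sr = np.zeros_like(current)
            np.add.at(Sr, scatter_idx, resid)

            def logf(x, Sr=Sr, prior_mean=prior_mean, prior_tau=prior_tau, n=n_cells):
                return (
                    -0.5 * prior_tau * (x - prior_mean[None, :]) ** 2
                    - 0.5 * params.tau_level * (n * x * x - 2.0 * Sr * x)
                )

            setattr(params, family, slice_sample_vec(logf, current, w, ms, rng))

    # -- step 5: global age and sex profiles ---------------------------
    def _update_global_profiles(self, latent: LatentState, params: ParameterState, rng) -> None:
        U = self.dims.n_units
        w, ms = self.cfg.slice_width, self.cfg.max_stepouts
        for name, fam_a, fam_b, tau_a, tau_b in (
            ("age_effect", params.dest_age, params.orig_age,
             params.tau_dest_age, params.tau_orig_age),
            ("sex_effect", params.dest_sex, params.orig_sex,
             params.tau_dest_sex, params.tau_orig_sex),
        ):
            vec = getattr(params, name)
            P = 1.0 + U * (tau_a + tau_b)
            L = tau_a * fam_a.sum(axis=0)[1:] + tau_b * fam_b.sum(axis=0)[1:]

            def logf(x, P=P, L=L):
                return -0.5 * P * x * x + L * x

            vec[1:] = slice_sample_vec(logf, vec[1:], w, ms, rng)
            vec[0] = 0.0  # identifiability constraint stays exact

    # -- step 6: precisions --------------------------------------------
    def _update_precisions(self, latent: LatentState, params: ParameterState, rng) -> None:
        d = self.dims
        pred = predictor(params, d)
        params.tau_level = update_precision(
            latent.log_m - pred, GAMMA_OBS_SHAPE, GAMMA_OBS_RATE, rng
        )
        K, Fi, Ti, Ai, Si = self.cells_as
        res = (
            latent.log_nu_agesex[self.cells_as]
            - latent.log_m[Fi, Ti, Ai, Si]
            - latent.report_effect[K, Fi, Ti]
        )
        params.tau_send = update_precision(
            res[K == SENDING], GAMMA_OBS_SHAPE, GAMMA_OBS_RATE, rng
        )
        params.tau_recv = update_precision(
            res[K == RECEIVING], GAMMA_OBS_SHAPE, GAMMA_OBS_RATE, rng
        )
        K1, F1, T1, S1 = self.cells_sx
        log_sum_m = logsumexp(latent.log_m, axis=2)
        res1 = (
            latent.log_nu_sexonly[self.cells_sx]
            - log_sum_m[F1, T1, S1]
            - latent.report_effect[K1, F1, T1]
        )
        params.tau_send_sexonly = update_precision(
            res1[K1 == SENDING], GAMMA_OBS_SHAPE, GAMMA_OBS_RATE, rng
        )
        params.tau_recv_sexonly = update_precision(
            res1[K1 == RECEIVING], GAMMA_OBS_SHAPE, GAMMA_OBS_RATE, rng
        )
        params.tau_dest_age = update_precision(
            params.dest_age - params.age_effect[None, :],
            GAMMA_HIER_SHAPE, GAMMA_HIER_RATE, rng,
        )
        params.tau_dest_sex = update_precision(
            params.dest_sex - params.sex_effect[None, :],
            GAMMA_HIER_SHAPE, GAMMA_HIER_RATE, rng,
        )
        params.tau_orig_age = update_precision(
            params.orig_age - params.age_effect[None, :],
            GAMMA_HIER_SHAPE, GAMMA_HIER_RATE, rng,
        )
        params.tau_orig_sex = update_precision(
            params.orig_sex - params.sex_effect[None, :],
            GAMMA_HIER_SHAPE, GAMMA_HIER_RATE, rng,
        )

    # ------------------------------------------------------------------
    def sweep(self, latent: LatentState, params: ParameterState, rng) -> None:
        steps = [
            self._update_log_nu,
            self._update_log_m,
            self._update_report_effect,
            self._update_effects,
            self._update_global_profiles,
            self._update_precisions,
        ]
        if self.cfg.randomized_scan:
            steps = [steps[i] for i in rng.permutation(len(steps))]
        for step in steps:
            step(latent, params, rng)


def gibbs_sweep(
    data: ReportedFlowData,
    latent: LatentState,
    params: ParameterState,
    cfg: McmcConfig,
    rng: np.random.Generator,
) -> tuple[LatentState, ParameterState]:
    """One full Gibbs sweep (functional wrapper around :class:`GibbsSampler`);
    mutates and returns the given state."""
    GibbsSampler(data, cfg).sweep(latent, params, rng)
    return latent, params


# ---------------------------------------------------------------------------
# Chains
# ---------------------------------------------------------------------------


def run_chain(
    data: ReportedFlowData,
    cfg: McmcConfig,
    init: tuple[LatentState, ParameterState] | None = None,
) -> PosteriorDraws:
    """Run one chain and return retained draws with full provenance.

    Initializes from :func:`initial_state` unless an explicit state is given,
    performs ``cfg.n_iterations`` sweeps, discards the burn-in and keeps every
    ``cfg.thinning``-th sweep; compositions are recomputed per retained draw.
    """
    sampler = GibbsSampler(data, cfg)
    rng = np.random.default_rng(cfg.seed)
    latent, params = init if init is not None else initial_state(data)
    d = data.dims
    n_keep = cfg.n_retained
    if n_keep < 1:
        raise ConfigError("configuration retains no draws")
    F, T, A = d.n_flows, d.n_years, d.n_ages
    pi = np.empty((n_keep, F, T, A, 2))
    age_eff = np.empty((n_keep, A))
    sex_eff = np.empty((n_keep, 2))
    scalars = {name: np.empty(n_keep) for name in params.precisions()}
    log_m = np.empty((n_keep, F, T, A, 2)) if cfg.store_m else None
    rep_eff = np.empty((n_keep, 2, F, T)) if cfg.store_report_effect else None

    burn = cfg.resolved_burn_in
    kept = 0
    for it in range(1, cfg.n_iterations + 1):
        sampler.sweep(latent, params, rng)
        if cfg.progress_every and it % cfg.progress_every == 0:
            print(f"sweep {it}/{cfg.n_iterations}", flush=True)
        if it > burn and (it - burn) % cfg.thinning == 0 and kept < n_keep:
            pi[kept] = pi_from_log_m(latent.log_m)
            age_eff[kept] = params.age_effect
            sex_eff[kept] = params.sex_effect
            for name, value in params.precisions().items():
                scalars[name][kept] = value
            if log_m is not None:
                log_m[kept] = latent.log_m
            if rep_eff is not None:
                rep_eff[kept] = latent.report_effect
            kept += 1
    return PosteriorDraws(
        dims=d,
        pi=pi,
        age_effect=age_eff,
        sex_effect=sex_eff,
        scalars=scalars,
        report_mask=data.report_mask.copy(),
        config=replace(cfg),
        seed=cfg.seed,
        log_m=log_m,
        report_effect=rep_eff,
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def autocorrelation(x: np.ndarray, lag: int) -> float:
    """Sample autocorrelation at one lag; 1 at lag 0 by definition."""
    if lag == 0:
        return 1.0
    x = np.asarray(x, dtype=float)
    n = x.size
    if lag >= n:
        return float("nan")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:  # constant chain
        return float("nan")
    return float(xc[:-lag] @ xc[lag:]) / denom


def chain_diagnostics(
    draws: PosteriorDraws,
    parameter_names: Sequence[str],
    lags: Sequence[int] = (0, 1, 5, 10, 25),
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Autocorrelations at requested lags plus cumulative-mean sequences for
    each monitored scalar; unknown names raise ``KeyError``."""
    if draws.n_draws < 2:
        raise ConfigError("need at least 2 retained draws for diagnostics")
    rows = []
    cum_means: dict[str, np.ndarray] = {}
    for name in parameter_names:
        series = draws.scalar_series(name)
        cum_means[name] = np.cumsum(series) / np.arange(1, series.size + 1)
        for lag in lags:
            rows.append(
                {"parameter": name, "lag": lag, "autocorrelation": autocorrelation(series, lag)}
            )
    return pd.DataFrame(rows), cum_means


def plot_diagnostics(
    draws: PosteriorDraws,
    parameter_names: Sequence[str],
    path: str,
    lags: Sequence[int] = (0, 1, 5, 10, 25),
) -> None:
    """Write cumulative-mean and autocorrelation panels to a figure file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table, cum_means = chain_diagnostics(draws, parameter_names, lags)
    n = len(parameter_names)
    fig, axes = plt.subplots(n, 2, figsize=(9, 2.4 * n), squeeze=False)
    for i, name in enumerate(parameter_names):
        axes[i, 0].plot(cum_means[name])
        axes[i, 0].set_title(f"{name}: cumulative mean", fontsize=9)
        sub = table[table["parameter"] == name]
        axes[i, 1].bar(sub["lag"].astype(str), sub["autocorrelation"])
        axes[i, 1].set_title(f"{name}: autocorrelation", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
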