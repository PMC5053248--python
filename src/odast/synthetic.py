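"""Synthetic study generator.

Emulates the statistical structure of Eurostat-style double-reported migration
tables: ground-truth flows from the multiplicative age–sex model, then
corrupted, partially missing sending/receiving reports from the measurement
model (log-normal overdispersion around the true flow shifted by a
reporter-by-block level effect, then Poisson counts), a configurable share of
sex-only reports, one-sided observation of rest-of-world flows, and stand-in
posterior draws of the origin–destination marginal flows.

Every stochastic stage derives an independent substream from the single root
seed in the scenario config, so any stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ODMarginalDraws, ReportedFlowData
from .dims import RECEIVING, SENDING, StudyDimensions
from .errors import ConfigError
from .model import ParameterState, pi_from_log_m

# fixed substream indices off the root seed
_STAGE_HYPER, _STAGE_FLOWS, _STAGE_REPORTS, _STAGE_OD = range(4)


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[stage])


@dataclass
class ScenarioConfig:
    """Generative constants of one synthetic scenario.

    Precisions are inverse variances on the log scale.  The defaults describe
    a realistic desk-scale study: moderate country-to-country variation in
    age–sex profiles (sd 0.5 around the global profile), measurement
    overdispersion of roughly 30% (precision 10), reporter level shifts of
    sd 0.5 (reported totals off by factors up to about e, matching the spread
    between permissive and restrictive national migrant definitions), 40% of
    reports missing per side and 20% of the present reports sex-only.
    """

    tau_dest_age: float = 4.0
    tau_dest_sex: float = 4.0
    tau_orig_age: float = 4.0
    tau_orig_sex: float = 4.0
    tau_level: float = 4.0
    tau_send: float = 10.0
    tau_recv: float = 10.0
    tau_send_sexonly: float = 10.0
    tau_recv_sexonly: float = 10.0
    report_effect_sd: float = 0.5
    report_effect_mean_send: float = 0.0
    report_effect_mean_recv: float = 0.0
    missing_fraction_send: float = 0.4
    missing_fraction_recv: float = 0.4
    sexonly_fraction: float = 0.2
    base_flow: float = 100.0  # persons/year scale of a typical cell
    seed: int = 20160122
    age_profile: np.ndarray | None = None  # optional fixed global age effects
    sex_profile: np.ndarray | None = None

    def validate(self) -> None:
        for name in (
            "tau_dest_age", "tau_dest_sex", "tau_orig_age", "tau_orig_sex",
            "tau_level", "tau_send", "tau_recv", "tau_send_sexonly",
            "tau_recv_sexonly",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigError(f"precision {name} must be positive, got {v}")
        for name in ("missing_fraction_send", "missing_fraction_recv", "sexonly_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.report_effect_sd < 0:
            raise ConfigError("report_effect_sd must be non-negative")
        if not self.base_flow > 0:
            raise ConfigError("base_flow must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated study: true flows, compositions and the
    generating parameter state."""

    dims: StudyDimensions
    m: np.ndarray  # (F, T, A, 2) true flows, persons/year
    pi: np.ndarray  # (F, T, A, 2) compositions, each (a, s) block sums to 1
    params: ParameterState

    def totals(self) -> np.ndarray:
        """Age- and sex-summed true flows, shape ``(F, T)``."""
        return self.m.sum(axis=(2, 3))

    def female_share(self) -> np.ndarray:
        """Share of females per (flow, year), in percent."""
        by_sex = self.m.sum(axis=2)  # (F, T, 2)
        return 100.0 * by_sex[:, :, 0] / by_sex.sum(axis=2)


# ---------------------------------------------------------------------------


def draw_hyperparameters(
    dims: StudyDimensions,
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> ParameterState:
    """Draw the hierarchical effects of one scenario.

    Global age and sex profiles come from the config if supplied, otherwise
    from standard normals; the identifiability constraints (youngest age
    group and females pinned at zero) hold exactly.  Country effects scatter
    around the global profiles with the configured precisions; the
    rest-of-world unit gets its own effects like any country.
    """
    cfg.validate()
    if rng is None:
        rng = _stage_rng(cfg.seed, _STAGE_HYPER)
    U, A = dims.n_units, dims.n_ages
    if cfg.age_profile is not None:
        age_effect = np.asarray(cfg.age_profile, dtype=float).copy()
        if age_effect.shape != (A,):
            raise ConfigError(f"age_profile must have length {A}")
    else:
        age_effect = rng.standard_normal(A)
    age_effect[0] = 0.0
    if cfg.sex_profile is not None:
        sex_effect = np.asarray(cfg.sex_profile, dtype=float).copy()
        if sex_effect.shape != (2,):
            raise ConfigError("sex_profile must have length 2")
    else:
        sex_effect = rng.standard_normal(2)
    sex_effect[0] = 0.0

    def around(mean: np.ndarray, tau: float, n: int) -> np.ndarray:
        return mean[None, :] + rng.standard_normal((n, mean.size)) / np.sqrt(tau)

    return ParameterState(
        age_effect=age_effect,
        sex_effect=sex_effect,
        dest_age=around(age_effect, cfg.tau_dest_age, U),
        dest_sex=around(sex_effect, cfg.tau_dest_sex, U),
        orig_age=around(age_effect, cfg.tau_orig_age, U),
        orig_sex=around(sex_effect, cfg.tau_orig_sex, U),
        tau_level=cfg.tau_level,
        tau_send=cfg.tau_send,
        tau_recv=cfg.tau_recv,
        tau_send_sexonly=cfg.tau_send_sexonly,
        tau_recv_sexonly=cfg.tau_recv_sexonly,
        tau_dest_age=cfg.tau_dest_age,
        tau_dest_sex=cfg.tau_dest_sex,
        tau_orig_age=cfg.tau_orig_age,
        tau_orig_sex=cfg.tau_orig_sex,
    )


def generate_true_flows(
    params: ParameterState,
    dims: StudyDimensions,
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticTruth:
    """Draw true flows from the multiplicative model.

    ``log m`` is normal around the four-effect predictor plus a base-level
    offset ``log(base_flow)`` (absorbed by the reporter interactions at fit
    time; it does not affect compositions), with the configured level
    precision.
    """
    cfg.validate()
    params.check()
    if rng is None:
        rng = _stage_rng(cfg.seed, _STAGE_FLOWS)
    from .model import predictor

    F, T, A = dims.n_flows, dims.n_years, dims.n_ages
    mean = predictor(params, dims) + np.log(cfg.base_flow)
    log_m = mean + rng.standard_normal((F, T, A, 2)) / np.sqrt(cfg.tau_level)
    return SyntheticTruth(
        dims=dims, m=np.exp(log_m), pi=pi_from_log_m(log_m), params=params
    )


def simulate_report_counts(
    m: np.ndarray,
    alpha: float,
    tau: float,
    rng: np.random.Generator,
    size: tuple[int, ...] | None = None,
) -> np.ndarray:
    """Low-level measurement chain for arbitrary true-flow cells: draw
    ``log nu ~ N(log m + alpha, tau)`` then Poisson counts.

    Used by the report generator and directly by distributional checks.
    """
    if tau <= 0:
        raise ConfigError("measurement precision must be positive")
    m = np.asarray(m, dtype=float)
    shape = m.shape if size is None else size
    log_nu = np.log(m) + alpha + rng.standard_normal(shape) / np.sqrt(tau)
    return rng.poisson(np.exp(log_nu))


def generate_reports(
    truth: SyntheticTruth,
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> ReportedFlowData:
    """Generate the double-reported, partially missing count tables.

    Per (flow, year, reporter): rest-of-world flows admit only their allowed
    side (sending for outflows to the aggregate, receiving for inflows from
    it); each admissible report is dropped with the side's missingness
    fraction; surviving reports are sex-only with probability
    ``sexonly_fraction`` and full age–sex otherwise, so at most one form is
    emitted per block.
    """
    cfg.validate()
    if rng is None:
        rng = _stage_rng(cfg.seed, _STAGE_REPORTS)
    d = truth.dims
    F, T = d.n_flows, d.n_years
    data = ReportedFlowData.empty(d)
    o_idx, d_idx = d.flow_arrays()
    allowed = np.ones((2, F, T), dtype=bool)
    if d.has_rest_of_world:
        allowed[SENDING, o_idx == 0, :] = False  # outflow from RoW: receiving only
        allowed[RECEIVING, d_idx == 0, :] = False  # inflow to RoW: sending only
    missing = np.array([cfg.missing_fraction_send, cfg.missing_fraction_recv])
    present = allowed & (rng.random((2, F, T)) >= missing[:, None, None])
    sexonly = present & (rng.random((2, F, T)) < cfg.sexonly_fraction)
    agesex = present & ~sexonly
    data.mask_agesex = agesex
    data.mask_sexonly = sexonly

    mean_shift = np.array([cfg.report_effect_mean_send, cfg.report_effect_mean_recv])
    alpha = (
        mean_shift[:, None, None]
        + cfg.report_effect_sd * rng.standard_normal((2, F, T))
    ) * present

    taus_as = np.array([cfg.tau_send, cfg.tau_recv])
    taus_sx = np.array([cfg.tau_send_sexonly, cfg.tau_recv_sexonly])
    m_sum_a = truth.m.sum(axis=2)  # (F, T, 2)
    for k in (SENDING, RECEIVING):
        blocks = np.where(agesex[k])
        if blocks[0].size:
            mb = truth.m[blocks]  # (n_blocks, A, 2)
            ab = alpha[k][blocks][:, None, None]
            log_nu = (
                np.log(mb) + ab
                + rng.standard_normal(mb.shape) / np.sqrt(taus_as[k])
            )
            data.z_agesex[(k,) + blocks] = rng.poisson(np.exp(log_nu))
        blocks1 = np.where(sexonly[k])
        if blocks1[0].size:
            mb1 = m_sum_a[blocks1]  # (n_blocks, 2)
            ab1 = alpha[k][blocks1][:, None]
            log_nu1 = (
                np.log(mb1) + ab1
                + rng.standard_normal(mb1.shape) / np.sqrt(taus_sx[k])
            )
            data.z_sexonly[(k,) + blocks1] = rng.poisson(np.exp(log_nu1))
    data.validate()
    return data


def generate_od_marginal_draws(
    truth: SyntheticTruth,
    n_draws: int,
    dispersion: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> ODMarginalDraws:
    """Stand-in posterior draws of the marginal origin–destination flows.

    Per (flow, year) the draws are centred on the log scale at the age- and
    sex-summed true flow, with log-scale variance ``dispersion``; zero
    dispersion replicates the exact totals.
    """
    if n_draws < 1:
        raise ConfigError("n_draws must be >= 1")
    if dispersion < 0:
        raise ConfigError("dispersion must be non-negative")
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    totals = truth.totals()  # (F, T)
    noise = (
        np.sqrt(dispersion) * rng.standard_normal((n_draws,) + totals.shape)
        if dispersion > 0
        else np.zeros((n_draws,) + totals.shape)
    )
    return ODMarginalDraws(dims=truth.dims, values=totals[None] * np.exp(noise))


def simulate_scenario(
    dims: StudyDimensions,
    cfg: ScenarioConfig,
    n_od_draws: int = 0,
    od_dispersion: float = 0.01,
) -> tuple[SyntheticTruth, ReportedFlowData, ODMarginalDraws | None]:
    """Full generator pipeline with per-stage substreams off the root seed."""
    params = draw_hyperparameters(dims, cfg, _stage_rng(cfg.seed, _STAGE_HYPER))
    truth = generate_true_flows(params, dims, cfg, _stage_rng(cfg.seed, _STAGE_FLOWS))
    data = generate_reports(truth, cfg, _stage_rng(cfg.seed, _STAGE_REPORTS))
    od = None
    if n_od_draws:
        od = generate_od_marginal_draws(
            truth, n_od_draws, od_dispersion, _stage_rng(cfg.seed, _STAGE_OD)
        )
    return truth, data, od
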