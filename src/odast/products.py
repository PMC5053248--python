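"""Posterior products: combined flow tables, goodness of fit, summaries.

Composition draws are combined with externally supplied posterior draws of
the marginal origin–destination flows (paired by draw index), yielding draws
of full origin–destination–age–sex–time tables whose age–sex sums reproduce
the marginals exactly.  Goodness of fit compares the common logarithm of each
observed non-zero proportion with the common logarithm of its
posterior-predictive mean, with a root-mean-square band; summary products are
female-share tables with credible intervals and age-profile quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ODMarginalDraws, ReportedFlowData
from .dims import RECEIVING, REPORTERS, SENDING, SEXES, StudyDimensions
from .errors import ConfigError, DataError, DiagnosticError, ModelAssemblyError
from .mcmc import PosteriorDraws

DIRECTION = {SENDING: "emigration", RECEIVING: "immigration"}


def _nanmean_quiet(arr: np.ndarray) -> np.ndarray:
    """nanmean over the draw axis without the all-NaN warning (unobserved
    blocks are legitimately all-NaN and stay NaN)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(arr, axis=0)


@dataclass
class CombinedFlowDraws:
    """Draws of full age–sex–specific flows (persons/year)."""

    dims: StudyDimensions
    values: np.ndarray  # (n_draws, F, T, A, 2)

    @property
    def n_draws(self) -> int:
        return self.values.shape[0]


@dataclass
class PredictiveProportions:
    """Posterior-predictive proportion draws, NaN where a block is unobserved
    or its simulated total was zero in that draw."""

    agesex: np.ndarray  # (n_draws, 2, F, T, A, 2)
    sexonly: np.ndarray  # (n_draws, 2, F, T, 2)

    def mean_agesex(self) -> np.ndarray:
        return _nanmean_quiet(self.agesex)

    def mean_sexonly(self) -> np.ndarray:
        return _nanmean_quiet(self.sexonly)


@dataclass
class GofReport:
    """Per-cell log10 differences between observed and predictive-mean
    proportions, with the root-mean-square band."""

    table: pd.DataFrame  # one row per observed non-zero cell
    rms: float

    @property
    def n_cells(self) -> int:
        return len(self.table)

    @property
    def n_beyond_band(self) -> int:
        return int(self.table["beyond_band"].sum())

    @property
    def frac_beyond_band(self) -> float:
        return self.n_beyond_band / self.n_cells if self.n_cells else 0.0

    def by_age(self) -> pd.DataFrame:
        """Boxplot-style summary of differences per age group and direction."""
        sub = self.table[self.table["form"] == "agesex"]
        return (
            sub.groupby(["direction", "age_group"])["difference"]
            .describe(percentiles=[0.25, 0.5, 0.75])
            .reset_index()
        )


# ---------------------------------------------------------------------------


def combine_with_od_marginals(
    pi_draws: PosteriorDraws, od_draws: ODMarginalDraws
) -> CombinedFlowDraws:
    """Scale composition draws by the paired marginal-flow draws.

    Draw ``i`` of the combined table is ``pi[i] * y[i]`` cellwise, so the
    age–sex sum of every (flow, year) block equals the marginal draw exactly.
    """
    if pi_draws.dims.units != od_draws.dims.units or pi_draws.dims.years != od_draws.dims.years:
        raise ModelAssemblyError("composition and marginal draws describe different systems")
    if pi_draws.n_draws != od_draws.n_draws:
        raise ModelAssemblyError(
            f"draw counts differ: {pi_draws.n_draws} compositions vs "
            f"{od_draws.n_draws} marginals (pairing is by draw index)"
        )
    values = pi_draws.pi * od_draws.values[:, :, :, None, None]
    return CombinedFlowDraws(dims=pi_draws.dims, values=values)


def posterior_predictive_proportions(
    draws: PosteriorDraws,
    data: ReportedFlowData,
    rng: np.random.Generator | None = None,
) -> PredictiveProportions:
    """Simulate reports out of the fitted measurement chain per retained draw.

    For every draw and observed block, draws log Poisson means around the
    draw's log true flow (age-summed for sex-only blocks) plus its reporter
    interaction with the draw's measurement precision, then Poisson counts,
    and forms the within-block proportions.  Blocks whose simulated total is
    zero are recorded as undefined (NaN) for that draw.
    """
    if draws.log_m is None or draws.report_effect is None:
        raise ConfigError(
            "posterior predictive simulation needs stored log_m and report_effect "
            "draws (configure store_m and store_report_effect)"
        )
    if rng is None:
        rng = np.random.default_rng()
    d = draws.dims
    n = draws.n_draws
    F, T, A = d.n_flows, d.n_years, d.n_ages
    out_as = np.full((n, 2, F, T, A, 2), np.nan)
    out_sx = np.full((n, 2, F, T, 2), np.nan)
    taus_as = np.stack([draws.scalars["tau_send"], draws.scalars["tau_recv"]], axis=1)
    taus_sx = np.stack(
        [draws.scalars["tau_send_sexonly"], draws.scalars["tau_recv_sexonly"]], axis=1
    )
    for i in range(n):
        log_m = draws.log_m[i]
        m_sum_a = np.exp(log_m).sum(axis=2)  # (F, T, 2)
        for k in (SENDING, RECEIVING):
            blocks = np.where(data.mask_agesex[k])
            if blocks[0].size:
                ref = log_m[blocks]  # (B, A, 2)
                alpha = draws.report_effect[i, k][blocks][:, None, None]
                log_nu = ref + alpha + rng.standard_normal(ref.shape) / np.sqrt(
                    taus_as[i, k]
                )
                z = rng.poisson(np.exp(np.minimum(log_nu, 700.0)))
                tot = z.sum(axis=(1, 2), keepdims=True)
                with np.errstate(invalid="ignore", divide="ignore"):
                    zeta = np.where(tot > 0, z / tot, np.nan)
                out_as[(i, k) + blocks] = zeta
            blocks1 = np.where(data.mask_sexonly[k])
            if blocks1[0].size:
                ref1 = np.log(m_sum_a[blocks1])  # (B, 2)
                alpha1 = draws.report_effect[i, k][blocks1][:, None]
                log_nu1 = ref1 + alpha1 + rng.standard_normal(ref1.shape) / np.sqrt(
                    taus_sx[i, k]
                )
                z1 = rng.poisson(np.exp(np.minimum(log_nu1, 700.0)))
                tot1 = z1.sum(axis=1, keepdims=True)
                with np.errstate(invalid="ignore", divide="ignore"):
                    zeta1 = np.where(tot1 > 0, z1 / tot1, np.nan)
                out_sx[(i, k) + blocks1] = zeta1
    return PredictiveProportions(agesex=out_as, sexonly=out_sx)


def gof_differences(
    data: ReportedFlowData,
    predictive: PredictiveProportions,
    base: float = 10.0,
) -> GofReport:
    """Per-cell differences ``log10(observed proportion) - log10(predictive
    mean proportion)`` over all observed non-zero cells, with the RMS band.

    A difference of 1 means the observed proportion is tenfold the predictive
    mean.  Zero observed counts are excluded; a non-positive predictive mean
    for an included cell is a diagnostic failure.  ``base`` defaults to the
    common (base-10) logarithm; natural log is available via ``base=np.e``.
    """
    d = data.dims
    labels = d.flow_labels()
    mean_as = predictive.mean_agesex()
    mean_sx = predictive.mean_sexonly()
    rows = []
    for k in (SENDING, RECEIVING):
        for f, t in zip(*np.where(data.mask_agesex[k])):
            z = data.z_agesex[k, f, t]  # (A, 2)
            tot = z.sum()
            if tot == 0:
                continue
            zeta = z / tot
            for a in range(d.n_ages):
                for s in range(2):
                    if z[a, s] == 0:
                        continue
                    pred = mean_as[k, f, t, a, s]
                    if not pred > 0:
                        raise DiagnosticError(
                            f"non-positive predictive mean for observed cell "
                            f"{labels[f]} year {d.years[t]} reporter {REPORTERS[k]}"
                        )
                    rows.append(
                        {
                            "origin": labels[f][0],
                            "destination": labels[f][1],
                            "year": d.years[t],
                            "reporter": REPORTERS[k],
                            "direction": DIRECTION[k],
                            "form": "agesex",
                            "age_group": a + 1,
                            "sex": SEXES[s],
                            "observed": zeta[a, s],
                            "predicted": pred,
                            "difference": (np.log(zeta[a, s]) - np.log(pred))
                            / np.log(base),
                        }
                    )
        for f, t in zip(*np.where(data.mask_sexonly[k])):
            z1 = data.z_sexonly[k, f, t]
            tot1 = z1.sum()
            if tot1 == 0:
                continue
            for s in range(2):
                if z1[s] == 0:
                    continue
                pred = mean_sx[k, f, t, s]
                if not pred > 0:
                    raise DiagnosticError(
                        f"non-positive predictive mean for observed sex-only cell "
                        f"{labels[f]} year {d.years[t]} reporter {REPORTERS[k]}"
                    )
                rows.append(
                    {
                        "origin": labels[f][0],
                        "destination": labels[f][1],
                        "year": d.years[t],
                        "reporter": REPORTERS[k],
                        "direction": DIRECTION[k],
                        "form": "sexonly",
                        "age_group": 0,  # 0 marks the pooled-age row
                        "sex": SEXES[s],
                        "observed": z1[s] / tot1,
                        "predicted": pred,
                        "difference": (np.log(z1[s] / tot1) - np.log(pred))
                        / np.log(base),
                    }
                )
    table = pd.DataFrame(rows)
    if len(table):
        rms = float(np.sqrt(np.mean(table["difference"] ** 2)))
        table["beyond_band"] = table["difference"].abs() > 3.0 * rms
    else:
        rms = 0.0
        table["beyond_band"] = pd.Series(dtype=bool)
    return GofReport(table=table, rms=rms)


# ---------------------------------------------------------------------------
# Summary tables
# ---------------------------------------------------------------------------


def _period_label(years: tuple[int, ...]) -> str:
    years = tuple(sorted(years))
    return f"{years[0]}" if len(years) == 1 else f"{years[0]}-{years[-1]}"


def female_share_summary(
    flows: "CombinedFlowDraws | ReportedFlowData",
    periods: list[tuple[int, ...]] | None = None,
    interval: float = 0.95,
    flow_weighted: bool = True,
) -> pd.DataFrame:
    """Percentage of females in total emigration and immigration per country.

    Given combined flow draws, returns posterior means with central credible
    intervals; given a reported-flow table, returns point percentages from
    each country's own reports (sending reports for emigration, receiving for
    immigration), blank where a country reported nothing.  Periods are sets
    of years; by default one period per study year.  ``flow_weighted`` sums
    flows over the years of a period before taking shares; the alternative
    averages the annual percentages.
    """
    dims = flows.dims
    if periods is None:
        periods = [(y,) for y in dims.years]
    for p in periods:
        if not p:
            raise ConfigError("empty period")
    t_idx = [[dims.year_index(y) for y in p] for p in periods]
    o_idx, d_idx = dims.flow_arrays()
    rows = []
    if isinstance(flows, CombinedFlowDraws):
        lo, hi = 50.0 * (1.0 - interval), 50.0 * (1.0 + interval)
        # per draw: females / total per (unit, direction, period)
        by_sex = flows.values.sum(axis=3)  # (n, F, T, 2)
        for u, unit in enumerate(dims.units):
            for direction, sel in (("emigration", o_idx == u), ("immigration", d_idx == u)):
                for p, ts in zip(periods, t_idx):
                    block = by_sex[:, sel][:, :, ts]  # (n, nf, nt, 2)
                    if flow_weighted:
                        tot = block.sum(axis=(1, 2))  # (n, 2)
                        share = 100.0 * tot[:, 0] / tot.sum(axis=1)
                    else:
                        annual = block.sum(axis=1)  # (n, nt, 2)
                        share = (
                            100.0 * annual[:, :, 0] / annual.sum(axis=2)
                        ).mean(axis=1)
                    rows.append(
                        {
                            "country": unit,
                            "direction": direction,
                            "period": _period_label(p),
                            "mean": float(share.mean()),
                            "lower": float(np.percentile(share, lo)),
                            "upper": float(np.percentile(share, hi)),
                        }
                    )
        return pd.DataFrame(rows)

    data: ReportedFlowData = flows
    k_for = {"emigration": SENDING, "immigration": RECEIVING}
    for u, unit in enumerate(dims.units):
        for direction, sel in (("emigration", o_idx == u), ("immigration", d_idx == u)):
            k = k_for[direction]
            for p, ts in zip(periods, t_idx):
                by_sex = np.zeros(2)
                for t in ts:
                    present = data.mask_agesex[k, sel, t]
                    by_sex += data.z_agesex[k, sel, t][present].sum(axis=(0, 1))
                    present1 = data.mask_sexonly[k, sel, t]
                    by_sex += data.z_sexonly[k, sel, t][present1].sum(axis=0)
                total = by_sex.sum()
                rows.append(
                    {
                        "country": unit,
                        "direction": direction,
                        "period": _period_label(p),
                        "share": 100.0 * by_sex[0] / total if total > 0 else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def age_profile_summary(
    flows: CombinedFlowDraws,
    quantiles: tuple[float, ...] = (0.1, 0.5, 0.9),
) -> pd.DataFrame:
    """Quantiles of the flow draws per origin, destination, year, sex and age.

    The default decile–median–decile set matches the usual presentation of
    estimated migration age schedules with 80% predictive bands.
    """
    for q in quantiles:
        if not 0.0 < q < 1.0:
            raise ConfigError(f"quantile {q} outside (0, 1)")
    dims = flows.dims
    qs = np.quantile(flows.values, quantiles, axis=0)  # (Q, F, T, A, 2)
    labels = dims.flow_labels()
    records = []
    for f, (o, dst) in enumerate(labels):
        for t, year in enumerate(dims.years):
            for s, sex in enumerate(SEXES):
                for a in range(dims.n_ages):
                    rec = {
                        "origin": o,
                        "destination": dst,
                        "year": year,
                        "sex": sex,
                        "age_group": a + 1,
                    }
                    for qi, q in enumerate(quantiles):
                        rec[f"q{q:g}"] = float(qs[qi, f, t, a, s])
                    records.append(rec)
    return pd.DataFrame(records)


def plot_gof(report: GofReport, path: str) -> None:
    """Boxplots of GOF differences by age group for each direction, with the
    ±3 RMS band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = report.table[report.table["form"] == "agesex"]
    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharey=True)
    for ax, direction in zip(axes, ("emigration", "immigration")):
        part = sub[sub["direction"] == direction]
        groups = sorted(part["age_group"].unique())
        ax.boxplot(
            [part[part["age_group"] == g]["difference"].to_numpy() for g in groups],
            tick_labels=[str(g) for g in groups],
        )
        band = 3.0 * report.rms
        ax.axhline(band, linestyle=":", color="k")
        ax.axhline(-band, linestyle=":", color="k")
        ax.axhline(0.0, linewidth=0.5, color="grey")
        ax.set_title(direction)
        ax.set_xlabel("age group")
    axes[0].set_ylabel("log10 observed - log10 predictive mean")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_age_profiles(
    flows: CombinedFlowDraws,
    origin: str,
    destination: str,
    year: int,
    path: str,
    quantiles: tuple[float, float, float] = (0.1, 0.5, 0.9),
) -> None:
    """Median age profile with a predictive band for one flow, by sex."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dims = flows.dims
    f = dims.flow_index(origin, destination)
    t = dims.year_index(year)
    qs = np.quantile(flows.values[:, f, t], quantiles, axis=0)  # (3, A, 2)
    ages = np.arange(1, dims.n_ages + 1)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for s, (ax, sex) in enumerate(zip(axes, ("females", "males"))):
        ax.fill_between(ages, qs[0, :, s], qs[2, :, s], alpha=0.3)
        ax.plot(ages, qs[1, :, s], marker="o", markersize=3)
        ax.set_title(f"{origin} to {destination}, {year}: {sex}")
        ax.set_xlabel("age group")
    axes[0].set_ylabel("migrants/year")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
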