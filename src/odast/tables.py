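"""Reading, validating and writing the long-format tables, and the
preprocessing that turns raw report rows into model-ready data.

All count tables share one schema::

    origin, destination, year, reporter, age_group, sex, count

with ``reporter`` in {S, R}, ``sex`` in {F, M}, ``age_group`` in 1..A or ALL
(ALL marks a sex-only row), and ``origin``/``destination`` either a study
unit code or the UNKNOWN placeholder before preprocessing.  Writers prepend a
``#`` comment carrying the generating seed and a config hash; readers skip
comment lines.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ODMarginalDraws, ReportedFlowData
from .dims import RECEIVING, REPORTERS, SENDING, SEXES, StudyDimensions
from .errors import DataError

log = logging.getLogger("odast")

REPORT_COLUMNS = ["origin", "destination", "year", "reporter", "age_group", "sex", "count"]
UNKNOWN = "UNKNOWN"
ALL_AGES = "ALL"


@dataclass
class RawReportTable:
    """Validated long-format report rows plus a small schema report."""

    frame: pd.DataFrame

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def levels(self) -> dict[str, list]:
        return {
            col: sorted(self.frame[col].unique().tolist())
            for col in ("origin", "destination", "year", "reporter", "age_group", "sex")
        }

    def grand_totals(self) -> pd.Series:
        """Total count per (reporter, year) — the quantity preprocessing must
        conserve."""
        if not len(self.frame):
            return pd.Series(dtype=np.int64)
        return self.frame.groupby(["reporter", "year"])["count"].sum()


def _validate_frame(df: pd.DataFrame, allow_unknown: bool = True) -> pd.DataFrame:
    missing = set(REPORT_COLUMNS) - set(df.columns)
    extra = set(df.columns) - set(REPORT_COLUMNS)
    if missing or extra:
        raise DataError(
            f"bad header: missing columns {sorted(missing)}, unknown columns {sorted(extra)}"
        )
    df = df[REPORT_COLUMNS].copy()
    for col in ("origin", "destination", "reporter", "age_group", "sex"):
        df[col] = df[col].astype(str).str.strip()

    def bad_rows(mask: pd.Series, what: str) -> None:
        if mask.any():
            row = int(df.index[mask][0]) + 2  # 1-based, counting the header line
            raise DataError(f"{what} at data row {row} (and {int(mask.sum()) - 1} more)")

    year = pd.to_numeric(df["year"], errors="coerce")
    bad_rows(year.isna(), "malformed year")
    df["year"] = year.astype(int)
    count = pd.to_numeric(df["count"], errors="coerce")
    bad_rows(count.isna() | (count != count.round()), "malformed count")
    bad_rows(count < 0, "negative count")
    df["count"] = count.astype(np.int64)
    bad_rows(~df["reporter"].isin(REPORTERS), "reporter must be S or R")
    bad_rows(~df["sex"].isin(SEXES), "sex must be F or M")
    age_ok = (df["age_group"] == ALL_AGES) | df["age_group"].str.fullmatch(r"\d+")
    bad_rows(~age_ok, "age_group must be a positive integer or ALL")
    if not allow_unknown:
        bad_rows(
            (df["origin"] == UNKNOWN) | (df["destination"] == UNKNOWN),
            "UNKNOWN origin/destination not allowed here",
        )
    return df


def read_reported_flows(path) -> RawReportTable:
    """Read and validate a long-format report table; errors name the first
    offending data row."""
    df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    return RawReportTable(frame=_validate_frame(df))


def _header_comment(seed=None, config_hash=None) -> str:
    parts = ["# odast"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config_hash={config_hash}")
    return " ".join(parts)


def config_hash(obj) -> str:
    """Short stable hash of any YAML-serializable configuration object."""
    import yaml

    text = yaml.safe_dump(obj, sort_keys=True, default_flow_style=True)
    return hashlib.sha1(text.encode()).hexdigest()[:12]


def write_frame(df: pd.DataFrame, path, seed=None, config_hash_=None) -> None:
    """Write a tidy CSV with the provenance comment line."""
    with open(path, "w") as fh:
        fh.write(_header_comment(seed, config_hash_) + "\n")
        df.to_csv(fh, index=False)


def write_reported_flows(table: "RawReportTable | ReportedFlowData", path,
                         seed=None, config_hash_=None) -> None:
    df = table.frame if isinstance(table, RawReportTable) else reported_data_to_frame(table)
    write_frame(df, path, seed, config_hash_)


# ---------------------------------------------------------------------------
# Array <-> frame conversion
# ---------------------------------------------------------------------------


def reported_data_to_frame(data: ReportedFlowData) -> pd.DataFrame:
    """Long rows for every observed block (all cells of a present block,
    including its zero cells)."""
    d = data.dims
    labels = d.flow_labels()
    rows = []
    for k in (SENDING, RECEIVING):
        for f, t in zip(*np.where(data.mask_agesex[k])):
            o, dst = labels[f]
            for a in range(d.n_ages):
                for s in range(2):
                    rows.append(
                        (o, dst, d.years[t], REPORTERS[k], str(a + 1), SEXES[s],
                         int(data.z_agesex[k, f, t, a, s]))
                    )
        for f, t in zip(*np.where(data.mask_sexonly[k])):
            o, dst = labels[f]
            for s in range(2):
                rows.append(
                    (o, dst, d.years[t], REPORTERS[k], ALL_AGES, SEXES[s],
                     int(data.z_sexonly[k, f, t, s]))
                )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def truth_to_frame(m: np.ndarray, dims: StudyDimensions, value_col: str = "value") -> pd.DataFrame:
    """Long rows for a dense (F, T, A, 2) array of true flows or compositions."""
    F, T, A, S = m.shape
    labels = dims.flow_labels()
    o = np.repeat([lab[0] for lab in labels], T * A * S)
    dst = np.repeat([lab[1] for lab in labels], T * A * S)
    years = np.tile(np.repeat(dims.years, A * S), F)
    ages = np.tile(np.repeat(np.arange(1, A + 1), S), F * T)
    sexes = np.tile(list(SEXES), F * T * A)
    return pd.DataFrame(
        {
            "origin": o,
            "destination": dst,
            "year": years,
            "age_group": ages,
            "sex": sexes,
            value_col: m.ravel(),
        }
    )


def write_od_marginal_draws(draws: ODMarginalDraws, path, seed=None) -> None:
    d = draws.dims
    labels = d.flow_labels()
    n, F, T = draws.values.shape
    df = pd.DataFrame(
        {
            "origin": np.tile(np.repeat([lab[0] for lab in labels], T), n),
            "destination": np.tile(np.repeat([lab[1] for lab in labels], T), n),
            "year": np.tile(np.tile(d.years, F), n),
            "draw_index": np.repeat(np.arange(n), F * T),
            "value": draws.values.ravel(),
        }
    )
    write_frame(df, path, seed)


def read_od_marginal_draws(path, dims: StudyDimensions) -> ODMarginalDraws:
    df = pd.read_csv(path, comment="#")
    needed = {"origin", "destination", "year", "draw_index", "value"}
    if set(df.columns) != needed:
        raise DataError(f"marginal draws need columns {sorted(needed)}")
    n = int(df["draw_index"].max()) + 1
    values = np.full((n, dims.n_flows, dims.n_years), np.nan)
    f_idx = [dims.flow_index(o, dst) for o, dst in zip(df["origin"], df["destination"])]
    t_idx = [dims.year_index(y) for y in df["year"]]
    values[df["draw_index"].to_numpy(), f_idx, t_idx] = df["value"].to_numpy()
    if np.isnan(values).any():
        raise DataError("marginal draws do not cover the full flow-year-draw grid")
    return ODMarginalDraws(dims=dims, values=values)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights`` that sums
    exactly to ``total``; ties in the fractional remainders break towards the
    earlier level."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise DataError("cannot allocate proportionally to all-zero weights")
    ideal = total * w / w.sum()
    base = np.floor(ideal).astype(np.int64)
    short = int(total - base.sum())
    if short:
        frac = ideal - base
        order = np.lexsort((np.arange(w.size), -frac))
        base[order[:short]] += 1
    return base


def _allocate(row: pd.Series, pattern: pd.Series, fill_cols: list[str]) -> pd.DataFrame:
    """Split one unknown row across the levels of an observed pattern."""
    alloc = largest_remainder(int(row["count"]), pattern.to_numpy())
    out = pd.DataFrame([row[REPORT_COLUMNS]] * len(pattern))
    levels = pattern.index.to_frame(index=False)
    for col in fill_cols:
        out[col] = levels[col].to_numpy()
    out["count"] = alloc
    return out[out["count"] > 0]


def redistribute_unknowns(table: RawReportTable) -> RawReportTable:
    """Proportion rows with UNKNOWN origin or destination across the observed
    patterns of the matching stratum.

    The stratum conditions on (reporter, year, known margin, age_group, sex);
    when no counterpart exists the allocation falls back to the
    (reporter, year) marginal pattern with a logged warning.  Counts remain
    integer via largest-remainder rounding, so per-(reporter, year) totals
    are conserved exactly.
    """
    df = table.frame
    known_mask = (df["origin"] != UNKNOWN) & (df["destination"] != UNKNOWN)
    if known_mask.all():
        return RawReportTable(frame=df.copy())
    known = df[known_mask]
    pieces = [known]
    jobs = (
        # (selector of unknown rows, unknown margin, stratum columns)
        ((df["destination"] == UNKNOWN) & (df["origin"] != UNKNOWN),
         ["destination"], ["reporter", "year", "origin", "age_group", "sex"]),
        ((df["origin"] == UNKNOWN) & (df["destination"] != UNKNOWN),
         ["origin"], ["reporter", "year", "destination", "age_group", "sex"]),
        ((df["origin"] == UNKNOWN) & (df["destination"] == UNKNOWN),
         ["origin", "destination"], ["reporter", "year", "age_group", "sex"]),
    )
    for selector, fill_cols, stratum_cols in jobs:
        for _, row in df[selector].iterrows():
            if row["count"] == 0:
                continue
            stratum = known
            for col in stratum_cols:
                stratum = stratum[stratum[col] == row[col]]
            pattern = stratum.groupby(fill_cols)["count"].sum()
            pattern = pattern[pattern > 0].sort_index()
            if not len(pattern):
                # fall back to the (reporter, year) marginal pattern
                marginal = known[
                    (known["reporter"] == row["reporter"]) & (known["year"] == row["year"])
                ]
                pattern = marginal.groupby(fill_cols)["count"].sum()
                pattern = pattern[pattern > 0].sort_index()
                if not len(pattern):
                    log.warning(
                        "dropping unknown-%s row (count %d): no observed pattern for "
                        "reporter %s year %s", "/".join(fill_cols), row["count"],
                        row["reporter"], row["year"],
                    )
                    continue
                log.warning(
                    "unknown-%s row allocated from the (reporter, year) marginal "
                    "pattern (no matching stratum)", "/".join(fill_cols),
                )
            pieces.append(_allocate(row, pattern, fill_cols))
    out = pd.concat(pieces, ignore_index=True)
    out = (
        out.groupby(REPORT_COLUMNS[:-1], as_index=False, sort=False)["count"]
        .sum()
        .reset_index(drop=True)
    )
    return RawReportTable(frame=out)


def assemble_model_data(table: RawReportTable, dims: StudyDimensions) -> ReportedFlowData:
    """Turn validated rows into masked count arrays.

    Applies the single-use rule (a sex-only block is discarded when the same
    (origin, destination, year, reporter) also reported full age–sex detail)
    and drops rows on the disallowed side of a rest-of-world flow, each with
    a logged notice.  Duplicate rows for the same cell are summed.
    """
    df = _validate_frame(table.frame, allow_unknown=False)
    data = ReportedFlowData.empty(dims)
    if not len(df):
        return data
    try:
        f_idx = np.array(
            [dims.flow_index(o, d) for o, d in zip(df["origin"], df["destination"])]
        )
        t_idx = np.array([dims.year_index(y) for y in df["year"]])
    except Exception as exc:
        raise DataError(str(exc)) from exc
    k_idx = np.array([REPORTERS.index(r) for r in df["reporter"]])
    s_idx = np.array([SEXES.index(s) for s in df["sex"]])
    is_all = (df["age_group"] == ALL_AGES).to_numpy()
    a_idx = np.where(is_all, 0, pd.to_numeric(df["age_group"].where(~is_all, "1"))).astype(int)
    if ((a_idx < 1) | (a_idx > dims.n_ages))[~is_all].any():
        bad = df["age_group"][~is_all & ((a_idx < 1) | (a_idx > dims.n_ages))].iloc[0]
        raise DataError(f"age_group {bad} outside 1..{dims.n_ages}")

    if dims.has_rest_of_world:
        o_arr, d_arr = dims.flow_arrays()
        disallowed = ((o_arr[f_idx] == 0) & (k_idx == SENDING)) | (
            (d_arr[f_idx] == 0) & (k_idx == RECEIVING)
        )
        if disallowed.any():
            log.warning(
                "dropping %d row(s) on the disallowed side of a rest-of-world flow",
                int(disallowed.sum()),
            )
            keep = ~disallowed
            df, f_idx, t_idx, k_idx, s_idx, a_idx, is_all = (
                df[keep], f_idx[keep], t_idx[keep], k_idx[keep], s_idx[keep],
                a_idx[keep], is_all[keep],
            )

    counts = df["count"].to_numpy()
    full = ~is_all
    np.add.at(data.z_agesex, (k_idx[full], f_idx[full], t_idx[full],
                              a_idx[full] - 1, s_idx[full]), counts[full])
    data.mask_agesex[k_idx[full], f_idx[full], t_idx[full]] = True
    np.add.at(data.z_sexonly, (k_idx[is_all], f_idx[is_all], t_idx[is_all],
                               s_idx[is_all]), counts[is_all])
    data.mask_sexonly[k_idx[is_all], f_idx[is_all], t_idx[is_all]] = True

    both = data.mask_agesex & data.mask_sexonly
    if both.any():
        log.info(
            "discarding %d sex-only block(s) where full age-sex detail exists "
            "(reports are not used twice)", int(both.sum()),
        )
        data.mask_sexonly[both] = False
        data.z_sexonly[both] = 0
    data.validate()
    return data


# ---------------------------------------------------------------------------
# Posterior draw storage (text files + structured provenance sidecar)
# ---------------------------------------------------------------------------


def _draws_long_frame(values: np.ndarray, dims: StudyDimensions) -> pd.DataFrame:
    """(n, F, T, A, 2) draw array as long rows keyed by draw index."""
    n, F, T, A, S = values.shape
    labels = dims.flow_labels()
    block = F * T * A * S
    return pd.DataFrame(
        {
            "draw": np.repeat(np.arange(n), block),
            "origin": np.tile(np.repeat([lab[0] for lab in labels], T * A * S), n),
            "destination": np.tile(np.repeat([lab[1] for lab in labels], T * A * S), n),
            "year": np.tile(np.tile(np.repeat(dims.years, A * S), F), n),
            "age_group": np.tile(np.tile(np.repeat(np.arange(1, A + 1), S), F * T), n),
            "sex": np.tile(list(SEXES), n * F * T * A),
            "value": values.ravel(),
        }
    )


def write_posterior_draws(draws, outdir, config_obj=None) -> None:
    """Persist retained draws as CSV files plus a provenance sidecar.

    Writes ``pi.csv`` (composition draws), ``scalars.csv`` (precisions and
    global profile elements, one row per draw), optionally ``log_m.csv`` and
    ``report_effect.csv``, and ``provenance.yaml`` (dimensions, config echo,
    seed).
    """
    import os

    import yaml

    os.makedirs(outdir, exist_ok=True)
    d = draws.dims
    chash = config_hash(config_obj) if config_obj is not None else None
    write_frame(_draws_long_frame(draws.pi, d), os.path.join(outdir, "pi.csv"),
                seed=draws.seed, config_hash_=chash)
    scalars = pd.DataFrame({"draw": np.arange(draws.n_draws)})
    for name, series in draws.scalars.items():
        scalars[name] = series
    for i in range(draws.age_effect.shape[1]):
        scalars[f"age_effect_{i}"] = draws.age_effect[:, i]
    for i in range(2):
        scalars[f"sex_effect_{i}"] = draws.sex_effect[:, i]
    write_frame(scalars, os.path.join(outdir, "scalars.csv"), seed=draws.seed,
                config_hash_=chash)
    if draws.log_m is not None:
        write_frame(_draws_long_frame(draws.log_m, d), os.path.join(outdir, "log_m.csv"),
                    seed=draws.seed, config_hash_=chash)
    if draws.report_effect is not None:
        n, K, F, T = draws.report_effect.shape
        labels = d.flow_labels()
        rep = pd.DataFrame(
            {
                "draw": np.repeat(np.arange(n), K * F * T),
                "reporter": np.tile(np.repeat(list(REPORTERS), F * T), n),
                "origin": np.tile(np.repeat([lab[0] for lab in labels], T), n * K),
                "destination": np.tile(np.repeat([lab[1] for lab in labels], T), n * K),
                "year": np.tile(np.tile(d.years, F), n * K),
                "value": draws.report_effect.ravel(),
            }
        )
        write_frame(rep, os.path.join(outdir, "report_effect.csv"), seed=draws.seed,
                    config_hash_=chash)
    mask_rows = []
    for k, f, t in zip(*np.where(draws.report_mask)):
        o, dst = d.flow_labels()[f]
        mask_rows.append({"reporter": REPORTERS[k], "origin": o, "destination": dst,
                          "year": int(d.years[t])})
    from dataclasses import asdict

    provenance = {
        "dims": {
            "countries": list(d.countries),
            "n_ages": d.n_ages,
            "years": list(d.years),
            "rest_of_world": d.rest_of_world,
            "has_rest_of_world": d.has_rest_of_world,
        },
        "config": asdict(draws.config),
        "seed": int(draws.seed),
        "n_draws": int(draws.n_draws),
        "report_blocks": mask_rows,
    }
    with open(os.path.join(outdir, "provenance.yaml"), "w") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=True)


def read_posterior_draws(outdir):
    """Reload draws written by :func:`write_posterior_draws`."""
    import os

    import yaml

    from .mcmc import McmcConfig, PosteriorDraws

    with open(os.path.join(outdir, "provenance.yaml")) as fh:
        prov = yaml.safe_load(fh)
    dd = prov["dims"]
    dims = StudyDimensions(
        countries=tuple(dd["countries"]), n_ages=int(dd["n_ages"]),
        years=tuple(dd["years"]), rest_of_world=dd["rest_of_world"],
        has_rest_of_world=bool(dd["has_rest_of_world"]),
    )
    n = int(prov["n_draws"])
    F, T, A = dims.n_flows, dims.n_years, dims.n_ages

    def dense(fname):
        path = os.path.join(outdir, fname)
        if not os.path.exists(path):
            return None
        df = pd.read_csv(path, comment="#")
        return df["value"].to_numpy().reshape(n, F, T, A, 2)

    pi = dense("pi.csv")
    log_m = dense("log_m.csv")
    scalars_df = pd.read_csv(os.path.join(outdir, "scalars.csv"), comment="#")
    from .model import PRECISION_NAMES

    scalars = {name: scalars_df[name].to_numpy() for name in PRECISION_NAMES}
    age_cols = sorted(
        (c for c in scalars_df.columns if c.startswith("age_effect_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    age_effect = scalars_df[age_cols].to_numpy()
    sex_effect = scalars_df[["sex_effect_0", "sex_effect_1"]].to_numpy()
    rep_path = os.path.join(outdir, "report_effect.csv")
    report_effect = None
    if os.path.exists(rep_path):
        rep = pd.read_csv(rep_path, comment="#")
        report_effect = rep["value"].to_numpy().reshape(n, 2, F, T)
    report_mask = np.zeros((2, F, T), dtype=bool)
    for row in prov.get("report_blocks", []):
        report_mask[
            REPORTERS.index(row["reporter"]),
            dims.flow_index(row["origin"], row["destination"]),
            dims.year_index(row["year"]),
        ] = True
    return PosteriorDraws(
        dims=dims, pi=pi, age_effect=age_effect, sex_effect=sex_effect,
        scalars=scalars, report_mask=report_mask,
        config=McmcConfig(**prov["config"]), seed=int(prov["seed"]),
        log_m=log_m, report_effect=report_effect,
    )
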