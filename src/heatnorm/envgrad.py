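"""Environmental gradients: daily heat indices, critical-period averages,
phenotype QC and the Legendre gradient basis.

Daily weather records (one row per farm-day with tmax/tmin/tmean/dewp/rh)
are turned into seven candidate environmental variables (ENVs):

* ``MeanT``, ``MaxT``, ``MinT``, ``DewP``, ``RH`` pass through,
* ``DI`` is Thom's discomfort index (Celsius form),
  ``DI = T - 0.55*(1 - 0.01*RH)*(T - 14.5)``,
* ``THI`` is the NRC-1971 temperature-humidity index (Fahrenheit form),
  ``THI = Tf - (0.55 - 0.0055*RH)*(Tf - 58)``.

Each phenotype record then receives, per ENV, the arithmetic mean of the
daily values inside a trait-specific critical period anchored on event
dates (measurement, breeding, farrowing, weaning).  The covariate is
standardized to [-1, 1] over its observed range and expanded in normalized
first-order Legendre polynomials phi0 = sqrt(1/2), phi1(x) = sqrt(3/2)*x.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENV_NAMES = ("MeanT", "MaxT", "MinT", "DewP", "RH", "DI", "THI")

ANCHOR_EVENTS = ("measurement", "breeding", "farrowing", "weaning")

PHI0 = np.sqrt(0.5)
PHI1_SLOPE = np.sqrt(1.5)

__all__ = [
    "ENV_NAMES",
    "ANCHOR_EVENTS",
    "PHI0",
    "PHI1_SLOPE",
    "compute_daily_env",
    "daily_env_table",
    "CriticalPeriodSpec",
    "window_average",
    "qc_phenotypes",
    "PhenotypeQCReport",
    "GradientBasis",
    "build_gradient",
]


def compute_daily_env(tmean, tmax, tmin, dewp, rh) -> dict:
    """Map one day's weather (scalars or arrays) to the seven ENVs.

    Raises ``ValueError`` when relative humidity leaves [0, 100].
    """
    tmean = np.asarray(tmean, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any(rh < 0.0) or np.any(rh > 100.0):
        raise ValueError("relative humidity outside [0, 100]")
    di = tmean - 0.55 * (1.0 - 0.01 * rh) * (tmean - 14.5)
    tf = tmean * 9.0 / 5.0 + 32.0
    thi = tf - (0.55 - 0.0055 * rh) * (tf - 58.0)
    return {
        "MeanT": tmean,
        "MaxT": np.asarray(tmax, dtype=float),
        "MinT": np.asarray(tmin, dtype=float),
        "DewP": np.asarray(dewp, dtype=float),
        "RH": rh,
        "DI": di,
        "THI": thi,
    }


def daily_env_table(weather: pd.DataFrame) -> pd.DataFrame:
    """ENV values for every farm-day of a weather table.

    Expects columns ``farm, date, tmax, tmin, tmean, dewp, rh``; validates
    the ordering invariant tmin <= tmean <= tmax.
    """
    if np.any(weather["tmin"].to_numpy() > weather["tmean"].to_numpy()) or np.any(
        weather["tmean"].to_numpy() > weather["tmax"].to_numpy()
    ):
        raise ValueError("weather violates tmin <= tmean <= tmax")
    env = compute_daily_env(
        weather["tmean"], weather["tmax"], weather["tmin"], weather["dewp"], weather["rh"]
    )
    out = weather[["farm", "date"]].copy()
    for name in ENV_NAMES:
        out[name] = np.asarray(env[name])
    return out


# ---------------------------------------------------------------------------
# critical periods

@dataclass(frozen=True)
class CriticalPeriodSpec:
    """A calendar window anchored on one or two reproductive/growth events.

    Offsets are in days and the resolved window is inclusive of both
    endpoints; e.g. the 30 days before measurement are
    ``start=("measurement", -30), end=("measurement", -1)`` -- the event day
    itself is excluded by convention.
    """

    trait: str
    start_anchor: str
    start_offset: int
    end_anchor: str
    end_offset: int

    def __post_init__(self):
        for anchor in (self.start_anchor, self.end_anchor):
            if anchor not in ANCHOR_EVENTS:
                raise ValueError(f"unknown anchor event {anchor!r}; expected one of {ANCHOR_EVENTS}")

    def resolve(self, events: pd.Series) -> tuple[pd.Timestamp, pd.Timestamp]:
        start = pd.Timestamp(events[self.start_anchor]) + pd.Timedelta(days=self.start_offset)
        end = pd.Timestamp(events[self.end_anchor]) + pd.Timedelta(days=self.end_offset)
        if start > end:
            raise ValueError(f"critical period for {self.trait!r} resolves to start > end")
        return start, end


def window_average(
    weather: pd.DataFrame,
    records: pd.DataFrame,
    period: CriticalPeriodSpec,
    envs: tuple[str, ...] = ENV_NAMES,
    min_coverage: float = 0.8,
) -> pd.DataFrame:
    """Average daily ENVs over each record's critical period.

    ``records`` must carry ``record_id``, ``farm`` and the anchor date
    columns the period refers to.  Records whose farm has no weather, or
    whose window coverage (fraction of days with weather) falls below
    ``min_coverage``, are dropped with a logged count.  Returns a long table
    ``record_id, env, value, coverage``.
    """
    env_tab = daily_env_table(weather)
    by_farm: dict = {}
    for farm, grp in env_tab.groupby("farm"):
        grp = grp.sort_values("date")
        dates = grp["date"].to_numpy(dtype="datetime64[D]")
        by_farm[farm] = (dates, grp[list(envs)].to_numpy())

    rows = []
    n_no_farm = 0
    n_low_coverage = 0
    for rec in records.itertuples(index=False):
        rec = rec._asdict()
        start, end = period.resolve(pd.Series(rec))
        n_days = (end - start).days + 1
        farm = rec["farm"]
        if farm not in by_farm:
            n_no_farm += 1
            continue
        dates, values = by_farm[farm]
        lo = np.searchsorted(dates, np.datetime64(start, "D"))
        hi = np.searchsorted(dates, np.datetime64(end, "D"), side="right")
        window = values[lo:hi]
        coverage = len(window) / n_days
        if coverage < min_coverage:
            n_low_coverage += 1
            continue
        means = window.mean(axis=0)
        for j, env in enumerate(envs):
            rows.append((rec["record_id"], env, means[j], coverage))
    if n_no_farm or n_low_coverage:
        logger.warning(
            "window_average dropped %d records without farm weather and %d below %.0f%% coverage",
            n_no_farm, n_low_coverage, 100 * min_coverage,
        )
    out = pd.DataFrame(rows, columns=["record_id", "env", "value", "coverage"])
    out.attrs["n_dropped_no_weather"] = n_no_farm
    out.attrs["n_dropped_low_coverage"] = n_low_coverage
    return out


# ---------------------------------------------------------------------------
# phenotype QC

@dataclass
class PhenotypeQCReport:
    n_in: int = 0
    n_outliers: int = 0
    n_small_cg_records: int = 0
    n_small_cg_groups: int = 0
    n_out: int = 0


def qc_phenotypes(
    pheno: pd.DataFrame,
    value_col: str = "value",
    cg_col: str = "cg",
    trait_col: str | None = None,
    sd_limit: float = 3.5,
    min_cg_size: int = 10,
) -> tuple[pd.DataFrame, PhenotypeQCReport]:
    """Edit phenotypes: drop +-``sd_limit`` SD outliers, then small CGs.

    The outlier filter is a single pass per trait with the n-1 SD; a zero SD
    removes nothing.  Contemporary groups with fewer than ``min_cg_size``
    remaining records are then discarded.  Raises if nothing survives.
    """
    rep = PhenotypeQCReport(n_in=len(pheno))
    df = pheno.copy()
    groups = df.groupby(trait_col)[value_col] if trait_col else [(None, df[value_col])]
    keep = pd.Series(True, index=df.index)
    for _, vals in groups:
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            continue
        z = (vals - vals.mean()).abs() / sd
        keep.loc[vals.index[z > sd_limit]] = False
    rep.n_outliers = int((~keep).sum())
    df = df[keep]

    cg_keys = [trait_col, cg_col] if trait_col else [cg_col]
    sizes = df.groupby(cg_keys)[value_col].transform("size")
    small = sizes < min_cg_size
    rep.n_small_cg_records = int(small.sum())
    rep.n_small_cg_groups = int(df.loc[small].groupby(cg_keys).ngroups)
    df = df[~small]
    rep.n_out = len(df)
    if df.empty:
        raise ValueError("phenotype QC removed every record")
    if rep.n_outliers or rep.n_small_cg_records:
        logger.info(
            "phenotype QC removed %d outliers and %d records in %d small CGs",
            rep.n_outliers, rep.n_small_cg_records, rep.n_small_cg_groups,
        )
    return df.copy(), rep


# ---------------------------------------------------------------------------
# gradient basis

@dataclass(frozen=True)
class GradientBasis:
    """Normalized first-order Legendre basis over an observed covariate range.

    The covariate v is standardized to x = 2(v - vmin)/(vmax - vmin) - 1 and
    expanded as (phi0, phi1) = (sqrt(1/2), sqrt(3/2) x).
    """

    vmin: float
    vmax: float

    def standardize(self, values) -> np.ndarray:
        return 2.0 * (np.asarray(values, dtype=float) - self.vmin) / (self.vmax - self.vmin) - 1.0

    def design(self, values) -> np.ndarray:
        """Rows (phi0, phi1(x)) for each covariate value."""
        x = np.atleast_1d(self.standardize(values))
        return np.column_stack([np.full(x.shape, PHI0), PHI1_SLOPE * x])

    def grid(self, n: int = 101) -> np.ndarray:
        """Equally spaced covariate values spanning the observed range."""
        return np.linspace(self.vmin, self.vmax, n)


def build_gradient(values) -> GradientBasis:
    """Standardization range from the observed covariate values.

    Raises on a constant covariate (the gradient would be undefined).
    """
    values = np.asarray(values, dtype=float)
    vmin, vmax = float(np.min(values)), float(np.max(values))
    if vmax <= vmin:
        raise ValueError("constant environmental covariate: gradient undefined")
    return GradientBasis(vmin=vmin, vmax=vmax)
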