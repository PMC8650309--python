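"""Synthetic herd generator with known ground truth.

Generates a multi-generation pig pedigree with repeated sow records and
litters, gene-dropped SNP genotypes, farm-linked seasonal weather, and
phenotypes produced under the linear reaction-norm model

    y = alpha + CG + parity + omega*phi1 + (a0*phi0 + a1*phi1)
        + (pe0*phi0 + pe1*phi1) + (ce0*phi0 + ce1*phi1) + e

where (a0, a1) follow N(0, G0_a (x) A) sampled by the pedigree recursion,
pe is a sow effect, ce a litter effect, and phi0/phi1 the normalized
first-order Legendre basis of the environmental covariate.  Every
configured (co)variance is therefore the exact estimand of the sampler,
which makes parameter-recovery tests possible without any real data.

The generator does not model linkage disequilibrium, selection, genotyping
error or missing weather; see the methods note for what that implies.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import relmat
from .envgrad import ENV_NAMES, PHI0, PHI1_SLOPE, build_gradient

__all__ = ["SimConfig", "SimTruth", "simulate_pedigree", "simulate_genotypes",
           "simulate_weather", "make_records", "simulate_phenotypes",
           "correlated_env_covariates", "simulate_study"]


def _check_psd(m, name):
    m = np.asarray(m, dtype=float)
    if m.shape != (2, 2) or not np.allclose(m, m.T):
        raise ValueError(f"{name} must be a symmetric 2x2 matrix")
    if np.min(np.linalg.eigvalsh(m)) < -1e-10:
        raise ValueError(f"{name} must be positive semi-definite")
    return m


@dataclass
class SimConfig:
    """Stated world of the synthetic herd.

    Defaults describe a nucleus-herd reproduction trait (litter-size-like,
    phenotypic SD near 3): intercept heritability around 0.10 with slope
    variance of comparable order to the intercept variance so that G x E is
    clearly present, sows recorded over 3 parities, contemporary groups of
    farm x year x season.
    """

    n_founders: int = 80
    n_generations: int = 3
    litter_size_mean: float = 8.0
    dams_per_generation: int | None = None   # default n_founders // 2
    records_per_sow: int = 3                 # litters (parities) per dam

    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)

    n_farms: int = 4
    years: int = 3
    first_year: int = 2015
    base_temp_mean: float = 14.0             # deg C, farm baselines ~N(mean, 3)
    base_temp_sd: float = 3.0
    seasonal_amplitude_T: float = 10.0       # deg C
    daily_noise_sd_T: float = 3.0            # deg C
    diurnal_range: float = 9.0               # deg C, tmax - tmin before noise
    rh_mean: float = 70.0                    # %
    rh_amplitude: float = 10.0               # %
    rh_noise_sd: float = 8.0                 # %

    # reaction-norm (co)variances on the normalized Legendre basis
    true_G0_a: np.ndarray = field(default_factory=lambda: np.array([[1.0, 0.3], [0.3, 0.5]]))
    true_G0_pe: np.ndarray = field(default_factory=lambda: np.array([[0.5, 0.1], [0.1, 0.25]]))
    true_G0_ce: np.ndarray = field(default_factory=lambda: np.array([[0.3, 0.0], [0.0, 0.1]]))
    sigma2_e: float = 1.0

    mu: float = 13.0                         # overall intercept alpha
    omega: float = -0.5                      # fixed regression on phi1
    cg_effect_sd: float = 0.5
    fixed_effect_levels: dict = field(default_factory=lambda: {"parity": 3})
    fixed_effect_sd: float = 0.3

    seed: int = 1

    def __post_init__(self):
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        self.true_G0_a = _check_psd(self.true_G0_a, "true_G0_a")
        self.true_G0_pe = _check_psd(self.true_G0_pe, "true_G0_pe")
        self.true_G0_ce = _check_psd(self.true_G0_ce, "true_G0_ce")
        if self.sigma2_e < 0:
            raise ValueError("sigma2_e must be >= 0")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class SimTruth:
    """Ground truth behind one simulated phenotype table."""

    effects: pd.DataFrame        # animal, a0, a1 (+ pe0/pe1 for sows)
    litter_effects: pd.DataFrame # litter, ce0, ce1
    records: pd.DataFrame        # record_id, phi (realized phi1 value)
    n_skipped: int = 0


# ---------------------------------------------------------------------------
# pedigree

def simulate_pedigree(cfg: SimConfig) -> pd.DataFrame:
    """Overlapping-generation pedigree with litters and repeated-parity dams.

    Founders are generation 0 with unknown parents.  Each later generation
    mates a fixed number of dams from the previous generation to sires drawn
    from all earlier generations; each dam farrows ``records_per_sow``
    litters of Poisson(litter_size_mean) piglets (at least one).  Columns:
    animal, sire, dam, sex (1=male, 2=female), gen, farm, litter,
    birth_year, birth_season.
    """
    rng = np.random.default_rng(cfg.seed)
    n_dams = cfg.dams_per_generation or max(1, cfg.n_founders // 2)

    animal = list(range(1, cfg.n_founders + 1))
    sire = [0] * cfg.n_founders
    dam = [0] * cfg.n_founders
    sex = [1 + (i % 2) for i in range(cfg.n_founders)]
    gen = [0] * cfg.n_founders
    farm = list(rng.integers(1, cfg.n_farms + 1, size=cfg.n_founders))
    litter = [0] * cfg.n_founders
    byear = [cfg.first_year - 1] * cfg.n_founders
    bseason = list(rng.integers(1, 5, size=cfg.n_founders))

    next_id = cfg.n_founders + 1
    next_litter = 1
    for g in range(1, cfg.n_generations + 1):
        males = [a for a, s, gg in zip(animal, sex, gen) if s == 1 and gg < g]
        females = [a for a, s, gg in zip(animal, sex, gen) if s == 2 and gg == g - 1]
        if not males or not females:
            break
        dams_g = rng.choice(females, size=min(n_dams, len(females)), replace=False)
        year = cfg.first_year + min(g - 1, cfg.years - 1)
        farm_of = dict(zip(animal, farm))
        for d in sorted(int(x) for x in dams_g):
            for parity in range(1, cfg.records_per_sow + 1):
                s = int(rng.choice(males))
                n_kids = max(1, int(rng.poisson(cfg.litter_size_mean)))
                season = int(rng.integers(1, 5))
                for _ in range(n_kids):
                    animal.append(next_id)
                    sire.append(s)
                    dam.append(d)
                    sex.append(int(rng.integers(1, 3)))
                    gen.append(g)
                    farm.append(farm_of[d])
                    litter.append(next_litter)
                    byear.append(year)
                    bseason.append(season)
                    next_id += 1
                next_litter += 1
    return pd.DataFrame({
        "animal": animal, "sire": sire, "dam": dam, "sex": sex, "gen": gen,
        "farm": farm, "litter": litter, "birth_year": byear, "birth_season": bseason,
    })


# ---------------------------------------------------------------------------
# genotypes

def simulate_genotypes(ped: pd.DataFrame, cfg: SimConfig) -> relmat.GenotypeMatrix:
    """Gene-dropped 0/1/2 genotypes: founders in HWE, Mendelian inheritance.

    Founder allele frequencies are uniform on ``cfg.maf_range``.  No linkage
    is modelled -- each SNP segregates independently, which is all a
    relationship estimator needs.
    """
    rng = np.random.default_rng(cfg.seed + 104729)
    sped = relmat.sort_pedigree(ped)
    sire_ix, dam_ix, ids = relmat._codes(sped)
    n, m = len(ids), cfg.n_snps
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    geno = np.zeros((n, m), dtype=np.int8)
    founders = np.nonzero((sire_ix < 0) & (dam_ix < 0))[0]
    geno[founders] = rng.binomial(2, p, size=(len(founders), m))
    # one unknown parent: sample the missing gamete from the founder pool
    for i in range(n):
        s, d = sire_ix[i], dam_ix[i]
        if s < 0 and d < 0:
            continue
        from_sire = rng.binomial(1, geno[s] / 2.0) if s >= 0 else rng.binomial(1, p)
        from_dam = rng.binomial(1, geno[d] / 2.0) if d >= 0 else rng.binomial(1, p)
        geno[i] = from_sire + from_dam
    return relmat.GenotypeMatrix(ids, [f"snp{j+1}" for j in range(m)], geno.astype(float))


# ---------------------------------------------------------------------------
# weather

def simulate_weather(cfg: SimConfig) -> pd.DataFrame:
    """Daily farm weather: seasonal sinusoid + noise, farm-specific baselines.

    Temperature peaks mid-July (northern-hemisphere farms); relative
    humidity has its own seasonal cycle and independent noise; dew point is
    derived from tmean and RH with the Magnus formula, so dewp <= tmean
    always holds.  With zero amplitude and zero noise the series is constant.
    """
    rng = np.random.default_rng(cfg.seed + 7919)
    n_days = cfg.years * 365
    dates = pd.date_range(f"{cfg.first_year}-01-01", periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy()
    season_T = -np.cos(2.0 * np.pi * (doy - 15.0) / 365.0)
    season_RH = np.cos(2.0 * np.pi * (doy - 15.0) / 365.0)
    frames = []
    for f in range(1, cfg.n_farms + 1):
        base = cfg.base_temp_mean + cfg.base_temp_sd * rng.standard_normal()
        tmean = base + cfg.seasonal_amplitude_T * season_T + cfg.daily_noise_sd_T * rng.standard_normal(n_days)
        half = cfg.diurnal_range / 2.0
        spread_hi = np.abs(cfg.daily_noise_sd_T * rng.standard_normal(n_days)) * 0.5
        spread_lo = np.abs(cfg.daily_noise_sd_T * rng.standard_normal(n_days)) * 0.5
        tmax = tmean + half + spread_hi
        tmin = tmean - half - spread_lo
        rh = cfg.rh_mean + cfg.rh_amplitude * season_RH + cfg.rh_noise_sd * rng.standard_normal(n_days)
        rh = np.clip(rh, 5.0, 100.0)
        a, b = 17.27, 237.7
        gamma = np.log(rh / 100.0) + a * tmean / (b + tmean)
        dewp = b * gamma / (a - gamma)
        dewp = np.minimum(dewp, tmean)
        frames.append(pd.DataFrame({
            "farm": f, "date": dates, "tmax": tmax, "tmin": tmin,
            "tmean": tmean, "dewp": dewp, "rh": rh,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# records and phenotypes

_SEASON_MONTH = {1: 2, 2: 5, 3: 8, 4: 11}


def make_records(ped: pd.DataFrame, cfg: SimConfig, record_all_females: bool = False) -> pd.DataFrame:
    """Phenotype records with reproductive event dates.

    By default one record per pedigree litter (the farrowing event of its
    dam).  With ``record_all_females`` every female is a recorded sow with
    ``records_per_sow`` parities -- a dam-line recording scheme in which
    litters of non-retained sows are phenotyped without their piglets
    entering the pedigree; this gives recorded parent-offspring pairs in
    every branch and is the design the parameter-recovery studies use.

    Breeding is 115 days before farrowing (gestation) and weaning 21 days
    after.  Columns: record_id, animal (the sow), litter, farm, parity, cg
    and the anchor dates measurement/breeding/farrowing/weaning.
    """
    rng = np.random.default_rng(cfg.seed + 15485863)
    rows = []

    def add(record_id, sow, litter, farm, parity, year, season):
        month = _SEASON_MONTH[int(season)]
        day = int(rng.integers(1, 28))
        farrow = pd.Timestamp(year=int(year), month=month, day=day)
        rows.append({
            "record_id": int(record_id),
            "animal": int(sow),
            "litter": int(litter),
            "farm": int(farm),
            "parity": min(int(parity), cfg.fixed_effect_levels.get("parity", 3)),
            "cg": f"{int(farm)}_{int(year)}_{int(season)}",
            "measurement": farrow,
            "breeding": farrow - pd.Timedelta(days=115),
            "farrowing": farrow,
            "weaning": farrow + pd.Timedelta(days=21),
        })

    if record_all_females:
        next_litter = int(ped["litter"].max()) + 1
        next_rec = 1
        females = ped[ped["sex"] == 2].sort_values("animal")
        for sow in females.itertuples(index=False):
            for parity in range(1, cfg.records_per_sow + 1):
                year = min(int(sow.birth_year) + 1, cfg.first_year + cfg.years - 1)
                add(next_rec, sow.animal, next_litter, sow.farm, parity,
                    year, int(rng.integers(1, 5)))
                next_rec += 1
                next_litter += 1
        return pd.DataFrame(rows)

    litters = ped[ped["litter"] > 0].groupby("litter").first().reset_index()
    parity_counter: dict[int, int] = {}
    for rec in litters.sort_values("litter").itertuples(index=False):
        sow = int(rec.dam)
        parity_counter[sow] = parity_counter.get(sow, 0) + 1
        add(rec.litter, sow, rec.litter, rec.farm, parity_counter[sow],
            rec.birth_year, rec.birth_season)
    return pd.DataFrame(rows)


def _chol_psd(G: np.ndarray) -> np.ndarray:
    """Cholesky-like square root that tolerates PSD-singular targets."""
    G = np.asarray(G, dtype=float)
    try:
        return np.linalg.cholesky(G)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(G)
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _sample_reaction_norm_effects(ped: pd.DataFrame, G0: np.ndarray, rng) -> pd.DataFrame:
    """(a0, a1) ~ N(0, G0 (x) A) by the pedigree recursion.

    child = (a_sire + a_dam)/2 + Mendelian deviation with variance d_i * G0,
    d_i = 1/2 - (F_s + F_d)/4 adjusted for unknown parents.  Exact without
    ever forming A.
    """
    sped = relmat.sort_pedigree(ped)
    sire, dam, ids = relmat._codes(sped)
    F = relmat.compute_inbreeding(sped).to_numpy()
    d = relmat._mendelian_d(sire, dam, F)
    L = _chol_psd(G0)
    n = len(ids)
    eff = np.zeros((n, 2))
    z = rng.standard_normal((n, 2))
    for i in range(n):
        mean = np.zeros(2)
        if sire[i] >= 0:
            mean += 0.5 * eff[sire[i]]
        if dam[i] >= 0:
            mean += 0.5 * eff[dam[i]]
        eff[i] = mean + np.sqrt(d[i]) * (L @ z[i])
    return pd.DataFrame({"animal": ids, "a0": eff[:, 0], "a1": eff[:, 1]})


def simulate_phenotypes(
    ped: pd.DataFrame,
    env: pd.DataFrame,
    cfg: SimConfig,
    records: pd.DataFrame | None = None,
    env_name: str | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Phenotypes under the linear reaction-norm model with known truth.

    ``env`` is a long covariate table (record_id, env, value) as produced by
    :func:`heatnorm.envgrad.window_average`; one ENV (``env_name``, default
    the first present) drives the true slopes.  Records without a covariate
    are skipped with a warning count in the returned truth object.
    """
    rng = np.random.default_rng(cfg.seed + 32452843)
    if records is None:
        records = make_records(ped, cfg)
    if env_name is None:
        env_name = env["env"].iloc[0]
    cov = env[env["env"] == env_name].set_index("record_id")["value"]
    basis = build_gradient(cov.to_numpy())

    a = _sample_reaction_norm_effects(ped, cfg.true_G0_a, rng)
    a_ix = a.set_index("animal")
    sows = np.sort(records["animal"].unique())
    pe = pd.DataFrame(rng.standard_normal((len(sows), 2)) @ _chol_psd(cfg.true_G0_pe).T,
                      index=sows, columns=["pe0", "pe1"])
    litters = np.sort(records["litter"].unique())
    ce = pd.DataFrame(rng.standard_normal((len(litters), 2)) @ _chol_psd(cfg.true_G0_ce).T,
                      index=litters, columns=["ce0", "ce1"])

    cgs = np.sort(records["cg"].unique())
    cg_eff = pd.Series(rng.normal(0.0, cfg.cg_effect_sd, size=len(cgs)), index=cgs)
    n_par = cfg.fixed_effect_levels.get("parity", 3)
    par_eff = pd.Series(rng.normal(0.0, cfg.fixed_effect_sd, size=n_par),
                        index=range(1, n_par + 1))

    rows = []
    phis = []
    n_skipped = 0
    for rec in records.itertuples(index=False):
        if rec.record_id not in cov.index:
            n_skipped += 1
            continue
        x = basis.standardize(cov.loc[rec.record_id])
        phi1 = PHI1_SLOPE * float(x)
        sow = rec.animal
        y = (cfg.mu
             + cg_eff[rec.cg]
             + par_eff[rec.parity]
             + cfg.omega * phi1
             + a_ix.at[sow, "a0"] * PHI0 + a_ix.at[sow, "a1"] * phi1
             + pe.at[sow, "pe0"] * PHI0 + pe.at[sow, "pe1"] * phi1
             + ce.at[rec.litter, "ce0"] * PHI0 + ce.at[rec.litter, "ce1"] * phi1
             + rng.normal(0.0, np.sqrt(cfg.sigma2_e)))
        row = rec._asdict()
        row["value"] = y
        row["env_value"] = float(cov.loc[rec.record_id])
        rows.append(row)
        phis.append((rec.record_id, phi1))
    pheno = pd.DataFrame(rows)
    effects = a.merge(pe.reset_index(names="animal"), on="animal", how="left")
    truth = SimTruth(
        effects=effects,
        litter_effects=ce.reset_index(names="litter"),
        records=pd.DataFrame(phis, columns=["record_id", "phi"]),
        n_skipped=n_skipped,
    )
    return pheno, truth


def correlated_env_covariates(
    records: pd.DataFrame,
    rho: float = 0.65,
    names: tuple[str, ...] = ENV_NAMES,
    seed: int = 1,
    value_range: tuple[float, float] = (5.0, 35.0),
) -> pd.DataFrame:
    """Seven synthetic candidate covariates with controlled correlation.

    Used for driving-ENV recovery studies: an equicorrelated Gaussian
    copula (pairwise latent correlation ``rho``; realistic candidate sets
    stay below |r| = 0.8) with uniform marginals over ``value_range``.
    Seasonal window averages sweep their observed range rather than piling
    at the centre, and a thin-tailed marginal would leave the standardized
    gradient with almost no slope information; the uniform marginal
    reproduces the informative spread.  Returns the long
    (record_id, env, value) layout of :func:`window_average`.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    k = len(names)
    C = np.full((k, k), rho) + (1.0 - rho) * np.eye(k)
    L = np.linalg.cholesky(C)
    z = rng.standard_normal((len(records), k)) @ L.T
    lo, hi = value_range
    values = lo + (hi - lo) * norm.cdf(z)
    out = pd.DataFrame({
        "record_id": np.repeat(records["record_id"].to_numpy(), k),
        "env": np.tile(np.array(names), len(records)),
        "value": values.ravel(),
        "coverage": 1.0,
    })
    return out


def simulate_study(cfg: SimConfig, genotype_fraction: float = 0.0):
    """Convenience wrapper: pedigree, records, weather and genotypes.

    Returns (ped, records, weather, geno) where ``geno`` covers a random
    fraction of the youngest generations (or None when the fraction is 0).
    """
    ped = simulate_pedigree(cfg)
    records = make_records(ped, cfg)
    weather = simulate_weather(cfg)
    geno = None
    if genotype_fraction > 0:
        rng = np.random.default_rng(cfg.seed + 49979687)
        full = simulate_genotypes(ped, cfg)
        young = ped[ped["gen"] >= max(0, ped["gen"].max() - 1)]["animal"].to_numpy()
        n_pick = max(2, int(round(genotype_fraction * len(ped))))
        pick = np.sort(rng.choice(young, size=min(n_pick, len(young)), replace=False))
        ix = full.animals.get_indexer(pick)
        geno = relmat.GenotypeMatrix(pick, full.snps, full.calls[ix])
    return ped, records, weather, geno
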