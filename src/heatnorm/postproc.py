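"""Derived genetic parameters along the environmental gradient.

From the posterior variance components and GEBV table this module computes

* covariance functions Gamma_n = Phi G0_n Phi' over the gradient,
* the heritability trajectory h2_k = Gamma_a,kk / (sum_n Gamma_n,kk + s2_e),
* theoretical GEBV accuracies Acc = sqrt(1 - PSD^2 / ((1+F) sigma2)),
* across-environment genetic correlations r_kk' (closed form, trimmed to a
  percentile window) with the large/moderate/weak G x E classification,
* sire reaction-norm curves with the most heat-tolerant / heat-susceptible
  extremes, and
* accuracy-weighted between-trait GEBV correlations with their standard
  errors, plus plain Spearman rank correlations.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .envgrad import GradientBasis

logger = logging.getLogger(__name__)

__all__ = [
    "covariance_function", "heritability_trajectory", "gebv_accuracy",
    "env_genetic_correlation", "classify_gxe", "reaction_norm_curves",
    "weighted_trait_correlation", "rank_correlation", "TraitCorrelationEstimate",
]


def covariance_function(g0: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Gamma = Phi G0 Phi' over the gradient grid (exact triple product)."""
    g0 = np.asarray(g0, dtype=float)
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    if g0.shape != (2, 2) or phi.shape[1] != 2:
        raise ValueError("need a 2x2 G0 and basis rows with 2 columns")
    return phi @ g0 @ phi.T


def heritability_trajectory(
    gammas: dict[str, np.ndarray],
    sigma2_e: float,
    values: np.ndarray | None = None,
) -> pd.DataFrame:
    """h2 at each gradient point; inactive effects simply contribute zero.

    ``gammas`` maps effect name -> covariance function from
    :func:`covariance_function`; the additive effect "a" must be present.
    """
    if "a" not in gammas:
        raise ValueError("additive covariance function 'a' is required")
    diag = {n: np.diag(np.asarray(g)) for n, g in gammas.items()}
    denom = sum(diag.values()) + float(sigma2_e)
    if np.any(denom <= 0):
        raise ValueError("non-positive phenotypic variance along the gradient")
    out = pd.DataFrame({f"var_{n}": d for n, d in diag.items()})
    out["var_e"] = float(sigma2_e)
    out["h2"] = diag["a"] / denom
    if values is not None:
        out.insert(0, "value", np.asarray(values))
    return out


def gebv_accuracy(
    gebv: pd.DataFrame,
    F: pd.Series,
    sigma2: dict[str, float],
    terms: tuple[str, ...] = ("a0", "a1"),
) -> pd.DataFrame:
    """Theoretical accuracy sqrt(1 - PSD^2 / ((1+F) sigma2)) per animal/term.

    ``sigma2`` maps each term to its posterior-mean additive variance.
    Sampling noise can push PSD^2 above (1+F)*sigma2; such accuracies are
    clipped to 0 and the clip count logged.
    """
    out = gebv[["animal"]].copy()
    Fv = F.reindex(gebv["animal"]).to_numpy(dtype=float)
    if np.any(np.isnan(Fv)):
        raise KeyError("inbreeding coefficients missing for some animals")
    n_clipped = 0
    for term in terms:
        s2 = float(sigma2[term])
        if s2 <= 0:
            raise ValueError(f"additive variance for {term} must be > 0")
        ratio = 1.0 - gebv[f"{term}_sd"].to_numpy() ** 2 / ((1.0 + Fv) * s2)
        n_clipped += int(np.sum(ratio < 0))
        out[f"acc_{term}"] = np.sqrt(np.clip(ratio, 0.0, 1.0))
    if n_clipped:
        logger.info("gebv_accuracy clipped %d negative reliabilities to 0", n_clipped)
    out.attrs["n_clipped"] = n_clipped
    return out


def env_genetic_correlation(
    g0_a: np.ndarray,
    basis: GradientBasis,
    values: np.ndarray,
    percentiles: tuple[float, float] = (10.0, 90.0),
    n_grid: int = 25,
) -> pd.DataFrame:
    """Additive genetic correlations between environments (closed form).

    The gradient is trimmed to the ``percentiles`` window of the observed
    covariate distribution.  With basis rows (phi0, phi1), the additive
    covariance between environments k and k' expands as

        sigma_ukk' = s2_a0 phi0^2 + s_a0a1 phi0 (phi1_k + phi1_k')
                     + s2_a1 phi1_k phi1_k'

    which equals Gamma_a,kk' exactly; the correlation matrix therefore has a
    unit diagonal by construction.  The result carries the grid values in
    ``attrs["values"]`` plus mean/min summaries and the G x E class.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = np.percentile(values, percentiles)
    grid = np.linspace(lo, hi, n_grid)
    phi = basis.design(grid)
    g0_a = np.asarray(g0_a, dtype=float)
    p0 = phi[:, 0]
    p1 = phi[:, 1]
    cov = (g0_a[0, 0] * np.outer(p0, p0)
           + g0_a[0, 1] * (np.outer(p0, p1) + np.outer(p1, p0))
           + g0_a[1, 1] * np.outer(p1, p1))
    var = np.diag(cov)
    if np.any(var <= 0):
        raise ValueError("zero additive variance at a gradient point")
    r = cov / np.sqrt(np.outer(var, var))
    out = pd.DataFrame(r, index=grid, columns=grid)
    off = r[~np.eye(len(grid), dtype=bool)]
    out.attrs["values"] = grid
    out.attrs["mean"] = float(off.mean())
    out.attrs["min"] = float(off.min())
    out.attrs["gxe_class"] = classify_gxe(float(off.mean()))
    return out


def classify_gxe(r: float) -> str:
    """G x E magnitude from a genetic correlation: boundaries are inclusive
    into the moderate band (0.50 <= r <= 0.80)."""
    if r < 0.50:
        return "large"
    if r <= 0.80:
        return "moderate"
    return "weak"


def reaction_norm_curves(
    gebv: pd.DataFrame,
    basis: GradientBasis,
    values: np.ndarray,
    min_offspring: int = 30,
    n_extreme: int = 5,
    n_grid: int = 25,
) -> pd.DataFrame:
    """Sire reaction norms GEBV(k) = a0 phi0 + a1 phi1(x_k) over the gradient.

    Only sires with at least ``min_offspring`` offspring are eligible; the
    ``n_extreme`` highest slopes ("tolerant") and lowest slopes
    ("susceptible") are returned together with the eligible-population mean
    curve.  When fewer than 2*n_extreme sires qualify, all are returned with
    a warning.
    """
    if "n_offspring" not in gebv.columns:
        raise ValueError("gebv table lacks n_offspring; pass the pedigree to summarize_posterior")
    grid = np.linspace(float(np.min(values)), float(np.max(values)), n_grid)
    phi = basis.design(grid)
    elig = gebv[gebv["n_offspring"] >= min_offspring]
    if len(elig) < 2 * n_extreme:
        logger.warning("only %d sires with >= %d offspring; returning all", len(elig), min_offspring)
        chosen = elig
        groups = pd.Series("eligible", index=elig.index)
    else:
        order = elig.sort_values(["a1", "animal"])
        low = order.head(n_extreme)
        high = order.tail(n_extreme)
        chosen = pd.concat([high, low])
        groups = pd.Series(["tolerant"] * n_extreme + ["susceptible"] * n_extreme,
                           index=chosen.index)
    rows = []
    for idx, sire in chosen.iterrows():
        curve = sire["a0"] * phi[:, 0] + sire["a1"] * phi[:, 1]
        for v, c in zip(grid, curve):
            rows.append((int(sire["animal"]), groups.loc[idx], v, c))
    mean_curve = (elig["a0"].mean() * phi[:, 0] + elig["a1"].mean() * phi[:, 1]
                  if len(elig) else np.zeros(n_grid))
    for v, c in zip(grid, mean_curve):
        rows.append((0, "population", v, c))
    return pd.DataFrame(rows, columns=["animal", "group", "value", "gebv"])


@dataclass(frozen=True)
class TraitCorrelationEstimate:
    trait_x: str
    trait_y: str
    term_x: str
    term_y: str
    r: float
    se: float
    n: int


def weighted_trait_correlation(
    gebv_x: pd.DataFrame,
    gebv_y: pd.DataFrame,
    acc_x: pd.DataFrame,
    acc_y: pd.DataFrame,
    term_x: str = "a1",
    term_y: str = "a1",
    threshold: float = 0.30,
    trait_x: str = "x",
    trait_y: str = "y",
) -> TraitCorrelationEstimate:
    """Reliability-weighted Pearson correlation between two traits' GEBVs.

    Animals need accuracy >= ``threshold`` on the intercept *and* slope of
    both traits.  Weights are w_i = sqrt(Rel_x * Rel_y) with Rel = Acc^2 of
    the correlated terms; SE = sqrt((1 - r^2) / (n - 2)).
    """
    ax = acc_x.set_index("animal")
    ay = acc_y.set_index("animal")
    gx = gebv_x.set_index("animal")[term_x]
    gy = gebv_y.set_index("animal")[term_y]
    common = gx.index.intersection(gy.index).intersection(ax.index).intersection(ay.index)
    ok = pd.Series(True, index=common)
    for acc in (ax, ay):
        for col in ("acc_a0", "acc_a1"):
            ok &= acc.loc[common, col] >= threshold
    keep = common[ok]
    n = len(keep)
    if n < 3:
        raise ValueError(f"only {n} animals pass the {threshold} accuracy cut; need >= 3")
    x = gx.loc[keep].to_numpy()
    y = gy.loc[keep].to_numpy()
    rel_x = ax.loc[keep, f"acc_{term_x}"].to_numpy() ** 2
    rel_y = ay.loc[keep, f"acc_{term_y}"].to_numpy() ** 2
    w = np.sqrt(rel_x * rel_y)
    xb = np.sum(w * x) / np.sum(w)
    yb = np.sum(w * y) / np.sum(w)
    cov = np.sum(w * (x - xb) * (y - yb)) / np.sum(w)
    vx = np.sum(w * (x - xb) ** 2) / np.sum(w)
    vy = np.sum(w * (y - yb) ** 2) / np.sum(w)
    r = float(cov / np.sqrt(vx * vy))
    se = float(np.sqrt(max(1.0 - r * r, 0.0) / (n - 2)))
    return TraitCorrelationEstimate(trait_x=trait_x, trait_y=trait_y,
                                    term_x=term_x, term_y=term_y, r=r, se=se, n=n)


def rank_correlation(x, y) -> float:
    """Spearman rho (average ranks for ties); NaN when a vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("rank correlation undefined for a constant vector")
        return float("nan")
    return float(spearmanr(x, y).statistic)
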