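"""Weighted three-criterion recommendation of the environmental variable.

Each candidate "ENV x critical period" fit is scored on

1. the slope additive variance sigma2_a1 (strength of G x E),      weight 0.5
2. the mean slope-GEBV accuracy,                                   weight 0.3
3. the dispersion of GEBV along the gradient (SD across animals of
   GEBV evaluated at the 0/25/50/75/100th percentile covariate
   values, averaged over the five points),                         weight 0.2

after min-max normalization of each criterion within the comparison set.
The candidate with the highest weighted total is recommended; ties break by
criterion 1, then by ENV name.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .envgrad import GradientBasis

logger = logging.getLogger(__name__)

DEFAULT_WEIGHTS = (0.5, 0.3, 0.2)
PERCENTILES = (0.0, 25.0, 50.0, 75.0, 100.0)

__all__ = ["CandidateResult", "EnvRecommendation", "dispersion_score",
           "score_envs", "recommend", "DEFAULT_WEIGHTS"]


@dataclass(frozen=True)
class CandidateResult:
    """Raw criterion inputs from one completed reaction-norm fit."""

    trait: str
    env: str
    period: str
    sigma2_a1: float
    slope_accuracy: float
    dispersion: float


@dataclass(frozen=True)
class EnvRecommendation:
    trait: str
    env: str
    period: str
    scores: pd.DataFrame


def dispersion_score(
    gebv: pd.DataFrame,
    basis: GradientBasis,
    values: np.ndarray,
    percentiles: tuple[float, ...] = PERCENTILES,
) -> float:
    """Mean across-animal SD of GEBV at the percentile gradient points."""
    if len(gebv) < 2:
        raise ValueError("need at least 2 animals to measure GEBV dispersion")
    pts = np.percentile(np.asarray(values, dtype=float), percentiles)
    phi = basis.design(pts)
    curves = np.outer(gebv["a0"].to_numpy(), phi[:, 0]) + np.outer(gebv["a1"].to_numpy(), phi[:, 1])
    return float(curves.std(axis=0, ddof=1).mean())


def _minmax(col: pd.Series) -> pd.Series:
    rng = col.max() - col.min()
    if rng == 0:
        return pd.Series(1.0, index=col.index)
    return (col - col.min()) / rng


def score_envs(
    candidates: list[CandidateResult],
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    normalization: str = "minmax",
    by_period: bool = True,
) -> pd.DataFrame:
    """Normalize the three criteria and attach the weighted total.

    Normalization happens within each (trait, period) comparison set when
    ``by_period`` is true (candidate periods are judged separately, then a
    joint ranking can still be read off the returned table).  ``rank``
    normalization is available as an alternative to ``minmax``.
    """
    if abs(sum(weights) - 1.0) > 1e-12:
        raise ValueError("criterion weights must sum to 1")
    df = pd.DataFrame([c.__dict__ for c in candidates])
    if df.empty:
        raise ValueError("no candidates to score")
    if len(df) == 1:
        logger.warning("single candidate: normalization is degenerate, returning raw ranking")
    keys = ["trait", "period"] if by_period else ["trait"]

    def norm(col: pd.Series) -> pd.Series:
        if normalization == "minmax":
            return col.groupby(df[keys].apply(tuple, axis=1)).transform(_minmax)
        if normalization == "rank":
            return col.groupby(df[keys].apply(tuple, axis=1)).transform(
                lambda c: (c.rank(method="average") - 1) / max(len(c) - 1, 1)
            )
        raise ValueError(f"unknown normalization {normalization!r}")

    df["c1"] = norm(df["sigma2_a1"])
    df["c2"] = norm(df["slope_accuracy"])
    df["c3"] = norm(df["dispersion"])
    df["total"] = weights[0] * df["c1"] + weights[1] * df["c2"] + weights[2] * df["c3"]
    return df.sort_values(["trait", "total", "sigma2_a1", "env"],
                          ascending=[True, False, False, True],
                          kind="mergesort").reset_index(drop=True)


def recommend(
    candidates: list[CandidateResult] | pd.DataFrame,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    normalization: str = "minmax",
) -> list[EnvRecommendation]:
    """Argmax of the weighted total per trait, with the full audit table."""
    scores = (candidates if isinstance(candidates, pd.DataFrame)
              else score_envs(candidates, weights=weights, normalization=normalization))
    out = []
    for trait, grp in scores.groupby("trait", sort=True):
        best = grp.iloc[0]
        out.append(EnvRecommendation(trait=trait, env=best["env"],
                                     period=best["period"], scores=grp.reset_index(drop=True)))
    return out
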