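"""End-to-end orchestration: fit one candidate, compare candidates, recommend.

Glue between the modules: builds the gradient from a covariate table, joins
it to the phenotype records, assembles and samples the mixed model, and
derives the selection criteria for each candidate ENV.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import envselect, postproc, rnm_gibbs
from .envgrad import GradientBasis, build_gradient
from .relmat import RelationshipOperator

__all__ = ["CandidateFit", "fit_candidate", "run_env_study"]


@dataclass
class CandidateFit:
    """Everything downstream analyses need from one ENV x period fit."""

    trait: str
    env: str
    period: str
    basis: GradientBasis
    values: np.ndarray
    varcomps: rnm_gibbs.VarianceComponents
    gebv: pd.DataFrame
    accuracy: pd.DataFrame
    samples: rnm_gibbs.PosteriorSamples

    def criteria(self) -> envselect.CandidateResult:
        g0a = self.varcomps.mean["a"]
        return envselect.CandidateResult(
            trait=self.trait,
            env=self.env,
            period=self.period,
            sigma2_a1=float(g0a[1, 1]),
            slope_accuracy=float(self.accuracy["acc_a1"].mean()),
            dispersion=envselect.dispersion_score(self.gebv, self.basis, self.values),
        )


def fit_candidate(
    pheno: pd.DataFrame,
    env_table: pd.DataFrame,
    env: str,
    rel: RelationshipOperator,
    spec: rnm_gibbs.ModelSpec,
    chain: rnm_gibbs.ChainConfig,
    period: str = "default",
) -> CandidateFit:
    """Fit the reaction-norm model for one candidate environmental variable."""
    cov = env_table.loc[env_table["env"] == env, ["record_id", "value"]]
    data = pheno.drop(columns=["env_value"], errors="ignore").merge(
        cov.rename(columns={"value": "env_value"}), on="record_id")
    if data.empty:
        raise ValueError(f"no records with a covariate for ENV {env!r}")
    basis = build_gradient(data["env_value"].to_numpy())
    system = rnm_gibbs.assemble_mme(data, spec, basis, rel.Hinv, rel.animals)
    samples = rnm_gibbs.gibbs_sample(system, chain)
    varcomps, gebv = rnm_gibbs.summarize_posterior(samples, pedigree=rel.pedigree)
    g0a = varcomps.mean["a"]
    acc = postproc.gebv_accuracy(
        gebv, rel.F, sigma2={"a0": g0a[0, 0], "a1": g0a[1, 1]}
    )
    return CandidateFit(
        trait=spec.trait, env=env, period=period, basis=basis,
        values=data["env_value"].to_numpy(), varcomps=varcomps,
        gebv=gebv, accuracy=acc, samples=samples,
    )


def run_env_study(
    pheno: pd.DataFrame,
    env_table: pd.DataFrame,
    rel: RelationshipOperator,
    spec: rnm_gibbs.ModelSpec,
    chain: rnm_gibbs.ChainConfig,
    envs: tuple[str, ...] | None = None,
    period: str = "default",
    weights: tuple[float, float, float] = envselect.DEFAULT_WEIGHTS,
) -> tuple[list[CandidateFit], pd.DataFrame, list[envselect.EnvRecommendation]]:
    """Fit every candidate ENV and emit the weighted recommendation."""
    if envs is None:
        envs = tuple(env_table["env"].unique())
    fits = [fit_candidate(pheno, env_table, env, rel, spec, chain, period=period)
            for env in envs]
    scores = envselect.score_envs([f.criteria() for f in fits], weights=weights)
    recs = envselect.recommend(scores)
    return fits, scores, recs
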