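"""Bayesian reaction-norm animal model fitted by Gibbs sampling.

The single-trait linear reaction-norm model is

    y_ik = alpha + x_i' beta + omega * phi1_k
           + sum_n (n0_i * phi0 + n1_i * phi1_k) + e_ik,

with n in a subset of {a, pe, ce}: the additive effect (2-vectors
distributed N(0, G0_a (x) H)), the sow permanent-environment effect and the
litter effect (both identity-structured).  phi0/phi1 are the normalized
first-order Legendre basis of the environmental covariate.

Location parameters are updated by single-site (2x2-block for random
regressions) Gauss-Seidel Gibbs sweeps; each G0 block has an
inverse-Wishart full conditional with scale U' K^-1 U + S0, and the
residual variance a scaled inverse-chi-square full conditional.  Records
are sorted canonically before sampling so a fixed seed reproduces chains
exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve
from scipy.stats import invwishart

from . import _kernels
from .envgrad import GradientBasis, build_gradient

logger = logging.getLogger(__name__)

RANDOM_EFFECTS = ("a", "pe", "ce")

__all__ = [
    "ModelSpec", "PriorSpec", "ChainConfig", "RandomEffectBlock",
    "MixedModelSystem", "PosteriorSamples", "VarianceComponents",
    "assemble_mme", "gibbs_sample", "solve_blup", "summarize_posterior",
    "convergence_check",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which effects enter the model for one trait x gradient analysis."""

    trait: str = "trait"
    fixed: tuple[str, ...] = ("cg",)          # categorical columns
    random: tuple[str, ...] = ("a", "pe", "ce")
    env: str | None = None
    period: str | None = None

    def __post_init__(self):
        for r in self.random:
            if r not in RANDOM_EFFECTS:
                raise ValueError(f"unknown random effect {r!r}")


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative proper priors (config-overridable).

    2x2 covariance blocks: inverse-Wishart with df = 4 and, by default
    (``g0_scale=None``), scale 0.1 * Var(y) * I.  A tiny fixed scale such as
    0.01*I may look less informative but its density grows like |G0|^-3
    toward singular matrices with no exponential barrier, so it actively
    drags weakly identified blocks into collapse; a scale of the trait's
    own magnitude keeps the prior negligible against thousands of levels
    while suppressing the singular ridge.  Residual: scaled
    inverse-chi-square with df 2 and scale 0.01.  Fixed effects flat.
    """

    g0_df: float = 4.0
    g0_scale: float | None = None   # None: 0.1 * Var(y)
    e_df: float = 2.0
    e_scale: float = 0.01

    def g0_scale_matrix(self, var_y: float) -> np.ndarray:
        scale = 0.1 * var_y if self.g0_scale is None else self.g0_scale
        return scale * np.eye(2)


@dataclass(frozen=True)
class ChainConfig:
    n_iter: int = 5000
    burn_in: int = 2000
    thin: int = 10
    seed: int = 1
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @classmethod
    def preset(cls, name: str, seed: int = 1) -> "ChainConfig":
        """Named chain settings: "desk" (default) or "full" (study scale)."""
        if name == "desk":
            return cls(n_iter=5000, burn_in=2000, thin=10, seed=seed)
        if name == "full":
            return cls(n_iter=600_000, burn_in=300_000, thin=60, seed=seed)
        if name == "full-ibf":
            return cls(n_iter=900_000, burn_in=600_000, thin=60, seed=seed)
        raise ValueError(f"unknown chain preset {name!r}")


@dataclass
class RandomEffectBlock:
    name: str
    offset: int                  # first coefficient column
    levels: pd.Index             # level ids, defines K^-1 ordering
    kinv: sp.csr_matrix
    cross: np.ndarray            # per-level sum of phi0*phi1 over records
    rec_lev: np.ndarray = None   # level index of each record

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class MixedModelSystem:
    """Sparse mixed-model system for one trait x gradient analysis."""

    y: np.ndarray
    W: sp.csc_matrix
    n_fixed: int
    fixed_names: list
    effects: list
    basis: GradientBasis
    record_ids: np.ndarray
    phi: np.ndarray = None       # (n_records, 2) basis rows
    diag_wtw: np.ndarray = None

    def __post_init__(self):
        if self.diag_wtw is None:
            self.diag_wtw = np.asarray(self.W.multiply(self.W).sum(axis=0)).ravel()

    @property
    def n_coef(self) -> int:
        return self.W.shape[1]

    @property
    def pe_of_a(self) -> np.ndarray:
        """Map additive level -> pe level (-1 when the animal has no records)."""
        cached = getattr(self, "_pe_of_a", None)
        if cached is None:
            by_name = {eff.name: eff for eff in self.effects}
            cached = np.asarray(
                by_name["pe"].levels.get_indexer(by_name["a"].levels), dtype=np.int64
            )
            object.__setattr__(self, "_pe_of_a", cached)
        return cached

    @property
    def n_records(self) -> int:
        return len(self.y)

    def rhs(self) -> np.ndarray:
        return self.W.T @ self.y

    def lhs(self, g0: dict, sigma2_e: float) -> sp.csc_matrix:
        """Full coefficient matrix W'W/s2e + prior precision."""
        C = (self.W.T @ self.W) / sigma2_e
        blocks = [sp.csr_matrix((self.n_fixed, self.n_fixed))]
        for eff in self.effects:
            blocks.append(sp.kron(eff.kinv, np.linalg.inv(g0[eff.name]), format="csr"))
        return (C + sp.block_diag(blocks, format="csr")).tocsc()

    def solve(self, g0: dict, sigma2_e: float) -> np.ndarray:
        """Direct sparse solve of the mixed-model equations (BLUP)."""
        return spsolve(self.lhs(g0, sigma2_e), self.rhs() / sigma2_e)


def assemble_mme(
    data: pd.DataFrame,
    spec: ModelSpec,
    basis: GradientBasis | None,
    hinv: sp.spmatrix,
    animal_order: pd.Index,
    value_col: str = "value",
    env_col: str = "env_value",
) -> MixedModelSystem:
    """Build the sparse design for the reaction-norm mixed model.

    ``data`` carries one row per record: the trait value, the raw
    environmental covariate, an ``animal`` column (ids must appear in
    ``animal_order``, the row order of ``hinv``), a ``litter`` column when
    the ce effect is active, and the categorical fixed-effect columns named
    by ``spec.fixed``.  One level of every fixed factor is dropped against
    the overall intercept; a rank check names confounded columns.
    """
    df = data.sort_values(["animal", "record_id"] if "record_id" in data.columns
                          else ["animal"], kind="mergesort").reset_index(drop=True)
    y = df[value_col].to_numpy(dtype=float)
    n = len(df)
    if basis is None:
        basis = build_gradient(df[env_col].to_numpy())
    phi = basis.design(df[env_col].to_numpy())    # (n, 2) columns phi0, phi1

    # fixed part: intercept + dummies (drop first level) + fixed regression on phi1
    cols = [np.ones((n, 1))]
    names: list = ["intercept"]
    for f in spec.fixed:
        d = pd.get_dummies(df[f].astype("category"), prefix=f, drop_first=True, dtype=float)
        cols.append(d.to_numpy())
        names += list(d.columns)
    cols.append(phi[:, 1:2])
    names.append("omega")
    X = np.hstack(cols)
    _check_rank(X, names)
    n_fixed = X.shape[1]

    parts = [sp.csc_matrix(X)]
    effects: list[RandomEffectBlock] = []
    offset = n_fixed
    identity = lambda q: sp.identity(q, format="csr")
    hinv = sp.csr_matrix(hinv)
    for name in spec.random:
        if name == "a":
            levels = pd.Index(animal_order)
            kinv = hinv
        elif name == "pe":
            levels = pd.Index(np.sort(df["animal"].unique()))
            kinv = identity(len(levels))
        else:  # ce
            levels = pd.Index(np.sort(df["litter"].unique()))
            kinv = identity(len(levels))
        key = "animal" if name in ("a", "pe") else "litter"
        lev_ix = levels.get_indexer(df[key])
        if np.any(lev_ix < 0):
            raise KeyError(f"records reference {key}s missing from the {name} levels")
        q = len(levels)
        rows = np.repeat(np.arange(n), 2)
        colix = np.column_stack([2 * lev_ix, 2 * lev_ix + 1]).ravel()
        Z = sp.coo_matrix((phi.ravel(), (rows, colix)), shape=(n, 2 * q)).tocsc()
        cross = np.bincount(lev_ix, weights=phi[:, 0] * phi[:, 1], minlength=q)
        parts.append(Z)
        effects.append(RandomEffectBlock(name=name, offset=offset, levels=levels,
                                         kinv=kinv, cross=cross, rec_lev=lev_ix))
        offset += 2 * q
    W = sp.hstack(parts, format="csc")
    rec_ids = df["record_id"].to_numpy() if "record_id" in df.columns else np.arange(n)
    return MixedModelSystem(y=y, W=W, n_fixed=n_fixed, fixed_names=names,
                            effects=effects, basis=basis, record_ids=rec_ids, phi=phi)


def _check_rank(X: np.ndarray, names: list) -> None:
    from scipy.linalg import qr

    # all-zero columns (e.g. the fixed regression when every record sits at
    # the gradient midpoint) are inactive, not confounded: skip them
    active = np.flatnonzero(np.abs(X).sum(axis=0) > 0)
    X = X[:, active]
    names = [names[j] for j in active]
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"fixed-effect design is rank deficient; confounded columns: {bad}")


# ---------------------------------------------------------------------------
# sampling

@dataclass
class PosteriorSamples:
    """Retained draws of the variance components plus location summaries.

    Location effects are not stored per draw; their posterior mean/SD are
    accumulated online over the retained iterations.
    """

    g0: dict
    sigma2_e: np.ndarray
    coef_mean: np.ndarray
    coef_sd: np.ndarray
    system: MixedModelSystem
    chain: ChainConfig

    @property
    def n_retained(self) -> int:
        return len(self.sigma2_e)

    def component_table(self) -> pd.DataFrame:
        """Long table of scalar variance-component chains."""
        out = {}
        for name, draws in self.g0.items():
            out[f"var_{name}0"] = draws[:, 0, 0]
            out[f"cov_{name}0{name}1"] = draws[:, 0, 1]
            out[f"var_{name}1"] = draws[:, 1, 1]
        out["var_e"] = self.sigma2_e
        return pd.DataFrame(out)


def _sweep(system, theta, e, g0inv, s2e, z, noise):
    W = system.W
    _kernels.sweep_scalar(W.data, W.indices, W.indptr, e, theta,
                          system.diag_wtw, 0, system.n_fixed, s2e,
                          z, noise)
    by_name = {eff.name: eff for eff in system.effects}
    joint = "a" in by_name and "pe" in by_name
    if joint:
        a = by_name["a"]
        pe = by_name["pe"]
        # z slots: additive pairs first, then the pe pairs, matching offsets
        zj = np.concatenate([
            z[a.offset:a.offset + 2 * a.n_levels],
            z[pe.offset:pe.offset + 2 * pe.n_levels],
        ])
        _kernels.sweep_joint_a_pe(
            W.data, W.indices, W.indptr, e, theta, system.diag_wtw, a.cross,
            a.offset, a.n_levels, system.pe_of_a, pe.offset,
            a.kinv.data, a.kinv.indices, a.kinv.indptr,
            g0inv["a"], g0inv["pe"], s2e, zj, noise,
        )
    for eff in system.effects:
        if joint and eff.name in ("a", "pe"):
            continue
        _kernels.sweep_block2(
            W.data, W.indices, W.indptr, e, theta, system.diag_wtw, eff.cross,
            eff.offset, eff.n_levels,
            eff.kinv.data, eff.kinv.indices, eff.kinv.indptr,
            g0inv[eff.name], s2e, z[eff.offset:eff.offset + 2 * eff.n_levels],
            noise,
        )


def _log_prior_chol(L: np.ndarray, df: float, scale: np.ndarray) -> float:
    """Log density of the inverse-Wishart prior mapped to the Cholesky factor.

    Includes the Jacobian |dG/dL| = 2^p prod l_ii^(p-i+1) for p = 2.
    """
    G = L @ L.T
    return (float(invwishart.logpdf(G, df=df, scale=scale))
            + 2.0 * np.log(L[0, 0]) + np.log(L[1, 1]) + 2.0 * np.log(2.0))


def _asis_rescale(system, eff, theta, e, g0, s2e, rng, pri):
    """Interweaving move: re-sample the G0 scale in the non-centered frame.

    The centered sampler mixes very slowly along flat likelihood ridges that
    exchange variance between effects sharing records (additive vs permanent
    environment).  Whitening the effect (u_i = L eta_i, eta invariant) and
    drawing the 2x2 Cholesky scale L from its conditional -- a 3-parameter
    Gaussian regression, Metropolis-corrected for the inverse-Wishart prior
    and the G = LL' Jacobian -- lets the amplitude jump to the value the data
    support in one move.  The target posterior is unchanged.
    """
    q = eff.n_levels
    sl = slice(eff.offset, eff.offset + 2 * q)
    U = theta[sl].reshape(q, 2).copy()   # copy: theta is overwritten below
    G = g0[eff.name]
    try:
        L = np.linalg.cholesky(G)
    except np.linalg.LinAlgError:
        return False
    if min(L[0, 0], L[1, 1]) < 1e-10:
        return False
    eta = np.linalg.solve(L, U.T).T          # whitened effects, prior free of L
    lev = eff.rec_lev
    phi = system.phi
    # adjusted response: residual plus this effect's current contribution
    contrib = phi[:, 0] * U[lev, 0] + phi[:, 1] * U[lev, 1]
    r = e + contrib
    X = np.column_stack([
        phi[:, 0] * eta[lev, 0],
        phi[:, 1] * eta[lev, 0],
        phi[:, 1] * eta[lev, 1],
    ])
    XtX = X.T @ X
    try:
        C = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return False
    m = C @ (X.T @ r)
    Lc = np.linalg.cholesky(C * s2e)
    beta = m + Lc @ rng.standard_normal(3)
    Lstar = np.array([[beta[0], 0.0], [beta[1], beta[2]]])
    flip0 = Lstar[0, 0] < 0
    flip1 = Lstar[1, 1] < 0
    if flip0:
        Lstar[0, 0] = -Lstar[0, 0]
        Lstar[1, 0] = -Lstar[1, 0]
    if flip1:
        Lstar[1, 1] = -Lstar[1, 1]
    if min(Lstar[0, 0], Lstar[1, 1]) < 1e-10:
        return False
    S0 = pri.g0_scale_matrix(float(np.var(system.y)))
    # independence proposal from the likelihood: Hastings ratio = prior ratio
    log_acc = _log_prior_chol(Lstar, pri.g0_df, S0) - _log_prior_chol(L, pri.g0_df, S0)
    if np.log(rng.uniform()) >= log_acc:
        return False
    if flip0:
        eta[:, 0] = -eta[:, 0]
    if flip1:
        eta[:, 1] = -eta[:, 1]
    U_new = eta @ Lstar.T
    theta[sl] = U_new.ravel()
    e -= (phi[:, 0] * (U_new[lev, 0] - U[lev, 0])
          + phi[:, 1] * (U_new[lev, 1] - U[lev, 1]))
    g0[eff.name] = Lstar @ Lstar.T
    return True


def gibbs_sample(
    system: MixedModelSystem,
    chain: ChainConfig,
    start_g0: dict | None = None,
    start_sigma2_e: float | None = None,
) -> PosteriorSamples:
    """Run the Gibbs sampler and return retained posterior samples."""
    rng = np.random.default_rng(chain.seed)
    pri = chain.priors
    g0 = {eff.name: np.asarray(start_g0[eff.name], dtype=float).copy()
          if start_g0 else np.eye(2) * max(0.1, np.var(system.y) / 4)
          for eff in system.effects}
    s2e = float(start_sigma2_e) if start_sigma2_e else max(0.1, np.var(system.y) / 2)
    g0inv = {k: np.linalg.inv(v) for k, v in g0.items()}
    S0 = pri.g0_scale_matrix(float(np.var(system.y)))

    theta = np.zeros(system.n_coef)
    e = system.y.copy()
    n_keep = chain.n_retained
    kept_g0 = {eff.name: np.empty((n_keep, 2, 2)) for eff in system.effects}
    kept_e = np.empty(n_keep)
    mean = np.zeros(system.n_coef)
    m2 = np.zeros(system.n_coef)
    kept = 0

    for it in range(chain.n_iter):
        z = rng.standard_normal(system.n_coef)
        _sweep(system, theta, e, g0inv, s2e, z, 1.0)
        # variance components
        for eff in system.effects:
            q = eff.n_levels
            U = theta[eff.offset:eff.offset + 2 * q].reshape(q, 2)
            S = U.T @ (eff.kinv @ U) + S0
            try:
                np.linalg.cholesky(S)
            except np.linalg.LinAlgError as err:
                raise RuntimeError(
                    f"non-PD full-conditional scale for {eff.name} at iteration {it}"
                ) from err
            g0[eff.name] = invwishart.rvs(df=q + pri.g0_df, scale=S, random_state=rng)
            g0inv[eff.name] = np.linalg.inv(g0[eff.name])
        for eff in system.effects:
            if _asis_rescale(system, eff, theta, e, g0, s2e, rng, pri):
                g0inv[eff.name] = np.linalg.inv(g0[eff.name])
        sse = float(e @ e)
        s2e = (sse + pri.e_df * pri.e_scale) / rng.chisquare(system.n_records + pri.e_df)

        # keep every thin-th post-burn-in draw: exactly n_retained samples
        if it >= chain.burn_in and (it - chain.burn_in + 1) % chain.thin == 0:
            for eff in system.effects:
                kept_g0[eff.name][kept] = g0[eff.name]
            kept_e[kept] = s2e
            kept += 1
            delta = theta - mean
            mean += delta / kept
            m2 += delta * (theta - mean)

    sd = np.sqrt(m2 / max(kept - 1, 1)) if kept > 1 else np.zeros_like(mean)
    return PosteriorSamples(
        g0={k: v[:kept] for k, v in kept_g0.items()},
        sigma2_e=kept_e[:kept], coef_mean=mean, coef_sd=sd,
        system=system, chain=chain,
    )


def solve_blup(
    system: MixedModelSystem,
    g0: dict,
    sigma2_e: float,
    n_sweeps: int = 2000,
    tol: float = 0.0,
) -> np.ndarray:
    """Gauss-Seidel (noise-free Gibbs) solution with fixed variances.

    Iterates the conditional-mean updates; the fixed point is the direct
    sparse solution of the mixed-model equations.  Stops early when the
    largest coefficient move in a sweep falls below ``tol``.
    """
    g0inv = {k: np.linalg.inv(np.asarray(v, dtype=float)) for k, v in g0.items()}
    theta = np.zeros(system.n_coef)
    e = system.y.copy()
    z = np.zeros(system.n_coef)
    for _ in range(n_sweeps):
        prev = theta.copy()
        _sweep(system, theta, e, g0inv, float(sigma2_e), z, 0.0)
        if tol > 0.0 and np.max(np.abs(theta - prev)) < tol:
            break
    return theta


# ---------------------------------------------------------------------------
# summaries and diagnostics

@dataclass
class VarianceComponents:
    """Posterior mean and SD of every G0 block and the residual variance."""

    mean: dict
    sd: dict
    sigma2_e: float
    sigma2_e_sd: float

    def table(self) -> pd.DataFrame:
        rows = []
        for name, m in self.mean.items():
            s = self.sd[name]
            rows += [
                (f"var_{name}0", m[0, 0], s[0, 0]),
                (f"cov_{name}0{name}1", m[0, 1], s[0, 1]),
                (f"var_{name}1", m[1, 1], s[1, 1]),
            ]
        rows.append(("var_e", self.sigma2_e, self.sigma2_e_sd))
        return pd.DataFrame(rows, columns=["component", "mean", "sd"])


def summarize_posterior(
    samples: PosteriorSamples,
    pedigree: pd.DataFrame | None = None,
    min_retained: int = 50,
) -> tuple[VarianceComponents, pd.DataFrame]:
    """Posterior summaries: variance components and the per-animal GEBV table.

    The GEBV table holds the posterior mean and SD of the additive intercept
    and slope for every animal in the pedigree (plus pe/ce summaries for
    their levels when active, as extra frames in ``attrs``).  When a
    pedigree is passed, per-sire offspring counts are attached.
    """
    if samples.n_retained < min_retained:
        raise ValueError(
            f"only {samples.n_retained} retained samples (< {min_retained}); run a longer chain"
        )
    mean = {k: v.mean(axis=0) for k, v in samples.g0.items()}
    sd = {k: v.std(axis=0, ddof=1) for k, v in samples.g0.items()}
    for m in mean.values():
        m[0, 1] = m[1, 0] = 0.5 * (m[0, 1] + m[1, 0])
    vc = VarianceComponents(
        mean=mean, sd=sd,
        sigma2_e=float(samples.sigma2_e.mean()),
        sigma2_e_sd=float(samples.sigma2_e.std(ddof=1)),
    )
    sys_ = samples.system
    gebv = None
    extras = {}
    for eff in sys_.effects:
        sl = slice(eff.offset, eff.offset + 2 * eff.n_levels)
        em = samples.coef_mean[sl].reshape(-1, 2)
        es = samples.coef_sd[sl].reshape(-1, 2)
        frame = pd.DataFrame({
            "level": eff.levels,
            f"{eff.name}0": em[:, 0], f"{eff.name}0_sd": es[:, 0],
            f"{eff.name}1": em[:, 1], f"{eff.name}1_sd": es[:, 1],
        })
        if eff.name == "a":
            gebv = frame.rename(columns={"level": "animal"})
        else:
            extras[eff.name] = frame
    if gebv is None:
        raise ValueError("no additive effect in the model; GEBV table undefined")
    if pedigree is not None:
        counts = pd.concat([pedigree["sire"], pedigree["dam"]]).value_counts()
        counts = counts.drop(index=0, errors="ignore")
        gebv["n_offspring"] = gebv["animal"].map(counts).fillna(0).astype(int)
    gebv.attrs["extras"] = extras
    return vc, gebv


def convergence_check(samples, min_retained: int = 100) -> pd.DataFrame:
    """Geweke z-score and effective sample size per variance component.

    Accepts :class:`PosteriorSamples`, a DataFrame of scalar chains, or a
    single 1-D chain.  Flags |z| > 2 (first 10% vs last 50% of the chain)
    or ESS < 100.  Report-only: never raises on a bad chain.
    """
    import warnings

    import arviz as az

    if isinstance(samples, PosteriorSamples):
        table = samples.component_table()
    elif isinstance(samples, pd.DataFrame):
        table = samples
    else:
        table = pd.DataFrame({"chain": np.asarray(samples, dtype=float)})
    if len(table) < min_retained:
        raise ValueError(f"need >= {min_retained} retained samples for diagnostics")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, chain in table.items():
            x = chain.to_numpy()
            a = x[: max(2, int(0.1 * len(x)))]
            b = x[int(0.5 * len(x)):]
            ess_a = min(max(float(az.ess(a)), 1.0), len(a))
            ess_b = min(max(float(az.ess(b)), 1.0), len(b))
            se_a = a.std(ddof=1) / np.sqrt(ess_a)
            se_b = b.std(ddof=1) / np.sqrt(ess_b)
            denom = np.sqrt(se_a ** 2 + se_b ** 2)
            z = (a.mean() - b.mean()) / denom if denom > 0 else 0.0
            ess = float(az.ess(x))
            rows.append((name, z, ess, abs(z) > 2.0 or ess < 100.0))
    return pd.DataFrame(rows, columns=["component", "geweke_z", "ess", "flagged"])
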