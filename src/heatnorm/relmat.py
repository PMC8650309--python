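"""Relationship matrices for single-step genomic evaluation.

This module builds every relationship operator used by the mixed model:

* the numerator relationship matrix ``A`` from a pedigree (tabular method),
* inbreeding coefficients ``F`` (Meuwissen & Luo style traversal),
* Henderson's sparse ``A^-1`` with inbreeding,
* the genomic relationship matrix ``G`` (VanRaden method 1) with marker QC,
* the blended matrix ``G_w = alpha*G + beta*A22`` and the single-step
  ``H^-1 = A^-1 + [[0,0],[0, tau*G_w^-1 - omega*A22^-1]]``.

Pedigrees are plain DataFrames with integer columns ``animal``, ``sire``,
``dam`` where 0 denotes an unknown parent.  All dense matrices returned here
follow the (topologically sorted) pedigree row order, or the genotyped-animal
order for the genomic blocks.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "sort_pedigree",
    "compute_inbreeding",
    "tabular_A",
    "ancestor_subset",
    "A22_matrix",
    "build_Ainv",
    "GenotypeMatrix",
    "GenotypeQCReport",
    "qc_genotypes",
    "build_G",
    "blend_G",
    "build_Hinv",
    "RelationshipOperator",
    "build_relationships",
]


# ---------------------------------------------------------------------------
# pedigree handling

def sort_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the pedigree sorted parents-first (Kahn's algorithm).

    Raises ``ValueError`` on cycles or on parents that are missing from the
    ``animal`` column.
    """
    animals = ped["animal"].to_numpy()
    if len(np.unique(animals)) != len(animals):
        raise ValueError("duplicate animal ids in pedigree")
    known = set(int(a) for a in animals)
    for col in ("sire", "dam"):
        parents = set(int(p) for p in ped[col].to_numpy() if p != 0)
        missing = parents - known
        if missing:
            raise ValueError(f"{col}s not in pedigree: {sorted(missing)[:5]}")

    pos = {int(a): i for i, a in enumerate(animals)}
    sire = ped["sire"].to_numpy()
    dam = ped["dam"].to_numpy()
    n = len(animals)
    indeg = np.zeros(n, dtype=np.int64)
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p != 0:
                j = pos[int(p)]
                children[j].append(i)
                indeg[i] += 1
    order: list[int] = []
    ready = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(ready)
    while ready:
        i = heapq.heappop(ready)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, c)
    if len(order) != n:
        raise ValueError("pedigree contains a cycle")
    return ped.iloc[order].reset_index(drop=True)


def _codes(ped: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    """0-based sire/dam index arrays (-1 = unknown) for a sorted pedigree."""
    ids = pd.Index(ped["animal"].astype(np.int64))
    pos = {int(a): i for i, a in enumerate(ids)}
    sire = np.array([pos[int(s)] if s != 0 else -1 for s in ped["sire"]], dtype=np.int64)
    dam = np.array([pos[int(d)] if d != 0 else -1 for d in ped["dam"]], dtype=np.int64)
    if np.any(sire >= np.arange(len(ids))) or np.any(dam >= np.arange(len(ids))):
        raise ValueError("pedigree is not sorted parents-first")
    return sire, dam, ids


def _mendelian_d(sire: np.ndarray, dam: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Within-family (Mendelian sampling) variance coefficients d_i."""
    n = len(sire)
    d = np.ones(n)
    both = (sire >= 0) & (dam >= 0)
    d[both] = 0.5 - 0.25 * (F[sire[both]] + F[dam[both]])
    only_s = (sire >= 0) & (dam < 0)
    d[only_s] = 0.75 - 0.25 * F[sire[only_s]]
    only_d = (sire < 0) & (dam >= 0)
    d[only_d] = 0.75 - 0.25 * F[dam[only_d]]
    return d


def compute_inbreeding(ped: pd.DataFrame) -> pd.Series:
    """Inbreeding coefficients by the Meuwissen & Luo traversal.

    Equals ``diag(A) - 1`` from the tabular method.  Animals with at least
    one unknown parent get F = 0.
    """
    sped = sort_pedigree(ped)
    sire, dam, ids = _codes(sped)
    n = len(ids)
    F = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        D[i] = _mendelian_d(sire[i : i + 1], dam[i : i + 1], F)[0]
        if sire[i] < 0 or dam[i] < 0:
            continue
        # back-trace the L row of animal i over its ancestors
        L: dict[int, float] = {i: 1.0}
        heap = [-i]
        in_heap = {i}
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            in_heap.discard(j)
            lj = L.pop(j)
            aii += lj * lj * D[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    L[p] = L.get(p, 0.0) + 0.5 * lj
                    if p not in in_heap:
                        heapq.heappush(heap, -p)
                        in_heap.add(p)
        F[i] = aii - 1.0
    out = pd.Series(F, index=ids, name="F")
    return out.reindex(ped["animal"].astype(np.int64)).set_axis(ped["animal"])


def tabular_A(ped: pd.DataFrame) -> np.ndarray:
    """Dense numerator relationship matrix by the recursive tabular method.

    Rows follow the parents-first sort of the input; use it at desk scale
    (a few thousand animals) only.
    """
    sped = sort_pedigree(ped)
    sire, dam, _ = _codes(sped)
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0:
            A[i, :i] = 0.5 * A[s, :i]
            A[i, i] = 1.0
        elif d >= 0:
            A[i, :i] = 0.5 * A[d, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return A


def ancestor_subset(ped: pd.DataFrame, ids) -> pd.DataFrame:
    """Restrict a pedigree to ``ids`` and all of their ancestors."""
    pos = {int(a): i for i, a in enumerate(ped["animal"])}
    sire = ped["sire"].to_numpy()
    dam = ped["dam"].to_numpy()
    keep: set[int] = set()
    stack = [pos[int(a)] for a in ids]
    while stack:
        i = stack.pop()
        if i in keep:
            continue
        keep.add(i)
        for p in (sire[i], dam[i]):
            if p != 0:
                stack.append(pos[int(p)])
    return ped.iloc[sorted(keep)].reset_index(drop=True)


def A22_matrix(ped: pd.DataFrame, genotyped_ids) -> np.ndarray:
    """Pedigree relationship matrix restricted to the genotyped animals.

    Computed by the tabular method on the ancestor-restricted pedigree and
    sliced to ``genotyped_ids`` (in that order).
    """
    sub = sort_pedigree(ancestor_subset(ped, genotyped_ids))
    A = tabular_A(sub)
    pos = {int(a): i for i, a in enumerate(sub["animal"])}
    idx = np.array([pos[int(g)] for g in genotyped_ids])
    return A[np.ix_(idx, idx)]


def build_Ainv(ped: pd.DataFrame, F: pd.Series | None = None) -> sp.csr_matrix:
    """Sparse inverse of A by Henderson's rules with inbreeding.

    Row/column order follows the parents-first sort of ``ped`` (the order
    returned by :func:`sort_pedigree`).
    """
    sped = sort_pedigree(ped)
    sire, dam, ids = _codes(sped)
    if F is None:
        Fv = compute_inbreeding(sped).to_numpy()
    else:
        Fv = F.reindex(ids).to_numpy()
    d = _mendelian_d(sire, dam, Fv)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(len(ids)):
        b = 1.0 / d[i]
        parents = [p for p in (sire[i], dam[i]) if p >= 0]
        rows.append(i)
        cols.append(i)
        vals.append(b)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * b, -0.5 * b]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(0.25 * b)
    n = len(ids)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


# ---------------------------------------------------------------------------
# genomic relationships

@dataclass
class GenotypeMatrix:
    """Allele-count matrix (animals x SNPs), 0/1/2 with NaN for missing."""

    animals: pd.Index
    snps: pd.Index
    calls: np.ndarray

    def __post_init__(self):
        self.animals = pd.Index(self.animals)
        self.snps = pd.Index(self.snps)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.animals), len(self.snps)):
            raise ValueError("calls shape does not match animal/snp ids")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(df.index, df.columns, df.to_numpy(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.animals, columns=self.snps)

    def allele_frequencies(self) -> np.ndarray:
        return np.nanmean(self.calls, axis=0) / 2.0


@dataclass
class GenotypeQCReport:
    n_animals_in: int = 0
    n_snps_in: int = 0
    animals_call_rate: int = 0
    snps_call_rate: int = 0
    snps_maf: int = 0
    snps_het_deviation: int = 0
    n_animals_out: int = 0
    n_snps_out: int = 0


def qc_genotypes(
    geno: GenotypeMatrix,
    min_animal_call: float = 0.90,
    min_snp_call: float = 0.90,
    min_maf: float = 0.01,
    max_het_dev: float = 0.15,
) -> tuple[GenotypeMatrix, GenotypeQCReport]:
    """Marker and sample QC preceding G construction.

    Drops animals with call rate < ``min_animal_call``; then SNPs with call
    rate < ``min_snp_call``, minor allele frequency < ``min_maf``, or absolute
    deviation between observed and expected (2p(1-p)) heterozygote frequency
    >= ``max_het_dev``.  Surviving missing calls are imputed with the SNP
    mean (2p), which contributes zero after centring.
    """
    calls = geno.calls
    rep = GenotypeQCReport(n_animals_in=calls.shape[0], n_snps_in=calls.shape[1])

    a_call = np.mean(~np.isnan(calls), axis=1)
    keep_a = a_call >= min_animal_call
    rep.animals_call_rate = int(np.sum(~keep_a))
    calls = calls[keep_a]

    with np.errstate(invalid="ignore"):
        s_call = np.mean(~np.isnan(calls), axis=0)
        p = np.nanmean(calls, axis=0) / 2.0
        maf = np.minimum(p, 1.0 - p)
        het_obs = np.nanmean(calls == 1.0, axis=0)
        het_dev = np.abs(het_obs - 2.0 * p * (1.0 - p))
    bad_call = s_call < min_snp_call
    bad_maf = ~bad_call & (np.nan_to_num(maf) < min_maf)
    bad_het = ~bad_call & ~bad_maf & (het_dev >= max_het_dev)
    rep.snps_call_rate = int(bad_call.sum())
    rep.snps_maf = int(bad_maf.sum())
    rep.snps_het_deviation = int(bad_het.sum())
    keep_s = ~(bad_call | bad_maf | bad_het)
    if not keep_s.any():
        raise ValueError("genotype QC removed every SNP")
    calls = calls[:, keep_s]

    # mean imputation of surviving missing calls
    p2 = np.nanmean(calls, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(calls))
    calls = calls.copy()
    calls[nan_r, nan_c] = p2[nan_c]

    rep.n_animals_out = calls.shape[0]
    rep.n_snps_out = calls.shape[1]
    out = GenotypeMatrix(geno.animals[keep_a], geno.snps[keep_s], calls)
    return out, rep


def build_G(geno: GenotypeMatrix) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    ``G = ZZ' / (2 * sum p_j (1-p_j))`` with Z column-centred at 2p, allele
    frequencies observed in the genotyped set.
    """
    calls = geno.calls
    if np.isnan(calls).any():
        raise ValueError("missing genotypes: run qc_genotypes first")
    p = calls.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0.0:
        raise ValueError("all SNPs are monomorphic: sum 2p(1-p) = 0")
    Z = calls - 2.0 * p
    return (Z @ Z.T) / denom


def blend_G(G: np.ndarray, A22: np.ndarray, alpha: float = 0.95, beta: float = 0.05) -> np.ndarray:
    """Weighted blend ``alpha*G + beta*A22`` guaranteeing invertibility."""
    return alpha * G + beta * A22


def build_Hinv(
    Ainv: sp.spmatrix,
    A22: np.ndarray,
    Gw: np.ndarray,
    genotyped_pos: np.ndarray,
    tau: float = 1.0,
    omega: float = 1.0,
) -> sp.csr_matrix:
    """Single-step inverse ``H^-1 = A^-1 + [[0,0],[0, tau*Gw^-1 - omega*A22^-1]]``.

    ``genotyped_pos`` gives the positions of the genotyped animals within the
    row order of ``Ainv``.  With no genotyped animals the result is ``A^-1``
    exactly.
    """
    Ainv = sp.csr_matrix(Ainv)
    genotyped_pos = np.asarray(genotyped_pos, dtype=np.int64)
    if genotyped_pos.size == 0:
        return Ainv.copy()
    try:
        Gw_inv = np.linalg.inv(Gw)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            f"blended G is singular (cond={np.linalg.cond(Gw):.3e}); "
            "increase the A22 blending weight"
        ) from err
    corr = tau * Gw_inv - omega * np.linalg.inv(A22)
    g = len(genotyped_pos)
    rows = np.repeat(genotyped_pos, g)
    cols = np.tile(genotyped_pos, g)
    block = sp.coo_matrix((corr.ravel(), (rows, cols)), shape=Ainv.shape)
    return (Ainv + block.tocsr()).tocsr()


# ---------------------------------------------------------------------------
# convenience bundle

@dataclass
class RelationshipOperator:
    """All relationship operators of one single-step evaluation."""

    animals: pd.Index                      # pedigree order of Ainv / Hinv rows
    pedigree: pd.DataFrame                 # sorted parents-first
    F: pd.Series
    Ainv: sp.csr_matrix
    Hinv: sp.csr_matrix
    genotyped: pd.Index = field(default_factory=lambda: pd.Index([]))
    G: np.ndarray | None = None
    A22: np.ndarray | None = None
    Gw: np.ndarray | None = None
    qc_report: GenotypeQCReport | None = None
    tau: float = 1.0
    omega: float = 1.0
    alpha: float = 0.95
    beta: float = 0.05


def build_relationships(
    ped: pd.DataFrame,
    geno: GenotypeMatrix | None = None,
    tau: float = 1.0,
    omega: float = 1.0,
    alpha: float = 0.95,
    beta: float = 0.05,
    qc: bool = True,
) -> RelationshipOperator:
    """Build A^-1 (and H^-1 when genotypes are supplied) for a pedigree."""
    sped = sort_pedigree(ped)
    F = compute_inbreeding(sped)
    Ainv = build_Ainv(sped, F=F)
    ids = pd.Index(sped["animal"].astype(np.int64))
    if geno is None or len(geno.animals) == 0:
        return RelationshipOperator(
            animals=ids, pedigree=sped, F=F, Ainv=Ainv, Hinv=Ainv.copy(),
            tau=tau, omega=omega, alpha=alpha, beta=beta,
        )
    report = None
    if qc:
        geno, report = qc_genotypes(geno)
    missing = pd.Index(geno.animals).difference(ids)
    if len(missing):
        raise KeyError(f"genotyped animals absent from pedigree: {list(missing[:5])}")
    G = build_G(geno)
    A22 = A22_matrix(sped, geno.animals)
    Gw = blend_G(G, A22, alpha=alpha, beta=beta)
    pos = ids.get_indexer(pd.Index(geno.animals))
    Hinv = build_Hinv(Ainv, A22, Gw, pos, tau=tau, omega=omega)
    return RelationshipOperator(
        animals=ids, pedigree=sped, F=F, Ainv=Ainv, Hinv=Hinv,
        genotyped=pd.Index(geno.animals), G=G, A22=A22, Gw=Gw,
        qc_report=report, tau=tau, omega=omega, alpha=alpha, beta=beta,
    )
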