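"""Plain-text readers/writers for the pipeline's file interfaces."""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .relmat import GenotypeMatrix

__all__ = [
    "read_pedigree", "write_pedigree", "read_genotypes", "write_genotypes",
    "read_weather", "write_weather", "read_phenotypes", "write_phenotypes",
    "write_sparse_lower",
]


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path)
    for col in ("animal", "sire", "dam"):
        ped[col] = ped[col].astype(np.int64)
    return ped


def write_pedigree(ped: pd.DataFrame, path) -> None:
    ped.to_csv(path, index=False)


def read_genotypes(path) -> GenotypeMatrix:
    """Animal x SNP table of 0/1/2 calls (TSV, first column = animal id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix.from_frame(df)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    df = geno.to_frame()
    df.index.name = "animal"
    df.to_csv(path, sep="\t", float_format="%g")


def read_weather(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])


def write_weather(weather: pd.DataFrame, path) -> None:
    weather.to_csv(path, index=False, float_format="%.3f")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("measurement", "breeding", "farrowing", "weaning"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


def write_sparse_lower(mat: sp.spmatrix, path) -> None:
    """Lower-triangle coordinate text export (i, j, value), 1-based."""
    coo = sp.coo_matrix(sp.tril(mat))
    out = pd.DataFrame({"i": coo.row + 1, "j": coo.col + 1, "value": coo.data})
    out.to_csv(Path(path), sep="\t", index=False, float_format="%.10g")
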