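"""Clade-frequency tables for East Asian Y-chromosome populations.

A clade table holds, for each population (column), the relative frequency of
each of the seven Y-chromosome clades observed in the mainland Japanese
sample (rows ``clade1`` .. ``clade7``).  Published tables of this kind carry
rounding error and occasionally unassigned chromosomes, so columns are used
exactly as printed and are *not* renormalised.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

#: Canonical clade identifiers, in order.
CLADE_LABELS: tuple[str, ...] = tuple(f"clade{i}" for i in range(1, 8))


def read_clade_table(path, tol: float = 0.05) -> pd.DataFrame:
    """Read a TSV clade table (clade rows x population columns).

    Parameters
    ----------
    path
        TSV file whose first column is the clade label.
    tol
        Maximum tolerated deviation of any population column sum from 1.
        Published frequency columns can fall short of 1 when some
        chromosomes were left unassigned, hence the loose default.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_clade_table(df, tol=tol)
    return df


def validate_clade_table(df: pd.DataFrame, tol: float = 0.05) -> None:
    if (df.values < 0).any():
        raise ValueError("clade frequencies must be non-negative")
    sums = df.sum(axis=0)
    bad = sums[(sums - 1.0).abs() > tol]
    if not bad.empty:
        raise ValueError(
            f"population columns do not sum to 1 within {tol}: {dict(bad)}"
        )


def east_asian_clade_table(tol: float = 0.05) -> pd.DataFrame:
    """The packaged seven-clade frequency table for East Asian populations.

    Columns: Mainland Japanese, Korean, JPT, CHB, CHS, CDX, KHV.  The
    Mainland Japanese column plays the role of the admixed population and
    the Korean column the role of the continental (Yayoi-immigrant) source
    in the admixture Monte Carlo.
    """
    ref = importlib.resources.files("ydemos") / "data" / "east_asian_clades.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_clade_table(path, tol=tol)


def frequency_vector(df: pd.DataFrame, population: str) -> np.ndarray:
    """Extract one population column as a length-7 float vector."""
    if population not in df.columns:
        raise KeyError(f"unknown population {population!r}")
    v = df[population].to_numpy(dtype=float)
    if v.shape != (7,):
        raise ValueError("clade table must have exactly 7 clade rows")
    return v
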