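"""Readers and writers for the pipeline's tabular artifacts.

Conventions
-----------
* Frequency tables: long CSV (population, locus, allele, frequency), wide
  CSV/XLSX (population index × ``locus.allele`` dotted columns).
* Peak tables: CSV with bulk_id, locus, size_bp, height and an optional
  quality column — the shape of a Genotyper-style fragment export.
* Genotypes: CSV with population, individual, locus, allele1, allele2.
* Distance matrices: square labeled CSV. Trees: newick.

All writers round-trip through the matching reader to 1e-9 per cell.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .freqtable import FrequencyTable
from .loci import LocusDef, read_locus_defs, write_locus_defs

__all__ = [
    "read_locus_defs",
    "write_locus_defs",
    "read_frequency_table",
    "write_frequency_table",
    "read_peak_table",
    "write_peak_table",
    "read_genotypes",
    "write_genotypes",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_q_matrix",
    "write_q_matrix",
    "read_newick",
    "write_newick",
]

logger = logging.getLogger("bulkpop")

_LONG_COLS = {"population", "locus", "allele", "frequency"}
_PEAK_COLS = {"bulk_id", "locus", "size_bp", "height"}


def _read_tabular(path, sheet: str | int | None) -> pd.DataFrame:
    if str(path).lower().endswith((".xlsx", ".xls")):
        return pd.read_excel(path, sheet_name=sheet if sheet is not None else 0)
    return pd.read_csv(path)


def read_frequency_table(
    path,
    locus_defs: dict[str, LocusDef] | None = None,
    sheet: str | int | None = None,
    norm_tol: float = 0.02,
) -> FrequencyTable:
    """Read a frequency table, auto-detecting long vs wide layout.

    Long layout has the columns population/locus/allele/frequency; anything
    else is treated as wide, with the first column naming populations and the
    remaining headers dotted ``locus.allele``.

    Cells whose frequencies sum within ``1 ± norm_tol`` are renormalized;
    sums outside the tolerance raise (they indicate corrupted rows, not
    rounding). When ``locus_defs`` is given, loci must be known and allele
    sizes must fall inside each locus' size range (± one repeat unit).
    """
    df = _read_tabular(path, sheet)
    if _LONG_COLS <= set(df.columns):
        df = df.dropna(subset=["frequency"])
        table = FrequencyTable.from_long_df(df, norm_tol=norm_tol)
    else:
        table = _wide_to_table(df, norm_tol)
    if locus_defs is not None:
        _validate_against_loci(table, locus_defs)
    return table


def _wide_to_table(df: pd.DataFrame, norm_tol: float) -> FrequencyTable:
    df = df.set_index(df.columns[0])
    data: dict[str, dict[str, dict[int, float]]] = {}
    parsed: list[tuple[str, int]] = []
    for col in df.columns:
        locus, _, allele = str(col).rpartition(".")
        if not locus:
            raise ValueError(f"wide column {col!r} is not 'locus.allele'")
        parsed.append((locus, int(float(allele))))
    for pop, row in df.iterrows():
        per: dict[str, dict[int, float]] = {}
        for (locus, allele), val in zip(parsed, row.to_numpy()):
            if pd.isna(val):
                continue
            per.setdefault(locus, {})[allele] = float(val)
        data[str(pop)] = per
    return FrequencyTable(data, norm_tol=norm_tol)


def _validate_against_loci(table: FrequencyTable, locus_defs: dict[str, LocusDef]) -> None:
    for locus in table.loci:
        if locus not in locus_defs:
            raise ValueError(f"unknown locus {locus!r} in frequency table")
        ld = locus_defs[locus]
        for a in table.alleles(locus):
            if not ld.contains(a):
                raise ValueError(
                    f"allele {a} bp outside the size range of locus {locus}"
                )


def write_frequency_table(table: FrequencyTable, path, layout: str = "long") -> None:
    if layout == "long":
        df = table.to_long_df()
        df["frequency"] = df["frequency"].map(lambda f: f"{f:.9f}")
        df.to_csv(path, index=False)
    elif layout == "wide":
        table.to_wide_df().to_csv(path, float_format="%.9f")
    else:
        raise ValueError(f"unknown layout {layout!r}")


# -- peak tables -----------------------------------------------------------


def read_peak_table(path, locus_defs: dict[str, LocusDef]) -> pd.DataFrame:
    """Read a raw fragment/peak table and apply coarse sanity filters.

    Rows with non-positive height are dropped (count logged). Rows whose
    size lies outside the locus range ± one repeat unit are dropped with a
    warning — they cannot be alleles of that locus. Unknown loci or
    unparseable numbers raise with the offending line number.
    """
    df = pd.read_csv(path)
    missing = _PEAK_COLS - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    if "quality" not in df.columns:
        df["quality"] = np.nan
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            float(row.size_bp), float(row.height)
        except (TypeError, ValueError):
            raise ValueError(f"malformed peak row at line {i}: {row!r}") from None
        if str(row.locus) not in locus_defs:
            raise ValueError(f"unknown locus {row.locus!r} at line {i}")
    df = df.astype({"size_bp": float, "height": float, "quality": float})

    nonpos = df["height"] <= 0
    if nonpos.any():
        logger.info("dropping %d peaks with non-positive height", int(nonpos.sum()))
        df = df[~nonpos]
    in_range = df.apply(
        lambda r: locus_defs[str(r["locus"])].contains(r["size_bp"]), axis=1
    )
    if not in_range.all():
        logger.warning(
            "dropping %d peaks outside locus size ranges", int((~in_range).sum())
        )
        df = df[in_range]
    return df.reset_index(drop=True)


def write_peak_table(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, index=False, float_format="%.6f")


# -- genotype matrices -----------------------------------------------------

_GENO_COLS = ["population", "individual", "locus", "allele1", "allele2"]


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_GENO_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"genotype table missing columns: {sorted(missing)}")
    return df[_GENO_COLS].astype(
        {"population": str, "individual": int, "locus": str, "allele1": int, "allele2": int}
    )


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    genotypes[_GENO_COLS].to_csv(path, index=False)


# -- distance matrices, Q matrices, trees ----------------------------------


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, float_format="%.9f"
    )


def read_q_matrix(path) -> pd.DataFrame:
    """Ancestry (Q) matrix: population index × cluster columns, rows sum to 1."""
    df = pd.read_csv(path, index_col=0)
    sums = df.sum(axis=1)
    bad = sums[(sums - 1.0).abs() > 1e-6]
    if len(bad):
        raise ValueError(f"Q rows do not sum to 1: {list(bad.index)}")
    df.index = df.index.astype(str)
    return df


def write_q_matrix(q: pd.DataFrame, path) -> None:
    q.to_csv(path, float_format="%.9f")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_newick(tree: TreeNode, path=None) -> str:
    text = str(tree)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
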