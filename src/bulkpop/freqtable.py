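"""Population × locus × allele frequency table — the pipeline's central object.

Each (population, locus) cell holds a map from allele size (bp, int) to a
relative frequency; cells sum to one. A missing (population, locus) pair is
simply absent — never encoded as a row of zeros, because zero is a valid
observed frequency.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["FrequencyTable"]

_SUM_TOL = 1e-9


class FrequencyTable:
    """Allele frequency profiles for a set of populations over shared loci.

    Parameters
    ----------
    data : mapping
        ``{population: {locus: {allele_size: frequency}}}``. Cells must sum
        to one within ``norm_tol``; sums inside the tolerance are
        renormalized, sums outside raise.
    populations, loci : sequence of str, optional
        Explicit orderings; default is insertion order of ``data``.
    norm_tol : float
        Half-width of the acceptable deviation of each cell's sum from 1
        (default 0.02, matching the rounding seen in exported spreadsheets).
    """

    def __init__(
        self,
        data: Mapping[str, Mapping[str, Mapping[int, float]]],
        populations: Iterable[str] | None = None,
        loci: Iterable[str] | None = None,
        norm_tol: float = 0.02,
    ) -> None:
        self._cells: dict[tuple[str, str], dict[int, float]] = {}
        pops = list(populations) if populations is not None else list(data)
        locus_order: list[str] = list(loci) if loci is not None else []
        for pop, per_locus in data.items():
            for locus, freqs in per_locus.items():
                if loci is None and locus not in locus_order:
                    locus_order.append(locus)
                cell = {int(a): float(f) for a, f in freqs.items()}
                if not cell:
                    continue  # empty cell == missing
                for a, f in cell.items():
                    if f < 0:
                        raise ValueError(
                            f"negative frequency {f} for allele {a} at ({pop}, {locus})"
                        )
                total = sum(cell.values())
                if abs(total - 1.0) > norm_tol:
                    raise ValueError(
                        f"frequencies at ({pop}, {locus}) sum to {total:.4f}, "
                        f"outside 1 ± {norm_tol}"
                    )
                if abs(total - 1.0) > _SUM_TOL:
                    cell = {a: f / total for a, f in cell.items()}
                self._cells[(pop, locus)] = cell
        self.populations: list[str] = pops
        self.loci: list[str] = locus_order

    # -- accessors ---------------------------------------------------------

    def freq(self, pop: str, locus: str) -> dict[int, float]:
        """Allele→frequency map for one cell (KeyError if missing)."""
        return dict(self._cells[(pop, locus)])

    def get(self, pop: str, locus: str) -> dict[int, float] | None:
        cell = self._cells.get((pop, locus))
        return dict(cell) if cell is not None else None

    def is_missing(self, pop: str, locus: str) -> bool:
        return (pop, locus) not in self._cells

    def loci_of(self, pop: str) -> list[str]:
        return [l for l in self.loci if (pop, l) in self._cells]

    def alleles(self, locus: str) -> list[int]:
        """Sorted union of allele sizes seen at a locus across populations."""
        out: set[int] = set()
        for (p, l), cell in self._cells.items():
            if l == locus:
                out.update(cell)
        return sorted(out)

    def subset(self, populations: Iterable[str]) -> "FrequencyTable":
        pops = list(populations)
        unknown = set(pops) - set(self.populations)
        if unknown:
            raise KeyError(f"unknown populations: {sorted(unknown)}")
        data = {
            p: {l: self._cells[(p, l)] for l in self.loci if (p, l) in self._cells}
            for p in pops
        }
        return FrequencyTable(data, populations=pops, loci=self.loci)

    def __len__(self) -> int:
        return len(self.populations)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyTable):
            return NotImplemented
        return self.allclose(other, atol=0.0)

    def allclose(self, other: "FrequencyTable", atol: float = 1e-9) -> bool:
        if set(self._cells) != set(other._cells):
            return False
        for key, cell in self._cells.items():
            oth = other._cells[key]
            if set(cell) != set(oth):
                return False
            for a, f in cell.items():
                if abs(f - oth[a]) > atol:
                    return False
        return True

    # -- conversions -------------------------------------------------------

    def to_long_df(self) -> pd.DataFrame:
        rows = [
            {"population": p, "locus": l, "allele": a, "frequency": f}
            for (p, l), cell in sorted(self._cells.items())
            for a, f in sorted(cell.items())
        ]
        return pd.DataFrame(rows, columns=["population", "locus", "allele", "frequency"])

    def to_wide_df(self) -> pd.DataFrame:
        """Population × 'locus.allele' matrix (the spreadsheet layout)."""
        cols: list[str] = []
        for l in self.loci:
            cols.extend(f"{l}.{a}" for a in self.alleles(l))
        mat = pd.DataFrame(np.nan, index=self.populations, columns=cols)
        for (p, l), cell in self._cells.items():
            for a, f in cell.items():
                mat.loc[p, f"{l}.{a}"] = f
        mat.index.name = "population"
        return mat

    @classmethod
    def from_long_df(
        cls, df: pd.DataFrame, norm_tol: float = 0.02
    ) -> "FrequencyTable":
        data: dict[str, dict[str, dict[int, float]]] = {}
        for row in df.itertuples(index=False):
            data.setdefault(str(row.population), {}).setdefault(str(row.locus), {})[
                int(row.allele)
            ] = float(row.frequency)
        return cls(data, norm_tol=norm_tol)

    def mean_profile(
        self, populations: Iterable[str] | None = None
    ) -> dict[str, dict[int, float]]:
        """Unweighted mean allele frequencies across populations, per locus.

        Populations missing a locus are excluded from that locus' mean
        (pairwise deletion); loci missing everywhere are omitted.
        """
        pops = list(populations) if populations is not None else self.populations
        out: dict[str, dict[int, float]] = {}
        for locus in self.loci:
            cells = [self._cells[(p, locus)] for p in pops if (p, locus) in self._cells]
            if not cells:
                continue
            acc: dict[int, float] = {}
            for cell in cells:
                for a, f in cell.items():
                    acc[a] = acc.get(a, 0.0) + f
            out[locus] = {a: s / len(cells) for a, s in acc.items()}
        return out
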