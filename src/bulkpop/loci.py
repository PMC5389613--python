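"""SSR locus definitions and the integer allele-size ladder.

A microsatellite (SSR) locus is scored by fragment length in base pairs.
True alleles sit on a ladder ``size_min + k * repeat_unit``; observed peak
sizes are real-valued and are snapped to the nearest rung.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LocusDef", "read_locus_defs", "write_locus_defs"]


@dataclass(frozen=True)
class LocusDef:
    """One SSR locus: name, genome location, repeat unit and allele size range.

    Parameters
    ----------
    name : str
        Marker name (e.g. ``phi96100``).
    genome_bin : str
        Chromosome.bin location, informational only.
    repeat_unit : int
        Repeat motif length in bp (di-/tri-/tetra-nucleotide SSRs are
        typical, but any positive integer is accepted).
    size_min, size_max : int
        Smallest and largest allele size in bp over the dataset.
    """

    name: str
    genome_bin: str
    repeat_unit: int
    size_min: int
    size_max: int

    def __post_init__(self) -> None:
        if self.repeat_unit <= 0:
            raise ValueError(f"locus {self.name}: repeat_unit must be > 0")
        if not self.size_min < self.size_max:
            raise ValueError(f"locus {self.name}: need size_min < size_max")

    @property
    def n_rungs(self) -> int:
        return (self.size_max - self.size_min) // self.repeat_unit + 1

    def ladder(self) -> np.ndarray:
        """Integer allele ladder size_min, size_min+unit, ... ≤ size_max."""
        return self.size_min + self.repeat_unit * np.arange(self.n_rungs)

    def snap(self, size_bp: float) -> int:
        """Nearest ladder rung for an observed fragment size.

        Equidistant observations break toward the lower rung, so the result
        is deterministic on half-unit boundaries.
        """
        k = (size_bp - self.size_min) / self.repeat_unit
        idx = math.ceil(k - 0.5)  # round half *down*
        idx = min(max(idx, 0), self.n_rungs - 1)
        return int(self.size_min + idx * self.repeat_unit)

    def contains(self, size_bp: float, slack: float | None = None) -> bool:
        """Whether a raw size is plausibly an allele of this locus.

        ``slack`` defaults to one repeat unit on either side of the range.
        """
        s = self.repeat_unit if slack is None else slack
        return self.size_min - s <= size_bp <= self.size_max + s


def read_locus_defs(path) -> dict[str, LocusDef]:
    """Read locus metadata from CSV with columns
    name, genome_bin, repeat_unit, size_min, size_max."""
    df = pd.read_csv(path)
    required = {"name", "repeat_unit", "size_min", "size_max"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"locus file missing columns: {sorted(missing)}")
    out: dict[str, LocusDef] = {}
    for row in df.itertuples(index=False):
        out[str(row.name)] = LocusDef(
            name=str(row.name),
            genome_bin=str(getattr(row, "genome_bin", "")),
            repeat_unit=int(row.repeat_unit),
            size_min=int(row.size_min),
            size_max=int(row.size_max),
        )
    return out


def write_locus_defs(loci: dict[str, LocusDef], path) -> None:
    pd.DataFrame(
        [
            {
                "name": l.name,
                "genome_bin": l.genome_bin,
                "repeat_unit": l.repeat_unit,
                "size_min": l.size_min,
                "size_max": l.size_max,
            }
            for l in loci.values()
        ]
    ).to_csv(path, index=False)
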