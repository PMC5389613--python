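"""Diploid pseudo-individuals from bulk allele frequencies.

Population bulks yield frequencies, but genotype-based software needs
individuals. This module deterministically apportions 2N allele copies to
match the bulk frequencies (largest-remainder rule), then pairs them into N
diploids whose realized heterozygosity is pushed within a tolerance of the
Hardy-Weinberg expectation 1 − Σ p̂² by swap repair. Pairing never changes
allele counts, so the simulated sample reproduces the bulk frequencies to
within 1/(2N) per allele by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .freqtable import FrequencyTable

__all__ = [
    "SimulationParams",
    "allocate_allele_copies",
    "pair_into_genotypes",
    "simulate_individuals",
    "frequencies_from_genotypes",
]

logger = logging.getLogger("bulkpop")


@dataclass(frozen=True)
class SimulationParams:
    """Knobs for pseudo-individual construction.

    n_individuals : int
        Diploids per population (default 15, the bulk size used in
        population-level SSR genotyping).
    het_tolerance : float
        Acceptable |realized − expected| heterozygosity per locus.
    max_repair_iters : int
        Cap on swap-repair steps before returning the best achieved.
    """

    n_individuals: int = 15
    seed: int = 0
    het_tolerance: float = 0.05
    max_repair_iters: int = 1000

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be ≥ 1")


def allocate_allele_copies(freqs: dict[int, float], n: int) -> dict[int, int]:
    """Integer copy numbers for 2n allele copies matching the frequencies.

    Largest-remainder (Hamilton) apportionment: each allele gets the floor
    of its quota ``2n·p``, and leftover copies go to the largest fractional
    remainders. Ties break toward the larger quota, then the smaller allele
    size, so the result is deterministic. Every count is within one copy of
    its quota.
    """
    total = 2 * n
    alleles = sorted(freqs)
    quotas = {a: total * freqs[a] for a in alleles}
    counts = {a: math.floor(quotas[a] + 1e-9) for a in alleles}
    leftover = total - sum(counts.values())
    order = sorted(
        alleles, key=lambda a: (-(quotas[a] - counts[a]), -quotas[a], a)
    )
    for a in order[:leftover]:
        counts[a] += 1
    return counts


def _heterozygosity(pairs: list[list[int]]) -> float:
    return sum(1 for a, b in pairs if a != b) / len(pairs)


def pair_into_genotypes(
    copies: dict[int, int],
    params: SimulationParams | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """Pair 2n allele copies into n diploid genotypes, matching H-W heterozygosity.

    Copies are shuffled (seeded) and paired; if the realized heterozygosity
    deviates from ``1 − Σ p̂²`` (p̂ from the apportioned counts) by more than
    ``het_tolerance``, alleles are exchanged between genotypes — raising or
    lowering the heterozygote count one swap at a time — until within
    tolerance or the iteration cap, whichever comes first. Swaps conserve
    allele counts exactly.
    """
    params = params or SimulationParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pool = [a for a, c in copies.items() for _ in range(c)]
    if len(pool) % 2:
        raise ValueError("total allele copies must be even")
    n = len(pool) // 2
    rng.shuffle(pool)
    pairs = [[pool[2 * i], pool[2 * i + 1]] for i in range(n)]

    total = float(len(pool))
    expected = 1.0 - sum((c / total) ** 2 for c in copies.values())
    prev_h: float | None = None
    prev_dir = 0
    snapshot: list[list[int]] | None = None
    for _ in range(params.max_repair_iters):
        h = _heterozygosity(pairs)
        if abs(h - expected) <= params.het_tolerance + 1e-12:
            break
        direction = 1 if h < expected else -1
        if prev_dir and direction != prev_dir:
            # swaps straddle the target (e.g. a parity constraint forbids
            # hitting it); keep the closer of the two neighboring states
            if prev_h is not None and abs(prev_h - expected) < abs(h - expected):
                pairs = snapshot  # type: ignore[assignment]
            break
        snapshot = [row[:] for row in pairs]
        moved = _raise_het(pairs) if direction > 0 else _lower_het(pairs)
        if not moved:
            break
        prev_h, prev_dir = h, direction
    if abs(_heterozygosity(pairs) - expected) > params.het_tolerance + 1e-12:
        logger.warning(
            "heterozygosity target %.3f unreachable for counts %s; best %.3f",
            expected,
            copies,
            _heterozygosity(pairs),
        )
    return [(min(a, b), max(a, b)) for a, b in pairs]


def _raise_het(pairs: list[list[int]]) -> bool:
    """One swap that increases the heterozygote count; False if impossible."""
    homs = [i for i, (a, b) in enumerate(pairs) if a == b]
    for i in homs:
        a = pairs[i][0]
        # homozygote × heterozygote not containing a: +1 heterozygote
        for j, (b, c) in enumerate(pairs):
            if b != c and a not in (b, c):
                pairs[i][1], pairs[j][0] = pairs[j][0], pairs[i][1]
                return True
        # fallback: two homozygotes of different alleles: +2
        for j in homs:
            if pairs[j][0] != a:
                pairs[i][1], pairs[j][0] = pairs[j][0], pairs[i][1]
                return True
    return False


def _lower_het(pairs: list[list[int]]) -> bool:
    """One swap that decreases the heterozygote count; False if impossible."""
    hets = [i for i, (a, b) in enumerate(pairs) if a != b]
    by_allele: dict[int, int] = {}
    for i in hets:
        for pos in (0, 1):
            a = pairs[i][pos]
            if a in by_allele and by_allele[a] != i:
                j = by_allele[a]
                # (a, x) and (a, y) -> (a, a) and (x, y)
                jpos = 0 if pairs[j][0] == a else 1
                pairs[i][1 - pos], pairs[j][jpos] = (
                    pairs[j][jpos],
                    pairs[i][1 - pos],
                )
                return True
            by_allele[a] = i
    return False


def simulate_individuals(
    table: FrequencyTable, params: SimulationParams | None = None
) -> pd.DataFrame:
    """Simulate diploid pseudo-individuals for every (population, locus).

    Returns a long genotype table (population, individual, locus, allele1,
    allele2); missing (population, locus) cells are simply absent. Fully
    deterministic for a given seed.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    rows = []
    for pop in table.populations:
        for locus in table.loci_of(pop):
            copies = allocate_allele_copies(table.freq(pop, locus), params.n_individuals)
            pairs = pair_into_genotypes(copies, params, rng)
            for ind, (a, b) in enumerate(pairs, start=1):
                rows.append((pop, ind, locus, a, b))
    return pd.DataFrame(
        rows, columns=["population", "individual", "locus", "allele1", "allele2"]
    )


def frequencies_from_genotypes(genotypes: pd.DataFrame) -> FrequencyTable:
    """Allele frequencies realized in a genotype table: p̂ = count / 2N."""
    data: dict[str, dict[str, dict[int, float]]] = {}
    pops = list(dict.fromkeys(genotypes["population"].astype(str)))
    for (pop, locus), sub in genotypes.groupby(["population", "locus"], sort=False):
        alleles = np.concatenate([sub["allele1"].to_numpy(), sub["allele2"].to_numpy()])
        vals, counts = np.unique(alleles, return_counts=True)
        data.setdefault(str(pop), {})[str(locus)] = {
            int(v): c / len(alleles) for v, c in zip(vals, counts)
        }
    return FrequencyTable({p: data.get(p, {}) for p in pops}, populations=pops)
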