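"""Summary statistics of allelic diversity: allele counts, unique alleles,
and Nei gene diversity (expected heterozygosity, H = 1 − Σ p²).

Group-level statistics average allele frequencies across the member
populations (unweighted, pairwise-deleting missing loci) before computing
H, matching the "average measurements per cluster" convention of
population-bulk SSR studies; a pooled-copy route from genotype tables is
also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .freqtable import FrequencyTable

__all__ = [
    "DiversitySummary",
    "gene_diversity",
    "group_diversity",
    "unique_alleles",
    "diversity_table",
]


@dataclass(frozen=True)
class DiversitySummary:
    """One row of a diversity summary table."""

    group: str
    n_populations: int
    n_alleles: int
    n_unique_alleles: int | None
    gene_diversity: float
    mean_alleles_per_locus: float


def gene_diversity(freqs: dict[int, float]) -> float:
    """Nei gene diversity 1 − Σ p² for one locus' allele frequencies."""
    return 1.0 - sum(f * f for f in freqs.values())


def group_diversity(
    table: FrequencyTable, populations: list[str] | None = None, group: str = "all"
) -> DiversitySummary:
    """Diversity summary for a group of populations.

    Per locus, allele frequencies are first averaged across the group's
    populations (populations missing the locus are excluded from that
    locus' mean); the group's gene diversity is the mean over loci of
    1 − Σ p̄², and the allele count is the number of distinct
    (locus, allele) pairs with positive pooled frequency.
    """
    pops = populations if populations is not None else table.populations
    if not pops:
        raise ValueError("empty group")
    profile = table.mean_profile(pops)
    if not profile:
        raise ValueError(f"group {group!r} has no scored loci")
    h = sum(gene_diversity(p) for p in profile.values()) / len(profile)
    n_alleles = sum(sum(1 for f in p.values() if f > 0) for p in profile.values())
    return DiversitySummary(
        group=group,
        n_populations=len(pops),
        n_alleles=n_alleles,
        n_unique_alleles=None,
        gene_diversity=h,
        mean_alleles_per_locus=n_alleles / len(profile),
    )


def unique_alleles(
    groups: dict[str, list[str]], table: FrequencyTable
) -> dict[str, int]:
    """Alleles private to each group among the groups compared.

    An allele is unique to group g iff its pooled (mean) frequency is
    positive in g and zero — or absent — in every other group of the
    comparison set. For sub-cluster comparisons, pass only the sub-groups
    sharing one parent cluster. Groups must be disjoint.
    """
    seen: dict[str, str] = {}
    for g, pops in groups.items():
        for p in pops:
            if p in seen:
                raise ValueError(f"population {p!r} in both {seen[p]!r} and {g!r}")
            seen[p] = g
    present: dict[str, set[tuple[str, int]]] = {}
    for g, pops in groups.items():
        prof = table.mean_profile(pops) if pops else {}
        present[g] = {
            (locus, a) for locus, cell in prof.items() for a, f in cell.items() if f > 0
        }
    out: dict[str, int] = {}
    for g in groups:
        others: set[tuple[str, int]] = set()
        for g2 in groups:
            if g2 != g:
                others |= present[g2]
        out[g] = len(present[g] - others)
    return out


def diversity_table(
    table: FrequencyTable, groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-group diversity summary plus a Total row, with unique alleles
    compared between the given groups (the layout of a cluster-level
    diversity table)."""
    uniq = unique_alleles(groups, table)
    rows = []
    for g, pops in groups.items():
        if not pops:
            continue
        s = group_diversity(table, pops, group=g)
        rows.append(
            {
                "group": g,
                "n_populations": s.n_populations,
                "n_alleles": s.n_alleles,
                "n_unique_alleles": uniq[g],
                "gene_diversity": s.gene_diversity,
            }
        )
    total = group_diversity(table, group="Total")
    rows.append(
        {
            "group": "Total",
            "n_populations": total.n_populations,
            "n_alleles": total.n_alleles,
            "n_unique_alleles": None,
            "gene_diversity": total.gene_diversity,
        }
    )
    return pd.DataFrame(rows)
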