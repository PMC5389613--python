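"""Synthetic SSR datasets with stored ground truth.

Emulates the shape of a bulked-SSR landrace survey — K ancestral clusters,
admixed populations, 15-plant bulks scored at ~28 microsatellites with
2–21 alleles per locus — so every pipeline stage can be verified without
external data. Population differentiation follows the F-model: cluster
allele frequencies are Dirichlet draws around an ancestral profile with
concentration (1 − F)/F, so F plays the role of a drift/F_ST parameter.
Ancestral profiles are symmetric Dirichlet(θ) draws; θ defaults to 0.3,
which gives study-scale datasets an expected overall gene diversity near
the ≈0.6 level typical of maize landrace SSR panels.

Peak tables are rendered as the inverse of the peak-calling stage: each
allele becomes a peak with height proportional to its bulk frequency (on
an arbitrary 10⁴ intensity scale), each peak spawns a −1-repeat stutter
peak, and low-level noise peaks are sprinkled on unused ladder rungs. A
registry records which peaks are artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .freqtable import FrequencyTable
from .loci import LocusDef

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "make_locus_defs",
    "generate_cluster_frequencies",
    "generate_population_bulks",
    "render_peak_table",
    "generate_dataset",
    "generate_hierarchical_dataset",
]

_INTENSITY = 1.0e4


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped generator settings.

    The defaults mirror the surveyed data: 28 SSR loci with 2–21 alleles
    each, 15-individual bulks, moderate drift (F = 0.2) and strong
    single-ancestry tendency (admixture Dirichlet α = 0.2), stutter at
    5–18% of the parent peak and occasional baseline noise peaks.
    """

    k_true: int = 3
    n_populations: int = 60
    n_loci: int = 28
    alleles_min: int = 2
    alleles_max: int = 21
    drift_f: float = 0.2
    admix_alpha: float = 0.2
    n_individuals: int = 15
    stutter_rate: float = 0.12
    noise_peak_rate: float = 0.02
    height_jitter_sd: float = 0.05
    ancestral_theta: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.drift_f < 1.0:
            raise ValueError("drift_f must be in (0, 1)")
        if self.k_true < 1 or self.n_populations < 1 or self.n_loci < 1:
            raise ValueError("k_true, n_populations, n_loci must be ≥ 1")
        if not 0 < self.alleles_min <= self.alleles_max:
            raise ValueError("bad alleles_per_locus range")


@dataclass
class SyntheticDataset:
    """A generated dataset plus its ground truth."""

    config: GeneratorConfig
    locus_defs: dict[str, LocusDef]
    ancestral: dict[str, dict[int, float]]
    cluster_freqs: list[dict[str, dict[int, float]]]  # per cluster
    true_q: pd.DataFrame  # population × cluster
    genotypes: pd.DataFrame
    bulk_freqs: FrequencyTable
    peaks: pd.DataFrame | None = None
    peak_registry: pd.DataFrame | None = None
    labels: pd.DataFrame | None = None  # hierarchical truth, if any
    extras: dict = field(default_factory=dict)


_REPEAT_UNITS = (2, 3, 4, 6)


def make_locus_defs(config: GeneratorConfig, rng: np.random.Generator) -> dict[str, LocusDef]:
    """Invent SSR loci: cycled repeat units, staggered size ranges.

    Allele ladders leave one empty rung below the lowest possible allele so
    that −1-repeat stutter of the smallest allele still lands on-ladder.
    """
    out: dict[str, LocusDef] = {}
    for i in range(config.n_loci):
        unit = _REPEAT_UNITS[i % len(_REPEAT_UNITS)]
        size_min = int(rng.integers(80, 220))
        n_rungs = config.alleles_max + 1  # rung 0 reserved for stutter
        out[f"ssr{i + 1:02d}"] = LocusDef(
            name=f"ssr{i + 1:02d}",
            genome_bin=f"{i % 10 + 1}.{i % 8:02d}",
            repeat_unit=unit,
            size_min=size_min,
            size_max=size_min + n_rungs * unit,
        )
    return out


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    # log-space sampling: Gamma(a) = Gamma(a+1) · U^(1/a); stable for the
    # tiny concentrations (α ~ 1e-3) where direct gamma draws underflow
    a = np.maximum(np.asarray(alpha, dtype=float), 1e-12)
    logs = (
        np.log(np.maximum(rng.gamma(a + 1.0), 1e-300))
        + np.log(np.maximum(rng.random(a.shape), 1e-300)) / a
    )
    g = np.exp(logs - logs.max())
    return g / g.sum()


def generate_cluster_frequencies(
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    locus_defs: dict[str, LocusDef] | None = None,
    k: int | None = None,
    ancestral: dict[str, dict[int, float]] | None = None,
    drift_f: float | None = None,
) -> tuple[dict[str, LocusDef], dict[str, dict[int, float]], list[dict[str, dict[int, float]]]]:
    """Draw ancestral and per-cluster allele frequencies (F-model).

    Per locus: the allele count is uniform on the configured range, the
    ancestral simplex is symmetric Dirichlet(θ), and each cluster draws
    Dirichlet(p_anc · (1 − F)/F) around it — small F means clusters hug the
    ancestral profile, large F means strong drift.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if locus_defs is None:
        locus_defs = make_locus_defs(config, rng)
    k = k if k is not None else config.k_true
    f = drift_f if drift_f is not None else config.drift_f
    if ancestral is None:
        ancestral = {}
        for name, ld in locus_defs.items():
            n_all = int(rng.integers(config.alleles_min, config.alleles_max + 1))
            ladder = ld.ladder()[1:]  # rung 0 reserved for stutter headroom
            sizes = np.sort(rng.choice(ladder, size=n_all, replace=False))
            p = _dirichlet(rng, np.full(n_all, config.ancestral_theta))
            ancestral[name] = {int(s): float(x) for s, x in zip(sizes, p)}
    conc = (1.0 - f) / f
    clusters = []
    for _ in range(k):
        cl: dict[str, dict[int, float]] = {}
        for name, anc in ancestral.items():
            sizes = list(anc)
            p = _dirichlet(rng, conc * np.array([anc[s] for s in sizes]))
            cl[name] = {s: float(x) for s, x in zip(sizes, p)}
        clusters.append(cl)
    return locus_defs, ancestral, clusters


def generate_population_bulks(
    cluster_freqs: list[dict[str, dict[int, float]]],
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    true_q: np.ndarray | None = None,
) -> tuple[pd.DataFrame, FrequencyTable, pd.DataFrame]:
    """Simulate admixed populations of diploid individuals and their bulks.

    Each population's ancestry vector is Dirichlet(α) over the clusters;
    each of its individuals draws two allele copies per locus from the
    Q-weighted mixture of cluster frequencies. Bulk frequencies are the
    realized copy proportions (what a pooled-DNA assay would measure,
    noise aside).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    k = len(cluster_freqs)
    loci = list(cluster_freqs[0])
    pops = [f"pop{i + 1:03d}" for i in range(config.n_populations)]
    if true_q is None:
        true_q = np.stack(
            [_dirichlet(rng, np.full(k, config.admix_alpha)) for _ in pops]
        )
    rows = []
    bulk: dict[str, dict[str, dict[int, float]]] = {}
    for pi, pop in enumerate(pops):
        q = true_q[pi]
        bulk[pop] = {}
        for locus in loci:
            sizes = list(cluster_freqs[0][locus])
            pmat = np.array(
                [[cluster_freqs[c][locus][s] for s in sizes] for c in range(k)]
            )
            n_copies = 2 * config.n_individuals
            z = rng.choice(k, size=n_copies, p=q)
            u = rng.random(n_copies)
            cum = pmat.cumsum(axis=1)
            a_idx = (cum[z] < u[:, None]).sum(axis=1).clip(max=len(sizes) - 1)
            copies = [sizes[int(i)] for i in a_idx]
            for ind in range(config.n_individuals):
                a, b = copies[2 * ind], copies[2 * ind + 1]
                rows.append((pop, ind + 1, locus, min(a, b), max(a, b)))
            vals, counts = np.unique(copies, return_counts=True)
            bulk[pop][locus] = {int(v): c / n_copies for v, c in zip(vals, counts)}
    genotypes = pd.DataFrame(
        rows, columns=["population", "individual", "locus", "allele1", "allele2"]
    )
    table = FrequencyTable(bulk, populations=pops, loci=loci)
    q_df = pd.DataFrame(true_q, index=pops, columns=[f"k{i + 1}" for i in range(k)])
    return genotypes, table, q_df


def render_peak_table(
    table: FrequencyTable,
    locus_defs: dict[str, LocusDef],
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render bulk frequencies into a stutter-contaminated peak table.

    Allele peaks get height ``frequency × 10⁴`` with lognormal jitter; each
    spawns a stutter peak one repeat unit below with height ratio
    U(0.05, 1.5 × stutter_rate); noise peaks appear on random unused rungs
    at ``noise_peak_rate`` per (bulk, locus) with sub-noise-floor heights.
    Stutter landing on a real allele's rung merges into that peak. The
    registry labels every emitted peak allele/stutter/noise.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    peak_rows = []
    reg_rows = []
    for pop in table.populations:
        for locus in table.loci_of(pop):
            ld = locus_defs[locus]
            freqs = table.freq(pop, locus)
            heights: dict[int, float] = {}
            kinds: dict[int, str] = {}
            for a, f in sorted(freqs.items()):
                h = f * _INTENSITY
                if config.height_jitter_sd > 0:
                    h *= float(rng.lognormal(0.0, config.height_jitter_sd))
                heights[a] = heights.get(a, 0.0) + h
                kinds.setdefault(a, "allele")
            if config.stutter_rate > 0:
                for a in sorted(freqs):
                    ratio = float(rng.uniform(0.05, 1.5 * config.stutter_rate))
                    s = a - ld.repeat_unit
                    heights[s] = heights.get(s, 0.0) + ratio * heights[a]
                    kinds.setdefault(s, "stutter")
                    reg_rows.append((pop, locus, s, "stutter", a))
            if config.noise_peak_rate > 0 and rng.random() < config.noise_peak_rate:
                free = [r for r in ld.ladder() if int(r) not in heights]
                if free:
                    r = int(rng.choice(free))
                    heights[r] = float(rng.uniform(0.005, 0.04)) * max(heights.values())
                    kinds[r] = "noise"
                    reg_rows.append((pop, locus, r, "noise", np.nan))
            for size, h in sorted(heights.items()):
                peak_rows.append((pop, locus, float(size), h, 1.0, kinds[size]))
                if kinds[size] == "allele":
                    reg_rows.append((pop, locus, size, "allele", np.nan))
    peaks = pd.DataFrame(
        peak_rows, columns=["bulk_id", "locus", "size_bp", "height", "quality", "kind"]
    )
    registry = pd.DataFrame(
        reg_rows, columns=["bulk_id", "locus", "size_bp", "kind", "parent_size"]
    )
    return peaks.drop(columns="kind"), registry


def generate_dataset(config: GeneratorConfig, render_peaks: bool = True) -> SyntheticDataset:
    """Full generator: clusters → populations/bulks → (optionally) peaks."""
    rng = np.random.default_rng(config.seed)
    locus_defs, ancestral, clusters = generate_cluster_frequencies(config, rng)
    genotypes, bulk, true_q = generate_population_bulks(clusters, config, rng)
    peaks = registry = None
    if render_peaks:
        peaks, registry = render_peak_table(bulk, locus_defs, config, rng)
    return SyntheticDataset(
        config=config,
        locus_defs=locus_defs,
        ancestral=ancestral,
        cluster_freqs=clusters,
        true_q=true_q,
        genotypes=genotypes,
        bulk_freqs=bulk,
        peaks=peaks,
        peak_registry=registry,
    )


def generate_hierarchical_dataset(
    config: GeneratorConfig,
    n_top: int = 3,
    n_sub: int = 2,
    drift_f_top: float | None = None,
    drift_f_sub: float = 0.05,
) -> SyntheticDataset:
    """Two-level structure: strongly drifted top clusters, each split into
    weakly drifted sub-clusters; populations are pure members of one leaf.

    ``config.n_populations`` is rounded down to a multiple of the number of
    leaves. The ``labels`` frame records each population's true top cluster
    and leaf sub-cluster.
    """
    rng = np.random.default_rng(config.seed)
    f_top = drift_f_top if drift_f_top is not None else config.drift_f
    locus_defs, ancestral, top = generate_cluster_frequencies(
        config, rng, k=n_top, drift_f=f_top
    )
    leaves: list[dict[str, dict[int, float]]] = []
    leaf_labels: list[tuple[int, int]] = []
    for t, parent in enumerate(top):
        _, _, subs = generate_cluster_frequencies(
            config, rng, locus_defs=locus_defs, k=n_sub, ancestral=parent,
            drift_f=drift_f_sub,
        )
        leaves.extend(subs)
        leaf_labels.extend((t, s) for s in range(n_sub))
    n_leaves = len(leaves)
    per_leaf = config.n_populations // n_leaves
    n_pops = per_leaf * n_leaves
    true_q = np.zeros((n_pops, n_leaves))
    tops, subs_lab = [], []
    for i in range(n_pops):
        leaf = i % n_leaves
        true_q[i, leaf] = 1.0
        tops.append(leaf_labels[leaf][0])
        subs_lab.append(leaf_labels[leaf][1])
    cfg = GeneratorConfig(
        **{**config.__dict__, "n_populations": n_pops, "k_true": n_leaves}
    )
    genotypes, bulk, q_df = generate_population_bulks(leaves, cfg, rng, true_q=true_q)
    labels = pd.DataFrame(
        {"top": tops, "sub": subs_lab}, index=q_df.index
    )
    return SyntheticDataset(
        config=cfg,
        locus_defs=locus_defs,
        ancestral=ancestral,
        cluster_freqs=leaves,
        true_q=q_df,
        genotypes=genotypes,
        bulk_freqs=bulk,
        labels=labels,
        extras={"n_top": n_top, "n_sub": n_sub},
    )
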