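"""Pooled-sample allele frequencies from electropherogram peak tables.

A population bulk (pooled DNA of many plants) amplified at an SSR locus
yields one peak per allele plus artifacts: *stutter* (a slippage product one
repeat unit below a true allele) and low-level noise. Relative peak heights
approximate allele frequencies in the pool, so the estimation pipeline is

    bin_peaks  →  remove_stutter  →  estimate_bulk_frequencies

applied per (bulk, locus). Stutter is filtered by a height-ratio rule
relative to the parent peak; an optional linear size re-weighting can
compensate preferential amplification of short fragments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .freqtable import FrequencyTable
from .loci import LocusDef

__all__ = [
    "PeakFilterParams",
    "bin_peaks",
    "remove_stutter",
    "estimate_bulk_frequencies",
    "peaks_to_frequencies",
]

logger = logging.getLogger("bulkpop")


@dataclass(frozen=True)
class PeakFilterParams:
    """Thresholds for artifact removal.

    stutter_ratio : float in [0, 1]
        A peak one repeat unit below a retained peak is deleted when its
        height is below ``stutter_ratio`` times the parent height
        (default 0.2, standard fragment-analysis practice).
    noise_floor : float in [0, 1]
        Peaks below this fraction of the tallest retained peak at the locus
        are deleted (default 0.05).
    bin_tolerance : float or None
        Maximum distance (bp) from a ladder rung for a peak to be binned;
        ``None`` means half a repeat unit.
    minus_two_stutter : bool
        Also remove −2-repeat stutter (off by default; −1 is the dominant
        mode for short-motif SSRs).
    size_reweight : float
        Relative height gain per bp compensating preferential amplification
        of shorter fragments: height is multiplied by
        ``1 + size_reweight * (size − size_min)`` before normalization.
        Default 0 (deletion-only artifact handling).
    """

    stutter_ratio: float = 0.2
    noise_floor: float = 0.05
    bin_tolerance: float | None = None
    minus_two_stutter: bool = False
    size_reweight: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.stutter_ratio <= 1.0:
            raise ValueError("stutter_ratio must be in [0, 1]")
        if not 0.0 <= self.noise_floor <= 1.0:
            raise ValueError("noise_floor must be in [0, 1]")
        if self.bin_tolerance is not None and self.bin_tolerance <= 0:
            raise ValueError("bin_tolerance must be positive")


def bin_peaks(
    peaks: pd.DataFrame, locus: LocusDef, params: PeakFilterParams | None = None
) -> dict[int, float]:
    """Snap raw peak sizes of one (bulk, locus) to the allele ladder.

    Returns a rung → summed-height map. Peaks farther than ``bin_tolerance``
    from every rung are dropped (count logged); equidistant peaks go to the
    lower rung.
    """
    params = params or PeakFilterParams()
    tol = (
        params.bin_tolerance
        if params.bin_tolerance is not None
        else locus.repeat_unit / 2.0
    )
    binned: dict[int, float] = {}
    n_dropped = 0
    for size, height in zip(peaks["size_bp"].to_numpy(), peaks["height"].to_numpy()):
        rung = locus.snap(float(size))
        if abs(float(size) - rung) > tol + 1e-12:
            n_dropped += 1
            continue
        binned[rung] = binned.get(rung, 0.0) + float(height)
    if n_dropped:
        logger.info(
            "locus %s: dropped %d off-ladder peaks (> %.2f bp from any rung)",
            locus.name,
            n_dropped,
            tol,
        )
    return binned


def remove_stutter(
    binned: dict[int, float], locus: LocusDef, params: PeakFilterParams | None = None
) -> dict[int, float]:
    """Delete stutter and noise peaks from a binned (bulk, locus) profile.

    Scanning rungs from largest to smallest, the peak one repeat unit below
    a *retained* peak at size ``a`` is removed iff its height is below
    ``stutter_ratio × height(a)`` (and likewise at −2 units when enabled).
    Afterwards, peaks below ``noise_floor`` × the tallest retained height go
    too. Idempotent: a cleaned profile passes through unchanged.
    """
    params = params or PeakFilterParams()
    kept = dict(binned)
    offsets = [locus.repeat_unit]
    if params.minus_two_stutter:
        offsets.append(2 * locus.repeat_unit)
    for a in sorted(binned, reverse=True):
        if a not in kept:
            continue
        for off in offsets:
            b = a - off
            if b in kept and kept[b] < params.stutter_ratio * kept[a]:
                del kept[b]
    if kept:
        tallest = max(kept.values())
        kept = {a: h for a, h in kept.items() if h >= params.noise_floor * tallest}
    if not kept:
        logger.info("locus %s: all peaks removed, marking missing", locus.name)
    return kept


def estimate_bulk_frequencies(
    filtered: dict[int, float],
    locus: LocusDef | None = None,
    params: PeakFilterParams | None = None,
) -> dict[int, float]:
    """Allele frequencies from retained peak heights: p(a) = h(a) / Σ h.

    With ``size_reweight`` > 0 heights are first rescaled linearly with
    fragment size to undo preferential amplification of short alleles.
    Returns {} for an empty profile (missing cell).
    """
    if not filtered:
        return {}
    params = params or PeakFilterParams()
    heights = dict(filtered)
    if params.size_reweight and locus is not None:
        heights = {
            a: h * (1.0 + params.size_reweight * (a - locus.size_min))
            for a, h in heights.items()
        }
    total = sum(heights.values())
    return {a: h / total for a, h in heights.items()}


def peaks_to_frequencies(
    peaks: pd.DataFrame,
    locus_defs: dict[str, LocusDef],
    params: PeakFilterParams | None = None,
) -> FrequencyTable:
    """Full peak-calling pipeline over a raw peak table.

    Applies bin → de-stutter → normalize per (bulk, locus); bulks and loci
    with no surviving peaks are left missing.
    """
    params = params or PeakFilterParams()
    data: dict[str, dict[str, dict[int, float]]] = {}
    bulks = list(dict.fromkeys(peaks["bulk_id"].astype(str)))
    for bulk in bulks:
        data[bulk] = {}
        sub_b = peaks[peaks["bulk_id"].astype(str) == bulk]
        for locus_name, locus in locus_defs.items():
            sub = sub_b[sub_b["locus"].astype(str) == locus_name]
            if sub.empty:
                continue
            prof = estimate_bulk_frequencies(
                remove_stutter(bin_peaks(sub, locus, params), locus, params),
                locus,
                params,
            )
            if prof:
                data[bulk][locus_name] = prof
    return FrequencyTable(data, populations=bulks, loci=list(locus_defs))
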