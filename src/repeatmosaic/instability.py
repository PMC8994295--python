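"""Expansion, contraction, and total instability indices.

The expansion index summarizes bulk somatic mosaicism from a fragment-sizing
trace.  Peaks below a relative height threshold (default 5% of the modal
peak) are discarded as noise/stutter; the remaining heights are normalized to
sum to one, and the index is the normalized-height-weighted sum of repeat-unit
distances from the modal allele, taken over peaks longer than the modal
allele.  Peaks shorter than the modal allele are dominated by PCR slippage,
so they enter only the contraction index, reported separately.

Index properties: scale-invariant in the heights, zero for a single-peak
trace, and strictly increasing when an above-threshold expansion peak is
added.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .traceio import AlleleDistribution

__all__ = [
    "IndexResult",
    "ReplicateSummary",
    "AllelesTooCloseError",
    "expansion_index",
    "compare_replicates",
    "split_two_allele_distribution",
]


class AllelesTooCloseError(ValueError):
    """Two alleles of an autosomal locus too close to index independently."""


@dataclass(frozen=True)
class IndexResult:
    """Instability indices for one allele distribution.

    ``instability_index`` is the sum of the expansion and contraction
    contributions by construction.
    """

    expansion_index: float
    contraction_index: float
    instability_index: float
    threshold_fraction: float
    peaks_retained: int
    modal_repeat: int


def expansion_index(
    dist: AlleleDistribution,
    threshold_fraction: float = 0.05,
    include_extrapolated: bool = True,
) -> IndexResult:
    """Compute expansion/contraction/instability indices from a distribution.

    Parameters
    ----------
    dist
        Allele distribution with a called modal allele.
    threshold_fraction
        Relative peak-height cut-off: peaks with height below
        ``threshold_fraction`` x modal height are excluded.  Default 0.05.
    include_extrapolated
        If False, repeat lengths sized by extrapolation outside the accurate
        window are dropped (the modal allele is always kept).

    Notes
    -----
    Retained heights (modal and both flanks) are normalized to sum to 1; the
    expansion index is sum over retained peaks with repeat > modal of
    normalized height x (repeat - modal), and the contraction index is the
    analogue over repeat < modal with |repeat - modal|.
    """
    if threshold_fraction < 0:
        raise ValueError("threshold_fraction must be non-negative")
    entries = dict(dist.entries)
    if not include_extrapolated:
        entries = {
            r: w
            for r, w in entries.items()
            if r == dist.modal_repeat or r not in dist.out_of_range_flags
        }
    modal_height = entries[dist.modal_repeat]
    if modal_height <= 0:
        raise ValueError("modal peak has zero height")
    cut = threshold_fraction * modal_height
    retained = {r: w for r, w in entries.items() if w >= cut and w > 0}
    retained[dist.modal_repeat] = modal_height
    total = sum(retained.values())
    exp_idx = sum(w * (r - dist.modal_repeat) for r, w in retained.items() if r > dist.modal_repeat)
    con_idx = sum(w * (dist.modal_repeat - r) for r, w in retained.items() if r < dist.modal_repeat)
    exp_idx /= total
    con_idx /= total
    return IndexResult(
        expansion_index=exp_idx,
        contraction_index=con_idx,
        instability_index=exp_idx + con_idx,
        threshold_fraction=threshold_fraction,
        peaks_retained=len(retained),
        modal_repeat=dist.modal_repeat,
    )


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean, sample SD and CV of each index across replicate PCRs."""

    n_replicates: int
    mean_expansion: float
    sd_expansion: float
    cv_expansion: float
    mean_contraction: float
    sd_contraction: float
    cv_contraction: float
    mean_instability: float
    sd_instability: float
    cv_instability: float


def _mean_sd_cv(values: list[float]) -> tuple[float, float, float]:
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    sd = math.sqrt(var)
    cv = sd / mean if mean != 0 else math.nan
    return mean, sd, cv


def compare_replicates(results: list[IndexResult]) -> ReplicateSummary:
    """Summarize technical spread of indices across replicate amplifications.

    Used to check that between-tissue differences exceed technical variation.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 replicates to assess spread")
    e = _mean_sd_cv([r.expansion_index for r in results])
    c = _mean_sd_cv([r.contraction_index for r in results])
    i = _mean_sd_cv([r.instability_index for r in results])
    return ReplicateSummary(len(results), *e, *c, *i)


def split_two_allele_distribution(
    dist: AlleleDistribution,
    modal_low: int,
    modal_high: int,
    min_separation: int = 4,
) -> tuple[AlleleDistribution, AlleleDistribution]:
    """Split an autosomal two-allele distribution at the inter-modal midpoint.

    Each half is re-called and can be indexed independently.  When the two
    declared modal alleles are closer than ``min_separation`` repeat units
    their stutter/expansion flanks overlap and a per-allele index is not
    meaningful; an :class:`AllelesTooCloseError` is raised so the caller can
    fall back to indexing a single allele.
    """
    if modal_low > modal_high:
        modal_low, modal_high = modal_high, modal_low
    for m in (modal_low, modal_high):
        if m not in dist.entries:
            raise ValueError(f"declared modal allele {m} not present in distribution")
    if modal_high - modal_low < min_separation:
        raise AllelesTooCloseError(
            f"alleles too close: modal alleles {modal_low} and {modal_high} are "
            f"{modal_high - modal_low} units apart (< {min_separation})"
        )
    midpoint = (modal_low + modal_high) / 2.0
    low_entries = {r: w for r, w in dist.entries.items() if r < midpoint}
    high_entries = {r: w for r, w in dist.entries.items() if r >= midpoint}
    if not low_entries or not high_entries:
        raise ValueError("split produced an empty half; check declared modal alleles")
    low = AlleleDistribution.from_entries(
        dist.locus, low_entries, dist.out_of_range_flags & set(low_entries)
    )
    high = AlleleDistribution.from_entries(
        dist.locus, high_entries, dist.out_of_range_flags & set(high_entries)
    )
    if low.modal_repeat != modal_low or high.modal_repeat != modal_high:
        warnings.warn(
            "re-called modal alleles differ from the declared ones; using re-called",
            stacklevel=2,
        )
    return low, high
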