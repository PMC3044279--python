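"""Haplotype length and accuracy metrics.

Length: a haplotype contig (SNP-graph component) is summarized by its
*size* (number of sites), *span* (distance between its distal sites) and
*adjusted span* (span scaled by the fraction of in-span sites belonging to
the contig, penalizing interleaved components). S50 / N50 / AN50 are the
median-type statistics over these: the size (span, adjusted span) such that
50% of all SNPs are in contigs at least that large.

Accuracy: HER (haplotype edit rate) is the fraction of phased alleles
miscalled relative to truth under the better of the two per-component
labelings; SER (switch error rate) is the number of crossovers per phased
site needed to reconcile an assembled haplotype with the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph import Component, SNPGraph, count_useful_edges
from .track import VariantTrack

__all__ = [
    "ComponentStats",
    "MetricSummary",
    "PhasingResult",
    "adjusted_span",
    "component_stats",
    "s50",
    "n50",
    "an50",
    "summarize_experiment",
    "haplotype_error_rate",
    "switch_error_rate",
]


@dataclass(frozen=True)
class ComponentStats:
    component: Component
    size: int
    span: int
    adjusted_span: float
    leftmost: int  # bp position, used as a deterministic tie-break


@dataclass(frozen=True)
class MetricSummary:
    """Length metrics for one simulated experiment."""

    S50: int
    N50: int
    AN50: float
    n_components: int
    useful_fraction: float
    largest_component_size: int
    n_sites: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    def tsv_row(self) -> str:
        return (
            f"{self.S50}\t{self.N50}\t{self.AN50:.1f}\t{self.n_components}"
            f"\t{self.useful_fraction:.6f}\t{self.largest_component_size}\t{self.n_sites}"
        )

    tsv_header = "S50\tN50\tAN50\tn_components\tuseful_fraction\tlargest_component_size\tn_sites"


@dataclass
class PhasingResult:
    """Assembled haplotype: one allele call per phased site.

    ``alleles[i]`` is the call at site ``i`` on one (arbitrarily labeled)
    haplotype, or -1 for unphased sites; components lists the contigs the
    calls were made within. HER/SER are filled by the evaluation functions.
    """

    alleles: np.ndarray  # int8, -1 where unphased
    components: List[Component]
    HER: Optional[float] = None
    SER: Optional[float] = None


def adjusted_span(component: Component, track: VariantTrack) -> float:
    """Span times the fraction of in-span track sites in the component.

    ``t`` counts every track site whose position lies within the
    component's ``[min, max]`` positional interval (inclusive); the
    adjusted span is ``span * v / t``. Singletons have span 0.
    """
    if component.v == 0:
        raise ValueError("component must be nonempty")
    if component.v == 1:
        return 0.0
    pos = track.positions[component.site_indices]
    lo, hi = int(pos.min()), int(pos.max())
    span = hi - lo
    t = int(
        np.searchsorted(track.positions, hi, side="right")
        - np.searchsorted(track.positions, lo, side="left")
    )
    return span * component.v / t


def component_stats(
    components: Sequence[Component], track: VariantTrack
) -> List[ComponentStats]:
    out = []
    for comp in components:
        pos = track.positions[comp.site_indices]
        span = int(pos.max() - pos.min()) if comp.v > 1 else 0
        out.append(
            ComponentStats(
                component=comp,
                size=comp.v,
                span=span,
                adjusted_span=adjusted_span(comp, track),
                leftmost=int(pos.min()),
            )
        )
    return out


def _weighted_50(
    values: Sequence[float], sizes: Sequence[int], leftmost: Sequence[int], n_sites: int
):
    """Generic x50: sort by value desc (ties: leftmost position first),
    accumulate component sizes, return the value where the cumulative site
    count first reaches half of ``n_sites``."""
    if n_sites <= 0 or not values:
        return 0
    order = sorted(range(len(values)), key=lambda i: (-values[i], leftmost[i]))
    half = n_sites / 2
    cum = 0
    for i in order:
        cum += sizes[i]
        if cum >= half:
            return values[i]
    return values[order[-1]]


def s50(components: Sequence[Component], n_sites: int) -> int:
    """Size S such that 50% of all sites are in contigs of size >= S."""
    sizes = [c.v for c in components]
    left = [int(c.site_indices[0]) for c in components]
    return int(_weighted_50(sizes, sizes, left, n_sites))


def n50(components: Sequence[Component], track: VariantTrack) -> int:
    """Span (bp) such that 50% of all SNPs are in contigs of span >= N50."""
    stats = component_stats(components, track)
    return int(
        _weighted_50(
            [s.span for s in stats],
            [s.size for s in stats],
            [s.leftmost for s in stats],
            track.n_sites,
        )
    )


def an50(components: Sequence[Component], track: VariantTrack) -> float:
    """Adjusted span such that 50% of all SNPs are in contigs with adjusted
    span >= AN50."""
    stats = component_stats(components, track)
    return float(
        _weighted_50(
            [s.adjusted_span for s in stats],
            [s.size for s in stats],
            [s.leftmost for s in stats],
            track.n_sites,
        )
    )


def summarize_experiment(graph: SNPGraph, track: VariantTrack) -> MetricSummary:
    comps = graph.connected_components()
    _, _, frac = count_useful_edges(graph)
    return MetricSummary(
        S50=s50(comps, track.n_sites),
        N50=n50(comps, track),
        AN50=an50(comps, track),
        n_components=len(comps),
        useful_fraction=frac,
        largest_component_size=max((c.v for c in comps), default=0),
        n_sites=track.n_sites,
    )


def _component_orientation(
    comp: Component, alleles: np.ndarray, h1: np.ndarray
) -> np.ndarray:
    """Per-site agreement (+1 agree / -1 disagree) of the assembled alleles
    with truth haplotype one, over the component's sites in positional order
    (site indices are position-sorted already)."""
    idx = comp.site_indices
    return np.where(alleles[idx] == h1[idx], 1, -1)


def haplotype_error_rate(
    truth: Tuple[np.ndarray, np.ndarray], assembled: PhasingResult
) -> float:
    """HER: fraction of phased alleles miscalled under the better labeling.

    Per component the assembly may be compared to either haplotype (labels
    are arbitrary), so mismatches are counted under the orientation with
    fewer errors. The denominator is the number of phased sites (components
    of size >= 2; singletons carry no phase information). Always <= 0.5.
    """
    h1 = np.asarray(truth[0])
    mismatches = 0
    phased = 0
    for comp in assembled.components:
        if comp.v < 2:
            continue
        agree = _component_orientation(comp, assembled.alleles, h1)
        n_dis = int(np.count_nonzero(agree == -1))
        mismatches += min(n_dis, comp.v - n_dis)
        phased += comp.v
    her = mismatches / phased if phased else 0.0
    assembled.HER = her
    return her


def switch_error_rate(
    truth: Tuple[np.ndarray, np.ndarray], assembled: PhasingResult
) -> float:
    """SER: orientation flips between adjacent phased sites, per phased site.

    Within each component, sites are taken in positional order and a switch
    is counted wherever the assembled-vs-truth agreement flips sign;
    component boundaries are free crossovers.
    """
    h1 = np.asarray(truth[0])
    switches = 0
    phased = 0
    for comp in assembled.components:
        if comp.v < 2:
            continue
        agree = _component_orientation(comp, assembled.alleles, h1)
        switches += int(np.count_nonzero(agree[1:] != agree[:-1]))
        phased += comp.v
    ser = switches / phased if phased else 0.0
    assembled.SER = ser
    return ser
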