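"""Sequencing-error injection, likelihood-ratio site filtering, and a
minimal greedy phaser.

Error model: each read originates from one of the two haplotypes uniformly;
at every covered site the observation is dropped with probability
``dropout`` (a stand-in for platform indels, justified because alignment is
assumed correct) or flipped to the other allele with probability
``epsilon``. A true heterozygous site therefore shows roughly balanced
allele counts, while a homozygous site corrupted by miscalls shows a
dominant allele with a thin minority — the contrast the likelihood-ratio
statistic exploits:

    Lambda = n1*ln(1 - eps) + n2*ln(eps) + n*ln(2)

comparing H1 (the site always shows one allele, miscalled at rate eps)
against H0 (both alleles appear with probability 1/2). Balanced counts
drive Lambda strongly negative; a site is called heterozygous when
Lambda <= cutoff (default -1, inclusive at the boundary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph import SNPGraph
from .metrics import PhasingResult
from .simulator import StrobeRead
from .track import VariantTrack

__all__ = [
    "AlleleCounts",
    "SiteCall",
    "ReadObservation",
    "inject_errors",
    "site_allele_counts",
    "likelihood_ratio",
    "filter_sites",
    "greedy_phase",
    "write_counts_tsv",
    "write_calls_tsv",
]

DEFAULT_CUTOFF = -1.0


@dataclass(frozen=True)
class AlleleCounts:
    """Allele counts at one site: ``n1`` dominant, ``n2`` minor."""

    site: int
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (self.n1 >= self.n2 >= 0):
            raise ValueError("require n1 >= n2 >= 0")
        if self.n == 0:
            raise ValueError("site must be covered at least once")

    @property
    def n(self) -> int:
        return self.n1 + self.n2


@dataclass(frozen=True)
class SiteCall:
    site: int
    lam: float
    called_heterozygous: bool


@dataclass(frozen=True)
class ReadObservation:
    """Alleles one read reports: site index -> observed allele in {0, 1}."""

    haplotype: int  # 0 or 1: which haplotype the read was drawn from
    alleles: Dict[int, int]


def inject_errors(
    reads: Sequence[StrobeRead],
    track: VariantTrack,
    epsilon: float,
    dropout: float,
    rng: np.random.Generator,
    homozygous_sites: Optional[np.ndarray] = None,
) -> List[ReadObservation]:
    """Simulate error-corrupted allele observations for each read.

    ``homozygous_sites`` is an optional boolean mask over track sites
    marking decoys that emit allele 0 regardless of the read's haplotype
    (with the same miscall/dropout process); these exercise the
    heterozygous-site filter.
    """
    if track.truth is None:
        raise ValueError("track has no truth haplotypes")
    if not (0 <= epsilon < 1 and 0 <= dropout <= 1):
        raise ValueError("require 0 <= epsilon < 1 and 0 <= dropout <= 1")
    h = track.truth
    out: List[ReadObservation] = []
    for read in reads:
        hap = int(rng.integers(2))
        alleles: Dict[int, int] = {}
        for site in read.covered_sites:
            if dropout and rng.random() < dropout:
                continue
            if homozygous_sites is not None and homozygous_sites[site]:
                allele = 0
            else:
                allele = int(h[hap][site])
            if epsilon and rng.random() < epsilon:
                allele = 1 - allele
            alleles[site] = allele
        out.append(ReadObservation(haplotype=hap, alleles=alleles))
    return out


def site_allele_counts(
    observations: Sequence[ReadObservation], n_sites: int
) -> List[AlleleCounts]:
    """Aggregate per-read observations into dominant/minor counts per site.

    Sites with zero observations are omitted.
    """
    zeros = np.zeros(n_sites, dtype=np.int64)
    ones = np.zeros(n_sites, dtype=np.int64)
    for obs in observations:
        for site, allele in obs.alleles.items():
            if allele:
                ones[site] += 1
            else:
                zeros[site] += 1
    counts = []
    for site in range(n_sites):
        n0, n1_ = int(zeros[site]), int(ones[site])
        if n0 + n1_ == 0:
            continue
        counts.append(AlleleCounts(site=site, n1=max(n0, n1_), n2=min(n0, n1_)))
    return counts


def likelihood_ratio(counts: AlleleCounts, epsilon: float) -> float:
    """Log-likelihood ratio ln L(H1) - ln L(H0) for one site.

    ``L(H1) = (1-eps)^n1 * eps^n2`` (homozygous, miscalls at rate eps);
    ``L(H0) = (1/2)^n`` (heterozygous, balanced); binomial coefficients
    cancel, giving ``Lambda = n1 ln(1-eps) + n2 ln eps + n ln 2``. At
    ``eps = 0.5`` the hypotheses coincide and Lambda is identically 0.
    """
    if not (0 < epsilon < 1):
        raise ValueError(
            "epsilon must lie strictly in (0, 1); at the endpoints the ratio "
            "is infinite whenever the opposing count is nonzero"
        )
    return (
        counts.n1 * math.log1p(-epsilon)
        + counts.n2 * math.log(epsilon)
        + counts.n * math.log(2.0)
    )


def filter_sites(
    all_counts: Sequence[AlleleCounts],
    epsilon: float,
    cutoff: float = DEFAULT_CUTOFF,
) -> List[SiteCall]:
    """Call each site heterozygous iff its Lambda <= cutoff (inclusive)."""
    calls = []
    for counts in all_counts:
        lam = likelihood_ratio(counts, epsilon)
        calls.append(SiteCall(site=counts.site, lam=lam, called_heterozygous=lam <= cutoff))
    return calls


def greedy_phase(
    graph: SNPGraph, observations: Sequence[ReadObservation]
) -> PhasingResult:
    """Phase each component by majority vote along a spanning tree.

    For every site pair co-observed by a read, the read votes for the
    relative phase ``obs_u XOR obs_v`` (0: same allele on one haplotype, 1:
    opposite). Each edge's relative phase is the majority vote; ties, and
    edges with no surviving observations (all co-observations dropped),
    default to phase 0 — the documented tie rule, keeping the orientation of
    the lower site index. Starting from each component's lowest site
    (assigned allele 0), the walk always expands across the unvisited edge
    with the most observations (a maximum spanning tree by vote support), so
    thinly covered edges only decide sites nothing stronger reaches.
    Deterministic: ties in support break toward lower site indices.

    The tree assignment is then polished by local refinement sweeps: each
    site is flipped whenever the flip increases its total vote agreement
    over *all* incident edges (the redundant edges the length metrics call
    wasted are exactly what makes this error correction possible). Sweeps
    repeat until no site moves (bounded at 50).
    """
    import heapq

    # per-(u, v) votes: [count for phase 0, count for phase 1]
    votes: Dict[Tuple[int, int], List[int]] = {}
    for obs in observations:
        sites = sorted(obs.alleles)
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                u, v = sites[i], sites[j]
                phase = obs.alleles[u] ^ obs.alleles[v]
                votes.setdefault((u, v), [0, 0])[phase] += 1

    adjacency: Dict[int, List[int]] = {}
    for a, b in zip(graph.u, graph.v):
        adjacency.setdefault(int(a), []).append(int(b))
        adjacency.setdefault(int(b), []).append(int(a))

    def support(u: int, w: int) -> int:
        key = (u, w) if u < w else (w, u)
        v0, v1 = votes.get(key, (0, 0))
        return v0 + v1

    alleles = np.full(graph.n_sites, -1, dtype=np.int8)
    components = graph.connected_components()
    for comp in components:
        if comp.v < 2:
            continue
        root = int(comp.site_indices[0])
        alleles[root] = 0
        seen = {root}
        heap = [(-support(root, w), root, w) for w in adjacency.get(root, ())]
        heapq.heapify(heap)
        while heap:
            _, u, w = heapq.heappop(heap)
            if w in seen:
                continue
            key = (u, w) if u < w else (w, u)
            v0, v1 = votes.get(key, (0, 0))
            phase = 1 if v1 > v0 else 0  # tie -> 0
            alleles[w] = alleles[u] ^ phase
            seen.add(w)
            for x in adjacency.get(w, ()):
                if x not in seen:
                    heapq.heappush(heap, (-support(w, x), w, x))

    # local refinement: flip any site whose neighbors' votes say so
    for _ in range(50):
        changed = False
        for w in range(graph.n_sites):
            if alleles[w] < 0:
                continue
            gain = 0
            for u in adjacency.get(w, ()):
                key = (u, w) if u < w else (w, u)
                v0, v1 = votes.get(key, (0, 0))
                cur_phase = alleles[u] ^ alleles[w]
                gain += (v1 - v0) if cur_phase == 0 else (v0 - v1)
            if gain > 0:
                alleles[w] ^= 1
                changed = True
        if not changed:
            break
    return PhasingResult(alleles=alleles, components=components)


def write_counts_tsv(all_counts: Sequence[AlleleCounts], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site\tn1\tn2\n")
        for c in all_counts:
            fh.write(f"{c.site}\t{c.n1}\t{c.n2}\n")


def write_calls_tsv(calls: Sequence[SiteCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site\tlambda\tcalled_heterozygous\n")
        for c in calls:
            fh.write(f"{c.site}\t{c.lam:.6f}\t{int(c.called_heterozygous)}\n")
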