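"""Strobe-read simulator.

A strobe read sequences ``k`` subreads of length ``l = floor(L/k)`` from a
single fragment, separated by unsequenced *advances* drawn from
beta-distributions scaled to the admissible range. For ``k = 2`` the
advance maximum is ``A - L`` (``A`` is the maximum insert size); for
``k >= 3`` advances are nested: ``a_1`` (the gap between the first and the
furthest subread) has maximum ``A - 2l`` and each subsequent ``a_i`` has
maximum ``max(a_{i-1} - l, 0)``, which places intermediate subreads inside
the fragment without overlap. Every read records which heterozygous sites
its subreads cover; an experiment of ``N = floor(c*G/L)`` reads at coverage
``c`` turns those co-coverages into SNP-graph edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .graph import SNPGraph
from .track import VariantTrack

logger = logging.getLogger(__name__)

__all__ = [
    "DesignParams",
    "StrobeRead",
    "RegionTooSmallError",
    "num_reads",
    "sample_advance",
    "generate_read",
    "simulate_experiment",
    "write_reads_tsv",
]


class RegionTooSmallError(ValueError):
    """The region is shorter than the maximum insert size."""


@dataclass(frozen=True)
class DesignParams:
    """One experiment design.

    Parameters
    ----------
    L
        Total sequenced bp per fragment (summed over subreads).
    c
        Coverage: ``c = N*L/G``.
    A
        Maximum insert size in bp (end-to-end span bound); ``A >= L``.
    k
        Number of subreads per fragment (>= 1).
    beta_params
        ``k - 1`` shape pairs ``(alpha_i, beta_i)``, one per advance.
        Larger ``alpha`` skews toward long advances, larger ``beta`` toward
        short ones.
    fixed_advance
        If True, every advance takes its maximum value deterministically
        (a fixed-insert design, the degenerate limit of the beta family);
        ``beta_params`` must then be empty.
    seed
        Seed for the experiment's random stream.
    """

    L: int
    c: float
    A: int
    k: int = 2
    beta_params: Tuple[Tuple[float, float], ...] = ()
    fixed_advance: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "beta_params", tuple((float(a), float(b)) for a, b in self.beta_params)
        )
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.subread_length < 1:
            raise ValueError("subread length floor(L/k) must be >= 1")
        if self.A < self.L:
            raise ValueError("maximum insert A must be >= L")
        if self.c < 0:
            raise ValueError("coverage c must be >= 0")
        n_adv = self.k - 1
        if self.fixed_advance:
            if self.beta_params:
                raise ValueError("fixed_advance designs take no beta_params")
        elif len(self.beta_params) != n_adv:
            raise ValueError(f"need {n_adv} (alpha, beta) pairs for k={self.k}")
        for a, b in self.beta_params:
            if a <= 0 or b <= 0:
                raise ValueError("beta shapes must be positive")
        if self.L % self.k:
            logger.warning(
                "L=%d not divisible by k=%d; %d bp dropped per read",
                self.L, self.k, self.L - self.k * self.subread_length,
            )

    @property
    def subread_length(self) -> int:
        return self.L // self.k

    def advance_maximum(self, i: int, prev_advance: Optional[int] = None) -> int:
        """Maximum admissible value of advance ``a_i`` (1-based ``i``)."""
        l = self.subread_length
        if i == 1:
            return self.A - self.L if self.k == 2 else self.A - 2 * l
        if prev_advance is None:
            raise ValueError("nested advances need the previous advance")
        return max(prev_advance - l, 0)


@dataclass(frozen=True)
class StrobeRead:
    """One simulated fragment: subread intervals, advances, covered sites."""

    start: int
    subreads: Tuple[Tuple[int, int], ...]  # half-open [start, end) intervals
    advances: Tuple[int, ...]
    covered_sites: Tuple[int, ...]

    @property
    def insert_span(self) -> int:
        return self.subreads[-1][1] - self.subreads[0][0] if self.subreads else 0


def num_reads(c: float, G: int, L: int) -> int:
    """Number of reads at coverage ``c``: ``N = floor(c*G/L)``."""
    if G <= 0 or L <= 0 or c < 0:
        raise ValueError("require G, L > 0 and c >= 0")
    return int(c * G // L)


def sample_advance(
    alpha: float, beta: float, max_advance: int, rng: np.random.Generator
) -> int:
    """One advance: ``round(max_advance * B)`` with ``B ~ Beta(alpha, beta)``."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("beta shapes must be positive")
    if max_advance <= 0:
        return 0
    return int(np.rint(max_advance * rng.beta(alpha, beta)))


def _relative_starts(l: int, advances: Sequence[int]) -> List[int]:
    """Left ends of all subreads relative to the fragment start.

    The first subread sits at 0; the subread tied to advance ``a_i`` starts
    at ``l + a_i`` (advances are measured from the end of the first
    subread). ``a_1`` is the largest, so it places the furthest subread and
    the rest fill in between, later advances closer in. The nested advance
    maxima keep subreads disjoint except in the corner where an advance
    falls below ``l``; a left-to-right sweep then pushes subreads right
    until they abut, which can only shrink gaps already sampled and never
    grows the span beyond ``max(2l + a_1, k*l) <= A``.
    """
    starts = sorted([0] + [l + a for a in advances])
    for i in range(1, len(starts)):
        if starts[i] < starts[i - 1] + l:
            starts[i] = starts[i - 1] + l
    return starts


def generate_read(
    params: DesignParams,
    G: int,
    rng: np.random.Generator,
    track: Optional[VariantTrack] = None,
    advances: Optional[Sequence[int]] = None,
) -> StrobeRead:
    """Generate one strobe read (reference per-read path).

    Advances are drawn first (nested maxima), then the start ``d_0`` is
    drawn uniformly on ``[0, G - insert]`` so reads never truncate at the
    region boundary. ``advances`` may be supplied to bypass sampling.
    """
    if G < params.A:
        raise RegionTooSmallError(f"region G={G} shorter than max insert A={params.A}")
    l = params.subread_length
    if advances is None:
        adv: List[int] = []
        prev: Optional[int] = None
        for i in range(1, params.k):
            amax = params.advance_maximum(i, prev)
            a = amax if params.fixed_advance else sample_advance(
                *params.beta_params[i - 1], amax, rng
            )
            adv.append(a)
            prev = a
    else:
        adv = list(advances)
        if len(adv) != params.k - 1:
            raise ValueError(f"need {params.k - 1} advances")
    rel = _relative_starts(l, adv)
    insert = rel[-1] + l
    d0 = int(rng.integers(0, G - insert + 1))
    subreads = tuple((d0 + s, d0 + s + l) for s in rel)
    covered: Tuple[int, ...] = ()
    if track is not None:
        hits: List[int] = []
        for s, e in subreads:
            lo = int(np.searchsorted(track.positions, s, side="left"))
            hi = int(np.searchsorted(track.positions, e, side="left"))
            hits.extend(range(lo, hi))
        covered = tuple(sorted(set(hits)))
    return StrobeRead(start=d0, subreads=subreads, advances=tuple(adv), covered_sites=covered)


def simulate_experiment(
    track: VariantTrack,
    params: DesignParams,
    keep_reads: bool = True,
) -> Tuple[SNPGraph, List[StrobeRead]]:
    """Run one full experiment: N reads, clique edges among co-covered sites.

    The random stream is seeded from ``params.seed`` and consumed in
    vectorized blocks (all Beta variates for advance 1, then advance 2, ...,
    then all start positions), so a given seed always yields the same graph.
    A read covering ``s`` sites contributes all ``C(s, 2)`` edges with
    multiplicity. The returned graph carries ``n_reads`` and
    ``n_noninformative_reads`` (reads covering fewer than 2 sites) as
    attributes. Set ``keep_reads=False`` to skip materializing read objects
    (the graph is identical).
    """
    G = track.region_length
    if G < params.A:
        raise RegionTooSmallError(f"region G={G} shorter than max insert A={params.A}")
    rng = np.random.default_rng(params.seed)
    N = num_reads(params.c, G, params.L)
    l = params.subread_length
    k = params.k

    adv = np.zeros((max(k - 1, 0), N), dtype=np.int64)
    for i in range(1, k):
        if i == 1:
            amax = np.full(N, params.advance_maximum(1), dtype=np.int64)
        else:
            amax = np.maximum(adv[i - 2] - l, 0)
        if params.fixed_advance:
            adv[i - 1] = amax
        else:
            a_sh, b_sh = params.beta_params[i - 1]
            adv[i - 1] = np.rint(amax * rng.beta(a_sh, b_sh, size=N)).astype(np.int64)
    # relative subread starts: sort, then sweep to enforce disjointness
    rel = np.zeros((k, N), dtype=np.int64)
    for i in range(1, k):
        rel[i] = l + adv[i - 1]
    rel.sort(axis=0)
    for i in range(1, k):
        rel[i] = np.maximum(rel[i], rel[i - 1] + l)
    insert = rel[-1] + l
    d0 = rng.integers(0, G - insert + 1, size=N)
    starts = rel + d0
    pos = track.positions
    read_ids_parts, site_parts = [], []
    for i in range(k):
        lo = np.searchsorted(pos, starts[i], side="left")
        hi = np.searchsorted(pos, starts[i] + l, side="left")
        lens = hi - lo
        tot = int(lens.sum())
        if tot == 0:
            continue
        # flatten [lo, hi) ranges: repeat starts + within-range offsets
        offs = np.arange(tot) - np.repeat(np.cumsum(lens) - lens, lens)
        site_parts.append(np.repeat(lo, lens) + offs)
        read_ids_parts.append(np.repeat(np.arange(N), lens))

    if site_parts:
        sites_flat = np.concatenate(site_parts)
        reads_flat = np.concatenate(read_ids_parts)
        order = np.argsort(reads_flat, kind="stable")
        reads_flat, sites_flat = reads_flat[order], sites_flat[order]
        sizes = np.bincount(reads_flat, minlength=N)
    else:
        sites_flat = np.empty(0, dtype=np.int64)
        reads_flat = np.empty(0, dtype=np.int64)
        sizes = np.zeros(N, dtype=np.int64)

    # clique edges, batched by reads covering the same number of sites
    offsets = np.cumsum(sizes) - sizes
    edge_u, edge_v = [], []
    for s_val in np.unique(sizes[sizes >= 2]):
        sel = np.nonzero(sizes == s_val)[0]
        mat = sites_flat[offsets[sel][:, None] + np.arange(s_val)]
        for i, j in combinations(range(int(s_val)), 2):
            edge_u.append(mat[:, i])
            edge_v.append(mat[:, j])
    if edge_u:
        graph = SNPGraph(track.n_sites, np.concatenate(edge_u), np.concatenate(edge_v))
    else:
        graph = SNPGraph(track.n_sites)
    graph.n_reads = N
    graph.n_noninformative_reads = int(np.count_nonzero(sizes < 2))

    reads: List[StrobeRead] = []
    if keep_reads:
        for r in range(N):
            a = tuple(int(x) for x in adv[:, r])
            sr_starts = sorted(int(starts[i, r]) for i in range(k))
            covered = tuple(int(x) for x in sites_flat[offsets[r] : offsets[r] + sizes[r]])
            reads.append(
                StrobeRead(
                    start=int(d0[r]),
                    subreads=tuple((s, s + l) for s in sr_starts),
                    advances=a,
                    covered_sites=tuple(sorted(covered)),
                )
            )
    return graph, reads


def write_reads_tsv(reads: Sequence[StrobeRead], path: str | Path) -> None:
    """Audit output: one row per subread with the read's covered site ids."""
    with open(path, "w") as fh:
        fh.write("read_id\tsubread_start\tsubread_end\tcovered_sites\n")
        for rid, read in enumerate(reads):
            cov = ",".join(map(str, read.covered_sites))
            for s, e in read.subreads:
                fh.write(f"{rid}\t{s}\t{e}\t{cov}\n")
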