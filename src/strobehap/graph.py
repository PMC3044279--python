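"""SNP-graph: heterozygous sites as nodes, co-covering reads as edges.

Two sites can be phased if and only if they are connected in this graph, so
its connected components are the haplotype contigs. Edges carry
multiplicity (every read covering ``s`` sites contributes ``C(s, 2)``
edges): a component with ``v`` vertices needs only ``v - 1`` of its ``m``
edges to stay connected, and the remaining ``m - v + 1`` are wasted — the
accounting that separates good designs from bad ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

__all__ = ["SNPGraph", "Component", "connected_components", "count_useful_edges"]


@dataclass(frozen=True)
class Component:
    """One connected component: a haplotype contig."""

    site_indices: np.ndarray  # sorted site indices
    m: int  # internal multigraph edge count

    @property
    def v(self) -> int:
        return int(self.site_indices.size)


class SNPGraph:
    """Multigraph on site indices ``0..n_sites-1``.

    Edges are stored as parallel arrays ``(u, v, multiplicity)`` with
    ``u < v``; self-loops are rejected. Nodes without edges are still part
    of the graph (isolated sites are singleton components).
    """

    def __init__(
        self,
        n_sites: int,
        u: np.ndarray | None = None,
        v: np.ndarray | None = None,
        mult: np.ndarray | None = None,
    ):
        self.n_sites = int(n_sites)
        u = np.asarray(u if u is not None else [], dtype=np.int64)
        v = np.asarray(v if v is not None else [], dtype=np.int64)
        mult = np.asarray(mult if mult is not None else np.ones_like(u), dtype=np.int64)
        if not (u.shape == v.shape == mult.shape):
            raise ValueError("u, v, mult must have equal length")
        lo, hi = np.minimum(u, v), np.maximum(u, v)
        if lo.size:
            if np.any(lo == hi):
                raise ValueError("self-loops are not allowed")
            if lo.min() < 0 or hi.max() >= self.n_sites:
                raise ValueError("site index out of range")
            # collapse duplicate pairs, summing multiplicity
            key = lo * self.n_sites + hi
            order = np.argsort(key, kind="stable")
            key, lo, hi, mult = key[order], lo[order], hi[order], mult[order]
            uniq, start = np.unique(key, return_index=True)
            summed = np.add.reduceat(mult, start)
            lo, hi = lo[start], hi[start]
            mult = summed
        self.u, self.v, self.mult = lo, hi, mult

    @classmethod
    def from_edge_list(cls, n_sites: int, edges: Iterable[Tuple[int, int]]) -> "SNPGraph":
        """Build from an iterable of (i, j) pairs; repeats add multiplicity."""
        pairs = np.asarray(list(edges), dtype=np.int64).reshape(-1, 2)
        return cls(n_sites, pairs[:, 0], pairs[:, 1])

    @property
    def n_edges(self) -> int:
        """Total edges counting multiplicity."""
        return int(self.mult.sum())

    @property
    def n_distinct_edges(self) -> int:
        return int(self.u.size)

    def component_labels(self) -> Tuple[int, np.ndarray]:
        """(number of components, label per site) over the simple graph."""
        if self.u.size == 0:
            return self.n_sites, np.arange(self.n_sites)
        data = np.ones(self.u.size, dtype=np.int8)
        adj = coo_matrix(
            (data, (self.u, self.v)), shape=(self.n_sites, self.n_sites)
        )
        n_comp, labels = _cc(adj, directed=False)
        return int(n_comp), labels

    def connected_components(self) -> List[Component]:
        """Components sorted by leftmost (smallest) site index.

        Each component records ``v`` (site count) and ``m`` (internal
        multigraph edge count, multiplicity included).
        """
        n_comp, labels = self.component_labels()
        # internal edge mass per component (both endpoints share a label)
        m_per = np.zeros(n_comp, dtype=np.int64)
        if self.u.size:
            np.add.at(m_per, labels[self.u], self.mult)
        order = np.argsort(labels, kind="stable")
        sorted_labels = labels[order]
        boundaries = np.searchsorted(sorted_labels, np.arange(n_comp))
        comps = []
        for c in range(n_comp):
            start = boundaries[c]
            end = boundaries[c + 1] if c + 1 < n_comp else self.n_sites
            sites = np.sort(order[start:end])
            comps.append(Component(site_indices=sites, m=int(m_per[c])))
        comps.sort(key=lambda comp: int(comp.site_indices[0]))
        return comps

    def to_edge_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("site_i\tsite_j\tmultiplicity\n")
            for a, b, w in zip(self.u, self.v, self.mult):
                fh.write(f"{a}\t{b}\t{w}\n")


def connected_components(graph: SNPGraph) -> List[Component]:
    """Module-level alias for :meth:`SNPGraph.connected_components`."""
    return graph.connected_components()


def count_useful_edges(graph: SNPGraph) -> Tuple[int, int, float]:
    """Useful / wasted edge accounting over the whole graph.

    A component with ``v`` vertices and ``m`` edges has ``v - 1`` useful
    edges (a spanning tree) and ``m - v + 1`` wasted ones. Summed over
    components: useful = n_sites - n_components; wasted = total - useful.

    Returns ``(useful, wasted, useful_fraction)``; the fraction is 0 when
    the graph has no edges.
    """
    n_comp, _ = graph.component_labels()
    useful = graph.n_sites - n_comp
    total = graph.n_edges
    wasted = total - useful
    fraction = useful / total if total > 0 else 0.0
    return useful, wasted, fraction
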