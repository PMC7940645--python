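"""Zero-dimensional persistent homology of a graph filtration.

The filtration sweeps a threshold λ over [0, 1]; at each λ the network
contains every ROI pair with dissimilarity d_ij ≤ λ (closed threshold,
so the Betti-0 curve is right-continuous and breakpoints are attained).
All the objects computed here are facets of one structure:

* the minimum spanning tree (MST) of ``d`` — its edge weights are
  exactly the thresholds at which connected components merge;
* the Betti-0 curve β₀(λ), the component count, which drops at each
  distinct MST weight;
* the barcode — one bar per ROI, born at 0, dying at its component's
  merge threshold (the last survivor is capped at the filtration
  ceiling, 1 by default);
* the single-linkage distance (SLD), the minimax-path ultrametric
  sld_ij = smallest λ at which i and j share a component, with its
  dendrogram/merge tree;
* the SIP AUC, the integral of β₀ over [0, ceiling] — the aggregation
  cost of assembling the network into one component.  It satisfies the
  identity ``sip_auc = ceiling + Σ MST weights`` (checked at build
  time), so a larger value means slower, less efficient integration.

Under tied distances the MST edge *set* may be non-unique; Kruskal order
is fixed as (weight, smaller index, larger index), and everything
exposed as a result (total weight, β₀, barcode, SLD) is tie-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import DistanceMatrix

__all__ = [
    "Betti0Curve",
    "Barcode",
    "SingleLinkageResult",
    "PersistenceResult",
    "Snapshot",
    "compute_mst",
    "betti0_curve",
    "barcode",
    "single_linkage",
    "sip_auc",
    "snapshot_graph",
    "analyze_distance",
    "to_newick",
]


class _UnionFind:
    __slots__ = ("parent", "rank")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


@dataclass
class Betti0Curve:
    """Piecewise-constant component count over the filtration.

    ``counts[k]`` holds on the interval [breakpoints[k-1], breakpoints[k])
    (right-continuous; counts[0] holds below the first breakpoint and the
    final count from the last breakpoint onward).
    """

    breakpoints: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.counts) != len(self.breakpoints) + 1:
            raise ValueError("counts must have one more entry than breakpoints")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(np.diff(self.counts) >= 0):
            raise ValueError("component counts must strictly decrease")

    def __call__(self, lam: float) -> int:
        """β₀ at filtration value ``lam`` (edge present iff d ≤ lam)."""
        return int(self.counts[np.searchsorted(self.breakpoints, lam, side="right")])


@dataclass
class Barcode:
    """(birth, death) bars of connected components; births are all 0."""

    bars: list[tuple[float, float]]

    @property
    def finite_deaths(self) -> list[float]:
        """Deaths of all bars except the last survivor (capped bar)."""
        deaths = sorted(d for _, d in self.bars)
        return deaths[:-1]


@dataclass
class SingleLinkageResult:
    """Minimax-path ultrametric and its merge tree."""

    sld: np.ndarray
    merge_tree: list[tuple[float, tuple[int, ...], tuple[int, ...]]]
    roi_names: list[str]


@dataclass
class Snapshot:
    """The thresholded graph at one filtration value."""

    lam: float
    edges: list[tuple[int, int, float]]
    component_labels: np.ndarray
    roi_names: list[str]

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1


@dataclass
class PersistenceResult:
    """All zero-dimensional persistence facets of one distance matrix."""

    betti: Betti0Curve
    barcode: Barcode
    mst_edges: list[tuple[int, int, float]]
    single_linkage: SingleLinkageResult
    sip_auc: float
    roi_names: list[str]

    @property
    def mst_total(self) -> float:
        return float(sum(w for _, _, w in self.mst_edges))


def _sorted_edges(dist: DistanceMatrix) -> list[tuple[float, int, int]]:
    d = dist.d
    n = d.shape[0]
    edges = [(float(d[i, j]), i, j) for i in range(n) for j in range(i + 1, n)]
    edges.sort()
    return edges


def compute_mst(dist: DistanceMatrix) -> list[tuple[int, int, float]]:
    """Kruskal minimum spanning tree; ties broken by (weight, i, j)."""
    n = dist.n_rois
    if n < 2:
        raise ValueError("MST needs at least 2 ROIs")
    uf = _UnionFind(n)
    out: list[tuple[int, int, float]] = []
    for w, i, j in _sorted_edges(dist):
        if uf.union(i, j):
            out.append((i, j, w))
            if len(out) == n - 1:
                break
    return out


def betti0_curve(dist: DistanceMatrix) -> Betti0Curve:
    """Exact β₀ curve: breakpoints are the distinct MST edge weights."""
    n = dist.n_rois
    weights = np.array(sorted(w for _, _, w in compute_mst(dist)))
    bps: list[float] = []
    counts = [n]
    for w in weights:
        if bps and w == bps[-1]:
            counts[-1] -= 1
        else:
            bps.append(float(w))
            counts.append(counts[-1] - 1)
    return Betti0Curve(breakpoints=np.array(bps), counts=np.array(counts))


def barcode(dist: DistanceMatrix, ceiling: float = 1.0) -> Barcode:
    """One bar per ROI: finite deaths are the MST weights, plus one bar
    for the surviving component capped at the filtration ceiling."""
    deaths = sorted(w for _, _, w in compute_mst(dist))
    return Barcode(bars=[(0.0, d) for d in deaths] + [(0.0, float(ceiling))])


def single_linkage(dist: DistanceMatrix) -> SingleLinkageResult:
    """Single-linkage ultrametric via the Kruskal merge sequence.

    When components A and B merge at weight w, sld(a, b) = w for every
    a in A, b in B; the merge tree records (w, members of A, members of B)
    with each side sorted and the side containing the smaller index first.
    """
    n = dist.n_rois
    if n < 2:
        raise ValueError("single linkage needs at least 2 ROIs")
    uf = _UnionFind(n)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    sld = np.zeros((n, n))
    merges: list[tuple[float, tuple[int, ...], tuple[int, ...]]] = []
    n_merges = 0
    for w, i, j in _sorted_edges(dist):
        ri, rj = uf.find(i), uf.find(j)
        if ri == rj:
            continue
        side_a, side_b = sorted((members[ri], members[rj]), key=min)
        for a in side_a:
            for b in side_b:
                sld[a, b] = sld[b, a] = w
        merges.append((w, tuple(sorted(side_a)), tuple(sorted(side_b))))
        uf.union(ri, rj)
        root = uf.find(ri)
        members[root] = side_a + side_b
        n_merges += 1
        if n_merges == n - 1:
            break
    return SingleLinkageResult(sld=sld, merge_tree=merges, roi_names=list(dist.roi_names))


def sip_auc(betti: Betti0Curve, ceiling: float = 1.0) -> float:
    """Integral of the piecewise-constant β₀ over [0, ceiling].

    Breakpoints beyond the ceiling are clipped into it (with the default
    ``1 - |r|`` distance all weights already lie in [0, 1]).
    """
    edges = np.concatenate([[0.0], np.minimum(betti.breakpoints, ceiling), [ceiling]])
    widths = np.diff(edges)
    return float(np.dot(widths, betti.counts))


def snapshot_graph(dist: DistanceMatrix, lam: float) -> Snapshot:
    """Edges with d_ij ≤ lam plus connected-component labels."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"filtration value {lam} outside [0, 1]")
    n = dist.n_rois
    d = dist.d
    uf = _UnionFind(n)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= lam:
                edges.append((i, j, float(d[i, j])))
                uf.union(i, j)
    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for i in range(n):
        root = uf.find(i)
        labels[i] = seen.setdefault(root, len(seen))
    return Snapshot(lam=lam, edges=edges, component_labels=labels, roi_names=list(dist.roi_names))


def analyze_distance(dist: DistanceMatrix, ceiling: float = 1.0) -> PersistenceResult:
    """Compute every persistence facet and verify the AUC/MST identity."""
    mst = compute_mst(dist)
    betti = betti0_curve(dist)
    auc = sip_auc(betti, ceiling=ceiling)
    total = sum(w for _, _, w in mst)
    if abs(auc - (ceiling + total)) > 1e-9 and np.all(dist.d <= ceiling):
        raise AssertionError(
            f"persistence identity violated: AUC {auc} vs ceiling+MST {ceiling + total}"
        )
    return PersistenceResult(
        betti=betti,
        barcode=barcode(dist, ceiling=ceiling),
        mst_edges=mst,
        single_linkage=single_linkage(dist),
        sip_auc=auc,
        roi_names=list(dist.roi_names),
    )


def to_newick(result: SingleLinkageResult) -> str:
    """Newick dendrogram with merge heights as node heights (branch
    lengths are height differences, so the tree is ultrametric)."""
    names = result.roi_names
    # state per live component, keyed by sorted member tuple
    state: dict[tuple[int, ...], tuple[str, float]] = {
        (i,): (names[i].replace(" ", "_"), 0.0) for i in range(len(names))
    }
    for w, side_a, side_b in result.merge_tree:
        rep_a, h_a = state.pop(side_a)
        rep_b, h_b = state.pop(side_b)
        rep = f"({rep_a}:{w - h_a:.10g},{rep_b}:{w - h_b:.10g})"
        state[tuple(sorted(side_a + side_b))] = (rep, w)
    (rep, _), = state.values()
    return rep + ";"
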