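"""Cross-technology cell pairing via minimum-cost maximum-flow.

Cells of two technologies, embedded in the shared latent space, are paired
by solving a capacitated flow problem: a root node feeds one unit of flow to
every cell of the *bigger* dataset; candidate arcs (the union of the two
directed k-nearest-neighbor queries, costed by Euclidean latent distance)
carry flow to cells of the smaller dataset, whose arcs into the sink have
capacities that spread the larger dataset's cells uniformly (one-to-many
matching, at most ceil(n/m) per cell).  A densely connected *null node* with
a penalty cost at the p-th percentile of candidate costs absorbs cells with
no adequate analog, so poor matches are dropped rather than forced.

The flow problem is solved as a linear program (scipy's HiGHS simplex);
min-cost-flow constraint matrices are totally unimodular, so the basic
optimum is integral, which is asserted after every solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog
from sklearn.neighbors import NearestNeighbors

from .datasets import LatentCodes

__all__ = [
    "CandidateEdgeSet",
    "FlowNetwork",
    "MatchResult",
    "build_candidate_edges",
    "build_flow_network",
    "solve_min_cost_flow",
    "match_cells",
]

#: Euclidean costs are scaled by this factor and rounded to integers
COST_SCALE = 1_000_000


@dataclass
class CandidateEdgeSet:
    """Union of the two directed kNN queries between two code sets."""

    left: np.ndarray  # indices into the bigger (left) dataset
    right: np.ndarray  # indices into the smaller (right) dataset
    cost: np.ndarray  # Euclidean latent distances
    k: int
    n_left: int
    n_right: int

    def __len__(self) -> int:
        return len(self.left)


@dataclass
class FlowNetwork:
    """Capacitated arc list of the matching network.

    Node numbering: 0 = root, ``1..n`` = left cells, ``n+1..n+m`` = right
    cells, ``n+m+1`` = null, ``n+m+2`` = sink.  ``arcs`` columns are
    (tail, head, capacity); ``arc_cost`` holds the integerized costs.
    ``edge_slice`` marks which arcs are left-right candidate edges and
    ``null_slice`` the left-null arcs.
    """

    n: int
    m: int
    arcs: np.ndarray
    arc_cost: np.ndarray
    null_cost: float
    edges: CandidateEdgeSet
    edge_slice: slice = field(default_factory=lambda: slice(0, 0))
    null_slice: slice = field(default_factory=lambda: slice(0, 0))
    sink_capacity: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def root(self) -> int:
        return 0

    @property
    def null_node(self) -> int:
        return self.n + self.m + 1

    @property
    def sink(self) -> int:
        return self.n + self.m + 2


@dataclass
class MatchResult:
    """Pairs of matched cells plus the cells assigned to the null node."""

    pairs: list[tuple[str, str, float]]
    null_assigned: list[str]
    k: int
    p: float
    total_cost: float
    source_ids: list[str] = field(default_factory=list)
    target_ids: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def build_candidate_edges(Zs: LatentCodes, Zt: LatentCodes, k: int) -> CandidateEdgeSet:
    """Candidate matches: union of source->target and target->source kNN.

    ``Zs`` is treated as the left (bigger) side here; :func:`match_cells`
    handles orientation.  Costs are Euclidean distances in latent space; the
    same pair found by both directed queries is kept once.
    """
    A = Zs.codes if isinstance(Zs, LatentCodes) else np.asarray(Zs, dtype=float)
    B = Zt.codes if isinstance(Zt, LatentCodes) else np.asarray(Zt, dtype=float)
    if len(A) == 0 or len(B) == 0:
        raise ValueError("code sets must be non-empty")
    if not 1 <= k <= min(len(A), len(B)):
        raise ValueError(f"k must lie in [1, {min(len(A), len(B))}]")
    d_ab, i_ab = NearestNeighbors(n_neighbors=k).fit(B).kneighbors(A)
    d_ba, i_ba = NearestNeighbors(n_neighbors=k).fit(A).kneighbors(B)
    left = np.concatenate([np.repeat(np.arange(len(A)), k), i_ba.ravel()])
    right = np.concatenate([i_ab.ravel(), np.repeat(np.arange(len(B)), k)])
    cost = np.concatenate([d_ab.ravel(), d_ba.ravel()])
    key = left.astype(np.int64) * len(B) + right
    order = np.argsort(key, kind="stable")
    key, left, right, cost = key[order], left[order], right[order], cost[order]
    keep = np.ones(len(key), dtype=bool)
    keep[1:] = key[1:] != key[:-1]
    return CandidateEdgeSet(
        left=left[keep],
        right=right[keep],
        cost=cost[keep],
        k=k,
        n_left=len(A),
        n_right=len(B),
    )


def _sink_capacities(n: int, m: int) -> np.ndarray:
    """Spread n units over m sink arcs as evenly as integers allow."""
    base = n // m
    caps = np.full(m, base, dtype=np.int64)
    caps[: n % m] += 1
    return caps


def build_flow_network(
    cands: CandidateEdgeSet,
    p: float,
    n: int | None = None,
    m: int | None = None,
    *,
    allow_null: bool = True,
    unbounded_sink: bool = False,
) -> FlowNetwork:
    """Assemble the capacitated matching network from candidate edges.

    The null-match penalty is the ``p``-th percentile (linear interpolation)
    of the candidate costs.  Sink-arc capacities split ``n`` uniformly over
    the ``m`` right cells (``floor(n/m)`` with ``n mod m`` arcs incremented),
    or are unbounded when ``unbounded_sink`` is set.  ``allow_null=False``
    omits the null node entirely (the network may then be infeasible if the
    candidate graph is too sparse).
    """
    if len(cands) == 0:
        raise ValueError("candidate edge set is empty")
    if not 0.0 < p <= 100.0:
        raise ValueError("p must lie in (0, 100]")
    n = cands.n_left if n is None else n
    m = cands.n_right if m is None else m
    if n < m:
        raise ValueError("the left side must be the bigger dataset (n >= m)")
    null_cost = float(np.percentile(cands.cost, p))
    int_cost = np.round(cands.cost * COST_SCALE).astype(np.int64)
    # +1 breaks exact ties in favor of a real match over a null assignment
    int_null = int(round(null_cost * COST_SCALE)) + 1
    caps = (
        np.full(m, n, dtype=np.int64) if unbounded_sink else _sink_capacities(n, m)
    )

    root, null_node, sink = 0, n + m + 1, n + m + 2
    E = len(cands)
    blocks = [
        # root -> left, capacity 1, cost 0
        (
            np.full(n, root),
            1 + np.arange(n),
            np.ones(n, dtype=np.int64),
            np.zeros(n, dtype=np.int64),
        ),
        # left -> right candidate arcs, capacity 1
        (1 + cands.left, 1 + n + cands.right, np.ones(E, dtype=np.int64), int_cost),
    ]
    e0, e1 = n, n + E
    e2 = e1
    if allow_null:
        blocks.append(
            (
                1 + np.arange(n),
                np.full(n, null_node),
                np.ones(n, dtype=np.int64),
                np.full(n, int_null, dtype=np.int64),
            )
        )
        e2 = e1 + n
    blocks.append(
        (1 + n + np.arange(m), np.full(m, sink), caps, np.zeros(m, dtype=np.int64))
    )
    if allow_null:
        blocks.append(
            (
                np.array([null_node]),
                np.array([sink]),
                np.array([n], dtype=np.int64),
                np.zeros(1, dtype=np.int64),
            )
        )
    tails = np.concatenate([b[0] for b in blocks]).astype(np.int64)
    heads = np.concatenate([b[1] for b in blocks]).astype(np.int64)
    arc_caps = np.concatenate([b[2] for b in blocks]).astype(np.int64)
    arc_costs = np.concatenate([b[3] for b in blocks]).astype(np.int64)
    return FlowNetwork(
        n=n,
        m=m,
        arcs=np.column_stack([tails, heads, arc_caps]),
        arc_cost=arc_costs,
        null_cost=null_cost,
        edges=cands,
        edge_slice=slice(e0, e1),
        null_slice=slice(e1, e2),
        sink_capacity=caps,
    )


def solve_min_cost_flow(
    net: FlowNetwork,
    source_ids: list[str] | None = None,
    target_ids: list[str] | None = None,
) -> MatchResult:
    """Push ``n`` units of flow at minimum cost and read off the matching.

    Solved as an LP over the node-arc incidence matrix with HiGHS; the basic
    optimum of a min-cost-flow LP is integral, which is verified before the
    flow is decoded into pairs.  Raises if the network is infeasible (only
    possible when the null node was disabled).
    """
    n, m = net.n, net.m
    n_nodes = n + m + 3
    tails, heads, caps = net.arcs[:, 0], net.arcs[:, 1], net.arcs[:, 2]
    n_arcs = len(tails)
    rows = np.concatenate([tails, heads])
    cols = np.concatenate([np.arange(n_arcs), np.arange(n_arcs)])
    vals = np.concatenate([np.ones(n_arcs), -np.ones(n_arcs)])
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n_nodes, n_arcs))
    b = np.zeros(n_nodes)
    b[net.root] = n
    b[net.sink] = -n
    res = linprog(
        net.arc_cost.astype(float),
        A_eq=A,
        b_eq=b,
        bounds=np.column_stack([np.zeros(n_arcs), caps.astype(float)]),
        method="highs",
    )
    if res.status != 0:
        raise RuntimeError(
            f"flow solve failed (status {res.status}): {res.message}; "
            "a network with the null node enabled is always feasible"
        )
    flow = np.round(res.x)
    if not np.allclose(res.x, flow, atol=1e-6):
        raise RuntimeError("flow solution is not integral")
    if int(flow[: n].sum()) != n:  # root arcs come first, one per left cell
        raise RuntimeError("maximum flow does not cover the left side")

    source_ids = source_ids or [f"left{i}" for i in range(n)]
    target_ids = target_ids or [f"right{j}" for j in range(m)]
    pairs = []
    e = net.edge_slice
    used = flow[e] > 0.5
    for l, r, c in zip(
        net.edges.left[used], net.edges.right[used], net.edges.cost[used]
    ):
        pairs.append((source_ids[l], target_ids[r], float(c)))
    null_assigned = []
    if net.null_slice.stop > net.null_slice.start:
        null_flow = flow[net.null_slice] > 0.5
        null_assigned = [source_ids[i] for i in np.nonzero(null_flow)[0]]
    total = float(net.arc_cost @ flow) / COST_SCALE
    return MatchResult(
        pairs=pairs,
        null_assigned=null_assigned,
        k=net.edges.k,
        p=float("nan"),
        total_cost=total,
        source_ids=source_ids,
        target_ids=target_ids,
    )


def match_cells(
    Zs: LatentCodes,
    Zt: LatentCodes,
    k: int = 50,
    p: float = 95.0,
    *,
    allow_null: bool = True,
    unbounded_sink: bool = False,
) -> MatchResult:
    """End-to-end pairing of two technologies' cells from latent codes.

    Builds the kNN candidate graph, assembles the flow network (the bigger
    dataset always feeds the root side), solves it, and reports pairs in
    (source, target) orientation regardless of which side was bigger.
    Defaults ``k=50`` and ``p=95`` are the standard real-data settings.
    """
    Zs_arr = Zs if isinstance(Zs, LatentCodes) else LatentCodes(np.asarray(Zs, float))
    Zt_arr = Zt if isinstance(Zt, LatentCodes) else LatentCodes(np.asarray(Zt, float))
    swapped = Zs_arr.n_cells < Zt_arr.n_cells
    left, right = (Zt_arr, Zs_arr) if swapped else (Zs_arr, Zt_arr)
    cands = build_candidate_edges(left, right, k=k)
    net = build_flow_network(
        cands, p=p, allow_null=allow_null, unbounded_sink=unbounded_sink
    )
    result = solve_min_cost_flow(net, list(left.cell_ids), list(right.cell_ids))
    result.p = p
    if swapped:
        result.pairs = [(s, t, c) for t, s, c in result.pairs]
        result.source_ids, result.target_ids = result.target_ids, result.source_ids
    return result
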