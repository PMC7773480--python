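"""Simulated multi-technology single-cell data from a shared branching process.

Cells live on a rooted lineage tree whose branches carry pseudotime lengths.
Each "technology" owns an independent expression program: per feature, the
log-mean follows a Gaussian random walk along pseudotime (continuous across
branch points), and observed counts are negative-binomial draws around the
program mean.  Because the programs are drawn independently per technology,
the datasets share the latent branching structure but have no feature
correspondences at all — the regime the integration model is built for.

Every cell keeps its ground-truth branch label and pseudotime, which makes
matching accuracy and pseudotime agreement directly measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import CellTruth, ExpressionDataset

__all__ = [
    "LineageTree",
    "ExpressionProgram",
    "make_default_tree",
    "simulate_programs",
    "sample_cells",
    "sample_counts",
    "generate_technologies",
]

#: expected total counts per cell after library-size scaling
DEFAULT_LIBRARY_SIZE = 10_000.0

#: default standard deviation of the log-mean random walk per unit pseudotime
DEFAULT_WALK_SD = 0.3

#: per-feature NB dispersions are drawn log-uniformly from this range
DISPERSION_RANGE = (1.0, 100.0)


@dataclass
class LineageTree:
    """Rooted tree with branch lengths measured in pseudotime units.

    ``parent[b]`` is ``None`` for the root branch.  A cell on branch ``b`` at
    within-branch offset ``u`` has global pseudotime ``start(b) + u`` where
    ``start(b)`` is the summed length of all ancestor branches, so pseudotime
    is monotone along every root-to-leaf path.
    """

    parent: dict[str, str | None]
    length: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.parent) != set(self.length):
            raise ValueError("parent and length must cover the same branches")
        roots = [b for b, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root branch")
        for b, ln in self.length.items():
            if not ln > 0:
                raise ValueError(f"branch {b!r} has non-positive length {ln}")
        # cycle / connectivity check: every branch must reach the root
        for b in self.parent:
            seen = set()
            cur: str | None = b
            while cur is not None:
                if cur in seen:
                    raise ValueError("tree contains a cycle")
                seen.add(cur)
                cur = self.parent[cur]

    @property
    def root(self) -> str:
        return next(b for b, p in self.parent.items() if p is None)

    @property
    def branches(self) -> list[str]:
        """Branches in a deterministic parent-before-child order."""
        order: list[str] = []
        remaining = sorted(self.parent)
        while remaining:
            for b in list(remaining):
                p = self.parent[b]
                if p is None or p in order:
                    order.append(b)
                    remaining.remove(b)
        return order

    def children(self, branch: str) -> list[str]:
        return sorted(b for b, p in self.parent.items() if p == branch)

    def start(self, branch: str) -> float:
        """Pseudotime at which ``branch`` begins (cumulative ancestor length)."""
        t = 0.0
        p = self.parent[branch]
        while p is not None:
            t += self.length[p]
            p = self.parent[p]
        return t

    @property
    def total_length(self) -> float:
        return float(sum(self.length.values()))


def make_default_tree() -> LineageTree:
    """The default five-branch lineage tree with pairwise-distinct lengths.

    Root branch of length 20 splits into branches of lengths 15 and 25; the
    length-25 branch splits again into branches of lengths 10 and 30.  The mix
    of shallow and deep tips gives cells a broad pseudotime range (0-75).
    """
    parent = {"A": None, "B": "A", "C": "A", "D": "C", "E": "C"}
    length = {"A": 20.0, "B": 15.0, "C": 25.0, "D": 10.0, "E": 30.0}
    return LineageTree(parent=parent, length=length)


@dataclass
class ExpressionProgram:
    """Per-branch expression means on a pseudotime grid, plus NB dispersions.

    ``mu[b]`` has shape ``(n_grid_points(b), n_features)`` with grid points at
    within-branch offsets ``0, step, 2*step, ..., length(b)``.  Means are
    continuous at branch points: a child's first grid row equals its parent's
    last.  ``dispersion`` holds one NB size parameter per feature
    (``Var = mu + mu^2 / dispersion``).
    """

    tree: LineageTree
    mu: dict[str, np.ndarray]
    dispersion: np.ndarray
    grid_step: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.dispersion.shape[0]

    def mean_at(self, branch: str, pseudotime: float) -> np.ndarray:
        """Program mean at the grid point nearest to a cell's position."""
        offset = pseudotime - self.tree.start(branch)
        grid = self.mu[branch]
        idx = int(round(offset / self.grid_step))
        idx = min(max(idx, 0), grid.shape[0] - 1)
        return grid[idx]


def _branch_grid(length: float, step: float) -> np.ndarray:
    """Within-branch grid offsets 0..length (endpoint always included)."""
    n = int(np.floor(length / step + 1e-9))
    pts = np.arange(n + 1) * step
    if pts[-1] < length - 1e-9:
        pts = np.append(pts, length)
    return pts


def simulate_programs(
    tree: LineageTree,
    n_features: int,
    walk_sd: float = DEFAULT_WALK_SD,
    seed: int = 0,
    *,
    grid_step: float = 1.0,
    library_size: float = DEFAULT_LIBRARY_SIZE,
) -> ExpressionProgram:
    """Draw one technology's expression program along the tree.

    Each feature's log-mean performs a Gaussian random walk over the
    pseudotime grid: increments over a step of size ``dt`` have standard
    deviation ``walk_sd * sqrt(dt)``, and each child branch continues from its
    parent's terminal value, so means are continuous at branch points.  The
    exponentiated walks are scaled by a single global factor so that the
    expected total count of a cell drawn uniformly along the tree equals
    ``library_size``.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if walk_sd < 0:
        raise ValueError("walk_sd must be non-negative")
    rng = np.random.default_rng(seed)

    log_mu: dict[str, np.ndarray] = {}
    for b in tree.branches:  # parents precede children
        offsets = _branch_grid(tree.length[b], grid_step)
        parent = tree.parent[b]
        if parent is None:
            start = rng.normal(0.0, 1.0, size=n_features)
        else:
            start = log_mu[parent][-1]
        walk = np.empty((len(offsets), n_features))
        walk[0] = start
        steps = np.diff(offsets)
        incr = rng.normal(size=(len(steps), n_features)) * (
            walk_sd * np.sqrt(steps)[:, None]
        )
        walk[1:] = start + np.cumsum(incr, axis=0)
        log_mu[b] = walk

    mu = {b: np.exp(v) for b, v in log_mu.items()}
    # library-size scaling: average per-cell total under uniform sampling
    tot, wsum = 0.0, 0.0
    for b, v in mu.items():
        w = tree.length[b]
        tot += w * float(v.sum(axis=1).mean())
        wsum += w
    scale = library_size / (tot / wsum)
    mu = {b: v * scale for b, v in mu.items()}

    dispersion = np.exp(
        rng.uniform(np.log(DISPERSION_RANGE[0]), np.log(DISPERSION_RANGE[1]), n_features)
    )
    return ExpressionProgram(
        tree=tree,
        mu=mu,
        dispersion=dispersion,
        grid_step=grid_step,
        meta={"walk_sd": walk_sd, "seed": seed, "library_size": library_size},
    )


def sample_cells(tree: LineageTree, n_cells: int, seed: int = 0) -> list[CellTruth]:
    """Sample cell positions uniformly over the total tree length."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    branches = tree.branches
    lengths = np.array([tree.length[b] for b in branches])
    edges = np.concatenate([[0.0], np.cumsum(lengths)])
    u = rng.uniform(0.0, edges[-1], size=n_cells)
    idx = np.clip(np.searchsorted(edges, u, side="right") - 1, 0, len(branches) - 1)
    cells = []
    for i in range(n_cells):
        b = branches[idx[i]]
        offset = u[i] - edges[idx[i]]
        cells.append(CellTruth(branch=b, pseudotime=tree.start(b) + offset))
    return cells


def sample_counts(
    program: ExpressionProgram,
    truth: list[CellTruth],
    seed: int = 0,
    *,
    technology: str = "tech",
) -> ExpressionDataset:
    """Draw negative-binomial counts for each cell from the program.

    Counts are sampled via the gamma-Poisson mixture: with per-feature size
    ``r`` and mean ``mu``, ``lambda ~ Gamma(r, mu / r)`` and
    ``count ~ Poisson(lambda)``, which gives ``Var = mu + mu^2 / r``.
    """
    rng = np.random.default_rng(seed)
    n = len(truth)
    g = program.n_features
    mu = np.empty((n, g))
    for i, cell in enumerate(truth):
        if cell.branch not in program.mu:
            raise ValueError(f"branch {cell.branch!r} not covered by the program")
        mu[i] = program.mean_at(cell.branch, cell.pseudotime)
    r = program.dispersion[None, :]
    lam = np.where(mu > 0, rng.gamma(np.broadcast_to(r, mu.shape), mu / r), 0.0)
    counts = rng.poisson(lam)
    return ExpressionDataset(
        counts=counts.astype(np.int64),
        technology=technology,
        branch=np.array([c.branch for c in truth]),
        pseudotime=np.array([c.pseudotime for c in truth]),
    )


def generate_technologies(
    tree: LineageTree,
    n_tech: int,
    n_cells: int,
    n_features: int,
    seeds: list[int],
    *,
    walk_sd: float = DEFAULT_WALK_SD,
    shared_cells: bool = False,
) -> list[ExpressionDataset]:
    """Generate ``n_tech`` datasets with shared structure, disjoint features.

    Each technology receives an independently seeded expression program (so
    the feature spaces correspond in no way), while cells are drawn from the
    same tree and sampling density.  With ``shared_cells=True`` every
    technology profiles the *same* cell positions — useful when an exact
    ground-truth pairing is wanted; by default positions are re-drawn per
    technology (aliquots of a common suspension, as in real experiments).
    """
    if n_tech < 2:
        raise ValueError("n_tech must be >= 2")
    if len(seeds) != n_tech:
        raise ValueError("seeds must provide one entry per technology")
    datasets = []
    base_cells = sample_cells(tree, n_cells, seed=seeds[0]) if shared_cells else None
    for t, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        s_prog, s_cells, s_counts = rng.integers(0, 2**31 - 1, size=3)
        program = simulate_programs(tree, n_features, walk_sd=walk_sd, seed=int(s_prog))
        cells = base_cells if shared_cells else sample_cells(tree, n_cells, seed=int(s_cells))
        name = f"tech{t}"
        ds = sample_counts(program, cells, seed=int(s_counts), technology=name)
        ds.feature_names = [f"{name}_f{j}" for j in range(n_features)]
        datasets.append(ds)
    return datasets
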