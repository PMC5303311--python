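"""Synthetic ground truths and data for benchmarking network inference.

Biological interaction networks are approximately scale-free, so the
ground-truth graphs here are preferential-attachment trees (one edge per
arriving node, hence exactly p - 1 edges and edge density 2/p). A true
precision matrix is built on the graph topology, rescaled so the implied
covariance is a correlation matrix, and multivariate normal expression
data is drawn from it. Prior-knowledge weight matrices are derived from
the truth and corrupted to a chosen accuracy level to emulate interaction
databases that contain spurious entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "PrecisionTruth",
    "TwoGroupTruth",
    "generate_scale_free_graph",
    "build_precision_matrix",
    "sample_data",
    "corrupt_weight_matrix",
    "generate_two_group_data",
]

# Off-diagonal magnitude and diagonal boost of the true precision matrix.
DEFAULT_V = 0.3
DEFAULT_U = 0.1


@dataclass
class PrecisionTruth:
    """A simulated ground truth: graph, precision matrix, covariance."""

    adjacency: np.ndarray
    theta: np.ndarray
    sigma: np.ndarray

    @property
    def p(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edges(self) -> set[tuple[int, int]]:
        ii, jj = np.where(np.triu(self.adjacency, k=1))
        return {(int(i), int(j)) for i, j in zip(ii, jj)}

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, k=1).sum())


@dataclass
class TwoGroupTruth:
    """Two ground truths sharing a backbone, with planted differential hubs.

    ``differential_nodes`` lists the node indices that received extra
    edges in exactly one of the two groups; by construction their true
    scaled-degree difference is positive.
    """

    truth_a: PrecisionTruth
    truth_b: PrecisionTruth
    differential_nodes: list[int] = field(default_factory=list)

    def true_dns(self) -> np.ndarray:
        """|scaled degree in A - scaled degree in B| from the true graphs."""
        da = self.truth_a.adjacency.sum(axis=0).astype(float)
        db = self.truth_b.adjacency.sum(axis=0).astype(float)
        sa = da / da.max() if da.max() > 0 else da
        sb = db / db.max() if db.max() > 0 else db
        return np.abs(sa - sb)


def generate_scale_free_graph(p: int, seed: int) -> np.ndarray:
    """Preferential-attachment tree on ``p`` nodes (binary adjacency).

    Each arriving node attaches to a single existing node with probability
    proportional to its current degree, yielding exactly p - 1 edges, i.e.
    edge density 2/p, and a heavy-tailed degree sequence.
    """
    if p < 3:
        raise ValueError("p must be >= 3")
    g = nx.barabasi_albert_graph(p, 1, seed=int(seed))
    adj = nx.to_numpy_array(g, nodelist=range(p), dtype=np.int8)
    return adj


def build_precision_matrix(
    adjacency: np.ndarray, v: float = DEFAULT_V, u: float = DEFAULT_U
) -> PrecisionTruth:
    """Build a positive-definite precision matrix on a graph topology.

    The off-diagonal part is ``v`` times the adjacency; the diagonal is
    set to |smallest eigenvalue of the off-diagonal part| + 0.1 + u, which
    guarantees positive definiteness. The implied covariance is then
    rescaled to a correlation matrix and the precision matrix recomputed
    as its inverse; this diagonal rescaling leaves the support unchanged.
    """
    adjacency = np.asarray(adjacency)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(adjacency) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    if not np.isin(adjacency, (0, 1)).all():
        raise ValueError("adjacency must be binary")
    p = adjacency.shape[0]
    omega = v * adjacency.astype(float)
    if adjacency.any():
        eigmin = np.linalg.eigvalsh(omega)[0]
        diag = abs(eigmin) + 0.1 + u
    else:
        diag = 0.1 + u
    np.fill_diagonal(omega, diag)
    sigma_raw = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma_raw))
    sigma = sigma_raw / np.outer(d, d)
    sigma = 0.5 * (sigma + sigma.T)
    # inverse of D^-1 Sigma D^-1 is D Omega D: same support, exactly
    theta = omega * np.outer(d, d)
    theta = 0.5 * (theta + theta.T)
    return PrecisionTruth(adjacency=adjacency.astype(np.int8), theta=theta, sigma=sigma)


def sample_data(sigma: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Draw n i.i.d. N(0, sigma) rows, then center and scale columns.

    Columns of the returned matrix sum to 0 and have unit sum of squares,
    the convention under which X'X is the sample correlation matrix.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    sigma = np.asarray(sigma, dtype=float)
    L = np.linalg.cholesky(sigma)  # raises LinAlgError if not PD
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, sigma.shape[0])) @ L.T
    X = X - X.mean(axis=0)
    ss = np.sqrt((X**2).sum(axis=0))
    if np.any(ss == 0):
        raise ValueError("degenerate sample: constant column")
    return X / ss


def corrupt_weight_matrix(truth: PrecisionTruth, acc: float, seed: int) -> np.ndarray:
    """Prior weight matrix at accuracy ``acc``, support size preserved.

    A fraction ``acc`` of the m true edges keep a weight drawn from
    U(0, 1); the remaining round((1 - acc) * m) entries are moved to
    uniformly chosen non-edges with lower-confidence weights drawn from
    U(0, 0.5). Rounding is half-up. All other entries are zero.
    """
    if not (0 < acc <= 1):
        raise ValueError("acc must lie in (0, 1]")
    m = truth.n_edges
    if m < 1:
        raise ValueError("truth must have at least one edge")
    p = truth.p
    rng = np.random.default_rng(seed)
    n_wrong = int(np.floor((1.0 - acc) * m + 0.5))  # round half-up
    n_right = m - n_wrong

    ii, jj = np.triu_indices(p, k=1)
    is_edge = truth.adjacency[ii, jj] > 0
    edge_idx = np.where(is_edge)[0]
    non_edge_idx = np.where(~is_edge)[0]
    keep = rng.choice(edge_idx, size=n_right, replace=False)
    wrong = rng.choice(non_edge_idx, size=n_wrong, replace=False)

    w = np.zeros((p, p))
    w[ii[keep], jj[keep]] = rng.uniform(0.0, 1.0, size=n_right)
    w[ii[wrong], jj[wrong]] = rng.uniform(0.0, 0.5, size=n_wrong)
    w = w + w.T
    return w


def _bounded_degree_tree(p: int, max_degree: int, rng: np.random.Generator) -> np.ndarray:
    """Random recursive tree whose node degrees never exceed ``max_degree``.

    Used as the two-group backbone: capping the backbone degree keeps the
    planted differential hubs unambiguous degree outliers, so their true
    scaled-degree contrast is large and recovery is well-posed. (The
    single-group benchmark generator keeps the preferential-attachment
    tree with its natural hubs instead.)
    """
    adj = np.zeros((p, p), dtype=np.int8)
    deg = np.zeros(p, dtype=int)
    for k in range(1, p):
        open_nodes = np.where(deg[:k] < max_degree)[0]
        target = int(rng.choice(open_nodes))
        adj[k, target] = adj[target, k] = 1
        deg[k] += 1
        deg[target] += 1
    return adj


def generate_two_group_data(
    p: int,
    n_per_group: int,
    n_differential_hubs: int,
    seed: int,
    extra_edges_per_hub: int = 12,
    v: float = 0.5,
    u: float = DEFAULT_U,
) -> tuple[np.ndarray, np.ndarray, TwoGroupTruth]:
    """Two-group expression data with hubs rewired in exactly one group.

    Both groups share a bounded-degree random-tree backbone; each planted
    hub receives ``extra_edges_per_hub`` additional partners in exactly
    one group (alternating between the groups), so its degree — and hence
    its scaled node degree — differs strongly between the group truths
    while the bulk of the network is common to both. Couplings default to
    v = 0.5, near the feasibility cap ~1/sqrt(hub degree) that positive
    definiteness imposes on a hub's partial correlations, emulating
    condition-specific master regulators against a moderate-degree
    background.
    """
    if p < 10:
        raise ValueError("p must be >= 10")
    if n_per_group < 10:
        raise ValueError("n_per_group must be >= 10")
    if n_differential_hubs >= p:
        raise ValueError("n_differential_hubs must be < p")
    rng = np.random.default_rng(seed)
    backbone = _bounded_degree_tree(p, max_degree=4, rng=rng)
    adj_a = backbone.copy()
    adj_b = backbone.copy()
    # plant hubs on low-degree backbone nodes so the degree gain translates
    # into a large scaled-degree contrast (a pre-existing hub gaining edges
    # can leave its scaled degree at 1 in both groups)
    deg = backbone.sum(axis=0)
    candidates = np.where(deg <= 2)[0]
    if candidates.size < n_differential_hubs:
        candidates = np.argsort(deg)[: max(n_differential_hubs, 1)]
    hubs = rng.choice(candidates, size=n_differential_hubs, replace=False)
    for k, h in enumerate(hubs):
        target_adj = adj_a if k % 2 == 0 else adj_b
        non_nb = np.where((target_adj[h] == 0) & (np.arange(p) != h))[0]
        extra = rng.choice(non_nb, size=min(extra_edges_per_hub, non_nb.size), replace=False)
        target_adj[h, extra] = 1
        target_adj[extra, h] = 1
    truth_a = build_precision_matrix(adj_a, v=v, u=u)
    truth_b = build_precision_matrix(adj_b, v=v, u=u)
    X_a = sample_data(truth_a.sigma, n_per_group, seed=int(rng.integers(2**31 - 1)))
    X_b = sample_data(truth_b.sigma, n_per_group, seed=int(rng.integers(2**31 - 1)))
    truth = TwoGroupTruth(
        truth_a=truth_a, truth_b=truth_b, differential_nodes=[int(h) for h in hubs]
    )
    return X_a, X_b, truth
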