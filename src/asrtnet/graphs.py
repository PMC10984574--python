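"""Binary brain-network construction and small-world analysis.

Coherence matrices are thresholded at a percentile into unweighted,
undirected graphs; degree, characteristic path length and clustering are
computed per graph, and the small-world coefficient

    omega = L_rand / L_real - C_real / C_latt

compares each graph against ensembles of edge-count-matched uniform-random
references (for L_rand) and ring-lattice references (for C_latt).
omega < 0 indicates a lattice-like network, omega > 0 a random-like one and
values near zero a small-world balance of integration and segregation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

logger = logging.getLogger(__name__)

__all__ = [
    "AdjacencyNetwork",
    "GraphMetrics",
    "threshold_adjacency",
    "degree",
    "shortest_path_length",
    "clustering",
    "ring_lattice_adjacency",
    "random_gnm_adjacency",
    "null_ensemble",
    "small_world_omega",
    "subject_condition_metrics",
    "omega_reference_suite",
    "to_networkx",
    "write_edgelist",
    "write_graphml",
]


@dataclass
class AdjacencyNetwork:
    """Binary symmetric adjacency matrix with zero diagonal."""

    matrix: np.ndarray
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("adjacency matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("adjacency matrix must have a zero diagonal")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("adjacency matrix must be binary")
        self.matrix = m.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.matrix.sum()) // 2


@dataclass
class GraphMetrics:
    """Per-subject/condition graph metrics averaged over segments."""

    mean_degree_2k: float
    L_real: float
    C_real: float
    L_rand: float
    C_latt: float
    omega: float
    n_null: int
    n_segments: int = 1
    disconnected_flag: bool = False
    C_local: np.ndarray | None = None
    per_segment: list[dict] = field(default_factory=list)


def _upper_values(matrix: np.ndarray) -> np.ndarray:
    n = matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    return matrix[iu]


def threshold_adjacency(
    coh,
    percentile: float = 85.0,
    mode: str = "linear",
    node_labels: list[str] | None = None,
) -> AdjacencyNetwork:
    """Binarize one segment's coherence matrix at the given percentile.

    The percentile is computed over the n(n-1)/2 upper-triangle values of
    this single matrix (``mode`` selects the percentile convention: the
    default interpolates linearly between order statistics; ``"nearest"``
    uses the nearest rank). Pairs with values *strictly above* the
    percentile become edges, so a constant matrix yields an empty graph.
    """
    values = np.asarray(getattr(coh, "values", coh), dtype=float)
    if node_labels is None:
        node_labels = getattr(coh, "node_labels", None)
    pair_vals = _upper_values(values)
    cut = np.percentile(pair_vals, percentile, method=mode)
    mask = np.triu(values > cut, k=1)
    if not mask.any():
        warnings.warn(
            "thresholding produced an empty graph (all pair values equal?)",
            stacklevel=2,
        )
    adj = (mask | mask.T).astype(np.int8)
    return AdjacencyNetwork(adj, node_labels=node_labels)


def degree(adj: AdjacencyNetwork | np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node edge counts and their mean (the ``2k`` degree convention)."""
    m = np.asarray(getattr(adj, "matrix", adj))
    k = m.sum(axis=1).astype(float)
    return k, float(k.mean())


def shortest_path_length(adj: AdjacencyNetwork | np.ndarray) -> tuple[float, bool]:
    """Characteristic path length over finite ordered pairs.

    Returns ``(L, disconnected)``. Distances between nodes in different
    components are excluded from the mean; ``disconnected`` reports whether
    any pair was infinite. An edgeless graph has undefined L (NaN).
    """
    m = np.asarray(getattr(adj, "matrix", adj), dtype=float)
    n = m.shape[0]
    if m.sum() == 0:
        logger.warning("edgeless graph: path length undefined")
        return float("nan"), True
    dist = _csgraph_shortest_path(m, method="D", unweighted=True, directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    disconnected = bool((~np.isfinite(dist[off])).any())
    return float(dist[finite].mean()), disconnected


def clustering(adj: AdjacencyNetwork | np.ndarray) -> tuple[np.ndarray, float]:
    """Local clustering coefficients and their unweighted mean.

    ``C_i = 2 * (edges among neighbours of i) / (k_i (k_i - 1))``, defined
    as 0 for nodes with fewer than two neighbours.
    """
    a = np.asarray(getattr(adj, "matrix", adj), dtype=float)
    k = a.sum(axis=1)
    # (A^3)_ii counts closed 2-paths through i twice per triangle direction
    tri2 = np.einsum("ij,jk,ki->i", a, a, a)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_local = np.where(denom > 0, tri2 / denom, 0.0)
    return c_local, float(c_local.mean())


# ---------------------------------------------------------------------------
# Reference (null) networks


def _ring_positions(n: int, ring: int) -> tuple[np.ndarray, np.ndarray]:
    """Node pairs at cyclic distance ``ring`` on an n-ring."""
    if ring < 1 or 2 * ring > n:
        raise ValueError("ring distance out of range")
    count = n if 2 * ring < n else n // 2
    i = np.arange(count)
    j = (i + ring) % n
    return i, j


def ring_lattice_adjacency(
    n: int, n_edges: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Ring lattice with exactly ``n_edges`` edges.

    Full nearest-neighbour rings are laid down first; leftover edges that do
    not fill a complete ring are distributed uniformly at random among the
    next ring's positions (so an ensemble of such lattices averages over
    leftover placements).
    """
    max_edges = n * (n - 1) // 2
    if n_edges > max_edges:
        raise ValueError("n_edges exceeds the complete graph")
    adj = np.zeros((n, n), dtype=np.int8)
    remaining = n_edges
    ring = 1
    while remaining > 0:
        i, j = _ring_positions(n, ring)
        if remaining >= len(i):
            adj[i, j] = adj[j, i] = 1
            remaining -= len(i)
        else:
            if rng is None:
                rng = np.random.default_rng()
            pick = rng.choice(len(i), size=remaining, replace=False)
            adj[i[pick], j[pick]] = adj[j[pick], i[pick]] = 1
            remaining = 0
        ring += 1
    return adj


def random_gnm_adjacency(
    n: int, n_edges: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random graph with exactly ``n_edges`` edges (G(n, m))."""
    max_edges = n * (n - 1) // 2
    if n_edges > max_edges:
        raise ValueError("n_edges exceeds the complete graph")
    iu = np.triu_indices(n, k=1)
    pick = rng.choice(max_edges, size=n_edges, replace=False)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[0][pick], iu[1][pick]] = 1
    return adj | adj.T


def null_ensemble(
    n_nodes: int,
    n_edges: int,
    reps: int = 2000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Ensemble means (L_rand, C_latt) of the two reference constructions.

    ``reps`` independent uniform G(n, m) graphs give the random reference
    path length; ``reps`` ring lattices with randomized leftover-edge
    placement give the lattice reference clustering coefficient.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError("n_edges exceeds the complete graph")
    if n_edges < n_nodes:
        warnings.warn(
            "n_edges below n_nodes: mean degree < 2, references may be "
            "disconnected",
            stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    l_vals = np.empty(reps)
    c_vals = np.empty(reps)
    for r in range(reps):
        rand_adj = random_gnm_adjacency(n_nodes, n_edges, rng)
        l_vals[r], _ = shortest_path_length(rand_adj)
        latt_adj = ring_lattice_adjacency(n_nodes, n_edges, rng)
        _, c_vals[r] = clustering(latt_adj)
    return float(np.nanmean(l_vals)), float(c_vals.mean())


def small_world_omega(
    L_real: float, C_real: float, L_rand: float, C_latt: float
) -> float:
    """Small-world coefficient ``omega = L_rand/L_real - C_real/C_latt``."""
    if not L_real > 0:
        raise ValueError("L_real must be positive")
    if not C_latt > 0:
        raise ValueError("C_latt must be positive (degenerate density)")
    return float(L_rand / L_real - C_real / C_latt)


def to_networkx(adj: AdjacencyNetwork):
    """Convert to a networkx Graph with electrode labels as node names."""
    import networkx as nx

    labels = adj.node_labels or [str(i) for i in range(adj.n_nodes)]
    graph = nx.Graph()
    graph.add_nodes_from(labels)
    for i, j in zip(*np.nonzero(np.triu(adj.matrix, k=1))):
        graph.add_edge(labels[i], labels[j])
    return graph


def write_edgelist(adj: AdjacencyNetwork, path) -> None:
    """Plain-text edge list (one 'label_a label_b' pair per line)."""
    labels = adj.node_labels or [str(i) for i in range(adj.n_nodes)]
    with open(path, "w") as f:
        for i, j in zip(*np.nonzero(np.triu(adj.matrix, k=1))):
            f.write(f"{labels[i]} {labels[j]}\n")


def write_graphml(adj: AdjacencyNetwork, path) -> None:
    """GraphML export (degree stored as a node attribute)."""
    import networkx as nx

    graph = to_networkx(adj)
    nx.set_node_attributes(graph, dict(graph.degree()), "degree")
    nx.write_graphml(graph, path)


def omega_reference_suite(
    n_graphs: int = 500,
    n_nodes: int = 60,
    density: float = 0.15,
    reps: int = 2000,
    seed: int | None = None,
    rewire_range: tuple[float, float] = (0.05, 0.5),
) -> "pd.DataFrame":
    """Small-world coefficients across a seeded mixed-topology suite.

    Cycles through ring-lattice, Watts-Strogatz (rewiring probability
    drawn uniformly from ``rewire_range``) and uniform-random topologies
    at the given density, evaluating omega for each graph against
    ``reps``-replicate null ensembles. Used to calibrate and bound the
    omega scale at the electrode-montage problem size (omega must stay
    within [-1, 1] at the default 15 percent density).
    """
    import pandas as pd

    from .synthetic import generate_planted_network

    rng = np.random.default_rng(seed)
    cache = _NullCache(reps=reps, seed=seed)
    kinds = ("ring_lattice", "watts_strogatz", "erdos_renyi")
    rows = []
    for i in range(n_graphs):
        kind = kinds[i % 3]
        rewire = float(rng.uniform(*rewire_range))
        net = generate_planted_network(
            kind, n_nodes=n_nodes, density=density, rewire_p=rewire,
            seed=rng.integers(2**31),
        )
        adj = AdjacencyNetwork(net.adjacency)
        _, two_k = degree(adj)
        l_real, _ = shortest_path_length(adj)
        _, c_real = clustering(adj)
        l_rand, c_latt = cache.get(adj.n_nodes, adj.n_edges)
        rows.append(
            {
                "topology": kind,
                "rewire_p": rewire if kind == "watts_strogatz" else np.nan,
                "mean_degree_2k": two_k,
                "L_real": l_real,
                "C_real": c_real,
                "omega": small_world_omega(l_real, c_real, l_rand, c_latt),
            }
        )
    return pd.DataFrame(rows)


class _NullCache:
    """Memoize null_ensemble results per (n, m); one RNG stream per key."""

    def __init__(self, reps: int, seed: int | None):
        self.reps = reps
        self.seed_seq = np.random.SeedSequence(seed)
        self._store: dict[tuple[int, int], tuple[float, float]] = {}

    def get(self, n: int, m: int) -> tuple[float, float]:
        key = (n, m)
        if key not in self._store:
            child = np.random.SeedSequence(
                entropy=self.seed_seq.entropy, spawn_key=(n, m)
            )
            rng = np.random.default_rng(child)
            self._store[key] = null_ensemble(n, m, reps=self.reps, rng=rng)
        return self._store[key]


def subject_condition_metrics(
    coherence_matrices,
    percentile: float = 85.0,
    reps: int = 2000,
    seed: int | None = None,
    percentile_mode: str = "linear",
    averaging_mode: str = "per_segment",
    null_cache: _NullCache | None = None,
) -> GraphMetrics:
    """Graph metrics for one subject/condition from per-segment coherence.

    Default (``averaging_mode="per_segment"``): each segment's coherence
    matrix is thresholded individually, metrics and omega are computed per
    segment with null references matched to that segment's node and edge
    counts, and the subject/condition value is the mean over segments.
    ``averaging_mode="averaged"`` instead averages the coherence matrices
    over segments and thresholds once (sensitivity variant).
    """
    mats = [np.asarray(getattr(c, "values", c), dtype=float) for c in coherence_matrices]
    if not mats:
        raise ValueError("at least one segment is required")
    if averaging_mode == "averaged":
        mats = [np.mean(mats, axis=0)]
    elif averaging_mode != "per_segment":
        raise ValueError(f"unknown averaging_mode: {averaging_mode!r}")

    if null_cache is None:
        null_cache = _NullCache(reps=reps, seed=seed)
    rows = []
    for seg_id, values in enumerate(mats):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            adj = threshold_adjacency(values, percentile, mode=percentile_mode)
        if adj.n_edges == 0:
            rows.append(None)
            continue
        _, two_k = degree(adj)
        l_real, disc = shortest_path_length(adj)
        _, c_real = clustering(adj)
        l_rand, c_latt = null_cache.get(adj.n_nodes, adj.n_edges)
        rows.append(
            {
                "segment": seg_id,
                "mean_degree_2k": two_k,
                "L_real": l_real,
                "C_real": c_real,
                "L_rand": l_rand,
                "C_latt": c_latt,
                "omega": small_world_omega(l_real, c_real, l_rand, c_latt),
                "disconnected": disc,
            }
        )
    valid = [r for r in rows if r is not None]
    if not valid:
        raise ValueError("all segments produced empty graphs")
    if len(valid) < len(rows):
        logger.warning(
            "%d of %d segments produced empty graphs and were skipped",
            len(rows) - len(valid),
            len(rows),
        )

    def mean_of(key: str) -> float:
        return float(np.mean([r[key] for r in valid]))

    logger.info("subject/condition metrics over %d segments", len(valid))
    return GraphMetrics(
        mean_degree_2k=mean_of("mean_degree_2k"),
        L_real=mean_of("L_real"),
        C_real=mean_of("C_real"),
        L_rand=mean_of("L_rand"),
        C_latt=mean_of("C_latt"),
        omega=mean_of("omega"),
        n_null=null_cache.reps,
        n_segments=len(valid),
        disconnected_flag=any(r["disconnected"] for r in valid),
        per_segment=valid,
    )
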