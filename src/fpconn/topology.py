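"""Graph topology of fingerprint-derived subnetworks.

Subject FC matrices are reduced either to the edges of a differential
fingerprint mask or by proportional thresholding, yielding non-negative
weighted undirected graphs.  Eight measures summarize each graph, two per
topological domain: centrality (strength, eigenvector centrality),
integration (characteristic path length, mean first-passage time),
segregation (modularity, participation coefficient) and overall organization
(assortativity, rich-club coefficient).  Shortest paths use the standard
connectivity convention of edge length = 1/weight; the random-walk
first-passage time is evaluated on the largest connected component.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path

from .connectome import FPConnError, edge_index, n_edges
from .differential import EdgeMask

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "strength_mean",
    "eigenvector_centrality_mean",
    "characteristic_path_length",
    "mean_first_passage_time",
    "modularity_q",
    "participation_coefficient_mean",
    "assortativity",
    "rich_club_coefficient",
)


@dataclass
class WeightedGraph:
    """Symmetric non-negative weight matrix over a region subset."""

    nodes: np.ndarray
    weights: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T):
            raise FPConnError("graph weights must be symmetric")
        if np.any(w < 0):
            raise FPConnError("graph weights must be non-negative")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        self.nodes = np.asarray(self.nodes, dtype=int)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))


@dataclass
class GraphFeatureRecord:
    strength_mean: float
    eigenvector_centrality_mean: float
    characteristic_path_length: float
    mean_first_passage_time: float
    modularity_q: float
    participation_coefficient_mean: float
    assortativity: float
    rich_club_coefficient: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])


def _weight_transform(values: np.ndarray, weight_mode: str) -> np.ndarray:
    if weight_mode == "absolute":
        return np.abs(values)
    if weight_mode == "positive_only":
        return np.clip(values, 0.0, None)
    raise FPConnError(f"unknown weight_mode {weight_mode!r}")


def apply_edge_mask(fc: np.ndarray, mask: EdgeMask,
                    weight_mode: str = "absolute",
                    mode: str = "edge") -> WeightedGraph:
    """Restrict a subject's FC matrix to a discriminative subnetwork.

    ``mode='edge'`` (default) retains exactly the mask's edges; ``mode='roi'``
    retains every edge among the mask's ROI set.  Weights are absolute FC by
    default so all topology measures stay well defined on signed residual FC.
    """
    if mask.n_edges == 0:
        raise FPConnError("empty discriminative subnetwork")
    fc = np.asarray(fc, dtype=float)
    if fc.shape[0] != mask.n_regions:
        raise FPConnError("FC matrix and mask use different region counts")
    rois = mask.roi_set
    sub = np.zeros((rois.size, rois.size))
    pos = {r: k for k, r in enumerate(rois)}
    if mode == "edge":
        for i, j in mask.edge_pairs:
            w = fc[i, j]
            sub[pos[i], pos[j]] = sub[pos[j], pos[i]] = w
    elif mode == "roi":
        sub = fc[np.ix_(rois, rois)].copy()
        np.fill_diagonal(sub, 0.0)
    else:
        raise FPConnError(f"unknown mask mode {mode!r}")
    sub = _weight_transform(sub, weight_mode)
    deg = np.count_nonzero(sub, axis=1)
    keep = deg > 0
    if not np.all(keep):
        logger.info("dropping %d isolated node(s) from masked graph",
                    int((~keep).sum()))
        sub = sub[np.ix_(keep, keep)]
        rois = rois[keep]
    return WeightedGraph(rois, sub, provenance=f"mask:{mask.direction}")


def proportional_threshold(fc: np.ndarray, density: float,
                           weight_mode: str = "absolute") -> WeightedGraph:
    """Keep the top ``ceil(density * E)`` edges of |FC| at fixed density.

    Ties at the cut are broken by ascending edge index (stable sort) and
    logged.  The output keeps the retained edges' absolute weights.
    """
    if not 0 < density <= 1:
        raise FPConnError(f"density must be in (0, 1], got {density}")
    fc = np.asarray(fc, dtype=float)
    r = fc.shape[0]
    vals = _weight_transform(np.abs(fc[np.triu_indices(r, k=1)]), "absolute")
    e_total = n_edges(r)
    n_keep = math.ceil(density * e_total)
    order = np.argsort(-vals, kind="stable")
    kept = order[:n_keep]
    if n_keep < e_total and vals[order[n_keep - 1]] == vals[order[n_keep]]:
        logger.info("proportional threshold tie at the cut broken by edge order")
    keep_mask = np.zeros(e_total, dtype=bool)
    keep_mask[kept] = True
    out = np.zeros_like(fc)
    iu = np.triu_indices(r, k=1)
    out[iu] = np.where(keep_mask, vals, 0.0)
    out += out.T
    return WeightedGraph(np.arange(r), out, provenance=f"density:{density}")


# ---------------------------------------------------------------------------
# individual measures


def _largest_component(w: np.ndarray) -> np.ndarray:
    n_comp, labels = connected_components(w > 0, directed=False)
    if n_comp == 1:
        return np.arange(w.shape[0])
    sizes = np.bincount(labels)
    return np.flatnonzero(labels == sizes.argmax())


def eigenvector_centrality(w: np.ndarray, tol: float = 1e-12,
                           max_iter: int = 10_000) -> np.ndarray:
    """Principal eigenvector of the weight matrix by power iteration.

    Returned unit-norm and non-negative (Perron vector of the non-negative
    matrix); deterministic uniform start.
    """
    n = w.shape[0]
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        nxt = w @ v
        norm = np.linalg.norm(nxt)
        if norm == 0:
            raise FPConnError("eigenvector centrality undefined: zero matrix")
        nxt /= norm
        if np.linalg.norm(nxt - v) < tol:
            v = nxt
            break
        v = nxt
    return np.abs(v)


def characteristic_path_length(w: np.ndarray) -> float:
    """Mean shortest-path distance (edge length 1/weight) over connected pairs."""
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    d = shortest_path(lengths, method="D", directed=False, unweighted=False)
    off = ~np.eye(w.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise FPConnError("no connected node pairs")
    if finite.sum() < off.sum():
        logger.warning("graph disconnected: path length restricted to "
                       "connected pairs")
    return float(d[finite].mean())


def mean_first_passage_time(w: np.ndarray) -> float:
    """Mean random-walk first-passage time over ordered node pairs.

    The walk steps from i to j with probability w_ij / strength_i, on the
    largest connected component.  For each target the expected hitting times
    solve the linear system (I - Q) m = 1 with the target's row and column
    removed.
    """
    comp = _largest_component(w)
    sub = w[np.ix_(comp, comp)]
    n = sub.shape[0]
    if n < 2:
        raise FPConnError("largest component has < 2 nodes; MFPT undefined")
    p = sub / sub.sum(axis=1, keepdims=True)
    total = 0.0
    count = 0
    idx = np.arange(n)
    for j in range(n):
        keep = idx != j
        q = p[np.ix_(keep, keep)]
        m = np.linalg.solve(np.eye(n - 1) - q, np.ones(n - 1))
        total += m.sum()
        count += n - 1
    return float(total / count)


def _to_networkx(w: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(w.shape[0]))
    iu, ju = np.nonzero(np.triu(w, k=1))
    g.add_weighted_edges_from((int(i), int(j), float(w[i, j]))
                              for i, j in zip(iu, ju))
    return g


def modularity_partition(w: np.ndarray, seed: int = 0,
                         ) -> tuple[list[set[int]], float]:
    """Best Louvain partition of the weighted graph and its modularity Q."""
    g = _to_networkx(w)
    communities = nx.community.louvain_communities(g, weight="weight", seed=seed)
    q = nx.community.modularity(g, communities, weight="weight")
    return [set(c) for c in communities], float(q)


def participation_coefficient(w: np.ndarray,
                              communities: list[set[int]]) -> np.ndarray:
    """P_i = 1 - sum_m (kappa_im / s_i)^2 against the given partition."""
    n = w.shape[0]
    strength = w.sum(axis=1)
    p = np.ones(n)
    for comm in communities:
        idx = np.fromiter(comm, dtype=int)
        kappa = w[:, idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p -= np.where(strength > 0, (kappa / strength) ** 2, 0.0)
    p[strength == 0] = 0.0
    return p


def assortativity(w: np.ndarray) -> float:
    """Weighted degree (strength) assortativity: Pearson correlation of
    endpoint strengths over edges."""
    strength = w.sum(axis=1)
    iu, ju = np.nonzero(np.triu(w, k=1))
    if iu.size < 2:
        return float("nan")
    si, sj = strength[iu], strength[ju]
    num = (si * sj).mean() - ((si + sj) / 2).mean() ** 2
    den = ((si**2 + sj**2) / 2).mean() - ((si + sj) / 2).mean() ** 2
    if den == 0:
        return float("nan")
    return float(num / den)


def rich_club_curve(w: np.ndarray) -> dict[int, float]:
    """Weighted rich-club coefficient per degree level.

    At level k, the summed weight among nodes of degree > k is compared with
    the sum of the same number of strongest edges anywhere in the graph.
    """
    deg = np.count_nonzero(w, axis=1)
    iu = np.triu_indices(w.shape[0], k=1)
    all_weights = np.sort(w[iu])[::-1]
    all_weights = all_weights[all_weights > 0]
    curve: dict[int, float] = {}
    for k in range(1, int(deg.max())):
        rich = np.flatnonzero(deg > k)
        if rich.size < 2:
            continue
        sub = w[np.ix_(rich, rich)]
        e_sub = int(np.count_nonzero(np.triu(sub, k=1)))
        if e_sub == 0:
            continue
        w_sub = np.triu(sub, k=1).sum()
        curve[k] = float(w_sub / all_weights[:e_sub].sum())
    return curve


def rich_club_scalar(w: np.ndarray, mode: str = "mean") -> float:
    curve = rich_club_curve(w)
    if not curve:
        return float("nan")
    vals = np.array(list(curve.values()))
    return float(vals.max() if mode == "max" else vals.mean())


def compute_graph_features(g: WeightedGraph, seed: int = 0,
                           rich_club_mode: str = "mean") -> GraphFeatureRecord:
    """All eight topology measures of one subject's subnetwork graph."""
    w = g.weights
    if g.n_nodes < 2 or g.n_edges == 0:
        raise FPConnError("graph needs >= 2 nodes and >= 1 edge")
    strength = w.sum(axis=1)
    communities, q = modularity_partition(w, seed=seed)
    pc = participation_coefficient(w, communities)
    return GraphFeatureRecord(
        strength_mean=float(strength.mean()),
        eigenvector_centrality_mean=float(eigenvector_centrality(w).mean()),
        characteristic_path_length=characteristic_path_length(w),
        mean_first_passage_time=mean_first_passage_time(w),
        modularity_q=q,
        participation_coefficient_mean=float(pc.mean()),
        assortativity=assortativity(w),
        rich_club_coefficient=rich_club_scalar(w, rich_club_mode),
    )
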