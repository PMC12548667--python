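"""NaN-aware weighted graph metrics on Fisher-z connectomes.

Ten metrics at three aggregation levels:

* whole-brain averages — characteristic path length, nodal strength, degree,
  density, clustering coefficient, eigenvector centrality;
* global network-level — system segregation, within-network connectivity,
  between-network connectivity, modularity;
* per-network — within-network connectivity for each canonical network.

Missing entries are excluded from means (connectivity metrics) and treated as
absent edges (weight 0) for topology-dependent metrics.  Nodes whose whole
row is missing are excluded from every metric's node set.  Degree and density
use the edge threshold tau (default 0.10, applied in Fisher-z units).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .cohort import Parcellation
from .connectome import Connectome

logger = logging.getLogger(__name__)

#: default edge threshold for degree/density (z units)
DEFAULT_TAU = 0.10

METRIC_NAMES = (
    "segregation",
    "within_network",
    "between_network",
    "modularity",
    "path_length",
    "strength",
    "degree",
    "density",
    "clustering",
    "eigenvector",
)


@dataclass
class _Prepared:
    """Included-node view of a connectome."""

    z: np.ndarray          # n_inc x n_inc, NaN off support, diag NaN
    w: np.ndarray          # same with NaN -> 0, diag 0
    labels: np.ndarray     # network label per included node
    node_ids: tuple[str, ...]


def _prepare(conn: Connectome, parcellation: Parcellation | None = None) -> _Prepared:
    inc = conn.included
    z = conn.z[np.ix_(inc, inc)]
    w = np.where(np.isfinite(z), z, 0.0)
    np.fill_diagonal(w, 0.0)
    if np.any(w < 0):
        raise ValueError("negative finite weights: censor negatives first")
    if parcellation is not None:
        if parcellation.node_ids != conn.node_ids:
            raise ValueError("parcellation does not match connectome nodes")
        labels = parcellation.labels[inc]
    else:
        labels = np.asarray(["all"] * int(inc.sum()))
    node_ids = tuple(np.asarray(conn.node_ids)[inc])
    return _Prepared(z=z, w=w, labels=labels, node_ids=node_ids)


def _pair_mean(z: np.ndarray, mask: np.ndarray) -> float:
    """Mean of finite entries of z over unordered pairs selected by mask."""
    iu = np.triu_indices(z.shape[0], k=1)
    vals = z[iu][mask[iu]]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


# --------------------------------------------------------------------------- #
# connectivity (mean-based) metrics
# --------------------------------------------------------------------------- #


def within_network_connectivity(
    conn: Connectome, parcellation: Parcellation
) -> tuple[dict[str, float], float]:
    """Mean finite z over same-network node pairs, per network and pooled."""
    p = _prepare(conn, parcellation)
    same = p.labels[:, None] == p.labels[None, :]
    per_network: dict[str, float] = {}
    for net in parcellation.networks:
        in_net = p.labels == net
        value = _pair_mean(p.z, np.outer(in_net, in_net))
        if not np.isfinite(value):
            logger.info("network %s has no finite within pairs", net)
        per_network[net] = value
    return per_network, _pair_mean(p.z, same)


def between_network_connectivity(
    conn: Connectome, parcellation: Parcellation
) -> tuple[dict[str, float], float]:
    """Mean finite z over pairs spanning different networks."""
    p = _prepare(conn, parcellation)
    diff = p.labels[:, None] != p.labels[None, :]
    per_network: dict[str, float] = {}
    for net in parcellation.networks:
        in_net = p.labels == net
        spanning = np.outer(in_net, ~in_net) | np.outer(~in_net, in_net)
        per_network[net] = _pair_mean(p.z, spanning)
    return per_network, _pair_mean(p.z, diff)


def system_segregation(conn: Connectome, parcellation: Parcellation) -> float:
    """(WN - BN) / WN on the pooled within/between means (Chan convention)."""
    _, wn = within_network_connectivity(conn, parcellation)
    _, bn = between_network_connectivity(conn, parcellation)
    if not np.isfinite(wn) or wn <= 0:
        logger.warning("segregation undefined: pooled within-network mean <= 0")
        return float("nan")
    if not np.isfinite(bn):
        return float("nan")
    return (wn - bn) / wn


# --------------------------------------------------------------------------- #
# topology metrics (missing = absent edge)
# --------------------------------------------------------------------------- #


def modularity_q(
    conn: Connectome,
    parcellation: Parcellation,
    partition_mode: str = "atlas",
    seed: int = 0,
    resolution: float = 1.0,
    n_restarts: int = 10,
) -> float:
    """Newman weighted modularity Q of a node partition.

    ``atlas`` mode (default, deterministic) scores the canonical-network
    partition; ``louvain`` optimizes the partition with ``n_restarts``
    seeded restarts and returns the best Q found.
    """
    p = _prepare(conn, parcellation)
    if partition_mode == "atlas":
        return _newman_q(p.w, p.labels, resolution)
    if partition_mode != "louvain":
        raise ValueError("partition_mode must be 'atlas' or 'louvain'")
    import networkx as nx

    g = nx.from_numpy_array(p.w)
    best = -np.inf
    for r in range(n_restarts):
        communities = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=seed + r
        )
        labels = np.empty(p.w.shape[0], dtype=int)
        for c, nodes in enumerate(communities):
            labels[list(nodes)] = c
        best = max(best, _newman_q(p.w, labels, resolution))
    return best


def _newman_q(w: np.ndarray, labels: np.ndarray, resolution: float = 1.0) -> float:
    """Q = (1/2m) * sum_ij [w_ij - gamma k_i k_j / 2m] delta(c_i, c_j)."""
    two_m = w.sum()
    if two_m <= 0:
        logger.warning("modularity undefined on an empty graph")
        return float("nan")
    k = w.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    q = (w - resolution * np.outer(k, k) / two_m)[same].sum() / two_m
    return float(q)


def characteristic_path_length(conn: Connectome) -> float:
    """Mean shortest-path distance with edge lengths 1/z.

    Unreachable pairs are excluded from the mean (their count is logged).
    """
    p = _prepare(conn)
    n = p.w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 included nodes")
    with np.errstate(divide="ignore"):
        lengths = np.where(p.w > 0, 1.0 / p.w, 0.0)
    dist = shortest_path(lengths, method="D", directed=False)
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    finite = np.isfinite(d)
    if not finite.any():
        logger.warning("path length undefined: graph fully disconnected")
        return float("nan")
    n_inf = int((~finite).sum())
    if n_inf:
        logger.info("%d unreachable pairs excluded from path length", n_inf)
    return float(d[finite].mean())


def nodal_strength(conn: Connectome) -> tuple[np.ndarray, float]:
    """Sum of finite incident weights per node, and the node average."""
    p = _prepare(conn)
    s = p.w.sum(axis=1)
    return s, float(s.mean()) if s.size else float("nan")


def degree(
    conn: Connectome, tau: float = DEFAULT_TAU
) -> tuple[np.ndarray, float]:
    """Count of incident edges with z > tau per node, and the node average."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    p = _prepare(conn)
    adj = p.w > tau
    k = adj.sum(axis=1)
    return k, float(k.mean()) if k.size else float("nan")


def density(conn: Connectome, tau: float = DEFAULT_TAU) -> float:
    """Suprathreshold edge count over possible pairs among included nodes."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    p = _prepare(conn)
    n = p.w.shape[0]
    if n < 2:
        return float("nan")
    iu = np.triu_indices(n, k=1)
    return float(np.mean(p.w[iu] > tau))


def clustering_coefficient(conn: Connectome) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering on weights normalized by the maximum z.

    C_i = (1 / (k_i (k_i - 1))) * sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3), with
    k_i the count of finite incident edges; nodes with k_i < 2 get C_i = 0.
    """
    p = _prepare(conn)
    wmax = p.w.max()
    if wmax <= 0:
        return np.zeros(p.w.shape[0]), 0.0
    w_hat = (p.w / wmax) ** (1.0 / 3.0)
    triangles = np.diag(w_hat @ w_hat @ w_hat)
    k = (p.w > 0).sum(axis=1)
    denom = k * (k - 1)
    c = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1), 0.0)
    return c, float(c.mean()) if c.size else float("nan")


def eigenvector_centrality(conn: Connectome) -> tuple[np.ndarray, float]:
    """Leading eigenvector of the weight matrix, unit norm, nonnegative sign.

    On a disconnected graph the dominant component carries the scores (the
    rest are ~0); this is logged, not an error.
    """
    p = _prepare(conn)
    n = p.w.shape[0]
    if n == 0 or p.w.max() <= 0:
        raise ValueError("eigenvector centrality needs a nonempty graph")
    vals, vecs = np.linalg.eigh(p.w)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    norm = np.linalg.norm(v)
    v = v / norm if norm > 0 else v
    if np.any((p.w > 0).sum(axis=1) == 0):
        logger.info("isolated nodes present; eigenvector computed on full matrix")
    return v, float(v.mean())


# --------------------------------------------------------------------------- #
# aggregation
# --------------------------------------------------------------------------- #


def compute_all(
    conn: Connectome,
    parcellation: Parcellation,
    tau: float = DEFAULT_TAU,
) -> pd.DataFrame:
    """All ten global metric values plus per-network within-network rows.

    Returns a long-format frame with columns: subject, session, group, atlas,
    variant, metric, level, network, value.
    """
    wn_per, wn = within_network_connectivity(conn, parcellation)
    _, bn = between_network_connectivity(conn, parcellation)
    seg = system_segregation(conn, parcellation)
    rows: list[tuple[str, str, str | None, float]] = [
        ("segregation", "global_network", None, seg),
        ("within_network", "global_network", None, wn),
        ("between_network", "global_network", None, bn),
        ("modularity", "global_network", None, modularity_q(conn, parcellation)),
        ("path_length", "whole_brain", None, characteristic_path_length(conn)),
        ("strength", "whole_brain", None, nodal_strength(conn)[1]),
        ("degree", "whole_brain", None, degree(conn, tau)[1]),
        ("density", "whole_brain", None, density(conn, tau)),
        ("clustering", "whole_brain", None, clustering_coefficient(conn)[1]),
        ("eigenvector", "whole_brain", None, eigenvector_centrality(conn)[1]),
    ]
    for net, value in wn_per.items():
        rows.append(("within_network", "per_network", net, value))
    frame = pd.DataFrame(rows, columns=["metric", "level", "network", "value"])
    frame.insert(0, "subject", conn.subject_id)
    frame.insert(1, "session", conn.session)
    frame.insert(2, "group", conn.group)
    frame.insert(3, "atlas", conn.atlas_name or parcellation.atlas_name)
    frame.insert(4, "variant", conn.variant)
    return frame
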