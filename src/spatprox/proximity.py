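"""Spatial neighbour graphs and permutation-based cell-type proximity enrichment.

The enrichment statistic compares, for every unordered pair of cell-type
labels, the observed number of neighbour-graph edges joining the two types
with its expectation under random reassignment of the labels over spots
(label multiset preserved). Enrichment is summarised as
``log2((O + 1) / (E + 1))`` with a two-sided empirical p-value, BH-adjusted
within the sample, and the signed evidence score
``PI = log2 enrichment x -log10(adjusted p)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .errors import InvalidParameterError
from .group_stats import bh_adjust

_PERM_CHUNK = 256  # permutations per vectorised block, bounds memory


@dataclass
class SpatialNetwork:
    """Undirected proximity graph over spots.

    ``edges`` holds index pairs into ``node_ids`` with ``u < v``; no
    self-loops or duplicates. ``lengths`` are Euclidean edge lengths.
    """

    node_ids: list[str]
    edges: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.lengths = np.asarray(self.lengths, dtype=float).ravel()
        if self.edges.size:
            u, v = self.edges.T
            if (u == v).any():
                raise InvalidParameterError("network contains self-loops")
            if u.max(initial=-1) >= len(self.node_ids) or u.min(initial=0) < 0:
                raise InvalidParameterError("edge endpoint out of range")
            lo = np.minimum(u, v)
            hi = np.maximum(u, v)
            self.edges = np.column_stack([lo, hi])
            if len(np.unique(self.edges[:, 0] * len(self.node_ids) + self.edges[:, 1])) != len(self.edges):
                raise InvalidParameterError("duplicate edges in network")
        if len(self.lengths) != len(self.edges):
            raise InvalidParameterError("lengths do not match edges")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbor_lists(self) -> list[np.ndarray]:
        """Adjacency as a list of neighbour index arrays per node."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for u, v in self.edges:
            nbrs[u].append(v)
            nbrs[v].append(u)
        return [np.array(sorted(n), dtype=np.int64) for n in nbrs]


def build_network(
    coords: pd.DataFrame,
    method: str = "delaunay",
    k: int = 6,
    prune_factor: float = 4.0,
) -> SpatialNetwork:
    """Build a spot proximity graph by Delaunay triangulation or kNN union.

    Parameters
    ----------
    coords
        Frame with ``spot_id``, ``x``, ``y`` columns (or a 2-column array
        of positions, in which case node ids are row numbers).
    method
        ``"delaunay"`` — triangulation edges with long edges (length
        greater than ``prune_factor`` x the median edge length) removed;
        ``"knn"`` — symmetrised union of each node's ``k`` nearest
        neighbours.
    """
    if isinstance(coords, pd.DataFrame):
        node_ids = [str(s) for s in coords["spot_id"]]
        xy = coords[["x", "y"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(coords, dtype=float)
        node_ids = [str(i) for i in range(len(xy))]

    if method == "delaunay":
        if len(xy) < 3:
            raise InvalidParameterError(
                "delaunay needs at least 3 spots; use method='knn'"
            )
        try:
            tri = Delaunay(xy)
        except QhullError as exc:
            raise InvalidParameterError(
                "delaunay triangulation failed (collinear or degenerate "
                "coordinates); use method='knn'"
            ) from exc
        simp = tri.simplices
        pairs = np.vstack([simp[:, [0, 1]], simp[:, [1, 2]], simp[:, [0, 2]]])
        lo = pairs.min(axis=1)
        hi = pairs.max(axis=1)
        edges = np.unique(np.column_stack([lo, hi]), axis=0)
        lengths = np.linalg.norm(xy[edges[:, 0]] - xy[edges[:, 1]], axis=1)
        if prune_factor is not None and len(lengths):
            keep = lengths <= prune_factor * np.median(lengths)
            edges, lengths = edges[keep], lengths[keep]
    elif method == "knn":
        if k < 1:
            raise InvalidParameterError("k must be >= 1")
        from scipy.spatial import cKDTree

        tree = cKDTree(xy)
        kk = min(k + 1, len(xy))
        _, idx = tree.query(xy, k=kk)
        idx = np.atleast_2d(idx)
        src = np.repeat(np.arange(len(xy)), idx.shape[1] - 1)
        dst = idx[:, 1:].ravel()
        lo = np.minimum(src, dst)
        hi = np.maximum(src, dst)
        edges = np.unique(np.column_stack([lo, hi]), axis=0)
        lengths = np.linalg.norm(xy[edges[:, 0]] - xy[edges[:, 1]], axis=1)
    else:
        raise InvalidParameterError(f"unknown method {method!r}")

    return SpatialNetwork(node_ids, edges, lengths)


def pair_edge_counts(
    network: SpatialNetwork, labels: np.ndarray | pd.Series | list
) -> pd.Series:
    """Count edges per unordered endpoint-label pair.

    Returns a Series indexed by ``(type_a, type_b)`` with ``type_a <=
    type_b``; the counts sum to the number of edges. Every pair over the
    observed label set is present (zeros included).
    """
    labels = np.asarray(labels)
    if len(labels) != network.n_nodes:
        raise InvalidParameterError(
            f"{len(labels)} labels for {network.n_nodes} nodes"
        )
    if pd.isna(labels).any():
        raise InvalidParameterError("unlabeled (NA) node")
    codes, uniq = pd.factorize(labels, sort=True)
    K = len(uniq)
    counts = _edge_pair_counts(codes[np.newaxis, :], network.edges, K)[0]
    idx = pd.MultiIndex.from_tuples(
        [(uniq[i], uniq[j]) for i in range(K) for j in range(i, K)],
        names=["type_a", "type_b"],
    )
    vals = [counts[i * K + j] for i in range(K) for j in range(i, K)]
    return pd.Series(vals, index=idx, name="n_edges")


def _edge_pair_counts(
    label_rows: np.ndarray, edges: np.ndarray, K: int
) -> np.ndarray:
    """Pair-count rows for a stack of label assignments.

    ``label_rows`` is (n_rows, n_nodes) integer codes; returns
    (n_rows, K*K) with counts at flat index ``lo * K + hi``.
    """
    n_rows = label_rows.shape[0]
    if len(edges) == 0:
        return np.zeros((n_rows, K * K), dtype=np.int64)
    a = label_rows[:, edges[:, 0]]
    b = label_rows[:, edges[:, 1]]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    flat = (np.arange(n_rows)[:, None] * (K * K) + lo * K + hi).ravel()
    out = np.bincount(flat, minlength=n_rows * K * K)
    return out.reshape(n_rows, K * K)


def proximity_enrichment(
    network: SpatialNetwork,
    labels: np.ndarray | pd.Series | list,
    n_perm: int = 1000,
    seed: int = 0,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Permutation test for cell-type spatial proximity enrichment.

    Labels are permuted uniformly over nodes ``n_perm`` times (label
    multiset preserved); for each unordered type pair the expected edge
    count is the mean permuted count and the empirical p-value is
    two-sided with add-one correction:
    ``p = min(1, 2 * min(p_hi, p_lo))`` where
    ``p_hi = (1 + #{perm >= O}) / (n_perm + 1)``.

    Returns one row per type pair with columns ``type_a, type_b,
    n_observed, n_expected, log2_enrichment, p_value, adj_p_value, pi,
    low_support, absent`` (and ``sample_id`` first when given). Pairs of
    labels carried by fewer than two nodes are flagged ``low_support`` but
    still computed.
    """
    if n_perm < 100:
        raise InvalidParameterError("n_perm must be >= 100")
    labels = np.asarray(labels)
    if len(labels) != network.n_nodes:
        raise InvalidParameterError(
            f"{len(labels)} labels for {network.n_nodes} nodes"
        )
    codes, uniq = pd.factorize(labels, sort=True)
    K = len(uniq)
    if K < 2:
        raise InvalidParameterError("need at least 2 distinct labels")

    obs = _edge_pair_counts(codes[np.newaxis, :], network.edges, K)[0]

    rng = np.random.default_rng(seed)
    perm_sum = np.zeros(K * K)
    ge_obs = np.zeros(K * K, dtype=np.int64)
    le_obs = np.zeros(K * K, dtype=np.int64)
    done = 0
    while done < n_perm:
        block = min(_PERM_CHUNK, n_perm - done)
        P = rng.permuted(np.tile(codes, (block, 1)), axis=1)
        pc = _edge_pair_counts(P, network.edges, K)
        perm_sum += pc.sum(axis=0)
        ge_obs += (pc >= obs).sum(axis=0)
        le_obs += (pc <= obs).sum(axis=0)
        done += block

    expected = perm_sum / n_perm
    p_hi = (1 + ge_obs) / (n_perm + 1)
    p_lo = (1 + le_obs) / (n_perm + 1)
    p = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))

    type_counts = np.bincount(codes, minlength=K)
    rows = []
    for i in range(K):
        for j in range(i, K):
            f = i * K + j
            rows.append(
                {
                    "type_a": uniq[i],
                    "type_b": uniq[j],
                    "n_observed": int(obs[f]),
                    "n_expected": expected[f],
                    "p_value": p[f],
                    "low_support": bool(
                        type_counts[i] < 2 or type_counts[j] < 2
                    ),
                    "absent": bool(obs[f] == 0 and expected[f] == 0),
                }
            )
    res = pd.DataFrame(rows)
    res["log2_enrichment"] = np.log2(
        (res["n_observed"] + 1.0) / (res["n_expected"] + 1.0)
    )
    res["adj_p_value"] = bh_adjust(res["p_value"].to_numpy())
    floor = 1.0 / (n_perm + 1)
    res["pi"] = res["log2_enrichment"] * (
        -np.log10(np.maximum(res["adj_p_value"], floor))
    )
    cols = [
        "type_a",
        "type_b",
        "n_observed",
        "n_expected",
        "log2_enrichment",
        "p_value",
        "adj_p_value",
        "pi",
        "low_support",
        "absent",
    ]
    res = res[cols]
    if sample_id is not None:
        res.insert(0, "sample_id", sample_id)
    return res
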