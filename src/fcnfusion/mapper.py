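"""Mapper construction of functional connectivity networks.

The Mapper procedure covers a 2-D embedding with overlapping rectangles,
clusters the points inside each rectangle, and forms the nerve graph whose
nodes are clusters and whose edges join clusters sharing a member. At the
ROI level, two regions are connected when they co-occur in a cluster, and
(optionally) when they belong to two clusters that overlap through a shared
member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from fcnfusion.datatypes import Embedding, Fcn

__all__ = ["MapperConfig", "MapperResult", "build_mapper", "mapper_fcn"]

# relative tolerance so point pairs at exactly the linkage cutoff merge
_CUTOFF_SLACK = 1e-9


@dataclass
class MapperConfig:
    """Cover and clustering parameters of the Mapper.

    ``n_intervals`` rectangles per axis (so ``n_intervals**2`` bins),
    expanded by ``overlap_fraction`` of their base width on each side so
    neighbouring bins overlap. ``clusterer`` is ``single_linkage`` (flat
    clusters at distance ``cluster_param``, default: the median
    nearest-neighbour distance of the whole embedding) or ``density``
    (DBSCAN with ``eps=cluster_param``). Clusters smaller than
    ``min_cluster_size`` are discarded.
    """

    n_intervals: int = 10
    overlap_fraction: float = 0.3
    clusterer: str = "single_linkage"
    cluster_param: float | None = None
    min_cluster_size: int = 1
    connect_via_overlap: bool = True

    def __post_init__(self) -> None:
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        if not 0 < self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in (0, 1)")
        if self.clusterer not in ("single_linkage", "density"):
            raise ValueError(f"unknown clusterer {self.clusterer!r}")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class MapperResult:
    """Clusters (as sorted index arrays) and their nerve graph."""

    clusters: list[np.ndarray]
    nerve: nx.Graph
    config: MapperConfig = field(default_factory=MapperConfig)


def _axis_intervals(values: np.ndarray, n: int, overlap: float) -> list[tuple[float, float]]:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:  # degenerate axis: one interval containing the point
        return [(lo - 0.5, hi + 0.5)] * n
    base = (hi - lo) / n
    pad = overlap * base
    return [(lo + i * base - pad, lo + (i + 1) * base + pad) for i in range(n)]


def _default_cutoff(coords: np.ndarray) -> float:
    d = squareform(pdist(coords))
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    return float(np.median(nn))


def _cluster_bin(points: np.ndarray, members: np.ndarray, cfg: MapperConfig,
                 cutoff: float) -> list[np.ndarray]:
    if len(members) == 1:
        return [members]
    if cfg.clusterer == "single_linkage":
        Z = linkage(points, method="single")
        labels = fcluster(Z, t=cutoff * (1.0 + _CUTOFF_SLACK), criterion="distance")
    else:
        from sklearn.cluster import DBSCAN

        eps = cfg.cluster_param if cfg.cluster_param is not None else cutoff
        labels = DBSCAN(eps=eps * (1.0 + _CUTOFF_SLACK), min_samples=1).fit_predict(points)
    return [members[labels == lab] for lab in np.unique(labels)]


def build_mapper(emb: Embedding, cfg: MapperConfig | None = None) -> MapperResult:
    """Run the Mapper on a 2-D embedding.

    Returns the deduplicated cluster list and the nerve graph (nodes are
    cluster indices with a ``members`` attribute; edges join clusters with
    nonempty intersection).
    """
    cfg = cfg or MapperConfig()
    coords = emb.coords
    n = coords.shape[0]
    if n == 0:
        raise ValueError("cannot run Mapper on an empty embedding")

    cutoff = (
        cfg.cluster_param
        if (cfg.clusterer == "single_linkage" and cfg.cluster_param is not None)
        else _default_cutoff(coords)
    )

    x_ints = _axis_intervals(coords[:, 0], cfg.n_intervals, cfg.overlap_fraction)
    y_ints = _axis_intervals(coords[:, 1], cfg.n_intervals, cfg.overlap_fraction)

    covered = np.zeros(n, dtype=bool)
    raw: list[np.ndarray] = []
    for xlo, xhi in x_ints:
        in_x = (coords[:, 0] >= xlo) & (coords[:, 0] <= xhi)
        for ylo, yhi in y_ints:
            members = np.flatnonzero(in_x & (coords[:, 1] >= ylo) & (coords[:, 1] <= yhi))
            if members.size == 0:
                continue
            covered[members] = True
            raw.extend(_cluster_bin(coords[members], members, cfg, cutoff))
    # the padded intervals tile [min, max] on each axis, so this cannot fire
    assert covered.all(), "cover construction left points uncovered"

    # deduplicate, and drop clusters properly contained in another: a
    # sub-cluster inside a superset adds no nerve information (any overlap
    # it witnesses is inherited by the superset) but would inflate degrees
    keys: list[frozenset[int]] = []
    seen: set[frozenset[int]] = set()
    for c in raw:
        if len(c) < cfg.min_cluster_size:
            continue
        key = frozenset(int(i) for i in c)
        if key not in seen:
            seen.add(key)
            keys.append(key)
    keys = [k for k in keys if not any(k < other for other in keys)]
    clusters = [np.array(sorted(k)) for k in keys]

    nerve = nx.Graph()
    sets = [set(map(int, c)) for c in clusters]
    for i, c in enumerate(clusters):
        nerve.add_node(i, members=[int(j) for j in c])
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            if sets[i] & sets[j]:
                nerve.add_edge(i, j)
    return MapperResult(clusters=clusters, nerve=nerve, config=cfg)


def mapper_fcn(emb: Embedding, cfg: MapperConfig | None = None) -> Fcn:
    """ROI-level FCN from the Mapper cluster graph.

    Two ROIs are connected iff they co-occur in one cluster, or (when
    ``connect_via_overlap``) they lie in two clusters that share a member.
    """
    cfg = cfg or MapperConfig()
    result = build_mapper(emb, cfg)
    n = emb.coords.shape[0]
    adj = np.zeros((n, n), dtype=np.int8)
    for c in result.clusters:
        adj[np.ix_(c, c)] = 1
    if cfg.connect_via_overlap:
        for i, j in result.nerve.edges:
            adj[np.ix_(result.clusters[i], result.clusters[j])] = 1
            adj[np.ix_(result.clusters[j], result.clusters[i])] = 1
    np.fill_diagonal(adj, 0)
    return Fcn(
        adjacency=adj,
        roi_labels=emb.roi_labels,
        provenance={
            "embedding": emb.method,
            "n_intervals": cfg.n_intervals,
            "overlap_fraction": cfg.overlap_fraction,
            "clusterer": cfg.clusterer,
        },
    )
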