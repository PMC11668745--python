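"""Step 3b — group summary FCNs, ROI categorization, neighbor clusters.

The summary FCN of a group weights each edge by the fraction of subjects
whose individual FCN contains it (the connectivity ratio) and binarizes at
a threshold (default 0.2). ROIs selected in Step 2/3 are categorized across
the two compared groups — representative in both, more reactive in one, or
selected in only one — and each categorized ROI is reported together with
its direct neighbors in the thresholded summary network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from fcnfusion.datatypes import Fcn, TopRoiList

__all__ = [
    "SummaryFcn",
    "group_summary",
    "categorize_rois",
    "extract_clusters",
    "render_summary",
]

DEFAULT_THRESHOLD = 0.2

CATEGORY_COLORS = {
    "only": "tab:blue",
    "more_reactive": "tab:orange",
    "both": "tab:green",
}


@dataclass
class SummaryFcn:
    """Group-level connectivity-ratio matrix and its thresholded graph."""

    ratio: np.ndarray
    threshold: float
    group: str
    roi_labels: list[str]
    adjacency: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        if not np.allclose(self.ratio, self.ratio.T):
            raise ValueError("connectivity-ratio matrix must be symmetric")
        if self.ratio.min() < 0 or self.ratio.max() > 1:
            raise ValueError("connectivity ratios must lie in [0, 1]")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")
        adj = (self.ratio >= self.threshold).astype(np.int8)
        np.fill_diagonal(adj, 0)
        self.adjacency = adj


def group_summary(
    fcns: list[Fcn], threshold: float = DEFAULT_THRESHOLD, group: str | None = None
) -> SummaryFcn:
    """Summary FCN of one group of subjects.

    ``ratio[j, k]`` is the fraction of subjects whose FCN has edge (j, k);
    edges with ratio >= threshold survive (ties at the threshold kept).
    """
    if not fcns:
        raise ValueError("cannot summarize an empty group")
    labels = fcns[0].roi_labels
    for f in fcns:
        if f.roi_labels != labels:
            raise ValueError("all FCNs must share the same ROI labels")
    ratio = np.mean([f.adjacency for f in fcns], axis=0)
    np.fill_diagonal(ratio, 0.0)
    return SummaryFcn(
        ratio=ratio,
        threshold=threshold,
        group=group if group is not None else "group",
        roi_labels=list(labels),
    )


def categorize_rois(
    top_a: TopRoiList,
    top_b: TopRoiList,
    near_origin_a: set[str],
    near_origin_b: set[str],
    roi_labels: list[str],
) -> dict[str, str]:
    """Three-way categorization of ROIs across the two compared groups.

    Decision table per ROI:

    * in both top lists, near-origin in both fits  -> ``both``
    * in both top lists, near-origin in exactly one -> ``more_reactive_<g>``
    * in exactly one top list                       -> ``only_<g>``
    * otherwise                                     -> ``none``
    """
    ga, gb = top_a.group, top_b.group
    unknown = (set(top_a.labels) | set(top_b.labels)
               | near_origin_a | near_origin_b) - set(roi_labels)
    if unknown:
        raise ValueError(f"labels outside the ROI universe: {sorted(unknown)}")
    categories: dict[str, str] = {}
    for roi in roi_labels:
        in_a, in_b = roi in top_a, roi in top_b
        if in_a and in_b:
            na, nb = roi in near_origin_a, roi in near_origin_b
            if na and nb:
                categories[roi] = "both"
            elif na:
                categories[roi] = f"more_reactive_{ga}"
            elif nb:
                categories[roi] = f"more_reactive_{gb}"
            else:
                categories[roi] = "none"
        elif in_a:
            categories[roi] = f"only_{ga}"
        elif in_b:
            categories[roi] = f"only_{gb}"
        else:
            categories[roi] = "none"
    return categories


def extract_clusters(
    summary: SummaryFcn, category_map: dict[str, str]
) -> list[dict]:
    """Direct-neighbor cluster of every categorized ROI.

    Clusters are lettered A, B, C, ... in atlas (label-list) order of the
    categorized ROI; an isolated ROI yields a singleton cluster.
    """
    labels = summary.roi_labels
    index = {lab: j for j, lab in enumerate(labels)}
    clusters = []
    selected = [lab for lab in labels if category_map.get(lab, "none") != "none"]
    for k, roi in enumerate(selected):
        j = index[roi]
        neighbors = [labels[m] for m in np.flatnonzero(summary.adjacency[j])]
        name = _letter_name(k)
        clusters.append(
            {
                "name": name,
                "roi": roi,
                "category": category_map[roi],
                "members": [roi] + neighbors,
            }
        )
    return clusters


def _letter_name(k: int) -> str:
    name = ""
    k += 1
    while k:
        k, rem = divmod(k - 1, 26)
        name = chr(ord("A") + rem) + name
    return name


def render_summary(
    summary: SummaryFcn,
    category_map: dict[str, str],
    path: str | Path,
    seed: int = 0,
) -> Path:
    """Render the colored summary FCN to a vector-graphics (SVG) file.

    Categorized ROIs get saturated category colors (blue = only, orange =
    more reactive, green = both); their direct neighbors the same color
    dimmed; everything else gray.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import networkx as nx

    G = nx.from_numpy_array(summary.adjacency)
    G = nx.relabel_nodes(G, dict(enumerate(summary.roi_labels)))
    pos = nx.spring_layout(G, seed=seed)

    def base_color(cat: str) -> str | None:
        for prefix, color in CATEGORY_COLORS.items():
            if cat == prefix or cat.startswith(prefix + "_"):
                return color
        return None

    colors, alphas = [], []
    neighbor_color: dict[str, str] = {}
    for roi, cat in category_map.items():
        c = base_color(cat)
        if c and roi in G:
            for nb in G.neighbors(roi):
                neighbor_color.setdefault(nb, c)
    for roi in G.nodes:
        c = base_color(category_map.get(roi, "none"))
        if c:
            colors.append(c)
            alphas.append(1.0)
        elif roi in neighbor_color:
            colors.append(neighbor_color[roi])
            alphas.append(0.4)
        else:
            colors.append("lightgray")
            alphas.append(0.6)

    fig, ax = plt.subplots(figsize=(9, 9))
    nx.draw_networkx_edges(G, pos, ax=ax, alpha=0.2)
    nx.draw_networkx_nodes(G, pos, ax=ax, node_color=colors, alpha=alphas,
                           node_size=120)
    nx.draw_networkx_labels(G, pos, ax=ax, font_size=5)
    ax.set_title(f"Summary FCN — {summary.group} (threshold {summary.threshold})")
    ax.axis("off")
    out = Path(path)
    fig.savefig(out, format=out.suffix.lstrip(".") or "svg")
    plt.close(fig)
    return out
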