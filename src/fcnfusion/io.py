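"""Readers and writers for every on-disk artifact of the pipeline.

All tabular artifacts are plain CSV with an ROI-label header so each stage
can be rerun standalone; graphs additionally export as edge lists and
GraphML; posterior draws live in one HDF5 container per fit.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd

from fcnfusion.datatypes import (
    AttentionMatrix,
    ConnectivityMatrix,
    Fcn,
    GroupRepMatrix,
    RoiTimeSeries,
    TopRoiList,
)
from fcnfusion.lsirm import LsirmPosterior
from fcnfusion.summary import SummaryFcn


# ---- cohort ---------------------------------------------------------------

def read_subject_csv(path: str | Path, subject_id: str, group: str) -> RoiTimeSeries:
    df = pd.read_csv(path, index_col=0)
    return RoiTimeSeries(
        subject_id=subject_id,
        group=group,
        signals=df.to_numpy(dtype=float),
        roi_labels=[str(x) for x in df.index],
    )


def read_cohort(manifest_path: str | Path) -> list[RoiTimeSeries]:
    """Load a cohort from a manifest CSV (columns subject_id, group, path).

    Relative paths resolve against the manifest's directory. All subjects
    must share identical ROI labels.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"subject_id", "group", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    cohort = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        if not p.exists():
            raise FileNotFoundError(
                f"subject {row.subject_id}: file {p} listed in manifest is missing"
            )
        cohort.append(read_subject_csv(p, str(row.subject_id), str(row.group)))
    if cohort:
        labels = cohort[0].roi_labels
        bad = [ts.subject_id for ts in cohort if ts.roi_labels != labels]
        if bad:
            raise ValueError(f"ROI labels differ for subjects: {bad}")
    return cohort


# ---- matrices -------------------------------------------------------------

def write_matrix_csv(values: np.ndarray, roi_labels: list[str], path: str | Path) -> None:
    pd.DataFrame(values, index=roi_labels, columns=roi_labels).to_csv(path)


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(x) for x in df.index]


def write_connectivity(cm: ConnectivityMatrix, path: str | Path) -> None:
    write_matrix_csv(cm.values, cm.roi_labels, path)


def write_fcn(fcn: Fcn, path: str | Path) -> None:
    write_matrix_csv(fcn.adjacency, fcn.roi_labels, path)


def read_fcn(path: str | Path) -> Fcn:
    values, labels = read_matrix_csv(path)
    return Fcn(adjacency=values.astype(int), roi_labels=labels)


def fcn_to_graph(fcn: Fcn) -> nx.Graph:
    G = nx.from_numpy_array(fcn.adjacency)
    return nx.relabel_nodes(G, dict(enumerate(fcn.roi_labels)))


def write_graphml(fcn: Fcn, path: str | Path) -> None:
    nx.write_graphml(fcn_to_graph(fcn), path)


def write_edge_list(fcn: Fcn, path: str | Path) -> None:
    rows = [
        {"source": fcn.roi_labels[j], "target": fcn.roi_labels[k]}
        for j, k in zip(*np.triu_indices_from(fcn.adjacency, k=1))
        if fcn.adjacency[j, k]
    ]
    pd.DataFrame(rows, columns=["source", "target"]).to_csv(path, index=False)


# ---- attention ------------------------------------------------------------

def write_attention_set(
    matrices: list[AttentionMatrix], out_dir: str | Path
) -> Path:
    """One CSV per subject plus an index CSV; returns the index path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in matrices:
        fname = f"attn_{m.subject_id}.csv"
        write_matrix_csv(m.values, m.roi_labels, out / fname)
        rows.append({"subject_id": m.subject_id, "group": m.group, "path": fname})
    index = out / "attention_index.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    return index


def read_attention_set(index_path: str | Path) -> list[AttentionMatrix]:
    index_path = Path(index_path)
    df = pd.read_csv(index_path)
    matrices = []
    for row in df.itertuples(index=False):
        values, labels = read_matrix_csv(index_path.parent / row.path)
        matrices.append(
            AttentionMatrix(
                values=values,
                subject_id=str(row.subject_id),
                group=str(row.group),
                roi_labels=labels,
            )
        )
    return matrices


# ---- group matrix / top list ----------------------------------------------

def write_group_matrix(gm: GroupRepMatrix, path: str | Path) -> None:
    pd.DataFrame(gm.values, index=gm.subject_ids, columns=gm.roi_labels).to_csv(path)


def read_group_matrix(path: str | Path, group: str) -> GroupRepMatrix:
    df = pd.read_csv(path, index_col=0)
    return GroupRepMatrix(
        values=df.to_numpy(dtype=float),
        subject_ids=[str(x) for x in df.index],
        roi_labels=[str(x) for x in df.columns],
        group=group,
    )


def write_top_list(top: TopRoiList, path: str | Path) -> None:
    pd.DataFrame(
        {"rank": range(1, len(top.labels) + 1), "roi": top.labels}
    ).to_csv(path, index=False)


# ---- posterior ------------------------------------------------------------

def write_posterior(post: LsirmPosterior, path: str | Path) -> None:
    """Posterior draws to HDF5 (groups theta/beta/U/V/sigma2 + alignment)."""
    with h5py.File(path, "w") as f:
        for name in ("theta", "beta", "U", "V", "sigma2", "sigma_theta2"):
            f.create_dataset(name, data=getattr(post, name))
        if post.aligned_U is not None:
            f.create_dataset("aligned_U", data=post.aligned_U)
            f.create_dataset("aligned_V", data=post.aligned_V)
        f.attrs["roi_labels"] = post.roi_labels
        f.attrs["subject_ids"] = post.subject_ids
        for k, v in post.acceptance_rates.items():
            f.attrs[f"acceptance_{k}"] = v


def read_posterior(path: str | Path) -> LsirmPosterior:
    with h5py.File(path, "r") as f:
        kw = {
            name: f[name][()]
            for name in ("theta", "beta", "U", "V", "sigma2", "sigma_theta2")
        }
        rates = {
            k.removeprefix("acceptance_"): float(v)
            for k, v in f.attrs.items()
            if k.startswith("acceptance_")
        }
        post = LsirmPosterior(
            acceptance_rates=rates,
            roi_labels=[str(x) for x in f.attrs["roi_labels"]],
            subject_ids=[str(x) for x in f.attrs["subject_ids"]],
            **kw,
        )
        if "aligned_U" in f:
            post.aligned_U = f["aligned_U"][()]
            post.aligned_V = f["aligned_V"][()]
    return post


def write_position_summary(post: LsirmPosterior, path: str | Path) -> None:
    """Posterior-mean ROI positions and origin distances as CSV."""
    U = post.aligned_U if post.aligned_U is not None else post.U
    mean = U.mean(axis=0)
    pd.DataFrame(
        {
            "roi": post.roi_labels,
            "x": mean[:, 0],
            "y": mean[:, 1],
            "origin_distance": np.linalg.norm(mean, axis=1),
        }
    ).to_csv(path, index=False)


# ---- summary network ------------------------------------------------------

def write_summary_fcn(summary: SummaryFcn, base_path: str | Path) -> None:
    """Edge list CSV (with ratio attribute) and GraphML next to it."""
    base = Path(base_path)
    j_idx, k_idx = np.triu_indices_from(summary.adjacency, k=1)
    rows = [
        {
            "source": summary.roi_labels[j],
            "target": summary.roi_labels[k],
            "ratio": summary.ratio[j, k],
        }
        for j, k in zip(j_idx, k_idx)
        if summary.adjacency[j, k]
    ]
    pd.DataFrame(rows, columns=["source", "target", "ratio"]).to_csv(
        base.with_suffix(".csv"), index=False
    )
    G = nx.Graph()
    G.add_nodes_from(summary.roi_labels)
    for r in rows:
        G.add_edge(r["source"], r["target"], ratio=float(r["ratio"]))
    nx.write_graphml(G, base.with_suffix(".graphml"))


def write_category_map(
    category_map: dict[str, str], path: str | Path
) -> None:
    pd.DataFrame(
        {"roi": list(category_map), "category": list(category_map.values())}
    ).to_csv(path, index=False)
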