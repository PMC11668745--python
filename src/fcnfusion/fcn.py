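"""Step 1 — per-subject connectivity representations.

Correlation-based views (Pearson r, Fisher z) and 2-D ROI embeddings in
linear (PCA), stochastic (t-SNE) and topological (UMAP) spaces. Each ROI is
one point whose feature vector is its full time course, so the embedding
places strongly co-fluctuating regions close together.
"""

from __future__ import annotations

import warnings

import numpy as np

from fcnfusion.datatypes import ConnectivityMatrix, Embedding, RoiTimeSeries

# arctanh diverges at |r| = 1; correlations are clipped to this magnitude
_FISHER_CLIP = 1.0 - 1e-7

#: UMAP defaults used for the topological embedding
TOPOLOGICAL_DEFAULTS = {"n_neighbors": 15, "min_dist": 0.1}


def pearson_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation matrix between all ROI time courses.

    Raises ``ValueError`` naming the ROI if any row has zero variance.
    """
    flat = ts.constant_rois()
    if flat:
        raise ValueError(
            f"subject {ts.subject_id}: zero-variance ROI(s) {flat} have "
            "undefined correlations"
        )
    r = np.corrcoef(ts.signals)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, kind="pearson", roi_labels=ts.roi_labels)


def fisher_z(corr: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher z-transform ``z = arctanh(r)`` of a Pearson matrix.

    Correlations with ``|r| = 1`` (including the unit diagonal) are clipped
    to ``1 - 1e-7`` so the transform stays finite; a warning is emitted for
    off-diagonal clips.
    """
    if corr.kind != "pearson":
        raise ValueError("fisher_z expects a pearson matrix")
    r = corr.values.copy()
    off = ~np.eye(r.shape[0], dtype=bool)
    n_clip = int(np.count_nonzero(np.abs(r[off]) >= 1.0))
    if n_clip:
        warnings.warn(
            f"{n_clip} off-diagonal correlation(s) at |r|=1 clipped before "
            "Fisher transform",
            stacklevel=2,
        )
    z = np.arctanh(np.clip(r, -_FISHER_CLIP, _FISHER_CLIP))
    return ConnectivityMatrix(values=z, kind="fisher_z", roi_labels=corr.roi_labels)


def embed_rois(
    ts: RoiTimeSeries,
    method: str = "topological",
    params: dict | None = None,
    seed: int = 0,
) -> Embedding:
    """Embed ROIs into 2-D from their time courses.

    ``method`` selects the space: ``linear`` (PCA; deterministic),
    ``stochastic`` (t-SNE) or ``topological`` (UMAP, defaults
    ``n_neighbors=15, min_dist=0.1``). Stochastic methods are reproducible
    from ``seed``.
    """
    if method not in ("linear", "stochastic", "topological"):
        raise ValueError(f"unknown embedding method {method!r}")
    if ts.n_timepoints < 3:
        raise ValueError("at least 3 time points required to embed ROIs")
    X = ts.signals
    params = dict(params or {})

    if method == "linear":
        from sklearn.decomposition import PCA

        coords = PCA(n_components=2, svd_solver="full").fit_transform(X)
    elif method == "stochastic":
        from sklearn.manifold import TSNE

        perplexity = params.pop("perplexity", min(30.0, (ts.n_rois - 1) / 3.0))
        coords = TSNE(
            n_components=2,
            perplexity=perplexity,
            init="pca",
            random_state=seed,
            **params,
        ).fit_transform(X)
    else:
        import umap

        kw = {**TOPOLOGICAL_DEFAULTS, **params}
        kw["n_neighbors"] = min(kw["n_neighbors"], ts.n_rois - 1)
        coords = umap.UMAP(
            n_components=2, random_state=seed, **kw
        ).fit_transform(X)

    return Embedding(
        coords=np.asarray(coords, dtype=float),
        method=method,
        roi_labels=ts.roi_labels,
        params=params,
        seed=seed,
    )
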