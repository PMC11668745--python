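"""Synthetic two-group cohorts and item-response matrices with known truth.

The cohort generator targets exactly the statistical structure the pipeline
consumes: between-ROI correlation that differs by group in planted blocks.
Signals are zero-mean stationary Gaussian AR(1) processes whose marginal
(cross-sectional) covariance equals the group's block-correlation matrix —
no hemodynamic or scanner modeling is attempted.

The item-response generator draws directly from the continuous latent-space
item-response model: ``y_ij = theta_j + beta_i - ||u_j - v_i|| + noise``,
and returns the full ground truth for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from fcnfusion.atlas import roi_labels
from fcnfusion.datatypes import RoiTimeSeries

__all__ = [
    "CohortSpec",
    "ItemResponseSpec",
    "simulate_cohort",
    "simulate_item_response",
    "write_cohort",
]


@dataclass
class CohortSpec:
    """Configuration of a synthetic two-group ROI time-series cohort.

    Parameters
    ----------
    n_rois, n_timepoints : int
        Matrix dimensions per subject (defaults mirror a 116-ROI atlas
        acquisition with 200 volumes).
    n_subjects_per_group : dict
        Mapping of the two group labels to subject counts.
    block_partition : list of list of int
        Disjoint cover of ROI indices by connectivity blocks; ROIs not in
        any block are uncorrelated background.
    within_block_corr_by_group : dict
        ``group -> list of correlation levels``, one per block, each in
        ``[0, 1)``. The same partition is used for both groups; only the
        levels differ.
    noise_ar1 : float
        Temporal AR(1) coefficient in ``[0, 1)``.
    seed : int
        Base seed; the cohort is fully reproducible from it.
    """

    n_rois: int = 116
    n_timepoints: int = 200
    n_subjects_per_group: dict[str, int] = field(
        default_factory=lambda: {"A": 20, "B": 20}
    )
    block_partition: list[list[int]] = field(default_factory=list)
    within_block_corr_by_group: dict[str, list[float]] = field(default_factory=dict)
    noise_ar1: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_subjects_per_group) != 2:
            raise ValueError("exactly two groups are required")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must lie in [0, 1)")
        seen: set[int] = set()
        for b, block in enumerate(self.block_partition):
            for idx in block:
                if idx in seen:
                    raise ValueError(f"ROI {idx} assigned to more than one block")
                if not 0 <= idx < self.n_rois:
                    raise ValueError(f"block {b}: ROI index {idx} out of range")
                seen.add(idx)
        for group in self.n_subjects_per_group:
            levels = self.within_block_corr_by_group.get(group)
            if levels is None:
                raise ValueError(f"no correlation levels given for group {group!r}")
            if len(levels) != len(self.block_partition):
                raise ValueError(
                    f"group {group!r}: {len(levels)} correlation levels for "
                    f"{len(self.block_partition)} blocks"
                )
            for b, r in enumerate(levels):
                if not 0 <= r < 1:
                    raise ValueError(
                        f"group {group!r} block {b}: correlation {r} outside [0, 1)"
                    )
        # validate implied covariances up front
        for group in self.n_subjects_per_group:
            self.correlation_matrix(group)

    @property
    def groups(self) -> list[str]:
        return list(self.n_subjects_per_group)

    def correlation_matrix(self, group: str) -> np.ndarray:
        """The block compound-symmetry correlation matrix of ``group``.

        Raises ``ValueError`` naming the offending block if any block's
        implied covariance is not positive definite.
        """
        corr = np.eye(self.n_rois)
        levels = self.within_block_corr_by_group[group]
        for b, (block, r) in enumerate(zip(self.block_partition, levels)):
            for j in block:
                for k in block:
                    if j != k:
                        corr[j, k] = r
            sub = corr[np.ix_(block, block)]
            try:
                np.linalg.cholesky(sub)
            except np.linalg.LinAlgError:
                raise ValueError(
                    f"group {group!r} block {b} implies a non-positive-definite "
                    f"covariance (size {len(block)}, correlation {r})"
                ) from None
        np.linalg.cholesky(corr)  # full-matrix safety check
        return corr


def _default_spec_labels(spec: CohortSpec) -> list[str]:
    return roi_labels(spec.n_rois)


def simulate_cohort(spec: CohortSpec) -> list[RoiTimeSeries]:
    """Draw a reproducible two-group cohort of ROI time series.

    Each subject's signal matrix is a stationary Gaussian AR(1) process:
    ``x_t = phi * x_{t-1} + sqrt(1 - phi^2) * L e_t`` with ``e_t`` iid
    standard normal and ``L`` the Cholesky factor of the group correlation
    matrix, so the marginal covariance of every time point is exactly that
    matrix.
    """
    labels = _default_spec_labels(spec)
    rng = np.random.default_rng(spec.seed)
    cohort: list[RoiTimeSeries] = []
    for group in spec.groups:
        L = np.linalg.cholesky(spec.correlation_matrix(group))
        phi = spec.noise_ar1
        for s in range(spec.n_subjects_per_group[group]):
            innov = L @ rng.standard_normal((spec.n_rois, spec.n_timepoints))
            x = np.empty_like(innov)
            x[:, 0] = innov[:, 0]
            scale = np.sqrt(1.0 - phi**2)
            for t in range(1, spec.n_timepoints):
                x[:, t] = phi * x[:, t - 1] + scale * innov[:, t]
            cohort.append(
                RoiTimeSeries(
                    subject_id=f"{group}{s + 1:03d}",
                    group=group,
                    signals=x,
                    roi_labels=labels,
                )
            )
    return cohort


@dataclass
class ItemResponseSpec:
    """Configuration of a synthetic continuous item-response matrix.

    ROI latent positions are drawn around ``cluster_centers`` (ROIs split
    evenly across centers, spread ``cluster_sd``); subject positions are
    standard bivariate normal. Main effects ``theta_j`` (ROIs) and
    ``beta_i`` (subjects) are centered normals with the given SDs.
    """

    n_subjects: int
    n_rois: int
    latent_dim: int = 2
    true_theta_sd: float = 1.0
    true_beta_sd: float = 1.0
    cluster_centers: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 0.0)]
    )
    cluster_sd: float = 0.25
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.latent_dim != 2 and any(
            len(c) != self.latent_dim for c in self.cluster_centers
        ):
            raise ValueError("cluster centers must match latent_dim")
        if self.n_subjects < 1 or self.n_rois < 1:
            raise ValueError("n_subjects and n_rois must be positive")


def simulate_item_response(
    spec: ItemResponseSpec,
) -> tuple[np.ndarray, dict]:
    """Draw ``y_ij = theta_j + beta_i - ||u_j - v_i|| + N(0, noise_sd^2)``.

    Returns
    -------
    y : ndarray, shape (n_subjects, n_rois)
    truth : dict
        Ground-truth ``theta`` (n_rois), ``beta`` (n_subjects), ``U``
        (n_rois, latent_dim), ``V`` (n_subjects, latent_dim),
        ``cluster_of_roi`` assignments and ``noise_sd``.
    """
    rng = np.random.default_rng(spec.seed)
    theta = rng.normal(0.0, spec.true_theta_sd, size=spec.n_rois)
    beta = rng.normal(0.0, spec.true_beta_sd, size=spec.n_subjects)
    centers = np.asarray(spec.cluster_centers, dtype=float)
    cluster_of_roi = np.arange(spec.n_rois) % len(centers)
    U = centers[cluster_of_roi] + rng.normal(
        0.0, spec.cluster_sd, size=(spec.n_rois, spec.latent_dim)
    )
    V = rng.standard_normal((spec.n_subjects, spec.latent_dim))
    dist = np.linalg.norm(U[None, :, :] - V[:, None, :], axis=2)
    mean = theta[None, :] + beta[:, None] - dist
    y = mean + rng.normal(0.0, spec.noise_sd, size=mean.shape)
    truth = {
        "theta": theta,
        "beta": beta,
        "U": U,
        "V": V,
        "distances": dist,
        "cluster_of_roi": cluster_of_roi,
        "noise_sd": spec.noise_sd,
    }
    return y, truth


def write_cohort(
    cohort: list[RoiTimeSeries], out_dir: str | Path
) -> Path:
    """Write one CSV per subject plus a cohort manifest.

    Each subject CSV has the ROI label as first column followed by the time
    points; the manifest has columns ``subject_id,group,path``. Returns the
    manifest path.
    """
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in cohort:
        path = out / f"{ts.subject_id}.csv"
        df = pd.DataFrame(
            ts.signals, index=pd.Index(ts.roi_labels, name="roi")
        )
        df.columns = [f"t{t}" for t in range(ts.n_timepoints)]
        df.to_csv(path)
        rows.append({"subject_id": ts.subject_id, "group": ts.group, "path": path.name})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def write_truth(truth: dict, path: str | Path) -> None:
    """Serialize a generator truth record as JSON (arrays become lists)."""
    serializable = {
        k: v.tolist() if isinstance(v, np.ndarray) else v for k, v in truth.items()
    }
    Path(path).write_text(json.dumps(serializable, indent=1))
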