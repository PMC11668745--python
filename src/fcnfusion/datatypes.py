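"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class RoiTimeSeries:
    """One subject's ROI-by-time BOLD signal matrix.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    group : str
        Group/cohort label (e.g. a diagnosis group).
    signals : ndarray, shape (n_rois, n_timepoints)
        One row per ROI, one column per acquisition time point.
    roi_labels : list of str
        Region names, one per row of ``signals``.
    """

    subject_id: str
    group: str
    signals: np.ndarray
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D (n_rois, n_timepoints) matrix")
        if not np.isfinite(self.signals).all():
            raise ValueError(f"subject {self.subject_id}: non-finite signal values")
        if self.signals.shape[0] != len(self.roi_labels):
            raise ValueError(
                f"subject {self.subject_id}: {self.signals.shape[0]} signal rows "
                f"but {len(self.roi_labels)} ROI labels"
            )
        flat = self.constant_rois()
        if flat:
            warnings.warn(
                f"subject {self.subject_id}: zero-variance ROI rows: {flat}",
                stacklevel=3,
            )

    @property
    def n_rois(self) -> int:
        return self.signals.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.signals.shape[1]

    def constant_rois(self) -> list[str]:
        """Labels of ROIs whose time course has zero variance."""
        sd = self.signals.std(axis=1)
        return [lab for lab, s in zip(self.roi_labels, sd) if s == 0.0]


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI-by-ROI association matrix (Pearson r or Fisher z)."""

    values: np.ndarray
    kind: str  # "pearson" | "fisher_z"
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.roi_labels)
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix shape does not match ROI labels")
        if self.kind not in ("pearson", "fisher_z"):
            raise ValueError(f"unknown connectivity kind {self.kind!r}")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-10:
            raise ValueError("connectivity matrix is not symmetric")
        if self.kind == "pearson":
            if self.values.min() < -1 - 1e-12 or self.values.max() > 1 + 1e-12:
                raise ValueError("pearson correlations must lie in [-1, 1]")


@dataclass
class Embedding:
    """2-D coordinates of ROIs from a dimension-reduction method.

    ``method`` is one of ``linear`` (PCA), ``stochastic`` (t-SNE) or
    ``topological`` (UMAP); one coordinate row per ROI, in label order.
    """

    coords: np.ndarray
    method: str
    roi_labels: list[str]
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("embedding coordinates must be (n_rois, 2)")
        if self.coords.shape[0] != len(self.roi_labels):
            raise ValueError("one coordinate row per ROI required")
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding contains non-finite coordinates")


@dataclass
class Fcn:
    """Binary symmetric ROI adjacency (a functional connectivity network)."""

    adjacency: np.ndarray
    roi_labels: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        n = len(self.roi_labels)
        if a.shape != (n, n):
            raise ValueError("adjacency shape does not match ROI labels")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = a.astype(np.int8)


@dataclass
class AttentionMatrix:
    """Per-subject row-stochastic ROI-by-ROI attention distribution.

    Obtained by averaging one attention layer's weights over all heads;
    row j is the probability distribution of how ROI j attends to every
    ROI.
    """

    values: np.ndarray
    subject_id: str
    group: str
    roi_labels: list[str]
    comparison: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.roi_labels)
        if self.values.shape != (n, n):
            raise ValueError("attention matrix shape does not match ROI labels")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("attention weights must lie in [0, 1]")
        rows = self.values.sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-5:
            raise ValueError("attention matrix rows must sum to 1 (tol 1e-5)")


@dataclass
class GroupRepMatrix:
    """Subjects-by-ROI matrix of attention-row coefficients of variation.

    Row i holds, for subject i of group ``group``, the CV of each ROI's
    attention distribution row; this is the item-response input of the
    latent-space model (ROIs = items, subjects = respondents).
    """

    values: np.ndarray
    subject_ids: list[str]
    roi_labels: list[str]
    group: str
    comparison: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.roi_labels)):
            raise ValueError("group matrix shape must be (n_subjects, n_rois)")
        if not np.isfinite(self.values).all():
            raise ValueError("group matrix contains non-finite entries")
        if self.values.min() < 0:
            raise ValueError("CV of nonnegative attention rows cannot be negative")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class TopRoiList:
    """Ranked top-quartile ROI selection for one group.

    ``labels`` is ordered best-first and has length ``floor(0.25 * n_rois)``;
    ``selection_stats`` carries each ROI's mean attention and mean CV.
    """

    labels: list[str]
    group: str
    selection_stats: dict[str, dict[str, float]] = field(default_factory=dict)
    comparison: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("top-ROI list contains duplicates")

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __len__(self) -> int:
        return len(self.labels)
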