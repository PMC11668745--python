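"""Step 2b — group representative matrix and top-quartile ROI selection.

For each subject the coefficient of variation (population SD / mean) of
every ROI's attention row summarizes how unevenly that region attends to
the rest of the brain; stacking subjects of one group gives the
subjects-by-ROI group representative matrix. ROIs ranking in the top 25%
on both high mean attention and high mean CV form the group's candidate
list.
"""

from __future__ import annotations

import numpy as np

from fcnfusion.datatypes import AttentionMatrix, GroupRepMatrix, TopRoiList

__all__ = [
    "coefficient_of_variation",
    "roi_cv",
    "build_group_matrix",
    "top_quartile_rois",
]


def coefficient_of_variation(vec: np.ndarray, ddof: int = 0) -> float:
    """Population (``ddof=0``) coefficient of variation, SD / mean.

    Invariant to positive rescaling of ``vec``.
    """
    vec = np.asarray(vec, dtype=float)
    mean = vec.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero-mean data")
    return float(vec.std(ddof=ddof) / mean)


def roi_cv(attnM: AttentionMatrix, roi_index: int, axis: str = "row",
           ddof: int = 0) -> float:
    """Coefficient of variation of one ROI's attention distribution.

    ``axis="row"`` (default) uses how the ROI attends to others; ``"col"``
    uses how others attend to it. Population SD (``ddof=0``) by default.
    """
    vec = (
        attnM.values[roi_index, :] if axis == "row" else attnM.values[:, roi_index]
    )
    if vec.mean() == 0:
        raise ValueError(f"ROI {roi_index}: zero-mean attention row")
    return coefficient_of_variation(vec, ddof=ddof)


def build_group_matrix(
    attn_matrices: list[AttentionMatrix], axis: str = "row", ddof: int = 0
) -> GroupRepMatrix:
    """Stack per-subject, per-ROI attention CVs for one group."""
    if not attn_matrices:
        raise ValueError("at least one attention matrix required")
    labels = attn_matrices[0].roi_labels
    group = attn_matrices[0].group
    comparison = attn_matrices[0].comparison
    for m in attn_matrices:
        if m.roi_labels != labels:
            raise ValueError(f"subject {m.subject_id}: ROI labels differ")
        if m.group != group:
            raise ValueError(
                f"subject {m.subject_id} belongs to {m.group!r}, not {group!r}"
            )
    values = np.array([
        [roi_cv(m, j, axis=axis, ddof=ddof) for j in range(len(labels))]
        for m in attn_matrices
    ])
    return GroupRepMatrix(
        values=values,
        subject_ids=[m.subject_id for m in attn_matrices],
        roi_labels=list(labels),
        group=group,
        comparison=comparison,
    )


def top_quartile_rois(
    group_matrix: GroupRepMatrix,
    attn_matrices: list[AttentionMatrix],
    mode: str = "rank_sum",
) -> TopRoiList:
    """Select the top 25% of ROIs by mean CV and mean attention.

    Per ROI, the mean CV averages the group matrix over subjects and the
    mean attention averages each subject's attention row entries over
    subjects. ``mode="rank_sum"`` (default) combines the two statistics by
    unweighted rank sum and returns the best ``floor(0.25 * n_rois)``;
    ``mode="intersection"`` returns the ROIs in the top quartile of *both*
    statistics (ordered by rank sum, variable length). Ties break by higher
    mean attention, then lexicographic label.
    """
    labels = group_matrix.roi_labels
    R = len(labels)
    if R < 4:
        raise ValueError("top-quartile selection needs at least 4 ROIs")
    if mode not in ("rank_sum", "intersection"):
        raise ValueError(f"unknown selection mode {mode!r}")
    for m in attn_matrices:
        if m.roi_labels != labels:
            raise ValueError(f"subject {m.subject_id}: ROI labels differ")

    mean_cv = group_matrix.values.mean(axis=0)
    mean_attn = np.mean([m.values.mean(axis=1) for m in attn_matrices], axis=0)

    def rank_desc(x: np.ndarray) -> np.ndarray:
        # rank 1 = largest; average ranks for ties keep the sum comparable
        import scipy.stats

        return len(x) + 1 - scipy.stats.rankdata(x, method="average")

    cv_rank = rank_desc(mean_cv)
    attn_rank = rank_desc(mean_attn)
    rank_sum = cv_rank + attn_rank

    # sort key: lower rank sum, then higher mean attention, then label
    order = sorted(
        range(R), key=lambda j: (rank_sum[j], -mean_attn[j], labels[j])
    )
    k = R // 4
    if mode == "rank_sum":
        chosen = order[:k]
    else:
        q_cv = cv_rank <= k
        q_attn = attn_rank <= k
        chosen = [j for j in order if q_cv[j] and q_attn[j]]

    stats = {
        labels[j]: {
            "mean_cv": float(mean_cv[j]),
            "mean_attention": float(mean_attn[j]),
            "rank_sum": float(rank_sum[j]),
        }
        for j in chosen
    }
    return TopRoiList(
        labels=[labels[j] for j in chosen],
        group=group_matrix.group,
        selection_stats=stats,
        comparison=group_matrix.comparison,
    )
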