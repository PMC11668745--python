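"""AAL-116 atlas region labels.

The Automated Anatomical Labeling atlas parcellates the brain into 90
cerebral regions (45 left/right pairs) plus 26 cerebellar/vermis regions.
Labels follow the conventional AAL naming so reports read like standard
neuroimaging tables. :func:`roi_labels` falls back to generic ``ROI_###``
names for non-atlas region counts.
"""

from __future__ import annotations

_CEREBRAL_PAIRS = [
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
    "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
    "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
    "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
]

_CEREBELLAR_PAIRS = [
    "Cerebellum_Crus1", "Cerebellum_Crus2", "Cerebellum_3",
    "Cerebellum_4_5", "Cerebellum_6", "Cerebellum_7b", "Cerebellum_8",
    "Cerebellum_9", "Cerebellum_10",
]

_VERMIS = [
    "Vermis_1_2", "Vermis_3", "Vermis_4_5", "Vermis_6", "Vermis_7",
    "Vermis_8", "Vermis_9", "Vermis_10",
]

AAL116: list[str] = (
    [f"{name}_{side}" for name in _CEREBRAL_PAIRS for side in ("L", "R")]
    + [f"{name}_{side}" for name in _CEREBELLAR_PAIRS for side in ("L", "R")]
    + _VERMIS
)

assert len(AAL116) == 116


def roi_labels(n_rois: int) -> list[str]:
    """Return ROI labels for ``n_rois`` regions.

    AAL-116 names when ``n_rois == 116``, otherwise generic zero-padded
    ``ROI_###`` labels.
    """
    if n_rois == 116:
        return list(AAL116)
    width = max(3, len(str(n_rois)))
    return [f"ROI_{i + 1:0{width}d}" for i in range(n_rois)]
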