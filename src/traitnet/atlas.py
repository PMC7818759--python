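"""AAL-90 cerebral parcellation labels in standard atlas order.

The 90 cerebral regions of the Automated Anatomical Labelling atlas, in the
conventional interleaved order (odd indices left hemisphere, even indices
right).  These are the node labels of every 90-region connectome handled by
this package; synthetic cohorts reuse them so that results tables read like
the real thing.
"""

from __future__ import annotations

_BASE = [
    "Precentral",
    "Frontal_Sup",
    "Frontal_Sup_Orb",
    "Frontal_Mid",
    "Frontal_Mid_Orb",
    "Frontal_Inf_Oper",
    "Frontal_Inf_Tri",
    "Frontal_Inf_Orb",
    "Rolandic_Oper",
    "Supp_Motor_Area",
    "Olfactory",
    "Frontal_Sup_Medial",
    "Frontal_Med_Orb",
    "Rectus",
    "Insula",
    "Cingulum_Ant",
    "Cingulum_Mid",
    "Cingulum_Post",
    "Hippocampus",
    "ParaHippocampal",
    "Amygdala",
    "Calcarine",
    "Cuneus",
    "Lingual",
    "Occipital_Sup",
    "Occipital_Mid",
    "Occipital_Inf",
    "Fusiform",
    "Postcentral",
    "Parietal_Sup",
    "Parietal_Inf",
    "SupraMarginal",
    "Angular",
    "Precuneus",
    "Paracentral_Lobule",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Thalamus",
    "Heschl",
    "Temporal_Sup",
    "Temporal_Pole_Sup",
    "Temporal_Mid",
    "Temporal_Pole_Mid",
    "Temporal_Inf",
]

#: The 90 AAL region labels, left/right interleaved ("Precentral_L", "Precentral_R", ...).
AAL90_LABELS: list[str] = [f"{name}_{side}" for name in _BASE for side in ("L", "R")]

#: Right supramarginal gyrus: the AAL parcel containing the right
#: temporoparietal junction, the a-priori theory-of-mind region.
RIGHT_TPJ_LABEL = "SupraMarginal_R"
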