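"""Region labels for the 90-region AAL cortical/subcortical parcellation."""

_BASE = (
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
)

#: Left/right interleaved labels, AAL ordering (L before R within each region).
AAL90_LABELS: tuple[str, ...] = tuple(
    f"{name}_{hemi}" for name in _BASE for hemi in ("L", "R")
)

assert len(AAL90_LABELS) == 90
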