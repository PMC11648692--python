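"""Default predictor schema for the regional-volume feature table.

The analysis-ready table carries one row per participant with demographic /
clinical metadata plus 40 volumetric predictors: 34 Desikan cortical parcels
and 5 subcortical (aseg) structures, each merged across hemispheres, plus the
whole-brain segmentation volume without ventricles.
"""

from __future__ import annotations

# Metadata columns of a FeatureTable, in canonical order.
METADATA_COLS = ["subject_id", "group", "sex", "age", "education", "mmse", "icv"]

GROUP_LABELS = ("HC", "uHC")
SEX_LABELS = ("Male", "Female")

# Desikan-atlas cortical parcels (hemisphere-merged aparc volumes).
CORTICAL_REGIONS = [
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
]

# Subcortical segmentation structures (hemisphere-merged aseg volumes).
SUBCORTICAL_REGIONS = [
    "Lateral-Ventricle",
    "Inf-Lat-Vent",
    "Hippocampus",
    "Amygdala",
    "Accumbens-area",
]

# Whole-brain measure passed through unmerged.
GLOBAL_MEASURES = ["BrainSegVolNotVent"]

# 39 merged volumes + BrainSegVolNotVent = 40 predictors.
DEFAULT_PREDICTORS = CORTICAL_REGIONS + SUBCORTICAL_REGIONS + GLOBAL_MEASURES

# Regions carrying a nonzero group effect by default: the 8 regions that
# separate stable from converting elders in the reference cohort analysis.
EFFECT_REGIONS = [
    "Lateral-Ventricle",
    "Inf-Lat-Vent",
    "Hippocampus",
    "Accumbens-area",
    "entorhinal",
    "lateralorbitofrontal",
    "middletemporal",
    "BrainSegVolNotVent",
]


def feature_columns(table) -> list[str]:
    """Return the predictor columns of a feature table (non-metadata columns)."""
    return [c for c in table.columns if c not in METADATA_COLS]
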