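"""Feature manifest for the 150-measure morphometric table.

The table layout mirrors a standard FreeSurfer extraction: Desikan-Killiany
cortical parcellation (34 regions per hemisphere) for thickness and surface
area, plus 14 bilateral subcortical segmentation volumes, giving
68 + 68 + 14 = 150 regional features.  Three whole-brain measures
(intracranial volume, mean cortical thickness, mean surface area) travel
alongside as global covariates, not as regional outcomes.
"""

from __future__ import annotations

DK_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
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
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

SUBCORTICAL_STRUCTURES: tuple[str, ...] = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
)

HEMISPHERES = ("lh", "rh")
SIDES = ("left", "right")
SEXES = ("F", "M")

COVARIATES: tuple[str, ...] = ("icv", "mean_thickness", "mean_area")
METADATA_COLUMNS: tuple[str, ...] = ("subject_id", "age", "sex", "group")
CLINICAL_COLUMNS: tuple[str, ...] = (
    "ymrs",
    "madrs",
    "iq",
    "age_of_onset",
    "illness_duration",
    "lithium",
)


def thickness_features() -> list[str]:
    """Cortical thickness feature names (mm), 34 regions x 2 hemispheres."""
    return [f"{h}_{r}_thickness" for h in HEMISPHERES for r in DK_REGIONS]


def area_features() -> list[str]:
    """Cortical surface area feature names (mm^2), 34 regions x 2 hemispheres."""
    return [f"{h}_{r}_area" for h in HEMISPHERES for r in DK_REGIONS]


def volume_features() -> list[str]:
    """Subcortical volume feature names (mm^3), 7 structures x 2 sides."""
    return [f"{s}_{st}_volume" for s in SIDES for st in SUBCORTICAL_STRUCTURES]


def feature_manifest() -> list[str]:
    """The full ordered list of 150 regional morphometric feature names."""
    return thickness_features() + area_features() + volume_features()


def modality_counts() -> dict[str, int]:
    return {
        "thickness": len(thickness_features()),
        "area": len(area_features()),
        "subcortical_volume": len(volume_features()),
    }


def modality_of(feature: str) -> str:
    """Classify a manifest feature name by its measurement modality."""
    if feature.endswith("_thickness"):
        return "thickness"
    if feature.endswith("_area"):
        return "area"
    if feature.endswith("_volume"):
        return "subcortical_volume"
    raise ValueError(f"{feature!r} is not a manifest feature name")
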