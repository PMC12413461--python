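"""Builtin 84-node Desikan-Killiany + subcortical atlas and meta-ROI composites.

The default parcellation has 34 cortical and 8 subcortical regions per
hemisphere (84 nodes total).  Meta-ROI composites follow the standard
tau-staging assignment of regions to Braak stages (I-II entorhinal/
hippocampal, III-IV limbic and lateral temporal, V-VI remaining
neocortex) and an early/intermediate/late amyloid ordering.  The exact
region-to-composite assignment is overridable through a YAML atlas file;
see :func:`hemilat.core_data.load_atlas`.
"""

# (region_name, lobe) in canonical order; one entry per bilateral region.
DK_CORTICAL = [
    ("bankssts", "temporal"),
    ("caudalanteriorcingulate", "cingulate"),
    ("caudalmiddlefrontal", "frontal"),
    ("cuneus", "occipital"),
    ("entorhinal", "temporal"),
    ("fusiform", "temporal"),
    ("inferiorparietal", "parietal"),
    ("inferiortemporal", "temporal"),
    ("isthmuscingulate", "cingulate"),
    ("lateraloccipital", "occipital"),
    ("lateralorbitofrontal", "frontal"),
    ("lingual", "occipital"),
    ("medialorbitofrontal", "frontal"),
    ("middletemporal", "temporal"),
    ("parahippocampal", "temporal"),
    ("paracentral", "frontal"),
    ("parsopercularis", "frontal"),
    ("parsorbitalis", "frontal"),
    ("parstriangularis", "frontal"),
    ("pericalcarine", "occipital"),
    ("postcentral", "parietal"),
    ("posteriorcingulate", "cingulate"),
    ("precentral", "frontal"),
    ("precuneus", "parietal"),
    ("rostralanteriorcingulate", "cingulate"),
    ("rostralmiddlefrontal", "frontal"),
    ("superiorfrontal", "frontal"),
    ("superiorparietal", "parietal"),
    ("superiortemporal", "temporal"),
    ("supramarginal", "parietal"),
    ("frontalpole", "frontal"),
    ("temporalpole", "temporal"),
    ("transversetemporal", "temporal"),
    ("insula", "insula"),
]

SUBCORTICAL = [
    ("thalamus", "subcortical"),
    ("caudate", "subcortical"),
    ("putamen", "subcortical"),
    ("pallidum", "subcortical"),
    ("hippocampus", "subcortical"),
    ("amygdala", "subcortical"),
    ("accumbens", "subcortical"),
    ("ventraldc", "subcortical"),
]

ALL_REGIONS = DK_CORTICAL + SUBCORTICAL

BRAAK_1_2 = {"entorhinal", "hippocampus"}

BRAAK_3_4 = {
    "amygdala", "parahippocampal", "fusiform", "lingual",
    "inferiortemporal", "middletemporal", "temporalpole", "insula",
    "caudalanteriorcingulate", "rostralanteriorcingulate",
    "posteriorcingulate", "isthmuscingulate",
}

BRAAK_5_6 = {
    "superiorfrontal", "lateralorbitofrontal", "medialorbitofrontal",
    "frontalpole", "caudalmiddlefrontal", "rostralmiddlefrontal",
    "parsopercularis", "parsorbitalis", "parstriangularis",
    "lateraloccipital", "supramarginal", "inferiorparietal",
    "superiortemporal", "superiorparietal", "precuneus", "bankssts",
    "transversetemporal", "pericalcarine", "postcentral", "cuneus",
    "precentral", "paracentral",
}

ABETA_EARLY = {
    "precuneus", "posteriorcingulate", "isthmuscingulate",
    "medialorbitofrontal",
}

ABETA_LATE = {
    "lingual", "pericalcarine", "paracentral", "precentral", "postcentral",
}

# Neocortical amyloid composite used for A+/A- classification: all
# cortical regions except the medial temporal / paralimbic ones.
NEOCORTICAL = {name for name, _ in DK_CORTICAL} - {
    "entorhinal", "parahippocampal", "temporalpole",
}


def default_meta_rois() -> dict[str, set[str]]:
    """Return the builtin meta-ROI name -> member-region mapping."""
    cortical = {name for name, _ in DK_CORTICAL}
    everything = {name for name, _ in ALL_REGIONS}
    temporal = BRAAK_1_2 | BRAAK_3_4
    abeta_intermediate = cortical - ABETA_EARLY - ABETA_LATE
    return {
        "global": set(everything),
        "temporal": set(temporal),
        "braak_1_2": set(BRAAK_1_2),
        "braak_3_4": set(BRAAK_3_4),
        "braak_5_6": set(BRAAK_5_6),
        "abeta_early": set(ABETA_EARLY),
        "abeta_intermediate": abeta_intermediate,
        "abeta_late": set(ABETA_LATE),
        "neocortical": set(NEOCORTICAL),
    }
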