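"""Closed vocabularies shared across modules."""

CLUSTERS = (
    "naive B",
    "memory B",
    "activated B",
    "switched B",
    "unswitched B",
    "atypical B",
    "plasmablast",
    "PC1",
    "PC2",
    "PC3",
)

PC_CLUSTERS = ("plasmablast", "PC1", "PC2", "PC3")

ISOTYPES = (
    "IGHM",
    "IGHD",
    "IGHG1",
    "IGHG2",
    "IGHG3",
    "IGHG4",
    "IGHA1",
    "IGHA2",
    "IGHE",
)

TISSUES = ("tumor", "adjacent", "lymph_node", "blood")
TIMEPOINTS = ("pre", "post")
RESPONSES = ("R", "NR")

SPATIAL_MARKERS = ("CD3", "CD8", "CD20", "CD68", "FOXP3", "MZB1")
TLS_SEED_MARKERS = ("CD3", "CD8", "CD20")

ANTIGEN_CLASSES = ("CTA", "tumor_associated", "other")
SEROLOGY_CHANNELS = ("IgG", "IgA")

AIRR_COLUMNS = (
    "cell_id",
    "locus",
    "v_call",
    "j_call",
    "c_call",
    "junction",
    "junction_aa",
    "productive",
)
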