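"""Published reference gene lists and enrichment statistics.

These are the printed candidate-gene lists and the pathway-enrichment table
from the mouse/human neocortical-development screen that this pipeline
re-implements.  They serve as fixed inputs for worked examples and for
internal-consistency checks; they are not recomputable here because the
underlying atlases are external resources.
"""

from __future__ import annotations

from .symbols import GeneList, HUMAN, MOUSE

#: The 13-gene mouse neocortex VZ co-expression module (E15.5).
MOUSE_VZ_13 = GeneList(
    "mouse_vz_13",
    ["Cdon", "Celsr1", "Dbi", "E2f5", "Eomes", "Hmgn2", "Neurog2",
     "Notch1", "Pcnt", "Sox3", "Ssrp1", "Tead2", "Tgif2"],
    species=MOUSE,
    provenance="mouse neocortex VZ network, E15.5",
)

#: Mouse VZ genes that passed the human spatial (VZ/SVZ vs rest) screen.
HUMAN_SPATIAL_10 = GeneList(
    "human_spatial_10",
    ["CDON", "CELSR1", "E2F5", "EOMES", "HMGN2", "NEUROG2", "NOTCH1",
     "SOX3", "TEAD2", "TGIF2"],
    species=HUMAN,
    provenance="mouse VZ genes enriched in human VZ/SVZ, 15-21 pcw LMD screen",
)

#: Mouse VZ genes that passed the human temporal (8-9 pcw vs later) screen.
HUMAN_TEMPORAL_8 = GeneList(
    "human_temporal_8",
    ["CELSR1", "HMGN2", "NEUROG2", "NOTCH1", "SOX3", "SSRP1", "TEAD2", "TGIF2"],
    species=HUMAN,
    provenance="mouse VZ genes elevated at 8-9 pcw in the developmental transcriptome",
)

#: The seven-gene mouse/human core (members of the 407-gene human list that
#: are also in the 13-gene mouse module).
CORE_7 = GeneList(
    "core_7",
    ["CELSR1", "HMGN2", "NEUROG2", "NOTCH1", "SOX3", "TEAD2", "TGIF2"],
    species=HUMAN,
    provenance="407-gene human list ∩ 13-gene mouse module",
)

#: Genes of the 407-gene human list that overlap the mouse extended network
#: (beyond the seven core genes).
EXTENDED_OVERLAP_6 = GeneList(
    "extended_overlap_6",
    ["FZD2", "HIST1H3B", "NDE1", "SOX2", "TEAD1", "YAP1"],
    species=HUMAN,
    provenance="407-gene human list ∩ mouse extended-network associated genes",
)

#: Associated genes of the human extended network absent from the 407 list.
HUMAN_EXTENDED_UNIQUE_4 = GeneList(
    "human_extended_unique_4",
    ["MCM6", "KIF18B", "FEN1", "CCNF"],
    species=HUMAN,
    provenance="human extended-network associated genes outside the 407 list",
)

#: Top-10 pathway over-representation rows reported for the 407-gene human
#: list: (pathway, C annotated, O observed, E expected, R ratio, rawP, adjP).
PATHWAY_TABLE = [
    ("Cell cycle, Mitotic",                               318, 96, 2.99, 32.07, 6.24e-118, 2.10e-115),
    ("DNA Replication",                                   261, 76, 2.46, 30.93, 1.89e-91,  3.18e-89),
    ("Mitotic M-M/G1 phases",                             242, 69, 2.28, 30.29, 3.48e-82,  3.91e-80),
    ("M Phase",                                           158, 46, 1.49, 30.93, 3.06e-55,  2.58e-53),
    ("Mitotic prometaphase",                               99, 39, 0.93, 41.85, 4.88e-53,  3.29e-51),
    ("Mitotic G1-G1/S phases",                            141, 40, 1.33, 30.13, 1.33e-47,  7.47e-46),
    ("ATM pathway",                                       307, 45, 2.89, 15.57, 1.45e-39,  6.98e-38),
    ("G1/S Transition",                                   118, 32, 1.11, 28.81, 1.48e-37,  6.23e-36),
    ("Polo-like kinase signaling events in the cell cycle", 109, 31, 1.03, 30.21, 3.85e-37, 1.44e-35),
    ("S Phase",                                           121, 31, 1.14, 27.21, 1.48e-35,  4.99e-34),
]

#: Annotated-set sizes (the C column) of the pathway table, used as default
#: sizes for simulated enriched annotation sets.
PATHWAY_SET_SIZES = [row[1] for row in PATHWAY_TABLE]

#: Reported sizes of the screens' outputs at full scale.
HUMAN_SPATIAL_LIST_SIZE = 1781
HUMAN_TEMPORAL_LIST_SIZE = 1048
HUMAN_CORE_LIST_SIZE = 407
MOUSE_EXTENDED_SIZE = 63
EXTENDED_ASSOCIATED = 50
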