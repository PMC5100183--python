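"""Bundled reference tables for the worked accounting example.

Published per-accession repeat-family genome occupancies (Mb of monoploid
genome) for five accessions of a triploid apomictic dandelion lineage,
together with the matching cluster-count and methylation-call summaries.
These are inputs for the abundance/arithmetic operations — occupancies are
re-expressed as genome percentages against the 865 Mb monoploid size, family
rows are aggregated to class level, and the DMR and young-cluster fractions
are recomputed from the raw counts.
"""

from __future__ import annotations

import pandas as pd

#: Monoploid (1Cx) genome size of the study species, Mb.
G_MONOPLOID_MB = 865.0
PLOIDY = 3

#: Genomic read sample per accession: 5 million reads of 125 bp.
READS_SAMPLED = 5_000_000
READ_LENGTH_BP = 125

_ACCESSIONS = ("11", "8", "12", "13", "3")

# per family: (te_class, order, superfamily) then per accession
# (n_clusters, n_clusters_young, size_mb)
_FAMILY_ROWS = [
    ("I", "LTR", "Copia",
     (38, 15, 93.59), (37, 12, 84.05), (36, 14, 97.63), (36, 14, 99.99), (38, 16, 97.32)),
    ("I", "LTR", "Gypsy",
     (31, 6, 85.86), (28, 8, 78.05), (46, 22, 152.89), (32, 14, 104.24), (36, 14, 103.73)),
    ("I", "LTR", "Unclassified-LTR",
     (4, 0, 8.96), (5, 0, 13.44), (5, 4, 18.76), (10, 5, 26.92), (5, 1, 11.55)),
    ("I", "LINE", "LINE",
     (1, 1, 1.77), (0, 0, 0.0), (0, 0, 0.0), (0, 0, 0.0), (2, 0, 4.52)),
    ("I", "ParaRetrovirus", "Caulimovirus",
     (1, 1, 1.13), (0, 0, 0.0), (0, 0, 0.0), (0, 0, 0.0), (0, 0, 0.0)),
    ("I", "Unclassified-retro", "Unclassified-retro",
     (1, 0, 2.10), (4, 0, 9.62), (1, 0, 3.15), (0, 0, 0.0), (7, 6, 26.58)),
    ("II", "TIR", "DNA-transposons",
     (5, 1, 10.67), (6, 3, 23.55), (8, 3, 23.16), (14, 6, 41.12), (12, 5, 32.14)),
    ("unclassified", "", "",
     (12, 4, 26.93), (14, 8, 31.51), (8, 5, 16.50), (8, 5, 32.87), (10, 7, 24.25)),
    ("tandem", "satellite", "satellite",
     (1, 1, 1.13), (0, 0, 0.0), (1, 1, 1.65), (2, 2, 2.84), (1, 1, 1.45)),
    ("rDNA", "rDNA", "rDNA",
     (2, 2, 4.46), (2, 2, 3.66), (9, 9, 19.98), (9, 9, 18.45), (7, 7, 14.65)),
]

#: Printed grand totals per accession: (n_clusters, n_clusters_young, size_mb).
TOTALS = {
    "11": (96, 33, 236.60),
    "8": (96, 33, 243.87),
    "12": (113, 59, 333.72),
    "13": (111, 55, 326.44),
    "3": (118, 57, 316.19),
}

#: Gypsy Chromovirus occupancy in the most Chromovirus-rich accession, Mb.
CHROMOVIRUS_ACC12_MB = 130.0

#: Methylation-call counts: filtered CG loci and qualitative DMR calls.
METHYLATION_COUNTS = {
    "filtered_loci": 623,
    "partial": 111,   # low<->intermediate or intermediate<->high
    "true": 7,        # low<->high
    "variable_TE": 30,
    "variable_transcript": 48,
}


def family_abundance_table() -> pd.DataFrame:
    """Long-format per-family abundance records for all five accessions.

    Columns match :func:`tedyn.repeat_abundance.aggregate` input:
    accession, te_class, order, superfamily, family, size_mb, n_clusters,
    n_clusters_young.
    """
    rows = []
    for te_class, order, superfamily, *per_acc in _FAMILY_ROWS:
        for acc, (n, n_young, size_mb) in zip(_ACCESSIONS, per_acc):
            rows.append(
                {
                    "accession": acc,
                    "te_class": te_class,
                    "order": order,
                    "superfamily": superfamily,
                    "family": "",
                    "size_mb": size_mb,
                    "n_clusters": n,
                    "n_clusters_young": n_young,
                }
            )
    return pd.DataFrame(rows)
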