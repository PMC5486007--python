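"""Bundled snapshot of the published FTC-vs-FTA meta-analysis corpus.

Fourteen high-throughput studies (expression microarrays, SAGE, HDSS,
ATAC-PCR) published 2000-2014 compared follicular thyroid carcinoma with
adenoma; 365 tumours in total.  This module ships the 50 genes reported
with a concordant direction of change by at least two of those studies,
together with which study reported each gene and the direction relative to
FTC (``down`` = lower in carcinoma).  Reconstructing the per-study lists
from this snapshot lets the vote-counting machinery reproduce the consensus
tallies (seven genes supported by three independent studies, all
down-regulated in carcinoma) without any download.

Genes reported by a single study, or with discordant directions, are not
part of the snapshot; tallies over the full 600-gene universe therefore
cannot be reconstructed from it.
"""
from __future__ import annotations

import pandas as pd

from .meta import IdMap, StudyGeneListCollection, StudyRecord

# (entrez_id, symbol, direction w.r.t. FTC, supporting study ids)
_CONSENSUS_GENES = [
    (762, "CA4", "down", ("S05", "S09", "S16")),
    (1959, "EGR2", "down", ("S05", "S14", "S16")),
    (9413, "FAM189A2", "down", ("S05", "S09", "S12")),
    (7881, "KCNAB1", "down", ("S06", "S09", "S16")),
    (10404, "CPQ", "down", ("S09", "S11", "S14")),
    (5172, "SLC26A4", "down", ("S06", "S14", "S16")),
    (7033, "TFF3", "down", ("S05", "S06", "S10")),
    (185, "AGTR1", "down", ("S13", "S16")),
    (822, "CAPG", "down", ("S14", "S17")),
    (1306, "COL15A1", "down", ("S05", "S13")),
    (1363, "CPE", "down", ("S09", "S17")),
    (3491, "CYR61", "down", ("S08", "S16")),
    (1733, "DIO1", "down", ("S06", "S12")),
    (11072, "DUSP14", "down", ("S05", "S16")),
    (129080, "EMID1", "down", ("S05", "S07")),
    (953, "ENTPD1", "down", ("S09", "S14")),
    (8857, "FCGBP", "down", ("S05", "S17")),
    (2354, "FOSB", "down", ("S16", "S17")),
    (2697, "GJA1", "down", ("S05", "S11")),
    (55830, "GLT8D1", "down", ("S05", "S11")),
    (221395, "GPR116", "down", ("S05", "S09")),
    (3043, "HBB", "down", ("S12", "S15")),
    (3309, "HSPA5", "down", ("S09", "S17")),
    (3400, "ID4", "down", ("S05", "S08")),
    (3590, "IL11RA", "down", ("S05", "S11")),
    (9452, "ITM2A", "down", ("S09", "S16")),
    (3708, "ITPR1", "down", ("S05", "S11")),
    (3725, "JUN", "down", ("S05", "S16")),
    (3912, "LAMB1", "down", ("S05", "S11")),
    (744, "MPPED2", "down", ("S16", "S17")),
    (22795, "NID2", "down", ("S05", "S07")),
    (3164, "NR4A1", "down", ("S12", "S16")),
    (22925, "PLA2R1", "down", ("S12", "S16")),
    (83483, "PLVAP", "down", ("S09", "S13")),
    (5583, "PRKCH", "down", ("S09", "S14")),
    (23180, "RFTN1", "down", ("S05", "S09")),
    (8490, "RGS5", "down", ("S09", "S13")),
    (6414, "SEPP1", "down", ("S05", "S14")),
    (7038, "TG", "down", ("S10", "S17")),
    (4982, "TNFRSF11B", "down", ("S05", "S11")),
    (7173, "TPO", "down", ("S10", "S17")),
    (440, "ASNS", "up", ("S05", "S09")),
    (771, "CA12", "up", ("S05", "S12")),
    (1164, "CKS2", "up", ("S16", "S17")),
    (1649, "DDIT3", "up", ("S05", "S07")),
    (2358, "FPR2", "up", ("S05", "S11")),
    (9518, "GDF15", "up", ("S09", "S17")),
    (2896, "GRN", "up", ("S04", "S08")),
    (3486, "IGFBP3", "up", ("S05", "S10")),
    (23089, "PEG10", "up", ("S05", "S11")),
]


def consensus_table() -> pd.DataFrame:
    """The snapshot as a DataFrame (entrez_id, symbol, direction, studies)."""
    return pd.DataFrame(_CONSENSUS_GENES,
                        columns=["entrez_id", "symbol", "direction", "studies"])


def published_study_lists() -> StudyGeneListCollection:
    """Reconstruct the per-study gene lists implied by the snapshot.

    Each study contributes every consensus gene whose supporting-study set
    includes it, with the consensus direction.  Records carry symbol
    identifiers in the ``symbol`` namespace, so the collection exercises the
    full harmonization step before tallying.
    """
    records = []
    for _entrez, symbol, direction, studies in _CONSENSUS_GENES:
        for study in studies:
            records.append(StudyRecord(study_id=study, raw_id=symbol,
                                       namespace="symbol", direction=direction))
    records.sort(key=lambda r: (r.study_id, r.raw_id))
    return StudyGeneListCollection(records=records, canonical=False)


def published_idmap() -> IdMap:
    """Identifier map covering the snapshot's symbols and Entrez ids."""
    rows = []
    for entrez, symbol, _direction, _studies in _CONSENSUS_GENES:
        rows.append({"raw_id": symbol, "namespace": "symbol",
                     "gene_id": str(entrez), "symbol": symbol})
        rows.append({"raw_id": str(entrez), "namespace": "entrez",
                     "gene_id": str(entrez), "symbol": symbol})
    return IdMap(pd.DataFrame(rows))
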