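"""Published sample organization of the GSE60202 ovary microarray compendium.

The compendium assembles 511 fathead minnow (PPR, Agilent 019597,
single-color) and 80 zebrafish (DRE, Agilent 015064, two-color) arrays
of untreated, reproductively mature ovary samples, grouped under five
batch factors: Experiment, Sampling Date, RNA Date, RNA Person and Scan
Date.  The batch labels and sizes below are inputs to desk-scale
calculations (factor layouts, average batch sizes, split-configuration
combinatorics) and to design-table fixtures; no array data are needed
or downloaded.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["STUDY_BATCH_SIZES", "FACTORS", "total_samples", "average_batch_size", "design_table"]

FACTORS = ("Experiment", "Sampling Date", "RNA Date", "RNA Person", "Scan Date")

STUDY_BATCH_SIZES = {
    "DRE": {
        "Experiment": {
            "CTL_FAD24": 5, "CTL_FIP48_96": 10, "CTL_FLU48_96": 10,
            "CTL_KTC24_48_96": 15, "CTL_MUSC96": 5, "CTL_PRO48_96": 10,
            "CTL_TRB24_48": 10, "CTL_TRI96": 5, "CTL_VIN48_96": 10,
        },
        "Sampling Date": {
            "CTL_2004_12": 10, "CTL_2005_1": 5, "CTL_2006_10": 10,
            "CTL_2006_4": 10, "CTL_2006_5": 10, "CTL_2006_9": 10,
            "CTL_2007_2": 5, "CTL_2007_4": 5, "CTL_2007_5": 15,
        },
        "RNA Date": {
            "CTL_2005_1": 10, "CTL_2005_3": 5, "CTL_2006_11": 30, "CTL_2007_6": 35,
        },
        "RNA Person": {"CTL_A": 65, "CTL_B": 15},
        "Scan Date": {
            "CTL_2007_12": 47, "CTL_2007_2": 4, "CTL_2007_3": 24,
            "CTL_2007_4": 2, "CTL_2008_4": 3,
        },
    },
    "PPR": {
        "Experiment": {
            "BPA_NOTEL": 6, "FAD_I_Acute": 12, "FAD_III_Acute": 20, "FAD_Phase3": 60,
            "FLU_II_Acute": 20, "FLU_Phase3": 38, "GEM": 5, "KTC_I_Acute": 12,
            "KTC_IV_Acute": 28, "KTCv2_Phase3": 39, "PRO_I_Acute": 12, "PRO_Phase3": 54,
            "RDX_Repro": 4, "TNT_KTC_Acute": 24, "TRB_BPA": 6, "TRB_EE2": 4,
            "TRB_Phase3": 54, "TRB_TCC": 5, "TRI_II_Acute": 20, "TRI_Phase3": 32,
            "VIN_II_Acute": 19, "VIN_Phase3": 32, "WLSSD": 5,
        },
        "Sampling Date": {
            "2007_12": 4, "2007_2": 12, "2007_3": 72, "2007_6": 54, "2007_7": 24,
            "2008_1": 54, "2008_2": 12, "2008_4": 51, "2008_5": 78, "2008_8": 52,
            "2009_1": 5, "2009_10": 67, "2009_6": 4, "2009_7": 10, "2009_9": 6,
            "2010_1": 6,
        },
        "RNA Date": {
            "11111": 12, "2007_12": 58, "2007_4": 12, "2007_6": 60, "2008_11": 19,
            "2008_2": 12, "2008_6": 124, "2008_7": 44, "2008_9": 32, "2009_1": 20,
            "2009_10": 44, "2009_11": 29, "2009_7": 9, "2009_9": 5, "2010_02": 6,
            "2010_1": 5, "55555": 20,
        },
        "RNA Person": {
            "DDD": 20, "A": 32, "B": 124, "B_ROBOT": 54, "C": 24, "J": 23,
            "L": 126, "R": 60, "X": 36, "YYY": 12,
        },
        "Scan Date": {
            "2008_10": 10, "2008_11": 22, "2008_12": 62, "2008_4": 12, "2008_5": 10,
            "2008_6": 132, "2008_7": 38, "2008_8": 26, "2009_1": 40, "2009_10": 6,
            "2009_11": 39, "2009_2": 30, "2009_6": 23, "2009_7": 8, "2009_9": 14,
            "2010_1": 28, "2010_2": 5, "2010_7": 6,
        },
    },
}


def total_samples(species: str, factor: str = "Experiment") -> int:
    return sum(STUDY_BATCH_SIZES[species][factor].values())


def average_batch_size(species: str, factor: str = "Experiment") -> int:
    """Floor of total samples over batch count (e.g. 511 // 23 = 22 for PPR)."""
    sizes = STUDY_BATCH_SIZES[species][factor]
    return total_samples(species, factor) // len(sizes)


def design_table(species: str) -> pd.DataFrame:
    """Sample annotation table with the published per-factor batch sizes.

    Only the marginal batch sizes per factor are published, so each
    factor's labels are laid out in contiguous runs over a common
    sample ordering; the joint cross-tabulation of factors is synthetic.
    """
    n = total_samples(species)
    table = pd.DataFrame({"sample_id": [f"{species}_s{i:03d}" for i in range(n)]})
    for factor in FACTORS:
        sizes = STUDY_BATCH_SIZES[species][factor]
        if sum(sizes.values()) != n:
            raise ValueError(f"factor {factor!r} sizes do not sum to {n}")
        labels = []
        for batch in sorted(sizes):
            labels += [batch] * sizes[batch]
        table[factor] = labels
    return table
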