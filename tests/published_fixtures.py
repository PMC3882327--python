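"""Published stage-wise methylated gene lists for lung adenocarcinoma.

These reported gene lists serve as a set-arithmetic fixture: 34
genes methylated in all three analysed stages, stage-pair lists, and
the 25 of the 34 mapping to TRUE CpG islands.  The pairwise lists
are reduced to exclusive Venn regions here (the source lists contain
a few cross-list duplicates, which are resolved in favour of the
more inclusive region).
"""

# methylated in all of stages I, II and III (34 genes)
COMMON_ALL_STAGES = {
    "AJAP1", "ATP8A2", "CCDC140", "CNTP2", "CYYR1", "EVX1", "FERD3L",
    "FOXG1", "GRIK3", "GRM6", "HAND2", "HOXA9", "HOXB4", "HOXD4",
    "HOXD9", "HOXD12", "INPP5B", "OTX2", "KRTAP8-1", "MMP26", "PHOX2A",
    "PLEKHA6", "POU4F2", "PRAC", "PRKCB", "PTGDR", "REG3A", "SIX6",
    "SLC6A2", "SPAG6", "TBX20", "TLX3", "TMEM130", "ZNF560",
}

# methylated in stages I and II only (12 genes)
COMMON_I_II = {
    "ADCY4", "BHMT", "C12orf34", "CDO1", "LVRN", "LY96", "MSC",
    "PCDHGA12", "POU3F3", "ZNF154", "ZNF577", "IHH",
}

# methylated in stages II and III (30 listed genes, incl. duplicates
# of the all-stage and I&III lists)
COMMON_II_III = {
    "BARHL2", "C10orf81", "CCDC140", "DEFB119", "DIO3", "FAM135B",
    "FAM83A", "GRIK2", "HOXA4", "HOXD10", "HS3ST2", "KCNS2",
    "KRTAP15-1", "LEP", "LHX1", "LYPD5", "MAGEB6", "NEUROG1", "NKX6-2",
    "OR5I1", "SERPINB5", "SPHKAP", "TAL1", "TBX4", "TBX5", "TCN1",
    "TMEM132D", "VSX1", "ZNF454", "IGKV7-3",
}

# hypermethylated in both stages I and III (42 genes, incl. most of
# the all-stage list)
HYPER_I_III = {
    "AJAP1", "ATP8A2", "CCDC140", "CNTP2", "CYYR1", "EVX1", "FERD3L",
    "FOXG1", "FOXI2", "GALR1", "GAS7", "GRIK2", "GRM6", "HAND2",
    "HLA-G", "HOXA7", "HOXA9", "HOXB4", "HOXD4", "HOXD8", "HOXD9",
    "HOXD12", "INPP5B", "NID2", "NPY", "OTX2", "PAX7", "PHOX2A",
    "PLEKHA6", "POU4F2", "PRAC", "PRKCB", "PTGDR", "SIX6", "SLC6A2",
    "SOX17", "SPAG6", "TBX20", "TLX3", "TMEM130", "VIPR2", "ZNF560",
}

# hypomethylated in both stages I and III (4 genes)
HYPO_I_III = {"CORO6", "MMP26", "REG3A", "KRTAP8-1"}

# the 25 of the 34 all-stage genes located in TRUE CpG islands
CPG_TRUE_OF_COMMON = {
    "AJAP1", "ATP8A2", "CYYR1", "EVX1", "FERD3L", "GRIK3", "GRM6",
    "HAND2", "HOXA9", "HOXB4", "HOXD9", "HOXD4", "HOXD12", "OTX2",
    "PRAC", "PHOX2A", "POU4F2", "PTGDR", "SIX6", "SLC6A2", "SPAG6",
    "TBX20", "TMEM130", "TLX3", "ZNF560",
}

# exclusive pairwise Venn regions after duplicate resolution
REGION_I_III = (HYPER_I_III | HYPO_I_III) - COMMON_ALL_STAGES
REGION_II_III = COMMON_II_III - COMMON_ALL_STAGES - REGION_I_III
REGION_I_II = COMMON_I_II - COMMON_ALL_STAGES


def stage_sets() -> dict[str, set[str]]:
    """Reconstructed per-stage methylated gene sets."""
    return {
        "I": COMMON_ALL_STAGES | REGION_I_II | REGION_I_III | {"U_I_1", "U_I_2"},
        "II": COMMON_ALL_STAGES | REGION_I_II | REGION_II_III | {"U_II_1"},
        "III": COMMON_ALL_STAGES | REGION_II_III | REGION_I_III | {"U_III_1"},
    }
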