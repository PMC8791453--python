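"""Published reference values for the stage-stratified EEC SMG analysis.

These constants are the printed outputs of the source cohorts — the NHGRI
late-stage exome cohort (n = 15) and the TCGA non-ultramutated EEC cohorts
(66 late-stage, 270 early-stage) — and serve two purposes: they are the
*inputs* to the restricted-hypothesis re-test exactly as it was originally
run (the early-stage p-values come from MutSigCV v1.4, whose covariate
background model this package deliberately does not re-implement), and they
are fixed cross-checks for the test suite.
"""

from __future__ import annotations

#: Late-stage SMGs in the NHGRI cohort (n = 15): gene -> (n_mutated, percent, p, q).
NHGRI_LATE_SMG_TABLE: dict[str, tuple[int, float, float, float]] = {
    "PTEN": (13, 86.7, 2.11e-15, 3.98e-11),
    "ARID1A": (11, 73.3, 1.27e-10, 1.20e-06),
    "RPL22": (4, 26.7, 1.44e-07, 9.07e-04),
    "OR6C75": (4, 26.7, 7.84e-06, 3.70e-02),
    "CTCF": (5, 33.3, 1.26e-05, 4.74e-02),
    "AP1S1": (3, 20.0, 2.13e-05, 6.70e-02),
}

#: Late-stage SMGs in the TCGA cohort (n = 66): gene -> (n_mutated, percent, p, q).
TCGA_LATE_SMG_TABLE: dict[str, tuple[int, float, float, float]] = {
    "ARID1A": (29, 43.9, 0.0, 0.0),
    "PIK3R1": (21, 31.8, 5.55e-16, 5.24e-12),
    "PTEN": (46, 69.7, 2.00e-15, 1.26e-11),
    "PIK3CA": (25, 37.9, 7.27e-14, 3.43e-10),
    "TP53": (19, 28.8, 3.07e-13, 1.16e-09),
    "KRAS": (18, 27.3, 7.22e-11, 2.27e-07),
    "RPL22": (6, 9.1, 4.89e-08, 1.08e-04),
    "CTCF": (12, 18.2, 4.99e-08, 1.08e-04),
    "CTNNB1": (18, 27.3, 5.16e-08, 1.08e-04),
    "PAX6": (7, 10.6, 1.04e-06, 1.96e-03),
    "RNF43": (9, 13.6, 4.61e-06, 7.91e-03),
    "KLF3": (7, 10.6, 6.34e-06, 9.96e-03),
}

#: The 14 unique late-stage SMGs (union of the two tables above).
LATE_STAGE_SMGS: tuple[str, ...] = tuple(
    sorted(set(NHGRI_LATE_SMG_TABLE) | set(TCGA_LATE_SMG_TABLE))
)

#: MutSigCV (v1.4) p-values for the 14 late-stage SMGs in the TCGA
#: early-stage cohort (n = 270) — the inputs to the restricted re-test.
EARLY_STAGE_MUTSIGCV_P: dict[str, float] = {
    "AP1S1": 0.0,
    "ARID1A": 0.0,
    "CTNNB1": 0.0,
    "PIK3CA": 0.0,
    "PTEN": 0.0,
    "RNF43": 0.0,
    "RPL22": 0.0,
    "TP53": 1.11e-15,
    "CTCF": 2.78e-15,
    "PIK3R1": 2.89e-15,
    "KRAS": 6.88e-15,
    "OR6C75": 1.89e-03,
    "PAX6": 1.29e-01,
    "KLF3": 9.99e-01,
}

#: Published early-stage q-values corrected for 14 tests (for cross-checks).
EARLY_STAGE_PUBLISHED_Q: dict[str, float] = {
    "AP1S1": 0.0,
    "ARID1A": 0.0,
    "CTNNB1": 0.0,
    "PIK3CA": 0.0,
    "PTEN": 0.0,
    "RNF43": 0.0,
    "RPL22": 0.0,
    "TP53": 1.94e-15,
    "CTCF": 4.05e-15,
    "PIK3R1": 4.05e-15,
    "KRAS": 8.76e-15,
    "OR6C75": 2.21e-03,
    "PAX6": 1.39e-01,
    "KLF3": 9.99e-01,
}

#: NHGRI cohort burden summary: 2,306 nonsynonymous + splice-site variants
#: over 15 tumors (range 9-542 per tumor, 1,968 genes).
NHGRI_NONSILENT_TOTAL = 2306
NHGRI_N_TUMORS = 15
NHGRI_BURDEN_RANGE = (9, 542)
NHGRI_MEAN_BURDEN = 153.7  # printed to one decimal

#: TCGA cohort sizes by stage class and molecular subgroup.
TCGA_SUBGROUP_SIZES: dict[tuple[str, str], int] = {
    ("early", "MSI_hypermutated"): 114,
    ("early", "CN_low"): 119,
    ("early", "CN_high"): 37,
    ("late", "MSI_hypermutated"): 27,
    ("late", "CN_low"): 21,
    ("late", "CN_high"): 18,
}
TCGA_N_EARLY = 270
TCGA_N_LATE = 66
TCGA_N_TOTAL = 336

#: Non-silent mutation counts per subgroup, all stages: gene -> {subgroup: (mutated, total)}.
MSI_TARGET_SUBGROUP_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "KLF3": {
        "MSI_hypermutated": (20, 141),
        "CN_low": (0, 140),
        "CN_high": (0, 55),
    },
    "PAX6": {
        "MSI_hypermutated": (11, 141),
        "CN_low": (1, 140),
        "CN_high": (0, 55),
    },
}

#: Stage-stratified mutation frequencies within the MSI-hypermutated subgroup.
MSI_TARGET_STAGE_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "KLF3": {"late": (7, 27), "early": (13, 114)},
    "PAX6": {"late": (7, 27), "early": (4, 114)},
}

#: Recurrent homopolymer-tract frameshifts in the MSI target genes.
RECURRENT_FRAMESHIFTS: dict[str, tuple[str, ...]] = {
    "KLF3": ("K106Nfs*21", "P226Rfs*52", "Q227Afs*37"),
    "PAX6": ("P375Hfs*7",),
}

#: Power-analysis constants: 90th-percentile gene factor and length,
#: mis-detection rate, family level over k tests.
POWER_F_G = 3.9
POWER_L = 1500
POWER_M = 0.1
POWER_ALPHA = 0.1
POWER_K = 14
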