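"""Published group-level summary values used as validation fixtures.

These are the printed cohort summaries of the hemodialysis study whose
analysis this package reimplements: per-scale multiscale-entropy group
means, the LFnu spectral row, the Bayes-factor column, and the 2x2
cluster-by-group counts.  The raw recordings behind them are not public,
so tests validate arithmetic identities on these printed numbers rather
than re-deriving them from data.
"""

# HS-group (n=21) per-scale MSE means, scales 1..20
HS_MSE_MEANS = [
    1.52, 1.64, 1.58, 1.56, 1.55, 1.51, 1.45, 1.39, 1.31, 1.22,
    1.16, 1.08, 1.00, 0.92, 0.88, 0.84, 0.80, 0.75, 0.71, 0.67,
]

# printed AUC summaries for the HS group
HS_AUC_1_20 = 22.43
HS_AUC_1_5 = 6.30
HS_AUC_6_20 = 14.60

# LFnu row: mean, SD, n per group
LFNU_HS = (72.6, 12.3, 21)
LFNU_HU = (61.0, 21.6, 25)
LFNU_BF10 = 1.93
LFNU_PROB = 65.9

# Bayes-factor column (feature -> BF10), spectral + entropy variables
BF10_BY_FEATURE = {
    "LFnu": 1.93, "HFnu": 1.92, "FuzzyEn": 0.31,
    "MSE1": 0.37, "MSE2": 1.67, "MSE3": 3.86, "MSE4": 15.8, "MSE5": 25.9,
    "MSE6": 8.13, "MSE7": 10.1, "MSE8": 9.79, "MSE9": 6.42, "MSE10": 5.39,
    "MSE11": 7.31, "MSE12": 6.27, "MSE13": 10.00, "MSE14": 4.6,
    "MSE15": 6.11, "MSE16": 5.2, "MSE17": 7.34, "MSE18": 5.00,
    "MSE19": 5.65, "MSE20": 3.62,
    "MSE_1_20": 12.8, "MSE_1_5": 6.63, "MSE_6_20": 7.34,
}

# BF -> replication-probability pairs as printed
BF_PROB_PAIRS = [(1.93, 65.9), (25.9, 96.3), (12.8, 92.8)]

# 2x2 cluster-by-group counts: rows Cluster 1 / Cluster 2, columns HS / HU
CLUSTER_COUNTS = [[17, 11], [4, 14]]
RR_PRINTED = 2.94
RR_CI_PRINTED = (1.14, 7.58)
CLUSTER1_HS_PCT = 81.0
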