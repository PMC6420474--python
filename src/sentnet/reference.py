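"""Published reference values from the original 144-right-hander cohort.

The raw imaging data behind the atlas are access-restricted, but the
study's printed summary tables are public.  They are transcribed here so
that the deterministic parts of the analysis (hub thresholds and hub
classification from the per-region centrality table, network volume
ratios, the conjunction-threshold arithmetic, and the sign-test worked
examples) can be recomputed from the published numbers.

Contents
--------
SELECTED_REGIONS
    The 32 supramodal sentence regions (joint activation + leftward
    asymmetry in all three tasks), their network labels and MNI
    coordinates.
CORE_CENTRALITY
    Per-region betweenness/degree centrality summaries of the 18-region
    SENT_CORE network (cohort means over 138 subjects).
NETWORK_VOLUMES_MM3, NETWORK_ACTIVATION
    Network volumes and volume-weighted activation/asymmetry profiles.
CONJUNCTION_COUNTS
    Numbers of regions passing each selection stage.
SIGN_TEST_EXAMPLES
    Inter-network correlation sign-test counts with their printed p
    values.
"""

from __future__ import annotations

import pandas as pd

# abbreviation -> (network, MNI x, y, z)
SELECTED_REGIONS = pd.DataFrame(
    [
        ("prec3", "SENT_MEM", -18.2, -8.7, 69.3),
        ("prec4", "SENT_CORE", -42.2, 0.7, 49.9),
        ("F1_2", "SENT_CORE", -11.9, 46.5, 41.4),
        ("f2_2", "SENT_CORE", -43.1, 14.8, 29.4),
        ("F3t", "SENT_CORE", -49.4, 25.6, 4.7),
        ("F3O1", "SENT_CORE", -42.2, 30.5, -16.9),
        ("INSa1", "SENT_VISU", -20.3, 5.0, -19.3),
        ("INSa2", "SENT_CORE", -33.8, 16.8, -12.7),
        ("INSa3", "SENT_CORE", -33.7, 23.7, 0.6),
        ("T1_4", "SENT_CORE", -58.7, -23.3, 3.7),
        ("T2_3", "SENT_CORE", -61.0, -35.0, -4.8),
        ("T2_4", "SENT_CORE", -53.1, -59.4, 7.0),
        ("T3_4", "SENT_VISU", -50.0, -60.6, -7.6),
        ("STS1", "SENT_CORE", -49.7, 14.0, -21.5),
        ("STS2", "SENT_CORE", -54.9, -7.2, -12.8),
        ("STS3", "SENT_CORE", -54.7, -33.0, -1.7),
        ("STS4", "SENT_CORE", -56.5, -48.4, 13.4),
        ("SMG7", "SENT_CORE", -55.2, -51.7, 25.5),
        ("AG2", "SENT_CORE", -37.5, -70.4, 39.5),
        ("O3_1", "SENT_VISU", -48.4, -69.0, -4.3),
        ("FUS4", "SENT_VISU", -43.1, -49.8, -17.4),
        ("pHIPP1", "SENT_VISU", -15.7, -4.0, -18.4),
        ("HIPP2", "SENT_MEM", -24.9, -32.5, -2.7),
        ("SMA2", "SENT_CORE", -10.6, 18.2, 63.1),
        ("SMA3", "SENT_CORE", -7.2, 7.6, 65.6),
        ("pCENT4", "SENT_MEM", -6.4, -29.2, 75.9),
        ("CINGp3", "SENT_MEM", -5.1, -42.9, 10.0),
        ("PRECU6", "SENT_MEM", -7.4, -61.3, 64.1),
        ("AMYG", "SENT_VISU", -21.9, -0.4, -11.5),
        ("THA4", "SENT_MEM", -3.2, -14.4, 8.4),
        ("PUT2", "SENT_VISU", -23.3, 6.3, 0.8),
        ("PUT3", "SENT_VISU", -28.0, -6.3, 1.8),
    ],
    columns=["abbreviation", "network", "mni_x", "mni_y", "mni_z"],
)

# Per-region cohort summaries for the 18 SENT_CORE regions:
# (BC mean, BC SD, % subjects with BC = 0, DC mean, DC SD,
#  DC skewness, DC excess kurtosis, Shapiro-Wilk normality p)
CORE_CENTRALITY = pd.DataFrame(
    [
        ("prec4", 6.88, 7.00, 11, 4.94, 1.50, -0.07, -0.24, 0.87),
        ("F1_2", 6.30, 5.42, 17, 4.64, 1.40, 0.28, -0.32, 0.27),
        ("f2_2", 3.33, 4.45, 37, 3.35, 1.53, 0.60, -0.42, 0.0002),
        ("F3t", 18.98, 9.77, 1, 6.48, 1.26, -0.06, -0.29, 0.78),
        ("F3O1", 2.18, 4.04, 54, 4.31, 1.50, 0.50, -0.02, 0.018),
        ("INSa2", 2.49, 3.66, 43, 3.84, 1.46, 0.27, -0.23, 0.14),
        ("INSa3", 2.54, 3.98, 40, 3.01, 1.29, 0.76, 0.63, 0.0005),
        ("T1_4", 0.75, 2.19, 77, 3.12, 1.47, 0.56, -0.20, 0.0012),
        ("T2_3", 5.28, 5.96, 29, 5.44, 1.43, 0.05, -0.17, 0.71),
        ("T2_4", 2.21, 4.28, 58, 3.46, 1.79, 0.24, -0.60, 0.074),
        ("STS1", 2.46, 3.57, 41, 4.55, 1.52, -0.10, -0.18, 0.44),
        ("STS2", 3.07, 4.85, 41, 4.30, 1.44, 0.14, -0.58, 0.11),
        ("STS3", 13.04, 9.66, 6, 6.32, 1.36, -0.36, 0.23, 0.088),
        ("STS4", 13.33, 8.25, 2, 5.58, 1.51, 0.09, -0.22, 0.95),
        ("SMG7", 6.23, 6.86, 22, 5.28, 1.60, -0.21, -0.64, 0.037),
        ("AG2", 0.72, 1.65, 71, 2.24, 1.17, 0.88, 1.11, 0.0002),
        ("SMA2", 2.21, 3.58, 46, 4.35, 1.33, 0.33, -0.09, 0.32),
        ("SMA3", 2.24, 3.60, 49, 4.22, 1.28, 0.05, -0.36, 0.45),
    ],
    columns=[
        "abbreviation",
        "bc_mean",
        "bc_sd",
        "bc_pct_null",
        "dc_mean",
        "dc_sd",
        "dc_skewness",
        "dc_kurtosis",
        "dc_p_norm",
    ],
)

NETWORK_VOLUMES_MM3 = {
    "SENT_CORE": 83_232,
    "SENT_MEM": 9_024,
    "SENT_VISU": 24_368,
}

# network -> task -> (left activation mean, SD, asymmetry mean, SD)
NETWORK_ACTIVATION = {
    "SENT_CORE": {
        "PROD": (0.73, 0.31, 0.41, 0.22),
        "LISN": (0.43, 0.20, 0.25, 0.14),
        "READ": (0.55, 0.26, 0.28, 0.19),
    },
    "SENT_MEM": {
        "PROD": (0.40, 0.36, 0.11, 0.17),
        "LISN": (0.28, 0.23, 0.08, 0.12),
        "READ": (0.21, 0.26, 0.07, 0.14),
    },
    "SENT_VISU": {
        "PROD": (0.37, 0.27, 0.16, 0.13),
        "LISN": (0.30, 0.17, 0.11, 0.08),
        "READ": (0.25, 0.21, 0.12, 0.10),
    },
}

# per-stage conjunction counts: task -> (activated, asymmetric, both);
# "ALL" row = conjunction across the three tasks
CONJUNCTION_COUNTS = {
    "PROD": (133, 93, 75),
    "LISN": (116, 73, 64),
    "READ": (97, 60, 43),
    "ALL": (80, 46, 32),
}

# (positive count, n, printed one-sided p) for the inter-network
# correlation sign tests
SIGN_TEST_EXAMPLES = {
    "SENT_CORE-SENT_VISU": (78, 138, 0.074),
    "SENT_MEM-SENT_VISU": (86, 138, 0.0024),
}

# pooled DC-activation correlations over 138 subjects x 18 regions
POOLED_COUPLING_R = {"PROD": 0.158, "LISN": 0.216, "READ": 0.294}
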