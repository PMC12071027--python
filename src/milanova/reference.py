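"""Published worked-example tables for validating the ANOVA/LSD arithmetic.

A published factorial sensitivity study of this classifier family reports
Type III main-effects ANOVA tables and least-squares means for a five-factor
design (factor levels 2, 3, 3, 4, 4; n = 861 surviving runs) over three
responses: macro F1, logit-transformed one-vs-rest AUC, and training time in
seconds.  The raw runs behind those tables are not available, but every cell
that is *derivable* from the printed inputs — mean squares from SS/df,
F ratios against the residual mean square, p-values from the F distribution,
residual degrees of freedom from the design, and differences of least-squares
means — can be recomputed and compared at printed precision.  This module
stores those printed inputs; nothing here is used in model fitting.
"""

from __future__ import annotations

#: Per response: factor -> (SumSq, df, printed MeanSq, printed F, printed p),
#: plus the residual (SumSq, df) and corrected total (SumSq, df) rows.
ANOVA_TABLES = {
    "F1": {
        "factors": {
            "Wd": (0.000697502, 1, 0.000697502, 0.20, 0.6566),
            "Ly": (0.224158, 2, 0.112079, 31.76, 0.0000),
            "Nt": (0.054888, 3, 0.018296, 5.19, 0.0015),
            "Nb": (0.0474815, 3, 0.0158272, 4.49, 0.0039),
            "Dp": (0.105687, 2, 0.0528436, 14.98, 0.0000),
        },
        "residual": (2.99578, 849),
        "total": (3.47639, 860),
    },
    "LOGIT_AUC": {
        "factors": {
            "Wd": (0.0720822, 1, 0.0720822, 0.66, 0.4148),
            "Ly": (0.417128, 2, 0.208564, 1.92, 0.1467),
            "Nt": (2.40306, 3, 0.801019, 7.39, 0.0001),
            "Nb": (1.54485, 3, 0.514949, 4.75, 0.0027),
            "Dp": (0.145252, 2, 0.0726261, 0.67, 0.5120),
        },
        "residual": (92.0456, 849),
        "total": (97.7375, 860),
    },
    "T": {
        "factors": {
            "Wd": (271.83, 1, 271.83, 20.52, 0.0000),
            "Ly": (1087.5, 2, 543.749, 41.05, 0.0000),
            "Nt": (3696.49, 3, 1232.16, 93.02, 0.0000),
            "Nb": (914.478, 3, 304.826, 23.01, 0.0000),
            "Dp": (10.8907, 2, 5.44534, 0.41, 0.6630),
        },
        "residual": (11245.6, 849),
        "total": (19650.1, 860),
    },
}

#: Printed least-squares means (mean, SE, lower, upper) for the level pairs
#: whose differences are quoted in the study's range tests.
LS_MEANS = {
    ("T", "Wd"): {
        0.0: (489.085, 0.289366, 488.518, 489.652),
        0.1: (490.591, 0.165357, 490.267, 490.915),
    },
    ("LOGIT_AUC", "Nb"): {
        0: (1.6471, 0.0220043, 1.60397, 1.69023),
        5: (1.72697, 0.0218313, 1.68418, 1.76975),
        10: (1.75967, 0.0260306, 1.70865, 1.81069),
        20: (1.70754, 0.0323426, 1.64415, 1.77093),
    },
}

#: The design behind the published tables: factor -> number of levels.
DESIGN_LEVELS = {"Wd": 2, "Ly": 3, "Dp": 3, "Nt": 4, "Nb": 4}

#: Number of runs surviving the outlier screen in the published analysis.
N_RUNS = 861
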