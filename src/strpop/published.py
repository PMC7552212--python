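"""Published per-locus reference values for the Konik sire-line STR study.

The six paternal founder lines of the Polish Konik horse were genotyped at the
17 ISAG-recommended equine STR loci (12 core + 5 additional markers, one of
them X-linked).  The raw genotypes were not deposited, but the study reports
per-locus summary statistics.  Those printed values are stored here verbatim:
they are legitimate *inputs* for panel-level aggregation (cumulative exclusion
and identity probabilities, column means) and for checking functional
relationships such as PE as a function of observed heterozygosity.

All values are dimensionless probabilities/indices as printed (4 decimals).
"""

from __future__ import annotations

import numpy as np

#: Locus order used throughout (12 ISAG core + 5 additional; LEX3 is X-linked).
LOCI: tuple[str, ...] = (
    "AHT4", "AHT5", "ASB2", "HMS2", "HMS3", "HMS6", "HMS7", "HTG10",
    "HTG4", "HTG6", "HTG7", "VHL20", "ASB17", "ASB23", "CA425", "HMS1",
    "LEX3",
)

X_LINKED_LOCI: tuple[str, ...] = ("LEX3",)

#: Sire lines and the number of genotyped individuals per line (196 total).
POPULATION_SIZES: dict[str, int] = {
    "Wicek": 48,
    "Myszak": 12,
    "GlejtI": 35,
    "Goraj": 32,
    "Chochlik": 36,
    "Liliput": 33,
}

# Whole-group per-locus population coefficients, in LOCI order.
HO = np.array([0.7602, 0.7908, 0.8010, 0.7398, 0.7653, 0.8163, 0.6684, 0.8112,
               0.4541, 0.1684, 0.6173, 0.7806, 0.7857, 0.7092, 0.6480, 0.7296,
               0.0357])
HE = np.array([0.7482, 0.7964, 0.7895, 0.7234, 0.7763, 0.7956, 0.7015, 0.8012,
               0.4681, 0.1663, 0.6195, 0.7931, 0.7926, 0.7371, 0.7122, 0.7457,
               0.8110])
PD = np.array([0.8914, 0.9280, 0.9303, 0.8819, 0.9101, 0.9222, 0.8654, 0.9326,
               0.6885, 0.3011, 0.7915, 0.9267, 0.9197, 0.8827, 0.8793, 0.8956,
               0.8230])
PE = np.array([0.5274, 0.5821, 0.6009, 0.4925, 0.5363, 0.6297, 0.3810, 0.6200,
               0.1504, 0.0217, 0.3122, 0.5636, 0.5728, 0.4426, 0.3524, 0.4755,
               0.0012])
PIC = np.array([0.7088, 0.7672, 0.7670, 0.6857, 0.7431, 0.7638, 0.6519, 0.7747,
                0.4421, 0.1593, 0.5522, 0.7683, 0.7662, 0.6954, 0.6813, 0.7124,
                0.7858])
PE1 = np.array([0.3486, 0.4240, 0.4333, 0.3207, 0.3902, 0.4146, 0.2914, 0.4393,
                0.1198, 0.0138, 0.1994, 0.4344, 0.4311, 0.3333, 0.3198, 0.3541,
                0.4552])
PE2 = np.array([0.5261, 0.6020, 0.6129, 0.5013, 0.5694, 0.5929, 0.4610, 0.6160,
                0.2785, 0.0843, 0.3475, 0.6121, 0.6081, 0.5094, 0.5046, 0.5358,
                0.6307])
PID = np.array([0.1028, 0.0706, 0.0669, 0.1142, 0.0832, 0.0735, 0.1387, 0.0661,
                0.3090, 0.7020, 0.2121, 0.0676, 0.0694, 0.1108, 0.1137, 0.0979,
                0.0609])

# Per-locus fixation indices for the whole group (Weir-Cockerham style).
FIT = np.array([-0.0096, 0.0162, -0.0100, -0.0191, 0.0231, -0.0185, 0.0613,
                -0.0061, 0.0342, 0.0000, 0.0105, 0.0261, 0.0142, 0.0449,
                0.1052, 0.0305, 0.9562])
FST = np.array([0.0213, 0.0373, 0.0113, 0.0053, 0.0357, 0.0269, 0.0673,
                0.0211, 0.0099, 0.0526, 0.0244, 0.0438, 0.0166, 0.0262,
                0.0756, 0.0362, 0.0079])
FIS = np.array([-0.0316, -0.0219, -0.0215, -0.0245, -0.0130, -0.0466, -0.0065,
                -0.0278, 0.0246, -0.0555, -0.0143, -0.0185, -0.0024, 0.0193,
                0.0319, -0.0059, 0.9559])


def columns() -> dict[str, np.ndarray]:
    """All published per-locus columns keyed by statistic name."""
    return {
        "Ho": HO, "He": HE, "PD": PD, "PE": PE, "PIC": PIC,
        "PE1": PE1, "PE2": PE2, "PID": PID,
        "FIT": FIT, "FST": FST, "FIS": FIS,
    }


def autosomal_mask() -> np.ndarray:
    return np.array([name not in X_LINKED_LOCI for name in LOCI])
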