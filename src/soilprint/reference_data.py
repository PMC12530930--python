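"""Reference values from the Guizhou tobacco-soil origin study system.

These constants describe the published study design this package emulates:
three geographic origin classes (honey-sweet regions MT I and MT II, and
the fresh-sweet region QT, six soils each), thirty common UPLC peaks of
which seventeen were selected as characteristic, the fitted per-region
Fisher classification functions over those seventeen peak areas, the
validation confusion matrices, and the region-wise soil physicochemical
summaries (mean, SD; n = 6 per region).

They serve two roles: the physicochemical summaries parameterize the
synthetic-soil generator, and the classification functions / confusion
matrices are fixed numeric inputs for arithmetic checks (evaluating a
printed discriminant function, recomputing an accuracy from printed
confusion rows).
"""

from __future__ import annotations

import numpy as np

GROUPS = ("MT I", "MT II", "QT")

#: 1-based ids of the 30 common peaks selected as characteristic (VIP > 1.0
#: and ANOVA p < 0.05 in the reference study).
CHARACTERISTIC_PEAKS = (3, 4, 6, 9, 10, 13, 14, 16, 18, 19, 21, 22, 23, 25, 28, 29, 30)

#: Feature symbols in the order the discriminant functions are written.
FISHER_FEATURES = tuple(f"X{i}" for i in CHARACTERISTIC_PEAKS)

#: Per-class Fisher linear classification functions: (coefficients over
#: FISHER_FEATURES, intercept).  Assignment rule: argmax_k b_k·x + c_k.
FISHER_FUNCTIONS: dict[str, tuple[np.ndarray, float]] = {
    "MT I": (
        np.array([43.811, -11.177, -46.433, -20.953, 18.292, -17.462, -50.305,
                  6.327, 3.618, -40.839, 27.402, -11.695, -10.305, -59.721,
                  -32.981, 32.284, -6.127]),
        -88.429,
    ),
    "MT II": (
        np.array([-344.321, -185.526, 92.928, 204.429, 149.402, 171.361,
                  292.261, -150.172, 10.565, 270.771, -132.852, 54.1,
                  -52.712, 134.148, 478.65, -135.442, -138.132]),
        -787.894,
    ),
    "QT": (
        np.array([238.804, 173.393, -19.953, -148.286, -151.577, -124.429,
                  -185.832, 120.585, -13.708, -179.583, 78.642, -31.335,
                  58.43, -38.2, -367.867, 74.586, 110.522]),
        -342.565,
    ),
}

#: Validation confusion matrices (rows = true class in GROUPS order,
#: columns = predicted class).
CONFUSION_TRAINING = np.array([[6, 0, 0], [0, 6, 0], [0, 0, 6]])
CONFUSION_CROSS_VALIDATION = np.array([[9, 0, 0], [0, 6, 0], [1, 0, 6]])
CONFUSION_EXTERNAL = {"MT I": (3, 0, 0), "QT": (0, 0, 1)}

#: Soil physicochemical summaries per region: variable -> (mean, SD).
#: Units: TN, TP, TK, OM in g/kg; AHN, AP, AK in mg/kg; pH unitless.
SOIL_VARIABLES = ("TN", "TP", "TK", "AHN", "AP", "AK", "OM", "pH")

SOIL_SUMMARIES: dict[str, dict[str, tuple[float, float]]] = {
    "MT I": {
        "TN": (1.87, 0.32), "TP": (0.83, 0.26), "TK": (18.63, 4.75),
        "AHN": (141.02, 24.48), "AP": (37.10, 21.33), "AK": (307.00, 59.25),
        "OM": (39.38, 10.48), "pH": (6.69, 0.56),
    },
    "MT II": {
        "TN": (1.55, 0.30), "TP": (0.90, 0.30), "TK": (19.12, 7.47),
        "AHN": (109.92, 17.79), "AP": (33.77, 18.28), "AK": (462.00, 249.08),
        "OM": (31.47, 7.51), "pH": (6.11, 0.76),
    },
    "QT": {
        "TN": (1.95, 0.29), "TP": (1.12, 0.35), "TK": (19.45, 9.33),
        "AHN": (120.92, 25.50), "AP": (30.68, 13.22), "AK": (709.33, 264.30),
        "OM": (43.22, 10.00), "pH": (7.56, 0.36),
    },
}

SOIL_N_PER_GROUP = 6

#: Reported QC precision envelope for the common peaks (RSD%, worst peak):
#: retention time and area, intraday and interday.
RSD_ENVELOPE = {
    "intraday": {"rt": 1.71, "area": 2.21},
    "interday": {"rt": 2.14, "area": 2.75},
}
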