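"""Published reference statistics for human musculoskeletal networks.

Descriptive network parameters (N, K, D, C, L, H) and modularity
summaries (module count, Q, jackknife error of Q) reported for the
musculoskeletal networks of normal adult, newborn and 7-month fetal
humans and of anencephalic and cyclopic trisomy-18 fetuses — heads,
forelimbs and hindlimbs.  These printed values serve as scale anchors
for the synthetic generators and as ground truth for consistency checks
(e.g. D must equal 2K/(N(N-1)) row by row); the underlying contact
matrices are not bundled.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["musculoskeletal_parameters", "musculoskeletal_modularity"]

_PARAMETER_ROWS = [
    # name, N, K, D, C, L, H
    ("Anencephaly 1 head", 58, 102, 0.061706, 0.355195, 3.804545, 0.850846),
    ("Anencephaly 2 head", 72, 172, 0.067293, 0.472950, 3.088811, 0.773803),
    ("T18 Cyclopic head", 94, 219, 0.050103, 0.477792, 2.641378, 1.228446),
    ("Normal 7-month head & neck", 120, 269, 0.037675, 0.466439, 3.099221, 1.088102),
    ("Normal newborn head", 120, 267, 0.037395, 0.443457, 3.100420, 1.098521),
    ("Normal adult head", 117, 259, 0.038167, 0.467010, 2.947963, 1.197874),
    ("Anencephaly 1 left forelimb", 92, 220, 0.052556, 0.381752, 3.315576, 0.686042),
    ("Anencephaly 1 right forelimb", 64, 138, 0.068452, 0.447620, 2.991817, 0.713071),
    ("T18 Cyclopic left forelimb", 90, 226, 0.056429, 0.384506, 3.201998, 0.694247),
    ("T18 Cyclopic right forelimb", 87, 212, 0.056669, 0.384841, 3.167068, 0.740351),
    ("Normal 7-month left forelimb", 92, 230, 0.054945, 0.405294, 3.173913, 0.751263),
    ("Normal 7-month right forelimb", 92, 231, 0.055184, 0.409056, 3.173674, 0.745664),
    ("Normal newborn forelimb", 92, 222, 0.053034, 0.371285, 3.190874, 0.779310),
    ("Normal adult forelimb", 93, 234, 0.054698, 0.396012, 3.187237, 0.743795),
    ("Anencephaly 1 left hindlimb", 93, 231, 0.053997195, 0.371448002, 3.351799906, 0.695074276),
    ("Anencephaly 1 right hindlimb", 90, 214, 0.053433208, 0.407361758, 3.429213483, 0.709996033),
    ("T18 Cyclopic left hindlimb", 92, 225, 0.053751, 0.378190, 3.255375, 0.765235),
    ("T18 Cyclopic right hindlimb", 91, 223, 0.054457, 0.381634, 3.263736, 0.746928),
    ("Normal 7-month left hindlimb", 92, 228, 0.054467, 0.389727, 3.257525, 0.750685),
    ("Normal 7-month right hindlimb", 92, 226, 0.053989, 0.385997, 3.258003, 0.761966),
    ("Normal newborn hindlimb", 92, 225, 0.053751, 0.381601, 3.258958, 0.767632),
    ("Normal adult hindlimb", 90, 220, 0.054931, 0.387431, 3.158052, 0.836054),
]

_MODULARITY_ROWS = [
    # name, n_modules, Q, Q_error
    ("Anencephaly 1 head", 10, 0.455690, 0.049859313),
    ("Anencephaly 2 head", 9, 0.482998, 0.036962801),
    ("T18 Cyclopic head", 19, 0.382947, 0.036572340),
    ("Normal 7-month head & neck", 7, 0.508775, 0.028077696),
    ("Normal newborn head", 9, 0.506263, 0.029119493),
    ("Normal adult head", 9, 0.463522, 0.031465810),
    ("Anencephaly 1 left forelimb", 7, 0.561591, 0.028813418),
    ("Anencephaly 1 right forelimb", 5, 0.560098, 0.034470211),
    ("T18 Cyclopic left forelimb", 8, 0.541879, 0.031696871),
    ("T18 Cyclopic right forelimb", 9, 0.531595, 0.032473200),
    ("Normal 7-month left forelimb", 8, 0.546560, 0.030912646),
    ("Normal 7-month right forelimb", 8, 0.546532, 0.030937066),
    ("Normal newborn forelimb", 9, 0.553608, 0.031548720),
    ("Normal adult forelimb", 9, 0.554889, 0.030755834),
    ("Anencephaly 1 left hindlimb", 4, 0.562461376, 0.024347756),
    ("Anencephaly 1 right hindlimb", 10, 0.531083524, 0.032337194),
    ("T18 Cyclopic left hindlimb", 7, 0.545788, 0.027457470),
    ("T18 Cyclopic right hindlimb", 7, 0.548583, 0.027516686),
    ("Normal 7-month left hindlimb", 7, 0.539820, 0.028671697),
    ("Normal 7-month right hindlimb", 9, 0.535447, 0.030326795),
    ("Normal newborn hindlimb", 8, 0.541768, 0.029096490),
    ("Normal adult hindlimb", 8, 0.535186, 0.028776155),
]


def musculoskeletal_parameters() -> pd.DataFrame:
    """Published N, K, D, C, L, H per network (22 rows)."""
    return pd.DataFrame(
        _PARAMETER_ROWS, columns=["name", "N", "K", "D", "C", "L", "H"]
    )


def musculoskeletal_modularity() -> pd.DataFrame:
    """Published module count, modularity Q and jackknife error of Q per
    network (22 rows)."""
    return pd.DataFrame(
        _MODULARITY_ROWS, columns=["name", "n_modules", "Q", "Q_error"]
    )
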