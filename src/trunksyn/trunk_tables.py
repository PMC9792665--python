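"""Reduced-set trunk MTU parameters from the published lumbar-spine model.

Twenty-nine musculotendon units (MTUs) per side spanning the lumbosacral
joint, grouped into six anatomical muscles: rectus abdominis (RA), erector
spinae (ES), quadratus lumborum (QL), multifidus (MF), external oblique (EO)
and internal oblique (IO).  Columns: anatomical cross-sectional area (ACSA,
cm^2; generic and subject-personalized), peak isometric force (N,
personalized), optimal fiber length (cm; generic and personalized) and tendon
slack length (cm; generic and personalized).  Peak isometric force follows
from the personalized ACSA at a maximum muscle stress of 100 N/cm^2.
"""

from __future__ import annotations

import pandas as pd

# name, group, acsa_generic, acsa_pers, fmo_pers, lmo_generic, lmo_pers,
# lts_generic, lts_pers
_REDUCED_SET = [
    ("rect_abd", "RA", 6.62, 7.50, 750, 34.11, 34.99, 9.28, 9.33),
    ("IL_L2", "ES", 2.95, 3.94, 394, 4.06, 3.69, 9.20, 8.22),
    ("IL_L4", "ES", 6.68, 8.92, 892, 2.01, 1.74, 4.55, 3.35),
    ("IL_R7", "ES", 2.73, 2.57, 257, 17.89, 17.16, 18.80, 18.01),
    ("IL_R10", "ES", 3.34, 3.16, 316, 15.58, 14.52, 9.17, 8.57),
    ("IL_R11", "ES", 2.93, 2.77, 277, 13.66, 11.90, 6.84, 6.11),
    ("IL_R12", "ES", 1.25, 1.18, 118, 10.33, 8.77, 5.17, 4.48),
    ("LTpT_T8", "ES", 2.94, 2.23, 223, 14.27, 13.66, 22.54, 21.53),
    ("LTpT_T12", "ES", 3.76, 2.85, 285, 8.78, 7.83, 14.88, 13.04),
    ("LTpT_R8", "ES", 3.06, 2.39, 239, 12.21, 11.83, 24.91, 24.28),
    ("LTpT_R11", "ES", 3.45, 2.69, 269, 11.55, 10.03, 16.45, 14.04),
    ("LTpL_L2", "ES", 1.67, 2.55, 255, 7.62, 6.72, 8.38, 7.32),
    ("LTpL_L4", "ES", 2.34, 3.57, 357, 4.70, 3.89, 5.06, 4.14),
    ("LTpL_L5", "ES", 2.44, 3.71, 371, 2.54, 4.06, 0.05, 0.10),
    ("QL_post_I1_L3", "QL", 0.76, 1.00, 100, 3.74, 3.85, 4.45, 3.23),
    ("QL_post_I2_L4", "QL", 2.51, 3.87, 387, 2.38, 2.58, 2.84, 2.10),
    ("QL_post_I3_L2", "QL", 2.30, 1.81, 181, 4.86, 5.22, 5.78, 4.37),
    ("QL_ant_I2_T12", "QL", 0.73, 0.57, 57, 5.81, 10.08, 11.18, 5.33),
    ("QL_ant_I3_R12_I2", "QL", 2.14, 1.68, 168, 5.07, 8.57, 9.76, 4.46),
    ("MF_m1t_3", "MF", 1.59, 1.47, 147, 12.00, 9.85, 3.60, 3.15),
    ("MF_m2t_3", "MF", 4.19, 3.52, 352, 10.69, 8.60, 3.25, 2.82),
    ("MF_m3s", "MF", 3.57, 3.10, 310, 6.39, 4.52, 2.66, 1.95),
    ("MF_m4t_3", "MF", 3.97, 3.62, 362, 9.40, 7.34, 3.81, 3.19),
    ("MF_m5_laminar", "MF", 1.95, 1.95, 195, 3.94, 2.53, 1.50, 0.99),
    ("EO10", "EO", 2.09, 2.30, 230, 10.46, 10.47, 1.16, 1.06),
    ("EO12", "EO", 2.26, 2.49, 249, 9.26, 8.72, 1.03, 0.88),
    ("IO2", "IO", 5.90, 7.82, 782, 11.63, 11.92, 1.29, 1.28),
    ("IO4", "IO", 3.29, 3.34, 334, 11.15, 11.35, 1.24, 1.22),
    ("IO5", "IO", 2.89, 2.93, 293, 8.01, 8.19, 0.89, 0.88),
]

TRUNK_GROUPS = ("RA", "ES", "QL", "MF", "EO", "IO")


def reduced_trunk_set() -> pd.DataFrame:
    """The 29 reduced-set trunk MTUs for one side, lengths in cm."""
    return pd.DataFrame(
        _REDUCED_SET,
        columns=["name", "group", "acsa_generic", "acsa_personalized",
                 "fmo_personalized", "lmo_generic", "lmo_personalized",
                 "lts_generic", "lts_personalized"],
    )
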