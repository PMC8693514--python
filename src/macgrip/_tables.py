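"""Published anatomical parameters of the Japanese macaque hand.

Inertial parameters (mass and principal moments of inertia per bone segment)
and muscle parameters (PCSA per muscle-tendon path) measured on one adult
male Macaca fuscata cadaver. Maximum isometric force is not stored: it is
always derived as PCSA x sigma_max (23 N/cm^2 by default).
"""

from __future__ import annotations

#: Maximum muscle stress, N/cm^2 (specific tension of skeletal muscle).
SIGMA_MAX = 23.0

#: Segment name -> (mass g, Ix g*mm^2, Iy g*mm^2, Iz g*mm^2), principal axes.
SEGMENT_INERTIA = {
    "carpus": (16.50, 2.05e3, 1.41e3, 2.36e3),
    "1MC": (4.70, 2.55e2, 3.73e2, 1.96e2),
    "2MC": (6.68, 6.77e2, 8.44e2, 2.78e2),
    "3MC": (7.42, 9.13e2, 1.10e3, 3.09e2),
    "4MC": (7.10, 8.05e2, 9.82e2, 2.96e2),
    "5MC": (6.16, 5.38e2, 6.92e2, 2.57e2),
    "1PP": (1.31, 4.90e1, 3.87e1, 2.15e1),
    "1DP": (0.43, 5.22e0, 3.41e0, 4.13e0),
    "2PP": (2.00, 8.18e1, 9.67e1, 3.90e1),
    "2MP": (0.60, 9.92e0, 9.18e0, 4.89e0),
    "2DP": (0.43, 5.40e0, 4.50e0, 3.05e0),
    "3PP": (3.79, 2.37e2, 2.86e2, 1.16e2),
    "3MP": (0.85, 2.04e1, 2.17e1, 7.80e0),
    "3DP": (0.68, 1.09e1, 1.20e1, 6.09e0),
    "4PP": (3.60, 2.13e2, 2.55e2, 9.96e1),
    "4MP": (0.95, 2.55e1, 2.37e1, 9.37e0),
    "4DP": (0.62, 1.01e1, 1.04e1, 4.85e0),
    "5PP": (2.62, 9.63e1, 1.05e2, 7.31e1),
    "5MP": (0.54, 9.11e0, 8.10e0, 4.15e0),
    "5DP": (0.41, 5.02e0, 4.38e0, 2.75e0),
}

#: abbreviation -> (muscle group, PCSA cm^2, printed max force N, numbered)
#: `numbered` marks the 23 numbered muscle entries of the published table;
#: CD2 is appended unnumbered with zero PCSA (absent in this species), as is
#: FDP1 within the FDP group.
MUSCLE_TABLE = {
    "FDS2": ("FDS", 0.45, 10.4, True),
    "FDS3": ("FDS", 0.85, 19.6, True),
    "FDS4": ("FDS", 0.95, 21.9, True),
    "FDS5": ("FDS", 1.23, 28.3, True),
    "FDP1": ("FDP", 0.00, 0.0, True),
    "FDP2": ("FDP", 1.81, 41.6, True),
    "FDP3": ("FDP", 1.39, 32.0, True),
    "FDP4": ("FDP", 1.29, 29.7, True),
    "FDP5": ("FDP", 1.63, 37.5, True),
    "EDC2": ("EDC", 0.29, 6.7, True),
    "EDC3": ("EDC", 0.08, 1.8, True),
    "EDC4": ("EDC", 0.12, 2.8, True),
    "EDC5": ("EDC", 0.32, 7.4, True),
    "ED2P": ("ED23P", 0.23, 5.3, True),
    "ED3P": ("ED23P", 0.08, 1.8, True),
    "ED4P": ("ED45P", 0.22, 5.1, True),
    "ED5P": ("ED45P", 0.19, 4.4, True),
    "ABPL": ("ABPL", 2.67, 61.4, True),
    "EPL": ("EPL", 0.19, 4.4, True),
    "ABPB": ("ABPB", 0.71, 16.3, True),
    "FPB": ("FPB", 0.32, 7.4, True),
    "OP": ("OP", 0.34, 7.8, True),
    "ADPo": ("ADP", 0.17, 3.9, True),
    "ADPt": ("ADP", 0.43, 9.9, True),
    "ABDM": ("ABDM", 1.17, 26.9, True),
    "FDMB": ("FDMB", 0.33, 7.6, True),
    "ODM": ("ODM", 0.63, 14.5, True),
    "1DIOr": ("1DIO", 0.52, 12.0, True),
    "1DIOu": ("1DIO", 0.52, 12.0, True),
    "2DIOr": ("2DIO", 0.40, 9.1, True),
    "2DIOu": ("2DIO", 0.40, 9.1, True),
    "3DIOr": ("3DIO", 0.30, 6.9, True),
    "3DIOu": ("3DIO", 0.30, 6.9, True),
    "4DIOr": ("4DIO", 0.23, 5.3, True),
    "4DIOu": ("4DIO", 0.23, 5.3, True),
    "1PIO": ("1PIO", 0.56, 12.9, True),
    "2PIO": ("2PIO", 0.18, 4.1, True),
    "3PIO": ("3PIO", 0.24, 5.5, True),
    "CD4": ("CD4", 0.21, 4.8, True),
    "CD5": ("CD5", 0.22, 5.1, True),
    "CD2": ("CD2", 0.00, 0.0, False),
}

#: Rows where the printed max force is not PCSA*23 rounded to one decimal
#: (consistent with the published PCSA itself being rounded): 0.40*23 = 9.20
#: vs printed 9.1.
PRINTED_FORCE_DISCREPANCIES = ("2DIOr", "2DIOu")
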