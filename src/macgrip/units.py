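"""Single-sourced unit converters.

Model files and anatomical tables use mm, g, g*mm^2, cm^2 and N; all internal
dynamics is SI (m, kg, kg*m^2, N, N*m). Every conversion in the package goes
through these constants so units cannot drift.
"""

MM_TO_M = 1e-3
M_TO_MM = 1e3
G_TO_KG = 1e-3
GMM2_TO_KGM2 = 1e-9  # g*mm^2 -> kg*m^2


def mm_to_m(x):
    return x * MM_TO_M


def m_to_mm(x):
    return x * M_TO_MM


def g_to_kg(x):
    return x * G_TO_KG


def gmm2_to_kgm2(x):
    return x * GMM2_TO_KGM2
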