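"""Unit conventions and conversions.

All internal quantities are SI (Pa, m, s, m^3). Millimetres of mercury,
millilitres and mm^2 appear only at I/O boundaries (tables, CLI output,
waveform CSV files).
"""

MMHG_TO_PA: float = 133.322
"""1 mmHg in pascal; the single conversion constant used package-wide."""

ML_TO_M3: float = 1e-6
MM2_TO_M2: float = 1e-6


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_TO_PA


def ml_s_to_m3_s(q: float) -> float:
    return q * ML_TO_M3


def m3_s_to_ml_s(q: float) -> float:
    return q / ML_TO_M3
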