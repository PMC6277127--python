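"""Unit conventions and conversions.

Internally the flow solver works in SI (m, Pa, m^3/s, Pa.s); geometry in
the graph containers and file formats stays in the field-conventional um,
and reports use mmHg, nL/s and ml/100g/min.
"""

#: 1 mmHg in Pa (120 mmHg = 15,999 Pa to the printed rounding)
PA_PER_MMHG = 133.322

#: metres per micrometre
M_PER_UM = 1e-6


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * PA_PER_MMHG


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / PA_PER_MMHG


def m3s_to_nls(q_m3s):
    """Volumetric flow m^3/s -> nL/s."""
    return q_m3s * 1e12


def perfusion_si_to_clinical(perf_m3_kg_s: float) -> float:
    """m^3 blood / kg tissue / s  ->  ml / 100 g / min."""
    # 1 m^3/kg/s = 1e6 ml / 1000 g / s = 1e5 ml/100g/s = 6e6 ml/100g/min
    return perf_m3_kg_s * 6.0e6


def perfusion_clinical_to_si(perf_ml_100g_min: float) -> float:
    return perf_ml_100g_min / 6.0e6
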