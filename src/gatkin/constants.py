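"""Physical constants and unit helpers.

Units are fixed package-wide: potentials in mV, time in s (fit windows and
protocol timing), currents in nA, charge in nC, temperature in K.
"""

FARADAY_C_PER_MOL = 96485.33212
GAS_R_J_PER_MOL_K = 8.31446262

#: Default absolute temperature: 18 degC, the oocyte incubation temperature.
DEFAULT_TEMPERATURE_K = 291.15


def thermal_voltage_mV(temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """R*T/F in millivolts (~25.09 mV at 18 degC)."""
    return 1000.0 * GAS_R_J_PER_MOL_K * temperature_K / FARADAY_C_PER_MOL


def boltzmann_sigma_mV(z_eff: float, temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Boltzmann slope factor sigma = R*T/(z_eff*F) in mV for effective valence z_eff."""
    if z_eff <= 0:
        raise ValueError(f"z_eff must be > 0, got {z_eff}")
    return thermal_voltage_mV(temperature_K) / z_eff
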