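"""Physical constants and unit conventions.

All energies are in kcal/mol, distances in angstroms, concentrations in nM
unless a function documents otherwise.
"""

#: Boltzmann constant in kcal/mol/K.
K_B = 0.0019872041

#: Default temperature (K). Assays were run at room temperature; simulations
#: do not state a thermostat setpoint, so a single configurable default is
#: used throughout.
DEFAULT_TEMPERATURE = 298.15


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return K_B * temperature
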