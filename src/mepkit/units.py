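"""Unit conventions.

Two modes are supported throughout the package:

* ``"physical"`` — energies in kcal/mol, lengths in Angstrom, temperatures in
  kelvin with the gas constant ``KB_KCAL_MOL_K``; default T = 300 K.
* ``"reduced"`` — kT = 1, lengths and times dimensionless.

Every dataset records its mode so downstream estimators can convert.
"""

KB_KCAL_MOL_K = 0.0019872041  # kcal/(mol K)

DEFAULT_TEMPERATURE_K = 300.0

MODES = ("physical", "reduced")


def kt(temperature: float, mode: str = "reduced") -> float:
    """Thermal energy for the given mode.

    In reduced mode ``temperature`` is interpreted directly as kT.
    """
    if mode not in MODES:
        raise ValueError(f"unknown unit mode {mode!r}; expected one of {MODES}")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if mode == "physical":
        return KB_KCAL_MOL_K * temperature
    return float(temperature)
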