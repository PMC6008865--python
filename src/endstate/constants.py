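"""Physical constants and model parameters shared across the pipeline.

Every energy/entropy routine reads these from a single :class:`Constants`
instance so that no numeric literal is buried in code.  The defaults are
the de facto standards of the GB/SA implicit-solvent literature:
``epsilon_out = 78.5`` (water), ``epsilon_in = 1`` (solute interior),
probe radius 1.4 Å, Coulomb constant 332.0636 kcal·Å·mol⁻¹·e⁻² and a
surface-tension coefficient of 5 cal·Å⁻²·mol⁻¹ for the apolar term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: gas constant, cal·mol⁻¹·K⁻¹ (1 e.u. = 1 cal·mol⁻¹·K⁻¹)
R_CAL = 1.987
#: Coulomb constant, kcal·Å·mol⁻¹·e⁻²
COULOMB_KCAL = 332.0636
#: standard-state volume per molecule at 1 M, Å³
V_STANDARD_A3 = 1660.6
#: Haar volume of SO(3) (Euler-angle normalization), dimensionless
SO3_VOLUME = 8.0 * math.pi ** 2


@dataclass(frozen=True)
class Constants:
    """Bundle of thermodynamic and solvation constants at temperature ``T``.

    Attributes
    ----------
    T : float
        Absolute temperature in kelvin (default 300 K).
    gas_constant : float
        R in cal·mol⁻¹·K⁻¹.
    coulomb : float
        Electrostatic conversion constant, kcal·Å·mol⁻¹·e⁻².
    eps_in, eps_out : float
        Interior / exterior dielectric constants of the GB model.
    probe_radius : float
        Solvent probe radius for accessible-surface calculations, Å.
    gamma : float
        Surface tension for the apolar solvation term, cal·Å⁻²·mol⁻¹.
    """

    T: float = 300.0
    gas_constant: float = R_CAL
    coulomb: float = COULOMB_KCAL
    eps_in: float = 1.0
    eps_out: float = 78.5
    probe_radius: float = 1.4
    gamma: float = 5.0
    v_standard: float = field(default=V_STANDARD_A3)

    @property
    def kT(self) -> float:
        """k_B·T expressed as RT in kcal/mol."""
        return self.gas_constant * self.T / 1000.0

    @property
    def beta(self) -> float:
        """1/(RT), mol/kcal."""
        return 1.0 / self.kT


DEFAULT_CONSTANTS = Constants()
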