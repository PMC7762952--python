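"""Physical constants and experimental reference conditions.

All free energies in this package are in kcal/mol, rate constants in
µM⁻¹s⁻¹ (association) and s⁻¹ (dissociation), concentrations in µM,
and time in seconds. Stopped-flow experiments on the NCBD/CID system
are performed at 4 °C, so the default temperature is 277.15 K.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Gas constant in kcal mol⁻¹ K⁻¹.
R_KCAL: float = 1.987e-3


@dataclass(frozen=True)
class Constants:
    """Thermodynamic constants used in ΔΔG and ϕ-value calculations.

    Parameters
    ----------
    R : float
        Gas constant, kcal mol⁻¹ K⁻¹.
    T : float
        Absolute temperature in K. Default 277.15 K (4 °C), the
        temperature of the stopped-flow measurements.
    """

    R: float = R_KCAL
    T: float = 277.15

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")
        if self.R <= 0:
            raise ValueError(f"gas constant must be positive, got {self.R}")

    @property
    def RT(self) -> float:
        """R·T in kcal/mol (≈0.5507 at the default 277.15 K)."""
        return self.R * self.T


DEFAULT_CONSTANTS = Constants()
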