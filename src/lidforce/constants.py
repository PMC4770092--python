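"""Physical constants and unit conversions.

All mechanical energies in this package are expressed in units of the
thermal energy kBT (pN·nm internally), lengths in nm for traces and
force–extension work and in Å for free-energy landscape coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant in pN·nm/K.
BOLTZMANN_PN_NM_PER_K = 0.0138065

#: Molar gas constant in kcal/(mol·K), used for kcal/mol <-> kBT conversion.
GAS_CONSTANT_KCAL_PER_MOL_K = 0.0019872


@dataclass(frozen=True)
class Constants:
    """Thermodynamic constants at a fixed absolute temperature.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Defaults to 298 K (room
        temperature, the condition of the trap experiments).
    """

    temperature: float = 298.0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def kBT(self) -> float:
        """Thermal energy kB·T in pN·nm."""
        return BOLTZMANN_PN_NM_PER_K * self.temperature

    def kcal_per_mol_to_kBT(self, energy_kcal_per_mol: float) -> float:
        """Convert an energy from kcal/mol to units of kBT."""
        return energy_kcal_per_mol / (GAS_CONSTANT_KCAL_PER_MOL_K * self.temperature)

    def kBT_to_kcal_per_mol(self, energy_kBT: float) -> float:
        return energy_kBT * GAS_CONSTANT_KCAL_PER_MOL_K * self.temperature

    def kBT_to_kJ_per_mol(self, energy_kBT: float) -> float:
        return self.kBT_to_kcal_per_mol(energy_kBT) * 4.184

    def pN_angstrom_to_kBT(self, force_pN: float, distance_A: float) -> float:
        """Mechanical work force(pN) × distance(Å) in units of kBT."""
        return force_pN * distance_A * 0.1 / self.kBT

    def pN_nm_to_kBT(self, work_pN_nm: float) -> float:
        return work_pN_nm / self.kBT


DEFAULT_CONSTANTS = Constants()
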