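"""Shared physical constants and unit conventions.

Conventions used throughout the package:

* rate constants: ``k_on`` in uM^-1 s^-1, ``k_off`` in s^-1
* dissociation constants: nM  (``K_d = k_off / k_on * 1e3``)
* energies: kcal mol^-1
* distances / coordinates: nm (PDB Angstrom converted on read/write)
"""

from dataclasses import dataclass

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL: float = 1.9872e-3

#: Default experimental temperature (stopped-flow experiments), K.
T_DEFAULT: float = 277.0

#: Conversion factor: (k_off [s^-1] / k_on [uM^-1 s^-1]) [uM] -> nM.
UM_TO_NM: float = 1.0e3

#: Angstrom -> nm.
ANG_TO_NM: float = 0.1


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable bundle of the constants entering free-energy formulas."""

    R: float = R_KCAL
    T_default: float = T_DEFAULT

    def RT(self, T: float | None = None) -> float:
        """R*T in kcal mol^-1 at temperature ``T`` (default 277 K)."""
        return self.R * (self.T_default if T is None else T)


def kd_nM(k_on: float, k_off: float) -> float:
    """Dissociation constant in nM from k_on (uM^-1 s^-1) and k_off (s^-1)."""
    return k_off / k_on * UM_TO_NM
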