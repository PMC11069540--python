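"""Internal unit system.

All analysis runs in reduced units: energies in units of the thermal energy
k_B*T, time in picoseconds, angles in radians (displayed in degrees) and
distances in nanometres.  Friction therefore carries units of
k_B*T * ps / unit**2 and the effective mass k_B*T * ps**2 / unit**2, where
``unit`` is the coordinate unit (rad or nm).  Conversion to physical energy
units is needed only at the I/O boundary and uses k_B*T at 300 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Thermal energy at 300 K in kJ/mol, used only for converting energies at I/O.
KBT_300K_KJ_PER_MOL = 2.494

DEG_PER_RAD = 180.0 / math.pi
RAD_PER_DEG = math.pi / 180.0


@dataclass(frozen=True)
class UnitSystem:
    """Reduced unit system with the thermal energy as the energy scale.

    Parameters
    ----------
    kBT : float
        Thermal energy in internal units (1.0 by convention).
    kBT_physical : float
        Thermal energy in kJ/mol for conversions to laboratory units.
    """

    kBT: float = 1.0
    kBT_physical: float = KBT_300K_KJ_PER_MOL

    # --- energies -----------------------------------------------------
    def energy_to_physical(self, e_internal: float) -> float:
        """k_BT units -> kJ/mol."""
        return e_internal / self.kBT * self.kBT_physical

    def energy_from_physical(self, e_kj_mol: float) -> float:
        """kJ/mol -> k_BT units."""
        return e_kj_mol / self.kBT_physical * self.kBT

    # --- angles -------------------------------------------------------
    @staticmethod
    def rad_to_deg(x):
        return x * DEG_PER_RAD

    @staticmethod
    def deg_to_rad(x):
        return x * RAD_PER_DEG

    # --- friction -----------------------------------------------------
    def friction_rad_to_deg(self, gamma_rad: float) -> float:
        """Friction per rad**2 -> friction per deg**2 (divide by (180/pi)**2)."""
        return gamma_rad * RAD_PER_DEG**2

    def friction_deg_to_rad(self, gamma_deg: float) -> float:
        return gamma_deg * DEG_PER_RAD**2


def wrap_angle(q, period: float = 2.0 * math.pi):
    """Wrap values into the principal interval [-period/2, period/2)."""
    import numpy as np

    q = np.asarray(q, dtype=float)
    return (q + period / 2.0) % period - period / 2.0


def minimum_image(dq, period: float):
    """Minimum-image difference for a periodic coordinate."""
    import numpy as np

    dq = np.asarray(dq, dtype=float)
    return dq - period * np.round(dq / period)
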