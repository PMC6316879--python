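"""Atomic reference properties used for the image atom-type channels.

Values are standard reference data: dipole polarizability (atomic units,
Schwerdtfeger & Nagle 2018 recommended values), electron affinity (eV),
Pauling electronegativity, van der Waals radius (pm, Alvarez/Bondi),
atomic volume (cm^3/mol, Batsanov) and the conceptual-DFT softness and
hardness. Hardness is (IE - EA) / 2 and softness 1 / (2 * hardness), both
from the first ionization energy (eV) and electron affinity (eV).
"""

from __future__ import annotations

from .errors import MissingPropertyError

DEFAULT_PROPERTIES = (
    "dipole_polarizability",
    "electron_affinity",
    "electronegativity",
    "vdw_radius",
    "atomic_volume",
    "softness",
    "hardness",
)

_IONIZATION_ENERGY_EV = {
    "H": 13.598, "C": 11.260, "N": 14.534, "O": 13.618, "F": 17.423,
    "P": 10.487, "S": 10.360, "Cl": 12.968, "Br": 11.814, "I": 10.451,
}

# element -> (dipole_polarizability, electron_affinity, electronegativity,
#             vdw_radius, atomic_volume)
_BASE = {
    "H": (4.507, 0.754, 2.20, 110.0, 14.1),
    "C": (11.30, 1.262, 2.55, 170.0, 5.3),
    "N": (7.40, -0.07, 3.04, 155.0, 17.3),
    "O": (5.30, 1.461, 3.44, 152.0, 14.0),
    "F": (3.74, 3.401, 3.98, 147.0, 17.1),
    "P": (25.00, 0.746, 2.19, 180.0, 17.0),
    "S": (19.40, 2.077, 2.58, 180.0, 15.5),
    "Cl": (14.60, 3.613, 3.16, 175.0, 18.7),
    "Br": (21.00, 3.364, 2.96, 185.0, 23.5),
    "I": (32.90, 3.059, 2.66, 198.0, 25.7),
}


def atomic_properties(element: str) -> dict[str, float]:
    """Return the seven reference properties for ``element``.

    Raises
    ------
    MissingPropertyError
        If the element is not covered by the built-in table.
    """
    if element not in _BASE or element not in _IONIZATION_ENERGY_EV:
        raise MissingPropertyError(
            f"no atomic property data for element {element!r}"
        )
    pol, ea, en, vdw, vol = _BASE[element]
    ie = _IONIZATION_ENERGY_EV[element]
    hardness = (ie - ea) / 2.0
    softness = 1.0 / (2.0 * hardness)
    return {
        "dipole_polarizability": pol,
        "electron_affinity": ea,
        "electronegativity": en,
        "vdw_radius": vdw,
        "atomic_volume": vol,
        "softness": softness,
        "hardness": hardness,
    }


def supported_elements() -> tuple[str, ...]:
    return tuple(_BASE)
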