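"""Complex refractive index constants for the phantom materials.

A hard X-ray beam sees a material through its complex refractive index
``n = 1 - delta - i*beta``: ``delta`` (the refractive decrement) drives the
phase shift and ``beta`` the absorption.  For soft tissue at hard X-ray
energies ``delta/beta`` is of order 10^3, which is the entire point of
propagation-based phase contrast: the phase term carries far more contrast
than absorption does.

The constants below are the package's documented stand-ins for the three
phantom materials, evaluated at the 18 keV reference energy:

* ``air`` — dry air at sea level (1.2 mg/cm^3). delta from the electron
  density (r_e * lambda^2 * n_e / 2pi with n_e ≈ 3.61e26 m^-3); beta from
  the NIST mass attenuation of air near 18 keV (~0.92 cm^2/g).
* ``soft_tissue`` — water-equivalent (1.0 g/cm^3, n_e ≈ 3.34e29 m^-3,
  linear attenuation ~1.0 cm^-1 at 18 keV).
* ``bone`` — cortical-bone-like (1.92 g/cm^3; electron density ~1.78x water;
  linear attenuation ~10 cm^-1 at 18 keV, photoelectric-dominated).

Scaling with energy uses the standard far-from-edge behaviour
delta ∝ E^-2 and beta ∝ E^-4, anchored at 18 keV.  These values are
swappable: replace ``_REFERENCE_TABLE`` to audit a different material set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

__all__ = ["MaterialTable", "build_material_table", "MATERIAL_NAMES"]

MATERIAL_NAMES = ("air", "soft_tissue", "bone")

_REFERENCE_ENERGY_KEV = 18.0

# (delta, beta) at 18 keV.  See module docstring for provenance.
_REFERENCE_TABLE: Dict[str, Tuple[float, float]] = {
    "air": (7.7e-10, 6.1e-13),
    "soft_tissue": (7.10e-7, 5.50e-10),
    "bone": (1.26e-6, 5.6e-9),
}

# Tunable monochromator range of the simulated beamline, keV.
ENERGY_RANGE_KEV = (8.0, 72.5)


@dataclass(frozen=True)
class MaterialTable:
    """delta/beta lookup for the phantom materials at one beam energy."""

    energy_keV: float
    entries: Dict[str, Tuple[float, float]]

    def delta(self, name: str) -> float:
        return self.entries[name][0]

    def beta(self, name: str) -> float:
        return self.entries[name][1]

    def __post_init__(self) -> None:
        for name in MATERIAL_NAMES:
            if name not in self.entries:
                raise ValueError(f"material table is missing {name!r}")
        d = {m: v[0] for m, v in self.entries.items()}
        b = {m: v[1] for m, v in self.entries.items()}
        if any(v < 0 for v in d.values()) or any(v < 0 for v in b.values()):
            raise ValueError("delta and beta must be non-negative")
        if not (d["air"] < d["soft_tissue"] < d["bone"]):
            raise ValueError("expected delta(air) < delta(soft_tissue) < delta(bone)")
        if not (b["air"] < b["soft_tissue"] < b["bone"]):
            raise ValueError("expected beta(air) < beta(soft_tissue) < beta(bone)")


def build_material_table(energy_keV: float) -> MaterialTable:
    """Return delta/beta for air, soft tissue and bone at ``energy_keV``.

    Values are the documented 18 keV reference constants rescaled by
    delta ∝ E^-2, beta ∝ E^-4.

    Raises
    ------
    ValueError
        If the energy lies outside the supported 8–72.5 keV range.
    """
    lo, hi = ENERGY_RANGE_KEV
    if not (lo <= energy_keV <= hi):
        raise ValueError(
            f"energy {energy_keV} keV outside the supported range "
            f"[{lo}, {hi}] keV"
        )
    s2 = (_REFERENCE_ENERGY_KEV / energy_keV) ** 2
    s4 = s2 * s2
    entries = {
        name: (delta * s2, beta * s4)
        for name, (delta, beta) in _REFERENCE_TABLE.items()
    }
    return MaterialTable(energy_keV=float(energy_keV), entries=entries)
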