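"""Osmotic-shock protocol arithmetic.

Small deterministic calculators for the bench-side numbers of an osmotic
shock experiment: ideal volume-weighted mixing of solutions and the
osmolarity contributed by a dissolved solute. Hypo-osmotic shocks are made
by diluting the medium with (ion-corrected) water; hyper-osmotic shocks by
adding a mannitol-supplemented medium-osmolarity solution. Osmolarities in
mOsm (mosmol/l), volumes in ml.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "Solution",
    "mix_osmolarity",
    "solute_osmolarity",
    "osmotic_shock_report",
]

MOLAR_MASS_MANNITOL_G_MOL = 182.17
MOLAR_MASS_CACL2_2H2O_G_MOL = 147.01
MOLAR_MASS_MGCL2_6H2O_G_MOL = 203.30

#: Default experiment constants: 340 mOsm medium, 0.5 ml in the dish,
#: 1.0 ml of 1.5x shock solution added, 96.9 g/l mannitol in the
#: hyper-osmotic diluent.
MEDIUM_OSMOLARITY_MOSM = 340.0
MEDIUM_VOLUME_ML = 0.5
SHOCK_VOLUME_ML = 1.0
MANNITOL_G_L = 96.9
CACL2_2H2O_MG_L = 264.0
MGCL2_6H2O_MG_L = 164.67


@dataclass(frozen=True)
class Solution:
    """A volume of liquid with a total osmolarity."""

    volume_ml: float
    osmolarity_mosm: float

    def __post_init__(self) -> None:
        if self.volume_ml < 0:
            raise ValueError("volume_ml must be >= 0")
        if self.osmolarity_mosm < 0:
            raise ValueError("osmolarity_mosm must be >= 0")


def mix_osmolarity(solutions: Iterable[Solution | tuple[float, float]]) -> float:
    """Osmolarity of an ideal mixture: the volume-weighted mean.

    Assumes ideal mixing (additive volumes, no activity corrections).
    Accepts :class:`Solution` objects or ``(volume_ml, osmolarity_mosm)``
    tuples.
    """
    parts = [s if isinstance(s, Solution) else Solution(*s) for s in solutions]
    total_volume = sum(s.volume_ml for s in parts)
    if total_volume <= 0:
        raise ValueError("total volume must be > 0")
    return sum(s.volume_ml * s.osmolarity_mosm for s in parts) / total_volume


def solute_osmolarity(
    concentration_g_l: float,
    molar_mass_g_mol: float,
    particles_per_formula: float = 1.0,
) -> float:
    """Osmolarity (mOsm) contributed by a dissolved solute.

    ``particles_per_formula`` is the van 't Hoff factor: 1 for a
    non-dissociating solute such as mannitol, ~2 for NaCl, ~3 for CaCl2
    (ideal full dissociation).
    """
    if molar_mass_g_mol <= 0:
        raise ValueError("molar_mass_g_mol must be > 0")
    if concentration_g_l < 0:
        raise ValueError("concentration_g_l must be >= 0")
    return concentration_g_l / molar_mass_g_mol * 1000.0 * particles_per_formula


def _ion_correction_mosm() -> float:
    # Ca/Mg salts added to the hypo-shock water to match medium ion levels.
    return solute_osmolarity(
        CACL2_2H2O_MG_L / 1000.0, MOLAR_MASS_CACL2_2H2O_G_MOL, 3.0
    ) + solute_osmolarity(MGCL2_6H2O_MG_L / 1000.0, MOLAR_MASS_MGCL2_6H2O_G_MOL, 3.0)


def osmotic_shock_report(
    medium_osmolarity_mosm: float = MEDIUM_OSMOLARITY_MOSM,
    medium_volume_ml: float = MEDIUM_VOLUME_ML,
    shock_volume_ml: float = SHOCK_VOLUME_ML,
    mannitol_g_l: float = MANNITOL_G_L,
    include_ion_correction: bool = False,
) -> dict[str, float]:
    """Final osmolarities after hypo- and hyper-osmotic shock mixing.

    Hypo: the dish medium is mixed with de-ionized water (optionally
    carrying the small Ca/Mg ion correction, ~5 mOsm after mixing, ignored
    by default). Hyper: the added solution is medium-osmolarity base
    supplemented with mannitol. Percentages are relative to the untouched
    medium.
    """
    water_osmolarity = _ion_correction_mosm() if include_ion_correction else 0.0
    hypo = mix_osmolarity(
        [
            (medium_volume_ml, medium_osmolarity_mosm),
            (shock_volume_ml, water_osmolarity),
        ]
    )
    mannitol = solute_osmolarity(mannitol_g_l, MOLAR_MASS_MANNITOL_G_MOL, 1.0)
    hyper = mix_osmolarity(
        [
            (medium_volume_ml, medium_osmolarity_mosm),
            (shock_volume_ml, medium_osmolarity_mosm + mannitol),
        ]
    )
    return {
        "baseline_mosm": medium_osmolarity_mosm,
        "hypo_mosm": hypo,
        "hyper_mosm": hyper,
        "mannitol_mosm": mannitol,
        "hypo_percent_of_baseline": 100.0 * hypo / medium_osmolarity_mosm,
        "hyper_percent_of_baseline": 100.0 * hyper / medium_osmolarity_mosm,
    }
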