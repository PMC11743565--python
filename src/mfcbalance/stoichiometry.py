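"""Compound-level electron and COD stoichiometry.

Every electron-balance quantity in this package rests on the electron
equivalent of a compound: the number of electrons ``N`` it releases on
complete mineralization to CO2, protons and electrons.  Concentrations in
mmol/L convert to electron-equivalents (e-mmol/L) by ``Se = Sm * N`` and to
chemical oxygen demand by a further factor of 8 mg O2 per e-mmol (one mole
of O2 accepts four moles of electrons; O2 is 32 g/mol, hence 8 g per mole
of electrons).

The default registry covers the compounds relevant to acetate- and
starch-fed anolytes.  ``N`` values follow from balancing the full oxidation
half-reaction of each compound; the half-reactions are listed next to each
registry entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import yaml

#: Faraday's constant, coulombs per mole of electrons.
FARADAY_C_PER_MOL = 96485.0

#: Molecular weight of O2, g/mol.
OXYGEN_MW_G_PER_MOL = 32.0

#: Electrons accepted per mole of O2.
ELECTRONS_PER_MOL_O2 = 4

#: mg of COD (as O2) per mmol of electrons: 32 g/mol / 4 e- = 8.
COD_MG_PER_ELECTRON_MMOL = OXYGEN_MW_G_PER_MOL / ELECTRONS_PER_MOL_O2


@dataclass(frozen=True)
class Species:
    """A compound with its electron-release stoichiometry.

    Parameters
    ----------
    name
        Canonical lower-case compound identifier.
    molecular_weight
        g/mol (for polymers, per monomer unit).
    n_electrons
        Electrons released per molecule on complete mineralization.
    is_dead_end
        True for acids electrogens cannot oxidize directly
        (propionate, butyrate, isobutyrate).
    """

    name: str
    molecular_weight: float
    n_electrons: int
    is_dead_end: bool = False

    def __post_init__(self) -> None:
        if self.n_electrons <= 0:
            raise ValueError(f"n_electrons must be positive for {self.name!r}")
        if self.molecular_weight <= 0:
            raise ValueError(f"molecular_weight must be positive for {self.name!r}")

    @property
    def cod_per_mmol(self) -> float:
        """mg O2 demand per mmol of compound (= N * 8)."""
        return self.n_electrons * COD_MG_PER_ELECTRON_MMOL

    @property
    def cod_per_mg(self) -> float:
        """mg COD per mg of compound."""
        return self.cod_per_mmol / self.molecular_weight

    def mg_per_l_to_mmol_per_l(self, mg_per_l: float) -> float:
        return mg_per_l / self.molecular_weight


# Oxidation half-reactions behind each N:
#   formate      HCOO-  + H2O  -> CO2 + 3H+  + 2e-             N = 2
#   acetate      CH3COO- + 2H2O -> 2CO2 + 7H+ + 8e-            N = 8
#   lactate      C3H5O3- + 3H2O -> 3CO2 + 11H+ + 12e-          N = 12
#   propionate   C2H5COO- + 4H2O -> 3CO2 + 13H+ + 14e-         N = 14
#   (iso)butyrate C3H7COO- + 6H2O -> 4CO2 + 19H+ + 20e-        N = 20
#   glucose      C6H12O6 + 6H2O -> 6CO2 + 24H+ + 24e-          N = 24
#   starch (per anhydroglucose unit, C6H10O5, 162 g/mol)
#                C6H10O5 + 7H2O -> 6CO2 + 24H+ + 24e-          N = 24
_DEFAULT_SPECIES = [
    Species("formate", 46.03, 2),
    Species("acetate", 60.05, 8),
    Species("lactate", 90.08, 12),
    Species("propionate", 74.08, 14, is_dead_end=True),
    Species("butyrate", 88.11, 20, is_dead_end=True),
    Species("isobutyrate", 88.11, 20, is_dead_end=True),
    Species("glucose", 180.16, 24),
    Species("starch", 162.14, 24),
]


class SpeciesTable:
    """Case-insensitive registry of :class:`Species`.

    Unknown names raise ``KeyError`` — a silent zero would corrupt an
    electron balance.  The registry round-trips through a plain YAML
    mapping so users can add compounds without code changes.
    """

    def __init__(self, species: Mapping[str, Species] | list[Species] | None = None):
        self._species: dict[str, Species] = {}
        if species is None:
            species = _DEFAULT_SPECIES
        if isinstance(species, Mapping):
            species = list(species.values())
        for sp in species:
            self.add(sp)

    def add(self, species: Species) -> None:
        key = species.name.strip().lower()
        if key in self._species:
            raise ValueError(f"duplicate species {key!r}")
        self._species[key] = species

    def __getitem__(self, name: str) -> Species:
        key = name.strip().lower()
        try:
            return self._species[key]
        except KeyError:
            known = ", ".join(sorted(self._species))
            raise KeyError(f"unknown species {name!r}; registered: {known}") from None

    def __contains__(self, name: str) -> bool:
        return name.strip().lower() in self._species

    def __iter__(self) -> Iterator[Species]:
        return iter(self._species.values())

    def __len__(self) -> int:
        return len(self._species)

    @property
    def names(self) -> list[str]:
        return list(self._species)

    def dead_end_names(self) -> list[str]:
        return [sp.name for sp in self if sp.is_dead_end]

    def with_dead_end_override(self, dead_end: Mapping[str, bool]) -> "SpeciesTable":
        """Return a copy with per-analysis dead-end reclassification."""
        out = []
        for sp in self:
            flag = dead_end.get(sp.name, sp.is_dead_end)
            out.append(Species(sp.name, sp.molecular_weight, sp.n_electrons, flag))
        return SpeciesTable(out)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            sp.name: {
                "molecular_weight": sp.molecular_weight,
                "n_electrons": sp.n_electrons,
                "is_dead_end": sp.is_dead_end,
            }
            for sp in self
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpeciesTable":
        data = yaml.safe_load(Path(path).read_text())
        species = [
            Species(
                name,
                float(entry["molecular_weight"]),
                int(entry["n_electrons"]),
                bool(entry.get("is_dead_end", False)),
            )
            for name, entry in data.items()
        ]
        return cls(species)


def default_species_table() -> SpeciesTable:
    return SpeciesTable()


def electron_equivalents(concentration_mmol_per_l: float, species: Species) -> float:
    """e-mmol/L released on full oxidation of ``concentration`` mmol/L."""
    if concentration_mmol_per_l < 0:
        raise ValueError("concentration must be non-negative")
    return concentration_mmol_per_l * species.n_electrons


def cod_equivalent(concentration_mmol_per_l: float, species: Species) -> float:
    """mg COD/L equivalent of ``concentration`` mmol/L of ``species``."""
    return electron_equivalents(concentration_mmol_per_l, species) * COD_MG_PER_ELECTRON_MMOL


def cod_from_mg_per_l(mg_per_l: float, species: Species) -> float:
    """mg COD/L from a mass concentration in mg/L."""
    if mg_per_l < 0:
        raise ValueError("concentration must be non-negative")
    return mg_per_l * species.cod_per_mg
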