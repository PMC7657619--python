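"""Chemical species registry and the chemostat condition data model.

All downstream accounting (balance closure, specific fluxes, the PP_i
budget) rests on two conventions that this module makes explicit:

* **Molar-mass convention.** Organic acids occur in two variants: the
  neutral free acid (e.g. acetic acid, 60.05 g/mol) and its anion
  (acetate, 59.04 g/mol).  At the cultivation pH both organisms see the
  anion, but published flux tables are frequently computed on the
  free-acid basis.  Every conversion therefore takes an explicit
  ``convention`` argument (``"free_acid"`` or ``"anion"``); there is no
  global switch.
* **Atomic masses** are fixed four-decimal IUPAC standard values so that
  every derived quantity is bit-stable across platforms.

Amino-acid masses are those of the free (zwitterionic, neutral)
molecules, not of protein-bound residues; the mean residue mass of
~110 g/mol appears only as a named constant in :mod:`ppiflux.energetics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional

__all__ = [
    "ATOMIC_MASS",
    "Compound",
    "CompoundRegistry",
    "ProteinComposition",
    "AminoAcidProfile",
    "ChemostatCondition",
    "default_registry",
    "formula_mass",
    "to_mmol",
    "UnknownSpeciesError",
]

#: Standard atomic masses (g/mol), four decimals.
ATOMIC_MASS: Dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "Cl": 35.45,
    "P": 30.974,
}

FREE_ACID = "free_acid"
ANION = "anion"
_CONVENTIONS = (FREE_ACID, ANION)


class UnknownSpeciesError(KeyError):
    """Raised when a species name does not resolve in the registry."""


def formula_mass(formula: Mapping[str, int]) -> float:
    """Molar mass (g/mol) of an elemental formula."""
    return sum(ATOMIC_MASS[el] * n for el, n in formula.items())


@dataclass(frozen=True)
class Compound:
    """A chemical species with an elemental formula.

    The stored ``formula`` is always that of the free (neutral) form.
    For carboxylic acids ``has_anion`` is set and the anion variant is
    the free form minus one hydrogen (mass lower by 1.008 g/mol).
    """

    name: str
    formula: Mapping[str, int]
    has_anion: bool = False

    def __post_init__(self) -> None:
        if not self.formula:
            raise ValueError(f"{self.name}: empty formula")
        if any(n <= 0 for n in self.formula.values()):
            raise ValueError(f"{self.name}: non-positive element count")

    @property
    def carbon_atoms(self) -> int:
        return int(self.formula.get("C", 0))

    @property
    def nitrogen_atoms(self) -> int:
        return int(self.formula.get("N", 0))

    @property
    def variant_masses(self) -> Dict[str, float]:
        masses = {FREE_ACID: formula_mass(self.formula)}
        if self.has_anion:
            masses[ANION] = masses[FREE_ACID] - ATOMIC_MASS["H"]
        return masses

    def molar_mass(self, convention: str = FREE_ACID, *, strict: bool = True) -> float:
        """Molar mass under ``convention``.

        With ``strict=False`` a species lacking an anion form silently
        falls back to its only (free) form — the behaviour wanted when a
        convention is applied across a whole product table that mixes
        acids with alcohols.
        """
        if convention not in _CONVENTIONS:
            raise ValueError(f"unknown mass convention {convention!r}")
        if convention == ANION and not self.has_anion:
            if strict:
                raise ValueError(f"{self.name} has no anion form")
            convention = FREE_ACID
        return self.variant_masses[convention]

    def element_fraction(self, element: str, convention: str = FREE_ACID) -> float:
        """Mass fraction of ``element`` (g/g) under ``convention``."""
        n = self.formula.get(element, 0)
        return n * ATOMIC_MASS[element] / self.molar_mass(convention, strict=False)


# (formula, has_anion) for the built-in registry.  Formulas are the free
# neutral molecules; masses are derived, never stored.
_BUILTINS: Dict[str, tuple[Dict[str, int], bool]] = {
    "cellobiose": ({"C": 12, "H": 22, "O": 11}, False),
    "glucose": ({"C": 6, "H": 12, "O": 6}, False),
    "acetate": ({"C": 2, "H": 4, "O": 2}, True),
    "ethanol": ({"C": 2, "H": 6, "O": 1}, False),
    "lactate": ({"C": 3, "H": 6, "O": 3}, True),
    "formate": ({"C": 1, "H": 2, "O": 2}, True),
    "pyruvate": ({"C": 3, "H": 4, "O": 3}, True),
    "isobutanol": ({"C": 4, "H": 10, "O": 1}, False),
    "co2": ({"C": 1, "O": 2}, False),
    "urea": ({"C": 1, "H": 4, "N": 2, "O": 1}, False),
    "ammonium": ({"N": 1, "H": 4}, False),
    "ammonium_chloride": ({"N": 1, "H": 4, "Cl": 1}, False),
    # Free amino acids (zwitterionic neutral molecules).
    "alanine": ({"C": 3, "H": 7, "N": 1, "O": 2}, False),
    "arginine": ({"C": 6, "H": 14, "N": 4, "O": 2}, False),
    "asparagine": ({"C": 4, "H": 8, "N": 2, "O": 3}, False),
    "aspartic_acid": ({"C": 4, "H": 7, "N": 1, "O": 4}, False),
    "glutamic_acid": ({"C": 5, "H": 9, "N": 1, "O": 4}, False),
    "glutamine": ({"C": 5, "H": 10, "N": 2, "O": 3}, False),
    "histidine": ({"C": 6, "H": 9, "N": 3, "O": 2}, False),
    "isoleucine": ({"C": 6, "H": 13, "N": 1, "O": 2}, False),
    "leucine": ({"C": 6, "H": 13, "N": 1, "O": 2}, False),
    "lysine": ({"C": 6, "H": 14, "N": 2, "O": 2}, False),
    "methionine": ({"C": 5, "H": 11, "N": 1, "O": 2, "S": 1}, False),
    "phenylalanine": ({"C": 9, "H": 11, "N": 1, "O": 2}, False),
    "proline": ({"C": 5, "H": 9, "N": 1, "O": 2}, False),
    "serine": ({"C": 3, "H": 7, "N": 1, "O": 3}, False),
    "threonine": ({"C": 4, "H": 9, "N": 1, "O": 3}, False),
    "tryptophan": ({"C": 11, "H": 12, "N": 2, "O": 2}, False),
    "tyrosine": ({"C": 9, "H": 11, "N": 1, "O": 3}, False),
    "valine": ({"C": 5, "H": 11, "N": 1, "O": 2}, False),
}

#: Amino acids measured in culture supernatants.
AMINO_ACIDS = tuple(
    name
    for name in _BUILTINS
    if name
    in {
        "alanine", "arginine", "asparagine", "aspartic_acid", "glutamic_acid",
        "glutamine", "histidine", "isoleucine", "leucine", "lysine",
        "methionine", "phenylalanine", "proline", "serine", "threonine",
        "tryptophan", "tyrosine", "valine",
    }
)


class CompoundRegistry:
    """Name → :class:`Compound` lookup, extensible by the user.

    The registry can be serialized to / rebuilt from a delimited text
    table (``name, formula, has_anion``) so users can add species
    without touching code; see :meth:`to_table` and :meth:`from_table`.
    """

    def __init__(self, compounds: Optional[Iterable[Compound]] = None) -> None:
        self._compounds: Dict[str, Compound] = {}
        for c in compounds or ():
            self.add(c)

    def add(self, compound: Compound) -> None:
        self._compounds[compound.name] = compound

    def __contains__(self, name: str) -> bool:
        return name in self._compounds

    def __iter__(self):
        return iter(self._compounds.values())

    def __len__(self) -> int:
        return len(self._compounds)

    def get(self, name: str) -> Compound:
        try:
            return self._compounds[name]
        except KeyError:
            raise UnknownSpeciesError(name) from None

    def mass(self, name: str, convention: str = FREE_ACID, *, strict: bool = False) -> float:
        return self.get(name).molar_mass(convention, strict=strict)

    def carbon_fraction(self, name: str, convention: str = FREE_ACID) -> float:
        return self.get(name).element_fraction("C", convention)

    def nitrogen_fraction(self, name: str, convention: str = FREE_ACID) -> float:
        return self.get(name).element_fraction("N", convention)

    # -- text serialization -------------------------------------------------

    @staticmethod
    def _format_formula(formula: Mapping[str, int]) -> str:
        return "".join(f"{el}{n}" for el, n in formula.items())

    @staticmethod
    def _parse_formula(text: str) -> Dict[str, int]:
        import re

        formula: Dict[str, int] = {}
        for el, n in re.findall(r"([A-Z][a-z]?)(\d*)", text):
            if el:
                formula[el] = formula.get(el, 0) + (int(n) if n else 1)
        if not formula:
            raise ValueError(f"unparseable formula {text!r}")
        return formula

    def to_table(self, path) -> None:
        lines = ["name\tformula\thas_anion\tfree_acid_mass\tanion_mass"]
        for c in self:
            m = c.variant_masses
            lines.append(
                "\t".join(
                    [
                        c.name,
                        self._format_formula(c.formula),
                        str(int(c.has_anion)),
                        f"{m[FREE_ACID]:.3f}",
                        f"{m.get(ANION, float('nan')):.3f}",
                    ]
                )
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_table(cls, path) -> "CompoundRegistry":
        reg = cls()
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            idx = {k: i for i, k in enumerate(header)}
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                comp = Compound(
                    name=cols[idx["name"]],
                    formula=cls._parse_formula(cols[idx["formula"]]),
                    has_anion=bool(int(cols[idx["has_anion"]])),
                )
                declared = float(cols[idx["free_acid_mass"]])
                if abs(declared - formula_mass(comp.formula)) > 0.02:
                    raise ValueError(
                        f"{comp.name}: declared mass {declared} disagrees with formula"
                    )
                reg.add(comp)
        return reg


def default_registry() -> CompoundRegistry:
    """Registry with every species of the built-in condition tables."""
    return CompoundRegistry(
        Compound(name, formula, has_anion) for name, (formula, has_anion) in _BUILTINS.items()
    )


_DEFAULT_REGISTRY = default_registry()


def to_mmol(
    concentration: float,
    species: str,
    convention: str = FREE_ACID,
    registry: Optional[CompoundRegistry] = None,
) -> float:
    """Convert a mass concentration (mg/liter) to mmol/liter.

    ``convention`` selects the molar-mass variant and is strict: asking
    for the anion of a species that has none raises ``ValueError``.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    reg = registry or _DEFAULT_REGISTRY
    return concentration / reg.get(species).molar_mass(convention, strict=True)


@dataclass(frozen=True)
class ProteinComposition:
    """Elemental composition of protein by weight.

    Defaults are the standard experimental values for bulk microbial
    protein: 0.532 g C and 0.161 g N per g protein.
    """

    c_frac: float = 0.532
    n_frac: float = 0.161

    def __post_init__(self) -> None:
        for v in (self.c_frac, self.n_frac):
            if not 0.0 < v < 1.0:
                raise ValueError("protein element fractions must lie in (0, 1)")


@dataclass
class AminoAcidProfile:
    """Per-amino-acid supernatant concentrations (mg/liter).

    ``declared_total_c`` / ``declared_total_n`` carry totals published
    alongside a profile.  The declared carbon total is what balance
    closure consumes when present; the elemental computation from free
    amino-acid formulas is always available via :meth:`element_mass` and
    the two can disagree (the declared nitrogen totals of the reference
    data do not equal the elemental sum — both values are reported,
    never silently merged).
    """

    concentrations: Dict[str, float] = field(default_factory=dict)
    declared_total_c: Optional[float] = None
    declared_total_n: Optional[float] = None

    def __post_init__(self) -> None:
        for aa, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {aa}")

    def total(self) -> float:
        """Arithmetic sum of per-amino-acid concentrations, mg/liter."""
        return float(sum(self.concentrations.values()))

    def element_mass(
        self,
        element: str,
        registry: Optional[CompoundRegistry] = None,
    ) -> float:
        """mg/liter of ``element`` from the free amino-acid formulas."""
        if element not in ("C", "N"):
            raise ValueError("element must be 'C' or 'N'")
        reg = registry or _DEFAULT_REGISTRY
        return float(
            sum(
                conc * reg.get(aa).element_fraction(element)
                for aa, conc in self.concentrations.items()
            )
        )

    def get(self, aa: str, default: float = 0.0) -> float:
        return self.concentrations.get(aa, default)


@dataclass
class ChemostatCondition:
    """One chemostat steady state.

    Concentrations are mg/liter.  A species absent from ``residual`` or
    ``products`` was not detected and is treated as exactly zero; names
    recorded in ``nd_flags`` were explicitly reported as "not detected"
    and parsed to zero with provenance retained.
    """

    organism: str = ""
    dilution_rate: float = 0.1  # h^-1
    feed: Dict[str, float] = field(default_factory=dict)
    residual: Dict[str, float] = field(default_factory=dict)
    products: Dict[str, float] = field(default_factory=dict)
    cell_carbon: float = 0.0  # mg C/liter
    cell_nitrogen: float = 0.0  # mg N/liter
    supernatant_protein: float = 0.0  # mg/liter
    amino_acids: AminoAcidProfile = field(default_factory=AminoAcidProfile)
    nd_flags: set = field(default_factory=set)
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.dilution_rate > 0:
            raise ValueError("dilution rate must be > 0")
        for table in (self.feed, self.residual, self.products):
            for sp, c in table.items():
                if c < 0 or math.isnan(c):
                    raise ValueError(f"invalid concentration for {sp}")
        for v in (self.cell_carbon, self.cell_nitrogen, self.supernatant_protein):
            if v < 0:
                raise ValueError("cell and protein concentrations must be >= 0")

    def product(self, species: str) -> float:
        """Product concentration; absent or ND species read as 0."""
        return self.products.get(species, 0.0)
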