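"""Reaction parsing, exact rational combination, and pathway nets.

Pathway-level claims in pyrophosphate bioenergetics come down to summing
small sets of reactions and checking what cancels: the PPDK +
adenylate-kinase couple, the malate shunt, tRNA charging with and
without a soluble pyrophosphatase, the transaldolase-free pentose cycle.
Coefficients are exact :class:`fractions.Fraction` values so that every
cancellation is bit-exact; floating-point stoichiometry is deliberately
impossible here.

Abstract species (ATP, PEP, ferredoxin...) carry no full elemental
formula, but phosphate conservation can still be audited through a
pseudo-element ledger giving each species its phosphate count (ATP 3,
ADP 2, AMP 1, PP_i 2, P_i 1, sugar phosphates per their name).  Two
printed pathway nets are deliberately unbalanced on this ledger — a
pentose-cycle net missing a product P_i and an in-vivo PPDK line missing
product ATP — and ship as ``*_as_printed`` variants flagged as such; the
corrected forms are the defaults.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

from .registry import CompoundRegistry, default_registry

__all__ = [
    "Reaction",
    "PathwayCombination",
    "ElementBalance",
    "parse_reaction",
    "combine",
    "element_balance",
    "canned_pathways",
    "PathwayLibrary",
    "net_atp_per_glucose",
    "phosphoryl_cost",
]

#: Canonical names for species spelled several ways in the literature.
SPECIES_ALIASES: Dict[str, str] = {
    "PP_i": "PPi",
    "PP_i_": "PPi",
    "P_i": "Pi",
    "P_i_": "Pi",
    "NAD+": "NAD",
    "NADP+": "NADP",
}

#: Phosphate pseudo-element ledger for abstract (formula-less) species.
PHOSPHATE_LEDGER: Dict[str, int] = {
    "ATP": 3, "ADP": 2, "AMP": 1,
    "GTP": 3, "GDP": 2,
    "PPi": 2, "Pi": 1,
    "PEP": 1,
    "F6P": 1, "FBP": 2, "C3P": 1, "C4P": 1, "C5P": 1, "C6P": 1, "C7P": 1,
    "SBP": 2,
    "OAA": 0, "malate": 0,
    "NAD": 0, "NADH": 0, "NADP": 0, "NADPH": 0,
    "Fd_red": 0, "Fd_ox": 0,
    "H2O": 0,
}


def _canon(name: str) -> str:
    return SPECIES_ALIASES.get(name, name)


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric map: negative coefficients consumed, positive produced.

    Zero net coefficients are never stored; a reaction must consume at
    least one species and produce at least one.
    """

    stoich: Dict[str, Fraction]
    name: str = ""
    reversible: bool = False
    as_printed: bool = False  # verbatim-from-print variant, possibly unbalanced

    def __post_init__(self) -> None:
        clean = {
            _canon(sp): Fraction(c) for sp, c in self.stoich.items() if Fraction(c) != 0
        }
        object.__setattr__(self, "stoich", clean)
        if not self.as_printed:
            if not any(c < 0 for c in clean.values()) or not any(
                c > 0 for c in clean.values()
            ):
                raise ValueError(
                    f"reaction {self.name or '<anonymous>'} must consume and produce"
                )

    @property
    def reactants(self) -> Dict[str, Fraction]:
        return {sp: -c for sp, c in self.stoich.items() if c < 0}

    @property
    def products(self) -> Dict[str, Fraction]:
        return {sp: c for sp, c in self.stoich.items() if c > 0}

    def coefficient(self, species: str) -> Fraction:
        return self.stoich.get(_canon(species), Fraction(0))

    def scale(self, k) -> "Reaction":
        k = Fraction(k)
        if k == 0:
            raise ValueError("zero multiplier")
        stoich = {sp: c * k for sp, c in self.stoich.items()}
        if k < 0:  # direction flips
            return Reaction(stoich, name=f"{self.name}_rev" if self.name else "")
        return Reaction(stoich, name=self.name, reversible=self.reversible)

    def __add__(self, other: "Reaction") -> "Reaction":
        stoich = dict(self.stoich)
        for sp, c in other.stoich.items():
            stoich[sp] = stoich.get(sp, Fraction(0)) + c
        return Reaction(stoich)

    def without(self, *species: str) -> "Reaction":
        """Copy with the given species dropped (e.g. water in schematic nets)."""
        drop = {_canon(s) for s in species}
        return Reaction(
            {sp: c for sp, c in self.stoich.items() if sp not in drop},
            name=self.name,
            as_printed=self.as_printed,
        )

    def equation(self) -> str:
        def side(terms: Dict[str, Fraction]) -> str:
            parts = []
            for sp in sorted(terms):
                c = terms[sp]
                parts.append(sp if c == 1 else f"{c} {sp}")
            return " + ".join(parts) if parts else "0"

        arrow = "<->" if self.reversible else "->"
        return f"{side(self.reactants)} {arrow} {side(self.products)}"

    def __eq__(self, other) -> bool:  # stoichiometric identity only
        return isinstance(other, Reaction) and self.stoich == other.stoich

    def __hash__(self):
        return hash(frozenset(self.stoich.items()))

    def __repr__(self) -> str:
        label = f"{self.name}: " if self.name else ""
        return f"<Reaction {label}{self.equation()}>"


@dataclass
class PathwayCombination:
    """An ordered, weighted list of reactions to be summed."""

    terms: List[Tuple[Reaction, Fraction]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.terms = [(r, Fraction(m)) for r, m in self.terms]
        if any(m == 0 for _, m in self.terms):
            raise ValueError("zero multiplier in pathway combination")

    def scale(self, k) -> "PathwayCombination":
        k = Fraction(k)
        return PathwayCombination([(r, m * k) for r, m in self.terms], name=self.name)


_TERM_RE = re.compile(r"^\s*(?:(\d+(?:/\d+)?)\s+)?(\S+)\s*$")


def _parse_side(text: str, sign: int, stoich: Dict[str, Fraction]) -> None:
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise ValueError(f"empty term in {text!r}")
        m = _TERM_RE.match(term)
        if not m:
            raise ValueError(f"malformed term {term!r}")
        coeff = Fraction(m.group(1)) if m.group(1) else Fraction(1)
        sp = _canon(m.group(2))
        stoich[sp] = stoich.get(sp, Fraction(0)) + sign * coeff


def parse_reaction(text: str, name: str = "", as_printed: bool = False) -> Reaction:
    """Parse ``"a A + b B -> c C"`` (or ``<->``) into a :class:`Reaction`.

    Coefficients may be integers or rationals (``1/2``); an omitted
    coefficient is 1.  A species on both sides is merged to its net
    coefficient; a fully cancelling equation is rejected.
    """
    reversible = "<->" in text
    arrow = "<->" if reversible else "->"
    sides = text.split(arrow)
    if len(sides) != 2:
        raise ValueError(f"equation must contain exactly one {arrow!r}: {text!r}")
    stoich: Dict[str, Fraction] = {}
    _parse_side(sides[0], -1, stoich)
    _parse_side(sides[1], +1, stoich)
    if not any(c != 0 for c in stoich.values()):
        raise ValueError(f"equation has empty net stoichiometry: {text!r}")
    return Reaction(stoich, name=name, reversible=reversible, as_printed=as_printed)


def combine(combo: PathwayCombination) -> Reaction:
    """Exact weighted sum of a pathway combination.

    Intermediates whose net coefficient is zero vanish from the result —
    with :class:`fractions.Fraction` arithmetic this cancellation is
    exact, never approximate.
    """
    if not combo.terms:
        raise ValueError("empty pathway combination")
    stoich: Dict[str, Fraction] = {}
    for reaction, mult in combo.terms:
        for sp, c in reaction.stoich.items():
            stoich[sp] = stoich.get(sp, Fraction(0)) + c * mult
    return Reaction(stoich, name=combo.name)


@dataclass
class ElementBalance:
    """Net element counts of a reaction; all-zero means balanced."""

    net: Dict[str, Fraction]
    skipped: List[str] = field(default_factory=list)

    def is_balanced(self, element: Optional[str] = None) -> bool:
        if element is not None:
            return self.net.get(element, Fraction(0)) == 0
        return all(v == 0 for v in self.net.values())


def element_balance(
    reaction: Reaction,
    registry: Optional[CompoundRegistry] = None,
    use_phosphate_ledger: bool = True,
) -> ElementBalance:
    """Net per-element count of a reaction.

    Species with a registry formula contribute their full elemental
    composition; abstract species contribute their phosphate ledger
    entry when available and are otherwise skipped (recorded in
    ``skipped``).
    """
    reg = registry or default_registry()
    net: Dict[str, Fraction] = {}
    skipped: List[str] = []
    for sp, coeff in reaction.stoich.items():
        lower = sp.lower()
        if lower in reg:
            for el, n in reg.get(lower).formula.items():
                net[el] = net.get(el, Fraction(0)) + coeff * n
        elif use_phosphate_ledger and sp in PHOSPHATE_LEDGER:
            net["P"] = net.get("P", Fraction(0)) + coeff * PHOSPHATE_LEDGER[sp]
        else:
            skipped.append(sp)
    return ElementBalance(net=net, skipped=skipped)


class PathwayLibrary:
    """Named reactions and pathway combinations, loadable from plain text."""

    def __init__(self) -> None:
        self.reactions: Dict[str, Reaction] = {}
        self.combinations: Dict[str, PathwayCombination] = {}

    def reaction(self, name: str) -> Reaction:
        return self.reactions[name]

    def combination(self, name: str) -> PathwayCombination:
        return self.combinations[name]

    def net(self, name: str) -> Reaction:
        """Net reaction of a named entry (combined if a combination)."""
        if name in self.combinations:
            return combine(self.combinations[name])
        return self.reactions[name]

    def names(self) -> List[str]:
        return sorted(set(self.reactions) | set(self.combinations))

    _COMBO_TERM_RE = re.compile(r"^\s*(?:(\d+(?:/\d+)?)\s*\*\s*)?(\w+)\s*$")

    @classmethod
    def from_text(cls, text: str) -> "PathwayLibrary":
        """Parse a library file.

        Line formats::

            reaction <name>: <equation>
            combo <name> = term [+ term | - term]...

        where a term is ``name`` or ``mult*name``; ``- name`` runs a
        reaction in reverse.  Names ending in ``_as_printed`` are stored
        verbatim and flagged, exempt from the consume-and-produce check.
        """
        lib = cls()
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("reaction "):
                head, eq = line[len("reaction "):].split(":", 1)
                name = head.strip()
                lib.reactions[name] = parse_reaction(
                    eq.strip(), name=name, as_printed=name.endswith("_as_printed")
                )
            elif line.startswith("combo "):
                head, rhs = line[len("combo "):].split("=", 1)
                name = head.strip()
                terms: List[Tuple[Reaction, Fraction]] = []
                # split on +/- while keeping signs
                for sign, chunk in re.findall(r"([+-]?)\s*([^+-]+)", rhs):
                    m = cls._COMBO_TERM_RE.match(chunk)
                    if not m:
                        raise ValueError(f"line {lineno}: malformed combo term {chunk!r}")
                    mult = Fraction(m.group(1)) if m.group(1) else Fraction(1)
                    if sign == "-":
                        mult = -mult
                    ref = m.group(2)
                    if ref not in lib.reactions:
                        raise ValueError(f"line {lineno}: unknown reaction {ref!r}")
                    terms.append((lib.reactions[ref], mult))
                lib.combinations[name] = PathwayCombination(terms, name=name)
            else:
                raise ValueError(f"line {lineno}: unrecognized directive {line!r}")
        return lib


def canned_pathways() -> PathwayLibrary:
    """The built-in pathway library (shipped as ``data/reactions.txt``)."""
    from importlib import resources

    text = resources.files("ppiflux.data").joinpath("reactions.txt").read_text()
    return PathwayLibrary.from_text(text)


def net_atp_per_glucose(ppi_atp_cost: float) -> float:
    """Net ATP yield of PP_i-dependent glycolysis per glucose.

    The gross stoichiometry glucose + 5 ADP + 3 PP_i -> 2 pyruvate +
    5 ATP + P_i yields 5 ATP but consumes 3 PP_i; if each PP_i costs
    ``ppi_atp_cost`` ATP to regenerate, the net yield is 5 - 3*cost.
    A proton-pumping pyrophosphatase running as a PP_i synthase at two
    PP_i per ATP (cost 1/2) would allow 3.5 ATP/glucose; cost 1
    recovers the classical 2 ATP/glucose.
    """
    if ppi_atp_cost < 0:
        raise ValueError("PP_i-to-ATP cost must be >= 0")
    return 5.0 - 3.0 * ppi_atp_cost


#: ATP-equivalent value of consuming one of these in an anabolic net:
#: one phosphoanhydride transfer each; PEP counts 1 because PEP + ADP ->
#: pyruvate + ATP regenerates one ATP forgone.
_ATP_EQUIVALENT = {"ATP": 1, "GTP": 1, "PEP": 1}


def phosphoryl_cost(net: Reaction) -> Fraction:
    """ATP-equivalents consumed by a net reaction.

    Counts net consumption of ATP, GTP and PEP, one equivalent each.
    Comparing the tRNA-charging net with a soluble pyrophosphatase
    (4 equivalents per peptide bond) against the variant that recycles
    PP_i through PPDK (3 equivalents) shows the one-ATP-per-bond saving.
    """
    cost = Fraction(0)
    for sp, weight in _ATP_EQUIVALENT.items():
        c = net.coefficient(sp)
        if c < 0:
            cost += -c * weight
    return cost
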