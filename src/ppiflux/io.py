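"""Readers and writers for condition tables, plus packaged fixtures.

Condition file layout (comma- or tab-delimited, auto-detected)::

    # organism = Clostridium thermocellum
    # dilution_rate_per_h = 0.1
    # declared_amino_acid_carbon_mg_per_l = 40.5
    species,concentration_mg_per_l,role
    cellobiose,4757.2,feed
    acetate,1062.4,product
    alanine,15.0,amino_acid
    ...

Metadata lines are ``# key = value`` pairs; exactly one dilution rate is
required.  Roles come from a fixed vocabulary; duplicate rows of one
species and role are summed; a concentration of ``ND`` (not detected)
parses to exactly 0 and the species is recorded in ``nd_flags``.

The packaged fixtures hold the published steady-state tables for the
two reference organisms, the enzyme-activity table (data only, no
computation attached) and the reference flux table.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, Optional, Union
from pathlib import Path

import pandas as pd

from .registry import (
    AminoAcidProfile,
    ChemostatCondition,
    CompoundRegistry,
    default_registry,
)

__all__ = [
    "read_condition",
    "write_condition",
    "load_fixture",
    "fixture_names",
    "load_enzyme_activities",
    "load_reference_fluxes",
    "SchemaError",
]

ROLES = ("feed", "residual", "product", "cell_c", "cell_n", "protein", "amino_acid")

_META_KEYS = {
    "organism": str,
    "dilution_rate_per_h": float,
    "ph": float,
    "temperature_c": float,
    "declared_amino_acid_carbon_mg_per_l": float,
    "declared_amino_acid_nitrogen_mg_per_l": float,
}


class SchemaError(ValueError):
    """A condition file violates the schema; message names the spot."""


def _parse_metadata(lines) -> Dict[str, object]:
    meta: Dict[str, object] = {}
    for lineno, line in lines:
        body = line.lstrip("#").strip()
        if not body:
            continue
        if "=" not in body:
            raise SchemaError(f"line {lineno}: metadata needs 'key = value': {line!r}")
        key, _, value = body.partition("=")
        key, value = key.strip(), value.strip()
        caster = _META_KEYS.get(key, str)
        try:
            meta[key] = caster(value)
        except ValueError:
            raise SchemaError(f"line {lineno}: bad value for {key}: {value!r}") from None
    return meta


def read_condition(
    path: Union[str, Path],
    registry: Optional[CompoundRegistry] = None,
) -> ChemostatCondition:
    """Read and validate a condition file into a :class:`ChemostatCondition`."""
    reg = registry or default_registry()
    path = Path(path)
    text = path.read_text()
    meta_lines, data_lines = [], []
    for lineno, line in enumerate(text.splitlines(), 1):
        if line.startswith("#"):
            meta_lines.append((lineno, line))
        elif line.strip():
            data_lines.append((lineno, line))
    meta = _parse_metadata(meta_lines)
    if "dilution_rate_per_h" not in meta:
        raise SchemaError(f"{path.name}: missing metadata 'dilution_rate_per_h'")

    if not data_lines:
        raise SchemaError(f"{path.name}: no data rows")
    delim = "\t" if "\t" in data_lines[0][1] else ","
    header = [h.strip() for h in data_lines[0][1].split(delim)]
    expected = ["species", "concentration_mg_per_l", "role"]
    if header != expected:
        raise SchemaError(
            f"line {data_lines[0][0]}: header must be {','.join(expected)}"
        )

    cond = ChemostatCondition(
        organism=str(meta.get("organism", "")),
        dilution_rate=float(meta["dilution_rate_per_h"]),
        metadata=meta,
    )
    cond.amino_acids = AminoAcidProfile(
        declared_total_c=meta.get("declared_amino_acid_carbon_mg_per_l"),
        declared_total_n=meta.get("declared_amino_acid_nitrogen_mg_per_l"),
    )
    for lineno, line in data_lines[1:]:
        cols = [c.strip() for c in line.split(delim)]
        if len(cols) != 3:
            raise SchemaError(f"line {lineno}: expected 3 columns, got {len(cols)}")
        species, conc_text, role = cols
        if role not in ROLES:
            raise SchemaError(f"line {lineno}: unknown role {role!r}")
        if conc_text.upper() == "ND":
            conc, nd = 0.0, True
        else:
            try:
                conc = float(conc_text)
            except ValueError:
                raise SchemaError(
                    f"line {lineno}, column concentration_mg_per_l: {conc_text!r}"
                ) from None
            nd = False
        if conc < 0:
            raise SchemaError(f"line {lineno}: negative concentration")
        if nd:
            cond.nd_flags.add(species)

        if role in ("feed", "residual", "product", "amino_acid") and species not in reg:
            raise SchemaError(
                f"line {lineno}: species {species!r} not in registry "
                "(extend the registry to accept it)"
            )
        if role == "feed":
            cond.feed[species] = cond.feed.get(species, 0.0) + conc
        elif role == "residual":
            cond.residual[species] = cond.residual.get(species, 0.0) + conc
        elif role == "product":
            cond.products[species] = cond.products.get(species, 0.0) + conc
        elif role == "amino_acid":
            aa = cond.amino_acids.concentrations
            aa[species] = aa.get(species, 0.0) + conc
        elif role == "cell_c":
            cond.cell_carbon += conc
        elif role == "cell_n":
            cond.cell_nitrogen += conc
        elif role == "protein":
            cond.supernatant_protein += conc
    return cond


def write_condition(condition: ChemostatCondition, path: Union[str, Path]) -> None:
    """Write a condition in the same schema :func:`read_condition` reads."""
    lines = []
    meta = dict(condition.metadata)
    meta.setdefault("organism", condition.organism)
    meta["dilution_rate_per_h"] = condition.dilution_rate
    if condition.amino_acids.declared_total_c is not None:
        meta["declared_amino_acid_carbon_mg_per_l"] = condition.amino_acids.declared_total_c
    if condition.amino_acids.declared_total_n is not None:
        meta["declared_amino_acid_nitrogen_mg_per_l"] = condition.amino_acids.declared_total_n
    for key, value in meta.items():
        if key in _META_KEYS:
            lines.append(f"# {key} = {value}")
    lines.append("species,concentration_mg_per_l,role")

    def fmt(species: str, conc: float, role: str) -> str:
        if species in condition.nd_flags and conc == 0:
            return f"{species},ND,{role}"
        return f"{species},{conc!r},{role}"

    for sp, c in condition.feed.items():
        lines.append(fmt(sp, c, "feed"))
    for sp, c in condition.residual.items():
        lines.append(fmt(sp, c, "residual"))
    if condition.cell_carbon:
        lines.append(f"cell_carbon,{condition.cell_carbon!r},cell_c")
    if condition.cell_nitrogen:
        lines.append(f"cell_nitrogen,{condition.cell_nitrogen!r},cell_n")
    for sp, c in condition.products.items():
        lines.append(fmt(sp, c, "product"))
    if condition.supernatant_protein:
        lines.append(f"supernatant_protein,{condition.supernatant_protein!r},protein")
    for aa, c in condition.amino_acids.concentrations.items():
        lines.append(fmt(aa, c, "amino_acid"))
    Path(path).write_text("\n".join(lines) + "\n")


_FIXTURES = {
    "table1_cthermocellum": "table1_cthermocellum.csv",
    "table1_tsaccharolyticum": "table1_tsaccharolyticum.csv",
}


def fixture_names():
    return sorted(_FIXTURES)


def _data_path(filename: str):
    return resources.files("ppiflux.data").joinpath(filename)


def load_fixture(
    name: str, registry: Optional[CompoundRegistry] = None
) -> ChemostatCondition:
    """Load a packaged steady-state condition by name."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; have {fixture_names()}")
    with resources.as_file(_data_path(_FIXTURES[name])) as p:
        return read_condition(p, registry=registry)


def load_enzyme_activities() -> pd.DataFrame:
    """Enzyme activities of core metabolism (data-only fixture)."""
    with resources.as_file(_data_path("table3_enzyme_activities.csv")) as p:
        return pd.read_csv(p, comment="#")


def load_reference_fluxes() -> pd.DataFrame:
    """Published specific-flux reference values (carbon-limited,
    nitrogen-limited and PTA-mutant columns).

    The q_cellobiose row carries ``irreconcilable`` in its flag column:
    the printed value cannot be re-derived from the condition table
    under any molar-mass convention and is excluded from validation.
    """
    with resources.as_file(_data_path("table4_reference_fluxes.csv")) as p:
        return pd.read_csv(p, comment="#")
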