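"""Specific production rates (q) per gram of cell nitrogen per hour.

At chemostat steady state every extracellular species obeys q = c * D / X,
where c is its concentration, D the dilution rate and X the catalytic
biomass.  Normalization here is per gram of cell *nitrogen* rather than
per gram dry weight: the biomass C/N ratio shifts strongly under
nitrogen limitation (glycogen accumulation), whereas cell nitrogen
tracks the protein machinery actually carrying the flux.  Dry-weight
normalization is available as an option via an assumed biomass carbon
content (default 0.45 g C/g cells).

Free-acid molar masses are the default for molar fluxes, matching how
the reference flux tables were computed; balance closure uses anion
masses instead (see :mod:`ppiflux.balances`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import pandas as pd

from .registry import (
    FREE_ACID,
    ChemostatCondition,
    CompoundRegistry,
    ProteinComposition,
    default_registry,
)

__all__ = [
    "FluxTable",
    "specific_flux",
    "mass_flux",
    "total_pyruvate_flux",
    "nitrogen_uptake_flux",
    "fold_change",
    "product_fraction",
    "build_flux_table",
]

#: Species whose fluxes sum (valine twice) to the pyruvate branch-point flux.
PYRUVATE_FAMILY = ("acetate", "ethanol", "lactate", "pyruvate", "valine")

_N_MOLAR_MASS = 14.007  # g/mol


def specific_flux(
    concentration: float,
    species: str,
    dilution_rate: float,
    cell_nitrogen: float,
    convention: str = FREE_ACID,
    registry: Optional[CompoundRegistry] = None,
) -> float:
    """Molar specific flux, mmol per g cell N per hour.

    ``(concentration / molar mass) * D / (cell_nitrogen / 1000)``.
    """
    if cell_nitrogen <= 0:
        raise ValueError("cell nitrogen must be > 0")
    reg = registry or default_registry()
    mmol = concentration / reg.mass(species, convention)
    return mmol * dilution_rate / (cell_nitrogen / 1000.0)


def mass_flux(concentration: float, dilution_rate: float, cell_nitrogen: float) -> float:
    """Mass-basis specific flux, mg per g cell N per hour.

    Used for quantities without a single molar mass (total excreted
    amino acids, supernatant protein).
    """
    if cell_nitrogen <= 0:
        raise ValueError("cell nitrogen must be > 0")
    return concentration * dilution_rate / (cell_nitrogen / 1000.0)


@dataclass
class FluxTable:
    """Specific rates for one condition plus derived aggregates."""

    q: Dict[str, float] = field(default_factory=dict)  # mmol/g N/h
    q_mass: Dict[str, float] = field(default_factory=dict)  # mg/g N/h
    q_total_pyruvate: Optional[float] = None
    q_nitrogen_uptake: Optional[float] = None
    convention: str = FREE_ACID
    normalization: str = "nitrogen"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"quantity": f"q_{sp}", "value": v, "units": f"mmol/g {self.normalization}/h"}
            for sp, v in self.q.items()
        ]
        rows += [
            {"quantity": f"q_{name}", "value": v, "units": f"mg/g {self.normalization}/h"}
            for name, v in self.q_mass.items()
        ]
        if self.q_total_pyruvate is not None:
            rows.append(
                {
                    "quantity": "q_total_pyruvate",
                    "value": self.q_total_pyruvate,
                    "units": f"mmol/g {self.normalization}/h",
                }
            )
        if self.q_nitrogen_uptake is not None:
            rows.append(
                {
                    "quantity": "q_nitrogen_uptake",
                    "value": self.q_nitrogen_uptake,
                    "units": f"mmol N/g {self.normalization}/h",
                }
            )
        return pd.DataFrame(rows)


def total_pyruvate_flux(table: FluxTable) -> float:
    """Pyruvate branch-point flux: acetate + ethanol + lactate +
    excreted pyruvate + 2 x valine (valine carries two pyruvate)."""
    try:
        q = table.q
        return (
            q["acetate"] + q["ethanol"] + q["lactate"] + q["pyruvate"] + 2.0 * q["valine"]
        )
    except KeyError as exc:
        raise KeyError(f"flux table lacks pyruvate-family component {exc}") from None


def nitrogen_uptake_flux(
    condition: ChemostatCondition,
    protein: ProteinComposition = ProteinComposition(),
    registry: Optional[CompoundRegistry] = None,
) -> float:
    """Specific nitrogen uptake, mmol N per g cell N per hour.

    Sums nitrogen found in cells, excreted amino acids (declared profile
    total when present, else elemental) and supernatant protein, converts
    to mmol N and normalizes like any other specific flux.
    """
    reg = registry or default_registry()
    profile = condition.amino_acids
    if profile.declared_total_n is not None:
        aa_n = profile.declared_total_n
    else:
        aa_n = profile.element_mass("N", reg) if profile.concentrations else 0.0
    total_n = condition.cell_nitrogen + aa_n + condition.supernatant_protein * protein.n_frac
    return mass_flux(total_n, condition.dilution_rate, condition.cell_nitrogen) / _N_MOLAR_MASS * 1.0


def fold_change(q_a: float, q_b: float) -> float:
    """Ratio of two fluxes (e.g. nitrogen-limited over carbon-limited)."""
    if q_b == 0:
        raise ZeroDivisionError("reference flux is zero")
    return q_a / q_b


def product_fraction(table: FluxTable, species: str) -> float:
    """Percent of the total pyruvate flux carried by one product.

    Valine counts its doubled contribution, mirroring its weight in the
    total.
    """
    if species not in PYRUVATE_FAMILY:
        raise ValueError(f"{species} is not a pyruvate-family product")
    total = table.q_total_pyruvate
    if total is None:
        total = total_pyruvate_flux(table)
    if total <= 0:
        raise ValueError("total pyruvate flux must be > 0")
    weight = 2.0 if species == "valine" else 1.0
    return 100.0 * weight * table.q[species] / total


def build_flux_table(
    condition: ChemostatCondition,
    convention: str = FREE_ACID,
    protein: ProteinComposition = ProteinComposition(),
    registry: Optional[CompoundRegistry] = None,
    normalization: str = "nitrogen",
    biomass_carbon_fraction: float = 0.45,
) -> FluxTable:
    """Compute the full specific-flux table for a condition.

    ``normalization="dry_weight"`` rescales per g cells using the
    biomass carbon content: g cells/liter = cell_carbon / carbon fraction.
    """
    reg = registry or default_registry()
    if normalization == "nitrogen":
        denom = condition.cell_nitrogen
    elif normalization == "dry_weight":
        if condition.cell_carbon <= 0:
            raise ValueError("dry-weight normalization needs cell carbon")
        denom = condition.cell_carbon / biomass_carbon_fraction
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    table = FluxTable(convention=convention, normalization=normalization)
    for sp, conc in condition.products.items():
        table.q[sp] = specific_flux(
            conc, sp, condition.dilution_rate, denom, convention, reg
        )
    # valine enters the molar table from the amino-acid profile
    table.q["valine"] = specific_flux(
        condition.amino_acids.get("valine"),
        "valine",
        condition.dilution_rate,
        denom,
        convention,
        reg,
    )
    for sp in PYRUVATE_FAMILY:
        table.q.setdefault(sp, 0.0)
    table.q_mass["excreted_amino_acids"] = mass_flux(
        condition.amino_acids.total(), condition.dilution_rate, denom
    )
    table.q_mass["supernatant_protein"] = mass_flux(
        condition.supernatant_protein, condition.dilution_rate, denom
    )
    table.q_total_pyruvate = total_pyruvate_flux(table)
    if normalization == "nitrogen" and condition.cell_nitrogen > 0:
        table.q_nitrogen_uptake = nitrogen_uptake_flux(condition, protein, reg)
    return table
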