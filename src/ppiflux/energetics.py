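"""Pyrophosphate budget and ATP accounting for biomass formation.

The central quantitative question: can the PP_i generated as a
by-product of anabolism (polymerization of amino acids, nucleotides,
lipid precursors, glycogen) cover the PP_i consumed by catabolic
glycolysis through PP_i-PFK and PPDK?  The budget is drawn per gram of
cells at steady state:

* anabolic PP_i supply: ~11 mmol/g cells, dominated by protein
  synthesis (tRNA charging);
* catabolic PP_i demand: from the cellobiose actually catabolized —
  total cellobiose per g cells (from the biomass yield) minus the
  anabolic requirement minus the unaccounted ("missing carbon")
  fraction — at 2 PP_i per cellobiose in PP_i-PFK plus up to 4 PP_i per
  cellobiose in PPDK, scaled by the fraction of the PEP->pyruvate flux
  carried by PPDK.

Supply (~11) falls far short of demand (~54 at a two-thirds PPDK
share), so catabolic PP_i must be bought with ATP (ATP + P_i ->
ADP + PP_i).  Conversely, if anabolic PP_i is recycled rather than
hydrolysed, the ATP requirement for biosynthesis drops and the
theoretical Y_ATP^max rises accordingly.

Every constant lives in :class:`EnergeticsDefaults` (mirrored in
``data/energetics_defaults.yaml``) and is overridable per call; nothing
is hard-wired into a formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Dict, Optional

__all__ = [
    "EnergeticsDefaults",
    "PPiBudget",
    "CellobiosePartition",
    "ATPAccounting",
    "anabolic_ppi_total",
    "cellobiose_partition",
    "catabolic_ppi_demand",
    "atp_requirement_with_ppi_credit",
    "protein_atp_saving",
    "lysis_required_cell_mass",
    "lysis_implied_concentration",
    "ANABOLIC_PPI_SOURCES",
]

#: Anabolic PP_i generated per g cells (mmol), by macromolecule class,
#: from metabolic-network accounting of an anaerobic heterotroph.
ANABOLIC_PPI_SOURCES: Dict[str, float] = {
    "protein": 7.67,
    "nucleic_acids": 1.16,
    "lipids_lps": 2.11,
    "glycogen": 0.03,
}


@dataclass(frozen=True)
class EnergeticsDefaults:
    """Budget constants, each overridable per run.

    biomass_yield          g cells per g cellobiose, observed.
    anabolic_cellobiose    mmol cellobiose needed to build 1 g cells.
    unaccounted_fraction   fraction of cellobiose leaving as unidentified
                           carbon (1 - carbon recovery/100).
    ppdk_fraction          share of the PEP->pyruvate flux through PPDK
                           (remainder via the malate shunt).
    pfk_ppi_per_cellobiose PP_i consumed by PP_i-PFK per cellobiose (two
                           hexoses, one PP_i each).
    pep_per_cellobiose     PEP formed per cellobiose (two per hexose).
    anabolic_ppi_credit    mmol PP_i/g cells generated in anabolism.
    base_atp_requirement   mmol ATP per g cells from biosynthetic
                           accounting (protein content 52.4%).
    protein_fraction       g protein per g cells in that accounting.
    residue_mass           mean amino-acid residue mass in protein, g/mol.
    cellobiose_mmol_mass   g per mmol cellobiose.
    carbon_fraction        g C per g cells.
    """

    biomass_yield: float = 0.16
    anabolic_cellobiose: float = 3.7
    unaccounted_fraction: float = 0.16
    ppdk_fraction: float = 2.0 / 3.0
    pfk_ppi_per_cellobiose: float = 2.0
    pep_per_cellobiose: float = 4.0
    anabolic_ppi_credit: float = 11.0
    base_atp_requirement: float = 34.7
    protein_fraction: float = 0.524
    residue_mass: float = 110.0
    cellobiose_mmol_mass: float = 0.34230
    carbon_fraction: float = 0.45

    @classmethod
    def from_yaml(cls, path) -> "EnergeticsDefaults":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown defaults keys: {sorted(unknown)}")
        return cls(**raw)

    def replace(self, **kw) -> "EnergeticsDefaults":
        return replace(self, **kw)


@dataclass
class CellobiosePartition:
    """Destinations of cellobiose per gram of cells formed (mmol/g)."""

    total: float
    anabolic: float
    unaccounted: float
    biomass_yield: float
    carbon_fraction: float = 0.45

    def __post_init__(self) -> None:
        if min(self.total, self.anabolic, self.unaccounted) < 0:
            raise ValueError("partition components must be >= 0")
        if self.catabolic < 0:
            raise ValueError(
                "anabolic + unaccounted cellobiose exceed the total: partition negative"
            )

    @property
    def catabolic(self) -> float:
        return self.total - self.anabolic - self.unaccounted


@dataclass
class PPiBudget:
    """Anabolic PP_i supply vs catabolic PP_i demand, mmol per g cells."""

    anabolic_sources: Dict[str, float] = field(default_factory=dict)
    catabolic_pfk: float = 0.0
    catabolic_ppdk: float = 0.0
    ppdk_flux_fraction: float = 0.0

    @property
    def anabolic_total(self) -> float:
        return float(sum(self.anabolic_sources.values()))

    @property
    def catabolic_total(self) -> float:
        return self.catabolic_pfk + self.catabolic_ppdk

    @property
    def deficit(self) -> float:
        """Catabolic PP_i that anabolism cannot supply (mmol/g cells)."""
        return self.catabolic_total - self.anabolic_total

    def to_text(self) -> str:
        lines = ["PP_i budget (mmol per g cells)", "  anabolic sources:"]
        for k, v in self.anabolic_sources.items():
            lines.append(f"    {k:<16}{v:>8.2f}")
        lines.append(f"    {'total':<16}{self.anabolic_total:>8.2f}")
        lines.append("  catabolic demand:")
        lines.append(f"    {'PPi-PFK':<16}{self.catabolic_pfk:>8.1f}")
        lines.append(
            f"    {'PPDK':<16}{self.catabolic_ppdk:>8.1f}"
            f"   (PPDK share {self.ppdk_flux_fraction:.2f})"
        )
        lines.append(f"    {'total':<16}{self.catabolic_total:>8.1f}")
        lines.append(f"  deficit (ATP-funded): {self.deficit:.1f}")
        return "\n".join(lines)


@dataclass
class ATPAccounting:
    """ATP requirement for biosynthesis with an anabolic PP_i credit."""

    base_atp_requirement: float  # mmol ATP / g cells
    ppi_credit: float  # mmol / g cells

    @property
    def adjusted_requirement(self) -> float:
        return self.base_atp_requirement - self.ppi_credit

    @property
    def y_atp_base(self) -> float:
        """g cells per mol ATP without the credit."""
        return 1000.0 / self.base_atp_requirement

    @property
    def y_atp_max(self) -> float:
        """g cells per mol ATP with the anabolic PP_i fully recycled."""
        return 1000.0 / self.adjusted_requirement


def anabolic_ppi_total(sources: Optional[Dict[str, float]] = None) -> float:
    """Total anabolic PP_i, mmol per g cells (defaults sum to 10.97 ~ 11)."""
    src = ANABOLIC_PPI_SOURCES if sources is None else sources
    if any(v < 0 for v in src.values()):
        raise ValueError("PP_i source amounts must be >= 0")
    return float(sum(src.values()))


def cellobiose_partition(
    biomass_yield: float = 0.16,
    anabolic: float = 3.7,
    unaccounted_fraction: float = 0.16,
    cellobiose_mmol_mass: float = 0.34230,
    carbon_fraction: float = 0.45,
) -> CellobiosePartition:
    """Partition cellobiose consumption per gram of cells.

    ``total = 1 / (yield * g-per-mmol)`` (0.16 g/g gives ~18.26 mmol/g,
    i.e. 1 g cells per ~18.2 mmol cellobiose); the unaccounted share is
    ``unaccounted_fraction`` of the total (from 100 minus the carbon
    recovery); the catabolic share is the remainder after also removing
    the anabolic requirement.
    """
    if biomass_yield <= 0:
        raise ValueError("biomass yield must be > 0")
    if not 0 <= unaccounted_fraction < 1:
        raise ValueError("unaccounted fraction must lie in [0, 1)")
    total = 1.0 / (biomass_yield * cellobiose_mmol_mass)
    return CellobiosePartition(
        total=total,
        anabolic=anabolic,
        unaccounted=unaccounted_fraction * total,
        biomass_yield=biomass_yield,
        carbon_fraction=carbon_fraction,
    )


def catabolic_ppi_demand(
    partition: CellobiosePartition,
    ppdk_fraction: float = 2.0 / 3.0,
    pfk_ppi_per_cellobiose: float = 2.0,
    pep_per_cellobiose: float = 4.0,
    anabolic_sources: Optional[Dict[str, float]] = None,
    quantize: bool = False,
) -> PPiBudget:
    """Catabolic PP_i demand per g cells at a given PPDK flux share.

    PP_i-PFK consumes ``pfk_ppi_per_cellobiose`` PP_i per catabolized
    cellobiose; PPDK consumes one PP_i per PEP it converts, i.e.
    ``ppdk_fraction * pep_per_cellobiose`` per cellobiose.

    ``quantize=True`` rounds the catabolic cellobiose and each demand
    component to 0.1 mmol before summing, reproducing the arithmetic of
    the published figure (catabolic 11.6 -> 23.2 + 30.9 = 54.1); the
    default is exact (23.3 + 31.0 = 54.3 for the same inputs).
    """
    if not 0 <= ppdk_fraction <= 1:
        raise ValueError("PPDK fraction must lie in [0, 1]")
    catabolic = partition.catabolic
    if quantize:
        catabolic = round(catabolic, 1)
    pfk = pfk_ppi_per_cellobiose * catabolic
    ppdk = ppdk_fraction * pep_per_cellobiose * catabolic
    if quantize:
        pfk, ppdk = round(pfk, 1), round(ppdk, 1)
    return PPiBudget(
        anabolic_sources=dict(
            ANABOLIC_PPI_SOURCES if anabolic_sources is None else anabolic_sources
        ),
        catabolic_pfk=pfk,
        catabolic_ppdk=ppdk,
        ppdk_flux_fraction=ppdk_fraction,
    )


def atp_requirement_with_ppi_credit(
    base: float = 34.7, credit: float = 11.0
) -> ATPAccounting:
    """ATP requirement after crediting recycled anabolic PP_i.

    One recycled PP_i replaces one ATP-funded phosphorylation, so the
    requirement drops from ``base`` to ``base - credit`` mmol ATP/g
    cells and Y_ATP^max rises from 1000/base to 1000/(base - credit).
    """
    if credit < 0:
        raise ValueError("credit must be >= 0")
    if credit >= base:
        raise ValueError("PP_i credit must be smaller than the base ATP requirement")
    return ATPAccounting(base_atp_requirement=base, ppi_credit=credit)


def protein_atp_saving(
    protein_fraction: float = 0.524,
    residue_mass: float = 110.0,
    base: float = 34.7,
    rounded: bool = True,
) -> float:
    """Percent ATP saved in protein synthesis when PP_i is recycled.

    1 g cells holds ``1000 * protein_fraction / residue_mass`` mmol of
    peptide bonds (0.524/110 -> 4.8 mmol); recycling the charging PP_i
    saves one ATP per bond, i.e. 4.8 of 34.7 mmol ATP (~14%).
    """
    if min(protein_fraction, residue_mass, base) <= 0:
        raise ValueError("inputs must be > 0")
    residues = 1000.0 * protein_fraction / residue_mass
    saving = 100.0 * residues / base
    return float(round(saving)) if rounded else saving


def lysis_required_cell_mass(
    extracellular_aa: float, min_protein_fraction: float = 0.6
) -> float:
    """Cell mass (mg/liter) that lysis would have to dissolve to explain
    the observed extracellular amino acids, at a minimum protein content."""
    if not 0 < min_protein_fraction <= 1:
        raise ValueError("protein fraction must lie in (0, 1]")
    if extracellular_aa < 0:
        raise ValueError("amino acid concentration must be >= 0")
    return extracellular_aa / min_protein_fraction


def lysis_implied_concentration(
    extracellular_aa: float = 100.0,
    mean_aa_mass: float = 111.0,
    min_protein_fraction: float = 0.6,
    specific_cell_volume: float = 2.0,
) -> float:
    """Intracellular amino-acid concentration (mol/liter) implied by lysis.

    If the extracellular amino acids all came from lysed cells, the
    lysed mass is ``extracellular_aa / min_protein_fraction`` and its
    volume that mass times the specific cell volume (ml/g).  100
    mg/liter at 111 g/mol from 167 mg cells occupying ~0.33 ml implies
    ~2.7 M — far beyond plausibility, ruling out lysis as the source.
    The specific cell volume is an explicit parameter (2.0 ml/g
    reproduces the 334 ul volume of the published argument).
    """
    if min(extracellular_aa, mean_aa_mass, min_protein_fraction, specific_cell_volume) <= 0:
        raise ValueError("inputs must be > 0")
    mmol = extracellular_aa / mean_aa_mass
    cell_mass_g = lysis_required_cell_mass(extracellular_aa, min_protein_fraction) / 1000.0
    volume_ml = cell_mass_g * specific_cell_volume
    return mmol / volume_ml
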