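"""Synthetic steady-state chemostat data with known ground truth.

The generator inverts the steady-state flux relation: given a
ground-truth specific-flux vector q (mmol per g cell N per h), the
product concentration of each species is

    c = q * (X_N / 1000) / D * M

with X_N the cell-nitrogen concentration (mg N/liter), D the dilution
rate and M the molar mass.  Feed cellobiose is then set so that, with a
prescribed "missing carbon" fraction f and before noise, the carbon
balance closes at exactly 100*(1-f) percent — mimicking the incomplete
recoveries of real anaerobic cultures.  Measurement error is
multiplicative lognormal with a given CV (concentrations are strictly
positive, and chemostat measurement scatter is proportional), applied
to the product concentrations of each replicate.

Default parameters emulate the carbon-limited reference condition:
D = 0.1/h, 102 mg cell N/liter, biomass C/N 3.31 g/g, a product
spectrum matching the measured mixed-acid fermentation, missing-carbon
fraction 0.16, measurement CV 2%.

Randomness: one child generator per replicate, seeded from
``(seed, replicate_index)``, so any subset of replicates is
reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import math

import numpy as np
import pandas as pd

from . import balances, fluxes
from .registry import (
    FREE_ACID,
    ChemostatCondition,
    CompoundRegistry,
    default_registry,
)

__all__ = ["GeneratorSpec", "GroundTruth", "generate", "recover_fluxes", "FluxRecovery"]

#: Carbon-limited reference fluxes, mmol per g cell N per h.
DEFAULT_FLUXES: Dict[str, float] = {
    "acetate": 17.34,
    "ethanol": 14.89,
    "formate": 5.15,
    "lactate": 0.38,
    "pyruvate": 0.17,
    "isobutanol": 0.33,
}


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic chemostat generator."""

    ground_truth_fluxes: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FLUXES)
    )
    cell_nitrogen: float = 102.0  # mg N/liter
    cell_cn_ratio: float = 3.31  # g C / g N
    dilution_rate: float = 0.1  # 1/h
    missing_carbon_fraction: float = 0.16
    noise_cv: float = 0.02
    seed: int = 0
    n_replicates: int = 1
    convention: str = FREE_ACID

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if not 0 <= self.missing_carbon_fraction < 1:
            raise ValueError("missing-carbon fraction must lie in [0, 1)")
        if any(q < 0 for q in self.ground_truth_fluxes.values()):
            raise ValueError("ground-truth fluxes must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class GroundTruth:
    """Bookkeeping of what the generator actually injected."""

    spec: GeneratorSpec
    noise_free_concentrations: Dict[str, float]
    feed_cellobiose: float
    co2: float
    cell_carbon: float

    @property
    def nitrogen_uptake(self) -> float:
        """Ground-truth specific nitrogen uptake (cells are the only sink)."""
        return (
            self.spec.cell_nitrogen
            * self.spec.dilution_rate
            / (self.spec.cell_nitrogen / 1000.0)
            / 14.007
        )


def _noise_free_condition(
    spec: GeneratorSpec, reg: CompoundRegistry
) -> Tuple[Dict[str, float], float, float, float]:
    conc = {
        sp: q * (spec.cell_nitrogen / 1000.0) / spec.dilution_rate
        * reg.mass(sp, spec.convention)
        for sp, q in spec.ground_truth_fluxes.items()
    }
    cell_carbon = spec.cell_cn_ratio * spec.cell_nitrogen
    probe = ChemostatCondition(
        organism="synthetic",
        dilution_rate=spec.dilution_rate,
        products=dict(conc),
        cell_carbon=cell_carbon,
        cell_nitrogen=spec.cell_nitrogen,
    )
    co2 = balances.infer_co2(probe, convention=spec.convention, registry=reg)
    carbon_out = (
        cell_carbon
        + sum(c * reg.carbon_fraction(sp, spec.convention) for sp, c in conc.items())
        + co2 * reg.carbon_fraction("co2")
    )
    feed = carbon_out / (1.0 - spec.missing_carbon_fraction) / reg.carbon_fraction(
        "cellobiose"
    )
    if feed <= 0 or math.isnan(feed):
        raise ValueError("infeasible generator spec: nonpositive feed")
    return conc, cell_carbon, co2, feed


def generate(
    spec: GeneratorSpec, registry: Optional[CompoundRegistry] = None
) -> Tuple[List[ChemostatCondition], GroundTruth]:
    """Generate replicate steady-state conditions plus the ground truth.

    Deterministic given ``spec.seed``; replicate i draws from a stream
    seeded with ``(seed, i)``.
    """
    reg = registry or default_registry()
    conc, cell_carbon, co2, feed = _noise_free_condition(spec, reg)
    sigma = math.sqrt(math.log1p(spec.noise_cv**2))
    conditions: List[ChemostatCondition] = []
    for i in range(spec.n_replicates):
        rng = np.random.default_rng([spec.seed, i])
        noisy = {}
        for sp, c in conc.items():
            if sigma > 0:
                # mean-one lognormal multiplier with the requested CV
                factor = math.exp(rng.normal(-0.5 * sigma**2, sigma))
            else:
                factor = 1.0
            noisy[sp] = c * factor
        conditions.append(
            ChemostatCondition(
                organism="synthetic",
                dilution_rate=spec.dilution_rate,
                feed={"cellobiose": feed},
                products=noisy,
                cell_carbon=cell_carbon,
                cell_nitrogen=spec.cell_nitrogen,
                metadata={"replicate": i, "seed": spec.seed},
            )
        )
    truth = GroundTruth(
        spec=spec,
        noise_free_concentrations=conc,
        feed_cellobiose=feed,
        co2=co2,
        cell_carbon=cell_carbon,
    )
    return conditions, truth


@dataclass
class FluxRecovery:
    """Estimated fluxes across replicates vs the injected truth."""

    estimates: pd.DataFrame  # replicates x species
    truth: Dict[str, float]

    @property
    def mean(self) -> pd.Series:
        return self.estimates.mean(axis=0)

    @property
    def sd(self) -> pd.Series:
        return self.estimates.std(axis=0, ddof=1) if len(self.estimates) > 1 else (
            self.estimates.iloc[0] * 0.0
        )

    @property
    def relative_error(self) -> pd.Series:
        truth = pd.Series(self.truth)
        err = (self.mean - truth).abs()
        nonzero = truth != 0
        rel = err.copy()
        rel[nonzero] = err[nonzero] / truth[nonzero]
        return rel

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "truth": pd.Series(self.truth),
                "mean": self.mean,
                "sd": self.sd,
                "relative_error": self.relative_error,
            }
        )


def recover_fluxes(
    conditions: List[ChemostatCondition],
    truth: GroundTruth,
    registry: Optional[CompoundRegistry] = None,
) -> FluxRecovery:
    """Re-estimate specific fluxes from generated replicates.

    Runs the ordinary flux computation on each replicate and compares
    the across-replicate mean with the generator's ground truth.
    """
    if not conditions:
        raise ValueError("need at least one replicate")
    reg = registry or default_registry()
    spec = truth.spec
    rows = []
    for cond in conditions:
        rows.append(
            {
                sp: fluxes.specific_flux(
                    cond.product(sp),
                    sp,
                    cond.dilution_rate,
                    cond.cell_nitrogen,
                    spec.convention,
                    reg,
                )
                for sp in spec.ground_truth_fluxes
            }
        )
    return FluxRecovery(
        estimates=pd.DataFrame(rows), truth=dict(spec.ground_truth_fluxes)
    )
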