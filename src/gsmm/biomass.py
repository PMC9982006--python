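"""Assemble a biomass pseudo-reaction from macromolecular mass fractions.

The biomass reaction consumes monomers (amino acids, nucleotides, lipids,
cell-wall precursors, small molecules) in mmol per gram dry weight and
produces one unit of a biomass pseudo-metabolite, so that its flux reads as
the specific growth rate mu (1/h). For each macromolecular class with mass
fraction f (g/gDW) and monomer mole fractions x_i with molecular weights
MW_i (g/mmol), the consumed coefficient of monomer i is

    coef_i = f * x_i / sum_j(x_j * MW_j)   [mmol/gDW]

which guarantees that the consumed monomer mass sums to exactly 1 g per gram
of biomass formed. Growth-associated ATP maintenance (GAM) adds
ATP + H2O -> ADP + Pi + H at the configured stoichiometry on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from gsmm.core import GprExpression, Reaction

MASS_TOLERANCE = 1e-6


class CompositionError(ValueError):
    """A macromolecular composition violates its mass-balance invariants."""


@dataclass
class MonomerSpec:
    """One monomer of a macromolecular class."""

    metabolite_key: str
    mole_fraction: float
    molecular_weight: float  # g/mmol


@dataclass
class MacromolecularComposition:
    """Mass fractions per class plus per-class monomer breakdowns.

    ``fractions`` maps class name (protein, rna, dna, lipid, cell_wall,
    small_molecules, ...) to its g/gDW mass fraction; fractions must sum to
    1 within 1e-6. ``monomers`` maps each class to its monomer list whose
    mole fractions each sum to 1. ``gam_atp`` is growth-associated ATP
    maintenance in mmol ATP per gDW.
    """

    fractions: dict[str, float]
    monomers: dict[str, list[MonomerSpec]]
    gam_atp: float = 0.0

    def validate(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > MASS_TOLERANCE:
            raise CompositionError(
                f"class mass fractions sum to {total:.6f}, expected 1"
            )
        for cls, frac in self.fractions.items():
            if frac < 0:
                raise CompositionError(f"negative mass fraction for {cls!r}")
            if cls not in self.monomers:
                raise CompositionError(f"class {cls!r} has no monomer table")
            mole_sum = sum(m.mole_fraction for m in self.monomers[cls])
            if abs(mole_sum - 1.0) > MASS_TOLERANCE:
                raise CompositionError(
                    f"class {cls!r}: monomer mole fractions sum to {mole_sum:.6f}"
                )
        if self.gam_atp < 0:
            raise CompositionError("GAM must be non-negative")


#: Metabolite keys the maintenance stoichiometry uses, resolvable through
#: the metabolite_map argument of build_biomass_reaction.
GAM_CONSUMED = ("atp", "h2o")
GAM_PRODUCED = ("adp", "pi", "h")


def build_biomass_reaction(
    composition: MacromolecularComposition,
    metabolite_map: Mapping[str, str],
    reaction_id: str = "BIOMASS",
    biomass_metabolite_id: Optional[str] = "biomass_c",
) -> Reaction:
    """Turn a composition into a mass-normalized biomass reaction.

    ``metabolite_map`` resolves monomer keys (and, when GAM > 0, the keys
    atp/adp/pi/h/h2o) to model metabolite ids. The reaction produces one
    unit of ``biomass_metabolite_id`` (skipped when set to None, for models
    that drain biomass directly).
    """
    composition.validate()
    missing = sorted(
        {
            m.metabolite_key
            for cls in composition.fractions
            for m in composition.monomers[cls]
            if m.metabolite_key not in metabolite_map
        }
    )
    if composition.gam_atp > 0:
        missing += sorted(
            k for k in GAM_CONSUMED + GAM_PRODUCED if k not in metabolite_map
        )
    if missing:
        raise CompositionError(f"unmapped monomer metabolites: {missing}")

    stoich: dict[str, float] = {}

    def add(met_id: str, coef: float) -> None:
        stoich[met_id] = stoich.get(met_id, 0.0) + coef

    for cls, frac in composition.fractions.items():
        if frac == 0.0:
            continue
        monomers = composition.monomers[cls]
        mean_mw = sum(m.mole_fraction * m.molecular_weight for m in monomers)
        if mean_mw <= 0:
            raise CompositionError(f"class {cls!r}: non-positive mean monomer MW")
        for m in monomers:
            if m.mole_fraction == 0.0:
                continue
            add(metabolite_map[m.metabolite_key], -frac * m.mole_fraction / mean_mw)

    if composition.gam_atp > 0:
        for key in GAM_CONSUMED:
            add(metabolite_map[key], -composition.gam_atp)
        for key in GAM_PRODUCED:
            add(metabolite_map[key], composition.gam_atp)

    if biomass_metabolite_id is not None:
        add(biomass_metabolite_id, 1.0)

    return Reaction(
        id=reaction_id,
        name="biomass assembly",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        gpr=GprExpression(),
        subsystem="Biomass",
    )


def streptomyces_like_composition() -> MacromolecularComposition:
    """A documented synthetic stand-in composition for testing.

    The fractions follow typical actinomycete biomass (protein-rich, heavy
    cell wall); the monomer tables are deliberately small. This is a
    synthetic fixture for exercising the assembly arithmetic, not a measured
    composition of any particular strain.
    """
    return MacromolecularComposition(
        fractions={
            "protein": 0.45,
            "rna": 0.10,
            "dna": 0.03,
            "lipid": 0.10,
            "cell_wall": 0.25,
            "small_molecules": 0.07,
        },
        monomers={
            "protein": [
                MonomerSpec("ala", 0.30, 0.0891),
                MonomerSpec("glu", 0.25, 0.1471),
                MonomerSpec("gly", 0.25, 0.0751),
                MonomerSpec("leu", 0.20, 0.1312),
            ],
            "rna": [
                MonomerSpec("amp", 0.25, 0.3472),
                MonomerSpec("gmp", 0.25, 0.3632),
                MonomerSpec("cmp", 0.25, 0.3232),
                MonomerSpec("ump", 0.25, 0.3242),
            ],
            "dna": [
                MonomerSpec("damp", 0.5, 0.3312),
                MonomerSpec("dtmp", 0.5, 0.3222),
            ],
            "lipid": [MonomerSpec("palmitate", 1.0, 0.2564)],
            "cell_wall": [MonomerSpec("peptido", 1.0, 1.0)],
            "small_molecules": [MonomerSpec("cofactor_pool", 1.0, 0.5)],
        },
        gam_atp=40.0,
    )
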