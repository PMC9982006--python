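"""Synthetic model and data generators.

Every analysis stage in the package gets a download-free, structurally
controlled input from here: a hand-solvable toy core model, a strain-design
testbed with planted up/down/knockout answers, phenotype fixtures with a
planted number of in-vivo/in-silico mismatches, and noisy logistic growth
series. Generators build networks from feasible pathway motifs (chains,
branches, cofactor loops) rather than random stoichiometry, because random
sparse S-matrices are almost surely infeasible; all are deterministic given
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from gsmm.core import GprExpression, MetabolicModel, Metabolite, Reaction
from gsmm.fba import fba
from gsmm.io import MediumDefinition, PhenotypeRecord
from gsmm.optforce import DOWN, KNOCKOUT, UP, FluxSpaceSpec


def _met(model: MetabolicModel, mid: str, compartment: str = "c") -> None:
    model.add_metabolite(Metabolite(id=mid, name=mid, compartment=compartment))


def _rxn(
    model: MetabolicModel,
    rid: str,
    stoich: dict[str, float],
    lb: float = 0.0,
    ub: float = 1000.0,
    gpr: str = "",
    subsystem: Optional[str] = None,
) -> None:
    model.add_reaction(
        Reaction(
            id=rid,
            name=rid,
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=GprExpression.from_string(gpr),
            subsystem=subsystem,
        )
    )


# ---------------------------------------------------------------------------
# Toy core model
# ---------------------------------------------------------------------------


def make_toy_core_model() -> tuple[MetabolicModel, MediumDefinition]:
    """Fixed 8-reaction network with a hand-derivable FBA optimum.

    Glucose uptake (bound 10 mmol/gDW/h) -> transport -> glycolysis-like
    split into 2 pyruvate -> biomass (3 pyruvate per unit) with an optional
    product branch. Maximum growth is therefore 10 * 2/3 = 20/3.
    """
    m = MetabolicModel(id="toy_core")
    for mid, comp in [
        ("glc_e", "e"),
        ("glc_c", "c"),
        ("pyr_c", "c"),
        ("prod_c", "c"),
        ("prod_e", "e"),
        ("biomass_c", "c"),
    ]:
        _met(m, mid, comp)
    _rxn(m, "EX_glc", {"glc_e": -1.0}, lb=-10.0, subsystem="Exchange")
    _rxn(m, "GLCt", {"glc_e": -1.0, "glc_c": 1.0}, gpr="g_transp",
         subsystem="Transport")
    _rxn(m, "GLY", {"glc_c": -1.0, "pyr_c": 2.0}, gpr="g_gly1 or g_gly2",
         subsystem="Central carbon")
    _rxn(m, "BIOMASS", {"pyr_c": -3.0, "biomass_c": 1.0}, subsystem="Biomass")
    _rxn(m, "EX_biomass", {"biomass_c": -1.0}, subsystem="Exchange")
    _rxn(m, "PROD", {"pyr_c": -1.0, "prod_c": 1.0}, gpr="g_prod",
         subsystem="Product")
    _rxn(m, "PRODt", {"prod_c": -1.0, "prod_e": 1.0}, subsystem="Transport")
    _rxn(m, "EX_prod", {"prod_e": -1.0}, subsystem="Exchange")
    m.objective_reaction_id = "BIOMASS"
    m.validate()
    medium = MediumDefinition(name="toy_glucose", exchanges={"EX_glc": (-10.0, 1000.0)})
    return m, medium


# ---------------------------------------------------------------------------
# Strain-design testbed
# ---------------------------------------------------------------------------


@dataclass
class TestbedSpec:
    """Parameters of the product-pathway testbed.

    The network routes glucose-derived acetyl-CoA either to the product
    (via an FPP-like precursor and an NADH-consuming synthase gated by a
    geoA analog) or to two biomass-feeding drains (a TCA-like branch, acnA
    analog, and a fatty-acid branch, fabD analog); an NADH oxidase (nuo
    analog) reoxidizes surplus NADH. The planted answer key is: synthase
    up, both drains down, oxidase knocked out.
    """

    __test__ = False  # keep pytest from collecting this dataclass

    seed: int = 0
    glucose_uptake: float = 10.0  # mmol/gDW/h
    nadh_per_product: float = 6.0  # NADH consumed per product; sets the
    # NADH-limited product maximum at 2*uptake/nadh_per_product
    tca_capacity: float = 1000.0
    fab_capacity: float = 1000.0
    product_capacity: float = 1000.0
    min_growth_fraction: float = 0.9  # wild-type growth bound

    def randomized(self) -> "TestbedSpec":
        """Seeded variation of drain capacities and NADH coupling that
        preserves the planted answer key (capacities stay above the level
        where the drains remain obligatory for wild-type growth)."""
        rng = np.random.default_rng(self.seed)
        return TestbedSpec(
            seed=self.seed,
            glucose_uptake=self.glucose_uptake,
            nadh_per_product=float(rng.choice([5.0, 6.0, 8.0])),
            tca_capacity=float(rng.uniform(5.0, 20.0)),
            fab_capacity=float(rng.uniform(5.0, 20.0)),
            product_capacity=self.product_capacity,
            min_growth_fraction=self.min_growth_fraction,
        )


@dataclass
class TestbedAnswerKey:
    directions: dict[str, str]  # reaction id -> planted direction
    gene_directions: dict[str, str]  # gene id -> planted direction
    product_exchange_id: str
    glucose_exchange_id: str


def make_geosmin_testbed(
    spec: Optional[TestbedSpec] = None,
) -> tuple[MetabolicModel, MediumDefinition, TestbedAnswerKey]:
    """Product-overproduction testbed with a planted intervention key.

    Stoichiometry (a = nadh_per_product, uptake u):

    * GLY:  glc + 2 nad -> 2 accoa + 2 nadh
    * FPPS: 3 accoa -> fpp
    * GEOS: fpp + a nadh -> product + a nad        (geoA analog, UP)
    * TCA:  accoa + 2 nad -> prec + 2 nadh         (acnA analog, DOWN)
    * FAB:  2 accoa + 2 nadh -> fa + 2 nad         (fabD analog, DOWN)
    * NUO:  nadh -> nad                            (nuo analog, KNOCKOUT)
    * BIOMASS: prec + fa -> biomass

    Biomass is NADH-neutral, so the product maximum is NADH-limited at
    2u/a while carbon remains in surplus; in any flux state achieving that
    maximum the oxidase flux is forced to zero, the drains are forced below
    the wild-type (growth >= 90% of maximum) level, and the synthase flux
    exceeds its wild-type maximum — which is exactly the planted key.
    """
    spec = spec or TestbedSpec()
    if spec.nadh_per_product <= 2.0:
        raise ValueError(
            "nadh_per_product must exceed 2 so the product maximum is "
            "NADH-limited; otherwise the planted knockout is not forced"
        )
    m = MetabolicModel(id=f"testbed_{spec.seed}")
    for mid, comp in [
        ("glc_e", "e"),
        ("glc_c", "c"),
        ("accoa_c", "c"),
        ("fpp_c", "c"),
        ("geo_c", "c"),
        ("geo_e", "e"),
        ("prec_c", "c"),
        ("fa_c", "c"),
        ("nadh_c", "c"),
        ("nad_c", "c"),
        ("biomass_c", "c"),
    ]:
        _met(m, mid, comp)
    u = spec.glucose_uptake
    a = spec.nadh_per_product
    _rxn(m, "EX_glc", {"glc_e": -1.0}, lb=-u, subsystem="Exchange")
    _rxn(m, "GLCt", {"glc_e": -1.0, "glc_c": 1.0}, gpr="g_pts",
         subsystem="Transport")
    _rxn(m, "GLY",
         {"glc_c": -1.0, "nad_c": -2.0, "accoa_c": 2.0, "nadh_c": 2.0},
         gpr="g_gly", subsystem="Central glycolysis")
    _rxn(m, "FPPS", {"accoa_c": -3.0, "fpp_c": 1.0}, gpr="g_fpps",
         subsystem="Terpenoid precursor")
    _rxn(m, "GEOS",
         {"fpp_c": -1.0, "nadh_c": -a, "geo_c": 1.0, "nad_c": a},
         ub=spec.product_capacity, gpr="g_geoA", subsystem="Geosmin synthesis")
    _rxn(m, "GEOt", {"geo_c": -1.0, "geo_e": 1.0}, subsystem="Transport")
    _rxn(m, "EX_geo", {"geo_e": -1.0}, subsystem="Exchange")
    _rxn(m, "TCA",
         {"accoa_c": -1.0, "nad_c": -2.0, "prec_c": 1.0, "nadh_c": 2.0},
         ub=spec.tca_capacity, gpr="g_acnA", subsystem="TCA cycle")
    _rxn(m, "FAB",
         {"accoa_c": -2.0, "nadh_c": -2.0, "fa_c": 1.0, "nad_c": 2.0},
         ub=spec.fab_capacity, gpr="g_fabD", subsystem="Fatty acid synthesis")
    _rxn(m, "NUO", {"nadh_c": -1.0, "nad_c": 1.0}, gpr="g_nuo",
         subsystem="Oxidative respiration")
    _rxn(m, "BIOMASS",
         {"prec_c": -1.0, "fa_c": -1.0, "biomass_c": 1.0},
         subsystem="Biomass")
    _rxn(m, "EX_biomass", {"biomass_c": -1.0}, subsystem="Exchange")
    m.objective_reaction_id = "BIOMASS"
    m.validate()
    medium = MediumDefinition(
        name=f"testbed_glucose_{spec.seed}", exchanges={"EX_glc": (-u, 1000.0)}
    )
    key = TestbedAnswerKey(
        directions={"GEOS": UP, "TCA": DOWN, "FAB": DOWN, "NUO": KNOCKOUT},
        gene_directions={
            "g_geoA": UP,
            "g_acnA": DOWN,
            "g_fabD": DOWN,
            "g_nuo": KNOCKOUT,
        },
        product_exchange_id="EX_geo",
        glucose_exchange_id="EX_glc",
    )
    return m, medium, key


def make_testbed_specs(
    model: MetabolicModel,
    medium: MediumDefinition,
    key: TestbedAnswerKey,
    min_growth_fraction: float = 0.9,
) -> tuple[FluxSpaceSpec, FluxSpaceSpec]:
    """Companion wild-type and overproduction flux-space specs.

    The wild type fixes glucose uptake at the medium rate and requires
    growth at >= ``min_growth_fraction`` of the maximum; the overproducer
    requires the product flux at its theoretical maximum (scaled by
    (1 - 1e-9) to absorb solver rounding), which is where the planted
    knockout becomes forced.
    """
    glc = key.glucose_exchange_id
    uptake = medium.exchanges[glc][0]
    fixed = {glc: (uptake, uptake)}

    snapshot = model.snapshot_bounds()
    try:
        medium.apply(model, strict=False)
        model.reactions[glc].lower_bound = uptake
        model.reactions[glc].upper_bound = uptake
        mu_max = fba(model).objective_value
        prod_max = fba(model, key.product_exchange_id).objective_value
    finally:
        model.restore_bounds(snapshot)

    wild = FluxSpaceSpec(
        name="wild_type",
        medium=medium,
        fixed_fluxes=fixed,
        min_growth=min_growth_fraction * mu_max,
    )
    over = FluxSpaceSpec(
        name="overproducer",
        medium=medium,
        fixed_fluxes=fixed,
        product_reaction_id=key.product_exchange_id,
        min_product_flux=prod_max * (1.0 - 1e-9),
    )
    return wild, over


# ---------------------------------------------------------------------------
# Phenotype fixtures
# ---------------------------------------------------------------------------


def make_phenotype_fixture(
    n_substrates: int,
    n_mismatches: int,
    seed: int = 0,
    role: str = "carbon",
) -> tuple[MetabolicModel, MediumDefinition, list[PhenotypeRecord]]:
    """Model plus phenotype table with exactly ``n_mismatches`` planted.

    Each substrate gets an exchange and transporter; a catabolic step into
    the biomass precursor pool exists only for substrates meant to grow.
    Mismatched substrates keep an in-vivo "+" call while their catabolic
    step is missing (the in-silico screen must call "-"), mirroring how a
    real reconstruction disagrees with plate data through pathway gaps.
    Roughly a quarter of the concordant substrates are true negatives
    (no pathway, in-vivo "-").
    """
    if not 0 <= n_mismatches <= n_substrates:
        raise ValueError("n_mismatches must lie in [0, n_substrates]")
    if role not in ("carbon", "nitrogen"):
        raise ValueError(f"unknown role {role!r}")
    rng = np.random.default_rng(seed)
    m = MetabolicModel(id=f"phenotypes_{role}_{seed}")
    _met(m, "pool_c")
    _met(m, "biomass_c")
    biomass_stoich = {"pool_c": -1.0, "biomass_c": 1.0}
    base_exchanges: dict[str, tuple[float, float]] = {}
    if role == "nitrogen":
        # glucose stays available as the carbon source; substrates feed the
        # nitrogen pool required by biomass alongside the carbon pool
        _met(m, "glc_e", "e")
        _met(m, "glc_c")
        _met(m, "npool_c")
        _rxn(m, "EX_glc", {"glc_e": -1.0}, lb=-10.0, subsystem="Exchange")
        _rxn(m, "GLCt", {"glc_e": -1.0, "glc_c": 1.0}, gpr="g_glct")
        _rxn(m, "GLC_CAT", {"glc_c": -1.0, "pool_c": 1.0}, gpr="g_glck")
        biomass_stoich = {"pool_c": -1.0, "npool_c": -1.0, "biomass_c": 1.0}
        base_exchanges["EX_glc"] = (-10.0, 1000.0)
    pool = "npool_c" if role == "nitrogen" else "pool_c"

    mismatch_idx = set(rng.choice(n_substrates, size=n_mismatches, replace=False))
    concordant = [i for i in range(n_substrates) if i not in mismatch_idx]
    n_neg = len(concordant) // 4
    negative_idx = set(concordant[:n_neg])

    records: list[PhenotypeRecord] = []
    for i in range(n_substrates):
        sub = f"sub{i:02d}"
        ex_id = f"EX_{sub}"
        _met(m, f"{sub}_e", "e")
        _met(m, f"{sub}_c")
        _rxn(m, ex_id, {f"{sub}_e": -1.0}, subsystem="Exchange")
        _rxn(m, f"T_{sub}", {f"{sub}_e": -1.0, f"{sub}_c": 1.0}, gpr=f"g_t{i}")
        has_pathway = i not in mismatch_idx and i not in negative_idx
        if has_pathway:
            _rxn(m, f"CAT_{sub}", {f"{sub}_c": -1.0, pool: 1.0}, gpr=f"g_c{i}")
        in_vivo = "-" if i in negative_idx else "+"
        records.append(
            PhenotypeRecord(
                substrate=sub,
                role=role,
                exchange_reaction_id=ex_id,
                in_vivo=in_vivo,
                reference="synthetic",
            )
        )
    m.add_reaction(
        Reaction(
            id="BIOMASS",
            name="biomass",
            stoichiometry=biomass_stoich,
            lower_bound=0.0,
            upper_bound=1000.0,
        )
    )
    _rxn(m, "EX_biomass", {"biomass_c": -1.0}, subsystem="Exchange")
    m.objective_reaction_id = "BIOMASS"
    m.validate()
    medium = MediumDefinition(name=f"base_{role}", exchanges=base_exchanges)
    return m, medium, records


# ---------------------------------------------------------------------------
# Growth series
# ---------------------------------------------------------------------------


def simulate_growth_series(
    K: float = 4.0,
    r: float = 0.15,
    X0: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
    times: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Logistic CDW series with multiplicative Gaussian noise.

    Defaults (K = 4 g/L, r = 0.15 1/h, X0 = 0.05 g/L over 72 h) emulate a
    slow filamentous batch culture. Returns (times_h, cdw_g_per_L).
    """
    if times is None:
        times = np.linspace(0.0, 72.0, 25)
    t = np.asarray(times, dtype=float)
    x = K / (1.0 + ((K - X0) / X0) * np.exp(-r * t))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x * (1.0 + rng.normal(0.0, noise_sd, size=t.shape))
        x = np.clip(x, 1e-9, None)
    return t, x
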