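"""OptForce-style identification of up/down/knockout engineering targets.

The procedure compares two flux spaces — the wild type (medium plus any
measured-flux constraints and a minimum growth) and a hypothetical
overproducer (the same constraints plus a minimum product flux) — by flux
variability analysis, and classifies reactions whose flux MUST change in
every overproducing state:

* MustU: the overproduction minimum exceeds the wild-type maximum — the
  flux must increase (upregulation candidates, e.g. the product synthase);
* MustL: the overproduction maximum falls below the wild-type minimum —
  the flux must decrease (downregulation candidates, e.g. competing
  drains);
* MustZero: the overproduction space forces the flux to zero while the
  wild-type range excludes zero (knockout candidates).

A greedy FORCE search then picks a minimal set of bound tightenings
(up: raise the lower bound to the wild-type maximum; down: cap the upper
bound at the wild-type minimum; knockout: close the reaction) that
guarantees the production target, verified by re-minimizing the product
flux over the modified space. Only first-order MUST sets are computed;
pairwise sets of the full algorithm are a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from gsmm.core import MetabolicModel
from gsmm.fba import InfeasibleProblemError, fba, fva
from gsmm.io import MediumDefinition

RANGE_TOLERANCE = 1e-6

UP = "upregulate"
DOWN = "downregulate"
KNOCKOUT = "knockout"

FUNCTIONAL_CLASSES = (
    "precursor_accumulation",
    "product_synthesis",
    "byproduct_elimination",
    "energy_supply",
)

#: Default subsystem-keyword rollup into the four functional classes.
_DEFAULT_CLASS_KEYWORDS = {
    "product_synthesis": ("geosmin", "terpenoid", "product"),
    "byproduct_elimination": ("tca", "citrate", "fatty", "drain", "byproduct"),
    "energy_supply": ("respiration", "oxidative", "energy", "nadh"),
    "precursor_accumulation": ("precursor", "glycolysis", "central"),
}


@dataclass
class FluxSpaceSpec:
    """Constraints carving one flux space out of the model's bounds."""

    name: str
    medium: Optional[MediumDefinition] = None
    fixed_fluxes: dict[str, tuple[float, float]] = field(default_factory=dict)
    min_growth: Optional[float] = None
    product_reaction_id: Optional[str] = None
    min_product_flux: Optional[float] = None

    def apply(self, model: MetabolicModel) -> None:
        """Impose the spec's constraints on the model bounds (in place)."""
        if self.medium is not None:
            self.medium.apply(model, strict=False)
        for rid, (lb, ub) in self.fixed_fluxes.items():
            model.reactions[rid].lower_bound = lb
            model.reactions[rid].upper_bound = ub
        if self.min_growth is not None:
            obj = model.objective_reaction_id
            model.reactions[obj].lower_bound = max(
                model.reactions[obj].lower_bound, self.min_growth
            )
        if self.min_product_flux is not None:
            rid = self.product_reaction_id
            if rid is None:
                raise ValueError(f"spec {self.name!r}: product flux set without id")
            model.reactions[rid].lower_bound = max(
                model.reactions[rid].lower_bound, self.min_product_flux
            )


@dataclass
class InterventionTarget:
    reaction_id: str
    gene_ids: tuple[str, ...]
    direction: str  # upregulate | downregulate | knockout
    wild_range: tuple[float, float]
    over_range: tuple[float, float]


@dataclass
class MustSets:
    must_u: list[InterventionTarget]
    must_l: list[InterventionTarget]
    must_zero: list[InterventionTarget]

    def all_targets(self) -> list[InterventionTarget]:
        return self.must_u + self.must_l + self.must_zero

    def reaction_ids(self) -> dict[str, str]:
        return {t.reaction_id: t.direction for t in self.all_targets()}


def _spec_fva(
    model: MetabolicModel,
    spec: FluxSpaceSpec,
    reaction_ids: Optional[Sequence[str]],
) -> dict[str, tuple[float, float]]:
    snapshot = model.snapshot_bounds()
    try:
        spec.apply(model)
        check = fba(model)
        if not check.optimal:
            if spec.min_product_flux is not None:
                # Name the theoretical maximum so the caller can fix the spec.
                model.restore_bounds(snapshot)
                relaxed = FluxSpaceSpec(
                    name=spec.name,
                    medium=spec.medium,
                    fixed_fluxes=spec.fixed_fluxes,
                    min_growth=spec.min_growth,
                )
                relaxed.apply(model)
                cap = fba(model, spec.product_reaction_id)
                cap_val = cap.objective_value if cap.optimal else float("nan")
                raise InfeasibleProblemError(
                    f"flux space {spec.name!r} is infeasible: product minimum "
                    f"{spec.min_product_flux} exceeds the theoretical maximum "
                    f"{cap_val:.6g}"
                )
            raise InfeasibleProblemError(f"flux space {spec.name!r} is infeasible")
        return fva(model, reaction_ids, fraction_of_optimum=0.0)
    finally:
        model.restore_bounds(snapshot)


def must_sets(
    model: MetabolicModel,
    wild_spec: FluxSpaceSpec,
    over_spec: FluxSpaceSpec,
    reaction_ids: Optional[Sequence[str]] = None,
    tol: float = RANGE_TOLERANCE,
) -> MustSets:
    """First-order MUST sets from wild-type vs overproduction flux ranges."""
    wild = _spec_fva(model, wild_spec, reaction_ids)
    over = _spec_fva(model, over_spec, reaction_ids)

    must_u: list[InterventionTarget] = []
    must_l: list[InterventionTarget] = []
    must_zero: list[InterventionTarget] = []
    for rid in wild:
        w_lo, w_hi = wild[rid]
        o_lo, o_hi = over[rid]
        genes = tuple(sorted(model.reactions[rid].gpr.genes()))
        target = lambda d: InterventionTarget(  # noqa: E731
            rid, genes, d, (w_lo, w_hi), (o_lo, o_hi)
        )
        forced_zero = abs(o_lo) <= tol and abs(o_hi) <= tol
        wild_excludes_zero = w_lo > tol or w_hi < -tol
        if forced_zero and wild_excludes_zero:
            must_zero.append(target(KNOCKOUT))
        elif o_lo > w_hi + tol:
            must_u.append(target(UP))
        elif o_hi < w_lo - tol:
            must_l.append(target(DOWN))
    return MustSets(must_u, must_l, must_zero)


@dataclass
class ForceSearchResult:
    intervention_sets: list[list[InterventionTarget]]
    achieved_min_product: float
    target: float

    @property
    def success(self) -> bool:
        return bool(self.intervention_sets)


def _tighten(model: MetabolicModel, t: InterventionTarget) -> None:
    rxn = model.reactions[t.reaction_id]
    if t.direction == UP:
        rxn.lower_bound = max(rxn.lower_bound, t.wild_range[1])
    elif t.direction == DOWN:
        rxn.upper_bound = min(rxn.upper_bound, t.wild_range[0])
    else:
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0


def _min_product(
    model: MetabolicModel,
    base_spec: FluxSpaceSpec,
    product_rid: str,
    interventions: Sequence[InterventionTarget],
) -> float:
    snapshot = model.snapshot_bounds()
    try:
        base_spec.apply(model)
        for t in interventions:
            _tighten(model, t)
        sol = fba(model, product_rid, direction="min")
        return sol.objective_value if sol.optimal else float("-inf")
    finally:
        model.restore_bounds(snapshot)


def force_set_search(
    model: MetabolicModel,
    sets: MustSets,
    wild_spec: FluxSpaceSpec,
    product_reaction_id: str,
    target_flux: float,
    max_interventions: int = 3,
) -> ForceSearchResult:
    """Greedy search for a FORCE set guaranteeing the production target.

    Candidates are the MUST-set members; each step picks the tightening
    with the largest marginal gain in the guaranteed (minimum) product
    flux, breaking ties by reaction id. The returned set is verified by
    re-minimizing the product flux under the tightened bounds.
    """
    if max_interventions < 1:
        raise ValueError("max_interventions must be at least 1")
    candidates = sets.all_targets()
    chosen: list[InterventionTarget] = []
    best_min = _min_product(model, wild_spec, product_reaction_id, chosen)
    while len(chosen) < max_interventions and best_min < target_flux:
        gains: list[tuple[float, str, InterventionTarget]] = []
        for cand in candidates:
            if any(c.reaction_id == cand.reaction_id for c in chosen):
                continue
            val = _min_product(
                model, wild_spec, product_reaction_id, chosen + [cand]
            )
            gains.append((val, cand.reaction_id, cand))
        if not gains:
            break
        # highest guaranteed product; ties broken by lexicographic reaction id
        gains.sort(key=lambda g: (-g[0], g[1]))
        val, _, cand = gains[0]
        if val <= best_min + RANGE_TOLERANCE and val < target_flux:
            break  # no candidate helps
        chosen.append(cand)
        best_min = val
    if best_min >= target_flux and chosen:
        verified = _min_product(model, wild_spec, product_reaction_id, chosen)
        assert verified >= target_flux - 1e-6
        return ForceSearchResult([chosen], verified, target_flux)
    return ForceSearchResult([], best_min, target_flux)


@dataclass
class GeneTarget:
    gene_id: str
    directions: tuple[str, ...]
    reactions: tuple[str, ...]
    conflicting: bool
    functional_class: Optional[str]


@dataclass
class GeneTargetReport:
    gene_targets: list[GeneTarget]
    non_genetic: list[InterventionTarget]
    counts: dict[str, int]


def _classify_subsystem(subsystem: Optional[str]) -> Optional[str]:
    if not subsystem:
        return None
    low = subsystem.lower()
    for cls, keywords in _DEFAULT_CLASS_KEYWORDS.items():
        if any(k in low for k in keywords):
            return cls
    return None


def targets_to_genes(
    interventions: Iterable[InterventionTarget],
    model: MetabolicModel,
    class_map: Optional[Mapping[str, str]] = None,
) -> GeneTargetReport:
    """Lift reaction-level interventions to a gene-level report.

    Genes inherit their reaction's direction; a gene hit with conflicting
    directions across reactions is flagged, never silently merged.
    Reactions with an empty GPR are reported as non-genetic targets
    (medium or process levers). Targets are grouped into four functional
    classes (precursor accumulation, product synthesis, by-product
    elimination, energy supply) from subsystem labels where possible;
    ``class_map`` overrides the keyword heuristic per subsystem.
    """
    per_gene: dict[str, dict[str, list[str]]] = {}
    gene_class: dict[str, Optional[str]] = {}
    non_genetic: list[InterventionTarget] = []
    for t in interventions:
        if not t.gene_ids:
            non_genetic.append(t)
            continue
        subsystem = model.reactions[t.reaction_id].subsystem
        if class_map and subsystem in class_map:
            fclass = class_map[subsystem]
        else:
            fclass = _classify_subsystem(subsystem)
        for gene in t.gene_ids:
            per_gene.setdefault(gene, {}).setdefault(t.direction, []).append(
                t.reaction_id
            )
            gene_class.setdefault(gene, fclass)

    gene_targets = []
    counts = {UP: 0, DOWN: 0, KNOCKOUT: 0, "conflicting": 0}
    for gene in sorted(per_gene):
        directions = tuple(sorted(per_gene[gene]))
        reactions = tuple(sorted({r for rs in per_gene[gene].values() for r in rs}))
        conflicting = len(directions) > 1
        gene_targets.append(
            GeneTarget(gene, directions, reactions, conflicting, gene_class[gene])
        )
        if conflicting:
            counts["conflicting"] += 1
        else:
            counts[directions[0]] += 1
    return GeneTargetReport(gene_targets, non_genetic, counts)
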