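"""Single-gene deletion analysis with three-class essentiality calls.

Deleting a gene disables every reaction whose GPR evaluates false without
it (AND = required complex subunit, OR = isozyme backup); the model is then
re-solved and the growth ratio mu_deleted / mu_wildtype classifies the gene:

* essential            ratio < 0.01
* partially essential  0.01 <= ratio < 0.5
* non-essential        ratio >= 0.5

The cutoffs are conventional, not measured, and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from gsmm.core import MetabolicModel
from gsmm.fba import fba
from gsmm.io import MediumDefinition

ESSENTIAL_CUTOFF = 0.01
PARTIAL_CUTOFF = 0.5

CLASS_ESSENTIAL = "essential"
CLASS_PARTIAL = "partially_essential"
CLASS_NON = "non_essential"


@dataclass
class DeletionOutcome:
    gene_id: str
    mu_deleted: float
    ratio: float
    essentiality_class: str
    error: Optional[str] = None


def classify_ratio(
    ratio: float,
    essential_cutoff: float = ESSENTIAL_CUTOFF,
    partial_cutoff: float = PARTIAL_CUTOFF,
) -> str:
    if ratio < essential_cutoff:
        return CLASS_ESSENTIAL
    if ratio < partial_cutoff:
        return CLASS_PARTIAL
    return CLASS_NON


def _delete_genes(model: MetabolicModel, genes: Iterable[str]) -> list[str]:
    """Zero the bounds of reactions losing catalysis; returns affected ids."""
    deleted = set(genes)
    disabled = []
    for rxn in model.reactions.values():
        if not rxn.gpr.is_empty and not rxn.gpr.evaluate(deleted):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
            disabled.append(rxn.id)
    return disabled


def growth_after_deletion(
    model: MetabolicModel,
    genes: Iterable[str],
    medium: Optional[MediumDefinition] = None,
) -> float:
    """Biomass optimum after deleting a gene set; bounds restored afterward."""
    snapshot = model.snapshot_bounds()
    try:
        if medium is not None:
            medium.apply(model, strict=False)
        _delete_genes(model, genes)
        sol = fba(model)
        return sol.objective_value if sol.optimal else 0.0
    finally:
        model.restore_bounds(snapshot)


def single_gene_deletion(
    model: MetabolicModel,
    gene_id: str,
    medium: Optional[MediumDefinition] = None,
    mu_wildtype: Optional[float] = None,
    essential_cutoff: float = ESSENTIAL_CUTOFF,
    partial_cutoff: float = PARTIAL_CUTOFF,
) -> DeletionOutcome:
    """Delete one gene and classify the resulting growth ratio."""
    if gene_id not in model.genes:
        raise KeyError(f"gene {gene_id!r} not in model gene set")
    if mu_wildtype is None:
        mu_wildtype = growth_after_deletion(model, (), medium)
    if mu_wildtype <= 0.0:
        raise ValueError(
            "wild-type growth is zero on this medium; essentiality undefined"
        )
    mu_del = growth_after_deletion(model, {gene_id}, medium)
    ratio = mu_del / mu_wildtype
    return DeletionOutcome(
        gene_id=gene_id,
        mu_deleted=mu_del,
        ratio=ratio,
        essentiality_class=classify_ratio(ratio, essential_cutoff, partial_cutoff),
    )


def classify_all_genes(
    model: MetabolicModel,
    medium: Optional[MediumDefinition] = None,
    essential_cutoff: float = ESSENTIAL_CUTOFF,
    partial_cutoff: float = PARTIAL_CUTOFF,
) -> tuple[list[DeletionOutcome], dict[str, int]]:
    """Delete each gene in turn; returns outcomes (sorted by gene id) and
    per-class counts. Per-gene solver failures are recorded on the outcome,
    not raised."""
    mu_wt = growth_after_deletion(model, (), medium)
    if mu_wt <= 0.0:
        raise ValueError(
            "wild-type growth is zero on this medium; essentiality undefined"
        )
    outcomes: list[DeletionOutcome] = []
    counts = {CLASS_ESSENTIAL: 0, CLASS_PARTIAL: 0, CLASS_NON: 0}
    for gene in sorted(model.genes):
        try:
            out = single_gene_deletion(
                model, gene, medium, mu_wt, essential_cutoff, partial_cutoff
            )
        except Exception as exc:  # pragma: no cover - defensive per-gene guard
            out = DeletionOutcome(gene, 0.0, 0.0, CLASS_ESSENTIAL, error=str(exc))
        outcomes.append(out)
        counts[out.essentiality_class] += 1
    return outcomes, counts


def match_reference_essentials(
    predicted: Iterable[str],
    reference_map: Mapping[str, bool],
) -> float:
    """Percent of predicted essential genes confirmed by a reference mapping.

    The mapping (gene id -> matched) is user-supplied, e.g. precomputed
    sequence-similarity hits against an essential-gene database. Predicted
    genes absent from the mapping count as unmatched (with a warning).
    """
    predicted = sorted(set(predicted))
    if not predicted:
        raise ValueError("empty predicted essential-gene set")
    import warnings

    matched = 0
    for gene in predicted:
        if gene not in reference_map:
            warnings.warn(f"gene {gene!r} missing from reference map; counted unmatched")
        elif reference_map[gene]:
            matched += 1
    return round(100.0 * matched / len(predicted), 1)
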