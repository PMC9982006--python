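"""Domain types for stoichiometric models and gene-protein-reaction logic.

A model is a set of metabolites, a set of reactions with flux bounds in
mmol/gDW/h, a gene set tied to reactions through boolean GPR expressions
(AND = complex subunits, OR = isozymes), and one objective reaction whose
flux is read as the specific growth rate mu in 1/h when it is the biomass
pseudo-reaction.

Sign conventions, used everywhere in the package:

* stoichiometric coefficients: negative = consumed, positive = produced;
* exchange reactions carry exactly one metabolite, negative flux = uptake,
  positive flux = secretion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Union

from scipy import sparse

DEFAULT_LOWER_BOUND = -1000.0
DEFAULT_UPPER_BOUND = 1000.0


class ModelStructureError(ValueError):
    """A model violates a structural invariant (dangling ids, bad bounds...)."""


class GprParseError(ValueError):
    """A GPR association string could not be parsed."""


# ---------------------------------------------------------------------------
# GPR boolean trees
# ---------------------------------------------------------------------------

#: Internal tree node: a gene id (leaf) or ("and"|"or", [children]).
GprNode = Union[str, tuple]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


@dataclass(frozen=True)
class GprExpression:
    """Boolean gene association tree.

    ``root`` is ``None`` for an empty association (spontaneous or orphan
    reaction): such a reaction is never disabled by gene deletions, which is
    the convention that makes the gene-associated fraction computable as the
    complement of empty-GPR reactions.
    """

    root: Optional[GprNode] = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> set[str]:
        """All distinct gene ids appearing as leaves."""
        out: set[str] = set()

        def walk(node: GprNode) -> None:
            if isinstance(node, str):
                out.add(node)
            else:
                for child in node[1]:
                    walk(child)

        if self.root is not None:
            walk(self.root)
        return out

    def evaluate(self, deleted_genes: Iterable[str] = ()) -> bool:
        """True iff the reaction remains catalyzed after deleting the genes."""
        deleted = set(deleted_genes)

        def walk(node: GprNode) -> bool:
            if isinstance(node, str):
                return node not in deleted
            op, children = node
            if op == "and":
                return all(walk(c) for c in children)
            return any(walk(c) for c in children)

        if self.root is None:
            return True
        return walk(self.root)

    def to_string(self) -> str:
        def walk(node: GprNode) -> str:
            if isinstance(node, str):
                return node
            op, children = node
            joined = f" {op} ".join(walk(c) for c in children)
            return f"({joined})"

        if self.root is None:
            return ""
        s = walk(self.root)
        # strip the outermost parentheses for readability
        if s.startswith("(") and s.endswith(")"):
            return s[1:-1]
        return s

    @classmethod
    def from_string(cls, text: str) -> "GprExpression":
        """Parse ``"g1 and (g2 or g3)"`` style association strings.

        ``and``/``or`` are case-insensitive; AND binds tighter than OR when
        unparenthesized.
        """
        if text is None or not text.strip():
            return cls(None)
        tokens = _TOKEN_RE.findall(text)
        pos = 0

        def peek() -> Optional[str]:
            return tokens[pos] if pos < len(tokens) else None

        def take() -> str:
            nonlocal pos
            tok = tokens[pos]
            pos += 1
            return tok

        def parse_or() -> GprNode:
            terms = [parse_and()]
            while peek() is not None and peek().lower() == "or":
                take()
                terms.append(parse_and())
            return terms[0] if len(terms) == 1 else ("or", terms)

        def parse_and() -> GprNode:
            factors = [parse_atom()]
            while peek() is not None and peek().lower() == "and":
                take()
                factors.append(parse_atom())
            return factors[0] if len(factors) == 1 else ("and", factors)

        def parse_atom() -> GprNode:
            tok = peek()
            if tok is None:
                raise GprParseError(f"unexpected end of GPR string: {text!r}")
            if tok == "(":
                take()
                node = parse_or()
                if peek() != ")":
                    raise GprParseError(f"unbalanced parentheses in {text!r}")
                take()
                return node
            if tok == ")" or tok.lower() in ("and", "or"):
                raise GprParseError(f"unexpected token {tok!r} in {text!r}")
            return take()

        root = parse_or()
        if pos != len(tokens):
            raise GprParseError(f"trailing tokens in GPR string {text!r}")
        return cls(root)


def evaluate_gpr(gpr: GprExpression, deleted_genes: Iterable[str] = ()) -> bool:
    """Functional form of :meth:`GprExpression.evaluate`."""
    return gpr.evaluate(deleted_genes)


# ---------------------------------------------------------------------------
# Metabolites and reactions
# ---------------------------------------------------------------------------


class ReactionKind(str, Enum):
    BIOCHEMICAL = "biochemical"
    TRANSPORT = "transport"
    EXCHANGE = "exchange"


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None
    charge: Optional[int] = None


@dataclass
class Reaction:
    """A (possibly reversible) flux with stoichiometry and gene association."""

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = DEFAULT_LOWER_BOUND
    upper_bound: float = DEFAULT_UPPER_BOUND
    gpr: GprExpression = field(default_factory=GprExpression)
    subsystem: Optional[str] = None
    kind: Optional[ReactionKind] = None

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelStructureError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelStructureError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)


def infer_kind(reaction: Reaction, metabolites: Mapping[str, Metabolite]) -> ReactionKind:
    """Classify a reaction as exchange / transport / biochemical.

    Exchange: touches exactly one metabolite (a system boundary).
    Transport: spans more than one compartment.
    Biochemical: everything else.
    """
    if reaction.is_exchange:
        return ReactionKind.EXCHANGE
    compartments = {
        metabolites[m].compartment for m in reaction.stoichiometry if m in metabolites
    }
    if len(compartments) > 1:
        return ReactionKind.TRANSPORT
    return ReactionKind.BIOCHEMICAL


# ---------------------------------------------------------------------------
# The model container
# ---------------------------------------------------------------------------


@dataclass
class MetabolicModel:
    id: str = "model"
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    genes: set[str] = field(default_factory=set)
    compartments: dict[str, str] = field(default_factory=dict)
    objective_reaction_id: Optional[str] = None
    genome_orf_count: Optional[int] = None

    # -- construction helpers ------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelStructureError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        self.compartments.setdefault(met.compartment, met.compartment)
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelStructureError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ModelStructureError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
        if rxn.kind is None:
            rxn.kind = infer_kind(rxn, self.metabolites)
        self.reactions[rxn.id] = rxn
        self.genes |= rxn.gpr.genes()
        return rxn

    # -- views ---------------------------------------------------------------

    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind == ReactionKind.EXCHANGE]

    def reactions_for_gene(self, gene_id: str) -> list[Reaction]:
        return [r for r in self.reactions.values() if gene_id in r.gpr.genes()]

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ModelStructureError` on any broken invariant."""
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelStructureError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelStructureError(f"reaction {rxn.id!r} has inverted bounds")
            if rxn.kind == ReactionKind.EXCHANGE and len(rxn.stoichiometry) != 1:
                raise ModelStructureError(
                    f"exchange reaction {rxn.id!r} touches "
                    f"{len(rxn.stoichiometry)} metabolites"
                )
        if self.objective_reaction_id is not None:
            if self.objective_reaction_id not in self.reactions:
                raise ModelStructureError(
                    f"objective reaction {self.objective_reaction_id!r} not in model"
                )
        gpr_genes = set()
        for rxn in self.reactions.values():
            gpr_genes |= rxn.gpr.genes()
        if not gpr_genes <= self.genes:
            missing = sorted(gpr_genes - self.genes)
            raise ModelStructureError(f"GPR leaves not in gene set: {missing}")

    # -- bound bookkeeping (used by every analysis that perturbs the model) --

    def snapshot_bounds(self) -> dict[str, tuple[float, float]]:
        return {rid: r.bounds() for rid, r in self.reactions.items()}

    def restore_bounds(self, snapshot: Mapping[str, tuple[float, float]]) -> None:
        for rid, (lb, ub) in snapshot.items():
            self.reactions[rid].lower_bound = lb
            self.reactions[rid].upper_bound = ub


# ---------------------------------------------------------------------------
# Stoichiometric matrix and model statistics
# ---------------------------------------------------------------------------


def build_stoichiometric_matrix(model: MetabolicModel) -> sparse.csr_matrix:
    """S matrix: rows = metabolites, columns = reactions, in insertion order.

    Entry (i, j) is the signed coefficient of metabolite i in reaction j;
    structural zeros are absent from the sparse representation.
    """
    met_index = {mid: i for i, mid in enumerate(model.metabolites)}
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    for j, rxn in enumerate(model.reactions.values()):
        for met_id, coef in rxn.stoichiometry.items():
            if met_id not in met_index:
                raise ModelStructureError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
            if coef != 0.0:
                rows.append(met_index[met_id])
                cols.append(j)
                data.append(float(coef))
    return sparse.csr_matrix(
        (data, (rows, cols)),
        shape=(len(model.metabolites), len(model.reactions)),
    )


@dataclass
class ModelStats:
    """Headline counts and coverage percentages for a model."""

    n_reactions: int
    n_metabolites: int
    n_genes: int
    n_biochemical: int
    n_transport: int
    n_exchange: int
    frac_gene_associated: float
    orf_coverage: Optional[float]
    subsystem_distribution: dict[str, float]


def orf_coverage(n_genes: int, genome_orf_count: int) -> float:
    """Percent of genomic ORFs included in the model, to one decimal."""
    if genome_orf_count <= 0:
        raise ValueError("genome ORF count must be positive")
    return round(100.0 * n_genes / genome_orf_count, 1)


def model_summary(model: MetabolicModel) -> ModelStats:
    """Count reactions/metabolites/genes and coverage statistics.

    ``frac_gene_associated`` counts reactions with a non-empty GPR over all
    reactions (exchanges included). ``orf_coverage`` is ``None`` — reported
    as unavailable, never as zero — when the genome ORF count is unset.
    """
    n_rxn = len(model.reactions)
    n_assoc = sum(1 for r in model.reactions.values() if not r.gpr.is_empty)
    kinds = {k: 0 for k in ReactionKind}
    sub_counts: dict[str, int] = {}
    for r in model.reactions.values():
        kind = r.kind or infer_kind(r, model.metabolites)
        kinds[kind] += 1
        if r.subsystem:
            sub_counts[r.subsystem] = sub_counts.get(r.subsystem, 0) + 1
    coverage = None
    if model.genome_orf_count is not None:
        coverage = orf_coverage(len(model.genes), model.genome_orf_count)
    return ModelStats(
        n_reactions=n_rxn,
        n_metabolites=len(model.metabolites),
        n_genes=len(model.genes),
        n_biochemical=kinds[ReactionKind.BIOCHEMICAL],
        n_transport=kinds[ReactionKind.TRANSPORT],
        n_exchange=kinds[ReactionKind.EXCHANGE],
        frac_gene_associated=round(100.0 * n_assoc / n_rxn, 1) if n_rxn else 0.0,
        orf_coverage=coverage,
        subsystem_distribution={
            s: round(100.0 * c / n_rxn, 1) for s, c in sorted(sub_counts.items())
        },
    )
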