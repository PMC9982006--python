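"""Readers and writers for models, media, phenotype tables and flux reports.

Supported formats:

* SBML Level 3 with the flux-balance-constraints (fbc) package — bounds,
  objective and gene associations;
* a versioned JSON model dialect (schema ``gsmm-model-1``), the package's
  canonical interchange form (ids, stoichiometry maps, GPR as nested
  arrays);
* TSV phenotype tables (columns: substrate, role, exchange_id, in_vivo,
  reference);
* YAML medium configs (exchange reaction id -> [lower, upper] bounds in
  mmol/gDW/h);
* CSV flux reports.

Bounds absent in input default to (-1000, 1000) for reversible reactions
and (0, 1000) for irreversible ones, the usual COBRA convention.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import libsbml
import yaml

from gsmm.core import (
    DEFAULT_LOWER_BOUND,
    DEFAULT_UPPER_BOUND,
    GprExpression,
    GprNode,
    MetabolicModel,
    Metabolite,
    ModelStructureError,
    Reaction,
)
from gsmm.fba import FluxSolution

JSON_SCHEMA_VERSION = "gsmm-model-1"

PathLike = Union[str, Path]


class TableFormatError(ValueError):
    """A tabular input file violates the documented layout."""


# ---------------------------------------------------------------------------
# Phenotype tables and media
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeRecord:
    """One substrate row of a sole-source utilization table."""

    substrate: str
    role: str  # "carbon" | "nitrogen"
    exchange_reaction_id: str
    in_vivo: str  # "+" | "-"
    reference: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("carbon", "nitrogen"):
            raise TableFormatError(
                f"substrate {self.substrate!r}: unknown role {self.role!r}"
            )
        if self.in_vivo not in ("+", "-"):
            raise TableFormatError(
                f"substrate {self.substrate!r}: growth call must be '+' or '-', "
                f"got {self.in_vivo!r}"
            )


@dataclass
class MediumDefinition:
    """Named set of exchange bounds defining a culture medium."""

    name: str
    exchanges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, (lb, ub) in self.exchanges.items():
            if lb > ub:
                raise ModelStructureError(
                    f"medium {self.name!r}: bounds for {rid!r} are inverted"
                )

    def apply(self, model: MetabolicModel, strict: bool = True) -> None:
        """Close every exchange, then open the ones listed in the medium."""
        unknown = [rid for rid in self.exchanges if rid not in model.reactions]
        if unknown and strict:
            candidates = sorted(r.id for r in model.exchanges())
            raise KeyError(
                f"medium {self.name!r} references unknown exchanges {unknown}; "
                f"model exchanges are {candidates}"
            )
        for rxn in model.exchanges():
            rxn.lower_bound = 0.0
            rxn.upper_bound = DEFAULT_UPPER_BOUND
        for rid, (lb, ub) in self.exchanges.items():
            if rid in model.reactions:
                model.reactions[rid].lower_bound = lb
                model.reactions[rid].upper_bound = ub


_CALL_SYMBOLS = {"+": "+", "-": "-", "−": "-", "–": "-"}

_PHENOTYPE_COLUMNS = ["substrate", "role", "exchange_id", "in_vivo", "reference"]


def read_phenotype_table(path: PathLike) -> list[PhenotypeRecord]:
    """Parse a TSV phenotype table into records; strict about +/- symbols."""
    path = Path(path)
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise TableFormatError(f"{path}: empty phenotype table")
        missing = [c for c in _PHENOTYPE_COLUMNS[:4] if c not in reader.fieldnames]
        if missing:
            raise TableFormatError(f"{path}: missing columns {missing}")
        records: list[PhenotypeRecord] = []
        for lineno, row in enumerate(reader, start=2):
            call = (row["in_vivo"] or "").strip()
            if call not in _CALL_SYMBOLS:
                raise TableFormatError(
                    f"{path}:{lineno}: bad growth call {call!r} (expected + or -)"
                )
            try:
                records.append(
                    PhenotypeRecord(
                        substrate=row["substrate"].strip(),
                        role=row["role"].strip().lower(),
                        exchange_reaction_id=row["exchange_id"].strip(),
                        in_vivo=_CALL_SYMBOLS[call],
                        reference=(row.get("reference") or "").strip(),
                    )
                )
            except TableFormatError as exc:
                raise TableFormatError(f"{path}:{lineno}: {exc}") from exc
    if not records:
        raise TableFormatError(f"{path}: phenotype table has no data rows")
    return records


def write_phenotype_table(records: list[PhenotypeRecord], path: PathLike) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_PHENOTYPE_COLUMNS)
        for r in records:
            writer.writerow(
                [r.substrate, r.role, r.exchange_reaction_id, r.in_vivo, r.reference]
            )


def read_medium(path: PathLike) -> MediumDefinition:
    with Path(path).open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "exchanges" not in doc:
        raise TableFormatError(f"{path}: medium config needs an 'exchanges' map")
    exchanges = {}
    for rid, bb in doc["exchanges"].items():
        lb, ub = float(bb[0]), float(bb[1])
        exchanges[str(rid)] = (lb, ub)
    return MediumDefinition(name=str(doc.get("name", Path(path).stem)), exchanges=exchanges)


def write_medium(medium: MediumDefinition, path: PathLike) -> None:
    doc = {
        "name": medium.name,
        "exchanges": {rid: [lb, ub] for rid, (lb, ub) in medium.exchanges.items()},
    }
    with Path(path).open("w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def write_flux_report(
    solution: FluxSolution, model: MetabolicModel, path: PathLike
) -> None:
    """CSV of reaction id, name, flux for every reaction in the model."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["reaction_id", "name", "flux"])
        for rid, rxn in model.reactions.items():
            writer.writerow([rid, rxn.name, repr(solution.fluxes.get(rid, 0.0))])


# ---------------------------------------------------------------------------
# JSON model dialect
# ---------------------------------------------------------------------------


def _gpr_to_json(gpr: GprExpression):
    def walk(node: GprNode):
        if isinstance(node, str):
            return node
        op, children = node
        return [op, [walk(c) for c in children]]

    return None if gpr.root is None else walk(gpr.root)


def _gpr_from_json(obj) -> GprExpression:
    def walk(node) -> GprNode:
        if isinstance(node, str):
            return node
        op, children = node
        if op not in ("and", "or"):
            raise TableFormatError(f"bad GPR operator {op!r}")
        return (op, [walk(c) for c in children])

    return GprExpression(None if obj is None else walk(obj))


def write_json_model(model: MetabolicModel, path: PathLike) -> None:
    doc = {
        "schema": JSON_SCHEMA_VERSION,
        "id": model.id,
        "genome_orf_count": model.genome_orf_count,
        "compartments": dict(model.compartments),
        "objective": model.objective_reaction_id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": _gpr_to_json(r.gpr),
                "subsystem": r.subsystem,
            }
            for r in model.reactions.values()
        ],
    }
    with Path(path).open("w") as fh:
        json.dump(doc, fh, indent=1)


def read_json_model(path: PathLike) -> MetabolicModel:
    with Path(path).open() as fh:
        doc = json.load(fh)
    if doc.get("schema") != JSON_SCHEMA_VERSION:
        raise TableFormatError(
            f"{path}: unsupported model schema {doc.get('schema')!r} "
            f"(expected {JSON_SCHEMA_VERSION!r})"
        )
    model = MetabolicModel(
        id=doc.get("id", "model"),
        genome_orf_count=doc.get("genome_orf_count"),
        objective_reaction_id=doc.get("objective"),
    )
    model.compartments.update(doc.get("compartments", {}))
    for m in doc["metabolites"]:
        model.add_metabolite(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula"),
                charge=m.get("charge"),
            )
        )
    for r in doc["reactions"]:
        model.add_reaction(
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", DEFAULT_LOWER_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_UPPER_BOUND)),
                gpr=_gpr_from_json(r.get("gpr")),
                subsystem=r.get("subsystem"),
            )
        )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML (Level 3 + fbc)
# ---------------------------------------------------------------------------


def _check(value, message: str):
    if value is None:
        raise RuntimeError(f"libsbml returned None: {message}")
    if isinstance(value, int) and value != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise RuntimeError(f"libsbml error {value}: {message}")
    return value


def _gpr_to_association(gpr: GprExpression, fbc_rxn) -> None:
    def render(node: GprNode) -> str:
        if isinstance(node, str):
            return node
        op, children = node
        return "(" + f" {op} ".join(render(c) for c in children) + ")"

    gpa = fbc_rxn.createGeneProductAssociation()
    _check(
        gpa.setAssociation(render(gpr.root), True, True),
        "setAssociation",
    )


def write_sbml(model: MetabolicModel, path: PathLike) -> None:
    """Serialize to SBML Level 3 Version 1 with the fbc v2 package."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for cid, cname in (model.compartments or {"c": "c"}).items():
        comp = sbml_model.createCompartment()
        comp.setId(cid)
        comp.setName(str(cname))
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if met.formula:
            splug.setChemicalFormula(met.formula)
        if met.charge is not None:
            splug.setCharge(int(met.charge))

    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(gene)
        gp.setLabel(gene)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(float(value))
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        sr = sbml_model.createReaction()
        sr.setId(rxn.id)
        sr.setName(rxn.name)
        sr.setFast(False)
        sr.setReversible(rxn.lower_bound < 0)
        if rxn.subsystem:
            sr.setNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>SUBSYSTEM: {rxn.subsystem}</p></body>"
            )
        for met_id, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if not rxn.gpr.is_empty:
            _gpr_to_association(rxn.gpr, rplug)

    if model.objective_reaction_id is not None:
        objective = mplug.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        flux_obj = objective.createFluxObjective()
        flux_obj.setReaction(model.objective_reaction_id)
        flux_obj.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise RuntimeError(f"could not write SBML to {path}")


def _association_to_gpr(assoc) -> GprNode:
    if isinstance(assoc, libsbml.GeneProductRef):
        gp = assoc.getGeneProduct()
        return gp
    if isinstance(assoc, libsbml.FbcAnd):
        return ("and", [_association_to_gpr(assoc.getAssociation(i))
                        for i in range(assoc.getNumAssociations())])
    if isinstance(assoc, libsbml.FbcOr):
        return ("or", [_association_to_gpr(assoc.getAssociation(i))
                       for i in range(assoc.getNumAssociations())])
    raise ModelStructureError(f"unsupported GPR association node {assoc}")


def read_sbml(path: PathLike) -> MetabolicModel:
    """Load an SBML file, mapping fbc bounds/objective/GPR onto domain types.

    Constructs the package does not model (events, rules, kinetic laws) are
    reported as warnings, never silently dropped.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise TableFormatError(f"{path}: SBML parse errors: {msgs[:3]}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise TableFormatError(f"{path}: no model element in SBML file")
    for attr, label in (
        ("getNumEvents", "events"),
        ("getNumRules", "rules"),
        ("getNumConstraints", "constraints"),
    ):
        n = getattr(sbml_model, attr)()
        if n:
            warnings.warn(f"{path}: {n} SBML {label} ignored (not modeled)")

    model = MetabolicModel(id=sbml_model.getId() or "model")
    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        model.compartments[comp.getId()] = comp.getName() or comp.getId()

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        model.add_metabolite(
            Metabolite(
                id=sp.getId(),
                name=sp.getName(),
                compartment=sp.getCompartment() or "c",
                formula=formula,
                charge=charge,
            )
        )

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }
    objective_id = None
    mplug = sbml_model.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives() > 0:
        active = mplug.getActiveObjective() or mplug.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            objective_id = active.getFluxObjective(0).getReaction()

    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        lb = DEFAULT_LOWER_BOUND if sr.getReversible() else 0.0
        ub = DEFAULT_UPPER_BOUND
        gpr = GprExpression()
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params[rplug.getLowerFluxBound()]
            if rplug.isSetUpperFluxBound():
                ub = params[rplug.getUpperFluxBound()]
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                try:
                    gpr = GprExpression(_association_to_gpr(gpa.getAssociation()))
                except ModelStructureError as exc:
                    raise TableFormatError(
                        f"{path}: reaction {sr.getId()!r}: {exc}"
                    ) from exc
        subsystem = None
        if sr.isSetNotes():
            notes = sr.getNotesString()
            marker = "SUBSYSTEM:"
            if marker in notes:
                frag = notes.split(marker, 1)[1]
                subsystem = frag.split("<", 1)[0].strip()
        model.add_reaction(
            Reaction(
                id=sr.getId(),
                name=sr.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                subsystem=subsystem,
            )
        )
    model.objective_reaction_id = objective_id
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Convenience: load either dialect by extension
# ---------------------------------------------------------------------------


def read_model(path: PathLike) -> MetabolicModel:
    path = Path(path)
    if path.suffix.lower() in (".xml", ".sbml"):
        return read_sbml(path)
    if path.suffix.lower() == ".json":
        return read_json_model(path)
    raise TableFormatError(f"{path}: unknown model format {path.suffix!r}")
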