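"""Sole carbon/nitrogen source growth screening and agreement scoring.

The screen mimics plate-based utilization tests in silico: starting from a
minimal base medium, all exchanges supplying the screened element are
closed, the candidate substrate's exchange is opened to a fixed uptake
rate, and growth is called "+" when the FBA biomass optimum clears a small
threshold. Carbon screens close every carbon exchange except the candidate;
nitrogen screens keep glucose as the carbon source and close all other
nitrogen exchanges. Amino-acid substrates screened as carbon sources keep
the nitrogen they carry available, matching how sole-carbon growth tests
are read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from gsmm.core import MetabolicModel
from gsmm.fba import fba
from gsmm.io import MediumDefinition, PhenotypeRecord

DEFAULT_UPTAKE_RATE = 10.0  # mmol/gDW/h
DEFAULT_GROWTH_THRESHOLD = 1e-6  # 1/h


@dataclass
class SubstrateCall:
    substrate: str
    role: str
    in_vivo: str
    in_silico: str  # "+" | "-" | "?" when the exchange is missing
    mu: Optional[float]
    error: Optional[str] = None

    @property
    def agrees(self) -> Optional[bool]:
        if self.in_silico == "?":
            return None
        return self.in_vivo == self.in_silico


@dataclass
class ScreenResult:
    """Per-substrate calls plus the aggregated agreement score."""

    calls: list[SubstrateCall]
    n_agree: int
    n_total: int
    accuracy: float  # percent, one decimal
    discordant: list[str] = field(default_factory=list)


def screen_sole_source(
    model: MetabolicModel,
    base_medium: MediumDefinition,
    record: PhenotypeRecord,
    uptake_rate: float = DEFAULT_UPTAKE_RATE,
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
    role_exchanges: Optional[Iterable[str]] = None,
) -> SubstrateCall:
    """Predict growth on one substrate as the sole source of its element.

    ``role_exchanges`` lists every exchange reaction able to supply the
    screened element (carbon or nitrogen); all of them except the candidate
    are closed for the solve. Model bounds are restored afterward, so
    screening is order-independent and side-effect free.
    """
    rid = record.exchange_reaction_id
    if rid not in model.reactions:
        return SubstrateCall(
            substrate=record.substrate,
            role=record.role,
            in_vivo=record.in_vivo,
            in_silico="?",
            mu=None,
            error=f"exchange reaction {rid!r} not in model",
        )
    snapshot = model.snapshot_bounds()
    try:
        base_medium.apply(model, strict=False)
        if role_exchanges is not None:
            for other in role_exchanges:
                if other != rid and other in model.reactions:
                    model.reactions[other].lower_bound = 0.0
        model.reactions[rid].lower_bound = -abs(uptake_rate)
        sol = fba(model)
        mu = sol.objective_value if sol.optimal else 0.0
        call = "+" if mu is not None and mu >= growth_threshold else "-"
        return SubstrateCall(
            substrate=record.substrate,
            role=record.role,
            in_vivo=record.in_vivo,
            in_silico=call,
            mu=mu,
        )
    finally:
        model.restore_bounds(snapshot)


def screen_table(
    model: MetabolicModel,
    base_medium: MediumDefinition,
    records: Sequence[PhenotypeRecord],
    role: Optional[str] = None,
    uptake_rate: float = DEFAULT_UPTAKE_RATE,
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
) -> ScreenResult:
    """Screen every record of a phenotype table and score the agreement.

    Exchanges of substrates sharing the screened role are treated as the
    role's supply set: each solve closes the other candidates so the
    substrate under test is the sole source.
    """
    selected = [r for r in records if role is None or r.role == role]
    by_role: dict[str, list[str]] = {}
    for r in selected:
        by_role.setdefault(r.role, []).append(r.exchange_reaction_id)
    calls = [
        screen_sole_source(
            model,
            base_medium,
            rec,
            uptake_rate=uptake_rate,
            growth_threshold=growth_threshold,
            role_exchanges=by_role[rec.role],
        )
        for rec in selected
    ]
    return compare_predictions(selected, [c.in_silico for c in calls], calls)


def compare_predictions(
    table: Sequence[PhenotypeRecord],
    calls: Sequence[str],
    call_objects: Optional[Sequence[SubstrateCall]] = None,
) -> ScreenResult:
    """Score in-silico calls against the table's in-vivo column.

    Accuracy is 100 * agreements / records, reported to one decimal; the
    discordant substrates are listed by name.
    """
    if len(table) != len(calls):
        raise ValueError(
            f"{len(calls)} calls supplied for {len(table)} table records"
        )
    if call_objects is None:
        call_objects = [
            SubstrateCall(
                substrate=rec.substrate,
                role=rec.role,
                in_vivo=rec.in_vivo,
                in_silico=call,
                mu=None,
            )
            for rec, call in zip(table, calls)
        ]
    n_total = len(table)
    n_agree = sum(1 for rec, call in zip(table, calls) if rec.in_vivo == call)
    discordant = [
        rec.substrate for rec, call in zip(table, calls) if rec.in_vivo != call
    ]
    accuracy = round(100.0 * n_agree / n_total, 1) if n_total else 0.0
    return ScreenResult(
        calls=list(call_objects),
        n_agree=n_agree,
        n_total=n_total,
        accuracy=accuracy,
        discordant=discordant,
    )
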