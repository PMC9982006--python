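"""End-to-end pipeline: summary -> screen -> essentiality -> robustness ->
strain design, with deterministic, config-stamped report files.

Each stage writes one TSV/JSON report into the output directory; a failure
in one stage is recorded in the run summary and later independent stages
still run. No stage mutates the loaded model persistently (bounds are
snapshot/restored around every analysis).
"""

from __future__ import annotations

import csv
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import gsmm
from gsmm.core import MetabolicModel, model_summary
from gsmm.essentiality import classify_all_genes
from gsmm.fba import fba, robustness_analysis
from gsmm.io import MediumDefinition, read_medium, read_model, read_phenotype_table
from gsmm.netstats import network_report
from gsmm.optforce import FluxSpaceSpec, force_set_search, must_sets, targets_to_genes
from gsmm.screen import screen_table


@dataclass
class RunConfig:
    """Canonical run configuration; every analysis knob is recorded here."""

    model_path: str
    medium_path: Optional[str] = None
    phenotype_table_path: Optional[str] = None
    control_reaction_id: Optional[str] = None
    product_reaction_id: Optional[str] = None
    uptake_rate: float = 10.0
    growth_threshold: float = 1e-6
    essential_cutoff: float = 0.01
    partial_cutoff: float = 0.5
    robustness_points: int = 20
    growth_fraction: float = 0.9
    product_fraction: float = 0.5
    max_interventions: int = 3
    seed: int = 0
    output_dir: str = "gsmm_run"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _model_hash(model: MetabolicModel) -> str:
    payload = json.dumps(
        {
            rid: [sorted(r.stoichiometry.items()), r.bounds(), r.gpr.to_string()]
            for rid, r in model.reactions.items()
        },
        sort_keys=True,
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns the machine-readable summary."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "version": gsmm.__version__}

    model = read_model(config.model_path)
    medium = read_medium(config.medium_path) if config.medium_path else None
    if medium is not None:
        medium.apply(model, strict=False)
    hash_before = _model_hash(model)

    summary: dict = {"stamp": stamp, "stages": {}, "errors": {}}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                summary["stages"][name] = fn()
            except Exception as exc:
                summary["errors"][name] = f"{type(exc).__name__}: {exc}"
            summary.setdefault("wall_time_s", {})[name] = round(
                time.perf_counter() - t0, 3
            )
            return fn

        return deco

    @stage("model_summary")
    def _summary():
        stats = model_summary(model)
        net = network_report(model)
        path = outdir / "model_summary.tsv"
        with path.open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["metric", "value"])
            for k, v in {**asdict(stats), **asdict(net)}.items():
                if k != "subsystem_distribution":
                    w.writerow([k, v])
            for sub, pct in stats.subsystem_distribution.items():
                w.writerow([f"subsystem_pct:{sub}", pct])
            w.writerow(["config_hash", stamp["config_hash"]])
            w.writerow(["version", stamp["version"]])
        return {"n_reactions": stats.n_reactions, "report": path.name}

    @stage("growth")
    def _growth():
        sol = fba(model)
        return {"status": sol.status.value, "mu_max": sol.objective_value}

    if config.phenotype_table_path:

        @stage("screen")
        def _screen():
            records = read_phenotype_table(config.phenotype_table_path)
            base = medium or MediumDefinition(name="closed", exchanges={})
            res = screen_table(
                model,
                base,
                records,
                uptake_rate=config.uptake_rate,
                growth_threshold=config.growth_threshold,
            )
            path = outdir / "screen.tsv"
            with path.open("w", newline="") as fh:
                w = csv.writer(fh, delimiter="\t")
                w.writerow(
                    ["substrate", "role", "in_vivo", "in_silico", "mu", "config_hash"]
                )
                for c in res.calls:
                    w.writerow(
                        [c.substrate, c.role, c.in_vivo, c.in_silico, c.mu,
                         stamp["config_hash"]]
                    )
            return {
                "accuracy": res.accuracy,
                "n_agree": res.n_agree,
                "n_total": res.n_total,
                "report": path.name,
            }

    @stage("essentiality")
    def _ess():
        outcomes, counts = classify_all_genes(
            model, medium, config.essential_cutoff, config.partial_cutoff
        )
        path = outdir / "essentiality.tsv"
        with path.open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["gene", "mu_deleted", "ratio", "class", "config_hash"])
            for o in outcomes:
                w.writerow(
                    [o.gene_id, repr(o.mu_deleted), repr(o.ratio),
                     o.essentiality_class, stamp["config_hash"]]
                )
        return {"counts": counts, "report": path.name}

    if config.control_reaction_id:

        @stage("robustness")
        def _rob():
            curve = robustness_analysis(
                model,
                config.control_reaction_id,
                n_points=config.robustness_points,
                objective_reaction_id=config.product_reaction_id,
            )
            path = outdir / "robustness.csv"
            with path.open("w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["control_flux", "objective_flux"])
                for cv, ov in zip(curve.control_values, curve.objective_values):
                    w.writerow([repr(cv), repr(ov)])
            return {"plateau_onset": curve.plateau_onset, "report": path.name}

    if config.product_reaction_id:

        @stage("strain_design")
        def _design():
            glc_fixed = {}
            mu = fba(model)
            if not mu.optimal or mu.objective_value <= 0:
                raise RuntimeError("no growth; strain design undefined")
            prod_max = fba(model, config.product_reaction_id).objective_value
            wild = FluxSpaceSpec(
                name="wild_type",
                fixed_fluxes=glc_fixed,
                min_growth=config.growth_fraction * mu.objective_value,
            )
            over = FluxSpaceSpec(
                name="overproducer",
                fixed_fluxes=glc_fixed,
                product_reaction_id=config.product_reaction_id,
                min_product_flux=config.product_fraction * prod_max,
            )
            sets = must_sets(model, wild, over)
            base = FluxSpaceSpec(name="engineering", fixed_fluxes=glc_fixed)
            search = force_set_search(
                model,
                sets,
                base,
                config.product_reaction_id,
                config.product_fraction * prod_max,
                max_interventions=config.max_interventions,
            )
            report = targets_to_genes(sets.all_targets(), model)
            path = outdir / "strain_design.tsv"
            with path.open("w", newline="") as fh:
                w = csv.writer(fh, delimiter="\t")
                w.writerow(
                    ["reaction", "genes", "direction", "wild_range", "over_range"]
                )
                for t in sets.all_targets():
                    w.writerow(
                        [t.reaction_id, ";".join(t.gene_ids), t.direction,
                         t.wild_range, t.over_range]
                    )
            return {
                "n_must_u": len(sets.must_u),
                "n_must_l": len(sets.must_l),
                "n_must_zero": len(sets.must_zero),
                "gene_counts": report.counts,
                "force_found": search.success,
                "report": path.name,
            }

    hash_after = _model_hash(model)
    summary["model_hash_stable"] = hash_before == hash_after
    with (outdir / "run_summary.json").open("w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
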