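"""End-to-end pipeline: config validation, stage orchestration, reporting.

A single declarative YAML config drives the run; every threshold and the
seed are echoed into the run report so a run is reproducible from its
artefacts alone.  Identical config + seed gives identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import data_model as dm
from . import diffmeth, epigenetic_age, expression_integration, genomic_context
from .data_model import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_all"]

_THRESHOLD_BOUNDS = {
    "q_max": (0.0, 1.0),
    "delta_min": (0.0, 1.0),
    "distinct_q": (0.0, 1.0),
    "welch_p": (0.0, 1.0),
    "integration_q": (0.0, 1.0),
    "expr_delta_min": (0.0, None),
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (paths, thresholds, stage toggles)."""

    # input paths (None disables the dependent stage)
    beta_matrix: str | None = None
    sample_sheet: str | None = None
    annotation: str | None = None
    blacklist: str | None = None
    clock: str | None = None
    expression: str | None = None
    gene_probe_map: str | None = None
    age_predictive_probes: str | None = None
    # thresholds
    q_max: float = 0.05
    delta_min: float = 0.1
    distinct_q: float = 0.01
    welch_p: float = 0.001
    integration_q: float = 0.01
    expr_delta_min: float = 0.1
    permutations: int = 50
    seed: int = 0
    # stage toggles
    simulate: bool = False
    run_context: bool = True
    run_clock: bool = True
    run_integration: bool = True
    # output
    out_dir: str = "methagesig_out"

    def validate(self) -> None:
        problems = []
        for name, (lo, hi) in _THRESHOLD_BOUNDS.items():
            v = getattr(self, name)
            if not isinstance(v, (int, float)):
                problems.append(f"{name} must be numeric, got {v!r}")
            elif (v <= lo) if name != "expr_delta_min" else (v < lo):
                problems.append(f"{name}={v} out of range")
            elif hi is not None and v > hi:
                problems.append(f"{name}={v} out of range (max {hi})")
        if self.permutations < 1:
            problems.append("permutations must be ≥ 1")
        if not self.simulate:
            if self.beta_matrix is None or self.sample_sheet is None:
                problems.append("beta_matrix and sample_sheet required unless simulate=true")
            for name in ("beta_matrix", "sample_sheet", "annotation", "blacklist",
                         "clock", "expression", "gene_probe_map", "age_predictive_probes"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    problems.append(f"{name}: path {p!r} does not exist")
            if self.run_clock and self.clock is None:
                problems.append("run_clock=true but no clock file given")
            if self.run_integration and (self.expression is None or self.gene_probe_map is None):
                problems.append("run_integration=true requires expression and gene_probe_map")
            if self.run_context and self.annotation is None:
                problems.append("run_context=true but no annotation given")
        if problems:
            raise ValidationError("invalid configuration:\n  " + "\n  ".join(problems))


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys and bad values are
    reported all at once."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValidationError(f"unknown config key(s): {unknown}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


@dataclass
class RunReport:
    """Machine-readable per-stage counts plus threshold and seed echo."""

    counts: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    seed: int = 0
    warnings: list = field(default_factory=list)
    stage_results: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "counts": self.counts,
                "thresholds": self.thresholds,
                "seed": self.seed,
                "warnings": self.warnings,
                "stage_results": self.stage_results,
            },
            indent=2,
            default=str,
        )

    def summary(self) -> str:
        lines = ["methagesig run report", "=" * 21]
        lines.append(f"seed: {self.seed}")
        lines += [f"{k}: {v}" for k, v in self.thresholds.items()]
        lines.append("-" * 21)
        lines += [f"{k}: {v}" for k, v in self.counts.items()]
        if self.warnings:
            lines.append("warnings:")
            lines += [f"  - {w}" for w in self.warnings]
        return "\n".join(lines)


def _write_table(df: pd.DataFrame, path: Path, provenance: dict) -> None:
    with open(path, "w") as fh:
        for key, value in provenance.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t")


def _write_signature(sig, path: Path) -> None:
    with open(path, "w") as fh:
        for key, value in sorted(sig.provenance.items()):
            fh.write(f"# {key}: {value}\n")
        for probe in sorted(sig.probe_ids):
            fh.write(probe + "\n")


def run_all(cfg: PipelineConfig, sim_config=None) -> RunReport:
    """Execute (optional simulate →) filter → signatures → context → clock
    → integration, writing all stage outputs under ``cfg.out_dir``.

    ``sim_config`` (a :class:`~methagesig.synthetic_data.SimulationConfig`)
    overrides the default synthetic-cohort parameters when
    ``cfg.simulate`` is set; its seed is forced to ``cfg.seed``.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=cfg.seed)
    report.thresholds = {
        k: getattr(cfg, k)
        for k in ("q_max", "delta_min", "distinct_q", "welch_p",
                  "integration_q", "expr_delta_min", "permutations")
    }

    stage = "inputs"
    try:
        if cfg.simulate:
            stage = "simulate"
            from .synthetic_data import (
                SimulationConfig,
                simulate_clock,
                simulate_expression,
                simulate_methylation,
            )

            sim = sim_config if sim_config is not None else SimulationConfig()
            sim.seed = cfg.seed
            bm, sheet, ann, truth = simulate_methylation(sim)
            clock = simulate_clock(sim)
            em, gene_map = simulate_expression(bm, truth, seed=cfg.seed)
            dm.write_beta_matrix(bm, out / "beta_matrix.tsv")
            dm.write_sample_sheet(sheet, out / "sample_sheet.csv")
            dm.write_probe_annotation(ann, out / "annotation.csv")
            truth.to_csv(out / "truth_table.csv")
            epigenetic_age.write_clock(clock, out / "clock.csv")
            dm.write_expression_matrix(em, out / "expression.tsv")
            gene_map.to_csv(out / "gene_probe_map.csv", index=False)
        else:
            bm = dm.read_beta_matrix(cfg.beta_matrix)
            sheet = dm.read_sample_sheet(cfg.sample_sheet)
            if "group" not in sheet.data.columns:
                sheet = dm.assign_groups(sheet)
            ann = dm.read_probe_annotation(cfg.annotation) if cfg.annotation else None
            clock = epigenetic_age.read_clock(cfg.clock) if cfg.clock else None
            em = dm.read_expression_matrix(cfg.expression) if cfg.expression else None
            gene_map = (
                dm.read_gene_probe_map(cfg.gene_probe_map) if cfg.gene_probe_map else None
            )

        stage = "filter"
        if cfg.blacklist:
            blacklist = dm.read_blacklist(cfg.blacklist)
            n_before = bm.shape[0]
            bm = dm.filter_probes(bm, blacklist)
            report.counts["n_probes_blacklisted"] = n_before - bm.shape[0]
        exclude = (
            dm.read_blacklist(cfg.age_predictive_probes)
            if cfg.age_predictive_probes
            else None
        )
        report.counts["samples_per_group"] = {
            g: len(sheet.samples_in_group(g)) for g in ("BCVY", "BCO", "NVY", "NO")
        }

        stage = "signatures"
        sig_result = diffmeth.run_signature_pipeline(
            bm, sheet, q_max=cfg.q_max, delta_min=cfg.delta_min,
            distinct_q=cfg.distinct_q, exclude_probes=exclude,
        )
        report.counts.update(sig_result.counts)
        for name, table in sig_result.contrasts.items():
            _write_table(table, out / f"contrast_{name}.tsv", dict(table.attrs))
        for sig in (sig_result.global_signature, sig_result.specific_pool,
                    sig_result.distinctive_signature):
            _write_signature(sig, out / f"signature_{sig.name}.txt")
        chi2, p = diffmeth.subtype_balance_test(sheet)
        report.stage_results["subtype_balance"] = {"chi2": chi2, "p": p}

        if cfg.run_context and ann is not None:
            stage = "context"
            results = sig_result.contrasts["bcvy_vs_bco_global"]
            for sig in (sig_result.global_signature, sig_result.distinctive_signature):
                if not len(sig):
                    report.warnings.append(f"context skipped for empty {sig.name}")
                    continue
                summary = genomic_context.categorize(sig, ann, results, cfg.welch_p)
                _write_table(summary.set_index("category"),
                             out / f"context_{sig.name}.tsv", dict(summary.attrs))
                split = genomic_context.platform_split(sig, ann)
                _write_table(split.set_index("category"),
                             out / f"platform_{sig.name}.tsv", {})
            if len(sig_result.distinctive_signature):
                clust = genomic_context.cluster_samples(
                    bm.subset_probes(sig_result.distinctive_signature.probe_ids), sheet
                )
                (out / "sample_tree.nwk").write_text(clust.newick + "\n")
                report.stage_results["clustering_agreement"] = clust.agreement

        if cfg.run_clock and clock is not None:
            stage = "clock"
            tumour = sheet.samples_in_group(("BCVY", "BCO"))
            dnam = epigenetic_age.predict_dnam_age(bm.subset_samples(tumour), clock)
            est, comparison = epigenetic_age.age_acceleration(dnam, sheet)
            _write_table(est.set_index("sample_id"), out / "age_estimates.tsv",
                         {"adult_age": clock.adult_age})
            report.stage_results["age_acceleration"] = comparison

        if cfg.run_integration and em is not None and gene_map is not None:
            stage = "integration"
            meth = sig_result.contrasts["bcvy_vs_bco_global"]
            sig_probes = sig_result.global_signature.probe_ids | \
                sig_result.distinctive_signature.probe_ids
            gm = gene_map[gene_map["probe_id"].isin(sig_probes)]
            if len(gm) == 0:
                report.warnings.append("integration skipped: no genes map to significant probes")
            else:
                integ = expression_integration.integrate(
                    meth, em, sheet, gm, q_max=cfg.integration_q,
                    expr_delta_min=cfg.expr_delta_min,
                    permutations=cfg.permutations, seed=cfg.seed,
                )
                _write_table(integ, out / "integration.tsv", dict(integ.attrs))
                report.counts["n_genes_tested"] = int(len(integ))
                report.counts["n_genes_retained"] = int(integ["retained"].sum())
    except Exception as exc:  # partial outputs stay on disk with a marker
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise ValidationError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "run_report.json").write_text(report.to_json() + "\n")
    (out / "run_report.txt").write_text(report.summary() + "\n")
    return report
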