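"""Staged pipeline: simulate → count → retention / events / expression.

A single structured config drives all stages; every ambiguous analysis
choice (strandedness, filter layer, test sidedness, event counting mode)
is a named key with a documented default. Outputs are TSV files plus a
manifest recording the config hash, seed and output checksums, so reruns
with an identical config are verifiably identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import counting, events as events_mod, expression, retention, simulate
from .annotation import read_gene_models
from .counting import CountMatrix, build_count_matrix, count_sample
from .design import SampleDesign, default_design, validate_design
from .simulate import SimulationConfig

log = logging.getLogger(__name__)

STAGES = ("simulate", "count", "retention", "events", "expression")


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    outdir: str = "spliceburden_out"
    seed: int = 0
    annotation: str | None = None  # external GTF; None = use simulated one
    alignments: dict[str, str] = field(default_factory=dict)  # sample_id -> SAM
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    design: list[dict] = field(default_factory=list)  # rows; empty = default 4x3
    protocol: str = "reverse"
    filter_layer: str = "exonic"
    pseudocount: float = 0.0
    retention_conditions: tuple[str, str] = ("Ccis", "Dcis")
    alternative: str = "two-sided"
    n_strata: int = 0  # 0 disables stratification
    event_mode: str = "placement"
    event_conditions: tuple[str, str] = ("Ccis", "Dcis")
    expression_genes: list[str] = field(default_factory=list)
    expression_conditions: tuple[str, str] = ("C", "Ccis")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(raw) - known)
        if bad:
            raise PipelineConfigError(f"unknown config keys: {bad}")
        for key in ("retention_conditions", "event_conditions", "expression_conditions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def build_design(self) -> list[SampleDesign]:
        if not self.design:
            return default_design()
        rows = [SampleDesign(**row) for row in self.design]
        validate_design(rows)
        return rows

    def build_simulation_config(self) -> SimulationConfig:
        sim = dict(self.simulation)
        sim.setdefault("seed", self.seed)
        if "include_presets" in sim:
            sim["include_presets"] = tuple(sim["include_presets"])
        known = {f.name for f in dataclasses.fields(SimulationConfig)}
        bad = sorted(set(sim) - known)
        if bad:
            raise PipelineConfigError(f"unknown simulation keys: {bad}")
        return SimulationConfig(**sim)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def save_count_matrix(matrix: CountMatrix, outdir: str) -> list[str]:
    paths = []
    for layer in ("exonic", "genic"):
        path = os.path.join(outdir, f"counts_{layer}.tsv")
        pd.DataFrame(
            getattr(matrix, layer), index=matrix.genes, columns=matrix.samples
        ).rename_axis("gene_id").to_csv(path, sep="\t")
        paths.append(path)
    return paths


def load_count_matrix(outdir: str, design: Sequence[SampleDesign]) -> CountMatrix:
    frames = {}
    for layer in ("exonic", "genic"):
        path = os.path.join(outdir, f"counts_{layer}.tsv")
        if not os.path.exists(path):
            raise PipelineConfigError(
                f"missing {path}; run the 'count' stage first"
            )
        frames[layer] = pd.read_csv(path, sep="\t", index_col="gene_id")
    ex = frames["exonic"]
    return CountMatrix(
        list(ex.index), list(ex.columns), ex.to_numpy(), frames["genic"].to_numpy(),
        [d for d in design if d.sample_id in set(ex.columns)],
    )


def run(config: PipelineConfig, stages: Sequence[str] = STAGES) -> dict:
    """Run the requested stages in dependency order; return the manifest."""
    unknown = sorted(set(stages) - set(STAGES))
    if unknown:
        raise PipelineConfigError(f"unknown stages: {unknown}")
    stages = [s for s in STAGES if s in set(stages)]
    os.makedirs(config.outdir, exist_ok=True)
    design = config.build_design()
    outputs: list[str] = []
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    def record(stage: str, paths: list[str], t0: float) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}
        outputs.extend(paths)
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

    gtf_path = config.annotation or os.path.join(config.outdir, "annotation.gtf")
    sam_paths = dict(config.alignments)

    if "simulate" in stages:
        t0 = time.time()
        sim_cfg = config.build_simulation_config()
        ann = simulate.simulate_annotation(sim_cfg)
        gtf_path = os.path.join(config.outdir, "annotation.gtf")
        with open(gtf_path, "w") as fh:
            fh.write(ann.gtf)
        result = simulate.simulate_alignments(ann, sim_cfg, design, config.outdir)
        sam_paths = result.sam_paths
        truth_paths = []
        for name, df in (
            ("truth_genes", result.truth.genes),
            ("truth_events", result.truth.events),
            ("truth_samples", result.truth.samples),
        ):
            p = os.path.join(config.outdir, f"{name}.tsv")
            df.to_csv(p, sep="\t", index=False)
            truth_paths.append(p)
        record("simulate", [gtf_path, *sam_paths.values(), *truth_paths], t0)

    if not sam_paths:
        sam_paths = {
            d.sample_id: os.path.join(config.outdir, f"{d.sample_id}.sam")
            for d in design
        }

    needs_genes = {"count", "events"} & set(stages)
    genes = None
    if needs_genes:
        if not os.path.exists(gtf_path):
            raise PipelineConfigError(
                f"annotation {gtf_path} not found; run the 'simulate' stage first "
                "or point 'annotation' at a GTF"
            )
        with open(gtf_path) as fh:
            genes = read_gene_models(fh)

    if "count" in stages:
        t0 = time.time()
        per_sample = []
        reasons_rows = []
        from .annotation import GeneIndex

        index = GeneIndex(genes)
        for d in design:
            path = sam_paths[d.sample_id]
            if not os.path.exists(path):
                raise PipelineConfigError(
                    f"missing alignments {path}; run the 'simulate' stage first"
                )
            sc = count_sample(path, genes, config.protocol, d.sample_id, index)
            per_sample.append(sc)
            for layer, tallies in sc.reasons.items():
                for reason, n in tallies.items():
                    reasons_rows.append(
                        {"sample_id": d.sample_id, "layer": layer,
                         "reason": reason, "n": n}
                    )
        matrix = build_count_matrix(per_sample, design)
        paths = save_count_matrix(matrix, config.outdir)
        rpath = os.path.join(config.outdir, "count_reasons.tsv")
        pd.DataFrame(reasons_rows).to_csv(rpath, sep="\t", index=False)
        record("count", [*paths, rpath], t0)

    if "retention" in stages:
        t0 = time.time()
        matrix = load_count_matrix(config.outdir, design)
        filtered, report = retention.filter_genes(matrix, config.filter_layer)
        ratios = retention.gene_ratio_table(filtered, design, config.pseudocount)
        cm = retention.condition_means(ratios, design)
        a, b = config.retention_conditions
        test = retention.paired_retention_test(cm, a, b, config.alternative)
        totals = retention.global_totals(filtered, design, a, b)
        paths = []
        p = os.path.join(config.outdir, "retention_ratios.tsv")
        ratios.join(cm.add_prefix("mean_")).to_csv(p, sep="\t")
        paths.append(p)
        rows = [
            {"comparison": f"{b}_vs_{a}", "stratum": "all", "n_genes": test.n_pairs,
             "statistic": test.statistic, "p_value": test.p_value,
             "median_difference": test.median_difference, "method": test.method}
        ]
        if config.n_strata > 1:
            for sr in retention.stratify_by_expression(
                ratios, filtered, design, a, b, config.n_strata
            ):
                if sr.result is None:
                    continue
                rows.append(
                    {"comparison": f"{b}_vs_{a}", "stratum": sr.stratum,
                     "n_genes": sr.result.n_pairs,
                     "statistic": sr.result.statistic,
                     "p_value": sr.result.p_value,
                     "median_difference": sr.result.median_difference,
                     "method": sr.result.method}
                )
        p = os.path.join(config.outdir, "retention_tests.tsv")
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        paths.append(p)
        p = os.path.join(config.outdir, "retention_totals.tsv")
        totals.per_sample.assign(
            t_statistic=totals.t_statistic, p_value=totals.p_value
        ).to_csv(p, sep="\t", index=False)
        paths.append(p)
        p = os.path.join(config.outdir, "retention_discard.tsv")
        pd.DataFrame(
            [{"n_input": report.n_input, "n_flagged": report.n_flagged,
              "n_zero": report.n_zero, "n_retained": report.n_retained,
              "fraction_flagged": report.fraction_flagged,
              "fraction_zero": report.fraction_zero}]
        ).to_csv(p, sep="\t", index=False)
        paths.append(p)
        record("retention", paths, t0)

    if "events" in stages:
        t0 = time.time()
        evs = events_mod.enumerate_events(genes)
        counts_by_sample = {}
        for d in design:
            path = sam_paths[d.sample_id]
            if not os.path.exists(path):
                raise PipelineConfigError(
                    f"missing alignments {path}; run the 'simulate' stage first"
                )
            counts_by_sample[d.sample_id] = events_mod.count_event_support(
                path, evs, d.sample_id
            )
        sim_cfg = config.build_simulation_config()
        psi_df = events_mod.psi_table(
            counts_by_sample, evs, genes,
            read_length=sim_cfg.read_length,
            fragment_length=int(round(sim_cfg.fragment_length_mean)),
            mode=config.event_mode,
        )
        a, b = config.event_conditions
        comparison = events_mod.compare_events(psi_df, design, a, b)
        summary = events_mod.category_summary(comparison)
        paths = []
        for name, df in (
            ("events_psi", psi_df),
            ("events_comparison", comparison),
            ("events_summary", summary),
        ):
            p = os.path.join(config.outdir, f"{name}.tsv")
            df.to_csv(p, sep="\t", index=False)
            paths.append(p)
        record("events", paths, t0)

    if "expression" in stages:
        t0 = time.time()
        matrix = load_count_matrix(config.outdir, design)
        counts = pd.DataFrame(
            matrix.exonic, index=matrix.genes, columns=matrix.samples
        )
        factors = expression.size_factors(counts)
        paths = []
        p = os.path.join(config.outdir, "size_factors.tsv")
        factors.rename_axis("sample_id").to_csv(p, sep="\t")
        paths.append(p)
        a, b = config.expression_conditions
        rows = []
        for gene in config.expression_genes or list(counts.index[:1]):
            if gene not in counts.index:
                log.warning("gene %s absent from counts; skipped", gene)
                continue
            fc = expression.fold_change(counts, factors, gene, a, b, design)
            ir = expression.interaction_ratio(counts, factors, gene, design)
            rows.append(
                {"gene_id": gene, "condition_a": a, "condition_b": b,
                 "mean_a": fc.mean_a, "mean_b": fc.mean_b, "fold": fc.fold,
                 "interaction_ratio": ir}
            )
        p = os.path.join(config.outdir, "fold_changes.tsv")
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        paths.append(p)
        record("expression", paths, t0)

    manifest["outputs"] = {
        os.path.relpath(p, config.outdir): _checksum(p) for p in sorted(set(outputs))
    }
    mpath = os.path.join(config.outdir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
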