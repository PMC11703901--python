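"""End-to-end orchestration: normalize -> stepwise enrich -> swarm infer ->
edge analysis -> drivers -> differential drivers.

One YAML config drives all stages; every stochastic step derives its seeds
from the single mandatory global seed, so a re-run with the same config
reproduces every output bit for bit.  A manifest records input/output
checksums, the resolved config, package versions and per-stage wall time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, replace

import yaml

from ._util import derive_seeds
from .ann import MLPConfig
from .drivers import differential_drivers, driver_scores
from .network import (
    export_network,
    filter_by_gene,
    summarize_distribution,
    to_edge_list,
    top_k_edges,
)
from .preprocess import (
    minmax_normalize,
    read_expression,
    read_gene_set,
    write_expression,
    write_gene_set,
)
from .stepwise import enrich_pathway
from .swarm import SwarmConfig, infer_network

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "load_config", "validate_config",
           "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, artifacts: list[str]):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.artifacts = artifacts


_STEPWISE_DEFAULTS = {
    "top_k": 10,
    "repetitions": 10,
    "mccv_iterations": 50,
    "max_epochs": 3000,
    "patience_epochs": 1000,
    "mse_improvement_threshold": 0.01,
    "learning_rate": 0.1,
    "momentum": 0.5,
    "train_fraction": 0.6,
    "val_fraction": 0.2,
    "test_fraction": 0.2,
}
_SWARM_DEFAULTS = {
    "replicates": 10,
    "r_cutoff": 0.7,
    "max_epochs": 3000,
    "patience_epochs": 100,
    "mse_improvement_threshold": 0.01,
    "learning_rate": 0.1,
    "momentum": 0.5,
    "score_method": "connection_weight",
}
_ANALYSIS_DEFAULTS = {"top_k_edges": 500, "focus_gene": None,
                      "export": ["tsv", "sif", "graphml"]}


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    cohorts: dict[str, str]  # cohort label -> expression file
    pathway_file: str
    groups: dict[str, list[str]] = field(default_factory=dict)
    stepwise: dict = field(default_factory=dict)
    swarm: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    constant_gene_policy: str = "drop"

    def resolved(self) -> "PipelineConfig":
        return replace(
            self,
            stepwise={**_STEPWISE_DEFAULTS, **self.stepwise},
            swarm={**_SWARM_DEFAULTS, **self.swarm},
            analysis={**_ANALYSIS_DEFAULTS, **self.analysis},
        )

    def stepwise_mlp(self) -> MLPConfig:
        s = {**_STEPWISE_DEFAULTS, **self.stepwise}
        (seed,) = derive_seeds(self.seed, "stepwise", n=1)
        return MLPConfig(
            learning_rate=s["learning_rate"],
            momentum=s["momentum"],
            max_epochs=s["max_epochs"],
            patience_epochs=s["patience_epochs"],
            mse_improvement_threshold=s["mse_improvement_threshold"],
            mccv_iterations=s["mccv_iterations"],
            train_fraction=s["train_fraction"],
            val_fraction=s["val_fraction"],
            test_fraction=s["test_fraction"],
            seed=seed,
        )

    def swarm_config(self) -> SwarmConfig:
        s = {**_SWARM_DEFAULTS, **self.swarm}
        (seed,) = derive_seeds(self.seed, "swarm", n=1)
        return SwarmConfig(
            replicates_per_output=s["replicates"],
            pearson_r_cutoff=s["r_cutoff"],
            score_method=s["score_method"],
            mlp=MLPConfig(
                learning_rate=s["learning_rate"],
                momentum=s["momentum"],
                max_epochs=s["max_epochs"],
                patience_epochs=s["patience_epochs"],
                mse_improvement_threshold=s["mse_improvement_threshold"],
                train_fraction=0.8,
                val_fraction=0.2,
                test_fraction=0.0,
            ),
            seed=seed,
        )


def load_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in doc:
        raise ValueError("config must set a seed")
    return PipelineConfig(**doc)


def validate_config(path: str) -> dict:
    """Schema/range check; returns {'valid', 'errors', 'resolved'}."""
    errors: list[str] = []
    try:
        cfg = load_config(path)
    except Exception as exc:
        return {"valid": False, "errors": [str(exc)], "resolved": None}
    if cfg.seed < 0:
        errors.append("seed: must be non-negative")
    base = os.path.dirname(os.path.abspath(path))

    def _resolve(p):
        return p if os.path.isabs(p) else os.path.join(base, p)

    if not cfg.cohorts:
        errors.append("cohorts: at least one cohort expression file is required")
    for label, f in cfg.cohorts.items():
        if not os.path.exists(_resolve(f)):
            errors.append(f"cohorts.{label}: file not found: {f}")
    if not os.path.exists(_resolve(cfg.pathway_file)):
        errors.append(f"pathway_file: file not found: {cfg.pathway_file}")
    for grp, members in cfg.groups.items():
        for m in members:
            if m not in cfg.cohorts:
                errors.append(f"groups.{grp}: unknown cohort {m!r}")
    res = cfg.resolved()
    try:
        res.stepwise_mlp()
        sw = res.swarm_config()
        if not (0 <= sw.pearson_r_cutoff <= 1):
            errors.append("swarm.r_cutoff: must be in [0, 1]")
    except Exception as exc:
        errors.append(str(exc))
    resolved_doc = {
        "seed": res.seed,
        "out_dir": res.out_dir,
        "cohorts": res.cohorts,
        "groups": res.groups,
        "pathway_file": res.pathway_file,
        "stepwise": res.stepwise,
        "swarm": res.swarm,
        "analysis": res.analysis,
    }
    return {"valid": not errors, "errors": errors, "resolved": resolved_doc}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, config_dir: str = ".") -> str:
    """Execute all stages; returns the run directory containing the outputs
    and a manifest enabling bit-identical re-runs."""
    cfg = config.resolved()

    def _resolve(p):
        return p if os.path.isabs(p) else os.path.join(config_dir, p)

    run_dir = _resolve(cfg.out_dir)
    os.makedirs(run_dir, exist_ok=True)
    artifacts: list[str] = []
    stage_times: dict[str, float] = {}
    manifest_inputs = {}

    _starts: dict[str, float] = {}

    def _stage(name):
        log.info("pipeline stage: %s", name)
        _starts[name] = time.perf_counter()

    def _done(name):
        stage_times[name] = time.perf_counter() - _starts[name]

    def _out(*parts):
        p = os.path.join(run_dir, *parts)
        artifacts.append(p)
        return p

    try:
        stage = "validate"
        _stage(stage)
        for label, f in cfg.cohorts.items():
            f = _resolve(f)
            if not os.path.exists(f):
                raise FileNotFoundError(f"cohort {label!r}: {f}")
            manifest_inputs[label] = {"path": f, "sha256": _sha256(f)}
        pathway_path = _resolve(cfg.pathway_file)
        manifest_inputs["pathway"] = {"path": pathway_path,
                                      "sha256": _sha256(pathway_path)}
        pathway = read_gene_set(pathway_path)
        _done(stage)

        stage = "normalize"
        _stage(stage)
        normalized = {}
        for label, f in cfg.cohorts.items():
            em = read_expression(_resolve(f))
            em = minmax_normalize(em, cfg.constant_gene_policy)
            normalized[label] = em
            write_expression(em, _out(f"{label}.normalized.tsv"))
        _done(stage)

        stage = "stepwise"
        _stage(stage)
        mlp_cfg = cfg.stepwise_mlp()
        enriched_union: list[str] = list(pathway)
        for label, em in normalized.items():
            enr = enrich_pathway(
                em, pathway, mlp_cfg,
                top_k=cfg.stepwise["top_k"],
                n_repetitions=cfg.stepwise["repetitions"],
            )
            rows = []
            for g, res in enr.per_gene_results.items():
                for rep, ranking in enumerate(res.repetition_rankings):
                    r = ranking.copy()
                    r.insert(0, "repetition", rep)
                    r.insert(0, "pathway_gene", g)
                    rows.append(r)
            import pandas as pd

            pd.concat(rows, ignore_index=True).to_csv(
                _out(f"{label}.stepwise_rankings.tsv"), sep="\t", index=False
            )
            prov = pd.DataFrame(
                [(g, ",".join(sorted(ps))) for g, ps in sorted(enr.provenance.items())],
                columns=["added_gene", "predicted_pathway_genes"],
            )
            prov.to_csv(_out(f"{label}.provenance.tsv"), sep="\t", index=False)
            if enr.added_genes is not None:
                for g in enr.added_genes:
                    if g not in enriched_union:
                        enriched_union.append(g)
        from .preprocess import GeneSet

        enriched = GeneSet("enriched_pathway", tuple(enriched_union))
        write_gene_set(enriched, _out("enriched_pathway.txt"))
        _done(stage)

        stage = "swarm"
        _stage(stage)
        swarm_cfg = cfg.swarm_config()
        matrices = {}
        for label, em in normalized.items():
            present = GeneSet("enriched", tuple(g for g in enriched
                                                if g in em.data.index))
            im = infer_network(em, present, swarm_cfg)
            matrices[label] = im
            artifacts.extend(im.save(os.path.join(run_dir, f"{label}.interactions")))
        _done(stage)

        stage = "analysis"
        _stage(stage)
        summaries = {}
        for label, im in matrices.items():
            edges = to_edge_list(im)
            top = top_k_edges(edges, cfg.analysis["top_k_edges"])
            for fmt in cfg.analysis["export"]:
                ext = {"tsv": "tsv", "sif": "sif", "graphml": "graphml"}[fmt]
                export_network(top, fmt, _out(f"{label}.top_edges.{ext}"))
            summaries[label] = summarize_distribution(edges)
            focus = cfg.analysis.get("focus_gene")
            if focus:
                fe = filter_by_gene(edges, focus, role="either")
                export_network(fe, "tsv", _out(f"{label}.{focus.upper()}_edges.tsv"))
        with open(_out("distribution_summary.json"), "w") as fh:
            json.dump(summaries, fh, indent=1)
        _done(stage)

        stage = "drivers"
        _stage(stage)
        scoresets = []
        for label, im in matrices.items():
            ds = driver_scores(im, cohort_label=label)
            ds.write_tsv(_out(f"{label}.drivers.tsv"))
            scoresets.append(ds)
        if cfg.groups and len(cfg.groups) >= 2:
            grouping = {c: g for g, members in cfg.groups.items() for c in members}
            diff = differential_drivers(scoresets, grouping)
            diff.to_csv(_out("differential_drivers.tsv"), sep="\t")
        _done(stage)

        stage = "manifest"
        _stage(stage)
        import numpy
        import pandas

        from . import __version__

        manifest = {
            "config": {
                "seed": cfg.seed,
                "out_dir": cfg.out_dir,
                "cohorts": cfg.cohorts,
                "groups": cfg.groups,
                "pathway_file": cfg.pathway_file,
                "stepwise": cfg.stepwise,
                "swarm": cfg.swarm,
                "analysis": cfg.analysis,
            },
            "inputs": manifest_inputs,
            "outputs": {
                os.path.relpath(p, run_dir): _sha256(p)
                for p in artifacts
                if os.path.exists(p)
            },
            "versions": {
                "swarmnet": __version__,
                "numpy": numpy.__version__,
                "pandas": pandas.__version__,
            },
            "stage_seconds": {k: round(v, 3) for k, v in stage_times.items()},
        }
        with open(os.path.join(run_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
        _done(stage)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc, [p for p in artifacts if os.path.exists(p)])
    return run_dir
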