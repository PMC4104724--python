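"""End-to-end orchestration from a declarative config.

A config (YAML file or dict) names either on-disk inputs or a synthetic-
generation block, plus the analysis parameters. ``run_pipeline`` executes

    standardize -> choose_h_cv -> nipals_fit -> compute_vip ->
    permutation_fdr -> select_genes -> enrich -> build_subnetwork ->
    select_hubs

and writes every result table, the CV curve, network exports and a
run-manifest JSON (parameters, derived seeds, input/output checksums,
package version). One global seed derives per-stage seeds, so any stage
can be re-run in isolation; identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .datasets import (SyntheticTruth, generate_annotation, generate_expression,
                       generate_gene_sets, generate_interactions)
from .enrichment import enrich
from .exceptions import ConfigError, PlsdeError
from .network import build_subnetwork, compute_degrees, select_hubs
from .selection import run_vip_selection
from .utils import derive_seed, sha256_of

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_config", "simulate_inputs"]

_DEFAULT_PARAMS: dict[str, Any] = {
    "h_max": 8, "n_folds": 3, "n_perm": 200, "fdr_threshold": 0.01,
    "fdr_method": "pooled", "scale_columns": True, "hub_cutoff": 10,
    "hub_strict": False,
}
_INPUT_KEYS = ("expression", "phenotype", "annotation", "gene_sets", "interactions")

_SYNTH_DEFAULTS: dict[str, Any] = {
    "n_probes": 1000, "n_cases": 63, "n_controls": 20, "n_de": 50,
    "effect_size": 1.5, "noise_sd": 1.0, "up_fraction": 0.5,
    "probes_per_gene": 1.2, "unannotated_fraction": 0.02,
    "n_sets": 50, "set_size_min": 10, "set_size_max": 50,
    "n_enriched": 1, "enrichment_strength": 0.8,
    "mean_degree": 2.0, "n_hubs": 3, "hub_degree": 15,
}


def load_config(source: str | Path | dict) -> dict:
    """Load and validate a pipeline config before any computation."""
    if isinstance(source, (str, Path)):
        cfg = yaml.safe_load(Path(source).read_text())
    else:
        cfg = dict(source)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    if "output_dir" not in cfg:
        raise ConfigError("config missing required key 'output_dir'")
    has_inputs = "inputs" in cfg
    has_synth = "synthetic" in cfg
    if has_inputs == has_synth:
        raise ConfigError("config must have exactly one of 'inputs' or 'synthetic'")
    if has_inputs:
        inputs = cfg["inputs"]
        missing = [k for k in _INPUT_KEYS if k not in inputs]
        if missing:
            raise ConfigError(f"config inputs missing: {', '.join(missing)}")
        absent = [str(inputs[k]) for k in _INPUT_KEYS
                  if not Path(inputs[k]).exists()]
        if absent:
            raise ConfigError(f"input file(s) not found: {', '.join(absent)}")
    else:
        unknown = set(cfg["synthetic"]) - set(_SYNTH_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown synthetic key(s): {', '.join(sorted(unknown))}")
    params = {**_DEFAULT_PARAMS, **cfg.get("params", {})}
    unknown = set(params) - set(_DEFAULT_PARAMS)
    if unknown:
        raise ConfigError(f"unknown parameter(s): {', '.join(sorted(unknown))}")
    cfg["params"] = params
    cfg.setdefault("seed", 0)
    return cfg


def simulate_inputs(synth: dict, seed: int, out_dir: Path) -> dict[str, Path]:
    """Generate the five input files plus a truth sidecar; return their paths."""
    opts = {**_SYNTH_DEFAULTS, **synth}
    expr, pheno, truth = generate_expression(
        n_probes=opts["n_probes"], n_cases=opts["n_cases"],
        n_controls=opts["n_controls"], n_de=opts["n_de"],
        effect_size=opts["effect_size"], noise_sd=opts["noise_sd"],
        up_fraction=opts["up_fraction"], seed=derive_seed(seed, 10))
    annotation = generate_annotation(
        expr.index, probes_per_gene=opts["probes_per_gene"],
        unannotated_fraction=opts["unannotated_fraction"],
        seed=derive_seed(seed, 11))
    truth.enriched_set_ids = [f"GS{i:04d}" for i in range(opts["n_enriched"])]
    sets = generate_gene_sets(
        annotation, n_sets=opts["n_sets"], set_size_min=opts["set_size_min"],
        set_size_max=opts["set_size_max"], truth=truth,
        enrichment_strength=opts["enrichment_strength"],
        seed=derive_seed(seed, 12))
    genes = sorted({s for s in annotation if s})
    de_genes = truth.de_genes(annotation)
    truth.hub_gene_ids = de_genes[: opts["n_hubs"]]
    graph = generate_interactions(
        genes, mean_degree=opts["mean_degree"], hub_ids=truth.hub_gene_ids,
        hub_degree=opts["hub_degree"], seed=derive_seed(seed, 13))

    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.tsv",
        "phenotype": out_dir / "phenotype.tsv",
        "annotation": out_dir / "annotation.tsv",
        "gene_sets": out_dir / "gene_sets.gmt",
        "interactions": out_dir / "interactions.sif",
        "truth": out_dir / "truth.json",
    }
    pio.write_expression(expr, paths["expression"])
    pio.write_phenotype(pheno, paths["phenotype"])
    pio.write_annotation(annotation, paths["annotation"])
    pio.write_gene_sets(sets, paths["gene_sets"])
    pio.write_network(graph, paths["interactions"], dialect="sif")
    truth.to_json(paths["truth"])
    return paths


def _portable_path(path: Path, base: Path) -> str:
    """Path relative to the run directory when possible (keeps the manifest
    identical across runs that differ only in where they were placed)."""
    try:
        return str(path.relative_to(base))
    except ValueError:
        return str(path)


def run_pipeline(config: str | Path | dict) -> dict[str, Any]:
    """Run the full analysis; returns result objects and output paths."""
    cfg = load_config(config)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    params = cfg["params"]
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "inputs"
        if "synthetic" in cfg:
            paths = simulate_inputs(cfg["synthetic"], seed, out / "inputs")
            written.extend(paths.values())
        else:
            paths = {k: Path(v) for k, v in cfg["inputs"].items()}
        expr = pio.read_expression(paths["expression"])
        pheno = pio.read_phenotype(paths["phenotype"], expr)
        annotation = pio.read_annotation(paths["annotation"])
        sets = pio.read_gene_sets(paths["gene_sets"])
        graph = pio.read_edge_list(paths["interactions"])

        stage = "vip_selection"
        table, curve, model = run_vip_selection(
            expr, pheno, annotation,
            h_max=params["h_max"], n_folds=params["n_folds"],
            n_perm=params["n_perm"], fdr_threshold=params["fdr_threshold"],
            fdr_method=params["fdr_method"],
            scale_columns=params["scale_columns"], seed=derive_seed(seed, 1))
        vip_path = out / "vip_table.tsv"
        table.to_csv(vip_path, sep="\t", index=False, float_format="%.10g")
        written.append(vip_path)
        if curve is not None:
            cv_path = out / "cv_curve.tsv"
            curve.to_frame().to_csv(cv_path, sep="\t", index=False,
                                    float_format="%.10g")
            written.append(cv_path)

        stage = "enrichment"
        sel = table[table["selected"]]
        selected_genes = sorted({g for g in sel["gene"] if g})
        if selected_genes:
            enr = enrich(selected_genes, annotation, sets)
        else:
            logger.warning("no selected gene is annotated; enrichment is empty")
            from .enrichment import ENRICHMENT_COLUMNS
            enr = pd.DataFrame(columns=ENRICHMENT_COLUMNS)
        enr_path = out / "enrichment.tsv"
        enr.to_csv(enr_path, sep="\t", index=False, float_format="%.10g")
        written.append(enr_path)

        stage = "network"
        sub = build_subnetwork(selected_genes, graph)
        degrees = compute_degrees(sub)
        direction = {g: d for g, d in zip(sel["gene"], sel["direction"]) if g}
        for v in sub.nodes:
            sub.nodes[v]["degree"] = degrees[v]
            sub.nodes[v]["direction"] = direction.get(v, "")
        hubs = select_hubs(degrees, cutoff=params["hub_cutoff"],
                           strict=params["hub_strict"])
        hub_path = out / "hubs.tsv"
        pd.DataFrame(hubs, columns=["symbol", "degree"]).to_csv(
            hub_path, sep="\t", index=False)
        written.append(hub_path)
        for dialect in ("sif", "graphml"):
            net_path = out / f"subnetwork.{dialect}"
            pio.write_network(sub, net_path, dialect=dialect)
            written.append(net_path)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": seed,
            "derived_seeds": {"selection": derive_seed(seed, 1)},
            "params": params,
            "inputs": {k: {"path": _portable_path(p, out), "sha256": sha256_of(p)}
                       for k, p in paths.items()},
            "outputs": {p.name: sha256_of(p) for p in written
                        if p.parent == out},
            "summary": {
                "n_probes": int(expr.shape[0]),
                "n_samples": int(expr.shape[1]),
                "chosen_h": int(model.n_components_),
                "n_selected_probes": int(table["selected"].sum()),
                "n_selected_genes": len(selected_genes),
                "n_enriched_sets": int(enr.shape[0]),
                "n_hubs": len(hubs),
            },
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(manifest_path)
    except PlsdeError:
        for p in written:
            p.unlink(missing_ok=True)
        logger.error("pipeline failed at stage %r; partial outputs removed", stage)
        raise
    except Exception as err:
        for p in written:
            p.unlink(missing_ok=True)
        raise PlsdeError(f"pipeline failed at stage {stage!r}: {err}") from err

    return {"config": cfg, "paths": paths, "output_dir": out,
            "vip_table": table, "cv_curve": curve, "model": model,
            "enrichment": enr, "subnetwork": sub, "hubs": hubs,
            "manifest": manifest}
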