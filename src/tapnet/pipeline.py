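"""End-to-end pipeline: gate → SAM (x4 mutants) → classify → enrich → heatmap.

The run is driven by a YAML/JSON config (or an equivalent dict) that either
names input files or carries a ``simulate`` block; every parameter and input
checksum lands in a JSON manifest so two runs with the same config and seed
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .cascade import (
    CascadeInput,
    CascadePartition,
    RecoveryReport,
    cascade_retention_percent,
    classify_specificity,
    gate_down_sets,
    score_recovery,
)
from .enrichment import enrich_all, log2fc_matrix, write_heatmap
from .exceptions import ConfigurationError
from .gating import StageCatalog, comparison_gate, summarize_stages
from .io import (
    AnnotationSets,
    ExpressionMatrix,
    read_design,
    read_expression_matrix,
    read_fpkm_table,
    read_gmt,
    write_gene_list,
)
from .sam import DeCallSet, SamSettings, call_down_regulated
from .simulate import (
    MUTANTS,
    SimConfig,
    SimulatedStudy,
    simulate_cascade,
    write_study,
)


@dataclass
class PipelineResult:
    gate: frozenset[str]
    stage_summary: dict
    de_calls: dict[str, DeCallSet]
    partition: CascadePartition
    retention: dict[str, float]
    enrichment: Any  # pandas DataFrame
    recovery: RecoveryReport | None
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_config(config: str | Path | Mapping[str, Any]) -> dict:
    if isinstance(config, Mapping):
        return dict(config)
    with Path(config).open(encoding="utf-8") as handle:
        loaded = yaml.safe_load(handle)
    if not isinstance(loaded, dict):
        raise ConfigurationError("pipeline config must be a mapping")
    return loaded


def run_pipeline(
    config: str | Path | Mapping[str, Any], out_dir: str | Path
) -> PipelineResult:
    """Execute every stage, writing outputs and a manifest under ``out_dir``."""
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    order = tuple(cfg.get("classify", {}).get("order", MUTANTS))

    checksums: dict[str, str] = {}
    study: SimulatedStudy | None = None
    if "simulate" in cfg:
        sim_params = dict(cfg["simulate"] or {})
        sim_params.setdefault("seed", seed)
        sim_config = SimConfig(**sim_params)
        study = simulate_cascade(sim_config)
        matrix = study.matrix
        fpkm_tables = list(study.fpkm_tables.items())
        annotations = study.annotations
        paths = write_study(study, out / "inputs")
        checksums = {k: _sha256(p) for k, p in paths.items()}
    elif "inputs" in cfg:
        inputs = cfg["inputs"]
        design = read_design(inputs["design"])
        matrix = read_expression_matrix(inputs["matrix"], design)
        fpkm_tables = [
            (str(label), read_fpkm_table(path))
            for label, path in dict(inputs["fpkm"]).items()
        ]
        annotations = read_gmt(inputs["gmt"]) if "gmt" in inputs else AnnotationSets()
        for key in ("matrix", "design", "gmt"):
            if key in inputs:
                checksums[key] = _sha256(Path(inputs[key]))
        for label, path in dict(inputs["fpkm"]).items():
            checksums[f"fpkm_{label}"] = _sha256(Path(path))
    else:
        raise ConfigurationError("config needs a 'simulate' or 'inputs' block")

    reference = cfg.get("reference", "wt")
    missing = [m for m in order if m not in matrix.conditions]
    if missing:
        raise ConfigurationError(
            "matrix lacks mutant condition(s): " + ", ".join(missing)
        )

    # --- stage 1: tapetum expression gating -------------------------------
    gate_cfg = cfg.get("gate", {})
    gate = comparison_gate(
        [records for _, records in fpkm_tables],
        threshold=float(gate_cfg.get("threshold", 2.0)),
        mode=gate_cfg.get("mode", "either"),
    )
    catalogs = [
        StageCatalog.from_records(label, records) for label, records in fpkm_tables
    ]
    stage_summary = (
        summarize_stages(catalogs[0], catalogs[1]) if len(catalogs) >= 2 else {}
    )
    write_gene_list(gate, out / "gate.txt")

    # --- stage 2: SAM differential expression per mutant ------------------
    sam_cfg = dict(cfg.get("sam", {}))
    per_mutant_delta = dict(sam_cfg.pop("deltas", {}) or {})
    de_calls: dict[str, DeCallSet] = {}
    for mutant in order:
        settings = SamSettings(
            s0_mode=sam_cfg.get("s0_mode", "auto"),
            s0_value=sam_cfg.get("s0_value"),
            n_permutations=sam_cfg.get("n_permutations", "all"),
            delta=per_mutant_delta.get(mutant, sam_cfg.get("delta")),
            fold_change_threshold=float(sam_cfg.get("fold_change_threshold", 2.0)),
            fdr_threshold=float(sam_cfg.get("fdr_threshold", 0.05)),
            q_threshold=float(sam_cfg.get("q_threshold", 0.05)),
            seed=seed,
        )
        pair = matrix.subset_conditions([reference, mutant])
        de_calls[mutant] = call_down_regulated(pair, settings, reference=reference)
        write_gene_list(de_calls[mutant].down_genes, out / f"down_{mutant}.txt")

    # --- stage 3: nested specificity classification -----------------------
    cascade = CascadeInput(
        down_sets={m: de_calls[m].down_genes for m in order},
        gate=gate,
        order=order,
    )
    partition = classify_specificity(cascade)
    gated = gate_down_sets(cascade)
    retention = {}
    counts = partition.nested_counts
    for j in range(1, len(counts)):
        if counts[j - 1] > 0:
            key = f"{order[j - 1]}->{order[j]}"
            retention[key] = cascade_retention_percent(counts[j - 1], counts[j], 1)
    for label, genes in partition.class_sets.items():
        write_gene_list(genes, out / f"class_{label}.txt")

    # --- stage 4: enrichment ----------------------------------------------
    enrich_cfg = cfg.get("enrich", {})
    background = gate if enrich_cfg.get("background", "gate") == "gate" else frozenset(
        matrix.genes
    )
    enrichment = enrich_all(
        partition, annotations.restrict_to(background) if len(annotations) else annotations,
        background, alpha=float(enrich_cfg.get("alpha", 0.05)),
    )
    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    # --- stage 5: heatmap ---------------------------------------------------
    heat_cfg = cfg.get("heatmap", {})
    heat_genes = sorted(set().union(*(gated[m] for m in order)) or set(matrix.genes[:2]))
    heatmap = log2fc_matrix(
        matrix.subset_conditions([reference, *order]),
        genes=heat_genes,
        pseudocount=float(heat_cfg.get("pseudocount", 1.0)),
        reference=reference,
    )
    write_heatmap(heatmap, out / "heatmap")

    # --- recovery scoring (simulated runs only) ----------------------------
    recovery = None
    if study is not None:
        recovery = score_recovery(partition, study.truth)
        (out / "recovery.json").write_text(
            json.dumps(
                {
                    "macro_precision": recovery.macro_precision,
                    "macro_recall": recovery.macro_recall,
                    "macro_f1": recovery.macro_f1,
                    "per_class": {
                        c: asdict(m) for c, m in recovery.per_class.items()
                    },
                },
                indent=1,
            )
            + "\n",
            encoding="utf-8",
        )

    manifest = {
        "tool_version": __version__,
        "format_version": 1,
        "seed": seed,
        "config": _jsonable(cfg),
        "input_checksums": checksums,
        "counts": {
            "gate": len(gate),
            "down": {m: len(de_calls[m].down_genes) for m in order},
            "gated_down": {m: len(gated[m]) for m in order},
            "nested": list(partition.nested_counts),
            "classes": {c: len(g) for c, g in partition.class_sets.items()},
        },
        "sam": {
            m: {
                "delta": de_calls[m].delta,
                "s0": de_calls[m].s0,
                "achieved_fdr": de_calls[m].achieved_fdr,
                "fdr_exceeded": de_calls[m].fdr_exceeded,
            }
            for m in order
        },
        "retention_percent": retention,
        "stage_summary": stage_summary,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return PipelineResult(
        gate=gate,
        stage_summary=stage_summary,
        de_calls=de_calls,
        partition=partition,
        retention=retention,
        enrichment=enrichment,
        recovery=recovery,
        manifest=manifest,
    )


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
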