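"""Synthetic knockout-transcriptome generator with a planted nested cascade.

Emulates the study's three data modalities so every downstream stage is
testable without the deposited arrays/RNA-seq:

* a replicated wild-type + four-mutant intensity matrix (log-normal replicate
  noise on linear intensities, three replicates per condition by default);
* two tapetum stage-pool FPKM tables with confidence bounds;
* flat gene-set annotations (GMT) with optional planted enrichment.

Ground truth per gene is the tier of the nested regulatory hierarchy it
belongs to: a ``dyt1_specific`` gene loses expression in *dyt1* only, a
``tdf1_specific`` gene in *dyt1* and *tdf1*, an ``ams_specific`` gene in
*dyt1*/*tdf1*/*ams*, and a ``common`` gene in all four mutants — exactly the
nested pattern the specificity classifier assumes.  An optional contamination
fraction plants non-nested effects (down in one downstream mutant only) to
exercise the classifier's ``unassigned`` path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .io import (
    AnnotationSets,
    ExpressionMatrix,
    FpkmRecord,
    write_design,
    write_expression_matrix,
    write_fpkm_table,
    write_gmt,
)

MUTANTS = ("dyt1", "tdf1", "ams", "ms188")
TIERS = ("none", "dyt1_specific", "tdf1_specific", "ams_specific", "common")
AFFECTED: dict[str, tuple[str, ...]] = {
    "none": (),
    "dyt1_specific": ("dyt1",),
    "tdf1_specific": ("dyt1", "tdf1"),
    "ams_specific": ("dyt1", "tdf1", "ams"),
    "common": MUTANTS,
}
STAGE_LABELS = ("6-7", "8-10")


@dataclass
class PlantedTruth:
    """Generative ground truth for one gene."""

    gene: str
    tier: str
    effect_log2: float  # <= -1 for affected tiers, 0.0 otherwise
    tapetum_expressed: bool
    categories: set[str] = field(default_factory=set)
    contaminant_mutant: str | None = None  # non-nested planted effect, if any

    @property
    def affected_mutants(self) -> tuple[str, ...]:
        if self.contaminant_mutant is not None:
            return (self.contaminant_mutant,)
        return AFFECTED[self.tier]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults encode the simulated study: 2,000 genes, 3 replicates per
    condition, planted log2 effects centred at -2 (clamped at -1), replicate
    noise sd 0.25 on the log2 scale, tier proportions
    (none, dyt1-, tdf1-, ams-specific, common) = (0.70, 0.06, 0.055, 0.07,
    0.115), and a fifth of genes not expressed in the tapetum.
    """

    n_genes: int = 2000
    tier_proportions: tuple[float, ...] = (0.70, 0.06, 0.055, 0.07, 0.115)
    effect_log2_mean: float = -2.0
    effect_log2_sd: float = 0.25
    replicate_sd: float = 0.25
    n_replicates: int = 3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    frac_not_tapetum: float = 0.20
    fpkm_margin: float = 1.0
    frac_non_nested: float = 0.0
    n_categories: int = 12
    enrichment_odds: float = 10.0
    category_base_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        if len(self.tier_proportions) != len(TIERS):
            raise ConfigurationError(f"need {len(TIERS)} tier proportions")
        props = np.asarray(self.tier_proportions, dtype=float)
        if (props < 0).any() or (props > 1).any() or abs(props.sum() - 1) > 1e-9:
            raise ConfigurationError("tier proportions must be in [0,1] and sum to 1")
        if self.n_replicates < 2:
            raise ConfigurationError("need at least 2 replicates per condition")
        if self.replicate_sd <= 0:
            raise ConfigurationError("replicate_sd must be positive")
        if not 0 <= self.frac_not_tapetum <= 1:
            raise ConfigurationError("frac_not_tapetum must be in [0,1]")
        if not 0 <= self.frac_non_nested <= 1:
            raise ConfigurationError("frac_non_nested must be in [0,1]")
        if self.fpkm_margin <= 0:
            raise ConfigurationError("fpkm_margin must be positive")
        if self.enrichment_odds > 1 and self.n_categories >= 1 and not any(
            p > 0 for p in self.tier_proportions[1:]
        ):
            raise ConfigurationError(
                "enrichment requested but every affected-tier proportion is 0"
            )


@dataclass
class SimulatedStudy:
    """Everything one simulated study produces."""

    matrix: ExpressionMatrix
    fpkm_tables: dict[str, list[FpkmRecord]]
    annotations: AnnotationSets
    truth: list[PlantedTruth]
    config: SimConfig


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_cascade(config: SimConfig) -> SimulatedStudy:
    """Draw one complete synthetic study; identical config ⇒ identical output."""
    ss = np.random.SeedSequence(config.seed)
    rng_truth, rng_matrix, rng_fpkm, rng_cat = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    n = config.n_genes
    genes = _gene_ids(n)

    tier_ix = rng_truth.choice(len(TIERS), size=n, p=list(config.tier_proportions))
    effects = np.minimum(
        rng_truth.normal(config.effect_log2_mean, config.effect_log2_sd, size=n),
        -1.0,
    )
    effects[tier_ix == 0] = 0.0
    tapetum = rng_truth.random(n) >= config.frac_not_tapetum

    truth = [
        PlantedTruth(
            gene=genes[i],
            tier=TIERS[tier_ix[i]],
            effect_log2=float(effects[i]),
            tapetum_expressed=bool(tapetum[i]),
        )
        for i in range(n)
    ]

    if config.frac_non_nested > 0:
        none_ix = np.nonzero(tier_ix == 0)[0]
        n_contam = int(round(config.frac_non_nested * none_ix.size))
        if n_contam:
            chosen = rng_truth.choice(none_ix, size=n_contam, replace=False)
            downstream = MUTANTS[1:]
            picks = rng_truth.choice(len(downstream), size=n_contam)
            contam_effects = np.minimum(
                rng_truth.normal(
                    config.effect_log2_mean, config.effect_log2_sd, size=n_contam
                ),
                -1.0,
            )
            for j, gi in enumerate(chosen):
                truth[gi].contaminant_mutant = downstream[picks[j]]
                truth[gi].effect_log2 = float(contam_effects[j])

    matrix = _simulate_matrix(truth, config, rng_matrix)
    fpkm_tables = {
        label: _simulate_fpkm(truth, config, rng_fpkm) for label in STAGE_LABELS
    }
    annotations = plant_enriched_categories(
        truth,
        n_categories=config.n_categories,
        enrichment_odds=config.enrichment_odds,
        rng=rng_cat,
        base_rate=config.category_base_rate,
    )
    return SimulatedStudy(matrix, fpkm_tables, annotations, truth, config)


def _simulate_matrix(
    truth: Sequence[PlantedTruth], config: SimConfig, rng: np.random.Generator
) -> ExpressionMatrix:
    n = len(truth)
    conditions = ("wt",) + MUTANTS
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    columns: dict[str, np.ndarray] = {}
    design: dict[str, str] = {}
    for cond in conditions:
        effect = np.array(
            [t.effect_log2 if cond in t.affected_mutants else 0.0 for t in truth]
        )
        for rep in range(1, config.n_replicates + 1):
            noise = rng.normal(0.0, config.replicate_sd, size=n)
            sample = f"{cond}_{rep}"
            columns[sample] = np.exp2(baseline + effect + noise)
            design[sample] = cond
    frame = pd.DataFrame(columns, index=[t.gene for t in truth])
    return ExpressionMatrix(frame, design)


def _simulate_fpkm(
    truth: Sequence[PlantedTruth], config: SimConfig, rng: np.random.Generator
) -> list[FpkmRecord]:
    records = []
    for t in truth:
        if t.tapetum_expressed:
            fpkm = 2.0 + float(rng.lognormal(mean=1.5, sigma=2.0))
            lo = max(0.0, fpkm - config.fpkm_margin)
            hi = fpkm + config.fpkm_margin
        else:
            fpkm = float(rng.uniform(0.0, 2.0))
            lo = 0.0
            hi = fpkm + config.fpkm_margin
        records.append(FpkmRecord(t.gene, fpkm, lo, hi))
    return records


def plant_enriched_categories(
    truth: Sequence[PlantedTruth],
    n_categories: int,
    enrichment_odds: float,
    seed: int | None = None,
    base_rate: float = 0.05,
    rng: np.random.Generator | None = None,
) -> AnnotationSets:
    """Random flat gene sets, the first few enriched in one affected tier each.

    With ``enrichment_odds`` > 1 the first ``min(4, n_categories)`` categories
    draw members from their target tier at an odds ratio of
    ``enrichment_odds`` relative to the base inclusion rate; remaining
    categories are uniform.  ``enrichment_odds == 1`` yields all-null sets.
    Category names record the planted tier.  Empty draws are topped up with
    one deterministic member so every set is valid.
    """
    if not truth:
        raise ValidationError("truth must be non-empty")
    if n_categories < 1:
        raise ConfigurationError("n_categories must be >= 1")
    if enrichment_odds < 1:
        raise ConfigurationError("enrichment_odds must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)

    odds_out = base_rate / (1.0 - base_rate)
    odds_in = enrichment_odds * odds_out
    p_in = odds_in / (1.0 + odds_in)

    affected_tiers = [t for t in TIERS[1:] if any(x.tier == t for x in truth)]
    categories: dict[str, tuple[str, frozenset[str]]] = {}
    for idx in range(n_categories):
        cid = f"C{idx + 1:02d}"
        target = (
            affected_tiers[idx % len(affected_tiers)]
            if enrichment_odds > 1 and idx < min(4, len(affected_tiers)) and affected_tiers
            else None
        )
        probs = np.array(
            [p_in if target is not None and t.tier == target else base_rate
             for t in truth]
        )
        mask = rng.random(len(truth)) < probs
        members = {t.gene for t, m in zip(truth, mask) if m}
        if not members:
            pool = [t.gene for t in truth if target is None or t.tier == target]
            members = {pool[0] if pool else truth[0].gene}
        name = f"planted:{target}" if target is not None else "null"
        categories[cid] = (name, frozenset(members))
        for t in truth:
            if t.gene in categories[cid][1]:
                t.categories.add(cid)
    return AnnotationSets(categories)


# ---------------------------------------------------------------------------
# Persistence


def write_truth_table(truth: Sequence[PlantedTruth], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write(
            "gene_id\ttier\teffect_log2\ttapetum_expressed\tcontaminant_mutant\n"
        )
        for t in truth:
            handle.write(
                f"{t.gene}\t{t.tier}\t{t.effect_log2!r}\t"
                f"{int(t.tapetum_expressed)}\t{t.contaminant_mutant or '-'}\n"
            )


def read_truth_table(path: str | Path) -> list[PlantedTruth]:
    truth = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        gene, tier, eff, tap, contam = line.split("\t")
        truth.append(
            PlantedTruth(
                gene=gene,
                tier=tier,
                effect_log2=float(eff),
                tapetum_expressed=bool(int(tap)),
                contaminant_mutant=None if contam == "-" else contam,
            )
        )
    return truth


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write all study artifacts to ``out_dir``; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.tsv",
        "design": out / "design.json",
        "gmt": out / "annotations.gmt",
        "truth": out / "truth.tsv",
    }
    write_expression_matrix(study.matrix, paths["matrix"])
    write_design(study.matrix.design, paths["design"])
    write_gmt(study.annotations, paths["gmt"])
    write_truth_table(study.truth, paths["truth"])
    for label, records in study.fpkm_tables.items():
        key = f"fpkm_{label}"
        paths[key] = out / f"fpkm_stage{label}.tsv"
        write_fpkm_table(records, paths[key])
    return paths
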