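"""Nested pathway-specificity classification along an ordered TF cascade.

Given per-mutant down-regulated gene sets for an ordered regulatory cascade
(default DYT1 → TDF1 → AMS → MS188) and a tapetum-expression gate, each gene
is assigned to exactly one class:

* ``<mutant>_specific`` — gated, down-regulated in the mutant and every
  upstream mutant but not in any downstream one (a nested prefix);
* ``common`` — gated and down-regulated in all mutants;
* ``unassigned`` — gated but not matching any nested prefix (down in a
  downstream mutant without the upstream ones, or down in no mutant at all);
* ``not_gated`` — down-regulated somewhere but not tapetum-expressed.

The partition is mutually exclusive and exhaustive over
gate ∪ (union of down sets), asserted on every run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .exceptions import DomainError, ValidationError
from .gating import round_half_away

DEFAULT_ORDER = ("dyt1", "tdf1", "ams", "ms188")


@dataclass(frozen=True)
class CascadeInput:
    """Ordered mutant labels, their down-regulated sets, and the gate."""

    down_sets: Mapping[str, frozenset[str]]
    gate: frozenset[str]
    order: tuple[str, ...] = DEFAULT_ORDER

    def __post_init__(self) -> None:
        if len(self.order) < 2:
            raise ValidationError("cascade order needs at least 2 mutants")
        if len(set(self.order)) != len(self.order):
            raise ValidationError("cascade labels must be distinct")
        missing = [m for m in self.order if m not in self.down_sets]
        if missing:
            raise ValidationError(f"down sets missing for: {', '.join(missing)}")
        object.__setattr__(
            self,
            "down_sets",
            {m: frozenset(self.down_sets[m]) for m in self.order},
        )
        object.__setattr__(self, "gate", frozenset(self.gate))


@dataclass(frozen=True)
class CascadePartition:
    """Result of nested specificity classification."""

    order: tuple[str, ...]
    assignment: Mapping[str, str]  # gene -> class label
    nested_counts: tuple[int, ...]  # c_j = |gate ∩ D_1 ∩ ... ∩ D_j|

    @property
    def class_labels(self) -> tuple[str, ...]:
        specific = tuple(f"{m}_specific" for m in self.order[:-1])
        return specific + ("common", "unassigned", "not_gated")

    def class_set(self, label: str) -> frozenset[str]:
        return frozenset(g for g, c in self.assignment.items() if c == label)

    @property
    def class_sets(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {label: set() for label in self.class_labels}
        for gene, label in self.assignment.items():
            out[label].add(gene)
        return {label: frozenset(genes) for label, genes in out.items()}

    @property
    def specific_counts(self) -> dict[str, int]:
        sets = self.class_sets
        return {m: len(sets[f"{m}_specific"]) for m in self.order[:-1]}

    @property
    def common_count(self) -> int:
        return len(self.class_set("common"))


def gate_down_sets(cascade: CascadeInput) -> dict[str, frozenset[str]]:
    """Intersect each mutant's down-regulated set with the tapetum gate."""
    import warnings

    if not cascade.gate:
        warnings.warn("tapetum gate is empty; all gated sets are empty", stacklevel=2)
    return {m: cascade.down_sets[m] & cascade.gate for m in cascade.order}


def classify_specificity(cascade: CascadeInput) -> CascadePartition:
    """Partition gate ∪ (∪ down sets) into nested specificity classes."""
    order = cascade.order
    k = len(order)
    union_down: set[str] = set()
    for m in order:
        union_down |= cascade.down_sets[m]
    domain = cascade.gate | union_down

    assignment: dict[str, str] = {}
    for gene in domain:
        if gene not in cascade.gate:
            assignment[gene] = "not_gated"
            continue
        member = [gene in cascade.down_sets[m] for m in order]
        if all(member):
            assignment[gene] = "common"
            continue
        prefix = 0
        while prefix < k and member[prefix]:
            prefix += 1
        if prefix >= 1 and not any(member[prefix:]):
            assignment[gene] = f"{order[prefix - 1]}_specific"
        else:
            assignment[gene] = "unassigned"

    nested: list[int] = []
    running = set(cascade.gate)
    for m in order:
        running &= cascade.down_sets[m]
        nested.append(len(running))

    partition = CascadePartition(order, assignment, tuple(nested))
    covered = set(partition.assignment)
    if covered != domain:  # pragma: no cover - structural safety net
        raise ValidationError("partition does not cover gate ∪ down sets")
    return partition


def cascade_retention_percent(
    parent_count: int, child_count: int, decimals: int = 1
) -> float:
    """Percentage of a parent nested set retained in its child set."""
    if parent_count <= 0:
        raise DomainError("parent count must be positive")
    if not 0 <= child_count <= parent_count:
        raise ValidationError("child count must lie in [0, parent count]")
    if decimals not in (0, 1):
        raise ValidationError("decimals must be 0 or 1")
    return round_half_away(100.0 * child_count / parent_count, decimals)


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    n_true: int
    n_predicted: int


@dataclass(frozen=True)
class RecoveryReport:
    per_class: Mapping[str, ClassMetrics]
    macro_precision: float
    macro_recall: float
    macro_f1: float


def expected_class(tier: str, tapetum_expressed: bool) -> str:
    """Partition class a planted gene should land in under perfect recovery."""
    if tier == "none":
        return "unassigned"
    return tier if tapetum_expressed else "not_gated"


def score_recovery(partition: CascadePartition, truth: Sequence) -> RecoveryReport:
    """Precision/recall/F1 of the partition against planted truth.

    ``truth`` is a sequence of objects with ``gene``, ``tier`` and
    ``tapetum_expressed`` attributes (:class:`~tapnet.simulate.PlantedTruth`).
    The scored classes are the affected tiers (the specific classes and
    ``common``); ``not_gated`` is excluded from macro averaging.  A planted
    gene whose expected class is scored but which the pipeline never placed
    in the partition domain counts as a recall miss.
    """
    truth_genes = {t.gene for t in truth}
    stray = set(partition.assignment) - truth_genes
    if stray:
        raise ValidationError(
            "partition genes absent from truth: " + ", ".join(sorted(stray)[:10])
        )
    scored = tuple(f"{m}_specific" for m in partition.order[:-1]) + ("common",)
    true_sets: dict[str, set[str]] = {c: set() for c in scored}
    for t in truth:
        cls = expected_class(t.tier, t.tapetum_expressed)
        if cls in true_sets:
            true_sets[cls].add(t.gene)
    pred_sets = partition.class_sets

    per_class: dict[str, ClassMetrics] = {}
    for cls in scored:
        true_c, pred_c = true_sets[cls], pred_sets.get(cls, frozenset())
        tp = len(true_c & pred_c)
        if not true_c and not pred_c:
            precision = recall = 1.0
        else:
            precision = tp / len(pred_c) if pred_c else 0.0
            recall = tp / len(true_c) if true_c else 1.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        per_class[cls] = ClassMetrics(precision, recall, f1, len(true_c), len(pred_c))

    macro_p = sum(m.precision for m in per_class.values()) / len(per_class)
    macro_r = sum(m.recall for m in per_class.values()) / len(per_class)
    macro_f = sum(m.f1 for m in per_class.values()) / len(per_class)
    return RecoveryReport(per_class, macro_p, macro_r, macro_f)
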