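"""FPKM-based expression gating for the tapetum stage catalogs.

Three gates are used downstream, all strict inequalities:

* *expressed*: the lower bound of the FPKM confidence interval is > 0;
* *highly expressed*: FPKM > 300 (extremely high-expressing genes);
* *comparison gate*: FPKM > 2, used to restrict mutant down-regulated sets
  to genes actually expressed in the tapetum.

Shared-set percentages are reported against the union of the two stage
catalogs, rounded half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

from .exceptions import DomainError, ValidationError
from .io import FpkmRecord


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero to ``decimals`` places (not banker's)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def compute_fpkm(
    fragments: float, gene_length_bp: int, total_mapped_fragments: float
) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if gene_length_bp < 1:
        raise DomainError("gene length must be >= 1 bp")
    if total_mapped_fragments < 1:
        raise DomainError("library size must be >= 1 fragment")
    if fragments < 0:
        raise DomainError("fragment count must be non-negative")
    return fragments / ((gene_length_bp / 1e3) * (total_mapped_fragments / 1e6))


def call_expressed(records: Iterable[FpkmRecord]) -> frozenset[str]:
    """Genes whose FPKM confidence lower bound is strictly positive."""
    return frozenset(r.gene for r in records if r.conf_lo > 0)


def call_highly_expressed(
    records: Iterable[FpkmRecord], threshold: float = 300.0
) -> frozenset[str]:
    """Genes with FPKM strictly above ``threshold`` (default 300)."""
    if threshold <= 0:
        raise DomainError("threshold must be positive")
    return frozenset(r.gene for r in records if r.fpkm > threshold)


def comparison_gate(
    stage_records: Sequence[Iterable[FpkmRecord]],
    threshold: float = 2.0,
    mode: Literal["either", "both"] = "either",
) -> frozenset[str]:
    """Tapetum-expression gate: FPKM > ``threshold`` in either/both stage pools.

    ``mode='either'`` (default) admits a gene expressed above the threshold
    in at least one stage; ``'both'`` requires all stages.
    """
    if not stage_records:
        raise ValidationError("at least one stage table required")
    per_stage = [call_highly_expressed(recs, threshold) for recs in stage_records]
    gate = per_stage[0]
    for stage in per_stage[1:]:
        gate = gate | stage if mode == "either" else gate & stage
    return gate


def shared_of_union_percent(count_a: int, count_b: int, shared: int) -> float:
    """Percentage of the two catalogs' union that is shared, to 1 decimal."""
    if shared > min(count_a, count_b) or min(count_a, count_b, shared) < 0:
        raise ValidationError("shared count exceeds a catalog size")
    union = count_a + count_b - shared
    if union == 0:
        raise DomainError("union of the two catalogs is empty")
    return round_half_away(100.0 * shared / union, 1)


@dataclass(frozen=True)
class StageCatalog:
    """Per-stage gene catalogs: expressed, highly expressed, comparison-gated."""

    stage_label: str
    expressed: frozenset[str]
    highly_expressed: frozenset[str]
    gated: frozenset[str]

    @classmethod
    def from_records(
        cls,
        stage_label: str,
        records: Sequence[FpkmRecord],
        high_threshold: float = 300.0,
        gate_threshold: float = 2.0,
    ) -> "StageCatalog":
        return cls(
            stage_label=stage_label,
            expressed=call_expressed(records),
            highly_expressed=call_highly_expressed(records, high_threshold),
            gated=call_highly_expressed(records, gate_threshold),
        )


def summarize_stages(catalog_a: StageCatalog, catalog_b: StageCatalog) -> dict:
    """Counts and shared-of-union percentages for a pair of stage catalogs."""
    shared_expressed = catalog_a.expressed & catalog_b.expressed
    shared_high = catalog_a.highly_expressed & catalog_b.highly_expressed
    summary = {
        "stages": [catalog_a.stage_label, catalog_b.stage_label],
        "expressed": [len(catalog_a.expressed), len(catalog_b.expressed)],
        "highly_expressed": [
            len(catalog_a.highly_expressed),
            len(catalog_b.highly_expressed),
        ],
        "shared_expressed": len(shared_expressed),
        "shared_highly_expressed": len(shared_high),
    }
    if catalog_a.expressed | catalog_b.expressed:
        summary["shared_expressed_percent"] = shared_of_union_percent(
            len(catalog_a.expressed), len(catalog_b.expressed), len(shared_expressed)
        )
    if catalog_a.highly_expressed | catalog_b.highly_expressed:
        summary["shared_highly_expressed_percent"] = shared_of_union_percent(
            len(catalog_a.highly_expressed),
            len(catalog_b.highly_expressed),
            len(shared_high),
        )
    return summary
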