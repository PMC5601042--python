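"""Domain types and readers/writers for the tabular formats the pipeline touches.

All interchange formats are plain text: tab-separated tables with headers for
FPKM records and expression matrices, YAML/JSON for the sample→condition
design, and GMT for annotation (gene-set) collections.  Gene identifiers are
normalized (stripped, uppercased) at ingest so the microarray/RNA-seq join is
case-safe; AGI locus identifiers are conventionally uppercase.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .exceptions import ConfigurationError, ParseError, ValidationError

FPKM_COLUMNS = ("gene_id", "fpkm", "conf_lo", "conf_hi")


def normalize_gene_id(raw: str) -> str:
    """Normalize a gene identifier: strip whitespace, uppercase.

    Idempotent; raises :class:`ValidationError` on empty ids.
    """
    gene = str(raw).strip().upper()
    if not gene:
        raise ValidationError("empty gene identifier")
    return gene


@dataclass(frozen=True)
class FpkmRecord:
    """One gene's abundance estimate in one stage pool.

    ``conf_lo``/``conf_hi`` are the bounds of the abundance confidence
    interval (same FPKM units); the invariant ``conf_lo <= fpkm <= conf_hi``
    is enforced at construction.
    """

    gene: str
    fpkm: float
    conf_lo: float
    conf_hi: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_gene_id(self.gene))
        for name in ("fpkm", "conf_lo", "conf_hi"):
            value = float(getattr(self, name))
            object.__setattr__(self, name, value)
            if not math.isfinite(value):
                raise ValidationError(f"{self.gene}: {name} is not finite")
            if value < 0:
                raise ValidationError(f"{self.gene}: {name} is negative")
        if not (self.conf_lo <= self.fpkm <= self.conf_hi):
            raise ValidationError(
                f"{self.gene}: confidence bounds violated "
                f"(conf_lo={self.conf_lo}, fpkm={self.fpkm}, conf_hi={self.conf_hi})"
            )


@dataclass
class ExpressionMatrix:
    """Genes × samples intensity table with a replicate design.

    ``values`` has gene ids as the index and sample names as columns;
    ``design`` maps every sample column to a condition label.  Intensities
    are linear-scale and non-negative; missing values are rejected rather
    than imputed.  Row order defines gene order downstream.
    """

    values: pd.DataFrame
    design: dict[str, str]

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.design]
        if missing:
            raise ConfigurationError(
                f"samples absent from design: {', '.join(map(str, missing))}"
            )
        self.values.index = [normalize_gene_id(g) for g in self.values.index]
        if self.values.index.has_duplicates:
            dups = sorted(set(self.values.index[self.values.index.duplicated()]))
            raise ValidationError(f"duplicate gene ids: {', '.join(dups)}")
        if self.values.isna().any().any():
            raise ValidationError("matrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("matrix contains negative intensities")
        for condition in self.conditions:
            if len(self.samples_for(condition)) < 2:
                raise ValidationError(
                    f"condition {condition!r} has fewer than 2 replicates"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for sample in self.values.columns:
            seen.setdefault(self.design[sample], None)
        return list(seen)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.design[s] == condition]

    def condition_means(self) -> pd.DataFrame:
        """Linear-scale per-condition means, genes × conditions."""
        return pd.DataFrame(
            {c: self.values[self.samples_for(c)].mean(axis=1) for c in self.conditions}
        )

    def subset_conditions(self, conditions: Sequence[str]) -> "ExpressionMatrix":
        keep = [s for s in self.values.columns if self.design[s] in set(conditions)]
        absent = set(conditions) - set(self.design.values())
        if absent:
            raise ConfigurationError(f"unknown conditions: {', '.join(sorted(absent))}")
        return ExpressionMatrix(
            self.values[keep].copy(), {s: self.design[s] for s in keep}
        )


@dataclass
class AnnotationSets:
    """Gene-set annotation collection (GMT-shaped).

    ``categories`` maps category id → (human-readable name, member gene set).
    Member sets must be non-empty.  If the collection was restricted to a
    gene universe at load time, that universe is recorded in ``universe``.
    """

    categories: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for cid, (_, members) in self.categories.items():
            if not members:
                raise ValidationError(f"category {cid!r} has no members")

    def __len__(self) -> int:
        return len(self.categories)

    def members(self, category_id: str) -> frozenset[str]:
        return self.categories[category_id][1]

    def restrict_to(self, universe: Iterable[str]) -> "AnnotationSets":
        """Intersect every category with ``universe``; empty categories drop."""
        uni = frozenset(normalize_gene_id(g) for g in universe)
        kept = {
            cid: (name, members & uni)
            for cid, (name, members) in self.categories.items()
            if members & uni
        }
        return AnnotationSets(kept, universe=uni)


# ---------------------------------------------------------------------------
# FPKM tables


def read_fpkm_table(path: str | Path) -> list[FpkmRecord]:
    """Read a TSV with header columns gene_id, fpkm, conf_lo, conf_hi."""
    path = Path(path)
    records: list[FpkmRecord] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n")
        expected = "\t".join(FPKM_COLUMNS)
        if header != expected:
            raise ParseError(
                f"{path}:1: expected header {expected!r}, got {header!r}"
            )
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            gene = normalize_gene_id(parts[0])
            try:
                fpkm, lo, hi = (float(x) for x in parts[1:])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
            if gene in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene id {gene}")
            seen.add(gene)
            records.append(FpkmRecord(gene, fpkm, lo, hi))
    return records


def write_fpkm_table(records: Iterable[FpkmRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("\t".join(FPKM_COLUMNS) + "\n")
        for rec in records:
            handle.write(
                f"{rec.gene}\t{rec.fpkm!r}\t{rec.conf_lo!r}\t{rec.conf_hi!r}\n"
            )


# ---------------------------------------------------------------------------
# Expression matrices and designs


def read_design(path: str | Path) -> dict[str, str]:
    """Read a YAML/JSON design file mapping sample name → condition label."""
    path = Path(path)
    with path.open(encoding="utf-8") as handle:
        loaded = yaml.safe_load(handle)
    if not isinstance(loaded, Mapping) or not loaded:
        raise ConfigurationError(f"{path}: design must be a non-empty mapping")
    return {str(k): str(v) for k, v in loaded.items()}


def write_design(design: Mapping[str, str], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(dict(design), indent=1, sort_keys=False) + "\n", encoding="utf-8"
    )


def read_expression_matrix(path: str | Path, design: Mapping[str, str]) -> ExpressionMatrix:
    """Read a TSV (gene_id + one column per sample) against a design map."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = frame.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}"
            )
        numeric[col] = converted.to_numpy()
    missing = [c for c in numeric.columns if c not in design]
    if missing:
        raise ConfigurationError(
            f"{path}: design does not cover sample columns: {', '.join(missing)}"
        )
    return ExpressionMatrix(numeric, {s: design[s] for s in numeric.columns})


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    # repr round-trips float64 exactly in python 3
    out.to_csv(path, sep="\t", float_format=None)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> AnnotationSets:
    """Read a GMT file: category_id TAB description TAB member TAB member ..."""
    path = Path(path)
    categories: dict[str, tuple[str, frozenset[str]]] = {}
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            cid, name = parts[0], parts[1]
            if cid in categories:
                raise ValidationError(f"{path}:{lineno}: duplicate category id {cid!r}")
            members = frozenset(normalize_gene_id(g) for g in parts[2:] if g.strip())
            if not members:
                raise ParseError(f"{path}:{lineno}: category {cid!r} has no members")
            categories[cid] = (name, members)
    return AnnotationSets(categories)


def write_gmt(annotations: AnnotationSets, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        for cid, (name, members) in annotations.categories.items():
            handle.write("\t".join([cid, name, *sorted(members)]) + "\n")


def read_gene_list(path: str | Path) -> frozenset[str]:
    """One gene id per line."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return frozenset(normalize_gene_id(x) for x in lines if x.strip())


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{g}\n" for g in sorted(genes)), encoding="utf-8"
    )
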