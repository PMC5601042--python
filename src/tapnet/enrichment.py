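"""Hypergeometric category enrichment and log2 fold-change heatmap matrices.

Enrichment is the one-sided upper-tail hypergeometric test of a gene
selection against a background: with ``N`` background genes, ``K`` of them in
the category, a selection of size ``n`` containing ``k`` category members,

    p = P(X >= k),  X ~ Hypergeometric(N, K, n).

Categories are flagged at raw p < alpha (mirroring asterisks at P < 0.05);
a Benjamini-Hochberg column is appended per class for modern use but does not
drive the flag.  Heatmap matrices are per-gene log2 ratios of mutant to
wild-type condition means with a pseudocount, row-ordered by deterministic
average-linkage hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .cascade import CascadePartition
from .exceptions import DomainError, ValidationError
from .io import AnnotationSets, ExpressionMatrix

ENRICHMENT_COLUMNS = (
    "class", "category_id", "category_name", "N", "K", "n", "k",
    "p_value", "bh_q", "enriched",
)


@dataclass(frozen=True)
class EnrichmentRow:
    category_id: str
    N: int
    K: int
    n: int
    k: int
    p_value: float
    enriched_flag: bool


def hypergeom_enrich(
    selection: Iterable[str],
    category: Iterable[str],
    background: Iterable[str],
    alpha: float = 0.05,
    category_id: str = "",
) -> EnrichmentRow:
    """Upper-tail hypergeometric enrichment of ``selection`` in ``category``."""
    background = frozenset(background)
    if not background:
        raise DomainError("background is empty")
    selection = frozenset(selection)
    if not selection <= background:
        stray = sorted(selection - background)[:10]
        raise ValidationError("selection not contained in background: " + ", ".join(stray))
    category = frozenset(category) & background
    N, K, n = len(background), len(category), len(selection)
    k = len(selection & category)
    # P(X >= k); sf(k-1) is exact for the discrete tail
    p = float(min(1.0, hypergeom.sf(k - 1, N, K, n)))
    return EnrichmentRow(category_id, N, K, n, k, p, p < alpha)


def enrich_all(
    classes: CascadePartition | Mapping[str, Iterable[str]],
    annotations: AnnotationSets,
    background: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment of every class against every category.

    Returns one row per (class, category), sorted by class, ascending p,
    then category id.  Selections are intersected with the background before
    testing (a class may contain genes outside the annotation universe).
    """
    background = frozenset(background)
    if isinstance(classes, CascadePartition):
        class_sets = {
            label: genes
            for label, genes in classes.class_sets.items()
            if label != "not_gated"
        }
    else:
        class_sets = {label: frozenset(genes) for label, genes in classes.items()}

    rows = []
    for label in class_sets:
        selection = frozenset(class_sets[label]) & background
        for cid, (name, members) in annotations.categories.items():
            row = hypergeom_enrich(selection, members, background, alpha, cid)
            rows.append(
                {
                    "class": label,
                    "category_id": cid,
                    "category_name": name,
                    "N": row.N,
                    "K": row.K,
                    "n": row.n,
                    "k": row.k,
                    "p_value": row.p_value,
                    "enriched": row.enriched_flag,
                }
            )
    frame = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c != "bh_q"])
    if frame.empty:
        return frame.reindex(columns=list(ENRICHMENT_COLUMNS))
    frame["bh_q"] = np.nan
    for label in frame["class"].unique():
        mask = frame["class"] == label
        frame.loc[mask, "bh_q"] = multipletests(
            frame.loc[mask, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    frame = frame.sort_values(
        ["class", "p_value", "category_id"], kind="stable"
    ).reset_index(drop=True)
    return frame[list(ENRICHMENT_COLUMNS)]


# ---------------------------------------------------------------------------
# Heatmap matrices


@dataclass(frozen=True)
class HeatmapMatrix:
    """Genes x mutants log2 fold-change matrix with a deterministic row order."""

    values: pd.DataFrame
    leaf_order: tuple[str, ...]

    def ordered(self) -> pd.DataFrame:
        return self.values.loc[list(self.leaf_order)]


def log2fc_matrix(
    matrix: ExpressionMatrix,
    genes: Sequence[str] | None = None,
    pseudocount: float = 1.0,
    reference: str = "wt",
) -> HeatmapMatrix:
    """log2((mutant mean + pc) / (WT mean + pc)) per gene and mutant.

    Rows are clustered with average linkage on Euclidean distances; the gene
    list is lexicographically pre-sorted so ties and leaf rotations resolve
    deterministically.
    """
    if reference not in matrix.conditions:
        raise ValidationError(f"reference condition {reference!r} not in matrix")
    if genes is None:
        genes = matrix.genes
    genes = sorted({str(g).strip().upper() for g in genes})
    unknown = [g for g in genes if g not in set(matrix.genes)]
    if unknown:
        raise ValidationError("unknown genes: " + ", ".join(unknown[:10]))
    means = matrix.condition_means().loc[genes]
    mutants = [c for c in matrix.conditions if c != reference]
    with np.errstate(divide="raise"):
        values = pd.DataFrame(
            {
                m: np.log2(
                    (means[m].to_numpy() + pseudocount)
                    / (means[reference].to_numpy() + pseudocount)
                )
                for m in mutants
            },
            index=genes,
        )
    if not np.isfinite(values.to_numpy()).all():
        raise DomainError("non-finite log2 ratios; use a positive pseudocount")
    if len(genes) > 2:
        z = linkage(values.to_numpy(), method="average", metric="euclidean")
        order = leaves_list(z)
        leaf_order = tuple(values.index[i] for i in order)
    else:
        leaf_order = tuple(genes)
    return HeatmapMatrix(values, leaf_order)


def write_heatmap(heatmap: HeatmapMatrix, prefix) -> None:
    from pathlib import Path

    prefix = Path(prefix)
    out = heatmap.ordered().copy()
    out.index.name = "gene_id"
    out.to_csv(prefix.with_suffix(".tsv"), sep="\t")
    prefix.with_name(prefix.name + "_leaf_order.txt").write_text(
        "".join(f"{g}\n" for g in heatmap.leaf_order), encoding="utf-8"
    )
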