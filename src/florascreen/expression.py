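"""Fold-change enrichment screen over a linear-scale expression matrix.

Genes are ranked per flower organ / developmental-stage category by their
log2 ratio against the developed-rosette reference, ``log2(FL) − log2(R)``;
a gene is called up-regulated when the ratio strictly exceeds 1 (i.e. more
than 2-fold).  Category up-sets are combined into Venn region counts and an
ordered union.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "log2fc",
    "rank_and_filter",
    "venn_counts",
    "union_unique",
    "collapse_probes",
    "screen_categories",
]


def log2fc(matrix: pd.DataFrame, category: str, reference: str) -> pd.Series:
    """Per-gene log2 fold change of ``category`` over ``reference``.

    ``matrix`` is genes × conditions on linear scale.  Genes with a
    non-positive or missing value in either column are excluded (the
    caller can diff the index to obtain the coverage report).
    """
    for col in (category, reference):
        if col not in matrix.columns:
            raise KeyError(f"column {col!r} not in matrix")
    fl = matrix[category].astype(float)
    r = matrix[reference].astype(float)
    ok = (fl > 0) & (r > 0) & fl.notna() & r.notna()
    return np.log2(fl[ok]) - np.log2(r[ok])


def rank_and_filter(values: pd.Series, threshold: float = 1.0) -> pd.Series:
    """Up-regulated genes sorted by descending log2FC.

    Strict inequality at the threshold: a gene at exactly 2-fold
    (log2FC = 1) is excluded.  Ties are broken by gene id.
    """
    vals = values[np.isfinite(values)]
    up = vals[vals > threshold]
    order = sorted(up.index, key=lambda g: (-up[g], str(g)))
    return up.loc[order]


def venn_counts(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Count of genes in every exclusive membership region.

    Keys are tuples of the category names a region belongs to (all
    ``2^k − 1`` non-empty patterns, in category order); values are the
    number of genes exactly in those categories and no others.
    """
    if len(sets) < 2:
        raise ValueError("venn needs at least 2 sets")
    if len(sets) > 6:
        raise ValueError("venn with more than 6 sets is unreadable")
    names = list(sets)
    counts: dict[tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            counts[combo] = len(inside - outside)
    return counts


def union_unique(sets: dict[str, list | set]) -> list:
    """Union of category gene lists preserving first-seen order."""
    seen: dict = {}
    for members in sets.values():
        for g in members:
            seen.setdefault(g, None)
    return list(seen)


def collapse_probes(matrix: pd.DataFrame, gene_col: str = "gene_id") -> pd.DataFrame:
    """Collapse multiple probes per gene by the per-condition maximum."""
    return matrix.groupby(gene_col).max()


def screen_categories(
    matrix: pd.DataFrame,
    categories: list[str],
    reference: str,
    threshold: float = 1.0,
) -> dict:
    """Run the fold-change screen over several categories.

    Returns a dict with per-category ranked up-sets (``Series`` of log2FC),
    the Venn region counts over the up-sets, the ordered union, and a
    coverage report (genes excluded per category for missing or
    non-positive values).
    """
    up: dict[str, pd.Series] = {}
    coverage: dict[str, int] = {}
    for cat in categories:
        fc = log2fc(matrix, cat, reference)
        coverage[cat] = len(matrix) - len(fc)
        up[cat] = rank_and_filter(fc, threshold)
    up_sets = {cat: set(s.index) for cat, s in up.items()}
    result = {
        "up": up,
        "coverage_excluded": coverage,
        "union": union_unique({c: list(s.index) for c, s in up.items()}),
    }
    if len(categories) >= 2:
        result["venn"] = venn_counts(up_sets)
    return result
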