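"""Gene-set enrichment by right-tailed Fisher exact test and the weighted
up-minus-down developmental score.

For a gene list of size ``n`` drawn from a universe of size ``N``, the
enrichment p-value of a category of size ``K`` with observed overlap
``k`` is the upper hypergeometric tail P(X >= k) -- equivalently a
right-tailed Fisher exact test on the 2x2 membership table. The weighted
developmental score of a category compares its enrichment in the
up-regulated versus the down-regulated list:

    score = -log10(p_up) - (-log10(p_down))

so positive scores mark net up-regulated programs and the score is
exactly antisymmetric under swapping the two lists.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

logger = logging.getLogger(__name__)


@dataclass
class AnnotationCollection:
    """Named gene categories over an explicit gene universe.

    Categories are clipped to the universe on construction, so the
    invariant ``category <= universe`` always holds.
    """

    categories: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        self.categories = {
            name: frozenset(genes) & self.universe for name, genes in self.categories.items()
        }

    def __len__(self) -> int:
        return len(self.categories)


def hypergeom_right_tail(overlap: int, list_size: int, category_size: int, universe_size: int):
    """P(X >= overlap) for X ~ Hypergeom(universe_size, category_size, list_size).

    Accepts scalars or equally-shaped integer arrays.
    """
    return stats.hypergeom.sf(np.asarray(overlap) - 1, universe_size, category_size, list_size)


def fisher_enrichment(gene_list, annotations: AnnotationCollection) -> pd.DataFrame:
    """Right-tailed Fisher enrichment of every category against a gene list.

    Genes outside the universe are dropped with a logged count. Returns a
    DataFrame indexed by category name with columns ``overlap``,
    ``category_size``, ``list_size``, ``universe_size`` and ``p``, sorted
    ascending by p with ties broken by category name.
    """
    if not annotations.universe:
        raise DataError("annotation universe is empty")
    genes = frozenset(gene_list)
    outside = genes - annotations.universe
    if outside:
        logger.info("dropping %d genes outside the annotation universe", len(outside))
        genes &= annotations.universe

    names = sorted(annotations.categories)
    n_univ = len(annotations.universe)
    n_list = len(genes)
    overlap = np.array([len(annotations.categories[c] & genes) for c in names], dtype=int)
    cat_size = np.array([len(annotations.categories[c]) for c in names], dtype=int)
    p = hypergeom_right_tail(overlap, n_list, cat_size, n_univ)
    result = pd.DataFrame(
        {
            "overlap": overlap,
            "category_size": cat_size,
            "list_size": n_list,
            "universe_size": n_univ,
            "p": np.clip(p, 0.0, 1.0),
        },
        index=pd.Index(names, name="category"),
    )
    return result.sort_values(["p", "category"], kind="stable").rename_axis("category")


def weighted_development_score(
    up_result: pd.DataFrame, down_result: pd.DataFrame
) -> pd.DataFrame:
    """Per-category score = -log10(p_up) + log10(p_down).

    Positive scores flag programs enriched in the up-regulated list (the
    red, positive half of the usual barplot), negative scores programs
    enriched in the down-regulated list. Zero p-values are clamped to the
    smallest positive float with a warning so the logarithm stays finite.
    """
    cats = set(up_result.index)
    if cats != set(down_result.index):
        raise DataError("up and down enrichment results cover different categories")
    names = sorted(cats)
    p_up = up_result.loc[names, "p"].to_numpy(dtype=float)
    p_down = down_result.loc[names, "p"].to_numpy(dtype=float)
    tiny = np.finfo(float).tiny
    if (p_up <= 0).any() or (p_down <= 0).any():
        logger.warning("zero p-values clamped to %.3g before taking logs", tiny)
        p_up = np.maximum(p_up, tiny)
        p_down = np.maximum(p_down, tiny)
    score = -np.log10(p_up) + np.log10(p_down)
    table = pd.DataFrame(
        {
            "p_up": p_up,
            "p_down": p_down,
            "score": score,
            "program": np.where(score > 0, "up", np.where(score < 0, "down", "balanced")),
        },
        index=pd.Index(names, name="category"),
    )
    return table.sort_values(["score", "category"], ascending=[False, True], kind="stable")


def rank_categories(table: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Top ``top_n`` categories of an enrichment or score table.

    Enrichment tables (column ``p``) rank ascending by p; score tables
    (column ``score``) rank by descending absolute score. Ties break
    alphabetically, so the ordering is stable and reproducible.
    """
    if top_n < 1:
        raise DataError("top_n must be >= 1")
    if "p" in table.columns:
        ranked = table.assign(_name=table.index).sort_values(["p", "_name"], kind="stable")
    elif "score" in table.columns:
        ranked = table.assign(_abs=table["score"].abs(), _name=table.index).sort_values(
            ["_abs", "_name"], ascending=[False, True], kind="stable"
        )
        ranked = ranked.drop(columns="_abs")
    else:
        raise DataError("table has neither a 'p' nor a 'score' column")
    ranked = ranked.drop(columns="_name").head(top_n)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return ranked
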