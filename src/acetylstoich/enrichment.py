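"""Category over-representation for significantly changed proteins.

Standard ORA: for a list of n significant proteins drawn from a background
universe of N quantifiable proteins, a category with m members in the
universe and k hits in the list has fold enrichment (k/n)/(m/N) and an
upper-tail hypergeometric p-value P(X >= k). The background is the set of
proteins with at least one quantified site (conditioning on detectability),
not the whole proteome; note this caps attainable fold enrichment at N/n.
p-values are BH-adjusted across all tested categories; display filters
(fold > min_fold, q < fdr_cut, top_n by fold) mirror the usual pathway-bar
presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .stats import bh_fdr

__all__ = [
    "CategoryAnnotation",
    "fold_enrichment",
    "hypergeom_upper",
    "enrich",
    "ENRICHMENT_COLUMNS",
]


@dataclass(frozen=True)
class CategoryAnnotation:
    """A named category (e.g. a pathway) with its member proteins."""

    category_id: str
    category_name: str
    member_protein_ids: frozenset

    def __post_init__(self):
        object.__setattr__(
            self, "member_protein_ids", frozenset(self.member_protein_ids)
        )


def fold_enrichment(k: int, n: int, m: int, N: int) -> float:
    """(k/n) / (m/N): hit rate in the list over rate in the universe."""
    if N <= 0 or n <= 0 or m <= 0:
        raise ValueError("list size, category size and universe must be positive")
    return (k / n) / (m / N)


def hypergeom_upper(k: int, n: int, m: int, N: int) -> float:
    """P(X >= k) drawing n from a universe of N with m marked proteins."""
    if N <= 0 or n <= 0 or m <= 0:
        raise ValueError("list size, category size and universe must be positive")
    if k > min(n, m) or k < 0 or n > N or m > N:
        raise ValueError("impossible hypergeometric configuration")
    return float(hypergeom.sf(k - 1, N, m, n))


ENRICHMENT_COLUMNS = [
    "category_id",
    "category_name",
    "hits",
    "list_size",
    "category_size",
    "universe_size",
    "fold_enrichment",
    "p",
    "q_bh",
]


def _as_annotations(
    annotations, names: Mapping[str, str] | None
) -> list[CategoryAnnotation]:
    if isinstance(annotations, pd.DataFrame):
        out = []
        for cat, rows in annotations.groupby("category_id", sort=True):
            name = (names or {}).get(cat, cat)
            out.append(CategoryAnnotation(cat, name, frozenset(rows["protein_id"])))
        return out
    return list(annotations)


def enrich(
    sig_proteins: Iterable,
    annotations,
    universe: Iterable,
    top_n: int | None = 10,
    min_fold: float = 5.0,
    fdr_cut: float = 0.05,
    names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Over-representation of categories in a significant-protein list.

    ``annotations`` is either a long-format DataFrame (category_id,
    protein_id) or an iterable of :class:`CategoryAnnotation`. Category
    membership is intersected with the universe; categories with fewer than
    two members in the universe are dropped before testing. BH adjustment
    runs across all tested categories, then rows are filtered to
    q < ``fdr_cut`` and fold > ``min_fold``, sorted by descending fold (ties
    by ascending q, then category_id) and truncated to ``top_n``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty background universe")
    sig = set(sig_proteins)
    if not sig <= universe:
        raise ValueError("significant proteins must be a subset of the universe")
    if not sig:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)

    N, n = len(universe), len(sig)
    rows = []
    for cat in _as_annotations(annotations, names):
        members = cat.member_protein_ids & universe
        m = len(members)
        if m < 2:  # singletons carry no testable signal
            continue
        k = len(members & sig)
        rows.append(
            {
                "category_id": cat.category_id,
                "category_name": cat.category_name,
                "hits": k,
                "list_size": n,
                "category_size": m,
                "universe_size": N,
                "fold_enrichment": fold_enrichment(k, n, m, N),
                "p": hypergeom_upper(k, n, m, N),
            }
        )
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    table = pd.DataFrame(rows).sort_values("category_id", kind="stable")
    table["q_bh"] = bh_fdr(table["p"])
    table = table[(table["q_bh"] < fdr_cut) & (table["fold_enrichment"] > min_fold)]
    table = table.sort_values(
        ["fold_enrichment", "q_bh", "category_id"],
        ascending=[False, True, True],
        kind="stable",
    )
    if top_n is not None:
        table = table.head(top_n)
    return table.reset_index(drop=True)[ENRICHMENT_COLUMNS]
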