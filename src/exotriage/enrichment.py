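"""Gene-set over-representation analysis (ORA) with an enrichment-strength
statistic.

For a query list of q genes and a term containing K genes out of a universe
of N, the expected overlap is ``K * q / N``, and

* ``strength = log10(observed / expected)`` — the magnitude statistic many
  annotation servers print at two decimals;
* the p-value is the one-sided (enrichment) hypergeometric tail, i.e.
  Fisher's exact test with alternative "greater";
* FDR control is Benjamini–Hochberg, applied within each annotation
  category independently (GO Process, KEGG, ...) by default.

The default universe is 19,566 genes (the human protein universe of the
annotation source whose strengths this module mirrors); it is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .variant_io import GeneSet, GeneSetCollection

DEFAULT_UNIVERSE = 19_566
DEFAULT_FDR_CUT = 0.05


@dataclass(frozen=True)
class EnrichRecord:
    term_id: str
    description: str
    category: str
    observed: int
    background_count: int
    expected: float
    strength: float  # NaN when observed == 0
    p: float
    fdr: float = math.nan
    genes: tuple[str, ...] = ()

    @property
    def strength_2dp(self) -> float:
        return round(self.strength, 2) if not math.isnan(self.strength) else math.nan


def ora_term(
    term: GeneSet,
    query: Sequence[str],
    universe_size: int = DEFAULT_UNIVERSE,
    category: str = "uncategorized",
) -> EnrichRecord:
    """Over-representation of one term within a query gene list.

    Query genes are assumed to be members of the universe. With zero
    overlap the strength is undefined (NaN) and p = 1.
    """
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query gene list")
    k_bg = len(term.genes)
    if universe_size < max(len(query_set), k_bg):
        raise ValueError(
            f"universe_size {universe_size} smaller than query ({len(query_set)}) "
            f"or term ({k_bg})"
        )
    hits = tuple(sorted(query_set.intersection(term.genes)))
    observed = len(hits)
    expected = k_bg * len(query_set) / universe_size
    if observed == 0:
        strength, p = math.nan, 1.0
    else:
        strength = math.log10(observed / expected)
        # P(X >= observed), X ~ Hypergeom(N, K, q)
        p = float(stats.hypergeom.sf(observed - 1, universe_size, k_bg, len(query_set)))
    return EnrichRecord(
        term_id=term.term_id,
        description=term.description,
        category=category,
        observed=observed,
        background_count=k_bg,
        expected=expected,
        strength=strength,
        p=min(1.0, p),
        genes=hits,
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    collections: Iterable[GeneSetCollection],
    query: Sequence[str],
    universe_size: int = DEFAULT_UNIVERSE,
    fdr_cut: float = DEFAULT_FDR_CUT,
    per_category_fdr: bool = True,
) -> pd.DataFrame:
    """ORA over every term of every collection, with BH FDR.

    FDR is controlled within each category independently (set
    ``per_category_fdr=False`` for a single global family). Rows are sorted
    by (category, fdr, term_id); ``enriched`` flags fdr < fdr_cut. The
    output is invariant to query order.
    """
    records: list[EnrichRecord] = []
    for coll in collections:
        for term in coll:
            records.append(ora_term(term, query, universe_size, category=coll.category))
    if not records:
        return pd.DataFrame(
            columns=[
                "category", "term_id", "description", "observed",
                "background_count", "expected", "strength", "strength_2dp",
                "p", "fdr", "enriched", "genes",
            ]
        )
    df = pd.DataFrame(
        {
            "category": [r.category for r in records],
            "term_id": [r.term_id for r in records],
            "description": [r.description for r in records],
            "observed": [r.observed for r in records],
            "background_count": [r.background_count for r in records],
            "expected": [r.expected for r in records],
            "strength": [r.strength for r in records],
            "strength_2dp": [r.strength_2dp for r in records],
            "p": [r.p for r in records],
            "genes": [",".join(r.genes) for r in records],
        }
    )
    if per_category_fdr:
        df["fdr"] = df.groupby("category", group_keys=False)["p"].transform(
            lambda s: bh_adjust(s.to_numpy())
        )
    else:
        df["fdr"] = bh_adjust(df["p"].to_numpy())
    df["enriched"] = df["fdr"] < fdr_cut
    df = df.sort_values(["category", "fdr", "term_id"], kind="mergesort").reset_index(drop=True)
    return df[
        [
            "category", "term_id", "description", "observed",
            "background_count", "expected", "strength", "strength_2dp",
            "p", "fdr", "enriched", "genes",
        ]
    ]
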