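"""Gene-level alternate/reference allele-ratio burden test.

For each gene, the ref and alt allele counts of *all* its called sites —
synonymous and non-synonymous alike; the candidate-variant filters do not
apply here — are pooled into one case-vs-control 2x2 table and tested with
Fisher's exact test. The odds ratio is the sample cross-product ratio with
a Woolf 95% interval, and p-values are Bonferroni-corrected by the number
of genes tested in the scan.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .assoc import AlleleCount2x2, fisher_exact_2x2, odds_ratio_ci
from .variant_io import Cohort, VariantRecord, site_allele_counts, variant_key_column

logger = logging.getLogger(__name__)


class NoSitesError(ValueError):
    """A gene with no assigned variant sites."""


@dataclass(frozen=True)
class BurdenRecord:
    gene: str
    table: AlleleCount2x2
    or_: float
    ci_low: float
    ci_high: float
    p: float
    p_bonf: float
    significant: bool
    n_sites: int = 0


def gene_allele_table(
    gene: str,
    variants: Sequence[VariantRecord],
    annots: pd.DataFrame,
    cohort: Cohort,
) -> tuple[AlleleCount2x2, int]:
    """Pool per-site allele counts over every site annotated to ``gene``.

    Sites annotated to multiple genes contribute to each (the annotation
    table carries one row per gene assignment). Missing allele slots are
    excluded from both cells. Returns the table and the number of sites.
    """
    keys = set(variant_key_column(annots[annots["gene"] == gene]))
    sites = [v for v in variants if v.key_str in keys]
    if not sites:
        raise NoSitesError(f"gene {gene!r} has no assigned variant sites")
    a = b = c = d = 0
    for v in sites:
        case = site_allele_counts(v, cohort, "case")
        ctrl = site_allele_counts(v, cohort, "control")
        a += case.n_ref
        b += case.n_alt
        c += ctrl.n_ref
        d += ctrl.n_alt
    return AlleleCount2x2(a, b, c, d), len(sites)


def burden_test(
    gene: str,
    table: AlleleCount2x2,
    n_genes: int,
    alpha: float = 0.05,
    n_sites: int = 0,
) -> BurdenRecord:
    """Fisher test + Woolf CI + Bonferroni for one pooled gene table."""
    p = fisher_exact_2x2(table)
    or_, lo, hi, _ = odds_ratio_ci(table)
    p_bonf = min(1.0, p * n_genes)
    return BurdenRecord(
        gene=gene, table=table, or_=or_, ci_low=lo, ci_high=hi,
        p=p, p_bonf=p_bonf, significant=p_bonf < alpha, n_sites=n_sites,
    )


def burden_scan(
    genes: Sequence[str],
    variants: Sequence[VariantRecord],
    annots: pd.DataFrame,
    cohort: Cohort,
    alpha: float = 0.05,
) -> list[BurdenRecord]:
    """One burden record per gene, in deterministic (sorted) gene order.

    The Bonferroni factor is the number of genes actually tested in this
    scan. Genes without sites are skipped with a log entry.
    """
    if not genes:
        raise ValueError("burden_scan needs at least one gene")
    tables: dict[str, tuple[AlleleCount2x2, int]] = {}
    for gene in sorted(set(genes)):
        try:
            tables[gene] = gene_allele_table(gene, variants, annots, cohort)
        except NoSitesError:
            logger.warning("burden_scan: gene %s skipped (no sites)", gene)
    m = len(tables)
    return [
        burden_test(g, t, m, alpha=alpha, n_sites=ns) for g, (t, ns) in tables.items()
    ]


def burden_from_tables(
    tables: Mapping[str, AlleleCount2x2] | Mapping[str, tuple[int, int, int, int]],
    alpha: float = 0.05,
) -> list[BurdenRecord]:
    """Burden scan from precomputed pooled allele-count tables.

    Accepts either :class:`AlleleCount2x2` values or raw
    (case_ref, case_alt, control_ref, control_alt) tuples. This is the entry
    point for published per-gene count tables where genotype-level data is
    not available.
    """
    if not tables:
        raise ValueError("no tables given")
    norm = {
        g: t if isinstance(t, AlleleCount2x2) else AlleleCount2x2(*t)
        for g, t in tables.items()
    }
    m = len(norm)
    return [burden_test(g, norm[g], m, alpha=alpha) for g in sorted(norm)]


def burden_frame(records: Sequence[BurdenRecord]) -> pd.DataFrame:
    """Tabulate burden records (odds ratios printed at 6 d.p. downstream)."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "odds_ratio": [r.or_ for r in records],
            "p": [r.p for r in records],
            "p_bonferroni": [r.p_bonf for r in records],
            "case_ref": [r.table.case_ref for r in records],
            "case_alt": [r.table.case_alt for r in records],
            "control_ref": [r.table.control_ref for r in records],
            "control_alt": [r.table.control_alt for r in records],
            "ci_low": [r.ci_low for r in records],
            "ci_high": [r.ci_high for r in records],
            "n_sites": [r.n_sites for r in records],
            "significant": [r.significant for r in records],
        }
    )
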