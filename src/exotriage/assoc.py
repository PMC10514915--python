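"""Per-variant allelic case-control association.

The association unit is a 2x2 table of allele counts::

                ref   alt
        case     a     b
        control  c     d

tested with Fisher's exact test. The two-sided p-value follows the
minimum-likelihood convention: it is the sum, over all tables with the
observed margins, of hypergeometric point probabilities no larger than the
observed one, with ties decided at a relative tolerance of 1e-7 so the
definition is reproducible across platforms. The odds ratio is the sample
cross-product ratio b*c / (a*d) — cases' alt odds over controls' — with a
Woolf (log-normal) confidence interval; tables with a zero cell report OR 0
or infinity and fall back to a Haldane–Anscombe (+0.5) interval, flagged.

The significance screen keeps variants with p < 1e-7 and OR > 1, both
strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

#: relative tolerance on the "no larger than observed" pmf comparison
TIE_RTOL = 1e-7

DEFAULT_P_THRESHOLD = 1e-7
DEFAULT_OR_MIN = 1.0


@dataclass(frozen=True)
class AlleleCount2x2:
    """Case/control x ref/alt allele-count contingency table."""

    case_ref: int
    case_alt: int
    control_ref: int
    control_alt: int

    def __post_init__(self) -> None:
        cells = (self.case_ref, self.case_alt, self.control_ref, self.control_alt)
        if any(c != int(c) or c < 0 for c in cells):
            raise ValueError(f"cells must be non-negative integers, got {cells}")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.case_ref, self.case_alt, self.control_ref, self.control_alt)

    @property
    def total(self) -> int:
        return sum(self.cells)


def fisher_exact_2x2(table: AlleleCount2x2, alternative: str = "two-sided") -> float:
    """Fisher's exact test p-value for an allele-count table.

    ``alternative`` is "two-sided", "greater" (cases enriched for alt) or
    "less". One-sided p-values are hypergeometric tail sums; the two-sided
    p-value sums point probabilities <= the observed one at relative
    tolerance 1e-7. An all-zero table is an error.
    """
    a, b, c, d = table.cells
    n_tot = a + b + c + d
    if n_tot == 0:
        raise ValueError("cannot test an all-zero table")
    # condition on margins: case alleles n, total alt K, draw = case_alt
    n = a + b
    k_alt = b + d
    lo = max(0, n - (n_tot - k_alt))
    hi = min(n, k_alt)
    support = np.arange(lo, hi + 1)
    # hypergeometric pmf over the whole support via log-gamma (cheaper than
    # a frozen scipy distribution when called hundreds of thousands of times)
    logpmf = (
        _log_comb(k_alt, support)
        + _log_comb(n_tot - k_alt, n - support)
        - _log_comb(n_tot, n)
    )
    pmf = np.exp(logpmf)
    if alternative == "greater":
        return float(min(1.0, pmf[support >= b].sum()))
    if alternative == "less":
        return float(min(1.0, pmf[support <= b].sum()))
    if alternative != "two-sided":
        raise ValueError(f"unknown alternative {alternative!r}")
    p_obs = pmf[b - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + TIE_RTOL)].sum())
    return min(1.0, p)


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def odds_ratio_ci(
    table: AlleleCount2x2, alpha: float = 0.05
) -> tuple[float, float, float, bool]:
    """Sample odds ratio and Woolf CI; returns (or_, lo, hi, corrected).

    ``corrected`` is True when a zero cell forced the Haldane–Anscombe +0.5
    continuity correction for the interval (the point OR is then reported as
    0 or infinity as the zero pattern dictates).
    """
    a, b, c, d = table.cells
    z = stats.norm.ppf(1 - alpha / 2)
    if min(a, b, c, d) > 0:
        or_ = (b * c) / (a * d)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        log_or = math.log(or_)
        return or_, math.exp(log_or - z * se), math.exp(log_or + z * se), False
    # zero-cell handling: point estimate at the boundary, corrected interval
    if b == 0 or c == 0:
        or_ = 0.0 if (a > 0 or d > 0) else math.nan
    else:
        or_ = math.inf
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    or_c = (bb * cc) / (aa * dd)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = math.log(or_c)
    return or_, math.exp(log_or - z * se), math.exp(log_or + z * se), True


@dataclass(frozen=True)
class AssocRecord:
    variant_key: str
    table: AlleleCount2x2
    p: float
    or_: float
    ci_low: float
    ci_high: float
    significant: bool
    ci_corrected: bool = False


def association_test(
    variant_key: str,
    table: AlleleCount2x2,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    or_min: float = DEFAULT_OR_MIN,
    alpha: float = 0.05,
) -> AssocRecord:
    p = fisher_exact_2x2(table)
    or_, lo, hi, corrected = odds_ratio_ci(table, alpha=alpha)
    return AssocRecord(
        variant_key=variant_key,
        table=table,
        p=p,
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        significant=(p < p_threshold and or_ > or_min),
        ci_corrected=corrected,
    )


def associate(
    variants: Sequence,
    cohort,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    or_min: float = DEFAULT_OR_MIN,
) -> list[AssocRecord]:
    """Test every variant record's allelic table (missing slots excluded)."""
    from .variant_io import site_allele_counts

    out = []
    for rec in variants:
        case = site_allele_counts(rec, cohort, "case")
        ctrl = site_allele_counts(rec, cohort, "control")
        table = AlleleCount2x2(case.n_ref, case.n_alt, ctrl.n_ref, ctrl.n_alt)
        out.append(association_test(rec.key_str, table, p_threshold, or_min))
    return out


def select_significant(
    records: Iterable[AssocRecord],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    or_min: float = DEFAULT_OR_MIN,
) -> list[AssocRecord]:
    """Keep records with p < p_threshold AND OR > or_min (both strict)."""
    return [r for r in records if r.p < p_threshold and r.or_ > or_min]


def assoc_frame(records: Sequence[AssocRecord]) -> pd.DataFrame:
    """Tabulate association records for TSV output."""
    return pd.DataFrame(
        {
            "variant_key": [r.variant_key for r in records],
            "case_ref": [r.table.case_ref for r in records],
            "case_alt": [r.table.case_alt for r in records],
            "control_ref": [r.table.control_ref for r in records],
            "control_alt": [r.table.control_alt for r in records],
            "p": [r.p for r in records],
            "odds_ratio": [r.or_ for r in records],
            "ci_low": [r.ci_low for r in records],
            "ci_high": [r.ci_high for r in records],
            "ci_corrected": [r.ci_corrected for r in records],
            "significant": [r.significant for r in records],
        }
    )
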