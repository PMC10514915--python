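"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the Fisher oracle
enumerates hypergeometric tables in exact integer arithmetic, and the BH
oracle is the step-up formula written directly.
"""

from __future__ import annotations

from math import comb

# same documented tie rule as the implementation (relative 1e-7), but applied
# in exact rational arithmetic: include k iff w_k * 10^7 <= w_obs * (10^7 + 1)
_TEN7 = 10**7


def fisher_two_sided_exact(a: int, b: int, c: int, d: int):
    """Two-sided Fisher p by exhaustive enumeration, as an exact Fraction."""
    from fractions import Fraction

    n_row = a + b
    k_col = b + d
    n_tot = a + b + c + d
    lo = max(0, n_row - (n_tot - k_col))
    hi = min(n_row, k_col)
    weights = {k: comb(k_col, k) * comb(n_tot - k_col, n_row - k) for k in range(lo, hi + 1)}
    w_obs = weights[b]
    num = sum(w for w in weights.values() if w * _TEN7 <= w_obs * (_TEN7 + 1))
    return Fraction(num, comb(n_tot, n_row))


def fisher_one_sided_greater_exact(a: int, b: int, c: int, d: int):
    """P(case_alt >= b) under the conditional hypergeometric null."""
    from fractions import Fraction

    n_row = a + b
    k_col = b + d
    n_tot = a + b + c + d
    hi = min(n_row, k_col)
    num = sum(comb(k_col, k) * comb(n_tot - k_col, n_row - k) for k in range(b, hi + 1))
    return Fraction(num, comb(n_tot, n_row))


def bh_step_up(pvalues):
    """Benjamini–Hochberg adjusted p-values by the direct formula."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end  # 1-based ascending rank
        running_min = min(running_min, pvalues[idx] * m / rank)
        adjusted[idx] = running_min
    return adjusted


def iter_tables_with_margins_le(max_margin: int):
    """Yield every 2x2 table (a, b, c, d) whose four margins are all
    <= max_margin, excluding the all-zero table."""
    for n_row in range(0, max_margin + 1):  # case alleles
        for n_row2 in range(0, max_margin + 1):  # control alleles
            n_tot = n_row + n_row2
            if n_tot == 0:
                continue
            for k_col in range(max(0, n_tot - max_margin), min(max_margin, n_tot) + 1):
                lo = max(0, n_row - (n_tot - k_col))
                hi = min(n_row, k_col)
                for b in range(lo, hi + 1):
                    a = n_row - b
                    d = k_col - b
                    c = n_row2 - d
                    yield a, b, c, d
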