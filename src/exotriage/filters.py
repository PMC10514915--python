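"""The two variant-filtering approaches, as composable predicates.

Approach "case_control": significance screen (Fisher p < 1e-7 and OR > 1)
-> impact filter (MODERATE/HIGH) -> population-frequency filter
(gnomAD AF < 0.01).

Approach "panel": gene-panel membership -> impact filter (MODERATE/HIGH)
-> population-frequency filter (AF < 0.01 in BOTH gnomAD and 1000G).

Each predicate is a pure row filter over the annotation table, so the
surviving set is the intersection of the predicates and does not depend on
stage order; only the per-stage in/out accounting does. A variant with no
population-frequency entry is treated as novel (AF 0): it is kept and
flagged, since variants absent from the reference databases are exactly the
rare candidates the screen is after.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_io import GenePanel, variant_key_column

logger = logging.getLogger(__name__)

DEFAULT_IMPACTS = frozenset({"MODERATE", "HIGH"})
DEFAULT_MAX_AF = 0.01
AF_COLUMNS = {"gnomad": "af_gnomad", "1kg": "af_1kg"}


@dataclass
class FilterTrace:
    approach: str
    stages: list[tuple[str, int, int]]  # (name, n_in, n_out)
    surviving: list[str]  # variant keys of the last stage's output

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_in", "n_out"])


def impact_filter(
    annots: pd.DataFrame, allowed: Iterable[str] = DEFAULT_IMPACTS
) -> pd.DataFrame:
    """Keep rows whose impact class is in ``allowed``; missing impact is
    excluded (and counted separately in the log)."""
    allowed = set(allowed)
    n_missing = int(annots["impact"].isna().sum())
    if n_missing:
        logger.info("impact_filter: %d rows with missing impact excluded", n_missing)
    return annots[annots["impact"].isin(allowed)]


def af_filter(
    annots: pd.DataFrame,
    sources: Sequence[str] = ("gnomad",),
    max_af: float = DEFAULT_MAX_AF,
) -> pd.DataFrame:
    """Keep rows rare (AF < max_af, strict) in EVERY requested source.

    A missing frequency counts as 0 (novel variant) and the row is flagged
    in the log. An out-of-range frequency is an error.
    """
    if not sources:
        raise ValueError("at least one AF source is required")
    mask = pd.Series(True, index=annots.index)
    for src in sources:
        try:
            col = AF_COLUMNS[src]
        except KeyError:
            raise ValueError(f"unknown AF source {src!r}; known: {sorted(AF_COLUMNS)}") from None
        af = pd.to_numeric(annots[col], errors="coerce")
        known = af.dropna()
        if ((known < 0) | (known > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
        n_novel = int((af.isna() & mask).sum())
        if n_novel:
            logger.info("af_filter: %d rows missing %s treated as novel (kept)", n_novel, col)
        mask &= af.fillna(0.0) < max_af
    return annots[mask]


def panel_filter(annots: pd.DataFrame, panel: GenePanel) -> pd.DataFrame:
    """Keep rows whose gene symbol belongs to the panel (case-sensitive)."""
    if len(panel) == 0:
        raise ValueError("empty gene panel")
    return annots[annots["gene"].isin(panel.genes)]


def run_cascade(
    annots: pd.DataFrame,
    approach: str,
    panel: GenePanel | None = None,
    assoc_records: Sequence | None = None,
    allowed_impacts: Iterable[str] = DEFAULT_IMPACTS,
    max_af: float = DEFAULT_MAX_AF,
    p_threshold: float = 1e-7,
    or_min: float = 1.0,
) -> tuple[FilterTrace, pd.DataFrame]:
    """Run one filtering approach with per-stage accounting.

    Returns the trace and the surviving annotation rows. ``approach`` is
    "case_control" (requires ``assoc_records``) or "panel" (requires
    ``panel``).
    """
    stages: list[tuple[str, int, int]] = []
    df = annots

    def _stage(name: str, out: pd.DataFrame, n_in: int) -> pd.DataFrame:
        stages.append((name, n_in, len(out)))
        logger.info("%s | %s: %d -> %d", approach, name, n_in, len(out))
        return out

    if approach == "case_control":
        if assoc_records is None:
            raise ValueError("case_control approach requires assoc_records")
        from .assoc import select_significant

        sig_keys = {r.variant_key for r in select_significant(assoc_records, p_threshold, or_min)}
        keys = variant_key_column(df) if len(df) else pd.Series(dtype=str)
        df = _stage("significant_association", df[keys.isin(sig_keys)], len(df))
        df = _stage("impact_moderate_high", impact_filter(df, allowed_impacts), len(df))
        df = _stage("af_lt_0.01_gnomad", af_filter(df, ("gnomad",), max_af), len(df))
    elif approach == "panel":
        if panel is None:
            raise ValueError("panel approach requires a gene panel")
        df = _stage("panel_membership", panel_filter(df, panel), len(df))
        df = _stage("impact_moderate_high", impact_filter(df, allowed_impacts), len(df))
        df = _stage("af_lt_0.01_gnomad_and_1kg", af_filter(df, ("gnomad", "1kg"), max_af), len(df))
    else:
        raise ValueError(f"unknown approach {approach!r}")

    surviving = list(variant_key_column(df)) if len(df) else []
    return FilterTrace(approach=approach, stages=stages, surviving=surviving), df
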