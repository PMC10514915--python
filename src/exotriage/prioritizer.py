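"""Consensus-vote prioritization of candidate variants.

A variant that survives the rare-variant filters is prioritized when

1. at least half of the available in-silico predictors call it deleterious
   (loss-of-function consequences bypass this missense-oriented vote),
2. its scaled CADD score exceeds 20 (strict), and
3. its clinical-significance label is not benign (uncertain and conflicting
   interpretations are retained).

Eighteen predictors are supported. Raw tool labels (``DC``, ``PD``, ``T``,
``M`` ...) are normalized to {deleterious, non_deleterious, uncertain,
missing} through a configurable mapping; Mutation Assessor's ordinal grades
get their own entry because "medium" counts as deleterious only there, and
that reading is reversible via :class:`PrioritizerConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

#: the 18 in-silico predictors, in canonical (annotation-column) order
TOOL_ROSTER: tuple[str, ...] = (
    "mutation_taster", "provean", "sift", "sift4g", "polyphen2",
    "metasvm", "revel", "list_s2", "lrt", "m_cap", "mutation_assessor",
    "bayesdel_noaf", "metalr", "dann", "eigen", "eigen_pc",
    "fathmm", "fathmm_mkl",
)

#: consequence terms that denote loss of function and bypass the vote
LOF_EFFECTS = frozenset({
    "stop_gained", "frameshift_variant", "frameshift",
    "splice_acceptor_variant", "splice_donor_variant",
})


class CallClass(str, Enum):
    DELETERIOUS = "deleterious"
    NON_DELETERIOUS = "non_deleterious"
    UNCERTAIN = "uncertain"
    MISSING = "missing"


# Raw label -> class, shared across tools. DC disease causing, D deleterious/
# damaging, LDC likely disease causing, PD/P probably damaging, T tolerated,
# N neutral, B/LB (likely) benign, L low, U uncertain.
_BASE_LABEL_MAP: dict[str, CallClass] = {
    "DC": CallClass.DELETERIOUS,
    "D": CallClass.DELETERIOUS,
    "LDC": CallClass.DELETERIOUS,
    "PD": CallClass.DELETERIOUS,
    "P": CallClass.DELETERIOUS,
    "H": CallClass.DELETERIOUS,
    "T": CallClass.NON_DELETERIOUS,
    "N": CallClass.NON_DELETERIOUS,
    "B": CallClass.NON_DELETERIOUS,
    "LB": CallClass.NON_DELETERIOUS,
    "L": CallClass.NON_DELETERIOUS,
    "U": CallClass.UNCERTAIN,
}


class UnmappedLabelError(ValueError):
    """A raw predictor label with no entry in the active mapping."""


@dataclass(frozen=True)
class PrioritizerConfig:
    """Tunable rules of the prioritization stage.

    cadd_min: strict lower bound on the scaled CADD score (default 20).
    ma_medium_deleterious: whether Mutation Assessor "M" (medium) counts as
        a deleterious vote (default True; set False to require high only).
    p_deleterious: whether the bare "P" label counts as deleterious.
    vote_denominator: "available" (non-missing calls, default) or "fixed18".
    benign_labels: clinical-significance labels that exclude a variant.
    label_overrides: extra (tool, raw label) -> class entries.
    """

    cadd_min: float = 20.0
    ma_medium_deleterious: bool = True
    p_deleterious: bool = True
    vote_denominator: str = "available"
    benign_labels: frozenset[str] = frozenset({"benign"})
    label_overrides: Mapping[tuple[str, str], CallClass] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vote_denominator not in ("available", "fixed18"):
            raise ValueError("vote_denominator must be 'available' or 'fixed18'")


DEFAULT_CONFIG = PrioritizerConfig()


def normalize_call(tool: str, raw: str | None, config: PrioritizerConfig = DEFAULT_CONFIG) -> CallClass:
    """Map one tool's raw label to a call class.

    Empty/absent labels are missing; an unmapped label raises
    :class:`UnmappedLabelError` naming the tool and label — labels are never
    silently dropped.
    """
    if tool not in TOOL_ROSTER:
        raise ValueError(f"unknown tool {tool!r}; roster has {len(TOOL_ROSTER)} tools")
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
        return CallClass.MISSING
    label = str(raw).strip()
    if (tool, label) in config.label_overrides:
        return config.label_overrides[(tool, label)]
    if label == "M":
        # Mutation Assessor's ordinal "medium"; other tools do not emit M
        if tool != "mutation_assessor":
            raise UnmappedLabelError(f"label 'M' is only defined for mutation_assessor, got tool {tool!r}")
        return CallClass.DELETERIOUS if config.ma_medium_deleterious else CallClass.NON_DELETERIOUS
    if label == "P" and not config.p_deleterious:
        return CallClass.UNCERTAIN
    try:
        return _BASE_LABEL_MAP[label]
    except KeyError:
        raise UnmappedLabelError(f"unmapped label {label!r} for tool {tool!r}") from None


@dataclass(frozen=True)
class VoteResult:
    n_deleterious: int
    n_available: int
    threshold: int
    passed: bool


def consensus_vote(
    calls: Mapping[str, CallClass],
    config: PrioritizerConfig = DEFAULT_CONFIG,
) -> VoteResult:
    """Majority vote over normalized predictor calls.

    Uncertain calls count in the denominator but never in the numerator.
    The threshold is ``ceil(denominator / 2)`` ("at least half"); with the
    default denominator rule the denominator is the number of non-missing
    calls. Zero available calls raise ``ValueError("no_calls")`` — the
    caller decides whether a loss-of-function bypass applies.
    """
    unknown = set(calls) - set(TOOL_ROSTER)
    if unknown:
        raise ValueError(f"calls from tools outside the roster: {sorted(unknown)}")
    n_available = sum(1 for c in calls.values() if c != CallClass.MISSING)
    if n_available == 0:
        raise ValueError("no_calls")
    n_del = sum(1 for c in calls.values() if c == CallClass.DELETERIOUS)
    denom = len(TOOL_ROSTER) if config.vote_denominator == "fixed18" else n_available
    threshold = math.ceil(denom / 2)
    return VoteResult(n_del, n_available, threshold, passed=n_del >= threshold)


@dataclass(frozen=True)
class PriorityDecision:
    variant_key: str
    vote: VoteResult | None  # None when bypassed (LoF) or no calls
    vote_bypassed: bool
    cadd_pass: bool
    benign_excluded: bool
    prioritized: bool
    reasons: tuple[str, ...]

    @property
    def reasons_str(self) -> str:
        return ";".join(self.reasons)


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def prioritize(
    variant: Mapping,
    config: PrioritizerConfig = DEFAULT_CONFIG,
) -> PriorityDecision:
    """Apply the full prioritization rule to one annotated variant.

    ``variant`` is a mapping (annotation-table row) carrying ``effect``,
    ``cadd``, ``clinical_sig`` and one raw-label field per roster tool.
    Every rule outcome is recorded in ``reasons`` so a decision is auditable.
    """
    key = variant.get("variant_key") or (
        f"{variant['chrom']}:{variant['pos']}:{variant['ref']}:{variant['alt']}"
        if "chrom" in variant else "?"
    )
    reasons: list[str] = []

    effect = str(variant.get("effect") or "").strip().lower().replace(" ", "_")
    is_lof = effect in LOF_EFFECTS

    calls = {t: normalize_call(t, variant.get(t), config) for t in TOOL_ROSTER}
    vote: VoteResult | None = None
    bypassed = False
    if is_lof:
        bypassed = True
        reasons.append("vote:bypassed_lof")
    else:
        try:
            vote = consensus_vote(calls, config)
            reasons.append(
                f"vote:{'pass' if vote.passed else 'fail'}"
                f"({vote.n_deleterious}/{vote.n_available}>=?{vote.threshold})"
            )
        except ValueError:
            reasons.append("vote:no_calls")

    cadd = variant.get("cadd")
    if _is_missing(cadd):
        cadd_pass = False
        reasons.append("cadd:missing")
    else:
        cadd_pass = float(cadd) > config.cadd_min
        reasons.append(f"cadd:{'pass' if cadd_pass else 'fail'}({float(cadd):g})")

    clin = variant.get("clinical_sig")
    clin_norm = "" if _is_missing(clin) else str(clin).strip().lower().replace(" ", "_")
    benign_excluded = clin_norm in config.benign_labels
    if benign_excluded:
        reasons.append(f"clinical:benign_excluded({clin_norm})")
    elif clin_norm:
        reasons.append(f"clinical:retained({clin_norm})")

    vote_ok = bypassed or (vote is not None and vote.passed)
    prioritized = vote_ok and cadd_pass and not benign_excluded
    reasons.append(f"prioritized:{prioritized}")
    return PriorityDecision(
        variant_key=str(key),
        vote=vote,
        vote_bypassed=bypassed,
        cadd_pass=cadd_pass,
        benign_excluded=benign_excluded,
        prioritized=prioritized,
        reasons=tuple(reasons),
    )


def prioritize_table(annots, config: PrioritizerConfig = DEFAULT_CONFIG):
    """Vectorize :func:`prioritize` over an annotation DataFrame.

    Returns a DataFrame with one row per input variant: the vote tallies,
    gate outcomes, the final verdict and a semicolon-joined reasons column.
    Row order follows the input; identical inputs and config produce
    byte-identical output.
    """
    import pandas as pd
    from .variant_io import variant_key_column

    keys = variant_key_column(annots)
    rows = []
    for key, (_, row) in zip(keys, annots.iterrows()):
        d = prioritize({**row.to_dict(), "variant_key": key}, config)
        rows.append({
            "variant_key": d.variant_key,
            "gene": row.get("gene"),
            "n_deleterious": d.vote.n_deleterious if d.vote else None,
            "n_available": d.vote.n_available if d.vote else None,
            "vote_threshold": d.vote.threshold if d.vote else None,
            "vote_passed": d.vote.passed if d.vote else None,
            "vote_bypassed": d.vote_bypassed,
            "cadd_pass": d.cadd_pass,
            "benign_excluded": d.benign_excluded,
            "prioritized": d.prioritized,
            "reasons": d.reasons_str,
        })
    return pd.DataFrame(
        rows,
        columns=[
            "variant_key", "gene", "n_deleterious", "n_available",
            "vote_threshold", "vote_passed", "vote_bypassed", "cadd_pass",
            "benign_excluded", "prioritized", "reasons",
        ],
    )
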