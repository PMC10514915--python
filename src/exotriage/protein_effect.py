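"""Protein-level consequence of a premature stop codon.

A stop-gain at coding (CDS) position ``c`` places the new termination codon
at amino-acid index ``ceil(c / 3)`` — the stop codon itself carries that
index, so the translated peptide has one residue fewer. Domains are then
classified by interval comparison against the stop index: fully lost,
partially lost (spanning the stop), or retained. Whether the mutant
transcript yields a truncated protein or is removed by nonsense-mediated
decay is not adjudicated here; the report notes both outcomes are possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

NMD_NOTE = (
    "Truncated-protein production and transcript degradation by "
    "nonsense-mediated decay are both possible outcomes; this report does "
    "not adjudicate between them."
)


@dataclass(frozen=True)
class Domain:
    name: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.aa_start <= self.aa_end):
            raise ValueError(
                f"domain {self.name}: need 1 <= aa_start <= aa_end, "
                f"got [{self.aa_start}, {self.aa_end}]"
            )


@dataclass(frozen=True)
class TranscriptModel:
    transcript: str
    protein_length: int
    domains: tuple[Domain, ...] = ()

    def __post_init__(self) -> None:
        for d in self.domains:
            if d.aa_end > self.protein_length:
                raise ValueError(
                    f"domain {d.name} ends at {d.aa_end} beyond protein "
                    f"length {self.protein_length}"
                )

    @classmethod
    def from_domain_table(
        cls, transcript: str, protein_length: int, domains: pd.DataFrame
    ) -> "TranscriptModel":
        rows = domains[domains["transcript"] == transcript]
        return cls(
            transcript=transcript,
            protein_length=protein_length,
            domains=tuple(
                Domain(r["domain"], int(r["aa_start"]), int(r["aa_end"]))
                for _, r in rows.iterrows()
            ),
        )


@dataclass(frozen=True)
class TruncationReport:
    transcript: str
    stop_codon_index: int
    full_length: int
    retained_fraction: float  # translated residues / full length
    lost_domains: tuple[str, ...]
    partially_lost: tuple[str, ...]
    retained: tuple[str, ...]
    note: str = NMD_NOTE


def stop_codon_index(cds_pos: int) -> int:
    """Amino-acid index of the codon containing CDS position ``cds_pos``.

    The premature stop codon itself carries this index (positions 3k-2,
    3k-1, 3k all map to codon k).
    """
    if cds_pos < 1:
        raise ValueError(f"CDS position must be >= 1, got {cds_pos}")
    return math.ceil(cds_pos / 3)


def truncation_report(model: TranscriptModel, cds_pos: int) -> TruncationReport:
    """Classify every domain of ``model`` against a stop-gain at ``cds_pos``.

    A domain is lost when it starts at or after the stop codon, partially
    lost when it spans the stop, and retained when it ends before the stop.
    The three lists partition the domain list.
    """
    stop = stop_codon_index(cds_pos)
    if stop > model.protein_length:
        raise ValueError(
            f"stop codon {stop} beyond protein length {model.protein_length} "
            f"of {model.transcript}"
        )
    lost, partial, retained = [], [], []
    for d in model.domains:
        if d.aa_start >= stop:
            lost.append(d.name)
        elif d.aa_end >= stop:
            partial.append(d.name)
        else:
            retained.append(d.name)
    return TruncationReport(
        transcript=model.transcript,
        stop_codon_index=stop,
        full_length=model.protein_length,
        retained_fraction=(stop - 1) / model.protein_length,
        lost_domains=tuple(lost),
        partially_lost=tuple(partial),
        retained=tuple(retained),
    )


def report_frame(report: TruncationReport) -> pd.DataFrame:
    """One-row tabular form of a truncation report."""
    return pd.DataFrame(
        [
            {
                "transcript": report.transcript,
                "stop_codon_index": report.stop_codon_index,
                "full_length": report.full_length,
                "retained_fraction": report.retained_fraction,
                "lost_domains": ",".join(report.lost_domains),
                "partially_lost": ",".join(report.partially_lost),
                "retained_domains": ",".join(report.retained),
                "note": report.note,
            }
        ]
    )
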