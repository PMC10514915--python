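"""End-to-end orchestration: associate -> filter -> prioritize -> burden ->
enrich -> truncate, with a single config and a fixed output layout.

The pipeline is a pure function of (inputs, config): rerunning with the
same inputs and configuration reproduces byte-identical TSVs. Odds ratios
are printed at 6 decimals and enrichment strengths carry both a 2-decimal
display column and a full-precision column, so published tables can be
compared textually.

Output layout in the run directory::

    assoc.tsv  filter_trace.tsv  decisions.tsv  burden.tsv
    enrichment.tsv  truncations.tsv  run.log  config.yaml
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import burden as burden_mod
from . import enrichment as enrich_mod
from .filters import run_cascade
from .prioritizer import PrioritizerConfig, prioritize_table
from .protein_effect import TranscriptModel, report_frame, truncation_report
from .variant_io import (
    read_annotations, read_domains, read_gene_sets, read_panel, read_vcf,
    variant_key_column,
)

logger = logging.getLogger(__name__)

_HGVS_C_POS = re.compile(r"c\.(\d+)")


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run (defaults are the screen's
    standard operating point)."""

    vcf: str = ""
    annotations: str = ""
    samples: str = ""  # TSV: sample TAB case|control
    panel: str = ""
    gmt: str = ""
    domains: str = ""  # optional TSV: transcript, domain, aa_start, aa_end
    transcript_lengths: str = ""  # optional TSV: transcript, protein_length
    burden_tables: str = ""  # optional TSV of pooled per-gene counts
    out_dir: str = "triage_run"
    approach: str = "panel"  # panel | case_control | both
    assoc_p: float = 1e-7
    or_min: float = 1.0
    max_af: float = 0.01
    impacts: tuple[str, ...] = ("MODERATE", "HIGH")
    cadd_min: float = 20.0
    ma_medium_deleterious: bool = True
    vote_denominator: str = "available"
    bonferroni_alpha: float = 0.05
    fdr_cut: float = 0.05
    universe_size: int = 19_566
    burden_genes: tuple[str, ...] = ()  # default: genes of prioritized variants
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("impacts", "burden_genes"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _read_samples(path: str | Path) -> dict[str, str]:
    groups: dict[str, str] = {}
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2 or parts[1] not in ("case", "control"):
                raise ValueError(f"{path} line {lineno}: expected 'sample case|control'")
            groups[parts[0]] = parts[1]
    return groups


def _write_tsv(df: pd.DataFrame, path: Path, float_formats: dict[str, str] | None = None) -> None:
    out = df.copy()
    for col, fmt in (float_formats or {}).items():
        if col in out.columns:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else fmt % v)
    out.to_csv(path, sep="\t", index=False, na_rep="")


def run_all(config: RunConfig) -> Path:
    """Run every stage; returns the run directory. Any stage error is logged
    with its stage name and re-raised (nonzero exit through the CLI)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("exotriage")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))

    stage = "load_inputs"
    try:
        variants, cohort = read_vcf(config.vcf, _read_samples(config.samples))
        annots = read_annotations(config.annotations)
        panel = read_panel(config.panel) if config.panel else None
        logger.info("[%s] %d variants, %d samples, %d annotation rows",
                    stage, len(variants), len(cohort.samples), len(annots))

        stage = "associate"
        assoc_records = assoc_mod.associate(variants, cohort, config.assoc_p, config.or_min)
        _write_tsv(assoc_mod.assoc_frame(assoc_records), out / "assoc.tsv",
                   {"p": "%.6g", "odds_ratio": "%.6f", "ci_low": "%.6f", "ci_high": "%.6f"})

        stage = "filter"
        approaches = ["panel", "case_control"] if config.approach == "both" else [config.approach]
        traces, surviving_frames = [], []
        for ap in approaches:
            trace, df = run_cascade(
                annots, ap, panel=panel, assoc_records=assoc_records,
                allowed_impacts=config.impacts, max_af=config.max_af,
                p_threshold=config.assoc_p, or_min=config.or_min,
            )
            tf = trace.as_frame()
            tf.insert(0, "approach", ap)
            traces.append(tf)
            df = df.copy()
            df["approach"] = ap
            surviving_frames.append(df)
        _write_tsv(pd.concat(traces, ignore_index=True), out / "filter_trace.tsv")
        survivors = pd.concat(surviving_frames, ignore_index=True)
        survivors = survivors.drop_duplicates(
            subset=["chrom", "pos", "ref", "alt"], keep="first")

        stage = "prioritize"
        prio_cfg = PrioritizerConfig(
            cadd_min=config.cadd_min,
            ma_medium_deleterious=config.ma_medium_deleterious,
            vote_denominator=config.vote_denominator,
        )
        decisions = prioritize_table(survivors, prio_cfg)
        _write_tsv(decisions, out / "decisions.tsv")
        candidates = survivors[decisions["prioritized"].to_numpy(dtype=bool)]
        candidate_genes = sorted(candidates["gene"].dropna().unique())
        logger.info("[%s] %d prioritized candidates in %d genes",
                    stage, len(candidates), len(candidate_genes))

        stage = "burden"
        if config.burden_tables:
            tables_df = pd.read_csv(config.burden_tables, sep="\t")
            tables = {
                r["gene"]: (int(r["case_ref"]), int(r["case_alt"]),
                            int(r["control_ref"]), int(r["control_alt"]))
                for _, r in tables_df.iterrows()
            }
            burden_records = burden_mod.burden_from_tables(tables, alpha=config.bonferroni_alpha)
        else:
            genes = list(config.burden_genes) or candidate_genes
            burden_records = (
                burden_mod.burden_scan(genes, variants, annots, cohort,
                                       alpha=config.bonferroni_alpha)
                if genes else []
            )
        _write_tsv(burden_mod.burden_frame(burden_records), out / "burden.tsv",
                   {"odds_ratio": "%.6f", "p": "%.6g", "p_bonferroni": "%.6g",
                    "ci_low": "%.6f", "ci_high": "%.6f"})

        stage = "enrich"
        if config.gmt and candidate_genes:
            coll = read_gene_sets(config.gmt, category=Path(config.gmt).stem)
            table = enrich_mod.enrich([coll], candidate_genes,
                                      universe_size=config.universe_size,
                                      fdr_cut=config.fdr_cut)
        else:
            table = enrich_mod.enrich([], candidate_genes or ["NONE"])
        _write_tsv(table, out / "enrichment.tsv",
                   {"expected": "%.6g", "strength": "%.6g", "strength_2dp": "%.2f",
                    "p": "%.6g", "fdr": "%.6g"})

        stage = "truncate"
        trunc_frames = []
        if config.domains and config.transcript_lengths:
            domains = read_domains(config.domains)
            lengths = pd.read_csv(config.transcript_lengths, sep="\t")
            lengths = dict(zip(lengths["transcript"], lengths["protein_length"]))
            stops = candidates[candidates["effect"] == "stop_gained"]
            for _, row in stops.iterrows():
                m = _HGVS_C_POS.search(str(row.get("hgvs_c") or ""))
                tx = row.get("transcript")
                if not m or tx not in lengths:
                    logger.warning("[truncate] skipping %s: no CDS position or length",
                                   row.get("hgvs_c"))
                    continue
                model = TranscriptModel.from_domain_table(tx, int(lengths[tx]), domains)
                rep = truncation_report(model, int(m.group(1)))
                frame = report_frame(rep)
                frame.insert(0, "gene", row.get("gene"))
                trunc_frames.append(frame)
        trunc = (pd.concat(trunc_frames, ignore_index=True) if trunc_frames
                 else pd.DataFrame(columns=["gene", "transcript", "stop_codon_index",
                                            "full_length", "retained_fraction",
                                            "lost_domains", "partially_lost",
                                            "retained_domains", "note"]))
        _write_tsv(trunc, out / "truncations.tsv", {"retained_fraction": "%.6f"})
    except Exception:
        logger.exception("[%s] stage failed", stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    logger.info("run complete: %s", out)
    return out
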