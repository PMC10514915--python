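"""Seeded case/control exome-cohort simulator with ground truth.

The generator emulates the statistical structure the triage pipeline
assumes: a small case cohort (default 20) against a larger control cohort
(default 100); per-site alternate-allele frequencies drawn from a
rare-skewed Beta spectrum; case enrichment acting multiplicatively on the
alt-allele probability of enriched genes (``p_case = min(1, r * p_ctrl)``,
the simplest mechanism that yields a target pooled odds ratio near ``r`` in
the rare regime); diploid genotypes drawn binomially per sample; and
per-site annotations whose predictor labels agree with a latent
pathogenicity indicator with probability ``q`` per tool and whose CADD
scores come from class-conditional distributions.

Planted candidates are variants *designed to pass* the rare-variant
cascade and the prioritization rule: in-panel gene, MODERATE/HIGH impact,
rare in both population references, CADD from the pathogenic class, and
(for missense) predictor calls drawn with concordance ``q`` conditional on
the consensus vote passing. Their genotypes are deterministic heterozygous
carriers, mirroring a handful of case patients.

Everything is drawn from a single :class:`numpy.random.Generator` stream
seeded by ``SimConfig.seed``; the draw order is sites -> genotypes ->
annotations (documented so configuration growth does not silently shift
earlier draws). Identical configs produce byte-identical output files.

All gene symbols, panels and gene sets emitted here are synthetic
fixtures, not curated biological resources.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .prioritizer import (
    TOOL_ROSTER, CallClass, PrioritizerConfig, DEFAULT_CONFIG, consensus_vote,
)
from .variant_io import (
    Cohort, GenePanel, GeneSet, GeneSetCollection, VariantRecord,
    write_annotations, write_panel, write_vcf,
)

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")

#: per-tool raw-label vocabulary used when emitting predictor calls
_TOOL_VOCAB: dict[str, dict[CallClass, tuple[str, ...]]] = {
    "mutation_taster": {CallClass.DELETERIOUS: ("DC",), CallClass.NON_DELETERIOUS: ("N",)},
    "polyphen2": {CallClass.DELETERIOUS: ("PD",), CallClass.NON_DELETERIOUS: ("B",)},
    "revel": {CallClass.DELETERIOUS: ("LDC",), CallClass.NON_DELETERIOUS: ("LB",)},
    "mutation_assessor": {CallClass.DELETERIOUS: ("H", "M"), CallClass.NON_DELETERIOUS: ("L", "N")},
    "eigen": {CallClass.DELETERIOUS: ("P",), CallClass.NON_DELETERIOUS: ("B",)},
    "eigen_pc": {CallClass.DELETERIOUS: ("P",), CallClass.NON_DELETERIOUS: ("B",)},
}
_DEFAULT_VOCAB = {CallClass.DELETERIOUS: ("D",), CallClass.NON_DELETERIOUS: ("T", "N")}

_EFFECT_BY_IMPACT = {
    "HIGH": "stop_gained",
    "MODERATE": "missense_variant",
    "LOW": "synonymous_variant",
    "MODIFIER": "intron_variant",
}


@dataclass(frozen=True)
class GeneConfig:
    """Per-gene simulation parameters.

    ``af_alpha``/``af_beta`` parameterize the Beta distribution the control
    alt-allele probabilities are drawn from; ``enrichment`` is the
    multiplicative case risk factor r >= 1.
    """

    name: str
    n_sites: int = 80
    enrichment: float = 1.0
    af_alpha: float = 0.5
    af_beta: float = 20.0
    in_panel: bool = False

    def __post_init__(self) -> None:
        if self.enrichment < 1:
            raise ValueError(f"{self.name}: enrichment must be >= 1")
        if self.n_sites < 0:
            raise ValueError(f"{self.name}: n_sites must be >= 0")


@dataclass(frozen=True)
class PlantedVariant:
    """Specification of one deliberately planted variant.

    In carrier mode (default) ``n_case_carriers``/``n_control_carriers``
    heterozygous carriers are placed deterministically. In probability mode
    (``case_alt_p``/``control_alt_p`` set) genotypes are drawn binomially —
    used for high-contrast association spikes.
    """

    gene: str
    effect: str = "missense_variant"
    impact: str = "MODERATE"
    n_case_carriers: int = 1
    n_control_carriers: int = 0
    af_gnomad: float = 1e-4
    af_1kg: float = 1e-4
    cadd: float | None = None  # drawn from the pathogenic class when None
    clinical_sig: str | None = None
    case_alt_p: float | None = None
    control_alt_p: float | None = None
    candidate: bool = True  # counted in GroundTruth.planted_candidates


@dataclass
class SimConfig:
    """Full simulation scenario; ``seed`` fully determines the output."""

    genes: list[GeneConfig]
    planted: list[PlantedVariant] = field(default_factory=list)
    n_case: int = 20
    n_control: int = 100
    impact_fracs: tuple[float, float, float, float] = (0.02, 0.48, 0.30, 0.20)  # HIGH, MODERATE, LOW, MODIFIER
    predictor_concordance: float = 0.9
    predictor_missing_rate: float = 0.05
    genotype_missing_rate: float = 0.01
    background_pathogenic_frac: float = 0.05
    cadd_pathogenic: tuple[float, float, float, float] = (27.0, 3.0, 20.5, 45.0)  # mean, sd, lo, hi
    cadd_benign: tuple[float, float, float, float] = (8.0, 5.0, 0.0, 19.5)
    af_jitter_sd: float = 0.05  # relative jitter of annotation AF around truth
    panel_extra_genes: int = 100  # filler panel symbols beyond simulated genes
    universe_size: int = 19_566
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.impact_fracs) - 1.0) > 1e-9:
            raise ValueError("impact_fracs must sum to 1")
        for p in (self.predictor_concordance, self.predictor_missing_rate,
                  self.genotype_missing_rate, self.background_pathogenic_frac):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("both cohorts must be non-empty")


@dataclass
class GroundTruth:
    """What the generator actually emitted, for oracle-style assertions."""

    site_alt_counts: dict[str, tuple[int, int]]  # key -> (case_alt, control_alt)
    gene_enrichment: dict[str, float]  # configured r per gene
    gene_true_or: dict[str, float]  # pooled OR implied by the true site probabilities
    planted_candidates: list[str]  # variant keys designed to pass the cascade
    latent_pathogenic: dict[str, bool]  # key -> latent class

    def to_json(self) -> str:
        return json.dumps(
            {
                "site_alt_counts": self.site_alt_counts,
                "gene_enrichment": self.gene_enrichment,
                "gene_true_or": self.gene_true_or,
                "planted_candidates": self.planted_candidates,
                "latent_pathogenic": self.latent_pathogenic,
            },
            indent=1, sort_keys=True,
        )


@dataclass
class CohortData:
    """In-memory simulation result."""

    variants: list[VariantRecord]
    cohort: Cohort
    annotations: pd.DataFrame
    panel: GenePanel
    gene_sets: list[GeneSetCollection]
    truth: GroundTruth
    config: SimConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit VCF, annotation TSV, panel, GMT and truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "annotations": outdir / "annotations.tsv",
            "panel": outdir / "panel.txt",
            "gmt": outdir / "gene_sets.gmt",
            "truth": outdir / "truth.json",
            "samples": outdir / "samples.tsv",
        }
        with open(paths["samples"], "wt") as fh:
            for s, g in zip(self.cohort.samples, self.cohort.groups):
                fh.write(f"{s}\t{g}\n")
        write_vcf(paths["vcf"], self.variants, self.cohort)
        write_annotations(paths["annotations"], self.annotations)
        write_panel(paths["panel"], self.panel)
        with open(paths["gmt"], "wt") as fh:
            for coll in self.gene_sets:
                for s in coll:
                    fh.write("\t".join((s.term_id, s.description, *s.genes)) + "\n")
        paths["truth"].write_text(self.truth.to_json())
        return paths


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling did not converge")


def _slots_from_counts(counts: np.ndarray) -> np.ndarray:
    """Alt-dosage vector {0,1,2} per sample -> (n, 2) slot matrix."""
    n = counts.shape[0]
    slots = np.zeros((n, 2), dtype=np.int8)
    slots[:, 0] = (counts >= 1).astype(np.int8)
    slots[:, 1] = (counts == 2).astype(np.int8)
    return slots


def _emit_predictor_calls(
    rng: np.random.Generator,
    pathogenic: bool,
    q: float,
    missing_rate: float,
    require_vote_pass: bool = False,
    prio_config: PrioritizerConfig = DEFAULT_CONFIG,
) -> dict[str, str]:
    """Draw raw predictor labels around the latent truth.

    Each tool abstains with ``missing_rate``, otherwise agrees with the
    latent class with probability ``q`` and emits a raw label uniformly
    among that tool's labels for the class. With ``require_vote_pass`` the
    draw is repeated (rejection sampling within the seeded stream) until
    the consensus vote passes — planted candidates are designed to pass.
    """
    truth = CallClass.DELETERIOUS if pathogenic else CallClass.NON_DELETERIOUS
    flipped = CallClass.NON_DELETERIOUS if pathogenic else CallClass.DELETERIOUS
    for _ in range(1000):
        calls: dict[str, str] = {}
        classes: dict[str, CallClass] = {}
        for tool in TOOL_ROSTER:
            if rng.random() < missing_rate:
                calls[tool] = ""
                classes[tool] = CallClass.MISSING
                continue
            cls = truth if rng.random() < q else flipped
            vocab = _TOOL_VOCAB.get(tool, _DEFAULT_VOCAB)[cls]
            calls[tool] = vocab[int(rng.integers(len(vocab)))]
            classes[tool] = cls
        if not require_vote_pass:
            return calls
        try:
            if consensus_vote(classes, prio_config).passed:
                return calls
        except ValueError:
            pass
    raise RuntimeError("could not draw a vote-passing call set")


def simulate_cohort(config: SimConfig) -> CohortData:
    """Generate a full cohort with annotations, panel, gene sets and truth."""
    rng = np.random.default_rng(config.seed)
    n_case, n_ctrl = config.n_case, config.n_control
    samples = tuple(
        [f"case{i:03d}" for i in range(1, n_case + 1)]
        + [f"ctrl{i:03d}" for i in range(1, n_ctrl + 1)]
    )
    cohort = Cohort(samples, tuple(["case"] * n_case + ["control"] * n_ctrl))

    # --- stage 1: site frequencies per gene (draw order: config.genes order)
    site_p_ctrl: dict[str, np.ndarray] = {}
    site_p_case: dict[str, np.ndarray] = {}
    for gi, gene in enumerate(config.genes):
        p = rng.beta(gene.af_alpha, gene.af_beta, size=gene.n_sites)
        pc = np.minimum(1.0, gene.enrichment * p)
        n_clipped = int((gene.enrichment * p > 1.0).sum())
        if n_clipped:
            msg = (f"gene {gene.name}: {n_clipped}/{gene.n_sites} sites clipped "
                   f"(r x AF > 1)")
            if n_clipped > 0.1 * max(1, gene.n_sites):
                raise ValueError(msg)
            logger.warning(msg)
        site_p_ctrl[gene.name] = p
        site_p_case[gene.name] = pc

    # --- stage 2: genotypes (case block then control block per gene)
    records: list[VariantRecord] = []
    ann_rows: list[dict] = []
    truth_counts: dict[str, tuple[int, int]] = {}
    latent: dict[str, bool] = {}
    gene_keys: dict[str, list[str]] = {g.name: [] for g in config.genes}

    base_meta: list[tuple[VariantRecord, str, bool]] = []  # record, gene, planted?
    for gi, gene in enumerate(config.genes):
        chrom = str(1 + gi % 22)
        base = (gi + 1) * 1_000_000
        p, pc = site_p_ctrl[gene.name], site_p_case[gene.name]
        case_dos = rng.binomial(2, pc[None, :], size=(n_case, gene.n_sites))
        ctrl_dos = rng.binomial(2, p[None, :], size=(n_ctrl, gene.n_sites))
        if config.genotype_missing_rate > 0:
            miss_case = rng.random((n_case, gene.n_sites, 2)) < config.genotype_missing_rate
            miss_ctrl = rng.random((n_ctrl, gene.n_sites, 2)) < config.genotype_missing_rate
        else:
            miss_case = miss_ctrl = None
        for j in range(gene.n_sites):
            ref = _BASES[j % 4]
            alt = _BASES[(j + 1) % 4]
            slots = np.vstack([
                _slots_from_counts(case_dos[:, j]),
                _slots_from_counts(ctrl_dos[:, j]),
            ])
            if miss_case is not None:
                miss = np.vstack([miss_case[:, j, :], miss_ctrl[:, j, :]])
                slots = np.where(miss, -1, slots).astype(np.int8)
            rec = VariantRecord(chrom=chrom, pos=base + 10 * j, ref=ref, alt=alt,
                                genotypes=slots)
            base_meta.append((rec, gene.name, False))

    # planted genotypes: deterministic carriers (or binomial in probability mode)
    gene_index = {g.name: i for i, g in enumerate(config.genes)}
    planted_keys: list[str] = []
    planted_count: dict[str, int] = {}
    carrier_cursor = 0
    n_carrier_pool = min(11, n_case)  # mirror: candidates concentrated in a subset of cases
    planted_p: dict[str, tuple[float, float]] = {}
    for pi, pv in enumerate(config.planted):
        if pv.gene not in gene_index:
            raise ValueError(f"planted variant references unknown gene {pv.gene!r}")
        gi = gene_index[pv.gene]
        chrom = str(1 + gi % 22)
        pos = (gi + 1) * 1_000_000 + 900_000 + 10 * planted_count.get(pv.gene, 0)
        planted_count[pv.gene] = planted_count.get(pv.gene, 0) + 1
        slots = np.zeros((n_case + n_ctrl, 2), dtype=np.int8)
        if pv.case_alt_p is not None or pv.control_alt_p is not None:
            case_dos = rng.binomial(2, pv.case_alt_p or 0.0, size=n_case)
            ctrl_dos = rng.binomial(2, pv.control_alt_p or 0.0, size=n_ctrl)
            slots = np.vstack([_slots_from_counts(case_dos), _slots_from_counts(ctrl_dos)])
        else:
            for _ in range(pv.n_case_carriers):
                slots[carrier_cursor % n_carrier_pool, 1] = 1  # heterozygous
                carrier_cursor += 1
            for k in range(pv.n_control_carriers):
                slots[n_case + k, 1] = 1
        rec = VariantRecord(chrom=chrom, pos=pos, ref="C", alt="T", genotypes=slots)
        base_meta.append((rec, pv.gene, True))
        pk = rec.key_str
        if pv.candidate:
            planted_keys.append(pk)
        planted_p[pk] = (
            pv.case_alt_p if pv.case_alt_p is not None else pv.n_case_carriers / (2 * n_case),
            pv.control_alt_p if pv.control_alt_p is not None else pv.n_control_carriers / (2 * n_ctrl),
        )

    # --- stage 3: annotations, in emitted-record order
    site_counter: dict[str, int] = {}
    planted_by_key: dict[str, PlantedVariant] = {}
    # rebuild key -> planted spec association in emission order
    pc_tmp: dict[str, int] = {}
    for pv in config.planted:
        gi = gene_index[pv.gene]
        pos = (gi + 1) * 1_000_000 + 900_000 + 10 * pc_tmp.get(pv.gene, 0)
        pc_tmp[pv.gene] = pc_tmp.get(pv.gene, 0) + 1
        planted_by_key[f"{1 + gi % 22}:{pos}:C:T"] = pv

    impact_labels = ("HIGH", "MODERATE", "LOW", "MODIFIER")
    for rec, gene_name, is_planted in base_meta:
        key = rec.key_str
        gene_keys[gene_name].append(key)
        gcfg = config.genes[gene_index[gene_name]]
        site_counter[gene_name] = site_counter.get(gene_name, 0) + 1
        j = site_counter[gene_name]
        case_slots = rec.genotypes[:n_case]
        ctrl_slots = rec.genotypes[n_case:]
        truth_counts[key] = (int((case_slots == 1).sum()), int((ctrl_slots == 1).sum()))

        if is_planted:
            pv = planted_by_key[key]
            pathogenic = True
            impact = pv.impact
            effect = pv.effect
            af_g, af_k = pv.af_gnomad, pv.af_1kg
            cadd = pv.cadd if pv.cadd is not None else _truncated_normal(
                rng, *config.cadd_pathogenic)
            clin = pv.clinical_sig
            if effect == "missense_variant":
                calls = _emit_predictor_calls(
                    rng, True, config.predictor_concordance,
                    config.predictor_missing_rate, require_vote_pass=True)
            else:
                calls = {t: "" for t in TOOL_ROSTER}  # tools abstain on non-missense
        else:
            pathogenic = bool(rng.random() < config.background_pathogenic_frac)
            impact = impact_labels[int(rng.choice(4, p=config.impact_fracs))]
            effect = _EFFECT_BY_IMPACT[impact]
            # annotation AF tracks the true site frequency with mild jitter
            p_true = site_p_ctrl[gene_name][j - 1] if j - 1 < gcfg.n_sites else 1e-4
            af_g = float(np.clip(p_true * (1 + rng.normal(0, config.af_jitter_sd)), 0, 1))
            af_k = float(np.clip(p_true * (1 + rng.normal(0, config.af_jitter_sd)), 0, 1))
            dist = config.cadd_pathogenic if pathogenic else config.cadd_benign
            cadd = _truncated_normal(rng, *dist)
            u = rng.random()
            clin = ("benign" if u < 0.05 else
                    "uncertain_significance" if u < 0.15 else None)
            if effect == "missense_variant":
                calls = _emit_predictor_calls(
                    rng, pathogenic, config.predictor_concordance,
                    config.predictor_missing_rate)
            else:
                calls = {t: "" for t in TOOL_ROSTER}

        latent[key] = pathogenic
        row = {
            "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": rec.alt,
            "gene": gene_name, "effect": effect, "impact": impact,
            "hgvs_c": f"c.{j * 3 + 1}{rec.ref}>{rec.alt}",
            "hgvs_p": "p.?" if effect != "synonymous_variant" else "p.(=)",
            "transcript": f"NM_SYN{gene_index[gene_name]:04d}.1",
            "af_gnomad": af_g, "af_1kg": af_k, "cadd": cadd,
            "clinical_sig": clin,
        }
        row.update({t: (c if c else None) for t, c in calls.items()})
        ann_rows.append(row)
        records.append(rec)

    order = sorted(range(len(records)), key=lambda i: (records[i].chrom, records[i].pos, records[i].alt))
    records = [records[i] for i in order]
    annotations = pd.DataFrame([ann_rows[i] for i in order])

    # --- true pooled odds ratio per gene from the true site probabilities
    gene_true_or: dict[str, float] = {}
    for gene in config.genes:
        ps_c, ps_t = [], []
        for key in gene_keys[gene.name]:
            if key in planted_p:
                pc_, pt_ = planted_p[key]
            else:
                idx = gene_keys[gene.name].index(key)
                pc_ = site_p_case[gene.name][idx]
                pt_ = site_p_ctrl[gene.name][idx]
            ps_c.append(pc_)
            ps_t.append(pt_)
        m = len(ps_c)
        sc, st = sum(ps_c), sum(ps_t)
        if m == 0 or st in (0, m) or sc in (0, m):
            gene_true_or[gene.name] = math.nan
        else:
            gene_true_or[gene.name] = (sc / (m - sc)) / (st / (m - st))

    panel_genes = [g.name for g in config.genes if g.in_panel]
    fillers = [f"TAG{i:03d}" for i in range(1, config.panel_extra_genes + 1)]
    panel = GenePanel(frozenset(panel_genes + fillers), name="synthetic_panel")

    gene_sets = _build_gene_sets(config)

    truth = GroundTruth(
        site_alt_counts=truth_counts,
        gene_enrichment={g.name: g.enrichment for g in config.genes},
        gene_true_or=gene_true_or,
        planted_candidates=planted_keys,
        latent_pathogenic=latent,
    )
    return CohortData(
        variants=records, cohort=cohort, annotations=annotations,
        panel=panel, gene_sets=gene_sets, truth=truth, config=config,
    )


def _build_gene_sets(config: SimConfig) -> list[GeneSetCollection]:
    """Small synthetic GMT: one term per enrichment tier plus fillers."""
    enriched = [g.name for g in config.genes if g.enrichment > 1]
    panel_genes = [g.name for g in config.genes if g.in_panel]
    all_genes = [g.name for g in config.genes]
    sets = []
    if enriched:
        sets.append(GeneSet("SIM:0001", "synthetic enriched-gene term",
                            tuple(enriched + [f"FILL{i:03d}" for i in range(1, 20)])))
    if panel_genes:
        sets.append(GeneSet("SIM:0002", "synthetic panel term",
                            tuple(panel_genes + [f"FILL{i:03d}" for i in range(20, 60)])))
    sets.append(GeneSet("SIM:0003", "synthetic background term",
                        tuple([f"FILL{i:03d}" for i in range(60, 200)])))
    go = GeneSetCollection(sets, category="GO Process")
    kegg = GeneSetCollection(
        [GeneSet("simKEGG:01", "synthetic pathway",
                 tuple(all_genes[: max(2, len(all_genes) // 2)]))],
        category="KEGG",
    )
    return [go, kegg]


# ---------------------------------------------------------------------------
# Scenario factories (the study conditions, fixed once)

#: the 12 panel genes carrying candidates; the 4 burden genes are enriched
STUDY_PANEL_GENES = (
    "EDAR", "WNT10A", "FGFR1", "LAMA3", "KREMEN1", "SMOC2",
    "ITGB4", "EVC2", "FLNB", "BBS1", "LAMB3", "CDH1",
)
BURDEN_GENES = ("CDH1", "ITGB4", "LAMA3", "LAMB3")


def default_config(seed: int = 0) -> SimConfig:
    """The study-structured cohort: 20 cases / 100 controls, 12 panel genes
    (four with 2-fold case enrichment), 8 non-panel background genes, 13
    planted candidates (12 missense + 1 stop-gain) and one high-contrast
    association spike."""
    genes = [
        GeneConfig(name=g, n_sites=80, in_panel=True,
                   enrichment=2.0 if g in BURDEN_GENES else 1.0)
        for g in STUDY_PANEL_GENES
    ] + [GeneConfig(name=f"BGD{i:02d}", n_sites=80) for i in range(1, 9)]
    planted = _thirteen_candidates()
    planted.append(PlantedVariant(
        gene="BGD01", effect="missense_variant", impact="MODERATE",
        case_alt_p=0.9, control_alt_p=0.05, af_gnomad=0.005, af_1kg=0.005,
        candidate=False,
    ))
    return SimConfig(genes=genes, planted=planted, seed=seed)


def _thirteen_candidates() -> list[PlantedVariant]:
    """13 cascade-passing candidates in 12 panel genes; one stop-gain, the
    second WNT10A variant mirrors a gene carrying two candidates."""
    out = []
    for g in STUDY_PANEL_GENES:
        if g == "LAMA3":
            out.append(PlantedVariant(gene=g, effect="stop_gained", impact="HIGH",
                                      cadd=36.0, clinical_sig="conflicting"))
        else:
            out.append(PlantedVariant(gene=g, clinical_sig=None))
    out.append(PlantedVariant(gene="WNT10A", clinical_sig="uncertain_significance"))
    return out


def candidate_recovery_config(seed: int = 0) -> SimConfig:
    """Scenario where the 13 planted candidates are the only rare
    MODERATE/HIGH panel variation: non-planted panel-gene sites draw from a
    common-variant spectrum (Beta(5, 45)) and a benign latent class, so the
    cascade + prioritizer ground truth is exactly the planted set for any
    seed."""
    cfg = default_config(seed)
    genes = [
        GeneConfig(name=g.name, n_sites=g.n_sites, enrichment=g.enrichment,
                   af_alpha=5.0, af_beta=45.0, in_panel=True)
        if g.in_panel else g
        for g in cfg.genes
    ]
    planted = [pv for pv in cfg.planted if pv.candidate]
    return SimConfig(genes=genes, planted=planted,
                     background_pathogenic_frac=0.0, seed=seed)


def burden_sim_config(
    seed: int = 0,
    enrichment: float = 2.0,
    n_genes: int = 1,
    n_sites: int = 60,
) -> SimConfig:
    """Minimal cohort for burden parameter-recovery studies: 20/100 samples
    and ``n_genes`` genes of ``n_sites`` rare-spectrum sites each."""
    genes = [GeneConfig(name=f"BRD{i:02d}", n_sites=n_sites, enrichment=enrichment)
             for i in range(1, n_genes + 1)]
    return SimConfig(genes=genes, genotype_missing_rate=0.0, seed=seed)
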