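"""Synthetic Lynch-carrier cohorts with a planted burden→phenotype effect.

The generator emulates the study conditions: ~35 endometrial-cancer
patients from ~29 families, EC diagnosis ages ≈ N(53.1, 10.7²) truncated to
[31, 81], a 154-gene panel (47 estrogen, 35 oncogene, 63 tumor-suppressor,
9 other) plus the four MMR genes, a rare-variant spectrum mixing dbSNP
(MAF < 0.001) and never-deposited variants, and a logistic phenotype model

    P(poor) = expit(beta0 + ln(OR) * 1[burden >= k])

with baseline beta0 = logit(6/17) and OR defaulting to the odds ratio the
dichotomized study table implies (~14.7).  Every planted variant is placed
on a toy transcript by running the real consequence annotator, so the
curation stage inverts the generator exactly when annotations are
noise-free.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from .cohort import (
    MMR_CHROMOSOME,
    FamilialMutation,
    Subject,
    TumorDiagnosis,
    TumorSite,
)
from .variants import (
    Consequence,
    FunctionalGroup,
    PanelGene,
    ProteinChange,
    ToyTranscript,
    VariantKey,
    VariantRecord,
    annotate_consequence,
    conservativeness,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"


def expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class SimulationConfig:
    """Study-condition defaults; ``seed`` is mandatory (no implicit entropy)."""

    seed: int
    n_subjects: int = 35
    n_families: int = 29
    age_mean: float = 53.1
    age_sd: float = 10.7
    age_min: int = 31
    age_max: int = 81
    # panel: genes per functional group (non-MMR) and toy transcript shape
    genes_per_group: dict = field(
        default_factory=lambda: {
            "estrogen": 47,
            "oncogene": 35,
            "tumor_suppressor": 63,
            "other": 9,
        }
    )
    n_codons: int = 100
    intron_length: int = 50
    pad_length: int = 20
    # per-subject variant rates (Poisson means)
    risk_variant_rate: float = 1.5
    background_variant_rate: float = 1.5
    common_variant_rate: float = 0.5
    mmr_variant_rate: float = 0.1
    rescue_rate: float = 0.05
    shared_variant_prob: float = 0.5
    # MAF spectrum
    frac_non_dbsnp: float = 0.47
    maf_threshold: float = 0.001
    # prior-annotation probabilities on planted risk variants
    prob_likely_pathogenic: float = 0.08
    prob_pathogenic_other: float = 0.04
    # phenotype model
    odds_ratio: float = 14.7
    burden_k: int = 2
    baseline_poor_rate: float = 6 / 17

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        for p in (
            self.frac_non_dbsnp,
            self.rescue_rate,
            self.shared_variant_prob,
            self.prob_likely_pathogenic,
            self.prob_pathogenic_other,
            self.baseline_poor_rate,
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.n_families > self.n_subjects:
            raise ValueError("more families than subjects")
        if self.n_subjects - self.n_families > self.n_families:
            raise ValueError("family-size distribution infeasible (sizes <= 2)")


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    subjects: list[Subject]
    records: list[VariantRecord]  # carriers, gene mapping and annotations set
    panel: list[PanelGene]
    transcripts: dict[str, ToyTranscript]
    maf_table: dict[VariantKey, tuple[Optional[float], Optional[str]]]
    annotations: dict[VariantKey, frozenset[str]]
    truth: dict[str, dict]


# ---------------------------------------------------------------------------
# panel / transcript construction


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    non_stop = [
        a + b + c
        for a in BASES
        for b in BASES
        for c in BASES
        if a + b + c not in STOP_CODONS
    ]
    codons.append("ATG")
    for _ in range(n_codons - 2):
        codons.append(non_stop[rng.integers(len(non_stop))])
    codons.append("TAA")
    return "".join(codons)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def build_panel(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[PanelGene], dict[str, ToyTranscript], dict[str, str]]:
    """Lay toy gene loci (two exons, one intron) along 22 autosomes.

    Returns the panel (captured intervals = exons ±10 nt flank), the
    transcripts, and the chromosome sequences.
    """
    groups = [
        (FunctionalGroup.ESTROGEN, "EST", config.genes_per_group["estrogen"]),
        (FunctionalGroup.ONCOGENE, "ONC", config.genes_per_group["oncogene"]),
        (
            FunctionalGroup.TUMOR_SUPPRESSOR,
            "TSG",
            config.genes_per_group["tumor_suppressor"],
        ),
        (FunctionalGroup.OTHER, "OTH", config.genes_per_group["other"]),
    ]
    gene_specs: list[tuple[str, FunctionalGroup, str]] = []
    chrom_cycle = [f"chr{i}" for i in range(1, 23)]
    i = 0
    for fg, prefix, count in groups:
        for j in range(count):
            gene_specs.append((f"{prefix}{j + 1:03d}", fg, chrom_cycle[i % 22]))
            i += 1
    for gene, chrom in MMR_CHROMOSOME.items():
        gene_specs.append((gene, FunctionalGroup.MMR, chrom))

    chrom_parts: dict[str, list[str]] = {c: [] for c in chrom_cycle}
    chrom_len: dict[str, int] = {c: 0 for c in chrom_cycle}
    panel: list[PanelGene] = []
    transcripts: dict[str, ToyTranscript] = {}
    pending: list[tuple[str, FunctionalGroup, str, tuple, str, int]] = []

    for symbol, fg, chrom in gene_specs:
        n_nt = 3 * config.n_codons
        len1 = (n_nt // 2) or 3
        len2 = n_nt - len1
        strand = "+" if rng.random() < 0.5 else "-"
        cds = _random_cds(rng, config.n_codons)
        genomic_spliced = (
            cds if strand == "+" else str(Seq(cds).reverse_complement())
        )
        locus = (
            _random_seq(rng, config.pad_length)
            + genomic_spliced[:len1]
            + _random_seq(rng, config.intron_length)
            + genomic_spliced[len1:]
            + _random_seq(rng, config.pad_length)
        )
        offset = chrom_len[chrom]
        e1 = (offset + config.pad_length, offset + config.pad_length + len1)
        e2 = (e1[1] + config.intron_length, e1[1] + config.intron_length + len2)
        chrom_parts[chrom].append(locus)
        chrom_len[chrom] += len(locus)
        pending.append((symbol, fg, chrom, (e1, e2), strand, len(locus)))

    chrom_seqs = {c: "".join(parts) for c, parts in chrom_parts.items()}
    for symbol, fg, chrom, exons, strand, _ in pending:
        flank = 10
        captured = tuple(
            (max(0, s - flank), e + flank) for s, e in exons
        )
        panel.append(
            PanelGene(
                symbol=symbol,
                chromosome=chrom,
                functional_group=fg,
                captured_intervals=captured,
            )
        )
        transcripts[symbol] = ToyTranscript(
            gene=symbol,
            chromosome=chrom,
            strand=strand,
            cds_intervals=exons,
            chrom_seq=chrom_seqs[chrom],
        )
    return panel, transcripts, chrom_seqs


# ---------------------------------------------------------------------------
# variant placement

_SNV_KINDS = {"silent", "missense_conservative", "missense_non_conservative", "nonsense"}


def plant_variant(
    transcript: ToyTranscript,
    kind: str,
    rng: np.random.Generator,
    used: set[int],
    max_tries: int = 2000,
) -> Optional[VariantKey]:
    """Search for a (pos, ref, alt) on the transcript whose annotated
    consequence matches ``kind``; returns None if the search fails."""
    exons = transcript.cds_intervals
    seq = transcript.chrom_seq
    for _ in range(max_tries):
        if kind in _SNV_KINDS:
            s, e = exons[rng.integers(len(exons))]
            pos0 = int(rng.integers(s, e))
            ref = seq[pos0]
            alt = BASES[rng.integers(4)]
            if alt == ref or pos0 in used:
                continue
        elif kind == "flank":
            s, e = exons[rng.integers(len(exons))]
            dist = int(rng.integers(1, 11))
            pos0 = s - dist if rng.random() < 0.5 else e - 1 + dist
            if pos0 < 0 or pos0 >= len(seq) or pos0 in used:
                continue
            ref = seq[pos0]
            alt = BASES[rng.integers(4)]
            if alt == ref:
                continue
        elif kind == "frameshift":
            s, e = exons[rng.integers(len(exons))]
            pos0 = int(rng.integers(s, e - 1))
            if pos0 in used:
                continue
            ref, alt = seq[pos0 : pos0 + 2], seq[pos0]
        elif kind == "inframe_deletion":
            s, e = exons[rng.integers(len(exons))]
            if e - s < 5:
                continue
            pos0 = int(rng.integers(s, e - 4))
            if pos0 in used:
                continue
            ref, alt = seq[pos0 : pos0 + 4], seq[pos0]
        elif kind == "inframe_insertion":
            s, e = exons[rng.integers(len(exons))]
            pos0 = int(rng.integers(s, e - 1))
            if pos0 in used:
                continue
            ref = seq[pos0]
            alt = ref + _random_seq(rng, 3)
        else:
            raise ValueError(f"unknown variant kind: {kind}")

        try:
            key = VariantKey(transcript.chromosome, pos0 + 1, ref, alt)
        except ValueError:
            continue
        probe = annotate_consequence(VariantRecord(key=key), transcript)
        cq = probe.consequence
        if kind == "silent" and cq is Consequence.SILENT:
            pass
        elif kind == "nonsense" and cq is Consequence.NONSENSE:
            pass
        elif kind.startswith("missense") and cq is Consequence.MISSENSE:
            if probe.protein_change.ref_aa == "*":
                continue  # stop-loss: not a plain missense
            call = conservativeness(
                probe.protein_change.ref_aa, probe.protein_change.alt_aa
            )
            want = (
                "non_conservative" if "non_conservative" in kind else "conservative"
            )
            if call != want:
                continue
        elif kind == "flank" and cq in (
            Consequence.INTRONIC_FLANK,
            Consequence.SPLICE_REGION,
        ):
            pass
        elif kind in ("frameshift", "inframe_deletion", "inframe_insertion") and (
            cq is Consequence(kind)
        ):
            pass
        else:
            continue
        used.add(pos0)
        return key
    return None


RISK_KINDS = [
    ("missense_non_conservative", 0.90),
    ("nonsense", 0.04),
    ("frameshift", 0.02),
    ("inframe_insertion", 0.02),
    ("inframe_deletion", 0.02),
]
BACKGROUND_KINDS = [
    ("silent", 0.5),
    ("missense_conservative", 0.3),
    ("flank", 0.2),
]


def _choice(pairs: list[tuple[str, float]], rng: np.random.Generator) -> str:
    names, weights = zip(*pairs)
    w = np.asarray(weights)
    return str(rng.choice(names, p=w / w.sum()))


def _trunc_normal_int(
    rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int
) -> int:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return int(round(x))
    return int(round(min(max(mean, lo), hi)))


MMR_GENE_WEIGHTS = [("MSH6", 0.65), ("MSH2", 0.20), ("MLH1", 0.08), ("PMS2", 0.07)]


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort; deterministic for a fixed seed."""
    rng_panel = np.random.default_rng([config.seed, 1])
    rng_clin = np.random.default_rng([config.seed, 2])
    rng_var = np.random.default_rng([config.seed, 3])
    rng_maf = np.random.default_rng([config.seed, 4])

    panel, transcripts, _ = build_panel(config, rng_panel)
    non_mmr_genes = [g for g in panel if g.functional_group is not FunctionalGroup.MMR]
    mmr_genes = [g for g in panel if g.functional_group is FunctionalGroup.MMR]

    # families: first (n_subjects - n_families) families have two members
    n_pairs = config.n_subjects - config.n_families
    family_of: list[Optional[str]] = []  # shared family id (None for singletons)
    gene_of_subject: list[str] = []
    fam_idx = 0
    while len(family_of) < config.n_subjects:
        fam_idx += 1
        fid = f"F{fam_idx:03d}"
        size = 2 if fam_idx <= n_pairs else 1
        gene = _choice(MMR_GENE_WEIGHTS, rng_clin)
        for _ in range(size):
            if len(family_of) < config.n_subjects:
                family_of.append(fid if size > 1 else None)
                gene_of_subject.append(gene)

    beta0 = math.log(config.baseline_poor_rate / (1 - config.baseline_poor_rate))
    log_or = math.log(config.odds_ratio)

    # per-subject burdens and phenotype labels
    burdens = rng_clin.poisson(config.risk_variant_rate, size=config.n_subjects)
    poor = np.array(
        [
            rng_clin.random() < expit(beta0 + log_or * (b >= config.burden_k))
            for b in burdens
        ]
    )

    # Stratify EC ages so their marginal stays the configured truncated
    # normal: the fraction of the cohort drawn from the young stratum
    # (age <= 49) must match that stratum's truncated-normal mass, and young
    # onset can only be realized among poor subjects.
    def _phi(x: float) -> float:
        return 0.5 * (1 + math.erf(x / math.sqrt(2)))

    z = lambda a: (a - config.age_mean) / config.age_sd
    total_mass = _phi(z(config.age_max + 0.5)) - _phi(z(config.age_min - 0.5))
    young_mass = (_phi(z(49.5)) - _phi(z(config.age_min - 0.5))) / total_mass
    p_high = 1.0 - sum(
        math.exp(-config.risk_variant_rate) * config.risk_variant_rate**j / math.factorial(j)
        for j in range(config.burden_k)
    )
    p_poor_marginal = (1 - p_high) * expit(beta0) + p_high * expit(beta0 + log_or)
    q_young_given_poor = min(1.0, young_mass / p_poor_marginal)

    subjects: list[Subject] = []
    truth: dict[str, dict] = {}
    for i in range(config.n_subjects):
        sid = f"S{i + 1:03d}"
        fid = family_of[i]
        gene = gene_of_subject[i]
        mut = FamilialMutation(
            gene=gene,
            cdna_change=f"c.{100 + i}A>T",
            protein_change=f"p.Gln{34 + i}*",
        )
        mechanisms = []
        tumors: list[TumorDiagnosis] = []
        if poor[i]:
            young = rng_clin.random() < q_young_given_poor
            multi = (not young) or rng_clin.random() < 0.3
            if young:
                age_ec = _trunc_normal_int(
                    rng_clin, config.age_mean, config.age_sd, config.age_min, 49
                )
                mechanisms.append("young_onset")
            else:
                age_ec = _trunc_normal_int(
                    rng_clin, config.age_mean, config.age_sd, 50, config.age_max
                )
            if multi:
                site = [TumorSite.COLORECTUM, TumorSite.OVARY, TumorSite.BREAST][
                    rng_clin.integers(3)
                ]
                t_age = max(25, age_ec - int(rng_clin.integers(0, 10)))
                tumors.append(TumorDiagnosis(site, t_age))
                mechanisms.append("multiple_cancers")
        else:
            age_ec = _trunc_normal_int(
                rng_clin, config.age_mean, config.age_sd, 50, config.age_max
            )
        followup = min(age_ec + int(rng_clin.integers(3, 20)), 95)
        subjects.append(
            Subject(
                subject_id=sid,
                family_id=fid,
                age_ec_diagnosis=age_ec,
                tumors=[TumorDiagnosis(TumorSite.ENDOMETRIUM, age_ec)] + tumors,
                familial_mutation=mut,
                age_at_last_followup=followup,
                ngs_passed_qc=True,
            )
        )
        truth[sid] = {
            "burden": int(burdens[i]),
            "phenotype": "poor" if poor[i] else "neutral",
            "mechanisms": mechanisms,
            "risk_variant_keys": [],
            "mmr_extra_keys": [],
        }

    # variant planting
    used_positions: dict[str, set[int]] = {g.symbol: set() for g in panel}
    records_by_key: dict[VariantKey, VariantRecord] = {}
    annotations: dict[VariantKey, set[str]] = {}

    def add_carrier(key: VariantKey, gene: PanelGene, sid: str) -> None:
        rec = records_by_key.get(key)
        if rec is None:
            rec = VariantRecord(
                key=key,
                gene=gene.symbol,
                functional_group=gene.functional_group,
            )
            records_by_key[key] = rec
        rec.zygosity[sid] = "het"

    def plant_on_new_gene(
        sid: str, kind: str, pool: list[PanelGene], taken_chroms: set[str],
        distinct_chrom: bool = True,
    ) -> Optional[tuple[VariantKey, PanelGene]]:
        candidates = [
            g for g in pool if not distinct_chrom or g.chromosome not in taken_chroms
        ]
        rng_var.shuffle(candidates)
        for gene in candidates:
            key = plant_variant(
                transcripts[gene.symbol], kind, rng_var, used_positions[gene.symbol]
            )
            if key is not None:
                add_carrier(key, gene, sid)
                return key, gene
        return None

    mmr_chrom_variant_planted = False
    first_shared: dict[str, VariantKey] = {}  # family -> shared key
    gene_of_key: dict[VariantKey, PanelGene] = {}

    for i, subj in enumerate(subjects):
        sid = subj.subject_id
        taken: set[str] = set()
        n_risk = int(burdens[i])
        planted = 0

        # family sharing: second member of a pair reuses the proband's variant
        fid = subj.family_id
        if (
            fid in first_shared
            and n_risk >= 1
            and rng_var.random() < config.shared_variant_prob
        ):
            key = first_shared[fid]
            gene = gene_of_key[key]
            if gene.chromosome not in taken:
                add_carrier(key, gene, sid)
                taken.add(gene.chromosome)
                truth[sid]["risk_variant_keys"].append(str(key))
                planted += 1

        rescue_here = planted < n_risk and rng_var.random() < config.rescue_rate
        while planted < n_risk:
            kind = _choice(RISK_KINDS, rng_var)
            out = plant_on_new_gene(sid, kind, non_mmr_genes, taken)
            if out is None:
                break
            key, gene = out
            gene_of_key[key] = gene
            taken.add(gene.chromosome)
            truth[sid]["risk_variant_keys"].append(str(key))
            planted += 1
            if rescue_here:
                annotations.setdefault(key, set()).add("disease_associated")
                records_by_key[key].prior_annotations |= {"disease_associated"}
                rescue_here = False
            else:
                r = rng_var.random()
                if r < config.prob_likely_pathogenic:
                    annotations.setdefault(key, set()).add("likely_pathogenic")
                    records_by_key[key].prior_annotations |= {"likely_pathogenic"}
                elif r < config.prob_likely_pathogenic + config.prob_pathogenic_other:
                    annotations.setdefault(key, set()).add("pathogenic")
                    records_by_key[key].prior_annotations |= {"pathogenic"}
            if fid is not None and fid not in first_shared:
                first_shared[fid] = key
        truth[sid]["burden"] = planted  # actual planted count (capacity-safe)

        # background class-1/2 variants
        for _ in range(int(rng_var.poisson(config.background_variant_rate))):
            kind = _choice(BACKGROUND_KINDS, rng_var)
            plant_on_new_gene(sid, kind, non_mmr_genes, set(), distinct_chrom=False)

        # common variants (excluded by the rare filter)
        for _ in range(int(rng_var.poisson(config.common_variant_rate))):
            kind = _choice(BACKGROUND_KINDS + RISK_KINDS, rng_var)
            out = plant_on_new_gene(sid, kind, non_mmr_genes, set(), distinct_chrom=False)
            if out is not None:
                key, _gene = out
                annotations.setdefault(key, set()).add("common")

        # occasional extra MMR-gene variant
        if rng_var.random() < config.mmr_variant_rate or (
            i == len(subjects) - 1 and not mmr_chrom_variant_planted
        ):
            on_familial = rng_var.random() < 0.5 or (
                i == len(subjects) - 1 and not mmr_chrom_variant_planted
            )
            pool = [
                g
                for g in mmr_genes
                if (g.chromosome == subj.familial_mutation.chromosome) == on_familial
            ]
            out = plant_on_new_gene(
                sid, "missense_non_conservative", pool, set(), distinct_chrom=False
            )
            if out is not None:
                key, gene = out
                truth[sid]["mmr_extra_keys"].append(str(key))
                if gene.chromosome == subj.familial_mutation.chromosome:
                    mmr_chrom_variant_planted = True

    # MAF spectrum per unique variant
    maf_table: dict[VariantKey, tuple[Optional[float], Optional[str]]] = {}
    rs = 1000
    for key in sorted(records_by_key):
        rec = records_by_key[key]
        tags = annotations.get(key, set())
        rs += 1
        if "common" in tags:
            maf = float(rng_maf.uniform(config.maf_threshold, 0.3))
            maf_table[key] = (maf, f"rs{rs}")
            rec.maf, rec.dbsnp_id = maf, f"rs{rs}"
            tags.discard("common")
            if not tags:
                annotations.pop(key, None)
        elif "disease_associated" in tags:
            # the rescue path: frequent but previously reported as disease-linked
            maf = float(rng_maf.uniform(config.maf_threshold, 0.01))
            maf_table[key] = (maf, f"rs{rs}")
            rec.maf, rec.dbsnp_id = maf, f"rs{rs}"
        elif rng_maf.random() < config.frac_non_dbsnp:
            rec.maf, rec.dbsnp_id = None, None
        else:
            maf = float(
                10 ** rng_maf.uniform(-5, math.log10(config.maf_threshold * 0.999))
            )
            maf_table[key] = (maf, f"rs{rs}")
            rec.maf, rec.dbsnp_id = maf, f"rs{rs}"

    records = [records_by_key[k] for k in sorted(records_by_key)]
    for rec in records:
        rec.prior_annotations = frozenset(rec.prior_annotations)

    return SyntheticCohort(
        config=config,
        subjects=subjects,
        records=records,
        panel=panel,
        transcripts=transcripts,
        maf_table=maf_table,
        annotations={k: frozenset(v) for k, v in annotations.items() if v},
        truth=truth,
    )


# ---------------------------------------------------------------------------
# fixture serialization


def write_fixture(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as the pipeline's input file set (all plain text)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        name: out / fname
        for name, fname in [
            ("clinical", "clinical.tsv"),
            ("vcf", "variants.vcf"),
            ("maf", "maf.tsv"),
            ("panel_bed", "panel.bed"),
            ("panel_meta", "panel_genes.tsv"),
            ("annotations", "annotations.tsv"),
            ("gff", "transcripts.gff3"),
            ("fasta", "reference.fa"),
            ("truth", "truth.json"),
        ]
    }

    site_code = {
        TumorSite.COLORECTUM: "C",
        TumorSite.OVARY: "O",
        TumorSite.BREAST: "B",
        TumorSite.URINARY_TRACT: "U",
        TumorSite.OTHER: "X",
    }
    with open(paths["clinical"], "w") as fh:
        cols = [
            "subject_id", "family_id", "age_ec", "ec_histology", "ec_grade",
            "ec_stage", "msi", "other_tumors", "phenotype_override",
            "mmr_gene", "mmr_cdna", "mmr_protein", "ngs_ok", "age_last_followup",
        ]
        fh.write("\t".join(cols) + "\n")
        for s in cohort.subjects:
            others = ";".join(
                f"{site_code[t.site]}-{t.age_at_diagnosis if t.age_at_diagnosis is not None else 'na'}"
                for t in s.non_ec_tumors
            )
            fh.write(
                "\t".join(
                    [
                        s.subject_id,
                        s.family_id or "-",
                        str(s.age_ec_diagnosis),
                        "", "", "", "",
                        others,
                        "",
                        s.familial_mutation.gene,
                        s.familial_mutation.cdna_change,
                        s.familial_mutation.protein_change,
                        "yes" if s.ngs_passed_qc else "no",
                        str(s.age_at_last_followup or ""),
                    ]
                )
                + "\n"
            )

    # VCF: group alt alleles sharing (chrom, pos, ref) into one line
    sample_ids = [s.subject_id for s in cohort.subjects]
    chrom_order = {f"chr{i}": i for i in range(1, 23)}
    sites: dict[tuple[str, int, str], list[VariantRecord]] = {}
    for rec in cohort.records:
        sites.setdefault(
            (rec.key.chromosome, rec.key.position, rec.key.ref), []
        ).append(rec)
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted(
            {t.chromosome for t in cohort.transcripts.values()},
            key=lambda c: chrom_order.get(c, 99),
        )
        lengths = {
            t.chromosome: len(t.chrom_seq) for t in cohort.transcripts.values()
        }
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={lengths[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for (chrom, pos, ref) in sorted(
            sites, key=lambda t: (chrom_order.get(t[0], 99), t[1], t[2])
        ):
            recs = sorted(sites[(chrom, pos, ref)], key=lambda r: r.key.alt)
            alts = [r.key.alt for r in recs]
            gts = []
            for sid in sample_ids:
                ai = next(
                    (
                        j + 1
                        for j, r in enumerate(recs)
                        if sid in r.zygosity
                    ),
                    None,
                )
                if ai is None:
                    gts.append("0/0")
                else:
                    zyg = recs[ai - 1].zygosity[sid]
                    gts.append(f"{ai}/{ai}" if zyg == "hom" else f"0/{ai}")
            ids = sorted({r.dbsnp_id for r in recs if r.dbsnp_id})
            fh.write(
                "\t".join(
                    [
                        chrom,
                        str(pos),
                        ";".join(ids) or ".",
                        ref,
                        ",".join(alts),
                        ".",
                        "PASS",
                        ".",
                        "GT",
                    ]
                    + gts
                )
                + "\n"
            )

    with open(paths["maf"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tdbsnp_id\tmaf\n")
        for key in sorted(cohort.maf_table):
            maf, dbsnp = cohort.maf_table[key]
            fh.write(
                f"{key.chromosome}\t{key.position}\t{key.ref}\t{key.alt}\t"
                f"{dbsnp or ''}\t{'' if maf is None else repr(maf)}\n"
            )

    with open(paths["panel_bed"], "w") as fh:
        for g in sorted(cohort.panel, key=lambda g: g.symbol):
            for s, e in g.captured_intervals:
                fh.write(f"{g.chromosome}\t{s}\t{e}\t{g.symbol}\n")
    with open(paths["panel_meta"], "w") as fh:
        fh.write("symbol\tchromosome\tfunctional_group\n")
        for g in sorted(cohort.panel, key=lambda g: g.symbol):
            fh.write(f"{g.symbol}\t{g.chromosome}\t{g.functional_group.value}\n")

    with open(paths["annotations"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tsource\tlabel\n")
        for key in sorted(cohort.annotations):
            for label in sorted(cohort.annotations[key]):
                fh.write(
                    f"{key.chromosome}\t{key.position}\t{key.ref}\t{key.alt}\t"
                    f"synthetic\t{label}\n"
                )

    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for symbol in sorted(cohort.transcripts):
            t = cohort.transcripts[symbol]
            lo = min(s for s, _ in t.cds_intervals)
            hi = max(e for _, e in t.cds_intervals)
            fh.write(
                f"{t.chromosome}\ttoy\tgene\t{lo + 1}\t{hi}\t.\t{t.strand}\t.\t"
                f"ID={symbol}\n"
            )
            for s, e in t.cds_intervals:
                fh.write(
                    f"{t.chromosome}\ttoy\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t0\t"
                    f"Parent={symbol}\n"
                )

    chrom_seqs = {}
    for t in cohort.transcripts.values():
        chrom_seqs[t.chromosome] = t.chrom_seq
    with open(paths["fasta"], "w") as fh:
        for chrom in sorted(chrom_seqs, key=lambda c: chrom_order.get(c, 99)):
            fh.write(f">{chrom}\n")
            seq = chrom_seqs[chrom]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "config": {
                    k: v for k, v in asdict(cohort.config).items()
                },
                "subjects": cohort.truth,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths


def read_transcripts(gff_path: str | Path, fasta_path: str | Path) -> dict[str, ToyTranscript]:
    """Rebuild toy transcripts from the GFF3 + FASTA fixture pair."""
    from Bio import SeqIO

    chrom_seqs = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    genes: dict[str, dict] = {}
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                genes[attr["ID"]] = {
                    "chromosome": chrom,
                    "strand": strand,
                    "cds": [],
                }
            elif ftype == "CDS":
                genes[attr["Parent"]]["cds"].append((int(start) - 1, int(end)))
    out = {}
    for symbol, info in genes.items():
        out[symbol] = ToyTranscript(
            gene=symbol,
            chromosome=info["chromosome"],
            strand=info["strand"],
            cds_intervals=tuple(sorted(info["cds"])),
            chrom_seq=chrom_seqs[info["chromosome"]],
        )
    return out


def read_annotations(path: str | Path) -> dict[VariantKey, frozenset[str]]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[VariantKey, set[str]] = {}
    for row in df.itertuples():
        key = VariantKey(row.chrom, int(row.pos), row.ref, row.alt)
        out.setdefault(key, set()).add(row.label)
    return {k: frozenset(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# burden-level replicate studies (null calibration and power)


def simulate_burden_phenotype(
    n_subjects: int,
    rng: np.random.Generator,
    risk_variant_rate: float = 1.5,
    odds_ratio: float = 14.7,
    burden_k: int = 2,
    baseline_poor_rate: float = 6 / 17,
) -> tuple[np.ndarray, np.ndarray]:
    """One replicate of the burden→phenotype layer (no variant I/O)."""
    beta0 = math.log(baseline_poor_rate / (1 - baseline_poor_rate))
    burden = rng.poisson(risk_variant_rate, size=n_subjects)
    p = 1.0 / (1.0 + np.exp(-(beta0 + math.log(odds_ratio) * (burden >= burden_k))))
    poor = rng.random(n_subjects) < p
    return burden, poor


def fisher_rejection_rate(
    n_replicates: int,
    n_subjects: int,
    odds_ratio: float,
    seed: int,
    alpha: float = 0.05,
    burden_k: int = 2,
    risk_variant_rate: float = 1.5,
    baseline_poor_rate: float = 6 / 17,
) -> float:
    """Fraction of replicates where the two-sided Fisher test on the
    dichotomized burden×phenotype table rejects at ``alpha``.  Degenerate
    tables (an empty margin) cannot reject and count as non-rejections."""
    from .association import ContingencyTable, fisher_exact_2x2
    from .errors import DegenerateTableError

    rng = np.random.default_rng([seed, 7])
    rejections = 0
    for _ in range(n_replicates):
        burden, poor = simulate_burden_phenotype(
            n_subjects,
            rng,
            risk_variant_rate=risk_variant_rate,
            odds_ratio=odds_ratio,
            burden_k=burden_k,
            baseline_poor_rate=baseline_poor_rate,
        )
        high = burden >= burden_k
        cells = (
            (int((~high & ~poor).sum()), int((~high & poor).sum())),
            (int((high & ~poor).sum()), int((high & poor).sum())),
        )
        try:
            table = ContingencyTable(("low", "high"), ("neutral", "poor"), cells)
            result = fisher_exact_2x2(table)
        except DegenerateTableError:
            continue
        if result.p_value < alpha:
            rejections += 1
    return rejections / n_replicates
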