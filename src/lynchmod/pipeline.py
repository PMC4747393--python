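"""End-to-end orchestration: inputs -> risk-variant matrix, panel accounting,
association report and survival outputs.

Defaults reproduce the study settings: MAF threshold 0.001, physicochemical
conservativeness, burden dichotomy at two risk-variants, age cutoff 50.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .association import (
    ContingencyTable,
    SurvivalRecord,
    burden_table,
    dichotomize,
    fisher_exact_2x2,
    kaplan_meier,
    log_rank,
    pearson_chi_square,
    two_sample_t,
)
from .cohort import Subject, classify_phenotype, read_clinical_table
from .curation import (
    assign_category,
    annotate_evidence,
    burden as compute_burden,
    linkage_check,
    rare_filter,
    read_somatic_table,
    select_risk_variants,
)
from .errors import DegenerateTableError, PipelineError
from .variants import (
    PROTEIN_ALTERING,
    Consequence,
    VariantRecord,
    annotate_consequence,
    annotate_frequency,
    read_maf_table,
    read_panel,
    read_vcf,
)
from .synthetic import read_annotations, read_transcripts


@dataclass
class RunConfig:
    clinical: Path
    vcf: Path
    maf: Path
    panel_bed: Path
    panel_meta: Path
    out_dir: Path
    transcripts_gff: Optional[Path] = None
    reference_fasta: Optional[Path] = None
    annotations: Optional[Path] = None
    somatic: Optional[Path] = None
    maf_threshold: float = 0.001
    scheme: str = "physicochemical"
    burden_k: int = 2
    collapse_mode: str = "none"
    age_cutoff: int = 50


def _apply_annotations(records, annotations):
    out = []
    for rec in records:
        tags = annotations.get(rec.key)
        if tags:
            rec = dataclasses.replace(
                rec, prior_annotations=rec.prior_annotations | tags
            )
        out.append(rec)
    return out


def summarize_panel(records: list[VariantRecord]) -> pd.DataFrame:
    """Panel accounting: functional group × dbSNP status × consequence class."""
    rows = []
    for rec in records:
        if rec.functional_group is None or rec.consequence is None:
            continue
        status = "dbsnp_rare" if rec.dbsnp_id else "non_dbsnp"
        if rec.consequence in PROTEIN_ALTERING:
            klass = "protein_altering"
        elif rec.consequence is Consequence.SILENT:
            klass = "silent"
        else:
            klass = "intron_exon"
        rows.append((rec.functional_group.value, status, klass))
    df = pd.DataFrame(rows, columns=["functional_group", "dbsnp_status", "class"])
    if df.empty:
        groups = ["estrogen", "oncogene", "tumor_suppressor", "other", "mmr"]
        idx = pd.MultiIndex.from_product(
            [["dbsnp_rare", "non_dbsnp"], ["protein_altering", "silent", "intron_exon"]]
        )
        return pd.DataFrame(0, index=groups, columns=idx)
    table = pd.crosstab(df["functional_group"], [df["dbsnp_status"], df["class"]])
    return table


def build_survival_records(
    subjects: list[Subject],
    burdens: dict[str, int],
    endpoint: str,
    burden_k: int = 2,
    age_cutoff: int = 50,
) -> list[SurvivalRecord]:
    """Age-scale survival records for one of three endpoints:
    ``any_poor`` (first poor-phenotype feature), ``young_ec`` (EC before the
    cutoff), ``second_tumor`` (first non-EC tumor); each subject contributes
    at most one event.  Censoring falls at the last follow-up age (or the
    latest known diagnosis age when follow-up is unrecorded)."""
    records = []
    for s in subjects:
        if s.subject_id not in burdens:
            continue
        group = "high_burden" if burdens[s.subject_id] >= burden_k else "low_burden"
        known = [
            t.age_at_diagnosis for t in s.tumors if t.age_at_diagnosis is not None
        ]
        censor_age = s.age_at_last_followup or (max(known) if known else None)
        event_age = None
        ec_age = s.age_ec_diagnosis
        other_ages = [
            t.age_at_diagnosis
            for t in s.non_ec_tumors
            if t.age_at_diagnosis is not None
        ]
        if endpoint == "young_ec":
            if ec_age is not None and ec_age < age_cutoff:
                event_age = ec_age
        elif endpoint == "second_tumor":
            if s.non_ec_tumors:
                event_age = min(other_ages) if other_ages else ec_age
        elif endpoint == "any_poor":
            candidates = []
            if ec_age is not None and ec_age < age_cutoff:
                candidates.append(ec_age)
            if s.non_ec_tumors:
                candidates.append(min(other_ages) if other_ages else ec_age)
            if candidates:
                event_age = min(c for c in candidates if c is not None)
        else:
            raise ValueError(f"unknown endpoint: {endpoint}")
        if event_age is not None:
            records.append(SurvivalRecord(s.subject_id, float(event_age), True, group))
        elif censor_age is not None:
            records.append(
                SurvivalRecord(s.subject_id, float(censor_age), False, group)
            )
    return records


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle under ``out_dir``.

    Returns a dict with the in-memory results (profiles, tables, tests).
    Any stage failure raises PipelineError carrying the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:  # surface the failing stage
            raise PipelineError(f"stage {name}: {exc}") from exc

    subjects = stage("clinical", read_clinical_table, config.clinical)
    panel = stage("panel", read_panel, config.panel_bed, config.panel_meta)
    records = stage("vcf", read_vcf, config.vcf, panel)
    if not Path(config.maf).exists():
        raise PipelineError(
            f"stage frequency-annotation: MAF table not found: {config.maf}"
        )
    maf_table = stage("frequency-annotation", read_maf_table, config.maf)
    records = annotate_frequency(records, maf_table)
    if config.annotations and Path(config.annotations).exists():
        records = _apply_annotations(records, read_annotations(config.annotations))

    transcripts = {}
    if config.transcripts_gff and config.reference_fasta:
        transcripts = stage(
            "transcripts", read_transcripts, config.transcripts_gff, config.reference_fasta
        )
    annotated = []
    for rec in records:
        if rec.gene and rec.gene in transcripts:
            annotated.append(annotate_consequence(rec, transcripts[rec.gene]))
        else:
            annotated.append(rec)

    usable = [r for r in annotated if r.consequence is not None]
    retained, excluded = rare_filter(usable, config.maf_threshold)
    assignments = [assign_category(r, config.scheme) for r in retained]
    risk_variants = select_risk_variants(assignments)

    somatic = (
        read_somatic_table(config.somatic)
        if config.somatic and Path(config.somatic).exists()
        else None
    )
    relatives = {
        s.subject_id: s.family_id for s in subjects if s.family_id is not None
    }
    risk_variants = [
        annotate_evidence(rv, somatic_table=somatic, relatives_index=relatives)
        for rv in risk_variants
    ]

    analyzed = [s for s in subjects if s.ngs_passed_qc]
    profiles = []
    matrix_rows = []
    phenotypes = {}
    for subj in analyzed:
        mine = [
            rv for rv in risk_variants if subj.subject_id in rv.variant.subject_ids
        ]
        mine = linkage_check(mine, subj.familial_mutation)
        profile = compute_burden(subj, mine, config.collapse_mode)
        profiles.append(profile)
        label = classify_phenotype(subj, config.age_cutoff)
        phenotypes[subj.subject_id] = label
        matrix_rows.append(
            {
                "subject_id": subj.subject_id,
                "phenotype": label.label,
                "familial_mutation": f"{subj.familial_mutation.gene}:"
                f"{subj.familial_mutation.protein_change}",
                "mmr_extra_variants": profile.n_risk_variants_mmr_extra,
                "total_risk_variants": profile.n_risk_variants_non_mmr,
                "risk_variants": ";".join(
                    f"{rv.variant.gene}:{rv.variant.protein_change or rv.variant.indel_descriptor}"
                    f"(cat{rv.assignment.category},{rv.linkage_flag})"
                    for rv in mine
                ),
            }
        )

    matrix = pd.DataFrame(matrix_rows)
    matrix.to_csv(out / "risk_variant_matrix.tsv", sep="\t", index=False)
    panel_summary = summarize_panel(retained)
    panel_summary.to_csv(out / "panel_accounting.tsv", sep="\t")

    full_table = burden_table(profiles, phenotypes)
    report: dict = {
        "n_subjects_analyzed": len(analyzed),
        "n_variants_total": len(usable),
        "n_variants_retained": len(retained),
        "n_variants_excluded": len(excluded),
        "n_risk_variants_unique": len(risk_variants),
        "burden_table": {
            "rows": full_table.row_labels,
            "cols": full_table.col_labels,
            "counts": full_table.counts,
        },
    }
    tests = {}
    try:
        two_by_two = dichotomize(full_table, config.burden_k)
        tests["fisher_exact"] = fisher_exact_2x2(two_by_two)
        report["dichotomized"] = {
            "rows": two_by_two.row_labels,
            "counts": two_by_two.counts,
        }
    except DegenerateTableError as exc:
        report["dichotomized"] = {"error": str(exc)}
    if len(full_table.row_labels) >= 2:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tests["chi_square"] = pearson_chi_square(full_table)

    followups = {
        "poor": [
            float(s.age_at_last_followup)
            for s in analyzed
            if s.age_at_last_followup and phenotypes[s.subject_id].label == "poor"
        ],
        "neutral": [
            float(s.age_at_last_followup)
            for s in analyzed
            if s.age_at_last_followup and phenotypes[s.subject_id].label == "neutral"
        ],
    }
    if len(followups["poor"]) >= 2 and len(followups["neutral"]) >= 2:
        tests["lifespan_t"] = two_sample_t(followups["neutral"], followups["poor"])

    burdens = {p.subject_id: p.n_risk_variants_non_mmr for p in profiles}
    survival = {}
    for endpoint in ("any_poor", "young_ec", "second_tumor"):
        recs = build_survival_records(
            analyzed, burdens, endpoint, config.burden_k, config.age_cutoff
        )
        groups = {r.group for r in recs}
        if len(groups) == 2 and any(r.event for r in recs):
            curves = kaplan_meier(recs)
            tests[f"log_rank_{endpoint}"] = log_rank(recs)
            rows = []
            for g, c in curves.items():
                for t, nr, ne, sv in zip(c.times, c.n_risk, c.n_event, c.survival):
                    rows.append((g, t, nr, ne, sv))
            pd.DataFrame(
                rows, columns=["group", "time", "n_risk", "n_event", "survival"]
            ).to_csv(out / f"km_{endpoint}.tsv", sep="\t", index=False)
            survival[endpoint] = curves

    report["tests"] = {
        name: {
            "p_value": t.p_value,
            "statistic": t.statistic,
            "df": t.df,
            "method": t.method,
        }
        for name, t in tests.items()
    }
    with open(out / "association_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)

    manifest = {
        "version": __version__,
        "config": {
            k: str(v) if isinstance(v, Path) else v
            for k, v in dataclasses.asdict(config).items()
        },
        "input_hashes": {
            name: _sha256(p)
            for name, p in [
                ("clinical", config.clinical),
                ("vcf", config.vcf),
                ("maf", config.maf),
                ("panel_bed", config.panel_bed),
                ("panel_meta", config.panel_meta),
            ]
            if p and Path(p).exists()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "subjects": subjects,
        "records": annotated,
        "retained": retained,
        "excluded": excluded,
        "assignments": assignments,
        "risk_variants": risk_variants,
        "profiles": profiles,
        "phenotypes": phenotypes,
        "burden_table": full_table,
        "tests": tests,
        "survival": survival,
        "report": report,
    }
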