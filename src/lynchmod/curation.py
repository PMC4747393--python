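"""Risk-variant selection: rare filter with pathogenic rescue, the five-tier
classification rules engine, evidence annotation, co-segregation checks and
per-subject burden.

Tiers follow clinical-genetics practice: 1/2 = no effect, 3 = unknown
significance (VUS), 4 = likely pathogenic, 5 = pathogenic.  A *risk-variant*
is any class ≥ 4 variant, or a class 3 variant whose protein change is
non-conservative (nonsense, frameshift and in-frame indels qualify).  Burden
counts only independent risk-variants outside the mismatch-repair genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

from .cohort import Subject
from .errors import AnnotationError, LinkageError
from .variants import (
    PROTEIN_ALTERING,
    Consequence,
    FunctionalGroup,
    VariantKey,
    VariantRecord,
    conservativeness,
)

# annotation vocabulary (bare "pathogenic" = pathogenic for another disorder)
ANNOT_DISEASE = "disease_associated"
ANNOT_DAMAGING = "predicted_damaging"
ANNOT_LIKELY = "likely_pathogenic"
ANNOT_PATHOGENIC_OTHER = "pathogenic"
ANNOT_PATHOGENIC_STUDY = "pathogenic_study_disease"

RESCUE_ANNOTATIONS = frozenset(
    {ANNOT_DISEASE, ANNOT_PATHOGENIC_OTHER, ANNOT_PATHOGENIC_STUDY}
)


@dataclass(frozen=True)
class CategoryAssignment:
    variant: VariantRecord
    category: int  # 1..5
    rule_trace: tuple[str, ...]
    conservativeness_call: Optional[str]  # conservative | non_conservative | None

    def __post_init__(self) -> None:
        if not 1 <= self.category <= 5:
            raise ValueError(f"category out of range: {self.category}")
        if not self.rule_trace:
            raise ValueError("empty rule trace")


@dataclass(frozen=True)
class EvidenceBundle:
    """Per-risk-variant supporting evidence; None means 'unavailable', never
    a defaulted False."""

    somatic_proximity_hit: Optional[bool] = None
    domain_conserved: Optional[bool] = None
    shared_among_relatives: bool = False
    in_relevant_domain: Optional[bool] = None
    predicted_consequence_note: Optional[str] = None
    independent_of_familial_mutation: bool = True


LINKAGE_INDEPENDENT = "independent"
LINKAGE_FAMILIAL = "possible_linkage_with_familial_mutation"
LINKAGE_SAME_CHROM = "same_chromosome_pair_within_subject"


@dataclass
class RiskVariant:
    assignment: CategoryAssignment
    evidence: EvidenceBundle = EvidenceBundle()
    linkage_flag: str = LINKAGE_INDEPENDENT

    def __post_init__(self) -> None:
        if self.assignment.category < 3:
            raise ValueError("risk-variants require category >= 3")

    @property
    def variant(self) -> VariantRecord:
        return self.assignment.variant


@dataclass(frozen=True)
class BurdenProfile:
    subject_id: str
    n_risk_variants_non_mmr: int
    n_risk_variants_mmr_extra: int
    risk_variant_ids: tuple[str, ...]
    collapsed_haplotypes: int = 0


def rare_filter(
    records: Iterable[VariantRecord], maf_threshold: float = 0.001
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split records into (retained, excluded) by population frequency.

    Retained: MAF strictly below the threshold, or unknown MAF (non-dbSNP
    variants are treated as rare), or — the rescue rule — frequent variants
    previously reported pathogenic or disease-associated, which are flagged
    ``rescued``.
    """
    retained, excluded = [], []
    for rec in sorted(records, key=lambda r: r.key):
        if rec.maf is None or rec.maf < maf_threshold:
            retained.append(rec)
        elif rec.prior_annotations & RESCUE_ANNOTATIONS:
            retained.append(replace(rec, rescued=True))
        else:
            excluded.append(rec)
    return retained, excluded


def assign_category(
    record: VariantRecord, scheme: str = "physicochemical"
) -> CategoryAssignment:
    """Apply the five-tier rules; when several rules fire the highest tier
    wins and the trace records every fired rule in order."""
    if record.consequence is None:
        raise AnnotationError(f"{record.key}: consequence not annotated")

    cons_call: Optional[str] = None
    if record.consequence is Consequence.MISSENSE and record.protein_change:
        pc = record.protein_change
        if "*" in (pc.ref_aa, pc.alt_aa):
            cons_call = "non_conservative"  # stop-loss alters the protein end
        else:
            cons_call = conservativeness(pc.ref_aa, pc.alt_aa, scheme)

    fired: list[tuple[str, int]] = []
    ann = record.prior_annotations
    cq = record.consequence
    if cq in (Consequence.SILENT, Consequence.SPLICE_REGION, Consequence.INTRONIC_FLANK):
        fired.append(("R1:silent_or_flank", 1))
    if cq is Consequence.MISSENSE and cons_call == "conservative":
        fired.append(("R2:conservative_missense", 2))
        if ann & {ANNOT_DISEASE, ANNOT_DAMAGING}:
            fired.append(("R3:conservative_missense_promoted", 3))
    if (cq in PROTEIN_ALTERING and cq is not Consequence.MISSENSE) or (
        cq is Consequence.MISSENSE and cons_call == "non_conservative"
    ):
        fired.append(("R4:non_conservative_or_truncating", 3))
    if ANNOT_LIKELY in ann:
        fired.append(("R5:prior_likely_pathogenic", 4))
    if ANNOT_PATHOGENIC_OTHER in ann:
        fired.append(("R6:pathogenic_other_disorder", 4))
    if ANNOT_PATHOGENIC_STUDY in ann:
        fired.append(("R7:pathogenic_study_disease", 5))
    if not fired:
        raise AnnotationError(f"{record.key}: no classification rule applies")
    category = max(level for _, level in fired)
    return CategoryAssignment(
        variant=record,
        category=category,
        rule_trace=tuple(name for name, _ in fired),
        conservativeness_call=cons_call,
    )


def replay_trace(assignment: CategoryAssignment) -> int:
    """Re-derive the category from the recorded trace (audit replay)."""
    levels = {"R1": 1, "R2": 2, "R3": 3, "R4": 3, "R5": 4, "R6": 4, "R7": 5}
    return max(levels[rule.split(":")[0]] for rule in assignment.rule_trace)


def select_risk_variants(
    assignments: Iterable[CategoryAssignment],
) -> list[RiskVariant]:
    """Keep class ≥ 4 unconditionally; class 3 only for non-conservative
    protein-altering changes.  Silent/flank variants never qualify."""
    selected = []
    for a in sorted(assignments, key=lambda a: a.variant.key):
        cq = a.variant.consequence
        if cq not in PROTEIN_ALTERING:
            continue
        if a.category >= 4:
            selected.append(RiskVariant(assignment=a))
        elif a.category == 3:
            altering_non_missense = cq is not Consequence.MISSENSE
            if altering_non_missense or a.conservativeness_call == "non_conservative":
                selected.append(RiskVariant(assignment=a))
    return selected


def read_somatic_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "aa_pos": int})
    df["nonsilent"] = df["nonsilent"].astype(bool)
    return df


def annotate_evidence(
    risk_variant: RiskVariant,
    somatic_table: Optional[pd.DataFrame] = None,
    relatives_index: Optional[dict[str, str]] = None,
    window_aa: int = 3,
) -> RiskVariant:
    """Attach evidence features; absent input tables leave fields unavailable.

    somatic_proximity_hit: a non-silent cancer somatic mutation within
    ``window_aa`` residues of the variant in the same gene.
    shared_among_relatives: the same variant key carried by ≥2 subjects of
    one family (via ``relatives_index``: subject_id -> family_id).
    """
    ev = risk_variant.evidence
    rec = risk_variant.variant

    somatic_hit: Optional[bool] = ev.somatic_proximity_hit
    if somatic_table is not None and rec.protein_position is not None:
        rows = somatic_table[
            (somatic_table["gene"] == rec.gene) & somatic_table["nonsilent"]
        ]
        somatic_hit = bool(
            (abs(rows["aa_pos"] - rec.protein_position) <= window_aa).any()
        )

    shared = ev.shared_among_relatives
    if relatives_index is not None:
        families = [
            relatives_index[s] for s in rec.subject_ids if relatives_index.get(s)
        ]
        shared = any(families.count(f) >= 2 for f in set(families))

    return replace(
        risk_variant,
        evidence=replace(
            ev, somatic_proximity_hit=somatic_hit, shared_among_relatives=shared
        ),
    )


def linkage_check(
    risk_variants: list[RiskVariant], familial_mutation
) -> list[RiskVariant]:
    """Flag co-segregation candidates among one subject's risk-variants.

    An MMR-gene risk-variant on the familial mutation's chromosome cannot be
    shown independent and is flagged; pairs of non-MMR risk-variants sharing
    a chromosome within the subject are flagged for the haplotype-collapse
    sensitivity mode.
    """
    for rv in risk_variants:
        if not rv.variant.key.chromosome:
            raise LinkageError(f"{rv.variant.key}: unknown chromosome")
    if not familial_mutation.chromosome:
        raise LinkageError("familial mutation chromosome unknown")

    non_mmr_chroms: dict[str, int] = {}
    for rv in risk_variants:
        if rv.variant.functional_group is not FunctionalGroup.MMR:
            c = rv.variant.key.chromosome
            non_mmr_chroms[c] = non_mmr_chroms.get(c, 0) + 1

    flagged = []
    for rv in risk_variants:
        rec = rv.variant
        if (
            rec.functional_group is FunctionalGroup.MMR
            and rec.key.chromosome == familial_mutation.chromosome
        ):
            flag = LINKAGE_FAMILIAL
            independent = False
        elif (
            rec.functional_group is not FunctionalGroup.MMR
            and non_mmr_chroms.get(rec.key.chromosome, 0) >= 2
        ):
            flag = LINKAGE_SAME_CHROM
            independent = True
        else:
            flag = LINKAGE_INDEPENDENT
            independent = True
        flagged.append(
            replace(
                rv,
                linkage_flag=flag,
                evidence=replace(
                    rv.evidence, independent_of_familial_mutation=independent
                ),
            )
        )
    return flagged


def burden(
    subject: Subject,
    risk_variants: list[RiskVariant],
    collapse_mode: str = "none",
) -> BurdenProfile:
    """Per-subject risk-variant burden after linkage checks.

    Headline count covers independent non-MMR risk-variants; under
    ``collapse_same_chromosome`` every within-subject same-chromosome group
    counts once (a putative haplotype).  MMR-gene extras are reported
    separately and never enter the headline count.
    """
    if collapse_mode not in ("none", "collapse_same_chromosome"):
        raise ValueError(f"unknown collapse mode: {collapse_mode}")
    rvs = sorted(risk_variants, key=lambda rv: rv.variant.key)
    non_mmr = [
        rv
        for rv in rvs
        if rv.variant.functional_group is not FunctionalGroup.MMR
        and rv.linkage_flag != LINKAGE_FAMILIAL
    ]
    mmr_extra = [
        rv for rv in rvs if rv.variant.functional_group is FunctionalGroup.MMR
    ]
    chroms = [rv.variant.key.chromosome for rv in non_mmr]
    groups = {c for c in chroms if chroms.count(c) >= 2}
    if collapse_mode == "collapse_same_chromosome":
        n = len(set(chroms))
    else:
        n = len(non_mmr)
    return BurdenProfile(
        subject_id=subject.subject_id,
        n_risk_variants_non_mmr=n,
        n_risk_variants_mmr_extra=len(mmr_extra),
        risk_variant_ids=tuple(str(rv.variant.key) for rv in non_mmr),
        collapsed_haplotypes=len(groups),
    )
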