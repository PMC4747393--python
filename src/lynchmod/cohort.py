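"""Clinical cohort model: subjects, tumors, familial MMR mutations, phenotype.

A cohort subject is a Lynch-syndrome mutation carrier diagnosed with
endometrial cancer (EC).  The clinical phenotype is *poor* when the EC
diagnosis came early (age 49 or younger) or when the subject developed more
than one cancer; it is *neutral* when the only cancer is an EC diagnosed at
50 or later.  A second diagnosis at the same site (e.g. colorectal cancer
twice) counts as multiple cancers.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import IndeterminatePhenotypeError, SchemaError


class TumorSite(str, enum.Enum):
    ENDOMETRIUM = "endometrium"
    COLORECTUM = "colorectum"
    OVARY = "ovary"
    BREAST = "breast"
    URINARY_TRACT = "urinary_tract"
    OTHER = "other"


#: compact site codes used in the clinical table's other_tumors column
SITE_CODES = {
    "C": TumorSite.COLORECTUM,
    "O": TumorSite.OVARY,
    "B": TumorSite.BREAST,
    "U": TumorSite.URINARY_TRACT,
}

#: chromosome carrying each mismatch-repair gene
MMR_CHROMOSOME = {"MLH1": "chr3", "MSH2": "chr2", "MSH6": "chr2", "PMS2": "chr7"}
MMR_GENES = frozenset(MMR_CHROMOSOME)


@dataclass(frozen=True)
class TumorDiagnosis:
    site: TumorSite
    age_at_diagnosis: Optional[int] = None  # None = unknown ("na")

    def __post_init__(self) -> None:
        age = self.age_at_diagnosis
        if age is not None and not (0 <= age <= 120):
            raise ValueError(f"implausible age at diagnosis: {age}")


@dataclass(frozen=True)
class FamilialMutation:
    """The pathogenic MMR mutation segregating in the subject's family."""

    gene: str
    cdna_change: str = ""
    protein_change: str = ""
    chromosome: str = ""

    def __post_init__(self) -> None:
        if self.gene not in MMR_CHROMOSOME:
            raise ValueError(f"not an MMR gene: {self.gene}")
        expected = MMR_CHROMOSOME[self.gene]
        if self.chromosome and self.chromosome != expected:
            raise ValueError(
                f"{self.gene} lies on {expected}, not {self.chromosome}"
            )
        if not self.chromosome:
            object.__setattr__(self, "chromosome", expected)


@dataclass
class Subject:
    subject_id: str
    age_ec_diagnosis: Optional[int]
    familial_mutation: FamilialMutation
    family_id: Optional[str] = None
    tumors: list[TumorDiagnosis] = field(default_factory=list)
    age_at_last_followup: Optional[int] = None
    ngs_passed_qc: bool = True
    # carried through for completeness; no statistic uses them
    ec_histology: Optional[str] = None
    ec_grade: Optional[str] = None
    ec_stage: Optional[str] = None
    msi: Optional[str] = None

    def __post_init__(self) -> None:
        ec = [t for t in self.tumors if t.site is TumorSite.ENDOMETRIUM]
        if not ec:
            self.tumors.insert(
                0, TumorDiagnosis(TumorSite.ENDOMETRIUM, self.age_ec_diagnosis)
            )
        elif len(ec) > 1:
            raise ValueError(f"{self.subject_id}: more than one EC entry")
        elif ec[0].age_at_diagnosis != self.age_ec_diagnosis:
            raise ValueError(f"{self.subject_id}: EC age mismatch")

    @property
    def non_ec_tumors(self) -> list[TumorDiagnosis]:
        return [t for t in self.tumors if t.site is not TumorSite.ENDOMETRIUM]


@dataclass(frozen=True)
class PhenotypeLabel:
    label: str  # "poor" | "neutral"
    reasons: frozenset[str] = frozenset()  # ⊆ {young_onset, multiple_cancers}

    def __post_init__(self) -> None:
        if (self.label == "poor") != bool(self.reasons):
            raise ValueError("poor label requires at least one reason")


REQUIRED_COLUMNS = [
    "subject_id",
    "family_id",
    "age_ec",
    "other_tumors",
    "mmr_gene",
    "mmr_cdna",
    "mmr_protein",
    "ngs_ok",
]
OPTIONAL_COLUMNS = [
    "ec_histology",
    "ec_grade",
    "ec_stage",
    "msi",
    "phenotype_override",
    "age_last_followup",
]


def _parse_age(token: str) -> Optional[int]:
    token = token.strip()
    if token in {"", "na", "NA", "nan", "-"}:
        return None
    try:
        return int(token)
    except ValueError:
        return None  # unparseable ages recorded as unknown, never dropped


def _parse_other_tumors(text: str) -> list[TumorDiagnosis]:
    """Parse the compact 'C-59;U-81' dialect (site code - age, 'na' allowed)."""
    tumors: list[TumorDiagnosis] = []
    for token in str(text).split(";"):
        token = token.strip()
        if not token or token in {"na", "nan"}:
            continue
        code, _, age = token.partition("-")
        site = SITE_CODES.get(code.strip().upper(), TumorSite.OTHER)
        tumors.append(TumorDiagnosis(site, _parse_age(age)))
    return tumors


def read_clinical_table(path: str | Path) -> list[Subject]:
    """Read the tab-separated clinical cohort table into Subject records.

    Subjects failing NGS QC are flagged (``ngs_passed_qc=False``) but
    retained, so cohort-level summaries still cover the full enrolment.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"clinical table missing mandatory column: {col}")
    ids = df["subject_id"].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise SchemaError(f"duplicate subject_id: {', '.join(dupes)}")

    subjects = []
    for _, row in df.iterrows():
        def opt(col: str) -> Optional[str]:
            val = str(row[col]).strip() if col in df.columns else ""
            return val or None

        age_ec = _parse_age(row["age_ec"])
        tumors = [TumorDiagnosis(TumorSite.ENDOMETRIUM, age_ec)]
        tumors += _parse_other_tumors(row["other_tumors"])
        family = str(row["family_id"]).strip()
        subjects.append(
            Subject(
                subject_id=str(row["subject_id"]).strip(),
                family_id=family if family not in {"", "-", "na"} else None,
                age_ec_diagnosis=age_ec,
                tumors=tumors,
                familial_mutation=FamilialMutation(
                    gene=str(row["mmr_gene"]).strip(),
                    cdna_change=str(row["mmr_cdna"]).strip(),
                    protein_change=str(row["mmr_protein"]).strip(),
                ),
                age_at_last_followup=_parse_age(row["age_last_followup"])
                if "age_last_followup" in df.columns
                else None,
                ngs_passed_qc=str(row["ngs_ok"]).strip().lower()
                in {"1", "true", "yes", "y"},
                ec_histology=opt("ec_histology"),
                ec_grade=opt("ec_grade"),
                ec_stage=opt("ec_stage"),
                msi=opt("msi"),
            )
        )
    return subjects


def classify_phenotype(subject: Subject, age_cutoff: int = 50) -> PhenotypeLabel:
    """Label a subject poor/neutral.

    Poor iff EC was diagnosed strictly before ``age_cutoff`` (default: 49 or
    younger) or the subject has at least one tumor diagnosis besides the EC.
    Tumors with unknown ages still count toward multiple cancers.
    """
    reasons = set()
    if subject.non_ec_tumors:
        reasons.add("multiple_cancers")
    age = subject.age_ec_diagnosis
    if age is not None and age < age_cutoff:
        reasons.add("young_onset")
    if age is None and not reasons:
        raise IndeterminatePhenotypeError(
            f"{subject.subject_id}: unknown EC age and no other tumors"
        )
    if reasons:
        return PhenotypeLabel("poor", frozenset(reasons))
    return PhenotypeLabel("neutral")


SECOND_LYNCH_SITES = {TumorSite.BREAST, TumorSite.COLORECTUM, TumorSite.OVARY}


def cohort_summary(subjects: list[Subject], age_cutoff: int = 50) -> dict:
    """Cohort-level tallies and EC-age moments (SD uses the n-1 denominator).

    ``n_second_lynch_tumor`` counts subjects with exactly one additional
    tumor at the breast, intestine or ovary; subjects with two extra events
    or a urinary-tract tumor are tallied outside that count.
    """
    ages = [s.age_ec_diagnosis for s in subjects if s.age_ec_diagnosis is not None]
    if len(ages) < 2:
        raise ValueError("need at least two subjects with known EC age")
    n = len(ages)
    mean = sum(ages) / n
    sd = math.sqrt(sum((a - mean) ** 2 for a in ages) / (n - 1))

    n_poor = n_neutral = n_indeterminate = 0
    for s in subjects:
        try:
            label = classify_phenotype(s, age_cutoff)
        except IndeterminatePhenotypeError:
            n_indeterminate += 1
            continue
        if label.label == "poor":
            n_poor += 1
        else:
            n_neutral += 1

    return {
        "n": len(subjects),
        "n_poor": n_poor,
        "n_neutral": n_neutral,
        "n_indeterminate": n_indeterminate,
        "n_young_onset": sum(
            1
            for s in subjects
            if s.age_ec_diagnosis is not None and s.age_ec_diagnosis < age_cutoff
        ),
        "n_second_lynch_tumor": sum(
            1
            for s in subjects
            if len(s.non_ec_tumors) == 1
            and s.non_ec_tumors[0].site in SECOND_LYNCH_SITES
        ),
        "mean_age_ec": mean,
        "sd_age_ec": sd,
        "min_age": min(ages),
        "max_age": max(ages),
    }


def load_study_cohort() -> list[Subject]:
    """The packaged 37-subject carrier cohort (shipped as a versioned TSV)."""
    ref = resources.files("lynchmod.data").joinpath("study_cohort.tsv")
    with resources.as_file(ref) as path:
        return read_clinical_table(path)
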