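"""Variant model, VCF/TSV ingestion, panel mapping and consequence calling.

Coordinate conventions: VCF positions are 1-based; panel BED intervals are
half-open 0-based.  Conversion happens exactly once, at the ingestion
boundary.  All toy transcripts carry their chromosome's reference sequence,
so a variant's coding consequence is determined by rebuilding the affected
codon (strand-aware) and translating it.
"""

from __future__ import annotations

import enum
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam
from Bio.Seq import Seq

from .errors import AnnotationError, SchemaError, VcfParseError
from .grantham import PROPERTIES, grantham_distance

VALID_BASES = set("ACGT")

AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}


def one_letter(aa: str) -> str:
    """Normalize a residue given in one- or three-letter code."""
    if len(aa) == 1:
        return aa.upper() if aa != "*" else "*"
    return AA3TO1[aa.capitalize()]


class Consequence(str, enum.Enum):
    SILENT = "silent"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INSERTION = "inframe_insertion"
    INFRAME_DELETION = "inframe_deletion"
    SPLICE_REGION = "splice_region"
    INTRONIC_FLANK = "intronic_flank"


#: consequences that alter the protein sequence
PROTEIN_ALTERING = {
    Consequence.MISSENSE,
    Consequence.NONSENSE,
    Consequence.FRAMESHIFT,
    Consequence.INFRAME_INSERTION,
    Consequence.INFRAME_DELETION,
}


class FunctionalGroup(str, enum.Enum):
    ESTROGEN = "estrogen"
    ONCOGENE = "oncogene"
    TUMOR_SUPPRESSOR = "tumor_suppressor"
    OTHER = "other"
    MMR = "mmr"


@dataclass(frozen=True, order=True)
class VariantKey:
    chromosome: str
    position: int  # 1-based, VCF convention
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - VALID_BASES:
                raise ValueError(f"invalid allele: {allele!r}")

    def __str__(self) -> str:
        return f"{self.chromosome}:{self.position}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class ProteinChange:
    ref_aa: str
    position: int  # 1-based residue index
    alt_aa: str

    def __str__(self) -> str:
        return f"p.{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass
class VariantRecord:
    key: VariantKey
    zygosity: dict[str, str] = field(default_factory=dict)  # subject -> het|hom
    gene: Optional[str] = None
    functional_group: Optional[FunctionalGroup] = None
    consequence: Optional[Consequence] = None
    protein_change: Optional[ProteinChange] = None
    indel_descriptor: Optional[str] = None
    maf: Optional[float] = None  # None = unknown (treated as rare downstream)
    dbsnp_id: Optional[str] = None
    prior_annotations: frozenset[str] = frozenset()
    off_target: bool = False
    rescued: bool = False

    @property
    def subject_ids(self) -> set[str]:
        return set(self.zygosity)

    @property
    def protein_position(self) -> Optional[int]:
        return self.protein_change.position if self.protein_change else None


@dataclass(frozen=True)
class PanelGene:
    symbol: str
    chromosome: str
    functional_group: FunctionalGroup
    captured_intervals: tuple[tuple[int, int], ...] = ()  # 0-based half-open

    def __post_init__(self) -> None:
        ivs = self.captured_intervals
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(f"{self.symbol}: intervals overlap or unsorted")

    def contains(self, pos_1based: int) -> bool:
        p = pos_1based - 1
        return any(s <= p < e for s, e in self.captured_intervals)


class PanelIndex:
    """Chromosome-indexed interval lookup over a gene panel."""

    def __init__(self, genes: Iterable[PanelGene]):
        self.genes = list(genes)
        self._by_chrom: dict[str, list[tuple[int, int, PanelGene]]] = {}
        for g in self.genes:
            for s, e in g.captured_intervals:
                self._by_chrom.setdefault(g.chromosome, []).append((s, e, g))
        for ivs in self._by_chrom.values():
            ivs.sort(key=lambda t: (t[0], t[1]))

    def lookup(self, chromosome: str, pos_1based: int) -> Optional[PanelGene]:
        ivs = self._by_chrom.get(chromosome, [])
        p = pos_1based - 1
        i = bisect_right([s for s, _, _ in ivs], p)
        for s, e, g in reversed(ivs[:i]):
            if s <= p < e:
                return g
        return None


def read_panel(bed_path: str | Path, meta_path: str | Path) -> list[PanelGene]:
    """Assemble PanelGene records from a capture BED and a gene-metadata TSV."""
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    for col in ("symbol", "chromosome", "functional_group"):
        if col not in meta.columns:
            raise SchemaError(f"panel metadata missing column: {col}")
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "start": int, "end": int, "name": str},
    )
    intervals: dict[str, list[tuple[int, int]]] = {}
    for row in bed.itertuples():
        intervals.setdefault(row.name, []).append((row.start, row.end))
    genes = []
    for row in meta.itertuples():
        ivs = tuple(sorted(intervals.get(row.symbol, [])))
        genes.append(
            PanelGene(
                symbol=row.symbol,
                chromosome=row.chromosome,
                functional_group=FunctionalGroup(row.functional_group),
                captured_intervals=ivs,
            )
        )
    return genes


def read_vcf(path: str | Path, panel: Iterable[PanelGene]) -> list[VariantRecord]:
    """Read a VCF into one record per (site, alt allele), mapped onto the panel.

    Multi-allelic sites are split; off-panel records are retained and flagged
    ``off_target``.  Genotypes must be present; carriers are recorded with
    het/hom zygosity.
    """
    index = PanelIndex(panel)
    records: list[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        samples = list(vcf.header.samples)
        for site in vcf:
            if site.alts is None:
                continue
            for ai, alt in enumerate(site.alts, start=1):
                if alt in (None, "*", "."):
                    continue
                try:
                    key = VariantKey(site.chrom, site.pos, site.ref, alt)
                except ValueError as exc:
                    raise VcfParseError(
                        f"{path} near {site.chrom}:{site.pos}: {exc}"
                    ) from exc
                zyg: dict[str, str] = {}
                for sample in samples:
                    gt = site.samples[sample].get("GT")
                    if gt is None:
                        continue
                    n_alt = sum(1 for a in gt if a == ai)
                    if n_alt == 0:
                        continue
                    zyg[sample] = "hom" if n_alt >= 2 else "het"
                if not zyg:
                    continue
                gene = index.lookup(key.chromosome, key.position)
                records.append(
                    VariantRecord(
                        key=key,
                        zygosity=zyg,
                        gene=gene.symbol if gene else None,
                        functional_group=gene.functional_group if gene else None,
                        off_target=gene is None,
                    )
                )
    records.sort(key=lambda r: r.key)
    return records


def read_maf_table(path: str | Path) -> dict[VariantKey, tuple[Optional[float], Optional[str]]]:
    """Frequency lookup TSV: chrom, pos, ref, alt, dbsnp_id, maf."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("chrom", "pos", "ref", "alt", "dbsnp_id", "maf"):
        if col not in df.columns:
            raise SchemaError(f"MAF table missing column: {col}")
    table = {}
    for row in df.itertuples():
        key = VariantKey(row.chrom, int(row.pos), row.ref, row.alt)
        maf = float(row.maf) if row.maf not in ("", "na") else None
        dbsnp = row.dbsnp_id or None
        table[key] = (maf, dbsnp)
    return table


def annotate_frequency(
    records: list[VariantRecord],
    maf_table: dict[VariantKey, tuple[Optional[float], Optional[str]]],
) -> list[VariantRecord]:
    """Fill maf/dbsnp_id from the lookup; unmatched keys stay unknown/non-dbSNP."""
    out = []
    for rec in records:
        maf, dbsnp = maf_table.get(rec.key, (None, None))
        out.append(replace(rec, maf=maf, dbsnp_id=dbsnp))
    return out


@dataclass(frozen=True)
class ToyTranscript:
    """A minimal single-transcript gene model over a short toy chromosome.

    ``cds_intervals`` are genomic, 0-based half-open, sorted; the spliced CDS
    (reverse-complemented on the minus strand) must be a whole number of
    codons and translate without an internal stop.
    """

    gene: str
    chromosome: str
    strand: str  # "+" | "-"
    cds_intervals: tuple[tuple[int, int], ...]
    chrom_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        cds = self.coding_sequence()
        if len(cds) % 3:
            raise ValueError(f"{self.gene}: CDS length not divisible by 3")
        protein = str(Seq(cds).translate())
        if "*" in protein[:-1]:
            raise ValueError(f"{self.gene}: internal stop codon in reference CDS")

    def spliced(self, chrom_seq: Optional[str] = None) -> str:
        seq = chrom_seq if chrom_seq is not None else self.chrom_seq
        return "".join(seq[s:e] for s, e in self.cds_intervals)

    def coding_sequence(self, chrom_seq: Optional[str] = None) -> str:
        cds = self.spliced(chrom_seq)
        return str(Seq(cds).reverse_complement()) if self.strand == "-" else cds

    def protein(self, chrom_seq: Optional[str] = None) -> str:
        return str(Seq(self.coding_sequence(chrom_seq)).translate())

    def cds_offset(self, pos_0based: int) -> Optional[int]:
        """Genome position -> offset in the (strand-oriented) CDS, else None."""
        off = 0
        plus_offset = None
        for s, e in self.cds_intervals:
            if s <= pos_0based < e:
                plus_offset = off + (pos_0based - s)
                break
            off += e - s
        if plus_offset is None:
            return None
        total = sum(e - s for s, e in self.cds_intervals)
        return plus_offset if self.strand == "+" else total - 1 - plus_offset

    def flank_distance(self, pos_0based: int) -> Optional[int]:
        """Distance (≥1) to the nearest exon boundary if intronic/UTR-side."""
        best = None
        for s, e in self.cds_intervals:
            if s <= pos_0based < e:
                return None
            d = (s - pos_0based) if pos_0based < s else (pos_0based - e + 1)
            best = d if best is None else min(best, d)
        return best


FLANK_NT = 10  # captured non-coding nucleotides at each exon end
SPLICE_NT = 2  # canonical splice donor/acceptor window


def annotate_consequence(
    record: VariantRecord, transcript: ToyTranscript
) -> VariantRecord:
    """Call the coding consequence of a variant on a toy transcript.

    SNVs inside the CDS are typed by rebuilding the affected codon; indels by
    the length difference modulo 3; positions within 10 nt of an exon end
    are splice_region (≤2 nt) or intronic_flank (3-10 nt).
    """
    key = record.key
    if key.chromosome != transcript.chromosome:
        raise AnnotationError(
            f"{key}: wrong chromosome for transcript {transcript.gene}"
        )
    pos0 = key.position - 1
    ref, alt = key.ref, key.alt

    expected = transcript.chrom_seq[pos0 : pos0 + len(ref)]
    if expected != ref:
        raise AnnotationError(f"{key}: reference allele mismatch ({expected!r})")

    if len(ref) == 1 and len(alt) == 1:
        offset = transcript.cds_offset(pos0)
        if offset is None:
            dist = transcript.flank_distance(pos0)
            if dist is None or dist > FLANK_NT:
                raise AnnotationError(f"{key}: outside CDS and captured flank")
            cons = (
                Consequence.SPLICE_REGION
                if dist <= SPLICE_NT
                else Consequence.INTRONIC_FLANK
            )
            return replace(record, consequence=cons, protein_change=None)
        cds = transcript.coding_sequence()
        cds_alt = alt if transcript.strand == "+" else str(Seq(alt).reverse_complement())
        codon_i = offset // 3
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        mutant = codon[: offset % 3] + cds_alt + codon[offset % 3 + 1 :]
        ref_aa = str(Seq(codon).translate())
        alt_aa = str(Seq(mutant).translate())
        change = ProteinChange(ref_aa, codon_i + 1, alt_aa)
        if alt_aa == ref_aa:
            cons = Consequence.SILENT
        elif alt_aa == "*":
            cons = Consequence.NONSENSE
        else:
            cons = Consequence.MISSENSE
        return replace(record, consequence=cons, protein_change=change)

    # indel: anchor base convention — change begins after the first ref base
    anchor = pos0 + 1
    touched = range(anchor, max(anchor + len(ref) - 1, anchor + 1))
    in_cds = any(transcript.cds_offset(p) is not None for p in touched)
    if not in_cds:
        dists = [transcript.flank_distance(p) for p in touched]
        dists = [d for d in dists if d is not None]
        if not dists or min(dists) > FLANK_NT:
            raise AnnotationError(f"{key}: indel outside CDS and captured flank")
        cons = (
            Consequence.SPLICE_REGION
            if min(dists) <= SPLICE_NT
            else Consequence.INTRONIC_FLANK
        )
        return replace(record, consequence=cons, protein_change=None)
    delta = len(alt) - len(ref)
    offset = transcript.cds_offset(anchor)
    aa_pos = offset // 3 + 1 if offset is not None else None
    if delta % 3 != 0:
        cons = Consequence.FRAMESHIFT
    elif delta > 0:
        cons = Consequence.INFRAME_INSERTION
    else:
        cons = Consequence.INFRAME_DELETION
    descriptor = f"{cons.value}@{aa_pos if aa_pos is not None else '?'}"
    change = (
        ProteinChange("?", aa_pos, "?") if aa_pos is not None else None
    )
    return replace(
        record, consequence=cons, protein_change=change, indel_descriptor=descriptor
    )


#: default physicochemical residue groups; a substitution within one group is
#: conservative.  Reproduces the curated calls used to build the risk-variant
#: set (Asp→Gly, Asp→Ser, Ala→Ser all non-conservative).
PHYSICOCHEMICAL_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("AVLIMFW"),   # hydrophobic / aliphatic-aromatic
    frozenset("GPC"),       # special conformation
    frozenset("STNQY"),     # polar uncharged
    frozenset("DE"),        # acidic
    frozenset("KRH"),       # basic
)


def conservativeness(ref_aa: str, alt_aa: str, scheme: str = "physicochemical") -> str:
    """Classify a substitution as 'conservative' or 'non_conservative'.

    scheme: 'physicochemical' (same fixed residue group) or
    'grantham:<threshold>' (Grantham distance ≤ threshold).  Symmetric in its
    arguments; identity substitutions are always conservative.
    """
    a, b = one_letter(ref_aa), one_letter(alt_aa)
    for aa in (a, b):
        if aa not in PROPERTIES:
            raise AnnotationError(f"nonstandard residue: {aa!r}")
    if a == b:
        return "conservative"
    if scheme == "physicochemical":
        same = any(a in g and b in g for g in PHYSICOCHEMICAL_GROUPS)
        return "conservative" if same else "non_conservative"
    if scheme.startswith("grantham:"):
        threshold = float(scheme.split(":", 1)[1])
        return (
            "conservative"
            if grantham_distance(a, b) <= threshold
            else "non_conservative"
        )
    raise ValueError(f"unknown conservativeness scheme: {scheme}")
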