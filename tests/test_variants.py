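"""Variant keys, panel lookup, VCF ingestion, consequence calling and
conservativeness schemes.

The consequence caller is checked against an independent oracle: mutate the
whole toy chromosome, re-splice, re-translate, and diff the full proteins.
"""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lynchmod.errors import AnnotationError, VcfParseError
from lynchmod.grantham import PROPERTIES, grantham_distance, grantham_matrix_value
from lynchmod.variants import (
    FLANK_NT,
    SPLICE_NT,
    Consequence,
    FunctionalGroup,
    PanelGene,
    PanelIndex,
    VariantKey,
    VariantRecord,
    annotate_consequence,
    annotate_frequency,
    conservativeness,
    read_vcf,
)

AMINO_ACIDS = sorted(PROPERTIES)
BASES = "ACGT"


class TestVariantKey:
    def test_rejects_identical_alleles(self):
        with pytest.raises(ValueError):
            VariantKey("chr1", 5, "A", "A")

    @pytest.mark.parametrize("ref,alt", [("", "A"), ("N", "A"), ("A", "AX")])
    def test_rejects_invalid_alleles(self, ref, alt):
        with pytest.raises(ValueError):
            VariantKey("chr1", 5, ref, alt)

    def test_ordering_is_lexicographic_then_positional(self):
        keys = [
            VariantKey("chr2", 1, "A", "T"),
            VariantKey("chr1", 9, "A", "T"),
            VariantKey("chr1", 2, "C", "G"),
            VariantKey("chr1", 2, "C", "A"),
        ]
        assert sorted(keys) == [keys[3], keys[2], keys[1], keys[0]]

    def test_str_round_trip_fields(self):
        assert str(VariantKey("chr3", 12, "AT", "A")) == "chr3:12:AT>A"


class TestPanelIndex:
    def test_lookup_matches_brute_force(self):
        rng = random.Random(11)
        genes = []
        start = 0
        for i in range(20):
            start += rng.randint(5, 40)
            end = start + rng.randint(1, 30)
            genes.append(
                PanelGene(
                    symbol=f"G{i}",
                    chromosome=f"chr{1 + i % 3}",
                    functional_group=FunctionalGroup.OTHER,
                    captured_intervals=((start, end),),
                )
            )
            start = end
        index = PanelIndex(genes)
        for _ in range(500):
            chrom = f"chr{rng.randint(1, 4)}"
            pos = rng.randint(1, start + 50)
            expect = next(
                (
                    g
                    for g in genes
                    if g.chromosome == chrom and g.contains(pos)
                ),
                None,
            )
            assert index.lookup(chrom, pos) is expect

    def test_boundaries_are_half_open(self):
        g = PanelGene("G", "chr1", FunctionalGroup.OTHER, ((10, 20),))
        index = PanelIndex([g])
        assert index.lookup("chr1", 10) is None  # 0-based 9
        assert index.lookup("chr1", 11) is g  # 0-based 10, first covered
        assert index.lookup("chr1", 20) is g  # 0-based 19, last covered
        assert index.lookup("chr1", 21) is None

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            PanelGene("G", "chr1", FunctionalGroup.OTHER, ((10, 20), (15, 30)))


VCF_TEMPLATE = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1,length=1000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr1\t15\t.\tA\tG,T\t.\t.\t.\tGT\t0/1\t2/2
chr1\t500\t.\tC\tA\t.\t.\t.\tGT\t0/0\t0/1
chr1\t600\t.\tG\tC\t.\t.\t.\tGT\t0/0\t0/0
"""


class TestReadVcf:
    @pytest.fixture()
    def panel(self):
        return [
            PanelGene("G1", "chr1", FunctionalGroup.ESTROGEN, ((10, 30),)),
        ]

    def test_multiallelic_split_and_zygosity(self, tmp_path, panel):
        p = tmp_path / "v.vcf"
        p.write_text(VCF_TEMPLATE)
        # fix reference base for pos 15 to match template
        recs = read_vcf(p, panel)
        keys = [str(r.key) for r in recs]
        assert keys == ["chr1:15:A>G", "chr1:15:A>T", "chr1:500:C>A"]
        assert recs[0].zygosity == {"S1": "het"}
        assert recs[1].zygosity == {"S2": "hom"}
        assert recs[0].gene == "G1" and not recs[0].off_target
        assert recs[2].gene is None and recs[2].off_target
        # non-carried site dropped entirely
        assert all(r.key.position != 600 for r in recs)

    def test_malformed_vcf_raises_parse_error(self, tmp_path, panel):
        p = tmp_path / "bad.vcf"
        p.write_text("this is not a vcf\n")
        with pytest.raises(VcfParseError):
            read_vcf(p, panel)


class TestAnnotateFrequency:
    def test_unmatched_keys_stay_unknown(self):
        key_known = VariantKey("chr1", 5, "A", "G")
        key_unknown = VariantKey("chr1", 6, "C", "T")
        recs = [VariantRecord(key=key_known), VariantRecord(key=key_unknown)]
        table = {key_known: (0.01, "rs1")}
        out = annotate_frequency(recs, table)
        assert (out[0].maf, out[0].dbsnp_id) == (0.01, "rs1")
        assert (out[1].maf, out[1].dbsnp_id) == (None, None)


def _oracle_snv(transcript, pos0, alt):
    """Expected consequence by full mutant-chromosome re-translation."""
    seq = transcript.chrom_seq
    mutant = seq[:pos0] + alt + seq[pos0 + 1 :]
    prot_ref = transcript.protein()
    prot_mut = transcript.protein(mutant)
    if prot_ref == prot_mut:
        return Consequence.SILENT, None
    diffs = [i for i, (x, y) in enumerate(zip(prot_ref, prot_mut)) if x != y]
    assert len(diffs) == 1
    i = diffs[0]
    ref_aa, alt_aa = prot_ref[i], prot_mut[i]
    if alt_aa == "*" and ref_aa != "*":
        return Consequence.NONSENSE, (ref_aa, i + 1, alt_aa)
    return Consequence.MISSENSE, (ref_aa, i + 1, alt_aa)


class TestConsequenceCalling:
    def test_random_cds_snvs_match_full_translation_oracle(self, toy_transcripts):
        rng = random.Random(202)
        n_checked = 0
        counts = {c: 0 for c in Consequence}
        transcripts = list(toy_transcripts.values())
        while n_checked < 1000:
            tx = rng.choice(transcripts)
            s, e = rng.choice(tx.cds_intervals)
            pos0 = rng.randrange(s, e)
            ref = tx.chrom_seq[pos0]
            alt = rng.choice([b for b in BASES if b != ref])
            rec = VariantRecord(key=VariantKey(tx.chromosome, pos0 + 1, ref, alt))
            got = annotate_consequence(rec, tx)
            expect_cons, expect_change = _oracle_snv(tx, pos0, alt)
            assert got.consequence is expect_cons, str(rec.key)
            if expect_change is not None:
                pc = got.protein_change
                assert (pc.ref_aa, pc.position, pc.alt_aa) == expect_change
            counts[got.consequence] += 1
            n_checked += 1
        # sanity: the sample exercises every SNV consequence class
        assert counts[Consequence.SILENT] > 50
        assert counts[Consequence.MISSENSE] > 300
        assert counts[Consequence.NONSENSE] > 10

    def test_flank_positions_split_into_splice_and_intronic(self, toy_transcripts):
        rng = random.Random(7)
        n_splice = n_flank = 0
        for tx in toy_transcripts.values():
            for s, e in tx.cds_intervals:
                for pos0 in list(range(s - FLANK_NT, s)) + list(
                    range(e, e + FLANK_NT)
                ):
                    if tx.cds_offset(pos0) is not None:
                        continue  # inside the other exon of a short intron
                    dist = min(abs(pos0 - s), abs(pos0 - (e - 1)),
                               *(abs(pos0 - b) for iv in tx.cds_intervals
                                 for b in (iv[0], iv[1] - 1)))
                    ref = tx.chrom_seq[pos0]
                    alt = rng.choice([b for b in BASES if b != ref])
                    rec = VariantRecord(
                        key=VariantKey(tx.chromosome, pos0 + 1, ref, alt)
                    )
                    got = annotate_consequence(rec, tx)
                    expect = (
                        Consequence.SPLICE_REGION
                        if dist <= SPLICE_NT
                        else Consequence.INTRONIC_FLANK
                    )
                    assert got.consequence is expect, str(rec.key)
                    assert got.protein_change is None
                    if expect is Consequence.SPLICE_REGION:
                        n_splice += 1
                    else:
                        n_flank += 1
        assert n_splice > 10 and n_flank > 10

    def test_random_indels_typed_by_length_delta(self, toy_transcripts):
        rng = random.Random(31)
        transcripts = list(toy_transcripts.values())
        seen = set()
        for _ in range(300):
            tx = rng.choice(transcripts)
            s, e = rng.choice(tx.cds_intervals)
            if rng.random() < 0.5:  # insertion after an anchor inside the exon
                pos0 = rng.randrange(s, e - 1)
                ref = tx.chrom_seq[pos0]
                ins = "".join(rng.choice(BASES) for _ in range(rng.randint(1, 6)))
                alt = ref + ins
                delta = len(ins)
            else:  # deletion of bases following the anchor, kept inside the exon
                ndel = rng.randint(1, min(6, e - s - 1))
                pos0 = rng.randrange(s, e - ndel)
                ref = tx.chrom_seq[pos0 : pos0 + ndel + 1]
                alt = ref[0]
                delta = -ndel
            if set(ref) - set(BASES):
                continue
            rec = VariantRecord(key=VariantKey(tx.chromosome, pos0 + 1, ref, alt))
            got = annotate_consequence(rec, tx)
            if delta % 3 != 0:
                expect = Consequence.FRAMESHIFT
            elif delta > 0:
                expect = Consequence.INFRAME_INSERTION
            else:
                expect = Consequence.INFRAME_DELETION
            assert got.consequence is expect, str(rec.key)
            assert got.indel_descriptor.startswith(expect.value)
            seen.add(expect)
        assert seen == {
            Consequence.FRAMESHIFT,
            Consequence.INFRAME_INSERTION,
            Consequence.INFRAME_DELETION,
        }

    def test_reference_mismatch_rejected(self, toy_transcripts):
        tx = next(iter(toy_transcripts.values()))
        s, _ = tx.cds_intervals[0]
        ref = tx.chrom_seq[s]
        wrong = next(b for b in BASES if b != ref)
        other = next(b for b in BASES if b not in (ref, wrong))
        rec = VariantRecord(key=VariantKey(tx.chromosome, s + 1, wrong, other))
        with pytest.raises(AnnotationError, match="mismatch"):
            annotate_consequence(rec, tx)

    def test_wrong_chromosome_rejected(self, toy_transcripts):
        tx = next(iter(toy_transcripts.values()))
        rec = VariantRecord(key=VariantKey("chrZZ", 1, "A", "G"))
        with pytest.raises(AnnotationError, match="chromosome"):
            annotate_consequence(rec, tx)

    def test_far_intergenic_position_rejected(self, toy_transcripts):
        tx = next(iter(toy_transcripts.values()))
        pos0 = tx.cds_intervals[-1][1] + FLANK_NT + 5
        ref = tx.chrom_seq[pos0]
        alt = next(b for b in BASES if b != ref)
        rec = VariantRecord(key=VariantKey(tx.chromosome, pos0 + 1, ref, alt))
        with pytest.raises(AnnotationError, match="outside"):
            annotate_consequence(rec, tx)


class TestConservativeness:
    @given(
        a=st.sampled_from(AMINO_ACIDS),
        b=st.sampled_from(AMINO_ACIDS),
        scheme=st.sampled_from(["physicochemical", "grantham:100"]),
    )
    @settings(max_examples=300, deadline=None)
    def test_symmetric_and_identity_conservative(self, a, b, scheme):
        assert conservativeness(a, b, scheme) == conservativeness(b, a, scheme)
        assert conservativeness(a, a, scheme) == "conservative"

    @pytest.mark.parametrize(
        "ref,alt,call",
        [
            ("D", "G", "non_conservative"),
            ("D", "S", "non_conservative"),
            ("A", "S", "non_conservative"),
            ("L", "I", "conservative"),
            ("K", "R", "conservative"),
            ("D", "E", "conservative"),
        ],
    )
    def test_physicochemical_reference_calls(self, ref, alt, call):
        assert conservativeness(ref, alt) == call

    def test_three_letter_codes_accepted(self):
        assert conservativeness("Asp", "Glu") == "conservative"

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(AnnotationError):
            conservativeness("B", "A")

    def test_grantham_threshold_scheme(self):
        assert conservativeness("L", "I", "grantham:50") == "conservative"
        assert conservativeness("R", "L", "grantham:50") == "non_conservative"

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            conservativeness("A", "V", "blosum62")


class TestGrantham:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("L", "I", 5), ("D", "E", 45), ("K", "R", 26), ("F", "L", 22), ("R", "L", 102)],
    )
    def test_reference_matrix_entries(self, a, b, expected):
        assert grantham_matrix_value(a, b) == expected

    @given(a=st.sampled_from(AMINO_ACIDS), b=st.sampled_from(AMINO_ACIDS))
    @settings(max_examples=200, deadline=None)
    def test_metric_like_properties(self, a, b):
        assert grantham_distance(a, b) == pytest.approx(grantham_distance(b, a))
        assert grantham_distance(a, a) == 0.0
        if a != b:
            assert grantham_distance(a, b) > 0.0
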