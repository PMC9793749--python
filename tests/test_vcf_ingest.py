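"""VCF parsing, key normalization, QUAL convention and call filters."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from ctvar.vcf_io import (
    FilterConfig,
    VariantKey,
    VcfParseError,
    apply_call_filters,
    classify_variant_type,
    max_impact,
    p_from_qual,
    parse_ann_field,
    qual_from_p,
    read_sample_vcf,
    region_of,
    functional_class_of,
)
from .conftest import make_call

HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=1000000>\n"
    "##contig=<ID=chr2,length=1000000>\n"
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">\n'
    '##INFO=<ID=ANN,Number=.,Type=String,Description="ann">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
)


def write_vcf(path, body):
    path.write_text(HEADER + body)
    return path


def test_single_record_parse(tmp_path):
    ann = "G|missense_variant|MODERATE|TP53|tp53_id|transcript|TP53.t1|protein_coding|1/1|||||||"
    vcf = write_vcf(
        tmp_path / "s.vcf", f"chr1\t100\t.\tA\tG\t35\t.\tDP=12;ANN={ann}\tGT\t0/1\n"
    )
    calls = read_sample_vcf(vcf, "S1")
    assert len(calls) == 1
    c = calls[0]
    assert c.key == VariantKey("chr1", 100, "A", "G")
    assert c.depth == 12 and c.qual == 35.0
    assert c.max_impact == "MODERATE"
    assert c.annotations[0].gene == "TP53"


def test_multiallelic_record_splits_into_two_calls(tmp_path):
    vcf = write_vcf(tmp_path / "s.vcf", "chr1\t100\t.\tA\tG,T\t40\t.\tDP=9\tGT\t1/2\n")
    calls = read_sample_vcf(vcf, "S1")
    assert {c.key for c in calls} == {
        VariantKey("chr1", 100, "A", "G"),
        VariantKey("chr1", 100, "A", "T"),
    }


def test_deletion_key_normalized(tmp_path):
    vcf = write_vcf(tmp_path / "s.vcf", "chr2\t200\t.\tAT\tA\t40\t.\tDP=9\tGT\t0/1\n")
    (call,) = read_sample_vcf(vcf, "S1")
    assert call.key == VariantKey("chr2", 200, "AT", "A")
    assert classify_variant_type(call.key) == "deletion"


def test_garbled_vcf_raises_parse_error(tmp_path):
    bad = tmp_path / "bad.vcf"
    bad.write_text("this is not a vcf at all\n")
    with pytest.raises(VcfParseError):
        read_sample_vcf(bad, "S1")


def test_short_ann_entry_skipped_call_retained():
    with pytest.warns(UserWarning):
        per_allele = parse_ann_field("G|missense_variant")
    assert per_allele == {}


@pytest.mark.parametrize(
    "chrom, pos, ref, alt, expect",
    [
        ("chr1", 100, "ATT", "GTT", VariantKey("chr1", 100, "A", "G")),  # suffix trim
        ("chr1", 100, "CAG", "CAT", VariantKey("chr1", 102, "G", "T")),  # prefix trim
        ("chr1", 100, "CTT", "CT", VariantKey("chr1", 100, "CT", "C")),  # indel parsimony
        ("chr1", 100, "a", "g", VariantKey("chr1", 100, "A", "G")),  # case folding
    ],
)
def test_key_normalization(chrom, pos, ref, alt, expect):
    assert VariantKey.normalized(chrom, pos, ref, alt) == expect


@given(
    pos=st.integers(1, 10_000),
    core=st.tuples(st.sampled_from("ACGT"), st.sampled_from("ACGT")).filter(
        lambda t: t[0] != t[1]
    ),
    pad_left=st.text(alphabet="ACGT", max_size=4),
    pad_right=st.text(alphabet="ACGT", max_size=4),
)
@settings(derandomize=True, max_examples=60)
def test_normalization_strips_any_shared_padding(pos, core, pad_left, pad_right):
    ref, alt = core
    key = VariantKey.normalized(
        "chr1", pos, pad_left + ref + pad_right, pad_left + alt + pad_right
    )
    assert key == VariantKey("chr1", pos + len(pad_left), ref, alt)
    # type classification invariant under re-normalization
    renorm = VariantKey.normalized(key.chrom, key.pos, key.ref, key.alt)
    assert classify_variant_type(renorm) == classify_variant_type(key) == "SNP"


def test_qual_p_conversion_round_trip():
    assert qual_from_p(1e-20) == pytest.approx(20.0)
    assert qual_from_p(1.0) == 0.0
    assert p_from_qual(5.0) == pytest.approx(1e-5)
    assert p_from_qual(qual_from_p(0.0123)) == pytest.approx(0.0123)
    for bad in (0.0, -1.0, 1.5):
        with pytest.raises(ValueError):
            qual_from_p(bad)


@pytest.mark.parametrize(
    "depth, qual, expect",
    [(5, 20.0, True), (4, 100.0, False), (100, 19.999, False), (6, 21.0, True)],
)
def test_filter_thresholds_inclusive(depth, qual, expect):
    (call,) = apply_call_filters([make_call("S1", depth=depth, qual=qual)])
    assert call.passed is expect


def test_filters_idempotent_and_monotone():
    calls = [make_call("S1", depth=d, qual=q) for d in (3, 5, 10) for q in (10.0, 20.0, 99.0)]
    base = apply_call_filters(calls)
    again = apply_call_filters(base)
    assert [c.passed for c in base] == [c.passed for c in again]
    stricter = apply_call_filters(calls, FilterConfig(depth_min=8, qual_min=30.0))
    for lax, strict in zip(base, stricter):
        assert not (strict.passed and not lax.passed)  # raising thresholds never adds


@pytest.mark.parametrize(
    "ref, alt, expect",
    [("A", "G", "SNP"), ("A", "AT", "insertion"), ("ATG", "A", "deletion"), ("AT", "GC", "MNP")],
)
def test_variant_type_classes(ref, alt, expect):
    assert classify_variant_type(VariantKey("chr1", 1, ref, alt)) == expect


def test_variant_level_impact_is_max_over_annotations():
    call = make_call("S1")
    low = make_call("S1", impact="LOW", effects=("synonymous_variant",))
    mixed = make_call("S1")
    mixed.annotations = low.annotations + call.annotations
    assert max_impact(mixed.annotations) == "HIGH"
    assert max_impact(()) == "MODIFIER"


@pytest.mark.parametrize(
    "terms, region",
    [
        (("splice_donor_variant", "intron_variant"), "splicing"),
        (("intron_variant",), "intron"),
        (("upstream_gene_variant",), "upstream"),
        (("downstream_gene_variant",), "downstream"),
        (("intergenic_region",), "intergenic"),
        (("missense_variant",), "exon"),
        (("non_coding_transcript_variant",), "genic_other"),
    ],
)
def test_region_mapping(terms, region):
    assert region_of(terms) == region


@pytest.mark.parametrize(
    "terms, fc",
    [
        (("missense_variant",), "missense"),
        (("synonymous_variant",), "synonymous"),
        (("stop_gained",), "nonsense"),
        (("intron_variant",), "none"),
    ],
)
def test_functional_class_mapping(terms, fc):
    assert functional_class_of(terms) == fc
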