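"""Hard-filter rules, monotonicity, and SNP region/effect classification."""
import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepibd.filtering import (
    NONSYNONYMOUS,
    STOP_GAIN,
    STOP_LOSS,
    SYNONYMOUS,
    AnnotationError,
    FilterConfig,
    classify_region,
    codon_effect,
    filter_matrix,
    hard_filter,
)
from sweepibd.intervals import GenomicInterval
from sweepibd.io import GeneModel, GenotypeMatrix, PopulationPanel, VariantRecord


def make_record(info=None, calls=(0, 1, 2, 0), pos=100):
    return VariantRecord(
        chrom="1", pos=pos, id=None, ref="A", alt="G",
        info=dict(info or {}), calls=np.array(calls, dtype=np.int8),
    )


GOOD_INFO = {"QD": 30.0, "FS": 1.0, "MQ": 60.0, "MQRankSum": 0.0, "ReadPosRankSum": 0.0}


def test_hard_filter_examples():
    ok, failed = hard_filter(make_record({**GOOD_INFO, "QD": 1.5}))
    assert not ok and failed == ["QD"]
    ok, failed = hard_filter(make_record(GOOD_INFO))
    assert ok and failed == []
    # 5 of 20 calls missing = 25% > 20% ceiling
    calls = [0] * 15 + [-1] * 5
    ok, failed = hard_filter(make_record(GOOD_INFO, calls=calls))
    assert not ok and failed == ["missingness"]
    # 4 of 20 missing = 20%, not strictly above the ceiling: passes
    ok, _ = hard_filter(make_record(GOOD_INFO, calls=[0] * 16 + [-1] * 4))
    assert ok


def test_absent_info_metric_does_not_fail():
    ok, failed = hard_filter(make_record({"QD": 30.0}))  # rank sums absent
    assert ok and failed == []


@settings(max_examples=60, derandomize=True)
@given(
    qd=st.floats(0, 50), fs=st.floats(0, 100), mq=st.floats(0, 70),
    mqrs=st.floats(-20, 20), rprs=st.floats(-15, 15),
    slack=st.floats(0, 10),
)
def test_hard_filter_monotone_in_thresholds(qd, fs, mq, mqrs, rprs, slack):
    """Relaxing every threshold never turns a pass into a fail."""
    rec = make_record({"QD": qd, "FS": fs, "MQ": mq, "MQRankSum": mqrs, "ReadPosRankSum": rprs})
    strict = FilterConfig()
    relaxed = FilterConfig(
        qd_min=strict.qd_min - slack, fs_max=strict.fs_max + slack,
        mq_min=strict.mq_min - slack, mqranksum_min=strict.mqranksum_min - slack,
        readposranksum_min=strict.readposranksum_min - slack,
    )
    if hard_filter(rec, strict)[0]:
        assert hard_filter(rec, relaxed)[0]


def test_filter_matrix_adjudicates_each_rule():
    panel = PopulationPanel(samples=["a", "b", "c", "d"], population_of=dict.fromkeys("abcd", "P"))
    records = [make_record(GOOD_INFO, pos=10 * (i + 1)) for i in range(7)]
    records.append(make_record({**GOOD_INFO, "FS": 99.0}, pos=80))
    records.append(make_record({**GOOD_INFO, "MQ": 10.0}, pos=90))
    records.append(make_record({**GOOD_INFO, "ReadPosRankSum": -9.0}, pos=100))
    matrix = GenotypeMatrix.from_records(records, panel)
    filtered, summary, mask = filter_matrix(matrix, records)
    assert filtered.n_variants == 7
    assert summary["FS"] == summary["MQ"] == summary["ReadPosRankSum"] == 1
    assert summary["n_retained"] == 7
    assert mask.sum() == 7

    # thresholds at +/- infinity retain everything
    lax = FilterConfig(qd_min=-np.inf, fs_max=np.inf, mq_min=-np.inf,
                       mqranksum_min=-np.inf, readposranksum_min=-np.inf,
                       max_missing_fraction=1.0)
    all_kept, _, _ = filter_matrix(matrix, records, lax)
    assert all_kept.n_variants == len(records)

    # every record failing still yields a valid empty matrix
    harsh = FilterConfig(qd_min=np.inf)
    none_kept, _, _ = filter_matrix(matrix, records, harsh)
    assert none_kept.n_variants == 0

    with pytest.raises(ValueError):
        filter_matrix(matrix, records[:-1])


# ---------------------------------------------------------------------------
# codon effects


def test_codon_effect_stop_gain_and_loss():
    # TAC -> TAA at the codon third position
    assert codon_effect("ATGTACGGG", 5, "C", "A") == STOP_GAIN
    # TGA -> TGG (stop -> Trp)
    assert codon_effect("ATGTGAGGG", 5, "A", "G") == STOP_LOSS
    # AAA -> AAG (Lys -> Lys)
    assert codon_effect("AAAGGG", 2, "A", "G") == SYNONYMOUS
    assert codon_effect("AAAGGG", 0, "A", "C") == NONSYNONYMOUS


def test_codon_effect_minus_strand_complements_alleles():
    # CDS codon GAC (Asp); genomic + strand carries the complement
    assert codon_effect("GACGGG", 0, "C", "T", strand="-") == NONSYNONYMOUS
    with pytest.raises(AnnotationError):
        codon_effect("GACGGG", 0, "G", "T", strand="-")  # complement(G)=C != G


def test_codon_effect_rejects_bad_cds():
    with pytest.raises(AnnotationError):
        codon_effect("ATGT", 0, "A", "G")
    with pytest.raises(AnnotationError):
        codon_effect("ATGTAA", 10, "A", "G")


def _oracle_effect(cds, offset, ref, alt):
    """Brute force: mutate the whole CDS, translate both, compare proteins."""
    assert cds[offset] == ref
    mutated = cds[:offset] + alt + cds[offset + 1:]
    aa_ref = str(Seq(cds).translate())
    aa_alt = str(Seq(mutated).translate())
    i = offset // 3
    if aa_ref[i] == aa_alt[i]:
        return SYNONYMOUS
    if aa_alt[i] == "*":
        return STOP_GAIN
    if aa_ref[i] == "*":
        return STOP_LOSS
    return NONSYNONYMOUS


def test_codon_effect_matches_exhaustive_oracle():
    rng = np.random.default_rng(123)
    cds = "".join(rng.choice(list("ACGT")) for _ in range(90))  # 30 codons
    for offset in range(90):
        ref = cds[offset]
        for alt in "ACGT":
            if alt == ref:
                continue
            assert codon_effect(cds, offset, ref, alt) == _oracle_effect(
                cds, offset, ref, alt
            ), f"offset {offset} {ref}>{alt}"


# ---------------------------------------------------------------------------
# region classification


@pytest.fixture
def gene():
    """+ strand gene on [1000, 5000): exons [1000,1500) and [4000,5000);
    UTRs at the CDS flanks; CDS carries a known sequence."""
    chrom = "1"
    cds_ivs = [GenomicInterval(chrom, 1100, 1500), GenomicInterval(chrom, 4000, 4899)]
    cds_seq = "A" * 1299  # poly-Lys: every position matches ref A
    return GeneModel(
        gene_id="g",
        interval=GenomicInterval(chrom, 1000, 5000),
        strand="+",
        exons=[GenomicInterval(chrom, 1000, 1500), GenomicInterval(chrom, 4000, 5000)],
        cds=cds_ivs,
        utr5=[GenomicInterval(chrom, 1000, 1100)],
        utr3=[GenomicInterval(chrom, 4900, 5000)],
        cds_sequence=cds_seq,
    )


@pytest.mark.parametrize(
    "pos, expected",
    [
        (1200, "exonic"),
        (1500, "splicing"),   # first intron base after exon 1
        (1501, "splicing"),   # 2 bp splice window
        (1502, "intronic"),
        (3999, "splicing"),   # last intron base before exon 2
        (1050, "utr5"),
        (4950, "utr3"),
        (2500, "intronic"),
        (999, "upstream"),
        (5000, "downstream"),
        (900, "upstream"),
        (9000, "downstream"),  # within 5 kb after the gene
        (50000, "intergenic"),
    ],
)
def test_classify_region_partition(gene, pos, expected):
    rec = VariantRecord(
        chrom="1", pos=pos + 1, id=None, ref="A", alt="G",
        info={}, calls=np.zeros(1, dtype=np.int8),
    )
    category, _ = classify_region(rec, [gene])
    assert category == expected


def test_classify_region_reports_codon_effect(gene):
    # genomic 1100 is CDS offset 0: 'A' of ATG; A->G is nonsynonymous
    rec = VariantRecord(chrom="1", pos=1101, id=None, ref="A", alt="G",
                        info={}, calls=np.zeros(1, dtype=np.int8))
    category, effect = classify_region(rec, [gene])
    assert category == "exonic"
    assert effect == NONSYNONYMOUS


def test_minus_strand_flanks():
    g = GeneModel(
        gene_id="m", interval=GenomicInterval("1", 1000, 2000), strand="-",
        exons=[GenomicInterval("1", 1000, 2000)],
    )
    rec = lambda pos: VariantRecord(chrom="1", pos=pos + 1, id=None, ref="A",
                                    alt="G", info={}, calls=np.zeros(1, dtype=np.int8))
    assert classify_region(rec(2500), [g])[0] == "upstream"
    assert classify_region(rec(500), [g])[0] == "downstream"
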