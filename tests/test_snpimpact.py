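"""SNP gain/loss-of-site classification and the pooled imbalance screen."""
import math

import numpy as np
import pytest

from mirqtl.io import read_vcf_pooled
from mirqtl.sequences import MatureMiRNA, UTRSequence
from mirqtl.snpimpact import (
    CLASS_CREATED, CLASS_DESTROYED, CLASS_NONE, FLAG_AMPLIFICATION, FLAG_LOH,
    FLAG_NONE, SNPRecord, allele_frequencies, apply_allele, classify_snp,
    flag_imbalance, imbalance_ratio, screen_candidates,
)

MIR = MatureMiRNA("mirX", "UAGGCACUUAGCAGCAUCAGGC")  # seed 2-8 = AGGCACU


def test_apply_allele_substitutes_and_validates():
    utr = UTRSequence("g", "AAAAGTGCCTAAAA")
    snp = SNPRecord("s1", "g", 8, "C", "A")
    assert apply_allele(utr, snp, "A").sequence == "AAAAGTGACTAAAA"
    assert apply_allele(utr, snp, "C").sequence == utr.sequence
    with pytest.raises(ValueError):
        apply_allele(utr, SNPRecord("s2", "g", 1, "C", "T"), "C")  # base is A
    with pytest.raises(IndexError):
        apply_allele(utr, SNPRecord("s3", "g", 99, "C", "T"), "C")


def _impacts_nonnone(snp, utr, mirnas=(MIR,)):
    return {
        i.mirna: i for i in classify_snp(snp, utr, list(mirnas))
        if i.classification != CLASS_NONE
    }


def test_destroyed_site_worked_example():
    # genome carries the perfect 7-mer AGTGCCT; the alternate allele breaks it.
    # Flanks are chosen so no in-register 8-mer survives with one mismatch:
    # the base 5' of the site window pairs mature position 9 (U) as a hard
    # mismatch (C), pre-consuming the 8-mer budget.
    utr = UTRSequence("g", "AAAC" + "AGTGCCT" + "CGAA")
    snp = SNPRecord("s1", "g", 9, "C", "A")  # site position pairing seed pos 4
    hits = _impacts_nonnone(snp, utr)
    assert set(hits) == {"mirX"}
    imp = hits["mirX"]
    assert imp.classification == CLASS_DESTROYED
    assert imp.effect_allele == "A"
    assert imp.site_before is not None and imp.site_after is None


def test_created_site_symmetric_example():
    utr = UTRSequence("g", "AAAC" + "AGTGACT" + "CGAA")  # broken site in genome
    snp = SNPRecord("s1", "g", 9, "A", "C")
    hits = _impacts_nonnone(snp, utr)
    assert hits["mirX"].classification == CLASS_CREATED
    assert hits["mirX"].effect_allele == "C"


def test_classification_is_symmetric_in_ref_alt_labels():
    utr = UTRSequence("g", "AAAC" + "AGTGCCT" + "CGAA")
    a = _impacts_nonnone(SNPRecord("s", "g", 9, "C", "A"), utr)["mirX"]
    b = _impacts_nonnone(SNPRecord("s", "g", 9, "A", "C"), utr)["mirX"]
    assert a.classification == b.classification == CLASS_DESTROYED
    assert a.effect_allele == b.effect_allele == "A"


def test_snp_outside_seed_windows_is_none():
    utr = UTRSequence("g", "AAAC" + "AGTGCCT" + "CGAAAAAA")
    snp = SNPRecord("s", "g", len(utr.sequence), "A", "T")
    assert _impacts_nonnone(snp, utr) == {}


def test_classification_locality_to_distant_edits():
    core = "AAAC" + "AGTGCCT" + "CGAA"
    snp = SNPRecord("s", "g", 9 + 10, "C", "A")
    far1 = UTRSequence("g", "GGGGGGGGGG" + core + "TTTTTTTTTT")
    far2 = UTRSequence("g", "CACACACACA" + core + "GCGCGCGCGC")
    i1 = {k: v.classification for k, v in _impacts_nonnone(snp, far1).items()}
    i2 = {k: v.classification for k, v in _impacts_nonnone(snp, far2).items()}
    assert i1 == i2 == {"mirX": CLASS_DESTROYED}


def test_planted_bundle_recovery_is_exact(small_bundle):
    utrs = {u.gene_id: u for u in small_bundle.utr_set}
    for s in small_bundle.planted_snps:
        snp = SNPRecord(s.snp_id, s.gene_id, s.position, s.ref_allele, s.alt_allele)
        hits = _impacts_nonnone(snp, utrs[s.gene_id], small_bundle.mirna_set)
        if s.intended_class == CLASS_NONE:
            assert hits == {}
        else:
            assert set(hits) == {s.mirna}
            assert hits[s.mirna].classification == s.intended_class


def test_filters_strict_thresholds():
    def rec(rh, ah, rl, al):
        return SNPRecord("s", "g", 5, "C", "T", {"high": (rh, ah), "low": (rl, al)})

    assert allele_frequencies(rec(3, 2, 3, 2)).filter_reason is not None  # total 10
    assert allele_frequencies(rec(48, 2, 48, 2)).filter_reason is not None  # minor 4
    assert allele_frequencies(rec(50, 3, 50, 2)).filter_reason is not None  # maf .0476
    ok = allele_frequencies(rec(20, 5, 10, 5))
    assert ok.passes
    assert ok.freq_alt["high"] == pytest.approx(0.2)
    assert allele_frequencies(rec(0, 0, 0, 0)).filter_reason == "no coverage"


def test_filter_monotonicity_under_tightening(rng):
    for _ in range(200):
        depths = {
            "high": (int(rng.integers(0, 40)), int(rng.integers(0, 40))),
            "low": (int(rng.integers(0, 40)), int(rng.integers(0, 40))),
        }
        snp = SNPRecord("s", "g", 5, "C", "T", depths)
        loose = allele_frequencies(snp, 10, 4, 0.05).passes
        tight = allele_frequencies(snp, 20, 6, 0.10).passes
        assert not (tight and not loose)


def test_imbalance_ratio_flags_and_sentinels():
    r, f = imbalance_ratio(0.25, 0.75)
    assert (r, f) == (pytest.approx(1 / 3), FLAG_LOH)
    assert imbalance_ratio(0.5, 0.5) == (1.0, FLAG_NONE)
    r, f = imbalance_ratio(0.5, 0.0)
    assert math.isinf(r) and f == FLAG_AMPLIFICATION
    assert imbalance_ratio(0.0, 0.0) == (None, FLAG_NONE)
    # inclusive (reported-methods) vs strict boundary behavior
    assert imbalance_ratio(0.5, 0.25)[1] == FLAG_AMPLIFICATION
    assert imbalance_ratio(0.5, 0.25, strict=True)[1] == FLAG_NONE
    with pytest.raises(ValueError):
        imbalance_ratio(1.5, 0.5)


def test_imbalance_ratio_reciprocal_symmetry(rng):
    for _ in range(100):
        a, b = rng.uniform(0.01, 1.0), rng.uniform(0.01, 1.0)
        ra, _ = imbalance_ratio(a, b)
        rb, _ = imbalance_ratio(b, a)
        assert ra == pytest.approx(1.0 / rb)


def test_toy_vcf_screen_funnel_hand_computed(toy_vcf_path):
    """12 crafted records: 8 pass the variant filters, 6 carry a flag."""
    design = {"high_pool": "high", "low_pool": "low"}
    snps, tally = read_vcf_pooled(toy_vcf_path, design)
    assert tally["snps"] == 12
    records = [
        flag_imbalance(allele_frequencies(s), "high", "low") for s in snps
    ]
    n_pass = sum(r.passes for r in records)
    n_flagged = sum(r.passes and r.flag != FLAG_NONE for r in records)
    assert n_pass == 8
    assert n_flagged == 6
    by_id = {r.snp_id: r for r in records}
    assert by_id["toy05"].flag == FLAG_AMPLIFICATION  # ratio exactly 2.0
    assert by_id["toy06"].flag == FLAG_LOH  # ratio exactly 0.5
    assert by_id["toy11"].flag == FLAG_LOH  # zero numerator
    assert by_id["toy12"].flag == FLAG_AMPLIFICATION  # zero denominator
    assert by_id["toy12"].ratio_repr == "0.5/0"


def test_screen_candidates_requires_both_conditions(small_bundle, rng):
    from mirqtl import synthetic
    from mirqtl.snpimpact import classify_snp

    utrs = {u.gene_id: u for u in small_bundle.utr_set}
    freq = {}
    for s in small_bundle.planted_snps:
        if s.intended_class == CLASS_NONE:
            freq[s.snp_id] = {"high": 0.4, "low": 0.4}
        else:
            freq[s.snp_id] = {"high": 0.7, "low": 0.1}
    snps = synthetic.simulate_pooled_alleles(
        small_bundle.planted_snps, freq, depth_range=(2000, 2000), rng_seed=rng
    )
    impacts, records = [], []
    for snp in snps:
        impacts.extend(classify_snp(snp, utrs[snp.gene_id], small_bundle.mirna_set))
        records.append(flag_imbalance(allele_frequencies(snp), "high", "low"))
    table, summary = screen_candidates(impacts, records)
    truth_effect = {
        s.snp_id for s in small_bundle.planted_snps if s.intended_class != CLASS_NONE
    }
    got = set(table[table["is_candidate"]]["snp_id"])
    assert got == truth_effect  # all planted, no spurious neutrals
    assert summary["n_candidates"] == len(truth_effect)
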