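"""Hard-filter semantics: depth/VAF/strand/parental, masks, AF, binomial."""

import math

import pytest

from macdnm.calling import (
    DNMCandidate,
    FilterThresholds,
    GenomeMask,
    SampleEvidence,
    TrioEvidence,
    binomial_fdr_filter,
    evaluate_site_filters,
    popfreq_filter,
    region_mask_filter,
)


def make_candidate(
    chrom="chr1",
    child=(40, 20, 10, 10),  # dp, ref, alt_fwd, alt_rev
    mother=(40, 40, 0),
    father=(40, 40, 0),
    sex="F",
    af=None,
    cand_id="c1",
    child_id="childA",
):
    c_dp, c_ref, c_fwd, c_rev = child
    trio = TrioEvidence(
        chrom=chrom, pos=1000, ref="A", alt="G",
        child=SampleEvidence(c_dp, c_ref, c_fwd + c_rev, c_fwd, c_rev),
        mother=SampleEvidence(mother[0], mother[1], mother[2], mother[2], 0),
        father=SampleEvidence(father[0], father[1], father[2], father[2], 0),
        child_sex=sex,
        population_af=af,
    )
    return DNMCandidate(evidence=trio, id=cand_id, child_id=child_id)


class TestSiteFilters:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            # clean de novo: depth 40, VAF 0.5, balanced strands, quiet parents
            (dict(), "pass"),
            # child depth below the callable window
            (dict(child=(3, 1, 1, 1)), "fail:depth"),
            # a parent outside the depth window also fails the site
            (dict(mother=(2, 2, 0)), "fail:depth"),
            (dict(father=(90, 90, 0)), "fail:depth"),
            # autosomal VAF 0.30 at depth 40
            (dict(child=(40, 28, 6, 6)), "fail:vaf"),
            # VAF bounds are inclusive: exactly 0.35 and 0.70 pass
            (dict(child=(40, 26, 7, 7)), "pass"),
            (dict(child=(40, 12, 14, 14)), "pass"),
            # VAF above 0.70 on an autosome
            (dict(child=(40, 8, 16, 16)), "fail:vaf"),
            # male X with VAF 0.95 passes the VAF stage
            (dict(chrom="chrX", sex="M", child=(40, 2, 19, 19)), "pass"),
            # male X with het-like VAF fails
            (dict(chrom="chrX", sex="M", child=(40, 20, 10, 10)), "fail:vaf"),
            # female X uses the autosomal window
            (dict(chrom="chrX", sex="F", child=(40, 20, 10, 10)), "pass"),
            # Y-chromosome sites are excluded outright
            (dict(chrom="chrY", sex="M"), "fail:vaf"),
            # 3 alt reads (VAF in bounds) but all on the forward strand
            (dict(child=(8, 5, 3, 0)), "fail:strand"),
            # a single alt read split is impossible; one per strand passes
            (dict(child=(40, 38, 1, 1)), "fail:vaf"),
            # father with 2 alt reads
            (dict(father=(30, 28, 2)), "fail:parental"),
            # parent VAF above 10% with a single alt read
            (dict(mother=(8, 7, 1)), "fail:parental"),
            # parent with exactly one alt read and low VAF is tolerated
            (dict(father=(30, 29, 1)), "pass"),
        ],
    )
    def test_verdicts(self, kwargs, expected):
        assert evaluate_site_filters(make_candidate(**kwargs)) == expected

    def test_unknown_chromosome_raises(self):
        with pytest.raises(ValueError, match="chromosome"):
            evaluate_site_filters(make_candidate(chrom="scaffold_7"))

    def test_missing_sex_on_x_raises(self):
        with pytest.raises(ValueError, match="sex"):
            evaluate_site_filters(make_candidate(chrom="chrX", sex=None))


class TestRegionMasks:
    def test_containment_and_half_open_boundary(self):
        mask = [("chr1", 100, 200)]
        inside = make_candidate()
        inside.evidence.pos = 150  # 1-based 150 -> 0-based 149 in [100,200)
        boundary = make_candidate(cand_id="c2")
        boundary.evidence.pos = 201  # 0-based 200 is outside [100,200)
        start = make_candidate(cand_id="c3")
        start.evidence.pos = 101  # 0-based 100 is the first masked base
        survivors, counts = region_mask_filter([inside, boundary, start], mask, None)
        assert [c.id for c in survivors] == ["c2"]
        assert counts == {"repeat_mask": 2, "segdup_mask": 0}

    def test_masks_counted_separately_repeats_first(self):
        both = make_candidate()
        both.evidence.pos = 150
        survivors, counts = region_mask_filter(
            [both], [("chr1", 100, 200)], [("chr1", 140, 160)]
        )
        assert survivors == []
        # site in both masks attributes to the repeat mask (applied first)
        assert counts == {"repeat_mask": 1, "segdup_mask": 0}

    def test_empty_masks_are_identity(self):
        cands = [make_candidate(cand_id=f"c{i}") for i in range(3)]
        survivors, counts = region_mask_filter(cands, None, None)
        assert survivors == cands
        assert sum(counts.values()) == 0

    def test_genome_mask_rejects_inverted_interval(self):
        with pytest.raises(ValueError):
            GenomeMask([("chr1", 200, 100)])


class TestPopFreqFilter:
    def test_common_variant_removed(self):
        survivors, removed = popfreq_filter([make_candidate(af=0.02)])
        assert survivors == [] and removed == 1

    def test_threshold_is_strict(self):
        survivors, removed = popfreq_filter([make_candidate(af=0.01)])
        assert len(survivors) == 1 and removed == 0

    def test_novel_allele_kept(self):
        survivors, removed = popfreq_filter([make_candidate(af=None)])
        assert len(survivors) == 1 and removed == 0

    def test_invalid_af_raises(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            popfreq_filter([make_candidate(af=1.5)])


class TestBinomialFdr:
    def test_balanced_site_kept_with_p_one(self):
        cand = make_candidate(child=(40, 20, 10, 10))
        survivors, removed = binomial_fdr_filter([cand])
        assert removed == 0
        assert cand.binomial_p == pytest.approx(1.0)

    def test_skewed_site_removed_with_exact_tail_p(self):
        # independent oracle: doubled lower tail of Binomial(40, 1/2)
        tail = sum(math.comb(40, k) for k in range(6)) / 2**40
        expected_p = 2 * tail
        cand = make_candidate(child=(40, 35, 3, 2))
        survivors, removed = binomial_fdr_filter([cand])
        assert removed == 1 and survivors == []
        assert cand.binomial_p == pytest.approx(expected_p, rel=1e-9)
        assert cand.binomial_p == pytest.approx(1.38e-6, rel=5e-3)

    def test_all_balanced_none_removed(self):
        cands = [
            make_candidate(child=(40, 20, 10, 10), cand_id=f"c{i}")
            for i in range(10)
        ]
        survivors, removed = binomial_fdr_filter(cands)
        assert removed == 0 and len(survivors) == 10

    def test_adjustment_grouped_per_offspring(self):
        # one extreme site among many balanced ones, in two offspring:
        # BH within each child leaves the extreme site's adjusted p small
        cands = [
            make_candidate(child=(40, 20, 10, 10), cand_id=f"a{i}", child_id="A")
            for i in range(5)
        ]
        skew = make_candidate(child=(40, 35, 3, 2), cand_id="skew", child_id="B")
        survivors, removed = binomial_fdr_filter(cands + [skew])
        assert removed == 1
        assert all(c.child_id == "A" for c in survivors)

    def test_zero_depth_raises(self):
        cand = make_candidate(child=(40, 20, 10, 10))
        cand.evidence.child = SampleEvidence(0, 0, 0, 0, 0)
        with pytest.raises(ValueError):
            binomial_fdr_filter([cand])
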