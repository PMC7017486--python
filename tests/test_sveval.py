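"""SV benchmarking: normalization, matching rules, genotype merging,
PR curves, region filtering."""
import numpy as np
import pytest

from snarlcall.dna import revcomp
from snarlcall import sveval as sv
from snarlcall.sveval import (EvalOptions, SVRecord, classify_inversion,
                              evaluate, filter_regions, match_insertions,
                              match_overlap, max_f1, merge_for_genotype_eval,
                              normalize, pr_curve)
from snarlcall.vcfio import VcfVariant

from conftest import random_sequence


def rec(start, end, svtype="DEL", seq="", gt=sv.HET, qual=10.0, contig="c"):
    return SVRecord(contig, start, end, svtype, alt_sequence=seq,
                    genotype=gt, quality=qual)


class TestNormalize:
    def test_right_trim_identifies_deletion(self):
        out = normalize([VcfVariant("c", 100, "v", "ATTT", ("AT",), {})])
        (r,) = out
        assert r.svtype == sv.DEL and r.size == 2
        # right-trim removes the shared T, left-trim the padding A
        assert (r.start, r.end) == (100, 102)

    def test_multiallelic_split(self):
        out = normalize([VcfVariant("c", 100, "v", "A", ("G", "ATTT"), {})])
        assert len(out) == 2
        assert {r.svtype for r in out} >= {sv.INS}
        ins = next(r for r in out if r.svtype == sv.INS)
        assert ins.size == 3

    def test_symbolic_deletion_from_end(self):
        out = normalize([VcfVariant("c", 1000, "v", "N", ("<DEL>",),
                                    {"END": 1200, "SVTYPE": "DEL"})])
        (r,) = out
        assert r.svtype == sv.DEL and r.size == 200

    def test_symbolic_insertion_without_sequence_excluded(self):
        out = normalize([VcfVariant("c", 1000, "v", "N", ("<INS>",),
                                    {"SVLEN": 300})])
        assert out == []

    def test_explicit_inversion_classified(self):
        rng = np.random.default_rng(0)
        seg = random_sequence(rng, 120)
        out = normalize([VcfVariant("c", 100, "v", "A" + seg,
                                    ("A" + revcomp(seg),), {})])
        (r,) = out
        assert r.svtype == sv.INV

    def test_sample_genotypes_and_ref_drop(self):
        recs = [VcfVariant("c", 100, "a", "ATTTTTT", ("A",), {},
                           samples={"s": {"GT": (0, 1)}}),
                VcfVariant("c", 300, "b", "ATTTTTT", ("A",), {},
                           samples={"s": {"GT": (0, 0)}}),
                VcfVariant("c", 500, "d", "ATTTTTT", ("A",), {},
                           samples={"s": {"GT": (1, 1)}})]
        out = normalize(recs, sample="s")
        assert [(r.source_id, r.genotype) for r in out] == \
            [("a", sv.HET), ("d", sv.HOM_ALT)]


class TestClassifyInversion:
    def test_exact_revcomp_is_inversion(self):
        rng = np.random.default_rng(1)
        seg = random_sequence(rng, 100)
        assert classify_inversion(seg, revcomp(seg))

    def test_unrelated_sequences_are_not(self):
        rng = np.random.default_rng(2)
        assert not classify_inversion(random_sequence(rng, 100),
                                      random_sequence(rng, 100))

    def test_short_sequences_gated(self):
        seg = "ACGTACGT"  # 8 bp <= 10 bp gate
        assert not classify_inversion(seg, revcomp(seg))


class TestMatchOverlap:
    def test_simple_covered_pair(self):
        (p,) = match_overlap([rec(100, 200)], [rec(105, 195)])
        assert p == pytest.approx(0.90)

    def test_low_reciprocal_overlap_not_candidate(self):
        (p,) = match_overlap([rec(100, 200)], [rec(195, 400)])
        assert p == 0.0  # RO = 5/300 < 0.10

    def test_union_of_fragmented_partners(self):
        (p,) = match_overlap([rec(0, 1000)], [rec(0, 400), rec(450, 1000)])
        assert p == pytest.approx(0.95)

    @pytest.mark.parametrize("seed", range(5))
    def test_union_coverage_matches_per_base_count(self, seed):
        rng = np.random.default_rng(seed)
        records = [rec(int(s), int(s) + int(l))
                   for s, l in zip(rng.integers(0, 5000, 40),
                                   rng.integers(50, 400, 40))]
        others = [rec(int(s), int(s) + int(l))
                  for s, l in zip(rng.integers(0, 5000, 40),
                                  rng.integers(50, 400, 40))]
        opts = EvalOptions()
        props = match_overlap(records, others, opts)
        for r, p in zip(records, props):
            mask = np.zeros(r.size, dtype=bool)
            for o in others:
                inter = min(r.end, o.end) - max(r.start, o.start)
                ro = inter / max(r.size, o.size)
                if inter > 0 and ro >= opts.min_ro:
                    lo = max(r.start, o.start) - r.start
                    hi = min(r.end, o.end) - r.start
                    mask[lo:hi] = True
            assert p == pytest.approx(mask.mean())

    def test_coverage_is_symmetric(self):
        a, b = rec(100, 200), rec(110, 220)
        (p_ab,) = match_overlap([a], [b])
        (p_ab2,) = match_overlap([a], [b])
        assert p_ab == p_ab2  # same record, roles unchanged -> identical
        # swapped roles compute the mirrored proportion on the other record
        (p_ba,) = match_overlap([b], [a])
        assert p_ab * a.size == pytest.approx(p_ba * b.size)


class TestMatchInsertions:
    def test_identical_sequences_nearby_are_covered(self):
        rng = np.random.default_rng(3)
        seq = random_sequence(rng, 100)
        (p,) = match_insertions([rec(100, 100, sv.INS, seq)],
                                [rec(115, 115, sv.INS, seq)])
        assert p == pytest.approx(1.0)

    def test_gap_over_20bp_is_no_candidate(self):
        rng = np.random.default_rng(4)
        seq = random_sequence(rng, 100)
        (p,) = match_insertions([rec(100, 100, sv.INS, seq)],
                                [rec(125, 125, sv.INS, seq)])
        assert p == 0.0

    def test_asymmetric_sizes_cover_only_the_smaller(self):
        rng = np.random.default_rng(5)
        block = random_sequence(rng, 100)
        big = random_sequence(rng, 100) + block + random_sequence(rng, 100)
        small = rec(100, 100, sv.INS, block)
        large = rec(110, 110, sv.INS, big)
        (p_small,) = match_insertions([small], [large])
        (p_large,) = match_insertions([large], [small])
        assert p_small == pytest.approx(1.0, abs=0.02)
        assert p_large < 0.5


class TestGenotypeMerge:
    def test_chain_merge_of_nearby_hets(self):
        out = merge_for_genotype_eval([rec(100, 200), rec(210, 300)])
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (100, 300)
        assert out[0].genotype == sv.HET

    def test_duplicate_hets_collapse_to_hom(self):
        out = merge_for_genotype_eval([rec(100, 200), rec(100, 200)])
        assert len(out) == 1
        assert out[0].genotype == sv.HOM_ALT

    def test_distant_hets_unchanged(self):
        out = merge_for_genotype_eval([rec(100, 200), rec(400, 500)])
        assert len(out) == 2
        assert all(r.genotype == sv.HET for r in out)


class TestEvaluate:
    def _random_set(self, rng, n=30):
        out = []
        pos = 100
        for _ in range(n):
            svtype = rng.choice([sv.DEL, sv.INS, sv.INV])
            size = int(rng.integers(50, 500))
            if svtype == sv.INS:
                out.append(rec(pos, pos, sv.INS, random_sequence(rng, size)))
            else:
                out.append(rec(pos, pos + size, svtype))
            pos += size + int(rng.integers(100, 300))
        return out

    @pytest.mark.parametrize("seed", range(3))
    def test_self_comparison_is_perfect(self, seed):
        rng = np.random.default_rng(seed)
        records = self._random_set(rng)
        res = evaluate(records, records)
        assert res["ALL"].precision == 1.0
        assert res["ALL"].recall == 1.0
        assert res["ALL"].f1 == 1.0

    def test_empty_calls_give_defined_zero_metrics(self):
        truth = [rec(100, 300)]
        res = evaluate([], truth)
        assert res["DEL"].precision == 0.0 and res["DEL"].recall == 0.0

    def test_min_size_counts_only_50bp_and_larger(self):
        calls = [rec(100, 149), rec(1000, 1050)]
        truth = [rec(100, 149), rec(1000, 1050)]
        res = evaluate(calls, truth)
        assert res["DEL"].tp_call == 1  # the 49 bp pair matches but isn't counted
        assert res["DEL"].fp == 0 and res["DEL"].fn == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_breakpoint_jitter_keeps_all_tps(self, seed):
        rng = np.random.default_rng(10 + seed)
        truth = []
        pos = 1000
        for size in (50, 120, 500, 2000, 10000):
            truth.append(rec(pos, pos + size))
            pos += size + 2000
        calls = []
        for t in truth:
            shift = int(rng.integers(0, max(1, t.size // 20)))  # <= 5% of length
            calls.append(rec(t.start + shift, t.end + shift))
        res = evaluate(calls, truth)
        assert res["DEL"].fn == 0 and res["DEL"].fp == 0

    def test_genotype_mode_scores_strata_separately(self):
        truth = [rec(100, 300, gt=sv.HOM_ALT), rec(1000, 1200, gt=sv.HET)]
        calls_right = [rec(100, 300, gt=sv.HOM_ALT), rec(1000, 1200, gt=sv.HET)]
        calls_wrong = [rec(100, 300, gt=sv.HET), rec(1000, 1200, gt=sv.HOM_ALT)]
        opts = EvalOptions(genotype_mode=True)
        assert evaluate(calls_right, truth, opts)["DEL"].f1 == 1.0
        assert evaluate(calls_wrong, truth, opts)["DEL"].f1 == 0.0

    def test_min_coverage_sensitivity_flag(self):
        # one call covering 60% of the truth record: covered at the 0.5
        # threshold, not at the 0.9 replication threshold
        calls = [rec(100, 160)]
        truth = [rec(100, 200)]
        loose = evaluate(calls, truth, EvalOptions(min_coverage=0.5))
        strict = evaluate(calls, truth, EvalOptions(min_coverage=0.9))
        assert loose["DEL"].tp_truth == 1
        assert strict["DEL"].tp_truth == 0


class TestPrCurve:
    def _sets(self, rng):
        truth = [rec(i * 1000, i * 1000 + 200, qual=0) for i in range(10)]
        calls = [rec(i * 1000, i * 1000 + 200, qual=float(rng.integers(1, 40)))
                 for i in range(7)]
        calls += [rec(50_000 + i * 1000, 50_200 + i * 1000, svtype=sv.DEL,
                      qual=float(rng.integers(1, 40))) for i in range(4)]  # FPs
        return calls, truth

    def test_recall_never_increases_with_threshold(self):
        rng = np.random.default_rng(7)
        calls, truth = self._sets(rng)
        curve = pr_curve(calls, truth)["DEL"]
        recalls = [r for _, _, r, _ in curve]
        assert recalls == sorted(recalls, reverse=True)

    def test_max_f1_matches_brute_force(self):
        rng = np.random.default_rng(8)
        calls, truth = self._sets(rng)
        curve = pr_curve(calls, truth)["DEL"]
        brute = max(evaluate([c for c in calls if c.quality >= thr],
                             truth)["DEL"].f1
                    for thr in sorted({0.0} | {c.quality for c in calls}))
        assert max_f1(curve) == pytest.approx(brute)

    def test_all_correct_calls_give_unit_precision_everywhere(self):
        truth = [rec(i * 1000, i * 1000 + 200) for i in range(5)]
        calls = [rec(i * 1000, i * 1000 + 200, qual=10.0) for i in range(5)]
        curve = pr_curve(calls, truth)["DEL"]
        assert all(p == 1.0 for _, p, _, _ in curve)


def test_evaluation_invariant_under_bcftools_normalization(tmp_path):
    """Re-normalizing one side with bcftools norm (split multi-allelics,
    realign alleles against the reference) must not change the matching:
    the two representations of the same variants still evaluate as
    identical sets."""
    import subprocess
    from snarlcall.simdata import SimConfig, generate_truth_set
    from snarlcall.vcfio import read_vcf, write_fasta, write_vcf

    ts = generate_truth_set(SimConfig(n_per_type=8, n_samples=1, seed=21))
    contig = next(iter(ts.genome))
    fa, vcf, out = tmp_path / "g.fa", tmp_path / "t.vcf", tmp_path / "n.vcf"
    write_fasta(fa, ts.genome)
    write_vcf(vcf, ts.truth, {contig: len(ts.genome[contig])}, ts.samples)
    subprocess.run(["samtools", "faidx", str(fa)], check=True)
    subprocess.run(["bcftools", "norm", "-f", str(fa), "-m", "-any",
                    "-o", str(out), str(vcf)],
                   check=True, capture_output=True)
    original = normalize(ts.truth, ts.genome, sample="s0")
    renormed = normalize(read_vcf(str(out)), ts.genome, sample="s0")
    res = evaluate(renormed, original)
    assert res["ALL"].fp == 0 and res["ALL"].fn == 0
    assert res["ALL"].precision == 1.0 and res["ALL"].recall == 1.0


class TestFilterRegions:
    REGIONS = [("c", 0, 1000), ("c", 5000, 9000)]

    def test_contained_deletion_kept(self):
        assert filter_regions([rec(100, 300)], self.REGIONS)

    def test_insertion_point_outside_dropped(self):
        assert not filter_regions([rec(2000, 2000, sv.INS, "A" * 60)],
                                  self.REGIONS)

    def test_straddling_record_kept_at_60_percent_inside(self):
        # [700, 1200): 300 of 500 bases inside [0, 1000)
        assert filter_regions([rec(700, 1200)], self.REGIONS)
        # [900, 1900): only 100 of 1000 inside
        assert not filter_regions([rec(900, 1900)], self.REGIONS)
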