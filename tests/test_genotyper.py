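"""Traversal enumeration, support averaging, and the calling rules."""
import numpy as np
import pytest

from snarlcall.genotyper import (CallerParams, Traversal, call_zygosity,
                                 enumerate_traversals, genotype_graph,
                                 genotype_snarl, traversal_support)
from snarlcall.graphmodel import GraphConfig, build_graph
from snarlcall.mapsupport import GraphIndex, PackIndex, compute_pack, map_read
from snarlcall.snarls import find_snarls, top_level_reference_snarls
from snarlcall.vcfio import VcfVariant

from conftest import random_sequence


def _top_snarls(g):
    return top_level_reference_snarls(g, find_snarls(g))


def _two_variant_graph():
    """Two overlapping deletions sharing one snarl."""
    rng = np.random.default_rng(1)
    genome = random_sequence(rng, 400)
    recs = [VcfVariant("c", 100, "a", genome[99:160], (genome[99],), {}),
            VcfVariant("c", 130, "b", genome[129:200], (genome[129],), {})]
    return build_graph({"c": genome}, recs), genome, recs


class TestEnumerateTraversals:
    def test_two_biallelic_variants_give_four_candidates(self):
        g, _, _ = _two_variant_graph()
        (snarl,) = _top_snarls(g)
        assert sorted(snarl.contained_variant_ids) == ["a", "b"]
        ts = enumerate_traversals(g, snarl, None)
        # 2x2 combinations; the del+del combination is edge-inconsistent
        # (the second deletion starts inside the first) and is dropped
        assignments = {tuple(sorted(t.allele_assignment.items())) for t in ts}
        assert (("a", 0), ("b", 0)) in assignments
        assert (("a", 1), ("b", 0)) in assignments
        assert (("a", 0), ("b", 1)) in assignments
        assert len(ts) == 3

    def test_triallelic_variant_gives_three(self):
        rng = np.random.default_rng(2)
        genome = random_sequence(rng, 300)
        rec = VcfVariant("c", 100, "m", genome[99:150],
                         (genome[99], genome[99] + "ACGTACGT"), {})
        g = build_graph({"c": genome}, [rec])
        (snarl,) = _top_snarls(g)
        assert len(enumerate_traversals(g, snarl, None)) == 3

    def test_prefilter_drops_unsupported_alleles(self):
        # 20 mutually overlapping biallelic deletions share one snarl:
        # 2^20 > max_traversals triggers the support prefilter; with zero
        # alt support only the reference traversal remains
        rng = np.random.default_rng(3)
        genome = random_sequence(rng, 600)
        recs = []
        for i in range(20):
            pos = 100 + 2 * i
            recs.append(VcfVariant("c", pos, f"s{i}",
                                   genome[pos - 1:pos + 300], (genome[pos - 1],),
                                   {}))
        g = build_graph({"c": genome}, recs)
        snarls = _top_snarls(g)
        snarl = max(snarls, key=lambda s: len(s.contained_variant_ids))
        assert len(snarl.contained_variant_ids) == 20
        pack = PackIndex(g)  # all-zero support
        params = CallerParams(max_traversals=500_000)
        ts = enumerate_traversals(g, snarl, pack, params)
        assert len(ts) == 1
        assert all(a == 0 for a in ts[0].allele_assignment.values())


class TestTraversalSupport:
    @pytest.fixture
    def supported_graph(self):
        g, genome, recs = _two_variant_graph()
        pack = PackIndex(g)
        return g, pack

    def _walk(self, g, snarl, allele):
        ts = enumerate_traversals(g, snarl, None)
        return next(t for t in ts
                    if set(t.allele_assignment.values()) == {allele})

    def test_uniform_support_averages_exactly(self, supported_graph):
        g, pack = supported_graph
        (snarl,) = _top_snarls(g)
        t = self._walk(g, snarl, 0)
        for nid in t.interior_node_ids():
            pack.node_base_coverage[nid][:] = 10
        for e in t.edges():
            pack.edge_coverage[e] = 10
        assert traversal_support(pack, t).average_support == pytest.approx(10.0)

    def test_pure_deletion_averages_over_edges_only(self):
        rng = np.random.default_rng(4)
        genome = random_sequence(rng, 300)
        rec = VcfVariant("c", 100, "d", genome[99:180], (genome[99],), {})
        g = build_graph({"c": genome}, [rec])
        (snarl,) = _top_snarls(g)
        ts = enumerate_traversals(g, snarl, None)
        deletion = next(t for t in ts if 1 in t.allele_assignment.values())
        pack = PackIndex(g)
        (edge,) = deletion.edges()
        pack.edge_coverage[edge] = 7
        summ = traversal_support(pack, deletion)
        assert summ.n_bases == 0
        assert summ.average_support == pytest.approx(7.0)

    def test_mixed_bases_and_edges_average(self):
        # bases {8,8,8,8} and edges {4,4} -> 40/6
        rng = np.random.default_rng(5)
        genome = random_sequence(rng, 200)
        rec = VcfVariant("c", 50, "i", genome[49], (genome[49] + "ACGT",), {})
        g = build_graph({"c": genome}, [rec])
        (snarl,) = _top_snarls(g)
        ts = enumerate_traversals(g, snarl, None)
        ins = next(t for t in ts if 1 in t.allele_assignment.values())
        pack = PackIndex(g)
        (nid,) = ins.interior_node_ids()
        pack.node_base_coverage[nid][:] = 8
        for e in ins.edges():
            pack.edge_coverage[e] = 4
        assert traversal_support(pack, ins).average_support == \
            pytest.approx((8 * 4 + 4 * 2) / 6)


class TestCallingRules:
    @pytest.mark.parametrize("best,second,expected", [
        (30.0, 2.0, "hom"),      # 30 > 6*2: strong bias, homozygous
        (14.0, 11.0, "het"),     # ratio < 6, runner-up supported
        (0.5, 0.2, "nocall"),    # below min support
        (3.0, 0.4, "hom"),       # runner-up below min support, ratio > 6
        (2.0, 0.5, "hom"),       # ratio <= 6 but only one supported haplotype
    ])
    def test_rule_examples(self, best, second, expected):
        assert call_zygosity(best, second) == expected

    def test_exhaustive_grid_matches_printed_rules(self):
        params = CallerParams()
        grid = [0.0, 0.2, 0.5, 0.999, 1.0, 1.001, 1.5, 2.0, 5.0,
                5.999, 6.0, 6.006, 7.0, 11.99, 12.0, 12.01, 30.0, 100.0]
        for best in grid:
            for second in grid + [None]:
                if second is not None and second > best:
                    continue
                got = call_zygosity(best, second, params)
                s2 = 0.0 if second is None else second
                if best > 1.0 and (second is None or best > 6.0 * s2):
                    want = "hom"
                elif s2 > 1.0:
                    want = "het"
                elif best > 1.0:
                    want = "hom"
                else:
                    want = "nocall"
                assert got == want, (best, second)

    def test_min_support_boundary_is_strict(self):
        assert call_zygosity(1.0, 0.0) == "nocall"
        assert call_zygosity(1.0 + 1e-9, 0.0) == "hom"

    def test_bias_boundary_is_strict(self):
        # best exactly B*second is NOT homozygous by rule 1
        assert call_zygosity(12.0, 2.0) == "het"
        assert call_zygosity(12.1, 2.0) == "hom"

    def test_monotonicity_hom_never_flips_to_het_with_more_support(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            second = float(rng.uniform(0, 5))
            best = float(rng.uniform(second, 40))
            if call_zygosity(best, second) == "hom":
                assert call_zygosity(best + float(rng.uniform(0, 20)),
                                     second) == "hom"


@pytest.fixture(scope="module")
def small_pipeline():
    rng = np.random.default_rng(8)
    genome = random_sequence(rng, 6000)
    recs = [
        VcfVariant("c", 1000, "del", genome[999:1150], (genome[999],),
                   {"SVTYPE": "DEL", "END": 1150}),
        VcfVariant("c", 2500, "ins", genome[2499],
                   (genome[2499] + random_sequence(rng, 120),),
                   {"SVTYPE": "INS", "END": 2500}),
        VcfVariant("c", 4000, "del2", genome[3999:4100], (genome[3999],),
                   {"SVTYPE": "DEL", "END": 4100}),
    ]
    g = build_graph({"c": genome}, recs, GraphConfig(max_node_length=512))
    idx = GraphIndex(g)
    return g, idx, genome, recs


class TestEndToEnd:
    def _reads_from(self, seq, rng, depth=15, rl=150):
        n = depth * len(seq) // rl
        return [seq[p:p + rl] for p in rng.integers(0, len(seq) - rl, n)]

    @pytest.mark.parametrize("genotypes,expected_gts", [
        ({"del": (1, 1), "ins": (0, 1), "del2": (0, 0)},
         {"del": (1, 1), "ins": (0, 1), "del2": (0, 0)}),
    ])
    def test_genotypes_recovered_from_simulated_reads(
            self, small_pipeline, genotypes, expected_gts):
        g, idx, genome, recs = small_pipeline
        rng = np.random.default_rng(9)
        haps = []
        for h in (0, 1):
            seq = []
            cursor = 0
            for rec in recs:
                if genotypes[rec.vid][h] != 1:
                    continue
                start, end = rec.pos, int(rec.info["END"])
                seq.append(genome[cursor:start])
                if rec.info["SVTYPE"] == "INS":
                    seq.append(rec.alts[0][1:])
                cursor = end
            seq.append(genome[cursor:])
            haps.append("".join(seq))
        alns = [map_read(g, idx, f"r{i}", r)
                for h in haps for i, r in enumerate(self._reads_from(h, rng))]
        pack = compute_pack(g, alns)
        out = genotype_graph(g, pack, recs, sample_name="S")
        got = {rec.vid: tuple(sorted(rec.samples["S"]["GT"])) for rec in out}
        assert got == {k: tuple(sorted(v)) for k, v in expected_gts.items()}

    def test_empty_pack_yields_no_calls(self, small_pipeline):
        g, _, _, recs = small_pipeline
        out = genotype_graph(g, PackIndex(g), recs, sample_name="S")
        assert all(rec.samples["S"]["GT"] == (None, None) for rec in out)

    def test_deterministic_output(self, small_pipeline):
        g, idx, genome, recs = small_pipeline
        rng = np.random.default_rng(10)
        alns = [map_read(g, idx, f"r{i}", genome[p:p + 150])
                for i, p in enumerate(rng.integers(0, 5800, 200))]
        pack = compute_pack(g, alns)
        a = genotype_graph(g, pack, recs, sample_name="S")
        b = genotype_graph(g, pack, recs, sample_name="S")
        assert [(r.vid, r.samples["S"]) for r in a] == \
            [(r.vid, r.samples["S"]) for r in b]

    def test_multi_variant_snarl_gt_assignment(self):
        g, genome, recs = _two_variant_graph()
        (snarl,) = _top_snarls(g)
        pack = PackIndex(g)
        ts = enumerate_traversals(g, snarl, None)
        # support the (a=1, b=0) traversal and the reference traversal
        alt = next(t for t in ts if t.allele_assignment == {"a": 1, "b": 0})
        ref = next(t for t in ts if t.allele_assignment == {"a": 0, "b": 0})
        for t, c in ((alt, 12), (ref, 10)):
            for nid in t.interior_node_ids():
                pack.node_base_coverage[nid][:] += c
            for e in t.edges():
                pack.edge_coverage[e] += c
        call = genotype_snarl(g, snarl, pack)
        assert call.zygosity == "het"
        assert call.genotype == {"a": (0, 1), "b": (0, 0)}
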