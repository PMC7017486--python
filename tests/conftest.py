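import pytest

from snarlcall.dna import revcomp
from snarlcall.graphmodel import (LEFT, RIGHT, GraphConfig, Side, Step,
                                  VariationGraph, build_graph)
from snarlcall.vcfio import VcfVariant


@pytest.fixture
def bubble_graph():
    """A -> {B | C} -> D, single-node branches."""
    g = VariationGraph()
    for seq in ("AAAA", "CC", "GG", "TTTT"):
        g.add_node(seq)
    for a, ea, b, eb in ((1, RIGHT, 2, LEFT), (1, RIGHT, 3, LEFT),
                         (2, RIGHT, 4, LEFT), (3, RIGHT, 4, LEFT)):
        g.add_edge(Side(a, ea), Side(b, eb))
    return g


@pytest.fixture
def chained_bubble_graph():
    """Two bubbles in a row sharing the middle anchor."""
    g = VariationGraph()
    for seq in ("AAAA", "CC", "GG", "TTTT", "AT", "GC", "AAGG"):
        g.add_node(seq)
    for a, ea, b, eb in ((1, RIGHT, 2, LEFT), (1, RIGHT, 3, LEFT),
                         (2, RIGHT, 4, LEFT), (3, RIGHT, 4, LEFT),
                         (4, RIGHT, 5, LEFT), (4, RIGHT, 6, LEFT),
                         (5, RIGHT, 7, LEFT), (6, RIGHT, 7, LEFT)):
        g.add_edge(Side(a, ea), Side(b, eb))
    return g


def random_sequence(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def random_vcf_graph(rng, max_node_length=120):
    """A small VCF-derived graph (DEL/INS/INV/SNV mix, <= 10 variants,
    <= ~30 nodes) for exhaustive snarl testing."""
    L = int(rng.integers(250, 700))
    genome = random_sequence(rng, L)
    recs = []
    pos = int(rng.integers(2, 10))
    for i in range(int(rng.integers(1, 11))):
        kind = rng.choice(["DEL", "INS", "INV", "SNV"])
        size = int(rng.integers(2, 30))
        if pos + size + 3 >= L - 2:
            break
        pad = genome[pos - 1]
        if kind == "DEL":
            recs.append(VcfVariant("c", pos, f"v{i}",
                                   pad + genome[pos:pos + size], (pad,), {}))
            end = pos + size
        elif kind == "INS":
            ins = random_sequence(rng, size)
            recs.append(VcfVariant("c", pos, f"v{i}", pad, (pad + ins,), {}))
            end = pos
        elif kind == "INV":
            seg = genome[pos:pos + size]
            recs.append(VcfVariant("c", pos, f"v{i}", pad + seg,
                                   (pad + revcomp(seg),), {}))
            end = pos + size
        else:
            b = genome[pos]
            recs.append(VcfVariant("c", pos + 1, f"v{i}", b,
                                   ("A" if b != "A" else "G",), {}))
            end = pos + 1
        pos = end + int(rng.integers(2, 20))
        if pos >= L - 5:
            break
    g = build_graph({"c": genome}, recs,
                    GraphConfig(max_node_length=max_node_length))
    return g, genome, recs


@pytest.fixture
def del_graph():
    """10 bp contig with one 4 bp deletion starting at base 2 (0-based)."""
    genome = "ACGTACGTAC"
    rec = VcfVariant("chr", 2, "del1", genome[1:6], (genome[1],), {})
    return build_graph({"chr": genome}, [rec]), genome, rec
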