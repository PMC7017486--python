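"""Traversal-based genotyping of top-level reference snarls.

For each site the Cartesian product of allele choices over the VCF variants
contained in the snarl is rendered as walks from the snarl start to its end
(|v1|x...x|vk| candidate haplotypes; alleles with average support below a
threshold are pre-filtered when the product exceeds a cap). Each walk's
support is averaged over its node bases and edge counts from the pack
index, the two best-supported walks are selected, and the genotype follows
the support-ratio rules: a site is homozygous when the best walk exceeds
the minimum support and carries more than B times the support of the
runner-up, heterozygous when the runner-up also exceeds the minimum
support.

Support averaging masks out elements that every candidate walk shares
(including the boundary nodes): shared elements receive coverage from reads
of every allele and cannot discriminate between walks. For inversions --
which reuse the reference nodes in reverse orientation -- the genotype is
thereby decided by the breakpoint edges, the only elements that differ.
"""
from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .graphmodel import Step, VariationGraph, make_edge
from .mapsupport import PackIndex
from .snarls import Snarl, find_snarls, top_level_reference_snarls
from .vcfio import VcfVariant

log = logging.getLogger(__name__)


@dataclasses.dataclass
class CallerParams:
    min_support: float = 1.0
    bias_b: float = 6.0
    max_traversals: int = 500_000
    prefilter_support: float = 1.0

    def __post_init__(self):
        for name in ("min_support", "bias_b", "max_traversals", "prefilter_support"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclasses.dataclass
class Traversal:
    steps: List[Step]
    allele_assignment: Dict[str, int]

    def interior_node_ids(self) -> List[int]:
        return [s.node_id for s in self.steps[1:-1]]

    def edges(self) -> List:
        return [make_edge(a.exit_side, b.entry_side)
                for a, b in zip(self.steps[:-1], self.steps[1:])]


@dataclasses.dataclass
class SupportSummary:
    average_support: float
    n_bases: int
    n_edges: int


@dataclasses.dataclass
class GenotypeCall:
    snarl: Snarl
    best: Optional[Traversal]
    second: Optional[Traversal]
    genotype: Optional[Dict[str, Tuple[int, int]]]  # variant_id -> allele pair
    supports: Tuple[float, float]
    quality: int
    zygosity: str  # "hom" | "het" | "nocall"


def traversal_support(pack: PackIndex, traversal: Traversal,
                      include_nodes: Optional[Set[int]] = None,
                      include_edges: Optional[Set] = None) -> SupportSummary:
    """Average support of a walk over its interior node bases and edges.

    Snarl boundary nodes (the first and last steps) are excluded. A walk
    with no interior nodes (a pure deletion) is averaged over its edges
    only. ``include_nodes``/``include_edges`` optionally restrict the
    averaged elements (used for shared-element masking)."""
    total = 0.0
    n_bases = 0
    for nid in traversal.interior_node_ids():
        if include_nodes is not None and nid not in include_nodes:
            continue
        cov = pack.node_base_coverage[nid]
        total += float(cov.sum())
        n_bases += len(cov)
    n_edges = 0
    for edge in traversal.edges():
        if include_edges is not None and edge not in include_edges:
            continue
        total += pack.edge_coverage[edge]
        n_edges += 1
    denom = n_bases + n_edges
    avg = total / denom if denom else 0.0
    return SupportSummary(avg, n_bases, n_edges)


def _reference_chain(g: VariationGraph, snarl: Snarl) -> List[Step]:
    path = g.reference_path(snarl.contig)
    ids = [s.node_id for s in path.steps]
    i0 = ids.index(snarl.start.node_id)
    i1 = ids.index(snarl.end.node_id)
    if i0 > i1:
        i0, i1 = i1, i0
    return path.steps[i0:i1 + 1]


def enumerate_traversals(g: VariationGraph, snarl: Snarl, pack: Optional[PackIndex],
                         params: Optional[CallerParams] = None) -> List[Traversal]:
    """All allele-combination walks through a top-level reference snarl.

    When the combination count exceeds ``params.max_traversals``, alleles
    whose own walk has average support below ``prefilter_support`` are
    dropped per variant (the reference allele and the best-supported allele
    are always kept) before enumeration. Edge-inconsistent combinations of
    overlapping alleles are discarded.
    """
    params = params or CallerParams()
    annos = {va.variant_id: va for va in g.variants}
    contained = [annos[vid] for vid in snarl.contained_variant_ids]
    contained.sort(key=lambda va: va.span)
    if not contained:
        return []

    allele_choices: List[List[int]] = [list(range(len(va.alleles))) for va in contained]
    n_combo = math.prod(len(c) for c in allele_choices)
    if n_combo > params.max_traversals:
        if pack is None:
            raise ValueError("traversal prefilter requires a pack index")
        for vi, va in enumerate(contained):
            supports = []
            for ai in allele_choices[vi]:
                walk = Traversal(list(va.alleles[ai]), {})
                supports.append(traversal_support(pack, walk).average_support)
            best_ai = allele_choices[vi][max(range(len(supports)),
                                             key=lambda i: supports[i])]
            kept = [ai for ai, s in zip(allele_choices[vi], supports)
                    if s >= params.prefilter_support or ai == 0 or ai == best_ai]
            allele_choices[vi] = kept
        n_combo = math.prod(len(c) for c in allele_choices)
        if n_combo > params.max_traversals:
            log.warning("snarl %s-%s: %d traversals even after pre-filtering; "
                        "site skipped", snarl.start, snarl.end, n_combo)
            return []

    chain = _reference_chain(g, snarl)
    chain_index = {s.node_id: i for i, s in enumerate(chain)}
    out: List[Traversal] = []
    seen: Set[Tuple[Step, ...]] = set()
    for combo in itertools.product(*allele_choices):
        walk: List[Step] = []
        cursor = 0  # next chain index to emit
        ok = True
        for va, ai in zip(contained, combo):
            if ai == 0:
                continue  # reference allele: the chain flows through
            allele = va.alleles[ai]
            li = chain_index.get(allele[0].node_id)
            ri = chain_index.get(allele[-1].node_id)
            if li is None or ri is None or li < cursor:
                ok = False  # anchors outside the chain or overlapping splice
                break
            walk.extend(chain[cursor:li + 1])
            walk.extend(allele[1:-1])
            cursor = ri
        if not ok:
            continue
        walk.extend(chain[cursor:])
        if not _edges_consistent(g, walk):
            continue
        key = tuple(walk)
        if key in seen:
            continue
        seen.add(key)
        out.append(Traversal(walk, {va.variant_id: ai
                                    for va, ai in zip(contained, combo)}))
    return out


def _edges_consistent(g: VariationGraph, walk: Sequence[Step]) -> bool:
    return all(g.has_edge(a.exit_side, b.entry_side)
               for a, b in zip(walk[:-1], walk[1:]))


def call_zygosity(best: float, second: Optional[float],
                  params: Optional[CallerParams] = None) -> str:
    """The support-ratio calling rules, applied in order.

    1. best > min_support and best > B * second  -> homozygous (best)
    2. else second > min_support                 -> heterozygous
    3. else best > min_support                   -> homozygous (best is the
       only supported haplotype)
    4. else                                      -> no-call
    Comparisons are strict, exactly as the thresholds are defined.
    """
    params = params or CallerParams()
    s2 = second if second is not None else 0.0
    if best > params.min_support and (second is None or best > params.bias_b * s2):
        return "hom"
    if s2 > params.min_support:
        return "het"
    if best > params.min_support:
        return "hom"
    return "nocall"


def genotype_quality(best: float, second: float,
                     params: Optional[CallerParams] = None) -> int:
    """Phred-like confidence, monotone in total support and in the
    best/second ratio (heuristic; downstream evaluation only thresholds it)."""
    params = params or CallerParams()
    eps = 1e-9
    conf = (best + second) * min(1.0, best / (params.bias_b * second + eps))
    return int(round(10 * math.log10(conf + 1)))


def genotype_snarl(g: VariationGraph, snarl: Snarl, pack: PackIndex,
                   params: Optional[CallerParams] = None) -> GenotypeCall:
    params = params or CallerParams()
    traversals = enumerate_traversals(g, snarl, pack, params)
    if not traversals:
        return GenotypeCall(snarl, None, None, None, (0.0, 0.0), 0, "nocall")

    interior_sets = [set(t.interior_node_ids()) for t in traversals]
    edge_sets = [set(t.edges()) for t in traversals]
    shared_nodes = set.intersection(*interior_sets) if interior_sets else set()
    shared_edges = set.intersection(*edge_sets) if edge_sets else set()

    scored = []
    for t, nodes, edges in zip(traversals, interior_sets, edge_sets):
        info_nodes = nodes - shared_nodes
        info_edges = edges - shared_edges
        if info_nodes or info_edges:
            summ = traversal_support(pack, t, include_nodes=info_nodes,
                                     include_edges=info_edges)
        else:
            summ = traversal_support(pack, t)
        scored.append((t, summ.average_support))

    # deterministic tie-break: reference-first, then lexicographic alleles
    def allele_key(t: Traversal):
        return tuple(a for _, a in sorted(t.allele_assignment.items()))

    scored.sort(key=lambda ts: (-ts[1], allele_key(ts[0])))
    best_t, best_s = scored[0]
    second_t, second_s = scored[1] if len(scored) > 1 else (None, None)

    zyg = call_zygosity(best_s, second_s, params)
    if zyg == "nocall":
        return GenotypeCall(snarl, best_t, second_t, None,
                            (best_s, second_s or 0.0), 0, "nocall")
    genotype: Dict[str, Tuple[int, int]] = {}
    for vid, a_best in best_t.allele_assignment.items():
        if zyg == "het":
            pair = tuple(sorted((a_best, second_t.allele_assignment[vid])))
        else:
            pair = (a_best, a_best)
        genotype[vid] = pair
    q = genotype_quality(best_s, second_s or 0.0, params)
    return GenotypeCall(snarl, best_t, second_t, genotype,
                        (best_s, second_s or 0.0), q, zyg)


def calls_to_vcf(calls: Iterable[GenotypeCall], input_variants: Sequence[VcfVariant],
                 sample_name: str = "SAMPLE") -> List[VcfVariant]:
    """One output record per input record, with GT/DP/AD/GQ from the snarl
    calls; variants in skipped or uncalled snarls come out as ./. ."""
    by_variant: Dict[str, GenotypeCall] = {}
    for call in calls:
        if call.snarl.contained_variant_ids:
            for vid in call.snarl.contained_variant_ids:
                by_variant[vid] = call
    out = []
    for rec in input_variants:
        call = by_variant.get(rec.vid)
        n_alleles = 1 + len(rec.alts)
        sample: Dict = {"GT": (None, None)}
        qual = 0.0
        if call is not None and call.genotype is not None and rec.vid in call.genotype:
            gt = call.genotype[rec.vid]
            best_s, second_s = call.supports
            ad = [0] * n_alleles
            if call.best is not None:
                ad[call.best.allele_assignment[rec.vid]] += int(round(best_s))
            if call.zygosity == "het" and call.second is not None:
                ad[call.second.allele_assignment[rec.vid]] += int(round(second_s))
            sample = {"GT": gt, "DP": int(round(best_s + second_s)),
                      "AD": tuple(ad), "GQ": call.quality}
            qual = float(call.quality)
        out.append(VcfVariant(contig=rec.contig, pos=rec.pos, vid=rec.vid,
                              ref=rec.ref, alts=rec.alts,
                              info=dict(rec.info), qual=qual,
                              samples={sample_name: sample}))
    return out


def genotype_graph(g: VariationGraph, pack: PackIndex,
                   input_variants: Sequence[VcfVariant],
                   params: Optional[CallerParams] = None,
                   sample_name: str = "SAMPLE",
                   snarls: Optional[List[Snarl]] = None) -> List[VcfVariant]:
    """Driver: snarl detection -> top-level filter -> per-snarl genotyping
    -> VCF records. Deterministic given identical inputs."""
    params = params or CallerParams()
    if snarls is None:
        snarls = find_snarls(g)
    top = top_level_reference_snarls(g, snarls)
    calls = [genotype_snarl(g, sn, pack, params)
             for sn in top if sn.contained_variant_ids]
    return calls_to_vcf(calls, input_variants, sample_name)
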