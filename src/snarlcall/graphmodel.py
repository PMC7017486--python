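"""Bidirected variation-graph model and construction from reference + VCF.

The graph substrate for genotyping: nodes carry DNA sequence and have two
*sides* (left/right); edges join sides, so a walk may traverse a node in
forward or reverse orientation. Reference contigs are embedded as paths, and
every VCF record is embedded as a set of allele walks anchored on the
reference path (deletions become bypass edges, insertions new nodes,
inversions orientation-reversing edges that reuse the reference nodes).

Coordinates: VCF input is 1-based; everything internal is 0-based half-open.
"""
from __future__ import annotations

import dataclasses
import json
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Set, Tuple

from .dna import check_dna, revcomp
from .vcfio import VcfVariant

LEFT = 0
RIGHT = 1


class Side(NamedTuple):
    """One end of a node; ``opposite`` is the paper's x' notation."""

    node_id: int
    end: int  # LEFT or RIGHT

    @property
    def opposite(self) -> "Side":
        return Side(self.node_id, 1 - self.end)


class Edge(NamedTuple):
    """Unordered pair of sides; always stored in canonical (sorted) order."""

    a: Side
    b: Side


def make_edge(a: Side, b: Side) -> Edge:
    return Edge(a, b) if a <= b else Edge(b, a)


class Step(NamedTuple):
    node_id: int
    reverse: bool = False

    @property
    def entry_side(self) -> Side:
        """Side through which a walk enters the node when taking this step."""
        return Side(self.node_id, RIGHT if self.reverse else LEFT)

    @property
    def exit_side(self) -> Side:
        return Side(self.node_id, LEFT if self.reverse else RIGHT)


@dataclasses.dataclass
class Node:
    id: int
    sequence: str

    def __post_init__(self):
        if self.id <= 0:
            raise ValueError("node ids must be positive")
        check_dna(self.sequence, f"node {self.id}")

    def __len__(self):
        return len(self.sequence)


@dataclasses.dataclass
class Path:
    name: str
    steps: List[Step]
    is_reference: bool = False


@dataclasses.dataclass
class VariantAnnotation:
    """Allele walks for one VCF record, anchored on the reference path.

    ``alleles[i]`` is the full walk (anchor node, allele nodes/edges, anchor
    node) spelling flank + allele-i sequence + flank. ``span`` is the
    0-based half-open reference interval the record rewrites after trimming.
    """

    variant_id: str
    contig: str
    position: int  # original 1-based VCF position
    alleles: List[List[Step]]
    span: Tuple[int, int]
    ref_allele_index: int = 0


class GraphValidationError(ValueError):
    pass


@dataclasses.dataclass
class GraphConfig:
    max_node_length: int = 1024

    def __post_init__(self):
        if self.max_node_length < 1:
            raise ValueError("max_node_length must be >= 1")


class VariationGraph:
    """Bidirected sequence graph with embedded reference and allele paths."""

    def __init__(self) -> None:
        self.nodes: Dict[int, Node] = {}
        self.edges: Set[Edge] = set()
        self.paths: List[Path] = []
        self.variants: List[VariantAnnotation] = []
        self._next_id = 1

    # -- construction primitives -------------------------------------------
    def add_node(self, sequence: str, node_id: Optional[int] = None) -> Node:
        if node_id is None:
            node_id = self._next_id
        if node_id in self.nodes:
            raise GraphValidationError(f"duplicate node id {node_id}")
        node = Node(node_id, sequence)
        self.nodes[node_id] = node
        self._next_id = max(self._next_id, node_id + 1)
        return node

    def add_edge(self, a: Side, b: Side) -> Edge:
        for s in (a, b):
            if s.node_id not in self.nodes:
                raise GraphValidationError(f"edge references missing node {s.node_id}")
        edge = make_edge(a, b)
        self.edges.add(edge)
        return edge

    def has_edge(self, a: Side, b: Side) -> bool:
        return make_edge(a, b) in self.edges

    def side_adjacency(self) -> Dict[Side, List[Side]]:
        adj: Dict[Side, List[Side]] = {}
        for e in self.edges:
            adj.setdefault(e.a, []).append(e.b)
            if e.b != e.a:
                adj.setdefault(e.b, []).append(e.a)
        return adj

    # -- paths --------------------------------------------------------------
    def reference_path(self, contig: str) -> Path:
        for p in self.paths:
            if p.is_reference and p.name == contig:
                return p
        raise KeyError(f"no reference path named {contig!r}")

    def reference_contigs(self) -> List[str]:
        return [p.name for p in self.paths if p.is_reference]

    def node_ref_offsets(self, contig: str) -> Dict[int, Tuple[int, int]]:
        """Map reference-path node id -> (start, end) offset on the contig."""
        offsets = {}
        pos = 0
        for step in self.reference_path(contig).steps:
            n = len(self.nodes[step.node_id])
            offsets[step.node_id] = (pos, pos + n)
            pos += n
        return offsets

    def step_sequence(self, step: Step) -> str:
        seq = self.nodes[step.node_id].sequence
        return revcomp(seq) if step.reverse else seq

    def path_sequence(self, steps: Sequence[Step]) -> str:
        """Concatenate node sequences along a walk (reverse steps revcomped)."""
        parts = []
        prev: Optional[Step] = None
        for step in steps:
            if step.node_id not in self.nodes:
                raise GraphValidationError(f"walk references missing node {step.node_id}")
            if prev is not None and not self.has_edge(prev.exit_side, step.entry_side):
                raise GraphValidationError(
                    f"walk steps {prev} -> {step} are not joined by an edge")
            parts.append(self.step_sequence(step))
            prev = step
        return "".join(parts)

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        for e in self.edges:
            for s in (e.a, e.b):
                if s.node_id not in self.nodes:
                    raise GraphValidationError(f"edge {e} references missing node")
        for p in self.paths:
            self.path_sequence(p.steps)  # raises on broken walks
        for va in self.variants:
            for walk in va.alleles:
                self.path_sequence(walk)

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": [{"id": n.id, "seq": n.sequence} for n in
                      sorted(self.nodes.values(), key=lambda n: n.id)],
            "edges": sorted(
                ({"from": e.a.node_id, "from_end": e.a.end,
                  "to": e.b.node_id, "to_end": e.b.end} for e in self.edges),
                key=lambda d: (d["from"], d["from_end"], d["to"], d["to_end"])),
            "paths": [
                {"name": p.name,
                 "steps": [{"id": s.node_id, "rev": s.reverse} for s in p.steps],
                 "reference": p.is_reference}
                for p in self.paths
            ],
            "variants": [
                {"id": va.variant_id, "contig": va.contig, "position": va.position,
                 "span": list(va.span), "ref_allele": va.ref_allele_index,
                 "alleles": [[{"id": s.node_id, "rev": s.reverse} for s in walk]
                             for walk in va.alleles]}
                for va in self.variants
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "VariationGraph":
        g = cls()
        try:
            for nd in data["nodes"]:
                g.add_node(nd["seq"], node_id=nd["id"])
            for ed in data["edges"]:
                g.add_edge(Side(ed["from"], ed["from_end"]), Side(ed["to"], ed["to_end"]))
            for pd in data["paths"]:
                g.paths.append(Path(pd["name"],
                                    [Step(s["id"], s["rev"]) for s in pd["steps"]],
                                    pd["reference"]))
            for vd in data.get("variants", []):
                g.variants.append(VariantAnnotation(
                    variant_id=vd["id"], contig=vd["contig"], position=vd["position"],
                    alleles=[[Step(s["id"], s["rev"]) for s in walk]
                             for walk in vd["alleles"]],
                    span=tuple(vd["span"]), ref_allele_index=vd["ref_allele"]))
        except KeyError as exc:
            raise GraphValidationError(f"graph JSON missing field {exc}") from exc
        g.validate()
        return g


def write_graph(g: VariationGraph, stream) -> None:
    json.dump(g.to_dict(), stream, indent=1)


def read_graph(stream) -> VariationGraph:
    try:
        data = json.load(stream)
    except json.JSONDecodeError as exc:
        raise GraphValidationError(f"graph JSON parse error: {exc}") from exc
    return VariationGraph.from_dict(data)


# ---------------------------------------------------------------------------
# Construction from reference FASTA + VCF
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class _AlleleSpec:
    """One record after trimming: the record span and each allele's
    replacement sequence over that span (ref allele first)."""

    record: VcfVariant
    span: Tuple[int, int]
    allele_seqs: List[str]


def _trim_allele(ref: str, alt: str, pos0: int) -> Tuple[int, int, str]:
    """Right- then left-trim shared sequence; return (start0, end0, alt_core)."""
    r, a = ref, alt
    while r and a and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    lead = 0
    while lead < len(r) and lead < len(a) and r[lead] == a[lead]:
        lead += 1
    start = pos0 + lead
    end = pos0 + len(r)
    return start, end, a[lead:]


def _resolve_record(rec: VcfVariant, contig_seq: str) -> _AlleleSpec:
    pos0 = rec.pos - 1
    if pos0 < 0 or pos0 + len(rec.ref) > len(contig_seq):
        raise GraphValidationError(f"{rec.vid}: REF outside contig bounds")
    spans: List[Tuple[int, int, str]] = []
    for alt in rec.alts:
        if alt.startswith("<"):
            svtype = alt.strip("<>").split(":")[0]
            end = rec.info.get("END")
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            if svtype in ("DEL", "INV"):
                if end is None and svlen is None:
                    raise GraphValidationError(
                        f"{rec.vid}: symbolic <{svtype}> without END or SVLEN")
                end0 = int(end) if end is not None else rec.pos + abs(int(svlen))
                if end0 <= rec.pos:
                    raise GraphValidationError(f"{rec.vid}: END before POS")
                seg = contig_seq[rec.pos:end0]
                spans.append((rec.pos, end0, "" if svtype == "DEL" else revcomp(seg)))
            elif svtype == "INS":
                seq = rec.info.get("SEQ")
                if not seq:
                    raise GraphValidationError(
                        f"{rec.vid}: symbolic <INS> without an inserted sequence")
                spans.append((rec.pos, rec.pos, str(seq).upper()))
            else:
                raise GraphValidationError(f"{rec.vid}: unknown symbolic type <{svtype}>")
        else:
            if contig_seq[pos0:pos0 + len(rec.ref)] != rec.ref.upper():
                raise GraphValidationError(
                    f"{rec.vid}: REF does not match reference at {rec.contig}:{rec.pos}")
            spans.append(_trim_allele(rec.ref.upper(), alt.upper(), pos0))
    start = min(s for s, _, _ in spans)
    end = max(e for _, e, _ in spans)
    if start == end and all(s == start for s, _, _ in spans):
        pass  # pure insertion record
    allele_seqs = [contig_seq[start:end]]
    for s, e, core in spans:
        allele_seqs.append(contig_seq[start:s] + core + contig_seq[e:end])
    return _AlleleSpec(rec, (start, end), allele_seqs)


def build_graph(reference: Mapping[str, str], variants: Iterable[VcfVariant],
                config: Optional[GraphConfig] = None) -> VariationGraph:
    """Construct a variation graph from reference contigs and VCF records.

    Every record's alleles are embedded as anchored walks: deletions as
    bypass edges, insertions as new nodes, exact inversions as
    orientation-reversing edges (no sequence duplication), anything else as
    a replacement node. Reference contigs become reference paths whose
    spelled-out sequence is byte-identical to the input.
    """
    config = config or GraphConfig()
    g = VariationGraph()
    by_contig: Dict[str, List[VcfVariant]] = {}
    for rec in variants:
        if rec.contig not in reference:
            raise GraphValidationError(f"{rec.vid}: contig {rec.contig!r} not in reference")
        by_contig.setdefault(rec.contig, []).append(rec)

    for contig, seq in reference.items():
        seq = seq.upper()
        check_dna(seq, f"contig {contig}")
        recs = sorted(by_contig.get(contig, []), key=lambda r: (r.pos, r.vid))
        specs = [_resolve_record(r, seq) for r in recs]
        for spec in specs:
            s, e = spec.span
            if s == 0 or e == len(seq):
                raise GraphValidationError(
                    f"{spec.record.vid}: variant touches the contig boundary; "
                    "a reference flank is required on both sides")

        breakpoints = {0, len(seq)}
        for spec in specs:
            breakpoints.update(spec.span)
        cuts = sorted(breakpoints)

        # reference nodes: split at breakpoints, then cap long segments
        node_at_start: Dict[int, int] = {}
        node_at_end: Dict[int, int] = {}
        ref_steps: List[Step] = []
        segments: List[Tuple[int, int, int]] = []  # (start, end, node_id)
        for seg_start, seg_end in zip(cuts[:-1], cuts[1:]):
            pos = seg_start
            while pos < seg_end:
                chunk_end = min(pos + config.max_node_length, seg_end)
                node = g.add_node(seq[pos:chunk_end])
                node_at_start[pos] = node.id
                node_at_end[chunk_end] = node.id
                segments.append((pos, chunk_end, node.id))
                if ref_steps:
                    g.add_edge(Side(ref_steps[-1].node_id, RIGHT), Side(node.id, LEFT))
                ref_steps.append(Step(node.id, False))
                pos = chunk_end
        g.paths.append(Path(contig, ref_steps, is_reference=True))

        def ref_walk(start: int, end: int) -> List[Step]:
            return [Step(nid, False) for s0, e0, nid in segments
                    if s0 >= start and e0 <= end]

        for spec in specs:
            s, e = spec.span
            left = node_at_end.get(s)
            right = node_at_start.get(e)
            if left is None or right is None:  # pragma: no cover - internal invariant
                raise GraphValidationError(
                    f"{spec.record.vid}: breakpoints not representable after splitting; "
                    "conflicting overlapping records")
            left_side = Side(left, RIGHT)
            right_side = Side(right, LEFT)
            walks: List[List[Step]] = []
            ref_seg = seq[s:e]
            inner_ref = ref_walk(s, e)
            for allele_seq in spec.allele_seqs:
                if allele_seq == ref_seg:
                    walk = [Step(left, False)] + inner_ref + [Step(right, False)]
                elif allele_seq == "":
                    g.add_edge(left_side, right_side)
                    walk = [Step(left, False), Step(right, False)]
                elif e > s and allele_seq == revcomp(ref_seg):
                    # inversion: reuse reference nodes in reverse orientation
                    g.add_edge(left_side, Side(inner_ref[-1].node_id, RIGHT))
                    g.add_edge(Side(inner_ref[0].node_id, LEFT), right_side)
                    walk = ([Step(left, False)]
                            + [Step(st.node_id, True) for st in reversed(inner_ref)]
                            + [Step(right, False)])
                else:
                    # replacement / insertion: new node(s) carrying the allele
                    prev_side = left_side
                    mid_steps: List[Step] = []
                    for off in range(0, len(allele_seq), config.max_node_length):
                        node = g.add_node(allele_seq[off:off + config.max_node_length])
                        g.add_edge(prev_side, Side(node.id, LEFT))
                        mid_steps.append(Step(node.id, False))
                        prev_side = Side(node.id, RIGHT)
                    g.add_edge(prev_side, right_side)
                    walk = [Step(left, False)] + mid_steps + [Step(right, False)]
                walks.append(walk)
            g.variants.append(VariantAnnotation(
                variant_id=spec.record.vid, contig=contig, position=spec.record.pos,
                alleles=walks, span=spec.span))

    g.validate()
    return g
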