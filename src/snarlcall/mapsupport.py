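"""Read mapping to the variation graph and the read-support ("pack") index.

A deliberately compact seed-and-extend graph mapper: exact k-mer seeds are
located on graph walks via an index that includes junction-spanning k-mers,
candidate walks through the graph are enumerated around each seed cluster,
and the read is aligned to each candidate walk with edlib (banded bit-vector
edit distance). Mapping quality reflects the edit-distance gap between the
best and second-best distinct placements (ties map to 0).

The pack index stores, for alignments at or above a mapping-quality
threshold (default 5), the number of reads covering each base of each node
and each edge. Graph bases skipped by a deletion in the read are not
counted as covered; read insertions and soft-clipped bases add no coverage.
"""
from __future__ import annotations

import dataclasses
import json
import re
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .dna import revcomp
from .graphmodel import Edge, RIGHT, Side, Step, VariationGraph, make_edge

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclasses.dataclass
class MapParams:
    k: int = 16
    max_seed_hits: int = 32
    max_anchors: int = 4
    max_walks: int = 16
    min_identity: float = 0.7
    mapq_scale: int = 10
    slack: int = 12


@dataclasses.dataclass
class GraphAlignment:
    """A read aligned to a walk through the graph.

    ``steps`` is the walk restricted to the aligned span; ``start_offset``
    and ``end_offset`` are offsets into the first/last step's oriented
    sequence (end exclusive). ``cigar`` uses extended ops (=, X, I, D) with
    the read as query and the walk as target. Unmapped reads have empty
    steps and mapping quality 0.
    """

    read_name: str
    steps: List[Step]
    start_offset: int
    end_offset: int
    cigar: str
    mapping_quality: int
    identity: float

    @property
    def is_mapped(self) -> bool:
        return bool(self.steps)

    def cigar_ops(self) -> List[Tuple[str, int]]:
        return [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(self.cigar)]

    def to_json(self) -> str:
        return json.dumps({
            "name": self.read_name,
            "steps": [[s.node_id, int(s.reverse)] for s in self.steps],
            "start": self.start_offset,
            "end": self.end_offset,
            "cigar": self.cigar,
            "mapq": self.mapping_quality,
            "identity": round(self.identity, 4),
        })

    @classmethod
    def from_json(cls, line: str) -> "GraphAlignment":
        d = json.loads(line)
        return cls(read_name=d["name"],
                   steps=[Step(nid, bool(rev)) for nid, rev in d["steps"]],
                   start_offset=d["start"], end_offset=d["end"],
                   cigar=d["cigar"], mapping_quality=d["mapq"],
                   identity=d["identity"])


def write_alignments(alignments: Iterable[GraphAlignment], stream) -> None:
    for aln in alignments:
        stream.write(aln.to_json())
        stream.write("\n")


def read_alignments(stream) -> Iterator[GraphAlignment]:
    for lineno, line in enumerate(stream, 1):
        line = line.strip()
        if not line:
            continue
        try:
            yield GraphAlignment.from_json(line)
        except (json.JSONDecodeError, KeyError) as exc:
            raise ValueError(f"malformed alignment at line {lineno}: {exc}") from exc


# ---------------------------------------------------------------------------
# Seeding index
# ---------------------------------------------------------------------------

def _enter_step(side: Side) -> Step:
    """Step taken when a walk crosses an edge into ``side``."""
    return Step(side.node_id, reverse=(side.end == RIGHT))


class GraphIndex:
    """Exact k-mer index over node sequences and junction-spanning walks.

    Every k-mer starting at every base of every node, in both node
    orientations, is recorded with the walk it lies on (extended across
    edges when it overhangs the node end), so reads from either strand and
    reads crossing variant junctions seed directly.
    """

    def __init__(self, g: VariationGraph, k: int = 16, max_ext_walks: int = 16):
        self.g = g
        self.k = k
        self.max_ext_walks = max_ext_walks
        self._kmers: Dict[str, List[Tuple[Tuple[Step, ...], int]]] = {}
        self._adj = g.side_adjacency()
        self._build()

    def _successors(self, exit_side: Side) -> List[Step]:
        return [_enter_step(t) for t in self._adj.get(exit_side, ())]

    def extensions(self, exit_side: Side, need: int,
                   max_walks: Optional[int] = None) -> List[Tuple[Tuple[Step, ...], str]]:
        """Walks leaving ``exit_side`` carrying at least ``need`` bases
        (fewer if a tip is reached). Bounded enumeration."""
        max_walks = max_walks or self.max_ext_walks
        done: List[Tuple[Tuple[Step, ...], str]] = []
        stack: List[Tuple[Tuple[Step, ...], str]] = [((), "")]
        while stack and len(done) < max_walks:
            steps, seq = stack.pop()
            if len(seq) >= need:
                done.append((steps, seq))
                continue
            exit_s = exit_side if not steps else steps[-1].exit_side
            succ = self._successors(exit_s)
            if not succ:
                done.append((steps, seq))  # tip
                continue
            for nxt in sorted(succ):
                stack.append((steps + (nxt,), seq + self.g.step_sequence(nxt)))
        return done

    def back_extensions(self, entry_side: Side, need: int,
                        max_walks: Optional[int] = None):
        """Walks arriving at ``entry_side`` with at least ``need`` bases,
        returned in forward order (steps precede the anchored node)."""
        flipped = self.extensions(entry_side, need, max_walks)
        out = []
        for steps, seq in flipped:
            back = tuple(Step(s.node_id, not s.reverse) for s in reversed(steps))
            out.append((back, revcomp(seq)))
        return out

    def _build(self) -> None:
        k = self.k
        add = self._kmers.setdefault
        for node in self.g.nodes.values():
            for rev in (False, True):
                step = Step(node.id, rev)
                seq = self.g.step_sequence(step)
                L = len(seq)
                whole_end = max(0, L - k + 1)
                for t in range(whole_end):
                    add(seq[t:t + k], []).append(((step,), t))
                for t in range(whole_end, L):
                    need = t + k - L
                    for ext_steps, ext_seq in self.extensions(step.exit_side, need):
                        if len(ext_seq) < need:
                            continue
                        kmer = seq[t:] + ext_seq[:need]
                        add(kmer, []).append(((step,) + ext_steps, t))

    def lookup(self, kmer: str):
        return self._kmers.get(kmer, ())


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------

def _walk_candidates(index: GraphIndex, step0: Step, diag: int, read_len: int,
                     params: MapParams):
    """Candidate (steps, target_seq, walk_start_offset) triples whose
    target sequence covers the read placement implied by ``diag`` (read
    start at oriented offset ``diag`` of ``step0``) plus slack."""
    g = index.g
    seq0 = g.step_sequence(step0)
    L0 = len(seq0)
    lo = diag - params.slack
    hi = diag + read_len + params.slack
    back_need = max(0, -lo)
    fwd_need = max(0, hi - L0)
    backs = (index.back_extensions(step0.entry_side, back_need, params.max_walks)
             if back_need else [((), "")])
    fwds = (index.extensions(step0.exit_side, fwd_need, params.max_walks)
            if fwd_need else [((), "")])
    out = []
    for bsteps, bseq in backs:
        for fsteps, fseq in fwds:
            if len(out) >= params.max_walks:
                return out
            steps = list(bsteps) + [step0] + list(fsteps)
            out.append((steps, bseq + seq0 + fseq, len(bseq)))
    return out


def _steps_at(steps: Sequence[Step], lengths: Sequence[int], walk_pos: int):
    """(step index, local offset) for a walk coordinate."""
    i = 0
    while walk_pos >= lengths[i]:
        walk_pos -= lengths[i]
        i += 1
    return i, walk_pos


def map_read(g: VariationGraph, index: GraphIndex, name: str, seq: str,
             params: Optional[MapParams] = None) -> GraphAlignment:
    """Align one read to the graph by seed-and-extend."""
    params = params or MapParams()
    k = params.k
    unmapped = GraphAlignment(name, [], 0, 0, "", 0, 0.0)
    if len(seq) < k:
        return unmapped
    seq = seq.upper()
    stride = max(1, (len(seq) - k) // 6)
    offsets = list(range(0, len(seq) - k + 1, stride))
    if offsets[-1] != len(seq) - k:
        offsets.append(len(seq) - k)

    votes: Dict[Tuple[Step, int], int] = {}
    for ro in offsets:
        hits = index.lookup(seq[ro:ro + k])
        if not hits or len(hits) > params.max_seed_hits:
            continue
        for steps, t in hits:
            key = (steps[0], t - ro)
            votes[key] = votes.get(key, 0) + 1
    if not votes:
        return unmapped

    # merge near-identical diagonals on the same step, then rank by votes
    merged: Dict[Tuple[Step, int], Tuple[int, int]] = {}
    for (step0, diag), n in sorted(votes.items()):
        key = (step0, diag // 8)
        cur = merged.get(key)
        if cur is None or n > cur[1]:
            merged[key] = (diag, n)
        else:
            merged[key] = (cur[0], cur[1] + n)
    anchors = sorted(((n, step0, diag) for (step0, _), (diag, n) in merged.items()),
                     key=lambda x: (-x[0], x[1], x[2]))[:params.max_anchors]

    best = None   # (dist, placement_key, steps, lengths, walk_interval, cigar)
    placements: Dict[Tuple, int] = {}
    for _, step0, diag in anchors:
        for steps, target, off0 in _walk_candidates(index, step0, diag, len(seq), params):
            res = edlib.align(seq, target, mode="HW", task="path")
            if res["editDistance"] < 0:
                continue
            ts, te = res["locations"][-1]
            lengths = [len(g.nodes[s.node_id]) for s in steps]
            i0, local0 = _steps_at(steps, lengths, ts)
            pk_step = steps[i0]
            pk_base = local0 if not pk_step.reverse else lengths[i0] - 1 - local0
            pkey = (pk_step.node_id, pk_step.reverse, pk_base)
            d = res["editDistance"]
            if pkey not in placements or d < placements[pkey]:
                placements[pkey] = d
            if best is None or d < best[0] or (d == best[0] and pkey < best[1]):
                best = (d, pkey, steps, lengths, (ts, te), res["cigar"])

    if best is None:
        return unmapped
    d1, pkey1, steps, lengths, (ts, te), cigar = best
    matches = sum(n for m in _CIGAR_RE.finditer(cigar)
                  for op, n in [(m.group(2), int(m.group(1)))] if op == "=")
    identity = matches / len(seq)
    if identity < params.min_identity:
        return unmapped
    others = [d for key, d in placements.items() if key != pkey1]
    if others:
        gap = min(others) - d1
        mapq = 0 if gap <= 0 else min(60, params.mapq_scale * gap)
    else:
        mapq = 60

    # trim the walk to the aligned span
    i0, local0 = _steps_at(steps, lengths, ts)
    i1, local1 = _steps_at(steps, lengths, te)  # te inclusive
    trimmed = list(steps[i0:i1 + 1])
    return GraphAlignment(name, trimmed, local0, local1 + 1, cigar, mapq, identity)


def map_read_pair(g: VariationGraph, index: GraphIndex, name: str,
                  seq1: str, seq2: str,
                  params: Optional[MapParams] = None):
    """Map both mates of a pair (independently; each read contributes its
    own support)."""
    return (map_read(g, index, name + "/1", seq1, params),
            map_read(g, index, name + "/2", seq2, params))


# ---------------------------------------------------------------------------
# Pack index
# ---------------------------------------------------------------------------

class PackIndex:
    """Per-node-base and per-edge read-support counts."""

    def __init__(self, g: VariationGraph, min_mapq: int = 5):
        self.node_base_coverage: Dict[int, np.ndarray] = {
            nid: np.zeros(len(node), dtype=np.int32)
            for nid, node in g.nodes.items()}
        self.edge_coverage: Dict[Edge, int] = {e: 0 for e in g.edges}
        self.min_mapq_applied = min_mapq

    def node_average(self, node_id: int) -> float:
        cov = self.node_base_coverage[node_id]
        return float(cov.mean()) if len(cov) else 0.0

    def total_covered_bases(self) -> int:
        return int(sum(int(c.sum()) for c in self.node_base_coverage.values()))

    def to_dict(self) -> dict:
        return {
            "min_mapq": self.min_mapq_applied,
            "nodes": {str(nid): cov.tolist()
                      for nid, cov in sorted(self.node_base_coverage.items())},
            "edges": sorted([[e.a.node_id, e.a.end, e.b.node_id, e.b.end, n]
                             for e, n in self.edge_coverage.items()]),
        }

    def write(self, stream) -> None:
        json.dump(self.to_dict(), stream)

    @classmethod
    def read(cls, g: VariationGraph, stream) -> "PackIndex":
        d = json.load(stream)
        pack = cls(g, min_mapq=d["min_mapq"])
        for nid, counts in d["nodes"].items():
            pack.node_base_coverage[int(nid)] = np.asarray(counts, dtype=np.int32)
        for a_id, a_end, b_id, b_end, n in d["edges"]:
            pack.edge_coverage[make_edge(Side(a_id, a_end), Side(b_id, b_end))] = n
        return pack


def covered_intervals(g: VariationGraph, aln: GraphAlignment
                      ) -> List[Tuple[int, int, int]]:
    """(node_id, start, end) node-forward base intervals covered by the
    aligned read positions of ``aln`` (read deletions skip graph bases)."""
    if not aln.is_mapped:
        return []
    lengths = []
    for s in aln.steps:
        if s.node_id not in g.nodes:
            raise KeyError(
                f"alignment {aln.read_name!r} references unknown node {s.node_id}")
        lengths.append(len(g.nodes[s.node_id]))
    bounds = np.cumsum([0] + lengths)
    covered: List[Tuple[int, int]] = []
    p = aln.start_offset  # walk coordinate from start of first step
    for op, n in aln.cigar_ops():
        if op in ("=", "X", "M"):
            covered.append((p, p + n))
            p += n
        elif op == "D":
            p += n
    out = []
    for lo, hi in covered:
        i = int(np.searchsorted(bounds, lo, side="right")) - 1
        while lo < hi:
            step_hi = bounds[i + 1]
            seg_hi = min(hi, step_hi)
            local_lo = lo - bounds[i]
            local_hi = seg_hi - bounds[i]
            step = aln.steps[i]
            L = lengths[i]
            if step.reverse:
                out.append((step.node_id, L - local_hi, L - local_lo))
            else:
                out.append((step.node_id, local_lo, local_hi))
            lo = seg_hi
            i += 1
    return out


def per_step_edits(g: VariationGraph, aln: GraphAlignment
                   ) -> List[List[Tuple[str, int]]]:
    """Split the alignment's cigar at step boundaries: one edit list
    (op, length) per step of the walk."""
    if not aln.is_mapped:
        return []
    lengths = [len(g.nodes[s.node_id]) for s in aln.steps]
    bounds = list(np.cumsum([0] + lengths))
    out: List[List[Tuple[str, int]]] = [[] for _ in aln.steps]
    p = aln.start_offset
    i = 0
    for op, n in aln.cigar_ops():
        if op == "I":  # consumes read only; attribute to the current step
            out[i].append((op, n))
            continue
        while n > 0:
            while p >= bounds[i + 1] and i + 1 < len(aln.steps):
                i += 1
            take = min(n, bounds[i + 1] - p)
            out[i].append((op, take))
            p += take
            n -= take
    return out


def compute_pack(g: VariationGraph, alignments: Iterable[GraphAlignment],
                 min_mapq: int = 5) -> PackIndex:
    """Single-pass coverage accumulation over alignments with mapping
    quality >= ``min_mapq``."""
    pack = PackIndex(g, min_mapq=min_mapq)
    for aln in alignments:
        if not aln.is_mapped or aln.mapping_quality < min_mapq:
            continue
        for nid, lo, hi in covered_intervals(g, aln):
            pack.node_base_coverage[nid][lo:hi] += 1
        for prev, nxt in zip(aln.steps[:-1], aln.steps[1:]):
            edge = make_edge(prev.exit_side, nxt.entry_side)
            if edge not in pack.edge_coverage:
                raise KeyError(
                    f"alignment {aln.read_name!r} traverses unknown edge {edge}")
            pack.edge_coverage[edge] += 1
    return pack
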