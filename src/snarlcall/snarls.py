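"""Snarl detection: sites of variation bounded by a pair of node sides.

A snarl is a pair of sides (x, y) in the bidirected graph such that

1. *separation*: removing every edge incident to x' and y' (the opposite
   sides of x's and y's nodes) leaves x and y in one connected component X
   that none of the removed edges' far endpoints can reach, with both
   sides facing into the site -- a bidirected walk leaving through x can
   arrive at y -- and
2. *minimality*: no side z inside X forms a separating pair with x (and
   likewise with y).

Connectivity is over the "biedged" view: each node links its two sides, and
each graph edge links the sides it joins. At a graph tip nothing is removed
and the separation condition holds vacuously, which makes a lone bubble a
snarl — matching how sites behave when the bubble is embedded in a longer
contig.

The search is definitional rather than the linear-time cactus decomposition:
every side with at least one edge is a candidate boundary, candidate
partners are collected from a bounded breadth-first region, and each pair is
tested directly against the definition. On graphs small enough to
enumerate (tests do this exhaustively) the bound never engages, so the
search is exact there; on large graphs the region bound caps the size of a
detectable snarl component.
"""
from __future__ import annotations

import dataclasses
from collections import deque
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

from .graphmodel import RIGHT, Side, VariationGraph

# Sides are encoded as ints (2*node_id + end) inside the search for speed.


def _encode(side: Side) -> int:
    return 2 * side.node_id + side.end


def _decode(s: int) -> Side:
    return Side(s // 2, s % 2)


def _adjacency(g: VariationGraph) -> Dict[int, List[int]]:
    adj: Dict[int, List[int]] = {}
    for e in g.edges:
        a, b = _encode(e.a), _encode(e.b)
        adj.setdefault(a, []).append(b)
        if b != a:
            adj.setdefault(b, []).append(a)
    return adj


def _component(adj: Dict[int, List[int]], x: int, y: int,
               bound: Optional[int]) -> Optional[Set[int]]:
    """Connected component containing x after removing edges at x' and y'.

    Traverses node-internal links (s <-> s^1) and graph edges, skipping any
    edge with an endpoint at x' or y'. Returns None when the component
    exceeds ``bound`` sides.
    """
    xp, yp = x ^ 1, y ^ 1
    comp = {x}
    queue = deque([x])
    while queue:
        s = queue.popleft()
        partner = s ^ 1
        if partner not in comp:
            comp.add(partner)
            queue.append(partner)
        if s == xp or s == yp:
            continue  # all grey edges at x'/y' are removed
        for t in adj.get(s, ()):
            if t == xp or t == yp:
                continue
            if t not in comp:
                comp.add(t)
                queue.append(t)
                if bound is not None and len(comp) > bound:
                    return None
    return comp


_KILLED = object()  # candidate provably non-minimal; aborted early


def _separates(adj: Dict[int, List[int]], x: int, y: int,
               bound: Optional[int] = None, kill=None):
    """Return the component X when (x, y) satisfies the separation
    criterion, else None.

    ``kill`` is an optional set of sides known to form separating pairs
    with x; if one of them enters the component, (x, y) cannot be minimal
    and the sentinel ``_KILLED`` is returned immediately.
    """
    if y == x or y == (x ^ 1):
        return None
    xp, yp = x ^ 1, y ^ 1
    # far endpoints of the removed edges; the two sets must cut into
    # different parts of the graph -- a shared endpoint means the pair
    # faces outward into one flank (or the graph is circular around it)
    px = set(adj.get(xp, ()))
    py = set(adj.get(yp, ()))
    if px & py:
        return None
    if kill:
        comp = _component_kill(adj, x, y, bound, kill)
        if comp is _KILLED:
            return _KILLED
    else:
        comp = _component(adj, x, y, bound)
    if comp is None or y not in comp:
        return None
    for t in px | py:
        if t in comp:
            return None  # removal failed to cut this connection
    if not _walk_reachable(adj, x, y):
        return None  # boundary sides do not face into a traversable site
    return comp


def _walk_reachable(adj, x: int, y: int, budget: int = 20000) -> bool:
    """Whether a node-simple bidirected walk leaving through side x can
    arrive at side y.

    A walk crosses a grey edge, enters the node through the landing side,
    traverses it, and exits through the opposite side; it may not revisit
    a node (site traversals are node-simple). This makes the pair (x, y)
    face into a site that traversals can actually cross, and excludes
    outward-facing pairs, including those reachable only by flipping
    strand at a distant inversion and doubling back. Depth-first with
    backtracking; gives up (returns False) after ``budget`` expansions.
    """
    visited = {x // 2, y // 2}
    # frames: (entered node or None, iterator over grey edges at the
    # current exit side); iterative to keep long walks off the C stack
    stack = [(None, iter(adj.get(x, ())))]
    while stack:
        node, it = stack[-1]
        pushed = False
        for t in it:
            if t == y:
                return True
            nxt = t // 2
            if nxt in visited:
                continue
            if budget <= 0:
                return False
            budget -= 1
            visited.add(nxt)
            stack.append((nxt, iter(adj.get(t ^ 1, ()))))
            pushed = True
            break
        if not pushed:
            stack.pop()
            if node is not None:
                visited.discard(node)
    return False


def _component_kill(adj, x: int, y: int, bound, kill):
    """Like :func:`_component` but aborts when a kill-set side is reached."""
    xp, yp = x ^ 1, y ^ 1
    comp = {x}
    queue = deque([x])
    while queue:
        s = queue.popleft()
        for t in ([s ^ 1] if s in (xp, yp) else
                  [s ^ 1] + [t for t in adj.get(s, ()) if t != xp and t != yp]):
            if t not in comp:
                if t in kill and t != y:
                    return _KILLED
                comp.add(t)
                queue.append(t)
                if bound is not None and len(comp) > bound:
                    return None
    return comp


def is_snarl(g: VariationGraph, x: Side, y: Side,
             bound: Optional[int] = None) -> Tuple[bool, Optional[Set[Side]]]:
    """Test the full snarl definition (separation + minimality) for (x, y).

    Returns (is_snarl, X) where X is the separated component as Side
    objects whenever the separation criterion holds (even if minimality
    fails). Raises KeyError for sides on nodes absent from the graph.
    """
    for s in (x, y):
        if s.node_id not in g.nodes:
            raise KeyError(f"side {s} references a node absent from the graph")
    adj = _adjacency(g)
    xe, ye = _encode(x), _encode(y)
    comp = _separates(adj, xe, ye, bound)
    if comp is None:
        return False, None
    sides = {_decode(s) for s in comp}
    ok = _minimal(adj, xe, ye, comp, bound)
    return ok, sides


def _minimal(adj, x: int, y: int, comp: Set[int],
             bound: Optional[int],
             sep_cache: Optional[Dict[FrozenSet[int], Optional[Set[int]]]] = None) -> bool:
    def sep(a: int, b: int) -> bool:
        if sep_cache is not None:
            key = frozenset((a, b))
            if key not in sep_cache:
                sep_cache[key] = _separates(adj, a, b, bound)
            return sep_cache[key] is not None
        return _separates(adj, a, b, bound) is not None

    for z in comp:
        if z not in (x, x ^ 1, y) and sep(x, z):
            return False
        if z not in (y, y ^ 1, x) and sep(z, y):
            return False
    return True


@dataclasses.dataclass
class Snarl:
    """A site of variation bounded by two sides."""

    start: Side
    end: Side
    component_sides: Set[Side]
    contained_node_ids: Set[int]
    contained_variant_ids: List[str] = dataclasses.field(default_factory=list)
    parent: Optional["Snarl"] = None
    contig: Optional[str] = None
    interval: Optional[Tuple[int, int]] = None  # interior 0-based half-open

    @property
    def boundary_node_ids(self) -> Set[int]:
        return {self.start.node_id, self.end.node_id}

    def key(self) -> Tuple:
        return tuple(sorted((self.start, self.end)))


def find_snarls(g: VariationGraph, bound: int = 400) -> List[Snarl]:
    """Find every snarl of the graph by definition-driven search.

    Candidate partners for a boundary side x are the sides reachable once
    the edges at x' are removed (any snarl component is a subset of that
    region), visited in breadth-first order so that near partners are found
    before far ones and can prune them. ``bound`` caps the number of sides
    in a snarl component; it never engages on graphs with fewer sides.
    """
    adj = _adjacency(g)
    active = sorted(adj.keys())

    pairs: Dict[FrozenSet[int], Set[int]] = {}
    for x in active:
        found: Set[int] = set()
        for z in _region_order(adj, x, bound):
            if z in (x, x ^ 1) or z not in adj:
                continue
            key = frozenset((x, z))
            if key in pairs:
                found.add(z)
                continue
            comp = _separates(adj, x, z, bound, kill=found)
            if comp is _KILLED or comp is None:
                continue
            pairs[key] = comp
            found.add(z)

    # exact minimality pass over the recorded separating pairs
    sep_cache: Dict[FrozenSet[int], Optional[Set[int]]] = dict(pairs)
    snarls = []
    for key, comp in pairs.items():
        x, z = sorted(key)
        if _minimal(adj, x, z, comp, bound, sep_cache):
            snarls.append((x, z, comp))

    out = [Snarl(start=_decode(x), end=_decode(z),
                 component_sides={_decode(s) for s in comp},
                 contained_node_ids={s // 2 for s in comp} - {x // 2, z // 2})
           for x, z, comp in snarls]
    out.sort(key=lambda s: s.key())
    _canonicalize(g, out)
    _link_parents(out)
    return out


def _region_order(adj, x: int, bound: Optional[int]) -> List[int]:
    """Sides reachable from x once edges at x' are removed, in BFS order,
    truncated at ``bound`` sides."""
    xp = x ^ 1
    seen = {x}
    order = [x]
    queue = deque([x])
    while queue:
        if bound is not None and len(seen) > bound:
            break
        s = queue.popleft()
        nbrs = [s ^ 1]
        if s != xp:
            nbrs.extend(t for t in adj.get(s, ()) if t != xp)
        for t in nbrs:
            if t not in seen:
                seen.add(t)
                order.append(t)
                queue.append(t)
    return order


def find_snarls_exhaustive(g: VariationGraph) -> List[Snarl]:
    """Reference implementation: evaluate the definition over all side
    pairs. Quadratic in sides; for small graphs and for testing the
    pruned search."""
    adj = _adjacency(g)
    sides = sorted(
        {s for nid in g.nodes for s in (2 * nid, 2 * nid + 1)})
    sep_cache: Dict[FrozenSet[int], Optional[Set[int]]] = {}

    def sep(a, b):
        key = frozenset((a, b))
        if key not in sep_cache:
            sep_cache[key] = _separates(adj, a, b, None)
        return sep_cache[key]

    out = []
    seen = set()
    for i, x in enumerate(sides):
        for y in sides[i + 1:]:
            comp = sep(x, y)
            if comp is None:
                continue
            if not _minimal(adj, x, y, comp, None, sep_cache):
                continue
            key = frozenset((x, y))
            if key in seen:
                continue
            seen.add(key)
            out.append(Snarl(start=_decode(x), end=_decode(y),
                             component_sides={_decode(s) for s in comp},
                             contained_node_ids={s // 2 for s in comp}
                             - {x // 2, y // 2}))
    out.sort(key=lambda s: s.key())
    _canonicalize(g, out)
    _link_parents(out)
    return out


def _canonicalize(g: VariationGraph, snarls: List[Snarl]) -> None:
    """Orient each snarl reference-forward (start at the smaller reference
    coordinate) and annotate its interior reference interval."""
    offsets = {contig: g.node_ref_offsets(contig) for contig in g.reference_contigs()}
    for sn in snarls:
        coords = []
        for side in (sn.start, sn.end):
            found = None
            for contig, offs in offsets.items():
                if side.node_id in offs:
                    s0, e0 = offs[side.node_id]
                    pos = e0 if side.end == RIGHT else s0
                    found = (contig, pos)
                    break
            coords.append(found)
        if coords[0] and coords[1] and coords[0][0] == coords[1][0]:
            if coords[0][1] > coords[1][1]:
                sn.start, sn.end = sn.end, sn.start
                coords.reverse()
            sn.contig = coords[0][0]
            sn.interval = (coords[0][1], coords[1][1])
        elif sn.end < sn.start:
            sn.start, sn.end = sn.end, sn.start


def _link_parents(snarls: List[Snarl]) -> None:
    for child in snarls:
        best = None
        for other in snarls:
            if other is child:
                continue
            if (child.component_sides < other.component_sides):
                if best is None or len(other.component_sides) < len(best.component_sides):
                    best = other
        child.parent = best


def top_level_reference_snarls(g: VariationGraph, snarls: List[Snarl]) -> List[Snarl]:
    """Keep snarls whose both boundary nodes lie on a reference path and
    that are not contained in another snarl; annotate contained variants.

    A variant is contained when its trimmed breakpoint span falls within the
    snarl's interior reference interval.
    """
    kept = []
    for sn in snarls:
        if sn.parent is not None or sn.contig is None or sn.interval is None:
            continue
        lo, hi = sn.interval
        sn.contained_variant_ids = [
            va.variant_id for va in g.variants
            if va.contig == sn.contig and lo <= va.span[0] and va.span[1] <= hi]
        kept.append(sn)
    kept.sort(key=lambda s: (s.contig, s.interval))
    return kept
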