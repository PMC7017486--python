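"""SV benchmarking: overlap- and alignment-based matching of call sets.

Calls and truth are first normalized (multi-allelics split, alleles
right- then left-trimmed, types inferred from allele lengths with an
alignment check for inversions). Deletions and inversions then match by
genomic overlap: a record is *covered* when candidate partners of the same
type with at least ``min_ro`` reciprocal overlap jointly cover more than
``min_coverage`` of its span. Insertions match by location (partners within
``ins_max_gap`` bp) and Smith-Waterman alignment of the inserted sequences:
a record is covered when at least ``min_coverage`` of its sequence aligns
to a partner. Covered call records are true positives for precision,
covered truth records for recall; records below ``min_size`` are not
counted (but still contribute coverage when larger than 1 bp).

Genotype-level evaluation first merges fragmented heterozygotes (chains
closer than ``merge_gap``), collapses duplicate heterozygotes (reciprocal
overlap >= ``merge_ro``) into homozygotes, then scores the het and hom
strata separately.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import edlib
from Bio import Align
from intervaltree import IntervalTree

from .dna import revcomp
from .vcfio import VcfVariant

log = logging.getLogger(__name__)

DEL, INS, INV = "DEL", "INS", "INV"
HET, HOM_ALT, HOM_REF, MISSING = "het", "hom_alt", "hom_ref", "missing"


@dataclasses.dataclass
class SVRecord:
    contig: str
    start: int  # 0-based
    end: int    # 0-based exclusive; == start for insertions
    svtype: str
    alt_sequence: str = ""
    genotype: str = HET
    quality: float = 0.0
    source_id: str = ""

    @property
    def size(self) -> int:
        return len(self.alt_sequence) if self.svtype == INS else self.end - self.start

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)


@dataclasses.dataclass
class EvalOptions:
    min_size: int = 50
    min_ro: float = 0.10
    min_coverage: float = 0.50
    ins_max_gap: int = 20
    genotype_mode: bool = False
    regions: Optional[Sequence[Tuple[str, int, int]]] = None
    merge_ro: float = 0.80
    merge_gap: int = 20
    coverage_contributor_min_size: int = 2  # "larger than 1 bp"


@dataclasses.dataclass
class EvalResult:
    tp_call: int
    fp: int
    tp_truth: int
    fn: int
    tp_call_records: List[SVRecord] = dataclasses.field(default_factory=list)
    fp_records: List[SVRecord] = dataclasses.field(default_factory=list)
    tp_truth_records: List[SVRecord] = dataclasses.field(default_factory=list)
    fn_records: List[SVRecord] = dataclasses.field(default_factory=list)

    @property
    def precision(self) -> float:
        d = self.tp_call + self.fp
        return self.tp_call / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp_truth + self.fn
        return self.tp_truth / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _trim(ref: str, alt: str, pos0: int) -> Tuple[int, int, str, str]:
    """Right-trim then left-trim shared bases; return 0-based half-open
    span plus the remaining REF/ALT cores."""
    r, a = ref, alt
    while r and a and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    lead = 0
    while lead < len(r) and lead < len(a) and r[lead] == a[lead]:
        lead += 1
    return pos0 + lead, pos0 + len(r), r[lead:], a[lead:]


def classify_inversion(ref_seq: str, alt_seq: str, min_len: int = 10,
                       min_aligned: float = 0.80) -> bool:
    """True when the reverse-complement of ALT aligns locally over more
    than ``min_aligned`` of the shorter sequence against REF (both
    sequences must be longer than ``min_len``)."""
    if len(ref_seq) <= min_len or len(alt_seq) <= min_len:
        return False
    aligned = _aligned_spans(revcomp(alt_seq), ref_seq)
    if aligned is None:
        return False
    span_q, _ = aligned
    return span_q / min(len(ref_seq), len(alt_seq)) > min_aligned


_ALIGNER = Align.PairwiseAligner(mode="local", match_score=1, mismatch_score=-1,
                                 open_gap_score=-3, extend_gap_score=-1)

_BIG_ALIGN_CELLS = 4_000_000


def _aligned_spans(query: str, target: str) -> Optional[Tuple[int, int]]:
    """Bases of query and of target spanned by the best local alignment.

    Smith-Waterman via Biopython; very large pairs fall back to edlib
    infix alignment of the shorter sequence into the longer."""
    if not query or not target:
        return None
    if query == target:
        return len(query), len(target)
    if len(query) * len(target) > _BIG_ALIGN_CELLS:
        short, lng, q_is_short = ((query, target, True)
                                  if len(query) <= len(target)
                                  else (target, query, False))
        res = edlib.align(short, lng, mode="HW", task="locations")
        if res["editDistance"] < 0 or res["editDistance"] > 0.3 * len(short):
            return None
        ls, le = res["locations"][-1]
        span_short, span_long = len(short), le - ls + 1
        return (span_short, span_long) if q_is_short else (span_long, span_short)
    try:
        aln = _ALIGNER.align(query, target)[0]
    except (IndexError, ValueError):
        return None
    if aln.score <= 0:
        return None
    t_seg, q_seg = aln.aligned
    span_t = int(t_seg[-1][1] - t_seg[0][0])
    span_q = int(q_seg[-1][1] - q_seg[0][0])
    return span_q, span_t


def normalize(records: Iterable[VcfVariant], reference: Optional[Mapping[str, str]] = None,
              sample: Optional[str] = None, drop_ref_genotypes: bool = True
              ) -> List[SVRecord]:
    """VCF records -> typed SVRecords: split multi-allelics, trim alleles,
    resolve symbolic alleles, classify DEL/INS/INV.

    When ``sample`` is given, genotypes are taken from that sample's GT and
    records carrying no alternate allele are dropped (they are not variants
    of that sample); without a sample every record is taken as present
    (het unless stated otherwise).
    """
    out: List[SVRecord] = []
    for rec in records:
        qual = rec.qual if rec.qual is not None else 0.0
        if qual == 0.0 and sample and "GQ" in rec.samples.get(sample, {}):
            qual = float(rec.samples[sample]["GQ"])
        for alt_index, alt in enumerate(rec.alts, start=1):
            genotype = HET
            if sample is not None:
                gt = rec.genotype(sample)
                if gt is None or gt == (None, None) or None in gt:
                    genotype = MISSING
                else:
                    n = sum(1 for a in gt if a == alt_index)
                    genotype = HOM_ALT if n == 2 else (HET if n == 1 else HOM_REF)
                if drop_ref_genotypes and genotype in (HOM_REF, MISSING):
                    continue
            sv = _classify(rec, alt, reference)
            if sv is None:
                continue
            sv.genotype = genotype
            sv.quality = float(qual)
            out.append(sv)
    out.sort(key=lambda r: (r.contig, r.start, r.end, r.svtype))
    return out


def _classify(rec: VcfVariant, alt: str, reference) -> Optional[SVRecord]:
    pos0 = rec.pos - 1
    if alt.startswith("<"):
        svtype = alt.strip("<>").split(":")[0]
        end = rec.info.get("END")
        svlen = rec.info.get("SVLEN")
        if isinstance(svlen, (tuple, list)):
            svlen = svlen[0]
        if svtype in (DEL, INV):
            end0 = int(end) if end is not None else (
                rec.pos + abs(int(svlen)) if svlen is not None else None)
            if end0 is None:
                log.warning("%s: symbolic <%s> without END/SVLEN; skipped",
                            rec.vid, svtype)
                return None
            return SVRecord(rec.contig, rec.pos, end0, svtype, source_id=rec.vid)
        if svtype == INS:
            seq = rec.info.get("SEQ")
            if not seq:
                log.warning("%s: symbolic <INS> without sequence; excluded", rec.vid)
                return None
            return SVRecord(rec.contig, rec.pos, rec.pos, INS,
                            alt_sequence=str(seq).upper(), source_id=rec.vid)
        log.warning("%s: unknown symbolic allele <%s>; skipped", rec.vid, svtype)
        return None
    ref = rec.ref.upper()
    alt = alt.upper()
    if reference is not None and rec.contig in reference:
        ref_at = reference[rec.contig][pos0:pos0 + len(ref)]
        if ref_at != ref:
            log.warning("%s: REF mismatch vs reference at %s:%d (kept as stated)",
                        rec.vid, rec.contig, rec.pos)
    start, end, ref_core, alt_core = _trim(ref, alt, pos0)
    if not ref_core and not alt_core:
        return None
    if len(ref_core) > 10 and len(alt_core) > 10 and classify_inversion(ref_core, alt_core):
        return SVRecord(rec.contig, start, end, INV, alt_sequence=alt_core,
                        source_id=rec.vid)
    if len(ref_core) >= len(alt_core):
        return SVRecord(rec.contig, start, end, DEL, source_id=rec.vid)
    if not ref_core:
        return SVRecord(rec.contig, start, start, INS, alt_sequence=alt_core,
                        source_id=rec.vid)
    # net insertion with replaced bases: treat as an insertion at the site
    return SVRecord(rec.contig, start, end, INS, alt_sequence=alt_core,
                    source_id=rec.vid)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _reciprocal_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return inter / max(a[1] - a[0], b[1] - b[0])


def match_overlap(records: Sequence[SVRecord], others: Sequence[SVRecord],
                  opts: Optional[EvalOptions] = None) -> List[float]:
    """Coverage proportion of each record by the other set (DEL/INV rule):
    union of candidate partners' intervals (reciprocal overlap >= min_ro,
    partner size >= 2 bp) intersected with the record, over record size."""
    opts = opts or EvalOptions()
    trees: Dict[str, IntervalTree] = {}
    for o in others:
        if o.size >= opts.coverage_contributor_min_size:
            trees.setdefault(o.contig, IntervalTree()).addi(o.start, o.end, o)
    props = []
    for r in records:
        if r.size <= 0:
            props.append(0.0)
            continue
        pieces = []
        for hit in trees.get(r.contig, IntervalTree()).overlap(r.start, r.end):
            o = hit.data
            if _reciprocal_overlap(r.interval, o.interval) >= opts.min_ro:
                pieces.append((max(r.start, o.start), min(r.end, o.end)))
        props.append(_union_length(pieces) / r.size if pieces else 0.0)
    return props


def _union_length(pieces: List[Tuple[int, int]]) -> int:
    total = 0
    last = None
    for lo, hi in sorted(pieces):
        if last is None or lo > last:
            total += hi - lo
            last = hi
        elif hi > last:
            total += hi - last
            last = hi
    return total


def match_insertions(records: Sequence[SVRecord], others: Sequence[SVRecord],
                     opts: Optional[EvalOptions] = None) -> List[float]:
    """Aligned proportion of each insertion's sequence against its best
    partner within ``ins_max_gap`` bp (local alignment; max over partners)."""
    opts = opts or EvalOptions()
    by_contig: Dict[str, List[SVRecord]] = {}
    for o in others:
        if o.alt_sequence and o.size >= opts.coverage_contributor_min_size:
            by_contig.setdefault(o.contig, []).append(o)
    for lst in by_contig.values():
        lst.sort(key=lambda r: r.start)
    props = []
    for r in records:
        if not r.alt_sequence:
            props.append(0.0)
            continue
        best = 0.0
        for o in by_contig.get(r.contig, ()):
            if abs(o.start - r.start) > opts.ins_max_gap:
                continue
            spans = _aligned_spans(r.alt_sequence, o.alt_sequence)
            if spans is not None:
                best = max(best, spans[0] / r.size)
        props.append(best)
    return props


# ---------------------------------------------------------------------------
# Genotype-mode merging
# ---------------------------------------------------------------------------

def merge_for_genotype_eval(records: Sequence[SVRecord],
                            opts: Optional[EvalOptions] = None) -> List[SVRecord]:
    """Merge fragmented heterozygotes, then collapse duplicate het pairs
    into homozygotes (per contig and svtype)."""
    opts = opts or EvalOptions()
    out: List[SVRecord] = [r for r in records if r.genotype not in (HET,)]
    by_key: Dict[Tuple[str, str], List[SVRecord]] = {}
    for r in records:
        if r.genotype == HET:
            by_key.setdefault((r.contig, r.svtype), []).append(r)
    for (contig, svtype), hets in by_key.items():
        hets.sort(key=lambda r: (r.start, r.end))
        # chain-merge consecutive hets closer than merge_gap
        chained: List[SVRecord] = []
        for r in hets:
            # chain fragmented neighbours; near-duplicates (high reciprocal
            # overlap) are left for the homozygote collapse below
            if chained and (r.start - chained[-1].end) < opts.merge_gap \
                    and _reciprocal_overlap(r.interval,
                                            chained[-1].interval) < opts.merge_ro:
                prev = chained[-1]
                chained[-1] = SVRecord(
                    contig, prev.start, max(prev.end, r.end), svtype,
                    alt_sequence=(prev.alt_sequence + r.alt_sequence
                                  if svtype == INS else ""),
                    genotype=HET, quality=max(prev.quality, r.quality),
                    source_id=prev.source_id)
            else:
                chained.append(dataclasses.replace(r))
        # collapse het pairs with high reciprocal overlap into hom-alt
        used = [False] * len(chained)
        for i, a in enumerate(chained):
            if used[i]:
                continue
            for j in range(i + 1, len(chained)):
                if used[j]:
                    continue
                b = chained[j]
                if svtype == INS:
                    match = (abs(a.start - b.start) < opts.merge_gap
                             and min(a.size, b.size) / max(a.size, b.size)
                             >= opts.merge_ro)
                else:
                    match = _reciprocal_overlap(a.interval, b.interval) >= opts.merge_ro
                if match:
                    used[j] = True
                    a.genotype = HOM_ALT
                    break
        out.extend(a for i, a in enumerate(chained) if not used[i])
    out.sort(key=lambda r: (r.contig, r.start, r.end, r.svtype))
    return out


# ---------------------------------------------------------------------------
# Region filtering & evaluation
# ---------------------------------------------------------------------------

def filter_regions(records: Sequence[SVRecord],
                   regions: Sequence[Tuple[str, int, int]]) -> List[SVRecord]:
    """Keep records with >= 50% of their reference span (the insertion
    point for insertions) inside the merged region set."""
    trees: Dict[str, IntervalTree] = {}
    for contig, lo, hi in regions:
        trees.setdefault(contig, IntervalTree()).addi(lo, hi)
    for t in trees.values():
        t.merge_overlaps()
    kept = []
    for r in records:
        tree = trees.get(r.contig)
        if tree is None:
            continue
        lo, hi = (r.start, r.start + 1) if r.svtype == INS else (r.start, r.end)
        inside = sum(min(hi, iv.end) - max(lo, iv.begin)
                     for iv in tree.overlap(lo, hi))
        if inside >= 0.5 * (hi - lo):
            kept.append(r)
    return kept


def _coverage(records, others, svtype, opts) -> List[float]:
    if svtype == INS:
        return match_insertions(records, others, opts)
    return match_overlap(records, others, opts)


def _covered(prop: float, svtype: str, opts: EvalOptions) -> bool:
    # printed wording: coverage "higher than 50%" for DEL/INV,
    # "at least 50%" for INS
    if svtype == INS:
        return prop >= opts.min_coverage
    return prop > opts.min_coverage


def evaluate(calls: Sequence[SVRecord], truth: Sequence[SVRecord],
             opts: Optional[EvalOptions] = None,
             svtypes: Sequence[str] = (DEL, INS, INV)) -> Dict[str, EvalResult]:
    """Match call and truth sets per svtype and count TP/FP/FN.

    Returns one EvalResult per svtype plus a summed "ALL" entry. With
    ``opts.genotype_mode`` the het and hom strata are scored separately
    (after merging) and their counts summed.
    """
    opts = opts or EvalOptions()
    if opts.regions is not None:
        calls = filter_regions(calls, opts.regions)
        truth = filter_regions(truth, opts.regions)
    truth_contigs = {t.contig for t in truth}
    for c in calls:
        if c.contig not in truth_contigs and truth:
            log.warning("contig %s present in calls but absent from truth; "
                        "its calls count as FP", c.contig)
            break
    if opts.genotype_mode:
        calls = merge_for_genotype_eval(calls, opts)
        truth = merge_for_genotype_eval(truth, opts)
        strata = [
            ([c for c in calls if c.genotype == HET],
             [t for t in truth if t.genotype == HET]),
            ([c for c in calls if c.genotype == HOM_ALT],
             [t for t in truth if t.genotype == HOM_ALT]),
        ]
    else:
        strata = [(list(calls), list(truth))]

    results: Dict[str, EvalResult] = {}
    for svtype in svtypes:
        agg = EvalResult(0, 0, 0, 0)
        for scalls, struth in strata:
            sc = [c for c in scalls if c.svtype == svtype]
            st = [t for t in struth if t.svtype == svtype]
            cov_c = _coverage(sc, st, svtype, opts)
            cov_t = _coverage(st, sc, svtype, opts)
            for rec, prop in zip(sc, cov_c):
                if rec.size < opts.min_size:
                    continue
                if _covered(prop, svtype, opts):
                    agg.tp_call += 1
                    agg.tp_call_records.append(rec)
                else:
                    agg.fp += 1
                    agg.fp_records.append(rec)
            for rec, prop in zip(st, cov_t):
                if rec.size < opts.min_size:
                    continue
                if _covered(prop, svtype, opts):
                    agg.tp_truth += 1
                    agg.tp_truth_records.append(rec)
                else:
                    agg.fn += 1
                    agg.fn_records.append(rec)
        results[svtype] = agg
    results["ALL"] = EvalResult(
        sum(r.tp_call for r in results.values()),
        sum(r.fp for r in results.values()),
        sum(r.tp_truth for r in results.values()),
        sum(r.fn for r in results.values()))
    return results


def pr_curve(calls: Sequence[SVRecord], truth: Sequence[SVRecord],
             opts: Optional[EvalOptions] = None,
             svtypes: Sequence[str] = (DEL, INS, INV)
             ) -> Dict[str, List[Tuple[float, float, float, float]]]:
    """Precision-recall curve per svtype: evaluate at every distinct call
    quality threshold (ascending, 0 always included). Points are
    (threshold, precision, recall, f1)."""
    opts = opts or EvalOptions()
    thresholds = sorted({0.0} | {c.quality for c in calls})
    curves: Dict[str, List[Tuple[float, float, float, float]]] = {
        t: [] for t in list(svtypes) + ["ALL"]}
    for thr in thresholds:
        kept = [c for c in calls if c.quality >= thr]
        res = evaluate(kept, truth, opts, svtypes)
        for key, r in res.items():
            curves[key].append((thr, r.precision, r.recall, r.f1))
    return curves


def max_f1(curve: Sequence[Tuple[float, float, float, float]]) -> float:
    return max((pt[3] for pt in curve), default=0.0)


def pr_auc(curve: Sequence[Tuple[float, float, float, float]]) -> float:
    """Trapezoidal area under precision over recall."""
    pts = sorted((r, p) for _, p, r, _ in curve)
    if not pts:
        return 0.0
    area = 0.0
    prev_r, prev_p = 0.0, pts[0][1]
    for r, p in pts:
        area += (r - prev_r) * (p + prev_p) / 2
        prev_r, prev_p = r, p
    return area
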