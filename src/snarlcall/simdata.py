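"""Synthetic truth sets: genomes, SV catalogs, samples, and reads.

The generator emulates a catalog-genotyping experiment: a random genome
carries equal numbers of deletions, insertions, and inversions with an
SV-like size distribution (>= 50 bp), consecutive variants separated by at
least a fixed buffer; per-sample genotypes are drawn uniformly from
hom-ref / het / hom-alt; a second "approximate-breakpoint" catalog carries
1-10 bp errors; paired-end reads are drawn from the sample haplotypes at a
grid of depths with a parametric substitution error model.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dna import revcomp
from .vcfio import VcfVariant

SV_TYPES = ("DEL", "INS", "INV")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclasses.dataclass
class SizeDistribution:
    """Stand-in for an empirical SV size distribution: a mixture of a broad
    log-uniform body, a mobile-element-like peak near 300 bp, and a
    log-uniform tail of large events. All draws are >= ``min_size``."""

    min_size: int = 50
    components: Sequence[Tuple[float, str, float, float]] = (
        (0.60, "loguniform", 50, 1000),
        (0.30, "normal", 300, 30),
        (0.10, "loguniform", 1000, 10000),
    )

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        weights = np.array([c[0] for c in self.components])
        picks = rng.choice(len(self.components), size=n, p=weights / weights.sum())
        out = np.empty(n, dtype=np.int64)
        for i, comp in enumerate(self.components):
            mask = picks == i
            m = int(mask.sum())
            if not m:
                continue
            _, kind, a, b = comp
            if kind == "loguniform":
                out[mask] = np.exp(rng.uniform(math.log(a), math.log(b), m)).astype(int)
            elif kind == "normal":
                out[mask] = np.maximum(self.min_size,
                                       rng.normal(a, b, m).astype(int))
            else:
                raise ValueError(f"unknown size component {kind!r}")
        return np.maximum(out, self.min_size)


@dataclasses.dataclass
class SimConfig:
    genome_length: Optional[int] = None  # None: sized to fit the catalog
    n_per_type: int = 1000
    buffer: int = 500
    size_distribution: SizeDistribution = dataclasses.field(default_factory=SizeDistribution)
    n_samples: int = 3
    depths: Sequence[float] = (1, 3, 7, 10, 13, 20)
    read_length: int = 150
    fragment_mean: float = 400.0
    fragment_sd: float = 50.0
    error_rate: float = 0.002
    max_bp_error: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.buffer < 0:
            raise ValueError("buffer must be >= 0")
        if any(d <= 0 for d in self.depths):
            raise ValueError("depths must be positive")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be a probability")


@dataclasses.dataclass
class TruthSet:
    genome: Dict[str, str]
    truth: List[VcfVariant]          # multi-sample, phased genotypes
    perturbed: List[VcfVariant]      # breakpoint-error catalog, no genotypes
    samples: List[str]
    config: SimConfig


def simulate_genome(length: int, seed) -> str:
    """Uniform-ACGT random genome, deterministic per seed."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    rng = np.random.default_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode()


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _plan_catalog(config: SimConfig, rng: np.random.Generator
                  ) -> List[Tuple[str, int, int]]:
    """(svtype, ref_span, margin-before) per variant, shuffled across types."""
    types = np.repeat(SV_TYPES, config.n_per_type)
    rng.shuffle(types)
    sizes = config.size_distribution.sample(rng, len(types))
    plan = []
    for svtype, size in zip(types, sizes):
        span = 0 if svtype == "INS" else int(size)
        gap = config.buffer + int(rng.integers(1, config.buffer // 2 + 2))
        plan.append((str(svtype), span, gap, int(size)))
    return plan


def required_genome_length(config: SimConfig, seed=None) -> int:
    """Length needed to place the default catalog (deterministic per seed)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    plan = _plan_catalog(config, rng)
    return sum(span + gap + 1 for _, span, gap, _ in plan) + 2 * config.buffer


def simulate_svs(genome: str, config: SimConfig,
                 rng: Optional[np.random.Generator] = None,
                 contig: str = "chr1") -> List[VcfVariant]:
    """Place the SV catalog on ``genome`` and draw per-sample genotypes.

    Consecutive records are separated by at least ``config.buffer`` bp
    (REF-span to REF-span). Raises when the genome is too short (simulate a
    longer genome or reduce n_per_type).
    """
    rng = rng or np.random.default_rng(config.seed)
    plan = _plan_catalog(config, rng)
    samples = [f"s{i}" for i in range(config.n_samples)]
    records = []
    cursor = config.buffer  # 0-based index of next usable base
    for i, (svtype, span, gap, size) in enumerate(plan):
        pad0 = cursor + gap          # 0-based index of the padding base
        start = pad0 + 1             # event interval [start, start+span)
        end = start + span
        if end + config.buffer > len(genome):
            raise ValueError(
                f"genome too short after {i} of {len(plan)} variants; "
                f"simulate a genome of at least {required_genome_length(config)} bp")
        pad = genome[pad0]
        if svtype == "DEL":
            ref, alt = pad + genome[start:end], pad
            svlen = -size
        elif svtype == "INV":
            ref, alt = pad + genome[start:end], pad + revcomp(genome[start:end])
            svlen = 0
        else:
            ins = _random_seq(rng, size)
            ref, alt = pad, pad + ins
            svlen = size
        sample_data = {}
        for s in samples:
            gt = [(0, 0), (0, 1), (1, 1)][int(rng.integers(3))]
            if gt == (0, 1) and rng.integers(2):
                gt = (1, 0)
            sample_data[s] = {"GT": gt, "phased": True}
        records.append(VcfVariant(
            contig=contig, pos=pad0 + 1, vid=f"sv{i}_{svtype}",
            ref=ref, alts=(alt,),
            info={"SVTYPE": svtype, "END": end, "SVLEN": svlen},
            samples=sample_data))
        cursor = end
    return records


def perturb_breakpoints(genome: str, records: Sequence[VcfVariant],
                        config: SimConfig,
                        rng: Optional[np.random.Generator] = None
                        ) -> List[VcfVariant]:
    """Inject 1-10 bp breakpoint errors and drop genotype columns.

    Deletions/inversions: one or both breakpoints shifted by 1..max_bp_error
    bp. Insertions: position shifted, or the sequence shortened at a flank,
    by the same amounts. REF/ALT are recomputed from the genome so records
    stay internally consistent; perturbations that would shrink an SV below
    50 bp are re-drawn.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    emax = config.max_bp_error
    out = []
    for rec in records:
        svtype = rec.info["SVTYPE"]
        pad0 = rec.pos - 1
        start, end = pad0 + 1, int(rec.info["END"])
        if emax == 0:
            new = dataclasses.replace(rec, samples={})
            out.append(new)
            continue
        for _ in range(100):
            if svtype in ("DEL", "INV"):
                which = rng.integers(3)  # start / end / both
                ds = int(rng.integers(1, emax + 1)) * (1 if rng.integers(2) else -1)
                de = int(rng.integers(1, emax + 1)) * (1 if rng.integers(2) else -1)
                s2 = start + (ds if which in (0, 2) else 0)
                e2 = end + (de if which in (1, 2) else 0)
                if s2 < 1 or e2 + 1 > len(genome) or e2 - s2 < 50:
                    continue
                pad = genome[s2 - 1]
                seg = genome[s2:e2]
                alt = pad if svtype == "DEL" else pad + revcomp(seg)
                out.append(VcfVariant(rec.contig, s2, rec.vid, pad + seg, (alt,),
                                      info={"SVTYPE": svtype, "END": e2,
                                            "SVLEN": (-(e2 - s2) if svtype == "DEL"
                                                      else 0)}))
                break
            else:  # INS: shift the site or trim a flank of the sequence
                seq = rec.alts[0][1:]
                d = int(rng.integers(1, emax + 1))
                mode = rng.integers(3)  # shift / trim left / trim right
                s2, seq2 = start, seq
                if mode == 0:
                    s2 = start + d * (1 if rng.integers(2) else -1)
                elif mode == 1:
                    seq2 = seq[d:]
                else:
                    seq2 = seq[:-d]
                if s2 < 1 or s2 + 1 > len(genome) or len(seq2) < 50:
                    continue
                pad = genome[s2 - 1]
                out.append(VcfVariant(rec.contig, s2, rec.vid, pad, (pad + seq2,),
                                      info={"SVTYPE": "INS", "END": s2,
                                            "SVLEN": len(seq2)}))
                break
        else:
            raise RuntimeError(f"{rec.vid}: could not draw a valid perturbation")
    return out


def apply_genotypes(genome: str, records: Sequence[VcfVariant], sample: str
                    ) -> Tuple[List[str], List[List[Tuple[int, int, int, int]]]]:
    """Splice a sample's phased alleles into two haplotype sequences.

    Returns (haplotypes, liftover) where liftover[h] lists
    (hap_start, hap_end, ref_start, ref_end) identity blocks mapping each
    haplotype back to the reference. Overlapping records are an error.
    """
    recs = sorted(records, key=lambda r: r.pos)
    for a, b in zip(recs[:-1], recs[1:]):
        if int(a.info["END"]) > b.pos - 1:
            raise ValueError(f"records {a.vid} and {b.vid} overlap")
    haplotypes = []
    liftovers = []
    for h in (0, 1):
        parts = []
        table = []
        cursor = 0
        hap_pos = 0
        for rec in recs:
            gt = rec.genotype(sample)
            if gt is None or gt[h] != 1:
                continue
            svtype = rec.info["SVTYPE"]
            start, end = rec.pos, int(rec.info["END"])  # event [start,end) 0-based
            parts.append(genome[cursor:start])
            table.append((hap_pos, hap_pos + (start - cursor), cursor, start))
            hap_pos += start - cursor
            if svtype == "DEL":
                pass
            elif svtype == "INV":
                parts.append(revcomp(genome[start:end]))
                hap_pos += end - start
            else:
                ins = rec.alts[0][1:]
                parts.append(ins)
                hap_pos += len(ins)
            cursor = end
        parts.append(genome[cursor:])
        table.append((hap_pos, hap_pos + (len(genome) - cursor), cursor, len(genome)))
        haplotypes.append("".join(parts))
        liftovers.append(table)
    return haplotypes, liftovers


def simulate_reads(haplotypes: Sequence[str], depth: float, config: SimConfig,
                   rng: Optional[np.random.Generator] = None,
                   name_prefix: str = "read"
                   ) -> List[Tuple[str, str, str, str, str]]:
    """Paired-end reads at total depth ``depth`` split evenly across the
    haplotypes: fragments uniform along each haplotype, mates from opposite
    strands at the fragment ends, i.i.d. substitution errors at
    ``config.error_rate``. Returns (name, seq1, qual1, seq2, qual2)."""
    rng = rng or np.random.default_rng(config.seed + 2)
    rl = config.read_length
    q = 40 if config.error_rate <= 0 else min(
        40, int(round(-10 * math.log10(config.error_rate))))
    qual = chr(33 + q) * rl
    out = []
    idx = 0
    per_hap_depth = depth / len(haplotypes)
    for hi, hap in enumerate(haplotypes):
        if len(hap) < rl:
            raise ValueError("haplotype shorter than the read length")
        n_pairs = int(round(per_hap_depth * len(hap) / (2 * rl)))
        frags = rng.normal(config.fragment_mean, config.fragment_sd, n_pairs)
        frags = np.clip(frags.astype(int), rl, len(hap))
        starts = rng.integers(0, len(hap) - frags + 1)
        for frag, start in zip(frags, starts):
            r1 = hap[start:start + rl]
            r2 = revcomp(hap[start + frag - rl:start + frag])
            if config.error_rate > 0:
                r1 = _inject_errors(r1, config.error_rate, rng)
                r2 = _inject_errors(r2, config.error_rate, rng)
            out.append((f"{name_prefix}_h{hi}_{idx}", r1, qual, r2, qual))
            idx += 1
    return out


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def generate_truth_set(config: SimConfig, contig: str = "chr1") -> TruthSet:
    """Genome + exact catalog + perturbed catalog, auto-sizing the genome
    when no length is configured."""
    length = config.genome_length or required_genome_length(config)
    genome = simulate_genome(length, config.seed + 7919)
    truth = simulate_svs(genome, config, contig=contig)
    perturbed = perturb_breakpoints(genome, truth, config)
    return TruthSet(genome={contig: genome}, truth=truth, perturbed=perturbed,
                    samples=[f"s{i}" for i in range(config.n_samples)],
                    config=config)


# ---------------------------------------------------------------------------
# The end-to-end simulation experiment
# ---------------------------------------------------------------------------

def run_simulation_experiment(config: SimConfig,
                              catalogs: Sequence[str] = ("exact", "perturbed"),
                              svtypes: Sequence[str] = SV_TYPES,
                              samples: Optional[Sequence[str]] = None,
                              progress: bool = False) -> pd.DataFrame:
    """Full loop: simulate -> build graph per catalog -> map reads at each
    depth -> pack -> genotype -> score against the exact truth.

    Returns a tidy table (depth, catalog, sample, svtype, mode, precision,
    recall, f1, max_f1)."""
    from .genotyper import CallerParams, genotype_graph
    from .graphmodel import build_graph
    from .mapsupport import GraphIndex, compute_pack, map_read_pair
    from .snarls import find_snarls
    from . import sveval

    ts = generate_truth_set(config)
    contig = next(iter(ts.genome))
    genome = ts.genome[contig]
    catalog_records = {"exact": ts.truth, "perturbed": ts.perturbed}
    graphs = {}
    for cat in catalogs:
        recs = [dataclasses.replace(r, samples={}) for r in catalog_records[cat]]
        g = build_graph(ts.genome, recs)
        graphs[cat] = (g, GraphIndex(g), find_snarls(g), recs)

    rng = np.random.default_rng(config.seed + 1000)
    rows = []
    use_samples = list(samples) if samples is not None else ts.samples
    for sample in use_samples:
        haps, _ = apply_genotypes(genome, ts.truth, sample)
        truth_svs = sveval.normalize(ts.truth, ts.genome, sample=sample)
        for depth in config.depths:
            reads = simulate_reads(haps, depth, config, rng,
                                   name_prefix=f"{sample}_d{depth}")
            for cat in catalogs:
                g, index, snarls, recs = graphs[cat]
                alns = []
                for name, s1, _, s2, _ in reads:
                    a1, a2 = map_read_pair(g, index, name, s1, s2)
                    alns.append(a1)
                    alns.append(a2)
                pack = compute_pack(g, alns)
                called = genotype_graph(g, pack, recs, CallerParams(),
                                        sample_name=sample, snarls=snarls)
                call_svs = sveval.normalize(called, ts.genome, sample=sample)
                opts = sveval.EvalOptions()
                curves = sveval.pr_curve(call_svs, truth_svs, opts)
                for mode in ("presence", "genotype"):
                    gopts = dataclasses.replace(opts, genotype_mode=(mode == "genotype"))
                    res = sveval.evaluate(call_svs, truth_svs, gopts)
                    for svtype in list(svtypes) + ["ALL"]:
                        r = res[svtype]
                        rows.append({
                            "depth": depth, "catalog": cat, "sample": sample,
                            "svtype": svtype, "mode": mode,
                            "precision": r.precision, "recall": r.recall,
                            "f1": r.f1,
                            "max_f1": (sveval.max_f1(curves[svtype])
                                       if mode == "presence" else float("nan")),
                        })
                if progress:  # pragma: no cover
                    print(f"{sample} depth={depth} catalog={cat} done")
    return pd.DataFrame(rows)
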