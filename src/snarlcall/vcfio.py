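"""File-format plumbing: FASTA, VCF, FASTQ, BED.

Everything in-memory uses lightweight records (:class:`VcfVariant`); pysam,
pyfaidx and Biopython handle the on-disk formats.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta


@dataclasses.dataclass
class VcfVariant:
    """One VCF record, 1-based position, as parsed from disk or built in memory."""

    contig: str
    pos: int  # 1-based
    vid: str
    ref: str
    alts: tuple
    info: dict = dataclasses.field(default_factory=dict)
    qual: Optional[float] = None
    # per-sample FORMAT data: {sample: {"GT": (a, b), "phased": bool, "DP": ..,
    # "AD": (..), "GQ": ..}}; GT allele None means no-call.
    samples: dict = dataclasses.field(default_factory=dict)

    def genotype(self, sample: str):
        data = self.samples.get(sample)
        return None if data is None else data.get("GT")


def read_fasta(path: str) -> dict:
    """Load a FASTA file into a {name: sequence} dict (uppercased)."""
    fa = Fasta(path, rebuild=False)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(path: str, records: Mapping[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        path,
        "fasta",
    )


def read_vcf(path: str) -> list:
    """Read all records of a VCF (plain or bgzipped) into VcfVariant objects."""
    out = []
    with pysam.VariantFile(path) as vf:
        sample_names = list(vf.header.samples)
        for rec in vf:
            samples = {}
            for s in sample_names:
                sd = rec.samples[s]
                entry = {"GT": tuple(sd.get("GT") or (None, None)),
                         "phased": bool(sd.phased)}
                for key in ("DP", "AD", "GQ"):
                    if key in sd and sd.get(key) is not None:
                        entry[key] = sd[key]
                samples[s] = entry
            info = dict(rec.info)
            info["END"] = rec.stop  # pysam: END is accessed via rec.stop
            out.append(
                VcfVariant(
                    contig=rec.contig,
                    pos=rec.pos,
                    vid=rec.id or f"{rec.contig}_{rec.pos}",
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    info=info,
                    qual=rec.qual,
                    samples=samples,
                )
            )
    return out


_INFO_DEFS = {
    "SVTYPE": ("1", "String", "Type of structural variant"),
    "END": ("1", "Integer", "End position of the variant described in this record"),
    "SVLEN": (".", "Integer", "Difference in length between REF and ALT alleles"),
    "SEQ": ("1", "String", "Inserted sequence for symbolic insertions"),
}

_FORMAT_DEFS = {
    "GT": ("1", "String", "Genotype"),
    "DP": ("1", "Integer", "Total read support at the site"),
    "AD": ("R", "Integer", "Read support for each allele"),
    "GQ": ("1", "Integer", "Genotype quality"),
}


def build_vcf_header(contigs: Mapping[str, int], samples: Sequence[str] = ()) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for key, (number, vtype, desc) in _INFO_DEFS.items():
        header.info.add(key, number, vtype, desc)
    for key, (number, vtype, desc) in _FORMAT_DEFS.items():
        header.formats.add(key, number, vtype, desc)
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(path: str, variants: Iterable[VcfVariant], contigs: Mapping[str, int],
              samples: Sequence[str] = ()) -> None:
    """Write records as a plain-text VCF 4.2 file."""
    header = build_vcf_header(contigs, samples)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for v in variants:
            rec = vf.new_record(
                contig=v.contig,
                start=v.pos - 1,
                alleles=(v.ref,) + tuple(v.alts),
                id=v.vid,
            )
            rec.qual = v.qual
            for key, value in v.info.items():
                if key == "END":
                    rec.stop = int(value)
                else:
                    rec.info[key] = value
            for s in samples:
                data = v.samples.get(s, {})
                gt = data.get("GT", (None, None))
                rec.samples[s]["GT"] = gt
                rec.samples[s].phased = bool(data.get("phased", False))
                for key in ("DP", "AD", "GQ"):
                    if key in data:
                        rec.samples[s][key] = data[key]
            vf.write(rec)


def read_bed(path: str) -> list:
    """Read a 3+ column BED file into (contig, start, end) tuples."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
            regions.append((fields[0], int(fields[1]), int(fields[2])))
    return regions


def write_fastq(path: str, reads: Iterable[tuple]) -> None:
    """Write (name, sequence, quality-string) triples as FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str) -> Iterator[tuple]:
    """Yield (name, sequence, quality-string) from a FASTQ file."""
    for rec in SeqIO.parse(path, "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield rec.id, str(rec.seq), qual
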