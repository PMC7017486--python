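# snarlcall

Structural-variant (SV) genotyping in pangenome variation graphs, at desk
scale. Given a reference genome and a catalog of known SVs (deletions,
insertions, inversions in a VCF), `snarlcall` embeds the catalog into a
bidirected sequence graph, maps short paired-end reads to that graph, and
decides each sample's genotype at every site from the read support of the
site's candidate haplotype paths. It also ships the matching benchmarking
machinery (overlap- and alignment-based call-set comparison) and a
simulator that generates the synthetic truth sets the package is validated
on.

It is aimed at people who want a transparent, fully testable
re-implementation of graph-based SV genotyping — for teaching, method
exploration, or as an executable specification — rather than a
production-scale caller.

## The method

**Graph.** Reference contigs are split into nodes at every variant
breakpoint; each VCF allele becomes an embedded walk: a deletion is a
bypass edge, an insertion a new node, an inversion a pair of edges entering
the reference segment in reverse orientation (no sequence duplication).
Nodes in the bidirected graph have two *sides*; edges join sides, so walks
may traverse nodes in either orientation.

**Sites.** A site of variation is a *snarl*: a pair of sides (x, y) such
that removing all edges incident to the opposite sides x′ and y′ separates
a component X containing x and y from the rest of the graph, minimal in
the sense that no side z inside X forms such a pair with x (or with y).
Genotyping operates on top-level snarls whose ends lie on a reference
path.

**Support.** Reads are mapped with a seed-and-extend graph mapper (exact
k-mer seeds on node- and junction-spanning walks, edlib alignment of the
read against candidate walks; the mapping quality scores the edit-distance
gap to the second-best placement). The *pack* index counts, for every
alignment with MAPQ ≥ 5, the reads covering each base of each node and
each edge.

**Genotype.** For variants v1…vk inside a snarl there are |v1|·…·|vk|
candidate haplotype walks (alleles with average support < 1 are
pre-filtered when this product exceeds 500 000). Each walk's support is
the mean of its node-base and edge counts, and with best and second-best
supported walks s₁ ≥ s₂ the site is called

* homozygous for the best walk if s₁ > 1 and s₁ > B·s₂ (B = 6),
* else heterozygous if s₂ > 1,
* else homozygous for the best walk if s₁ > 1, otherwise no-call.

**Evaluation.** Calls and truth are normalized (multi-allelics split,
alleles trimmed, inversions recognized by aligning the reverse-complement
of ALT against REF). Deletions/inversions match by genomic overlap
(partners with reciprocal overlap ≥ 10% must jointly cover > 50% of a
record); insertions match by position (≤ 20 bp apart) and Smith–Waterman
alignment of the inserted sequences (≥ 50% of the sequence must align).
Records ≥ 50 bp are counted as TP/FP/FN; precision-recall curves sweep the
call quality.

## Worked example

Simulate a tiny truth set (3 SVs per type, one sample, 20× reads) and run
the full pipeline:

```bash
snarlcall sim -o sim --n-per-type 3 --n-samples 1 --depths 20 --seed 4
snarlcall construct -r sim/genome.fa -v sim/truth.vcf -o graph.json
snarlcall map -g graph.json -1 sim/s0_d20_1.fq -2 sim/s0_d20_2.fq -o aln.jsonl
snarlcall pack -g graph.json -a aln.jsonl -o pack.json
snarlcall call -g graph.json -k pack.json -v sim/truth.vcf -o calls.vcf --sample s0
snarlcall sveval --calls calls.vcf --truth sim/truth.vcf -r sim/genome.fa --sample s0
```

The tool logs each stage:

```
INFO snarlcall: graph: 25 nodes, 36 edges, 9 variants
INFO snarlcall: mapped 2030 reads
INFO snarlcall: pack: 304347 covered bases
INFO snarlcall: wrote 9 genotyped records
INFO snarlcall: metrics written to sveval.metrics.tsv
```

`calls.vcf` carries one genotyped record per catalog record, e.g.

```
#CHROM  POS   ID       ...  QUAL  FORMAT       s0
chr1    1132  sv0_DEL  ...  8     GT:DP:AD:GQ  0/1:25:11,14:8
chr1    2031  sv1_DEL  ...  12    GT:DP:AD:GQ  0/0:15:14,0:12
chr1    5341  sv4_INV  ...  7     GT:DP:AD:GQ  0/1:18:10,8:7
```

`sv0_DEL` is called heterozygous with total support 25 split 11 (reference
walk) to 14 (deletion walk); `sv1_DEL` homozygous reference with all 15
supporting reads on the reference walk. The benchmark table
(`sveval.metrics.tsv`) confirms every simulated genotype was recovered on
this clean 20× run:

```
svtype  TP  TP_truth  FP  FN  precision  recall  f1   max_f1  genotyping_ratio
DEL     1   1         0   0   1.0        1.0     1.0  1.0     1.0
INS     2   2         0   0   1.0        1.0     1.0  1.0     1.0
INV     3   3         0   0   1.0        1.0     1.0  1.0     1.0
ALL     6   6         0   0   1.0        1.0     1.0  1.0     1.0
```

(TP counts presence-level matches for records that are non-reference in
sample s0; this seed has 1 deleted, 2 inserted, and 3 inverted alleles
present.)

The same loop is available in one shot — `snarlcall experiment` runs
simulate → construct → map → pack → call → evaluate over a grid of depths
and both the exact and the breakpoint-perturbed catalog, and writes a tidy
metrics table.

## Layout

```
src/snarlcall/
  graphmodel.py   bidirected graph, construction from FASTA+VCF, JSON I/O
  snarls.py       snarl detection and top-level site selection
  mapsupport.py   seed-and-extend graph mapper, pack (support) index
  genotyper.py    traversal enumeration, support-ratio genotyping, VCF out
  sveval.py       call-set vs truth-set benchmarking, PR curves
  simdata.py      genome/SV/read simulator and the end-to-end experiment
  cli.py          the `snarlcall` command
docs/methods.md   model, parameters, numerical choices, limitations
```
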