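# Methods

This note records the model the package implements, the parameters that
matter, the numerical and design choices made where more than one
reasonable option existed, and what the synthetic data do and do not
establish about behaviour on real sequencing data.

## Graph model and construction

The substrate is a bidirected sequence graph: nodes carry DNA, each node
has a left and a right *side*, and edges join sides, so a walk can
traverse a node forward or in reverse (spelling its reverse complement).
Reference contigs are embedded as paths whose concatenated node sequences
reproduce the input FASTA byte-for-byte; this invariant is asserted in
construction tests.

Each VCF record is resolved to a half-open replacement interval by
right-trimming then left-trimming shared REF/ALT sequence (symbolic
`<DEL>`/`<INV>` alleles use END or SVLEN; `<INS>` requires an explicit
sequence). Per allele, the embedding is chosen by what the allele sequence
is: equal to the reference span → the reference walk; empty → a bypass
edge (deletion); the exact reverse complement → two orientation-reversing
edges reusing the reference nodes (inversion, no sequence duplication);
anything else → new node(s) carrying the allele (insertions, SNVs,
replacements). Every allele is stored as an anchored walk from the node
ending at the interval start to the node starting at the interval end, so
the genotyper can splice alleles into site traversals without re-deriving
coordinates.

Coordinates are 0-based half-open internally; VCF positions are 1-based.
Reference segments longer than `max_node_length` (default 1024 bp, the
same order as the chunked nodes of production graph toolkits) are split
left-to-right. Variants touching a contig boundary are rejected: every
site needs a reference anchor on both sides. Overlapping records are
embedded whenever their breakpoints can coexist after splitting;
combinations of alleles that cannot be walked (edge-inconsistent splices)
are dropped at traversal time rather than at construction.

## Snarl detection

A snarl is a pair of sides (x, y) bounding a site of variation. The
implemented criteria, on the "biedged" view (node-internal links plus
graph edges):

1. removing all edges incident to x′ and y′ leaves x and y in one
   component X, and no removed edge's far endpoint lies in X;
2. the far-endpoint sets of the x′- and y′-removals are disjoint, and a
   **node-simple** bidirected walk leaving through x can arrive at y;
3. minimality: no side z in X forms a separating pair with x, nor with y.

Criterion 2 is the package's sharpening of the separation idea: without
it, "outward-facing" pairs — the two branch-entry sides of a bubble, or
the complement pair around a multi-node insertion chain — satisfy
criterion 1 literally yet bound no site that a traversal can cross. Walk
simplicity matters because a graph with two inversions on one contig
admits non-simple walks that flip strand downstream and double back;
requiring each node at most once matches what a site traversal is. At a
graph tip nothing is removed and separation holds vacuously, which makes
an unflanked bubble a snarl, consistent with how the same bubble behaves
inside a longer contig.

The search is definition-driven rather than the linear-time cactus
decomposition: every side with an edge is a candidate boundary; partners
are scanned outward in breadth-first order from each candidate, and a
candidate pair is abandoned as soon as its growing component swallows an
already-found nearer partner (which proves non-minimality). Two scale
bounds exist, both inactive on small graphs: a cap on component size
(`bound`, default 400 sides — far above any site our graphs produce, and
never reached on the ≤ 30-node graphs where the search is tested against
exhaustive evaluation of the definition over all side pairs) and a step
budget in the simple-walk test (20 000 expansions). Genotyping uses the
top-level snarls (no parent, both ends on a reference path); a variant
belongs to the snarl whose interior reference interval contains its
trimmed breakpoint span, which is stable under node splitting.

## Read mapping and the pack index

The mapper is deliberately small. An exact k-mer index (k = 16) stores
every k-mer starting at every base of every node in both orientations,
extended across junctions when it overhangs the node end, so
reverse-strand reads and reads crossing variant edges seed directly.
Seeds vote for (node, diagonal) anchors; around each of the top anchors
(≤ 4) candidate walks are enumerated through the graph (≤ 16 per anchor)
and the read is aligned to each walk with edlib in infix mode. The best
placement wins; mapping quality is `min(60, 10·(d₂ − d₁))` over distinct
placements (d = edit distance), 0 on ties, 60 when no second placement
exists; placements below 70% identity are discarded as unmapped. Edit
distance stands in for an affine-gap score deliberately — it keeps the
mapper to one fast primitive, and the module's correctness properties
(unique placement of error-free reads, MAPQ 0 on exact repeats, coverage
recovery at simulated depth) hold under it.

The pack index counts reads per node base and per edge, one pass over the
alignments, including only alignments with MAPQ ≥ 5. Deletions in the
read do not cover the skipped graph bases; read insertions and clips add
no coverage; each mate of a pair counts independently. The index is
order-independent and conserves mass (total counted bases equal the sum
of covered interval lengths over qualifying alignments), both tested.

## Genotyping

For the variants v1…vk in a top-level snarl, the Cartesian product of
allele choices is rendered as walks by splicing allele walks into the
reference chain; inconsistent splices are dropped and duplicate walks
deduplicated. If the product exceeds `max_traversals` (500 000), alleles
whose own anchored walk has average support below 1 are removed per
variant (the reference allele and the best-supported allele always
survive) before enumeration; a site still too large is skipped as a
no-call.

A walk's support is the average over its interior node bases and its
edges; the snarl boundary nodes are excluded, and a walk with no interior
node (a pure deletion) is averaged over edges alone. Inside
`genotype_snarl` the averaging additionally masks out elements shared by
*every* candidate walk, extending the same rationale as the boundary
exclusion: shared elements collect coverage from reads of all alleles and
cannot discriminate. This masking is what makes reverse-edge-embedded
inversions decidable — their traversals reuse the reference nodes, so only
the four breakpoint edges differ between the reference and inverted
walks, and the genotype is read off those edges. When every element is
shared (a single-traversal site) the mask falls back to the plain
average.

Calling rules, applied in order with strict comparisons (`min_support`
default 1, bias `B` default 6): homozygous when s₁ > 1 and s₁ > B·s₂;
else heterozygous when s₂ > 1; else homozygous for the only supported
walk when s₁ > 1; else no-call. The third rule fills the gap the first
two leave open (s₁ > 1, ratio ≤ B, s₂ ≤ 1): the best walk is then the
only supported haplotype. Ties in support break deterministically,
reference allele first, then lexicographically by allele indices.

The genotype quality is a heuristic Phred-like score,
`GQ = round(10·log₁₀((s₁+s₂)·min(1, s₁/(B·s₂+ε)) + 1))`: monotone in
total support and in the homozygosity ratio. Downstream evaluation only
thresholds it, so any monotone score yields the same PR sweep; the exact
form carries no calibration claim. Output records carry GT, DP (rounded
s₁+s₂), AD (per-allele support from the chosen walks) and GQ; uncalled
sites emit `./.`.

## Call-set evaluation

Records are normalized (multi-allelics split; right- then left-trimming;
types inferred from allele lengths, with a local-alignment check — more
than 80% of revcomp(ALT) aligning to REF, both > 10 bp — reclassifying
inversions). Deletions and inversions match by overlap: partners of the
same type with reciprocal overlap ≥ 0.10 and size > 1 bp contribute, and
a record is *covered* when the union of partner intervals exceeds 50% of
its span (union, not best-single-partner, so fragmented representations
still match). Insertions pair within 20 bp and are covered when at least
50% of their inserted sequence lies inside the best local alignment
against a partner's sequence (Smith–Waterman, match +1, mismatch −1, gap
open −3, extend −1; sequence pairs beyond 4·10⁶ cells fall back to edlib
infix alignment). Coverage uses any record larger than 1 bp, but only
records ≥ `min_size` (default 50 bp) are counted as TP, FP or FN;
precision counts covered calls, recall covered truth records. A
`min_coverage` of 0.9 replicates the stricter matching variant with one
flag.

Genotype-level scoring first merges consecutive heterozygotes closer than
20 bp (fragmented calls), then collapses duplicate heterozygous pairs with
reciprocal overlap ≥ 0.80 into a homozygote — near-duplicates are
deliberately exempt from the chain merge so the collapse can see them —
and scores the het and hom strata separately, summing counts. PR curves
evaluate at every distinct call quality (plus 0); max-F1 and a trapezoidal
area over recall summarize them. Region filtering keeps records with
≥ 50% of their reference span (the insertion point for insertions) inside
the merged region set; the 50% rule is this package's choice, as only the
region sets themselves, not the overlap rule, are standardized.

## Synthetic data

The generator emulates a catalog-genotyping study: a uniform-ACGT random
genome; equal numbers of deletions, insertions and inversions (default
1000 each) with every pair of consecutive records separated by at least a
500 bp buffer (realized gaps add a jitter of up to buffer/2); per-sample
genotypes i.i.d. uniform over hom-ref/het/hom-alt for 3 samples;
a companion "approximate-breakpoint" catalog in which deletion/inversion
breakpoints shift by 1–10 bp and insertions shift or lose 1–10 bp at a
flank, re-spelled from the genome so REF fields stay consistent; and
paired-end 150 bp reads (fragments ~N(400, 50²)) at depths 1–20×, with
i.i.d. substitution errors at 0.2% per base. Sizes come from a mixture
standing in for an empirical SV size distribution — 60% log-uniform on
[50, 1000], 30% ~N(300, 30) for the mobile-element-like peak, 10%
log-uniform on [1000, 10000], floored at 50 bp — configurable as a table.
The genome auto-sizes to fit the catalog when no length is given.

What this emulates well: allele-specific read support, breakpoint
uncertainty in the catalog, depth titration, strand-symmetric mapping.
What it omits: repeats and segmental duplications (a uniform random
genome is nearly repeat-free at these scales, so mapping ambiguity is far
rarer than in real genomes), indel sequencing errors, base-quality
structure, GC bias, and SVs at reference gaps. Consequently the
near-perfect accuracies at 20× on clean simulations bound what the
algorithm can do when mapping is easy; they are not estimates of accuracy
on real data, where repeat-mediated mis-mapping dominates the error
budget.

## Scales used in the shipped experiments

The end-to-end validation runs at reduced size by design: the scaled
simulation experiment uses 50 SVs per type on a 300 kb genome at 20×
(exact and perturbed catalogs, one sample), the depth trend uses 20 SVs
per type at 1×/3×/20× over three seeds, and snarl-search equivalence uses
200 random graphs of ≤ 30 nodes. These sizes exercise every code path —
multi-node inversions, insertion chains, overlapping records, ambiguous
reads — while keeping the full suite in the minutes range on one core.

## Known limitations

* Ploidy is fixed at 2; multi-sample joint calling and novel-variant
  discovery (graph augmentation) are out of scope.
* Cyclic graphs and snarl classification (ultrabubbles etc.) are not
  handled; the definitional search targets the acyclic graphs produced by
  VCF embedding, and the component bound caps detectable site size on
  large graphs.
* The mapper has no paired-end rescue and bounded walk enumeration
  (64 walks); extremely dense variant clusters can exhaust it and read as
  ambiguity (MAPQ 0).
* The GQ score is uncalibrated by design; only its ordering is
  meaningful.
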