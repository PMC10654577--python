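# Methods

## The problem and the data model

Spot-barcoded spatial transcriptomics libraries contain full-length
TCR cDNA that long-read sequencing can span entirely, at the cost of
a high per-base error rate. The pipeline's job is to recover, per
spot, which T-cell clones (CDR3 amino-acid clonotypes) are present
and in what molecular abundance, and then to quantify the spatial
organization of the repertoire.

A read is modeled as

    R1 adapter (22 nt) + spot barcode (16 nt) + UMI (12 nt)
      + transcript + revcomp(TSO, 22 nt)

optionally reverse-complemented, with iid per-base substitution,
insertion and deletion errors. The transcript is
`leader + V + junction body + J + C`, where the junction (the CDR3)
starts at the conserved cysteine codon that ends the V segment and
stops before the Phe/Trp-Gly anchor motif that begins the J segment.

## Synthetic data generator

The generator is first-class, tested code; it defines the conditions
under which every downstream claim is checked.

* **Spots** — a hexagonal lattice (spacing 100 abstract units), one
  random 16-mer barcode per spot; cells per spot ~ 1 + Poisson(5);
  total (short-read) UMIs per spot ~ Poisson(200 × cells). The
  whitelist is exactly the spot-barcode set.
* **References** — a closed toy set per locus (TRA, TRB): 4 V
  segments of 200–300 nt ending in the Cys codon `TGT`, 3 J segments
  of 50 nt starting with a `TTY-GG` anchor, 2 C segments of 150 nt;
  generated once from a fixed seed and shipped as a FASTA fixture
  (`data/toy_tcr_refs.fasta`, regenerated bit-identically by
  `toy_references()`). Each V also carries a private 350 nt leader
  emulating the 5′ UTR of captured full-length cDNA, which puts
  transcripts in the ~800 nt regime of real libraries.
* **Clones** — junctions are `TGT` + 4–19 random non-stop codons
  (5–20 aa). Planted CDR3s are pairwise ≥ 2 amino-acid edits apart so
  clonotype recovery is well-posed, and junction lengths stay inside
  the default repertoire length filter (5–30 aa). Spatial pattern:
  *expanded* clones occupy a contiguous patch grown by breadth-first
  search on the hex 6-neighborhood (hence Delaunay-connected);
  *dispersed* clones sample spots uniformly. Per occupied spot the
  clone plants 1 + Poisson(1) UMI molecules.
* **Reads** — per molecule either 1 + Poisson(mean_reads_per_umi − 1)
  reads, or, when a `reads_per_clone` range is given, a per-clone
  total drawn uniformly from that range and spread multinomially over
  the clone's molecules (each gets ≥ 1). Half the reads are
  reverse-complemented.
* **Error channel** — position-independent; defaults
  substitution 2.844%, insertion 0.948%, deletion 0.948%, totalling
  4.74% per base — the uncorrected error level of R9-pore nanopore
  TCR libraries, split substitution-heavy (60/20/20) as is typical
  for that chemistry. Rates are checked in tests against binomial
  bands at 10⁴–10⁵ bases.

What the generator does **not** emulate: homopolymer-biased or
signal-level error structure, quality-score realism (a constant Q
fills `qual`), chimeric artifacts beyond simple adapter fusions,
ambient/background off-target transcripts, and real repertoire
abundance distributions. Passing tests therefore demonstrate the
pipeline's correctness under iid errors and a closed reference, not
performance on real nanopore data.

## Demultiplexing and UMI deduplication

The Read1 adapter is located by semi-global edit-distance alignment
(edlib) on both strands, edit distance ≤ 4 over the 22-mer — a
tolerance chosen to admit the ~5% raw error rate — taking the
lowest-distance, leftmost hit. The 16 bases after the match are
compared against the whitelist; the read is assigned to the unique
barcode at minimal distance ≤ 2, and left unassigned on ties or
misses (conservative by design). UMIs are deduplicated with the
directional rule stated from the higher-count side: edge `u → v` iff
`Hamming(u, v) = 1` and `count(u) ≥ 2·count(v) − 1`; clusters are the
nodes reachable from local maxima processed in descending-count
(lexicographic tie-break) order. Hamming rather than Levenshtein
distance is used, matching the algorithm's standard definition.

## Orientation and splitting

All semi-global matches of the four adapter forms (R1, revcomp(TSO),
TSO, revcomp(R1)) at edit distance ≤ 4 are collected greedily
best-first without overlapping footprints. A valid segment is
`R1 … revcomp(TSO)` or its mirror; each is emitted reoriented to
start at R1 with the 28 nt barcode+UMI window trimmed, so annotation
sees pure transcript. To make the result exactly invariant under
reverse-complementing the input (tie-breaks would otherwise mirror),
detection runs on the lexicographically smaller of the two strands
and segment order is restored afterwards.

## Annotation

Local alignment with affine gaps (match 2, mismatch −4, open −4,
extend −2; Bio.Align.PairwiseAligner). A call requires score ≥ 50 —
high enough that uniform-random 500-mers never call (verified over 20
seeds), low enough that a 25 nt perfect match does. V is searched
over all loci; J and C only in the 3′ remainder of the called V's
locus. `v_identity` is matches / alignment columns. The CDR3 junction
is mapped through the alignment from the V reference's Cys-codon
offset to the J reference's motif offset; this is the IMGT junction
*minus* the J anchor, recorded explicitly since IgBLAST-style tools
report the inclusive junction. D segments are never aligned (the toy
references carry none); externally produced AIRR tables can be
imported instead.

## Clustering and consensus correction

Reads are partitioned by (V, C) call — off-target and V-less reads
are excluded; missing C groups under `(V, "none")`. Within a
partition, greedy centroid clustering visits inserts by descending
length and joins the first matching cluster.

The membership test is junction-aware by design: all reads in a
partition already share V and C, so whole-insert k-mer similarity is
nearly blind to clone identity — at ~5% per-base error two reads of
the *same* clone share only ≈ 0.21 exact 11-mer Jaccard, while two
*different* clones sharing V and C on clean reads share ≈ 0.85. The
decisive signal is the junction, so membership is decided by edit
identity between annotated junctions (`1 − lev/max len ≥ 0.7`: same
clone at 4.74% error scores ≈ 0.91, unrelated junctions ≈ 0.3–0.5).
Reads without an annotated junction fall back to whole-insert k-mer
Jaccard (k = 11, ≥ 0.35) and mostly end up as singletons, passing
through uncorrected. The cluster-purity guard (≥ 99% of clusters
single-clone on synthetic data) validates these defaults.

Consensus is iterative align-and-vote rather than a full partial-order
graph — equivalent at this scale and far simpler. The longest member
seeds the consensus; each member is globally aligned (edlib) to the
running consensus and votes per column over {A, C, G, T, gap}; a gap
never wins a tie, base ties fall back to the current consensus base;
insertions are applied only where a strict majority of members
inserts. Two refinement passes (configurable) stabilize the result.
Members are replaced by the consensus, so read and UMI counts are
conserved.

Error measurement aligns the full C reference semi-globally inside
each read; the rate is (mismatches + inserted + deleted bases) /
alignment columns — indels are counted because nanopore errors are
indel-rich. Reads whose best C alignment exceeds 35% error are
excluded and tallied. Only C segments are assessed: V(D)J
recombination alters the germline V/J.

## Clonotyping and normalization

UMI-collapsed records are filtered (CDR3 length 5–30 aa by default —
spanning plausible human CDR3s — minimum UMI support, V and J
required, stop/ambiguous residues dropped). Distinct CDR3s merge by
single-linkage connected components at `lev < 2`, i.e. at most one
edit: this reconciles the "minimal distance = 2" threshold with
treating CDR3s ≥ 2 edits apart as unique. Clustering is per locus
(optionally per V call); the representative is the longest member,
ties lexicographic; identities are averaged over member records and
per-spot counts summed. Normalization divides each raw per-spot count
by `UMI_c = total short-read UMIs / cells` for that spot; zero-cell
spots are excluded and tallied.

## Spatial metrics

The spot graph is the Delaunay triangulation of in-tissue
coordinates. Edges longer than 3× the median nearest-neighbor
distance are pruned (border artifacts of the convex hull); exact
duplicate coordinates are jittered by 1e-9 × spacing before
triangulation; all-collinear input raises a geometry error advising a
k-nearest fallback. Per clone and occupied spot, `m_b` is the number
of Delaunay neighbors sharing the clone (0 when none). The
clone-level **clonality index** is the *mean* of `m_b` over occupied
spots — the mean (rather than the sum, which is also emitted) keeps
the conventional "> 1" expansion threshold independent of clone size.
The **diversity index** of a spot is the mean over resident distinct
CDR3s of the mean Levenshtein distance to the other residents; this
equals the mean of all ordered off-diagonal pairwise distances, a
fact used as a test identity. A reciprocal-distance variant is
exposed behind a flag without being the default.

Spot classification: `none` without TCR UMIs; `expansion` when a
resident clone has > 5 total UMIs and clonality index > 1;
`diversity` when not expansion, ≥ 2 clones and DI ≥ 3.0; otherwise
`ambiguous`. The DI cutoff 3.0 is a package default meaning "more
than one amino-acid edit beyond the merge radius"; it is configurable
and deliberately conservative.

## Ecosystem analytics

*Cell graph*: Delaunay edges over (deconvolved) cell positions of the
selected feature labels, same machinery as the spot graph.

*Expression enhancement*: per significant gene `e = avg_log2FC + 1`;
step 1 scales the gene's row, `M ← M + |M|·e`; step 2 scales every
gene per spot by `f′ − 1` with `f = exp(x)` (multi-cell-type mode
averages the exponentials) and `f′ = f + (f − 1)·ē`. Two numerical
choices are deliberate: the per-spot update is applied as elementwise
column scaling (a literal transpose product is dimensionally
inconsistent for a genes × spots matrix), and the factor enters as
`(f′ − 1)` so the neutral configuration (e = 0, x = 0) is *exactly*
the identity. The exponent on `e` in the row-scaling step is 1.
Results are clipped at zero.

*Clone × state matrix*: a single-spot clone inherits its spot's state
score vector exactly; multi-spot clones sum over their support. Any
non-negative state × spot table is accepted — whether scores come
from deconvolution likelihoods or signature scoring is upstream's
choice.

*Receptor–ligand co-localization*: spatial profiles of ligand and
receptor are shifted by a 1e-9 pseudocount, normalized to sum 1, and
compared by KL divergence in nats with the ligand as `p`; pairs are
ranked ascending (lowest divergence = strongest co-localization) and
the first 100 kept. Direction, log base and pseudocount are package
conventions, stated here because reasonable alternatives exist.

*Composite T-cell state score*: marker rows are z-scored across
spots (constant rows skipped and tallied); the cytotoxic score is the
unweighted mean z over IL2, IFNG, PRF1, GZMB, GZMK, GZMA, CD69, CD25,
CD38, the exhaustion score over HAVCR2, PDCD1, CTLA4, CXCL8, LAG3,
EOMES, TOX, TIGIT, CD244, NR4A1. Spots without TCR presence are
unscored; otherwise `productive` iff cytotoxic > exhaustion (ties →
exhausted). Z-scoring makes labels invariant to gene-wise affine
rescaling; the unweighted mean is the package's normalization choice.

## Problem sizes and determinism

The standard verification run simulates 100 clones at 20–60 reads
each (~4,000 reads of ~800 nt) on a 225-spot lattice — large enough
for stable error statistics, small enough to run in minutes on one
CPU. All randomness flows from a single integer seed through
`numpy.random.default_rng`; reruns are byte-identical. Tie-breaking
is lexicographic throughout.

## Known limitations

* The annotator is a lightweight aligner, not an IgBLAST
  re-implementation: no frameshift analysis, no FR/CDR1-2
  delineation, no D-segment calls, no species logic.
* Clustering ignores spatial position; reads from different spots but
  the same clone are corrected together (this is what conserves
  counts, but it cannot separate identical CDR3s arising twice
  independently).
* Paired-chain (TRA+TRB) clone pairing and nucleotide-level
  clonotyping are out of scope.
* The expansion/diversity thresholds are heuristics on normalized
  counts; on shallow data most spots will be `ambiguous`.
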