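# Methods

## Scope and model

`repeatscreen` treats repeat discovery as a comparison of motif abundances
across accessions. The genome of each accession is modelled as a dosage
multiset of subgenomes (RR, RRDD, RRDDB, …); a repeat family confined to
one subgenome should show a read-level abundance proportional to that
subgenome's dosage and near zero in accessions lacking it. No assembly of
the underlying genomes is attempted: every statistic is computed directly
on shotgun reads.

### Genome proportion

For motif *m* and accession *a*,
`p(m, a) = |{reads containing an alignment of m, either strand, with at
most max_mismatches substitutions}| / |reads|`. The read-level definition
(count matching reads, not occurrences) is the default because it is
robust to tandem multiplicity inside a single read; a base-level variant
(alignment occurrences × k / total bases) is available on the match result
for reporting. Defaults: k = 50, max_mismatches = 2. The matcher seeds
with max_mismatches + 1 disjoint exact seeds of length
floor(k / (max_mismatches + 1)) per strand, which by pigeonhole guarantees
that every alignment within the mismatch budget is found, then verifies
with a full Hamming comparison.

Matching a read set against an assembled contig uses a local ungapped
criterion instead: a read matches if some seed-anchored diagonal (either
strand) carries a window of `min_span` (default 50) bases at identity ≥
`min_identity` (default 0.9). Substitution-only alignment is consistent
with the simulator's error model and keeps the oracle (an exhaustive
diagonal/window scan) exactly reproducible.

### Canonical counting

k-mers are counted canonically (lexicographic minimum of window and
reverse complement), the norm for strand-symmetric shotgun data. Windows
containing non-ACGT characters are skipped; reads are never split; mates
count independently. Internally windows are packed into one or two 64-bit
words (two for 32 < k ≤ 64); code order equals base order (A<C<G<T), so
integer comparison is lexicographic comparison. Counts are aggregated by
sorting the packed words; profiles expose a read-only mapping interface
with k-mer strings decoded on demand, which keeps multi-million-entry
profiles affordable. For k > 64 a plain dictionary path is used.

### Subsampling

Accessions are compared on uniform reservoir subsamples capped at
`max_bases` per accession (default 2 × 10⁷), mates kept together,
deterministic under the run seed. A fixed-size subset per accession is the
convention that makes proportions comparable across sequencing runs of
different depth; the desk default was chosen so a full multi-accession
study (several 4–8 Mb genomes at 10×) runs in minutes on one CPU. A
head-of-file mode is available by loading reads and truncating before the
pipeline (reservoir sampling is the default because run order in real
FASTQ files is not random).

## Exclusion filters

Applied to each accession's abundant motifs before comparison, with fixed
precedence telomeric > rdna > plastid > adapter > gc_extreme (the
precedence is a determinism choice; a motif in several classes is equally
excluded either way):

* **telomeric** — fraction of positions covered by occurrences of any
  cyclic rotation of TTTAGGG or its reverse complement ≥ 0.8. Rotation
  invariance matters because a 50-mer cut from an (TTTAGGG)n array can
  start at any phase.
* **rdna / plastid / adapter** — an exact shared canonical 25-mer with the
  corresponding reference library. Exact seed sharing rather than
  alignment is cheap, deterministic, and sensitive enough at 50-mer scale:
  a contaminant-derived motif shares long exact stretches with its source.
* **gc_extreme** — GC < 0.2 or > 0.8. The bounds exclude homopolymer-like
  artefacts while leaving typical satellite GC untouched; both are
  configurable.

Filtering is idempotent and order-preserving.

## Discovery strategies

* **differential**: accept motif *m* iff `min_target p ≥ ratio_min ×
  max_background p` and `max_background p < background_max`, with
  `ratio_min = 100` and `background_max = 10⁻⁴` (0.01 %) by default; a zero
  background with positive target counts as accepted (infinite ratio).
  The background ceiling is strict. Ranking is by minimum target
  proportion, ties lexicographic.
* **shared**: motifs appearing (exact canonical identity) in the abundant
  sets of *all* targets and at proportion ≥ `target_min` (default 0.0005)
  in each are assembled; contig proportions are then measured in every
  accession by local matching, contigs with background maximum <
  `background_max` are accepted and ranked by mean target proportion.
  Presence-by-identity was chosen over mismatch-tolerant presence because
  abundant motif sets from accessions sharing a subgenome contain the
  identical consensus windows; a tolerant variant can be had by lowering
  `target_min` and relying on the proportion check.

### Greedy assembly

Input motifs share one length k. All exact suffix–prefix overlaps ≥
`min_overlap` (default k/2) between oriented motifs are enumerated once by
hashing prefixes per overlap length; merging then proceeds greedily from
the longest overlap, with ties resolved toward the longer, then
lexicographically smaller, merged sequence. Because an overlap between
contigs is always an overlap between their terminal motifs, the motif-level
overlap table remains valid throughout. Every input motif ends in exactly
one contig; member offsets and adjacent overlaps are recorded so the
layout is auditable; duplicates collapse with a warning. A unitig-style
greedy was chosen over a de Bruijn construction because the input is a
small curated motif set where determinism and traceability matter more
than scalability.

### Probe scoring

A candidate is probe-suitable if GC ∈ [0.35, 0.65], no homopolymer run
exceeds 6, and it is not telomeric. This is a screening heuristic standing
in for full thermodynamic primer/probe design, which is out of scope.

### Recovery metrics

A planted family counts as recovered when some candidate matches its
consensus at ≥ 90 % identity over ≥ k bases. For tandem families the truth
consensus is the doubled monomer, so unit-junction k-mers (which span the
monomer boundary and are genuine family sequence) match. Precision is the
fraction of candidates matching any truth family; an empty candidate set
reports recall 0 with precision 1.0 by convention, flagged.

## Flow-cytometry ploidy caller

Histograms are uniform-width binned fluorescence counts. Peak detection
ignores the lowest 10 % of the fluorescence range (debris tail), smooths
with a 5-bin moving average to stabilise the maximum of flat-topped noisy
peaks, requires height ≥ 10 % of the maximum and ≥ 3 bins separation, and
refines positions by a centroid over ±2 raw bins; the G0/G1 peak is the
lowest-position survivor. The peak CV is the weighted sd/mean over the
contiguous window where counts stay ≥ 20 % of peak height (≥ 3 bins),
rescaled by the analytic truncated-Gaussian factor
sqrt(1 − 2c·φ(c)/(2Φ(c) − 1)) with c = sqrt(2 ln(1/0.2)), so the reported
CV estimates the full-peak value. The ploidy call is
ratio = standard_multiple × FL_sample / FL_standard rounded to the nearest
integer, ambiguous when the residual exceeds `tolerance` (default 0.15
x-units — chosen so that aneuploid ratios such as 8.4 flag as ambiguous
while simulation noise at CV ≤ 0.05 does not). The exact CV window used by
instrument software varies; the 20 %-height window is this package's
definition.

## Synthetic data generator

The generator emulates the study design the screen targets, not any
particular sequencing artefact:

* **Genomes.** Uniform-random background (25 % each base); families planted
  by replacing background: tandem families as one contiguous array,
  dispersed families at uniform non-overlapping positions; each copy
  carries independent substitutions at the family's divergence rate.
  Genome-specific families are scoped to a subset of subgenomes.
* **Reads.** 150-b reads, paired by default (fragment 2 × 150 + 50 with
  both orientations equiprobable), fragment starts uniform, subgenome
  choice proportional to dosage × length, i.i.d. substitution errors
  (default 0.001). Contaminant (rDNA-like/plastid-like) reads are drawn
  from tiled consensus pools and injected at a fixed read fraction rather
  than embedded in genomes, mirroring how organellar DNA appears in real
  shotgun data. Read records keep their origin labels for auditing.
* **Manifest.** The ground truth records realized copies, placements, and
  two expectations per (family, accession): the base fraction
  (copies × unit / genome) and the overlap-aware expected read fraction —
  the probability a read contains a full k-window of the family,
  `Σ_blocks (B + L − 2k + 1)` valid starts over total starts, dosage-
  weighted and scaled by (1 − contaminant fraction). The read fraction is
  what the genome-proportion statistic estimates; the base fraction is the
  quantity usually quoted as "x % of the genome".
* **Histograms.** G0/G1 events Gaussian at standard_position × multiple/2
  with sd = cv × mean, a G2 peak at twice the mean (10 % of events), and
  an exponential debris tail (5 %).
* **Determinism.** One master seed; every stage (per-subgenome genome
  build, per-accession reads, histograms) draws from a stream derived from
  it, so identical seeds give byte-identical output.

The default study scenarios plant, on 2-Mb subgenomes at 10× coverage: two
shared ancestral satellites (0.2 % and 0.08 % of bases), a telomere array
sized to ~0.1 % of reads, a GC-extreme family, contaminant pools at 1 % of
reads, and one subgenome-private satellite at 1 % of its subgenome (0.5 %
of a tetraploid's reads) — proportions inside the 0.01–2 % range where
genome-specific repeats are realistically found and FISH-visible.

What the simulator does **not** model: indels and quality-score error
structure, recombination or homoeologous exchange, GC-biased coverage,
PCR duplicates, and real satellite higher-order structure. Passing tests
therefore demonstrate the statistical machinery — counting, filtering,
thresholding, assembly, calibration of expectations — under a clean
substitution-only model, not robustness to every artefact of real
libraries.

## Numerical and engineering choices

* Tie-breaks are fixed everywhere (lexicographic after count/score) so
  every pipeline output is byte-reproducible; a rerun with the same config
  produces identical candidate JSON.
* Packed-word sorting uses two plain argsorts over combined 64-bit keys
  when the high word fits 36 bits (k ≤ 50), falling back to `np.lexsort`
  otherwise.
* `count_kmers` consumes reads whole, in order, stopping before the read
  that would cross `max_bases`.
* Proportions are exact rational counts divided by read numbers; no
  smoothing or pseudo-counts anywhere. Degenerate inputs (zero reads,
  empty consensus, all-zero histograms, infeasible planting) raise typed
  errors rather than returning sentinel values.
* Test and acceptance problem sizes: full-scale scenario checks use the
  2-Mb / 10× defaults with 5 fixed seeds for the two strategy round trips;
  unit and property tests use 100–200 kb genomes, where family depth
  separates from the single-copy Poisson tail only partially — those tests
  therefore assert recall and calibration, leaving exact precision to the
  full-scale runs.

## Known limitations

* The homology filter's exact-25-mer criterion can miss a contaminant
  motif diverged > ~4 % everywhere; real screens should supply generous
  reference libraries.
* The greedy assembler does not resolve genuine repeat-graph ambiguity
  (two families sharing a ≥ min_overlap stretch can chimerise); for
  curated 50-mer sets this has not been observed, but the contig member
  layout is recorded precisely so such events are detectable.
* `count_kmers` is in-memory; profiles beyond ~10⁸ distinct k-mers are out
  of scope.
* The ploidy caller assumes the G0/G1 peak is the lowest prominent peak
  above the debris floor; heavily degraded samples violating this need the
  floor raised.
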