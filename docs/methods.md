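# Methods

This note documents the models, algorithms and numerical choices behind
`satcons`, in the order data flows through the pipeline.

## The generative model (what the simulator emulates)

The simulator instantiates the *library model* of satellite evolution: all
species inherit one ancestral 52-bp monomer; each species' consensus
diverges from the ancestor by per-site i.i.d. substitution with probability
`branch_length × substitution_rate`; each lineage independently amplifies
the repeat into head-to-tail tandem arrays.  Within a species, each copy is
either an exact consensus copy (probability `homogenization`, default 0.5 —
our abstraction of concerted evolution; the real within-array mutation
process is unknown, so this single knob stands in for unequal crossover,
gene conversion and the rest) or a privately re-mutated consensus using the
same per-site probability, so intraspecific variation scales with the same
branch length that separates species.  Mutations are transition-biased:
given a hit, a transition occurs with probability κ/(κ+2) (default κ = 2),
matching the K2P model used downstream.

Genomes are random background of tunable A+T content (default 0.65, the
satellite family's compositional neighbourhood) with arrays carved in at
uniform non-overlapping positions on either strand.  Placement is rejection
sampling, longest segment first, with 1000 draws per segment and up to 50
whole-set redraws before a sizing error — naive sequential rejection dead-
ends at ~50% occupancy.  Single-copy "genes" for coverage normalization are
planted the same way.  Every planted array, copy and variant count is
recorded as ground truth.

Short reads are 2×101 inward-facing pairs from ~300±30-bp fragments with
optional per-base substitution error.  Long reads draw log-normal lengths,
may run off either genome end (truncated molecules — this keeps per-base
sampling uniform; with starts confined to `[0, G−L]` the first and last
read-length of a toy-sized genome fall in a coverage shadow and bias
density estimates), and accumulate errors at `error_rate` (default 0.15)
split `indel_fraction` (default 0.6) into half insertions/half deletions,
the remainder substitutions.  A coordinate map built during corruption
re-expresses truth intervals in read coordinates.  Every output stream
draws from its own child generator (master seed + stream label), so adding
an output never perturbs another; a fixed config is byte-reproducible.

What the simulator does *not* model: chimeric reads, quality-score
realism, platform-specific error profiles, higher-order repeat structure,
recombination between arrays.  Tests passing on these data show the
*estimators* are correct and calibrated, not that real libraries are free
of mapping bias, PCR duplicates or reference contamination.

## Monomer extraction and the two rotation conventions

A read (either strand) is scanned for its best 52-nt window against all 52
rotations of the consensus (ungapped identity, matches/52).  If the best
window reaches `min_identity` (default 0.70, a deliberately permissive
floor exposed as a flag), the window grid is locked **to the consensus
frame**: the matched rotation offset shifts the grid so every emitted
window starts at consensus coordinate 0.  Anchoring to the arrival phase
instead would split multi-substitution variants into chimeric windows at
copy junctions (we measured frequency errors of ~0.25 that way versus
~0.02 with frame anchoring).  Windows truncated by read ends, containing
N, or below a 0.50 identity floor to the consensus (flanking background
emitted by array-edge reads) are discarded.  Copies containing indels drop
out of ungapped extraction by design; the deletion subfamily is instead
caught by the coverage-valley detector.

Variants are tallied as exact sequences under the **canonical rotation**
(lexicographically minimal), and count-1 variants are discarded by default.
Canonical rotation is a stable identity key but an unstable alignment
frame: one substitution can move the minimal rotation, and comparing two
variants canonicalized into different frames produces nonsense distances.
All columnwise computations — landscapes, divergence summaries, the
pipeline MST — therefore re-phase variants onto the consensus frame first
(`monomers.phase_align`: maximal-identity rotation, smallest offset on
ties).

## Read mapping and copy number

Mapping to the reference panel (the consensus repeated k = 4 times, 208 bp,
so junction-spanning reads map contiguously, plus the gene panel) is k-mer
seeded (k = 12, seeds every 4 bp, both strands) and ungapped.  Two modes:

* **global** — the read must lie inside a reference; identity is
  matches/read-length; best identity wins, ties to the first-listed
  reference, then leftmost, then forward strand.
* **local** — on each seeded diagonal the maximal-scoring segment
  (Kadane's algorithm, match +1 / mismatch −3) is taken; candidates below
  `min_identity` (default 0.9) over the segment or shorter than 30 bp are
  dropped.  Optionally a read may contribute several segments disjoint in
  read coordinates (`max_segments`): a read crossing an indel inside the
  repeat continues on a shifted diagonal, and keeping both sides preserves
  depth around segregating indels.

Copy number per 1C is estimated as (satellite aligned bases / 52) divided
by the median gene depth (aligned bases / gene length).  The median, not
the mean, across the ten genes resists a mis-annotated or unusually
covered gene.  Local-mode mapping makes both numerator and denominator
unbiased by locus edges, so the ratio recovers planted copies even for a
single 520-bp array.  What limits accuracy is the genome's own sampling
noise: the realized depth of a 520-bp locus at 20× fluctuates with ~10%
relative SD, which no estimator can undo.  The calibration scenarios
therefore sequence the small-copy condition deepest (300× for 10 copies,
80× for 100, 20× for 1000) — a statement about experimental design, not
about the estimator.

Valley detection folds concatemer depth to monomer coordinates (mean over
the k images; the result is invariant to k) and reports runs of ≥ 2
positions below 0.6× the median folded depth, as 1-based inclusive monomer
intervals.  The planted 3-bp deletion in half of all copies yields a
~0.5× dip exactly at the deleted positions *provided* split mapping is on;
with one segment per read, the far side of every deletion junction is
dropped and the flank depth deflates until the valley fades (we measured
0.69× vs 0.52×).

## Divergence

K2P: P and Q are transition and transversion proportions;
K = −½ ln(1−2P−Q) − ¼ ln(1−2Q), reported in percent.  Non-positive log
arguments raise a saturation error; saturated pairs are skipped and
counted in summaries.  Landscapes bin each variant's base mass
(52 × count) by ⌊K%⌋.  Intraspecific divergence is the count-weighted
(cᵢ·cⱼ, i<j, self-pairs excluded) mean pairwise K within a species;
interspecific is the same across species pairs.  The weighting treats the
library as copy-weighted, matching the intuition that a variant present in
800 copies dominates the family's divergence.

## Variant MST

Nodes are exact variants, edges Hamming distances (mutational steps).
Kruskal with a fixed tie-break — distance ascending, combined endpoint
abundance descending, then lexicographic ids — makes the tree independent
of input order and prefers founding high-abundance nodes, in the spirit of
classical haplotype-network software whose exact rule is unpublished.
Optimality is verified in the tests against exhaustive enumeration of all
n^(n−2) labeled spanning trees (vectorized Prüfer decoding) for n ≤ 8.

## Long-read array detection

A read is aligned against the infinite cyclic concatenation of the monomer
(wraparound DP over 52 columns; the horizontal, read-gap relaxation is a
cyclic max-plus scan).  Noise is edit operations over alignment columns and
must not exceed `max_noise` (default 0.20).  Scoring is derived from that
ceiling: with match +1, mismatch/indel cost −(1−τ′)/τ′ where
τ′ = 1.25 × max_noise (−3 at the default).  Regions noisier than τ′ are
score-negative, so Smith–Waterman locality splits alignments where the
contract breaks; the exact ceiling is enforced by a final filter.  Unit
costs are not an option — on random DNA they sit in the score-positive
Chvátal–Sankoff regime (~+0.17/base) and alignments swallow the background
between arrays — and scoring at τ itself clips 0.5-kb arrays by up to 40%
when errors cluster at the ends; the 1.25 slack removes that at no cost to
locality.  Overlapping candidates are resolved greedily by score, then
span, then leftmost start, over both strands.  The kernel is numba-
compiled when available; a pure-numpy scan with identical output (asserted
in the tests) is the fallback.

Density is kb annotated per Mb sequenced after merging overlapping
intervals per read.  Flankers are the ≤10-kb windows adjacent to each
detected array, truncated at read ends; clustering is greedy longest-first
(CD-HIT style): a sequence joins the first cluster whose representative it
matches at ≥ 0.8 identity (edlib) over at least half of the shorter
sequence, clusters below size 3 are dropped from the report.

## Transcription

FPKM = count / (length/1000 × total/10⁶), fragments = pairs for paired
input and reads for single-end.  Group comparisons use Welch's t with
Welch–Satterthwaite df (the fractional df reported for such comparisons
identifies the Welch form); the tests cross-check against
`scipy.stats.ttest_ind(equal_var=False)`.  qPCR follows Livak: replicate
Ct values averaged arithmetically, ΔCt against the reference gene,
RQ = 2^−ΔCt, and ΔΔCt/fold against a calibrator sample.

## Problem sizes and defaults

The default community is 8 species on 50-kb genomes at 15× short-read
coverage, one species with ~20 kb of clustered satellite and the rest with
2–4 short arrays; the end-to-end run takes ~25 s on one CPU.  The
dedicated calibration scenarios use 10–120-kb genomes, 0.5–4-kb planted
arrays, and ~1.5 Mb of 15%-error long reads per density contrast.  These
sizes were chosen so that sampling noise sits well inside each check's
tolerance (e.g. ~170 array-read crossings for the density fold give ~8%
relative SD against a ±25% band) while the whole suite stays interactive.

## Known limitations

* Ungapped mapping under-recovers copies diverged ≳10% from the mapping
  consensus; in the default community the two most diverged species show
  clearly depressed copy-number estimates (their truth columns make this
  visible in `copy_number.tsv`).  A gapped or more permissive mapper would
  trade this against reference bleed-through.
* Canonical-rotation keys from different species align only through the
  consensus frame; variants more diverged than ~30% may re-phase
  ambiguously.
* The array detector reports maximal noise-bounded alignments; at 15%
  error the optimal alignment legitimately omits terminal error bursts, so
  single-read lengths of 0.5-kb arrays scatter by a few percent (the
  recovery checks average a handful of reads per size).
* The qPCR module implements the Livak arithmetic only; amplification-
  efficiency corrections are out of scope.
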