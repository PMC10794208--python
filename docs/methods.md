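# Methods

`contrabin` bins assembled metagenomic contigs by (1) learning a latent
embedding of each contig with multi-view contrastive learning over
heterogeneous features — tetranucleotide composition and multi-sample read
coverage — and (2) clustering the embeddings with a Leiden community
detection configured for the binning task (single-copy-gene constraints,
base-pair node sizes, automatic parameter selection).

## Data augmentation

Contiguous fragments of one contig come from the same genome (assembly
errors aside), so random fragments of a contig are valid positive pairs for
contrastive learning. Each contig yields `V = n_aug + 1` views: the full
sequence plus `n_aug = 5` fragments. The fragment law is: length uniform on
`[min_frag_len, L]` (inclusive, `min_frag_len = 1000` bp), then start
uniform over admissible positions. The text this design follows fixes only
the 1000 bp floor; the uniform length law is the simplest choice consistent
with it and is exposed in configuration. Views are drawn once per run (not
per epoch), from per-contig RNG streams derived from `(seed, contig_id)` so
the result is independent of contig order. Fragments may overlap or repeat;
no deduplication is applied.

## Feature vectors

**Composition.** Sliding 4-mer windows (stride 1); windows containing a
non-ACGT character are skipped (deterministic, rather than randomizing
ambiguous bases). A 4-mer and its reverse complement are one class: 120
complementary pairs + 16 palindromes = **136 classes**, assigned by
enumeration. Counts receive a +1 pseudocount and are normalized to sum to
one, removing contig-length effects.

**Coverage.** For each of the M samples, the per-base depth mean and
standard deviation over the view's interval, computed exactly from the
run-length encoding. We use the *population* standard deviation: the
statistic describes the multiset of per-base depths, not an estimator of a
sampling distribution. Each entry of the resulting 2M-vector is offset by
`+1e-5` so no vector is zero, then each column is divided by its maximum
over the *original* contig views. Using original-view maxima (and reusing
those divisors for fragments) keeps the original-contig features invariant
to which fragments were drawn; mean and std columns are normalized
independently, each by its own maximum. Contigs with zero aligned reads
everywhere are retained — the offset keeps their features finite.

## Encoders and objective

The **Coverage network** (three affine layers) maps the 2M coverage vector
to a fixed-dimensional embedding, making the architecture insensitive to
the number of samples; its output is L2-normalized (matching the cosine
geometry of the loss) and concatenated with the 136-dim composition vector
as input to the **Combine network** (three affine layers) whose output `z`
is both the contrastive space and the clustering input — there is no
separate projection head.

The objective is the multi-view NT-Xent loss with cosine similarity and
temperature τ: positives are all ordered same-contig view pairs; each
term's denominator is its positive term plus every view of every *other*
contig in the batch (the anchor contig's remaining views are excluded).
τ follows the assembly-contiguity rule: **0.07 if the assembly N50 exceeds
10,000 bp, else 0.15**.

Training: Adam (lr 1e-3), up to 200 epochs, batch size 1024 contigs (all V
views gathered per sampled contig), last incomplete batch dropped to keep
the negative structure fixed — except that a batch size exceeding the
number of contigs is clamped to it. Early stopping halts after 10 epochs
without a >1e-4 improvement of the epoch-mean training loss (there are no
labels to hold out, so training loss is monitored). Default layer widths
(2048/2048 hidden, coverage embedding 2048, latent 128, LeakyReLU, dropout
0.2) are package defaults chosen for realism at metagenome scale, not
values with external provenance; all are configuration.

The networks and training loop run on a small in-package reverse-mode
autograd over NumPy arrays (`_autograd.py`), whose operator gradients are
verified against central finite differences in the test suite; the
vectorized loss is verified against a brute-force triple-loop oracle.

**Scaling to small communities.** `EncoderConfig.small()` (128-wide layers,
latent 32, dropout 0.5) is the configuration used for the packaged
synthetic communities of ~10^3 contigs; tests train it for 60 epochs at
batch size 256. On such small instance sets, prolonged instance
discrimination eventually memorizes individual contigs and erodes
genome-level structure; the narrower widths and stronger dropout counteract
that. This is a problem-size choice, not a change of method.

## Clustering

Embeddings of the original contigs (view 0 only) are clustered as follows:

1. **k-NN graph** with squared L2 distances, `k = min(100, N-1)`. Neighbor
   lists are exact (scikit-learn `NearestNeighbors`) and symmetrized by
   union; an approximate index is admissible provided it passes the
   brute-force recall property in the tests.
2. **Edge pruning**: keep the fraction (50%, 80% or 100%) of edges with
   smallest distances, applied to the symmetrized edge list.
3. **Similarity**: `S_ij = exp(-d_ij / σ)` with `d_ij` the squared L2
   distance, so `S ∈ (0, 1]`.
4. **Leiden** with singleton initial membership; contigs carrying the *seed
   marker* — the single-copy gene hitting the most distinct contigs
   (lexicographic tie-break) — are frozen in their distinct initial
   communities, so no two can merge (the same single-copy gene on two
   contigs implies two genomes). Node sizes are contig lengths in bp. The
   quality function is the resolution-scaled Erdős–Rényi modularity
   (`RBERVertexPartition`), which treats each node as an aggregation of
   base pairs while remaining invariant to the overall node-size scale —
   the property that makes one resolution grid meaningful across
   assemblies. Optimisation is seeded and run to convergence.
5. **Sweep and selection**: all combinations of σ ∈ {0.05, 0.1, 0.15, 0.2,
   0.3}, resolution ∈ {1, 5, 10, 30, 50, 70, 90, 110}, edge ratio ∈ {0.5,
   0.8, 1.0} (120 partitions). Each partition is scored by a single-copy
   gene surrogate: per bin, completeness = 100 · (distinct markers)/G and
   contamination = 100 · (duplicated marker hits)/G; the score is the
   number of bins with contamination < {5, 10}% crossed with completeness
   > {50, 70, 90}% (strict inequalities), summed over the six combinations.
   The argmax partition wins; ties keep the earliest combination in
   (edge-ratio, σ, resolution) order, and each combination has a derived
   seed so results do not depend on execution schedule. This estimator is a
   deliberate simple surrogate for external quality tools, and is the one
   all tests target.
6. **Final filter**: bins with total length strictly below 200 kbp are
   dropped; their contigs are reported unbinned.

## Synthetic communities

The generator emulates the binner's inputs directly (no read simulation):

- **Genomes**: order-1 base-transition chains; genome g uses
  `P_g = (1-δ)·Uniform + δ·B_g` with `B_g` random row-stochastic and
  δ = `composition_divergence` (default 0.85). δ = 0 gives a shared law
  (composition carries no signal).
- **Contigs**: lognormal lengths (median ≈ 2.5 kbp, clipped to
  [1000, 15000] bp); short tails are absorbed so every contig is ≥ 1000 bp.
- **Depth**: per contig and sample, abundance × a lognormal per-contig
  factor (σ = 0.25) × a sinusoidal within-contig modulation (amplitude 0.3,
  period 700 bp — smooth variation with non-zero std), rounded to integer
  read counts and run-length encoded. Default abundances are i.i.d.
  lognormal around 10× per genome and sample.
- **Markers**: each of G = 20 markers placed exactly once per genome on a
  random contig: single-copy within genomes, multi-copy across the
  community.

The **easy preset** (10 genomes × 300 kbp, 5 samples, ~1000 contigs) is the
canonical end-to-end fixture. The **hard-strain preset** (two genomes, one
shared composition law, distinct abundance profiles) verifies that coverage
features separate what composition cannot. Passing on these communities
shows the machinery is correct on clean, well-separated input; it does not
bound performance on real assemblies with repeats, chimeras and strain
mixtures.

## Evaluation conventions

End-to-end agreement with truth labels is measured by the adjusted Rand
index on the *final* bin assignment (after the 200 kbp filter), i.e. over
binned contigs — the same convention as base-pair-weighted binning
evaluations, which score what the tool outputs as bins. Pre-filter
partitions typically carry tiny splinter bins that the size filter removes.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere; depth files follow the
  `genomecov -bga` dialect, gaps are filled with explicit zero runs,
  overlapping runs are an error.
- An empty SCG table disables both the Leiden constraint and the sweep
  score; the sweep then returns its first combination with a warning.
- `loss` with one contig in the batch is 0 (no negatives); batches always
  hold ≥ 2 contigs in practice.
- The N50 at or below 10,000 maps to τ = 0.15 (the rule's "larger than" is
  strict).
- A bin of exactly 200,000 bp survives the final filter ("smaller than" is
  strict).
- Checkpoints store weights plus both configs and feature dimensions under
  a versioned schema; loading refuses unknown schemas.

## Known limitations

- Exact k-NN is O(N²) at query time; beyond ~10^5 contigs an approximate
  index would be needed (the contract admits one that passes the recall
  property).
- The NumPy training loop is single-threaded except for BLAS matmuls;
  metagenome-scale runs at the default 2048-wide architecture are CPU-days,
  not CPU-minutes.
- The SCG quality surrogate ignores marker-set phylogeny (every marker is
  weighted equally) and therefore under- or over-estimates quality relative
  to tools that model lineage-specific marker sets.
- Single-copy-gene acquisition (gene calling + HMM search) is an input
  contract, not reimplemented; the synthetic generator is the
  no-dependency provider.
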