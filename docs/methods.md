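# Methods

## Problem and approach

N6-methyladenosine (m6A) perturbs two observable layers of a nanopore
direct RNA sequencing (DRS) read: the raw ionic current around the
modified adenosine, and the local basecalling outcome (more mismatches,
deletions and insertions, lower base qualities). `m6aduet` detects m6A at
DRACH/RRACH motifs by encoding both layers for the 5-mer centered on each
candidate A in each read, classifying the pair of matrices with a
dual-branch residual network, and aggregating read-level probabilities
into per-site calls.

The package does not basecall, align or re-squiggle. It consumes two
documented tab-separated intermediates that any Guppy/minimap2/Tombo-style
preprocessing can be converted to: an *event table* (per read, per
reference base, the list of raw current values assigned to that base) and
an *alignment table* (per read, per reference base: match/mismatch/
deletion status, basecall quality, and the count of inserted bases
anchored immediately 5' of the position). Coordinates are 0-based on the
transcript; DRS reads align to the transcriptome, so only the forward
strand exists, and U is mapped to T on ingest.

## Feature encoding

**Raw-signal feature, 5 x (5L).** Signals are normalized per read by
median shift and MAD scale, with the statistics computed once over all
signals of the read. Because a base's segment has variable length
(dwell), exactly L values are kept per base: a uniform draw *without
replacement, preserving temporal order* when the base has more than L
values, zero-padding on the right otherwise. L = 65 by default. Rows 1-4
are the 5-mer one-hot (channel order A, C, G, T), each base's column
repeated L times so the sequence channel is aligned with its signals; row
5 is the concatenated signal vector. Default shape 5 x 325.

Order-preserving sampling keeps the sequential time information that
motivates feeding raw signals (rather than summary statistics) to the
network; suffix padding keeps real signals left-aligned for the
convolution stem. The sampler is seeded per (read, transcript, site) by
hashing with the global seed, so extraction is deterministic and
independent of iteration order.

**Basecalling-error feature, 8 x 5.** Per base of the 5-mer: reference
one-hot (rows 1-4); basecall quality scaled by Phred/40 and clipped to
[0, 1], with 0 for deletions (row 5); mismatch and deletion indicators
(rows 6-7); insertion count (row 8, uncapped — values are small). The
4+1+3 row composition is the direct reading of "status plus base quality"
with match as the complement of the indicator rows; any fixed row order
works as long as it is used consistently, and this one is frozen here.

## Network

Each enabled branch: a 1-D convolution stem (32 channels; kernel 7 for
the raw-signal branch, 3 for the error branch) with ReLU and stride-2 max
pooling, then four residual blocks of four convolutions each (kernel 3,
batch normalization and ReLU around each convolution, output channels 32,
64, 128, 256), then global average pooling. The pooled outputs are
concatenated and passed to a fully connected head with two hidden layers
(128, 32); the scalar output x gives the read-level probability
Pr = 1/(1 + e^{-x}).

Within a block, ReLU follows the first three convolutions; the fourth
convolution's batch-normalized output is added to the skip path and the
sum passes through the final ReLU. The skip uses a 1x1 projection
whenever channels or stride change. The raw-signal branch downsamples by
stride 2 at the entry of blocks 2-4 (standard residual-network practice;
it cuts per-sample compute about fivefold with no measurable accuracy
cost at this input length). The error branch, whose temporal length is
only 5, never strides and its pooling never reduces length below 1. The
binding interface is the shape contract — inputs 5x325 and 8x5, scalar
sigmoid output — not any particular downsampling schedule.

The layers are implemented in NumPy (im2col convolutions, hand-derived
backward passes, Adam); gradient correctness is verified against
finite differences in double precision in the test suite. Everything is
float32 and deterministic given the seed.

**Training.** Binary cross-entropy on read-level labels; Adam with
learning rate 1e-3, batch size 64, up to 8 epochs with early stopping
(patience 2) on validation loss; the best-validation checkpoint is
restored. Batches of size 1 are dropped (batch statistics need two
examples). Training details beyond the architecture are deliberately
plain defaults exposed in `ModelConfig`; single-branch configurations
(`branch_enable`) are the ablation variants.

## Aggregation

Two schemes map the read probabilities pr_k of a site to the
transcriptome-level probability Pt:

* **multiple-instance pooling** (`mil`): Pt = 1 - prod(1 - pr_k) over a
  uniform, seeded, without-replacement sample of exactly 20 reads. Sites
  with fewer than 20 reads are reported uncalled with a reason code
  rather than raising — low coverage is a property of the data, not a
  bug. A single draw is made per site; no re-sampling/averaging.
* **frequency** (`frequency`): Pt = n_m / n with
  n_m = #{pr_k >= 0.5}; the boundary 0.5 counts as methylated. No
  coverage floor, but n is reported so users can filter.

MIL pooling is monotone in every pr_k and bounded below by their maximum;
frequency output lies exactly on the grid {0, 1/n, ..., 1}.

## Synthetic data

The generator emulates the joint structure the method exploits, not any
specific pore chemistry or segmentation algorithm:

* per-5-mer mean current levels drawn once from a seeded table
  (N(90, 8) in arbitrary current units), per-value noise N(0, 2.5);
* dwell (values per base) shifted-geometric with mean 10, support >= 1;
* modification shifts the mean by delta = 4 at all five positions of the
  windows covering a methylated A, for methylated reads only;
* mismatch/deletion/insertion rates 0.03/0.02/0.02 inflated 4x, and mean
  quality depressed from 32 to 22 (sd 4, clamped to [1, 40]), at the same
  positions — so the two branches carry partially redundant, partially
  complementary evidence;
* sites are drawn at RRACH motifs; candidate sites whose windows overlap
  (< 5 nt apart) share one methylation cluster per read so overlapping
  windows never contradict each other's labels; a cluster is modified
  with probability 0.5 and a read at a modified site is methylated with
  stoichiometry 0.8.

Reads are full-length and every reference position receives an event, so
coverage equals read depth at every site. The defaults
(24 transcripts x 400 nt x 30 reads, the `default` fixture) give roughly
3 400 (site, read) pairs and ~110 candidate sites — sized so that
held-out site-level metrics average over ~20 sites and the full training
run takes a couple of minutes on one CPU. The `tiny` fixture
(2 x 120 x 6) generates in well under a second for unit tests.

**The null fixture** sets all effect sizes to zero (delta = 0, inflation
1, no quality depression) *and* makes labels i.i.d. coin flips
(every site "modified", stoichiometry 0.5). The second part matters: with
zero effects the network can still memorize 5-mer context, and if the
label marginal depended on site identity the held-out AUC of a small
corpus would be dominated by a handful of between-site comparisons and
fluctuate far from 0.5 even with no leakage. With label-independent
draws, any systematic departure of the held-out AUC from 0.5 indicates
genuine leakage, and the estimate concentrates at rate 1/sqrt(n reads).

**What the generator does not emulate:** real pore k-mer models and their
autocorrelated noise, segmentation errors from re-squiggling, partial or
clipped reads, multi-mapping, isoform ambiguity, modification types other
than m6A, or sequence-dependent error profiles. Passing the end-to-end
checks therefore demonstrates that the pipeline recovers a known signal
of realistic shape and strength from data it has never seen — not that
the shipped defaults reach any particular accuracy on biological samples,
which require training on matched real datasets.

## Evaluation

ACC, SEN and SPE threshold scores at 0.5 (a call is positive when the
score is >= 0.5); AUC by tie-aware ROC integration and AUPR by
precision-recall step integration (scikit-learn). The test suite checks
the AUC against brute-force Mann-Whitney pairwise concordance. Site-level
evaluation thresholds Pt at 0.5; the threshold is exposed. Single-class
label sets report AUC/AUPR as undefined with a reason instead of a
number.

End-to-end evaluation splits *by transcript* (roughly 60/20/20
train/validation/test), so no read or site is shared between training and
testing; the split rotates deterministically if a draw leaves the test
set with single-class site truth.

## Numerical and degenerate-input choices

* A read with constant signal (MAD = 0) cannot be normalized and is
  rejected with a specific error; extraction drops and tallies it.
* Deletion records carry quality sentinel -1 in the TSV and contribute 0
  to the quality row after scaling, matching the padding value.
* Phred/40 clipping bounds the quality feature; insertion counts are used
  raw.
* Event tables store floats via `repr`, so write-then-read round trips
  are bit-exact.
* MIL sampling, signal sampling, splits, initialization and batch order
  all derive from explicit seeds; identical seeds give identical results,
  including byte-identical simulated datasets.

## Known limitations

* The trained weights shipped by any one run are corpus-specific; the
  package provides the method, not a pretrained model for real data.
* The NumPy network trains at desk scale (thousands of reads); training
  on transcriptome-scale datasets would need a GPU framework behind the
  same interfaces.
* The RNA004 chemistry, genome-coordinate lift-over and isoform
  reconciliation are out of scope.
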