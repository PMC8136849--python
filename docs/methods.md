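# Methods

## The prediction problem

A 5'UTR modulates how efficiently its mRNA is translated, largely through
upstream translation initiation sites (uTIS: AUG and the near-cognate CUG,
GUG), upstream open reading frames (uORFs: a uTIS with an in-frame stop
codon before the canonical start), and the Kozak context around each start.
Whether a uTIS is *in frame* with the canonical coding sequence decides its
consequence — an in-frame, non-terminating upstream start merely extends the
protein's N terminus, an out-of-frame one produces an aberrant product.
Because the 5'UTR's 3' end abuts the canonical start codon, the frame of
position `i` in a length-`L` UTR is `(L - i) mod 3`, anchored at the 3' end.

The regression target is mean ribosome load (MRL): the abundance-weighted
mean number of ribosomes per transcript measured by polysome profiling
(`mrl_from_polysome_fractions`). Massively parallel reporter assays (MPRA)
provide per-sequence MRL for libraries of random 5'UTRs — a fixed-length
library (50 nt) and a variable-length library (25–100 nt).

## Frame pooling

The model is a convolutional network whose pooling step preserves frame
information while discarding absolute position, which is what makes it
applicable to sequences of any length:

1. Three 1-D convolutions (kernel 7, 128 filters, ReLU, zero same-padding so
   the position count is preserved), with identity residual additions
   between consecutive equal-width layers (post-activation; parameter-free).
2. The final feature map is reversed along the position axis, so index 0 is
   the 3'-most position and frame classes are aligned across lengths, then
   sliced into three interleaved frame slices (`j, j+3, j+6, …`).
3. Each slice is pooled with masked global max and masked global average
   pooling, giving per-filter "is the motif present in this frame" and "how
   strongly on average" statistics. The pooled vector is
   `[max f0 | max f1 | max f2 | avg f0 | avg f1 | avg f2]` — length
   `6 × 128 = 768` for every input length (a 300-position map slices into
   three 100-position frames).
4. A 64-unit ReLU dense layer with dropout 0.2 and a scalar linear output
   complete the model: 282,625 trainable weights. A model trained on two
   libraries adds a per-library affine `(scale, bias)` on the scalar output
   (4 extra weights for two libraries; library 0 initialized at identity).

Frame-unaware baselines keep the same hyperparameters but replace frame
pooling with conventional global max+average pooling (pooled width 256),
optionally with dilations (1, 2, 4) or (1, 2, 4, 8) that enlarge the
receptive field `1 + Σ (kernel − 1) · dilation` from 19 to 43 or 91 nt.
The receptive field bounds the uORF span a single final-layer activation
can see — 19 nt for the main architecture.

### Batching, masking and padding invariance

Variable-length sequences are batched by zero-padding every sequence's 5'
end to the longest in the batch, with a boolean validity mask; 3' ends
coincide so frame classes are consistent across the batch. Two masking
rules make predictions *exactly* independent of the amount of padding:

- Convolution activations are multiplied by the mask after every layer.
  Otherwise `ReLU(bias)` at padded positions leaks into valid positions
  within one receptive field, and batch padding beyond the convolution's
  own same-padding would shift predictions.
- Pooling excludes invalid positions from both statistics: the mean uses
  the count of valid positions as denominator, the max is taken over valid
  positions only, and an all-invalid frame slice pools to 0 (the padding
  value). Sequences shorter than 3 nt are rejected — each frame needs at
  least the possibility of a member.

The batched pooling kernel is verified against an explicit per-position
loop oracle (`frame_pool_oracle`) on 1000+ random masked instances; max
blocks agree bitwise, average blocks to summation-order rounding.

### The numpy implementation

The network — dilated 1-D convolution, ReLU, residual additions, masked
frame/global pooling, dense, dropout, linear, library affine — is
implemented directly in numpy with hand-written backpropagation and Adam
(`nn.py`). Convolutions run as one matmul per kernel tap; the max-pool
backward routes the gradient to the argmax position (first index on exact
ties, a valid subgradient), the average-pool backward spreads it uniformly
over valid members. The same backward pass propagated to the input yields
exact input gradients, used for contribution scores and verified against
central finite differences. Weights initialize Glorot-uniform from an
explicit seed; dropout (inverted, rate 0.2) is active only during training,
so inference is deterministic.

## Training protocols

Adam with the conventional defaults (learning rate 1e-3, betas 0.9/0.999)
on a mean-squared-error loss; batch size 128 (moderate default, not
load-bearing). Two protocols:

- **Early stopped**: a seeded random validation split is withheld
  (260,000 → 20,000 at full MPRA scale); training stops after `patience = 3`
  consecutive epochs without a *strictly* lower validation MSE and the
  weights with the lowest validation error are restored.
- **Fixed epoch**: no validation set, exactly `max_epochs` epochs (the
  variable-length and combined protocols run six epochs straight).

**Combined two-library training** shuffles both libraries together each
epoch; each example's library label indexes the output affine. After
gradient training the four scaling weights are refit in closed form: given
the trunk, each library's `(scale, bias)` is a scalar least-squares
regression of its labels on the trunk output, with an exact solution.
Gradient training alone leaves these scalars lagging the still-moving
trunk — the relative bias error is amplified by the mean label (~5.4 on the
simulator scale), so even small scale misestimates swamp it. The refit is
the conditional optimum, never increases training MSE, and can be disabled
(`refit_scaling=False`) for pure end-to-end weights.

Optional length-bucketed batching (sorting by length inside shuffled
mega-chunks) is an efficiency toggle; the padding-invariance contract
guarantees it cannot change predictions.

## The leaky-scanning simulator

Real MPRA data is not redistributable at desk scale, so the synthetic data
generator produces random-sequence libraries whose labels come from an
explicit leaky-scanning model — the mechanism the frame-pooling
architecture is designed to exploit — with analytically known ground truth:

- A ribosome scans 5'→3'. At each candidate uTIS it initiates with
  probability `p = clip(logistic(a·context + b) · codon_strength, 0, 1)`,
  where `context` is a position-weight-matrix score over the −6…+5 window
  (missing flanks score 0).
- Defaults: the PWM concentrates weight on the −3 purine (A 2.0, G 1.5)
  and +4 G (1.0), with mild −2/−1 terms — the qualitative Kozak consensus
  GCC(A/G)CCAUGG; codon strengths AUG 1.0 ≫ CUG 0.3 > GUG 0.15;
  `a = 1`, `b = −1` (a neutral-context AUG initiates with p ≈ 0.27, a
  strong Kozak context ≈ 0.88 — leaky scanning).
- Outcomes: a uORF (in-frame stop before the CDS, stops scanned fully
  within the sequence) terminates and drops off with probability
  `1 − reinit_prob` (load `mu_uorf = 1`) or reinitiates
  (`reinit_prob = 0.5`); a non-uORF uTIS absorbs all initiating mass at
  load `mu_main = 6` in frame (N-terminal extension) or `mu_oof = 2` out
  of frame; mass reaching the canonical start contributes `mu_main`.
  Candidates are processed strictly 5'→3' with no re-scoring.
- The expectation over outcomes is the **oracle MRL**; labels add Gaussian
  noise (`noise_sd = 0.3`, a high-precision MPRA regime: the label
  noise ceiling on 50 nt random sequences is r ≈ 0.964) and an optional
  per-library affine.

The oracle wrapped as a predictor (`OraclePredictor`) supports the same
surface as a trained model, including the simulated frameshift (frames
evaluated as if `k` masked positions were appended 3'), so downstream
pipelines are testable against exact hand-derivable values without
trained weights.

What the simulator does *not* emulate: secondary structure, IRES elements,
length effects, codon-level elongation, assay count noise, or the
sequence-composition biases of real libraries. Passing recovery tests
shows the architecture extracts frame-dependent uTIS/uORF signal from
random sequences — not that it attains the published performance on real
MPRA or endogenous data.

### Study sizes used by the test suite

The simulator recovery study trains the frame-pooling preset and the
global-pooling baseline on 20,000 simulated 50 nt sequences (2,000
validation, early stopping with patience 3, at most 12 epochs) and
evaluates on a held-out 4,000; 4-mer random forests (100 trees, default
scikit-learn settings, framed and unframed features) fit the same data.
Under these conditions the frame-pooling model reaches held-out Pearson
r ≈ 0.90, the global-pooling baseline ≈ 0.78, framed forests ≈ 0.80 and
unframed ≈ 0.67. Smaller models (16 filters) back the fast unit tests.

## Variant effect scoring

BED (0-based half-open, BED6+, one row per 5'UTR exon, grouped by
transcript name) defines spliced, strand-aware UTRs; the reference sequence
is extracted from an indexed FASTA (reverse-complemented for minus-strand
transcripts) and VCF variants (1-based; multi-allelic records split;
symbolic alleles skipped) are injected in transcript coordinates,
right-to-left so indel edits do not shift one another. Variants spanning an
exon boundary, overlapping one another, or mismatching the reference
produce per-row error records rather than partial application. Scores per
(transcript, variant): `log2(MRL_alt / MRL_ref)` plus the same score after
appending one or two *masked* zero positions at the 3' end of both
sequences — a simulated frameshift that reclassifies every real position's
frame and exposes variants acting within the canonical frame (an in-frame
uAUG scores ~0 unshifted but strongly negative shifted). Saturation
mutagenesis scores all `3L` single-base substitutions and reports the
per-position mean of |log2 fold change| over the three alternatives.

## uTIS strength benchmarking

A codon-plus-context window (AUG: −6…+5 with 6 nt upstream / 2 nt
downstream flanks; alternative codons: −3…+4) is embedded at a fixed
out-of-frame position (+1 frame, closest valid slot to the sequence
center) in uniform random backgrounds of length equal to the predictor's
receptive field. MRL is predicted with the codon active and deactivated
(AGG, for all codon classes), and the fold change is averaged over 100
seeded backgrounds — plain-scale averaging by default, log2 optional.
The *same* background set serves every context (a paired design: between-
context comparisons are then free of background sampling noise). Contexts
containing an unintended AUG — any flank AUG for AUG contexts, any AUG at
all for other codons, in either the active or deactivated form — are
excluded with a reason. Predicted effects are correlated (Pearson and
Spearman) against measured strengths; strong contexts repress harder, so
the expected correlations are negative. Benchmarked against the simulator
oracle in a 14 nt window (too short to admit any background uTIS), the
mean fold change is exactly affine in the context's initiation
probability, and the benchmark recovers the generating PWM with
Pearson = −1.

## Evaluation utilities

- **Contribution scores**: exact input gradients (`raw_gradient`), or
  gradient × input, which zeroes off-sequence channels.
- **Paired bootstrap comparison**: resamples (pred_a, pred_b, obs) triples
  jointly, takes the per-replicate correlation difference, and reports
  mean ± `multiplier × SD` over 100 replicates (standard deviations, not
  standard errors — more replicates must not shrink the interval). The
  default multiplier 3.54 corresponds to a Bonferroni-style correction
  over 24 comparisons at the 95% level and is taken as a direct parameter
  rather than derived, since the published derivation does not reconcile
  exactly under the standard normal arithmetic.
- **Endogenous-measure preprocessing** as pure functions: translation
  efficiency TE = RPF/RNA with exclusion below 10 Ribo-Seq reads or at
  zero RNA; replicate filtering at 1 TPM (either replicate) then
  averaging; median protein-to-mRNA ratio across tissues ignoring missing
  values.

## Numerical choices and degenerate inputs

- Channel order fixed (A, C, G, U); T maps to U on input; N one-hot
  encodes as an all-zero row (the padding value) and invalidates k-mer
  windows that contain it.
- Framed k-mer occurrences are assigned the frame of their first base, so
  in-frame AUG counts land in frame block 0.
- Max pooling ties break to the first (3'-most within slice) position;
  the routed gradient is a valid subgradient.
- Empty frame slices pool to 0; `log2` fold changes with non-positive
  predictions become error records, not exceptions, in the pipeline table.
- Early-stopping "improvement" means strictly lower validation MSE.
- Non-finite training loss aborts with a diagnostic.

## Known limitations

- uORFs longer than the 19 nt receptive field cannot be reliably detected
  by the main architecture (the dilated baselines see further but lose
  frame awareness).
- The architecture senses which frames contain uTIS and how strong they
  are, but not their 5'→3' order, which true scanning respects.
- The simulator is structural, not biophysically calibrated; absolute MRL
  values and effect sizes are on its own scale.
- The numpy implementation is CPU-only and single-threaded except for
  BLAS; it trains the full 282,625-weight model at roughly 20 s per
  20,000-sequence epoch, which is fine for desk-scale studies but not for
  the full 260,000-sequence MPRA without patience.
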