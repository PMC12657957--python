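# Methods

`ribodwell` models codon-resolved ribosome footprint profiles from coding
sequence under a replete control and five branched-chain amino-acid
deprivation conditions (LEU, ILE, VAL, LEU+ILE, LEU+ILE+VAL), and interprets
the fitted model through gradient attributions and counterfactual codon
mutations. This note records the model, the numerical choices, and what the
synthetic test substrate does and does not establish.

## Data model and preprocessing

A sample is one gene in one condition: an in-frame codon sequence
`s = (c_1 … c_n)` with a control profile `y_CTRL`, a condition profile
`y_DC`, and the derived difference `y_ΔD = y_DC − y_CTRL`. Counts are
non-negative reals; a missing value (`NA` in files, `NaN` in memory) is
distinct from an observed zero. Positions are 0-based codon indices.

Preprocessing, in order:

1. **Replicate merge.** Each replicate is divided by its own mean over
   annotated positions (depth scaling), then replicates are averaged
   position-wise over non-missing values. A position is missing only if it
   is missing in every replicate. The scale-then-average order is a package
   choice; the alternative (merge-then-scale) differs only when replicate
   annotation patterns are very uneven.
2. **Normalization.** `y(i) ← log(y(i)/mean(y) + 1)` with the mean over
   annotated positions. The transform is invariant to library depth.
3. **Filters.** A sample is rejected if (a) it contains a run of more than
   20 consecutive observed zeros (missing values break a run — the filter is
   about observed zeros, not gaps), (b) the gene exceeds 2000 codons, or
   (c) coverage — the fraction of annotated positions with non-zero counts —
   is not strictly greater than 30%. The rejection reason reports the first
   failing rule in this fixed order; the decision itself is order-independent.
4. **Split.** Genes are sorted by coverage (a gene's coverage is the max
   over its samples; ties broken by gene id) and walked in the repeating
   order train → val → test, skipping val/test once they hold 5% / 20% of
   the pre-split sample count. All samples of a gene share its split, so a
   gene never leaks across splits, and the well-annotated genes populate
   the held-out sets.
5. **Interpretability set.** Samples rejected only for length, plus
   deprivation samples whose difference profile shows a codon-specific
   response in a likelihood-ratio test: Gaussian working likelihood, null =
   one mean for all annotated ΔD values, alternative = separate means for
   deprived-codon positions vs. the rest with shared variance;
   `Λ = n·log(σ̂₀²/σ̂₁²)` referred to χ²(1). The Gaussian working model and
   df = 1 are package choices; the test is a screen, not an inference tool.

## Model

Codon tokens (64) and the condition identifier (6) have separate learnable
embeddings of width `D`; the condition embedding is added at every position,
keeping the sequence length unchanged. The backbone is a stack of
bidirectional relative-position multi-head attention blocks in the
Transformer-XL parameterization:

    e_ij = (x_i W^Q + u)(x_j W_E^K)^T + (x_i W^Q + v)(r_{i−j} W_R^K)^T
    α_ij = softmax_j(e_ij / sqrt(d_head))
    h_i  = Σ_j α_ij (x_j W^V)

with fixed sinusoidal relative encodings `r_{i−j}` (distances clipped at the
sequence length), pre-norm residual blocks, a GELU feed-forward, and a final
layer norm. A bidirectional tanh-RNN backbone with the same input/output
contract is available as a drop-in alternative (`backbone="birnn"`); it is
exercised at small scale only. Two linear heads read out per position: the
control head predicts `y_CTRL` and the difference head `y_ΔD`; the condition
prediction is their sum by construction, so the DC identity
`ŷ_DC = ŷ_CTRL + ŷ_ΔD` holds exactly for every forward pass.

The 1/√d_head score scaling and the GELU activation follow the standard
practice for this architecture family. GELU is also load-bearing for
interpretability: a smooth network makes the attribution path integral
(below) converge rapidly in the number of quadrature steps, where a kinked
(ReLU) network does not.

Numerical choices: layer-norm variance floor `LN_EPS = 1e-2` — deliberately
large so that the normalization transition along the attribution path from
the zero baseline is wide enough for 64-step quadrature to resolve (fit
quality is indistinguishable from smaller floors on the synthetic data);
parameters float32 for training, float64 wherever gradients are compared
with finite differences.

Everything — the model, backprop, Adam, and integrated gradients — runs on a
small reverse-mode autodiff tape over numpy arrays (`autodiff.py`), with a
graph-free inference path (`fast_forward`) that is tested to be identical to
the tape forward.

## Training loss and metrics

    L = 3 − r(y_CTRL, ŷ_CTRL) − r(y_ΔD, ŷ_ΔD) − r(y_DC, ŷ_DC) + MAE(y_DC, ŷ_DC)

where `r` is the Pearson correlation and all terms are computed over
pairwise-annotated positions only; missing targets are masked out of every
term while predictions are still produced everywhere (needed for
imputation). A correlation term whose target is degenerate (fewer than two
annotated positions or zero variance) contributes zero rather than aborting
the step. The MAE term is the mean absolute error, per the loss's verbal
definition; a 1e-12 floor inside the square root guards the prediction-side
variance at initialization.

Evaluation metrics, all masked pairwise: Pearson r; Spearman ρ with
midranks for ties (equivalently Pearson on midranks — the classic
`1 − 6Σd²/(n(n²−1))` form assumes distinct ranks); MSE; and MAAPE
`= (100/N) Σ arctan(|y − ŷ| / max(|y|, 1e-6))` — the ε guard exists because
observed counts can be exactly zero. The headline number throughout is the
macro-averaged DC Pearson correlation: per-sample r between predicted and
observed condition profiles, averaged within condition, then across
conditions.

Training: Adam with cosine learning-rate decay (default peak 2e-3), batches
bucketed by sequence length with padding masked out of attention and loss,
early stopping on macro val DC-PCC, and the best-validation checkpoint
returned. Every random draw (init, batch order) is seeded, and the full
pipeline is reproducible bit-for-bit given its seeds.

## Pseudo-labeling

A teacher ensemble of 5 models differing only in initialization seed is
trained on the (un-imputed) train split. The ensembled prediction
`ŷ*_DC = Σ_s ŷ^s_DC / |S|` fills the missing DC targets of train samples
only — values clipped at zero, since profiles are non-negative; annotated
positions are untouched (asserted bit-exact in tests), and val/test are
never imputed. For control samples the filled value is written to both
profiles so the control identity `y_DC = y_CTRL` is preserved. The
difference target is recomputed and stays missing where the control profile
is itself missing. A fresh student (new seed) is then retrained on the
completed train split. Imputation operates on the normalized log scale, the
same scale on which all modeling happens.

## Attributions

Integrated Gradients explains one head's output at one A-site as per-codon
contributions: the straight-line path integral of the output gradient from a
zero embedding to the input embedding (codon + condition), summed over the
embedding axis to one value per codon. The quadrature is a Riemann sum with
midpoint samples over a warped partition `α = t³` with exact cell widths as
weights: the integrand has a boundary layer where the layer-norm variance
crosses its floor near the zero baseline, and the warp concentrates cells
there. Weights summing exactly to one makes attributions on a linear model
exact. At 64 steps the completeness identity `Σ_j a_j = f(x) − f(baseline)`
holds to well under 1% relative on the trained synthetic models (the package
asserts < 1%). The relative check is evaluated at sites where the head
meaningfully responds, |f(x) − f(baseline)| ≥ 0.1 on the log-profile scale:
where the explained difference is near zero the ratio is undefined (absolute
errors there are ~1e-3 regardless). The default is 64 steps; summaries over
many sites use 32 steps, where completeness precision is not needed.

Aggregation around stalling: peaks are annotated positions strictly above
mean + 1 sd of the profile's annotated values (troughs: below mean − 1 sd;
population sd), computed on the footprint profile for control samples and on
the difference profile for deprivation samples, with the matching head
(control head for control samples, difference head otherwise). Attributions
in the 21-codon significance window (A-site ± 10, truncated at CDS edges)
are max-abs normalized with signs kept — positive means the codon's presence
increases the predicted count, i.e. slows the ribosome. Summaries: the top-k
(default 5) signed salient window positions relative to the A-site; the
per-codon mean of normalized attributions over all occurrences inside
analyzed windows; and the Pearson correlation between those codon means and
the codon-wise mean (Δ)count.

## Counterfactual motif search

"Fast" windows are significance windows whose A-site lies in a trough of the
(difference) profile. For each window the model scores in-silico codon
substitutions by the predicted change at the A-site on an arctangent
percentage scale:

    s = sign(ŷ_mut − ŷ_orig) · 100 · arctan(|ŷ_mut − ŷ_orig| / max(|ŷ_orig|, 1e-6))

A beam of width 5 keeps the best single substitutions (motifs-L1), freezes
each, extends with the best remaining substitutions (motifs-L2 = 25), and
once more (motifs-L3 = 125) — 155 motifs per window, every level scored
against the unmutated baseline. The substitution alphabet is the 61 sense
codons (the CDS stays translatable), a codon is never "mutated" to itself,
frozen positions are never re-mutated, and ties break deterministically by
higher score, smaller relative position, then codon order. The model is
evaluated on the 21-codon window itself (A-site at offset 10) rather than
re-embedding the full gene per mutation — a locality assumption consistent
with the attribution finding that the A-site's prediction is dominated by
its ±10-codon context, and what makes 155 motifs × thousands of candidate
scores tractable.

Motifs are written as [SKIP]-gapped codon strings anchored at their smallest
relative position, e.g. `GTC [SKIP] GTC` at −3. Validation: for the 50 most
frequent motifs per condition, occurrences of the gapped pattern ([SKIP] =
any codon) are counted at alignments lying fully inside the merged
peak-window region versus everywhere else, candidate start positions are
partitioned the same way (overlapping windows merged first so nothing is
double-counted), and a two-sided Fisher exact test per motif is corrected
with Benjamini–Hochberg across the tested motifs.

## Synthetic data generator

The generator is first-class code and the package's only test substrate.
Expected log-intensity at position i is the sum of: a per-codon base dwell
(N(0, 0.5) draws), context-kernel contributions from neighboring codons
(defaults emulate poly-basic and acidic context effects), end-bias terms at
offsets −5 and +3 emulating footprint-end technical artifacts (amplitude
0.15, applied to the shared core so they cancel in the difference profile,
as technical artifacts do), and — under deprivation — planted stalling
effects on the deprived codons. Defaults: VAL +1.0 at the A-site (strongest),
ILE +0.8 plus +0.4 at offset −4 (a planted long-range determinant), LEU
+0.3 (mildest); combined conditions take unions. Observed counts are the
exponentiated intensity × per-replicate depth (lognormal around 50) ×
multiplicative lognormal noise (σ = 0.3), with missing runs (start rate
0.08/position, geometric mean length 2) — two replicates per condition, 200
genes of 150–400 codons in the default fixture. All draws flow through one
seeded generator in a documented order, and every planted parameter is
retrievable via `ground_truth`.

What the generator does *not* emulate: integer read sampling (counts are
continuous, as all modeling is post-normalization) — a consequence is that
observed zeros never occur, simulated coverage is always 1, and the
zero-run/coverage filters plus the coverage-sorted split ordering are
exercised on constructed fixtures rather than on generator output; ribosome
traffic and initiation limitation; fragment-length/P-site-offset read-level
effects; batch effects between data sources; and any 5'/3' ramp. Tests passing on
this substrate therefore show that the machinery recovers planted signal
under realistic noise, missingness and coverage — not that the model
attains any particular accuracy on real ribosome profiling data.

## Problem sizes used by the test suite and acceptance script

Chosen as desk-scale runs of the same pipeline: recovery runs train the
default small configuration (D = 64, 2 layers, 4 heads, feed-forward 128)
for 3 epochs on the 200-gene fixture (the planted signal saturates the
validation correlation within 2 epochs); attribution summaries use up to 80
peak sites at 32 steps; the beam search runs on 50 valine windows at width
5, depth 3; pseudo-labeling mechanics run on a 40-gene fixture with ~30%
missing targets, an ensemble of 5, and a 1-layer D = 32 model. The "shuffled
label" control for motif recovery redraws the deprived-codon set uniformly
among sense codons 200 times and compares the observed deprived-codon rate
among motif mutations with the shuffled mean.

## Known limitations

* The relative-attention oracle, gradient checks and IG exactness are
  verified in float64; training runs float32, where reductions are accurate
  to ~1e-6 relative — bit-reproducible, but not bit-portable across BLAS
  implementations.
* The recurrent backbone is a contract-compatible alternative, not a tuned
  baseline; it is slow in this numpy implementation (a Python loop over
  positions).
* The enrichment test conditions on the discovered motif list; p-values are
  screening statistics, not selective inference.
* With fewer qualifying trough windows than requested, the search returns
  all of them with a warning rather than sampling with replacement.
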