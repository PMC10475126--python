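# Methods

## Problem setting

Cas9-dependent base-editor off-targets arise because the Cas9 module
tolerates imperfect matches between the 20-nt gRNA protospacer and genomic
DNA: sites with a few mismatches, or with a one-to-two-base bulge on either
strand, can still be deaminated. `beoff` models the resulting activity as
the **off:on-target ratio** — the editing efficiency of an off-target site
divided by the same gRNA's on-target efficiency — which removes gRNA-level
efficiency variation and leaves a pure measure of mutation tolerance.
The package covers the full path from pooled-screen reads to a trained
predictor of that ratio for arbitrary gRNA/candidate-site pairs.

## Screen quantification (`beoff.screenproc`)

Each library oligo couples a gRNA to its designed target on one molecule:

```
left(20) gRNA(20) BsmBI(11) barcode1(20) BsmBI(11) barcode2(15)
GTACT  protospacer+PAM-N (variable)  GG  right(18)
```

Processing rules, in order:

1. bases with Phred score < 10 are masked to `N`;
2. a read is **valid** only if both designed barcodes jointly identify a
   unique oligo (an `N` inside a barcode invalidates the read — exact,
   conservative matching) and its gRNA segment is consistent with the
   design at all unmasked positions;
3. a read is **edited** if at least one editable protospacer base shows
   the canonical conversion relative to the *designed* target (A→G for
   ABE, C→T for CBE). Reads with `N` at an editable position are excluded
   from both numerator and denominator — the read is uninformative about
   editing, and counting it either way would bias the efficiency;
4. `efficiency = edited / valid`, with pairs under **100 valid reads**
   dropped (threshold configurable);
5. replicate efficiencies are averaged; the off:on ratio divides each
   off-target's merged efficiency by its group's on-target value. Ratios
   above 1 are kept for analytics and clipped to [0, 1] only as regression
   targets, because the model head is a sigmoid.

"Edited" is judged over the whole protospacer by default, with a
window-only mode (`window=(lo, hi)`, 1-based) available; the editable-base
override in prediction uses window positions 3–9 by default, approximating
the deamination window at the 5' end of the protospacer.

## Sequence representation (`beoff.seqrep`)

A pair is aligned end-to-end (Needleman–Wunsch; match +1, mismatch 0,
gap −0.5) and both gapped strings are encoded over the fixed vocabulary
`{<pad>:0, A:1, C:2, G:3, T:4, -:5}` with right padding to the batch
maximum. Gap columns are DNA bulges (gap in the guide = extra target base)
or RNA bulges (gap in the target). Ties among co-optimal alignments are
broken deterministically: the traceback walks from the end preferring
substitution, then gap-in-target, then gap-in-guide. Library-designed
variants carry their designed alignment and never pass through the
aligner — the design *is* the ground truth. Mutation-type labels count
substitutions and gaps over the protospacer columns only (the trailing
three non-gap guide bases, the PAM, are excluded).

## The regression model (`beoff.deepmodel`)

Both integer sequences are embedded with two tables that share
initialisation settings but not weights, and fused by elementwise sum
(E = E1 + E2); the fused matrix feeds a stacked bidirectional LSTM whose
per-position states H are pooled three ways — final hidden states h_Last,
positionwise max, and additive attention (score vᵀ tanh(W h_t + b),
softmax over non-pad positions) — concatenated into c = [h_Last; F_max;
F_attn] and passed through a fully connected head 6H → 3H → 1 with a
sigmoid, so predictions live in (0, 1). Two rule-based overrides follow:
a candidate identical to its on-target returns exactly 1, and a candidate
with no editable base in the editing window returns exactly 0.

The training loss is a mean squared error with inverse-prevalence weights
per mutation type, computed within each batch: with n samples, K types
present and n_k of type k, each sample of type k weighs n/(K·n_k), so
weights always average to 1 and rare classes (deletions, mixed mutations)
are not drowned out by the mismatch-heavy library.

Optimisation is Adam with a learning-rate ladder 1e-3 → 1e-4 → 1e-5 →
5e-6, stepped down when the internal-validation Spearman (on a held-back
10% of training *groups*) plateaus for 3 epochs; training stops early
after 8–10 plateau epochs with the ladder exhausted, and the
best-validation weights are restored. Dropout (0.5 in the full
configuration) acts between recurrent layers and after the first head
layer. All randomness (initialisation, batch order, dropout, validation
group choice) flows from one seed, making the full train→predict path
bit-reproducible on fixed hardware settings.

The published-scale configuration (embedding 256, hidden 512, 2 layers,
head 3072 → 1536 → 1) is the `ModelConfig` default. The model runs on the
package's own tape-based reverse-mode autodiff core (`beoff.autodiff`),
whose gradients are pinned to central finite differences in the tests;
the benchmark configuration (`ModelConfig.small()`: embedding 32, hidden
48, 2 layers, dropout 0.2, batch 256, ≤50 epochs) is sized so a full
train/evaluate cycle completes in minutes on one CPU core.

Splits are **group-aware throughout**: every on-target group (a gRNA and
all its designed variants) lands wholly in one partition, and
`train_model` refuses any split with group overlap. The k-fold splitter
chunks shuffled unique groups, so 1110 groups at 10 folds give exactly
999 training and 111 test groups per fold.

### Attribution

Positional attribution uses integrated gradients on the fused embedding:
the path runs from the all-pad baseline embedding to the input embedding,
a midpoint Riemann sum over `steps` points (default 50) approximates the
path integral, and per-position scores sum the attribution over embedding
dimensions. The all-pad baseline is the natural "absent sequence"
reference. Completeness (Σ attributions ≈ f(input) − f(baseline)) is
verified in the tests with the error shrinking as steps grow. Cohort
profiles average scores per alignment column across a testing set,
stratified by mutation type and mutated-vs-matched status; on the
synthetic benchmark, mutated positions attribute negative on average
while matched positions stay near zero on the (0, 1) output scale.

## Baselines (`beoff.baselines`)

Features per pair: position-dependent 1-mer indicators over {A, C, G, T, -}
for both aligned sequences (padded to 26 columns), position-independent
1-mer counts, off-target GC fraction, and a nearest-neighbor RNA/DNA
duplex free energy — a 2-bp window slides along the alignment and adds
its dinucleotide ΔG only when both columns match; windows touching a
mismatch or gap contribute 0. The shipped table is the Sugimoto 1995
RNA/DNA hybrid ΔG°37 set keyed by the guide-strand dinucleotide (T for U);
`EnergyTable` is swappable and the exact parameter set does not change
any contract. Linear regression, ridge, a multilayer perceptron and
gradient-boosted trees (XGBoost) are tuned with an in-repo Tree-structured
Parzen Estimator (top-quantile/rest Parzen densities, expected-improvement
ratio; deterministic per seed) on an inner group-aware validation block,
then refit on the full training side. Search spaces: ridge α ∈ [1e-3, 1e3]
(log); MLP width {32, 64, 128} × depth {1, 2}, α and initial rate (log);
XGBoost trees 100–500, depth 3–8, learning rate 0.02–0.3 (log), subsample
and column subsample 0.6–1, λ 0.01–10 (log).

## Synthetic data (`beoff.synthetic_data`)

The generator emulates the screen's *structure*, not its biology. Each
group gets a random protospacer (guaranteed an editable base in the
editing window) plus designed variants — default per group: 4×1mis,
2×2mis, 1 each of 3mis/1ins/2ins/1del/2del/mix, echoing the
mismatch-heavy composition of real libraries. The planted off:on ratio of
a variant is multiplicative over its events: each mutated position p
contributes a retention factor π(p) (default 0.95 at positions 1–10,
declining linearly to 0.45 at position 20) times a class multiplier
(mismatch 1.0, insertion 0.9, deletion 0.7) — the simplest structure
consistent with positional tolerance falling toward the PAM and deletions
being most disruptive. On-target efficiencies are Beta(5, 2); replicate
efficiencies add independent Gaussian noise (sd 0.02), which puts the
inter-replicate Pearson in the high-correlation regime the screens
operate in (≈0.97 at the default variance). Reads follow the oligo layout
exactly; edited reads convert every editable protospacer base (a
maximally-converted read model — adequate for the ≥1-conversion edit
call, not a model of partial-window editing); barcode corruption and
low-quality bases (default rate 0.002, Q2 vs Q40) are planted at
configured rates.

What passing on this generator does **not** show: real screens have
sequence-context-dependent editing, partial-window conversion, position-
and type-correlated effects richer than a product of per-position
factors, and non-Gaussian replicate structure. Synthetic recovery
demonstrates that the pipeline is correct and that the model can learn a
positional tolerance structure of this kind — not that it attains any
particular accuracy on biological data.

## Benchmark sizes

The standard benchmark trains on 250 groups × 12 off-target variants
(≈3,000 pairs), holding out one of 10 group-folds, with `ModelConfig.small`;
the read-level simulation in the acceptance script uses 12 groups at 150
reads per oligo and replicate. These sizes are the package's reference
configuration for single-CPU runs; all of them scale up through
`GeneratorConfig`/`ModelConfig` without code changes.

## Numerical and degenerate-case choices

- z-scores use the population sd (ddof=0) by default, configurable;
  constant groups are flagged as degenerate rather than emitted.
- Position-pair comparisons use Welch's unequal-variance t-test by
  default (pooled-variance Student available); Bonferroni adjustment is
  min(1, p × m) over the m comparisons actually made.
- Spearman on a constant vector is undefined: baseline fitting warns and
  reports NaN; stratified evaluation reports NaN for strata under 3 pairs.
- Attention masking adds −1e30 before the softmax and multiplies by the
  mask after exponentiation, so pad positions carry exactly zero weight.
- The max-pool gradient flows to the first argmax on ties.
- A missing replicate either drops the pair (default) or keeps the
  surviving value, flagged, under `missing_policy="single"`.

## Known limitations

- The recurrent core is CPU-bound numpy; the published-scale configuration
  trains slowly and is intended for release-gate runs, not iteration.
- The aligner's tie-break is a convention; designed alignments (which
  bypass it) are authoritative where available. Printed library
  alignments whose gaps sit mid-homopolymer are score-equivalent to, but
  not textually identical with, the convention's output.
- `nontarget` controls are recognised in the taxonomy but not emitted by
  the generator.
- Genome-wide candidate enumeration is out of scope; Cas-OFFinder-style
  candidate lists (plain and bulge-annotated dialects) are consumed as
  input instead.
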