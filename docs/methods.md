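# Methods

This note records the models, conventions and numerical choices behind
`bekit`, and what the synthetic-data experiments do and do not demonstrate.

## Coordinates and sequence conventions

Protospacer positions are 1-based; position 1 is PAM-distal and position 20
abuts the PAM. Locus offsets are 0-based half-open on the given (sense)
strand. A target site always lives on the strand carrying the target adenine:
C-to-T variants (T on the sense strand) are designed on the antisense strand,
because ABEs deaminate adenine only. Degenerate IUPAC letters in input
sequences are rejected rather than expanded.

The stored `pam_context` is 4 nt: the designer validates only its first 3 nt
against the requested PAM classes (matching how tiling libraries are built),
while the prediction model consumes all 4 nt. The 3' flank field starts
immediately after the 3-nt PAM, so the fourth PAM base equals `flank3[0]`.

`frame_offset` is the codon phase of protospacer position 1 *on the
protospacer strand* (0 = position 1 opens a codon), or `"noncoding"`. The
designer derives it from the supplied phase of the variant base; bystander
silent/non-silent calls read codons on the protospacer strand through the
standard genetic code. Genes coded on the opposite strand should supply the
phase already projected onto the protospacer strand; no splice-site logic is
applied. Codons that run past the available flank context are treated as
non-silent (conservative).

## Tiling design

Candidate protospacers place the target adenine at positions 6, 5, 7, 4, 8,
3, 9, 2, 10, 11, 12 — in exactly that priority order — and a candidate is
kept only when a PAM of an allowed class sits at positions 21–23. At most six
guides are emitted; positions, not PAMs, define candidates, so a position with
several matching classes still yields one guide. Loci yielding fewer than
five guides are logged. The designer is validated in the test suite against
an exhaustive oracle that enumerates all eleven candidates and truncates to
six.

## Outcome space and algebra

An editing outcome is the subset of protospacer adenines converted to G;
indels and non-A→G conversions are excluded from the outcome space and
accumulate in a separate "other" read bucket during quantification, so all
probabilities are conditional on clean A→G outcomes. The outcome space of a
site is capped at 2^12 by restricting the editable set to the 12 adenines
closest to position 6 (distance ties break PAM-distal); adenine counts above
12 essentially do not occur in designed libraries. Total efficiency counts an
edit anywhere in positions 1–20 (a positional window filter is exposed
separately). All transforms preserve normalization to 1e-9, and the
recombination identity `unedited + efficiency × conditional = original` is
exact by construction.

## Quantification

Reads are assigned to library members by exact match of the 20-nt spacer
(with its 5'-G substitution) anchored immediately before the scaffold;
duplicate spacers are rejected up front. Within the target cassette, a length
change is treated as an indel and bucketed "other"; substitutions are
compared against the reference protospacer, A→G differences set outcome mask
bits, and more than `mismatch_budget` (default 1) other mismatches send the
read to "other". Read totals are conserved (assigned + other + unassigned).
The cassette layout (flank length used at oligo synthesis) must be supplied
when it differs from the 30-nt default.

Summary statistics deliberately mirror the standard screen readouts: mean
total efficiency per 3-nt PAM (4×16 matrix, empty cells reported as missing,
never zero), per-position editing-window profiles whose denominators count
only sites carrying an adenine at that position, trinucleotide (5'N-A-3'N)
motif proportions split at the dataset mean efficiency (a site exactly at the
mean joins both splits, which keeps the degenerate all-equal case
well-defined), and both mean and median aggregations where relevant.
Bystander classification uses ≥10% on-target and ≤0.5% bystander cut-offs
with the *worst single* non-silent bystander (not their sum); sites without
frame annotation are classified conservatively and flagged.

## The synthetic screen generator

The generator is the package's ground-truth oracle. Each "gene" is one
pathogenic-variant locus (random 80-mer with a planted adenine) pushed
through the real tiling designer, so its 2–6 sgRNAs share sequence context —
exactly the leakage structure that motivates gene-level splitting.

Per-adenine latent propensity is a product of independent factors:

    x(p) = base_rate · window(p) · context(5'N-A-3'N) · pam_activity(PAM)

with a Gaussian positional window parameterized by its full width at half
maximum (11 positions for the ABE8e-like profile, 7 for the ABEmax-like one),
mild context multipliers with an elevated T-A-C motif, and SpRY-like PAM
activities (NGN 1.0, NAN 0.85, NYN ≈ 0.2).

The delivery-dose response acts on the **site-level** latent total
efficiency: `E = ceiling · (2/(1+exp(−dose·T)) − 1)` where
`T = 1 − ∏(1 − x(p))`, and per-adenine rates are rescaled by a common factor
(bisection) so that independent per-A editing reproduces `E`. For a single-A
site this reduces to saturating the adenine itself. Site-level saturation was
chosen over independent per-adenine saturation because only the former
reproduces the two phenomena high-dose screens show: a histogram of
efficiencies piling up near the ceiling (mode ≈ 0.42 with the default
ceiling of 0.45 at high dose) and degraded rank agreement between saturated
and unsaturated conditions; with per-adenine saturation, site totals remain
dominated by each site's adenine count and neither effect appears.

Replicate noise is a per-site, per-replicate shift on the log-odds of the
site total (sd `noise_sd`), followed by multinomial sampling at the requested
depth. An optional pairwise-interaction term multiplies outcomes by
`(1+interaction)` per adjacent co-edited pair, breaking the per-A independence
that the generative model otherwise assumes — the proportion predictor makes
no such assumption and can be tested against it.

Defaults (all exposed in `EditorProfile`/`DoseModel`/`generate_screen`):
unsaturated condition `dose = 2.0`, saturated `dose = 8.0`, `ceiling = 0.45`,
`depth = 5000`, three replicates, `noise_sd = 0.2`. These were set so the
simulated data land in the ranges screens of this kind report: replicate
Spearman ≈ 0.8, unsaturated median efficiency ≈ 0.28 for the ABE8e-like
profile, saturated-vs-unsaturated dataset Spearman ≈ 0.65 against
unsaturated-vs-unsaturated ≈ 0.85–0.9.

What passing simulator-based tests shows: that the pipeline recovers the
structures the generator encodes (windows, PAM classes, motifs, dose effects)
and that the model learns sequence-to-efficiency maps of realistic shape from
realistically noisy multinomial data. What it does not show: performance on
real screens, whose noise is not purely multinomial, whose context effects
are richer than a product model, and whose outcome space includes the indels
and contaminating edits the simulator omits.

## The prediction model

Two components with one tokenizer (A/C/G/T + padding, learned positional
embeddings; input modes: protospacer only, protospacer + 4-nt PAM (default),
or additionally ±5-nt flanks):

- **Efficiency**: a pre-norm transformer encoder (2 layers, 4 heads,
  embedding 64, feed-forward 128, dropout 0.1), mean-pooled, with a linear
  head squashed through a sigmoid. Loss: binary cross-entropy against the
  observed efficiency as a soft label, weighted by read depth.
- **Proportion**: the same encoder architecture with shared weights applied
  to the reference and to each candidate outcome sequence; pooled
  representations are concatenated and scored by a small MLP, and scores are
  softmax-normalized across the site's enumerated edited outcomes. Loss:
  cross-entropy against observed conditional frequencies, weighted by each
  site's edited-read count; sites with no edited reads are excluded. For
  adenine-rich sites the training pairs are subsampled to 32 outcomes per
  site (all observed plus random unobserved ones); the segment cross-entropy
  is minimized by the renormalized conditional, so subsampling biases only
  the negative support, not the target.

The combination multiplies the two outputs into a full outcome distribution;
per-position predictions are its exact marginals. Architecture sizes were
chosen for single-CPU training in minutes on 24-token inputs; the encoders
run on a purpose-built numpy reverse-mode autodiff engine whose every
operation is gradient-checked against finite differences in the test suite.
Computation is float32 (float64 for the gradient-check tests); checkpoints
are single `.npz` files carrying weights, configuration and training history,
and round-trip bit-identically.

Training uses AdamW (lr 1e-3, weight decay 0.01), batch 256, up to 30 epochs
with early stopping (patience 5) on validation Spearman when a validation set
is given, otherwise on training loss, restoring the best weights. All
randomness (initialization, shuffling, dropout, splits) flows from one seed.
Splits are performed on genes, never sites: test and validation gene counts
are rounded to the nearest integer (200 genes at 80/10/10 → 160/20/20) and
the remainder trains.

The estimator surface follows scikit-learn (fit/predict,
`get_params`/`set_params`, fitted attributes with trailing underscores) so the
efficiency model composes with sklearn model selection; the designer,
quantification and simulator are not fit/predict-shaped and remain plain
functions over typed containers.

## Evaluation and experiment harnesses

`evaluate` reports Spearman and Pearson over per-site total efficiencies, and
pooled per-base correlations computed from the full predicted distributions on
a seeded subsample of at most 100 sites (full outcome enumeration per site
makes per-base evaluation the most expensive step). `learning_curve` trains
one model per nested, gene-level subset of the training partition (10–100%)
against a fixed validation partition. `input_ablation` retrains per input
mode on a shared split.

The acceptance script scales the experiments to what one CPU completes in a
few minutes — 500 designer loci, a 200-site × 10,000-read quantification
round-trip, a 3,000-site screen for parameter recovery and the PAM ablation,
and 1,200-site screens for the saturation-transfer comparison. These sizes
are the package's reference experiment sizes; larger runs only tighten the
same comparisons.

## Known limitations

- The silent/non-silent bystander call assumes the supplied frame phase is on
  the protospacer strand and ignores splice sites and antisense-coded genes.
- Quantification handles substitution errors via the mismatch budget but does
  not model sequencing error rates, UMIs, or alignment; reads must span the
  full cassette.
- The proportion model's sampled-softmax training underweights never-observed
  outcomes of very adenine-rich sites.
- Simulator context effects are multiplicative by construction; epistatic
  context effects in real data are out of its scope (the interaction term
  covers only adjacent co-editing).
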