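# Methods

This note documents the models and procedures implemented in
`stfingerprint`, the choices made where the design was genuinely open, and
what the synthetic benchmarks do and do not demonstrate.

## Classifier

The stDNN treats a subject's `Nc x Nt` regional time-series matrix as an
`Nc`-channel 1-D signal. Two blocks of valid (unpadded) temporal
convolution + ReLU (default 64 then 32 filters, kernels 7 and 5, stride 1;
tests and the acceptance script use 32/16 and 16/8 variants, which train in
seconds at the cohort sizes simulated here) are followed by a masked
temporal average, producing one feature per filter. Variable run lengths
are handled by right-padding each batch to its maximum `Nt` and masking
every convolution output whose receptive field touches padding; the
temporal average divides by each subject's true number of valid positions,
so padded and unpadded presentations of a series produce identical logits
(this is asserted to 1e-6 in the tests). Inputs shorter than the combined
receptive field `k1 + (k2 - 1) * s1` are rejected with the required
minimum length.

The pooled features are concatenated with a one-hot encoding of the
subject's acquisition site and mapped to two class logits. Sites absent
from the training vocabulary encode as the all-zero vector: the site term
then contributes nothing, which is what allows the fold models to score a
cohort from entirely new sites without retraining.

### Output head and the margin loss

Training minimises the label-distribution-aware margin (LDAM) loss

    L(z, y) = -log softmax(s * (z - Delta .* onehot(y)))[y],
    Delta_j = C * n_j^(-1/4), rescaled so max_j Delta_j = 0.5; s = 30.

With `Delta = 0` and `s = 1` this is exactly two-class softmax
cross-entropy (asserted to 1e-12). The margins shrink with class size, so
the rare class is pushed to a larger decision margin; the `max_margin`
cap absorbs the constant `C`.

A fixed additive margin is only meaningful if the logit scale is
constrained: an unconstrained affine head can simply shrink its output
scale until any margin is trivially satisfied, which empirically erased
the margin's benefit and hurt minority generalisation. The training head
therefore normalises both the feature vector and the head weight rows and
uses cosine-similarity logits in [-1, 1], the construction under which
this margin form was originally derived. At inference and for attribution
the model is scored through the *evidence* head `f . w_j / ||w_j||` —
identical argmax decisions (the two heads differ by the positive factor
`1/||f||`) but positively homogeneous in the input, so attribution
magnitudes grade with signal strength rather than saturating at the
cosine bound. A plain affine head remains available (`head="linear"`).

The `cross_entropy` loss option keeps the same head and temperature and
only zeroes the margins, so the LDAM-versus-cross-entropy comparison in
the tests isolates the margin mechanism itself.

Optimisation is plain Adam (default learning rate 3e-3, batch size 16, 30
to 40 epochs at the simulated problem sizes), fully deterministic given
the seed; no batch normalisation, dropout or re-weighting schedules are
used. Margins are computed once from the training-set class counts.

## Evaluation protocol

Folds are stratified by class, and additionally by site whenever every
site x class cell has at least k members (members are dealt round-robin
with a running offset, which keeps per-fold class counts within one
subject of ideal); otherwise the assignment falls back to class-only
stratification with a warning. Each fold's model is trained on the other
k-1 folds (80% of the sample for k=5). Precision, recall and F1 are
computed per class and support-weighted averaged, with the raw per-class
values retained; summaries are means and sample standard deviations
(ddof=1) across folds. Decisions are the argmax of the logits — margins
act only at training time. `apply_models` evaluates the fold models on any
external cohort and implements both the transfer test (same generative
law, unseen sites) and the specificity test (signal-free cohort); the two
differ only in the cohort passed.

## Integrated gradients

Attribution of the target-class logit F uses the midpoint Riemann
approximation of the path integral from baseline x' to input x:

    IG_i = (x_i - x'_i) * (1/m) * sum_{t=1..m} dF/dx_i |_{x' + (t-.5)/m (x - x')}

with m = 50 by default. The baseline is the all-zero series — after
per-region z-scoring, the cohort-typical "no signal" reference; a
cohort-mean baseline is available. The site one-hot is held fixed along
the path, so completeness applies to the time-series input alone. For
affine F the rule is exact at any m; on trained ReLU networks the
completeness gap |sum IG - (F(x) - F(x'))| is below 1% of the logit
difference at m = 200 and shrinks roughly first-order in 1/m (the error is
concentrated at activation kinks crossed by the integration path; per-cell
agreement with a 100,000-step reference reaches 1e-3 of the attribution
scale around m = 800).

Group-level feature scores are nested medians — median across the target
group's subjects per fold model, then median across folds — computed on
*signed* attributions for the target-class logit (an absolute-value
variant is available via ``aggregate_group_features(..., absolute=True)``). Subjects are cropped to
the cohort-minimum `Nt` for stacking. The top-p% mask keeps the
`ceil(p% * Nc * Nt)` largest pooled consensus cells; ties at the threshold
value are all included and the achieved count reported. A region "hits" if
at least one of its cells survives; the pipeline's stricter *recovery*
flag additionally requires the region's cell count to exceed chance
scatter (binomial tail at 0.05), so a signal-free run reports an empty
recovery list even though the mask necessarily covers 5% of cells.

## Symptom association

Each subject's fingerprint is reduced to one scalar per region (temporal
mean of the signed attribution). The primary correlation uses the
per-subject score averaged across the k fold models; Spearman rho (mid-
ranks for ties) with the two-sided t-approximation p-value, then
Benjamini-Hochberg correction across all regions x domains within each
group. Per-fold-model consistency — the fraction of fold models whose own
corrected q falls below alpha (default 0.01) — is reported alongside,
covering both plausible aggregation orders. Constant inputs yield an
undefined rho, reported as missing and excluded from the FDR family.

## Synthetic cohorts

The generator emulates the structure the framework is designed for:

- **Noise:** stationary AR(1) per region (coefficient 0.3, unit marginal
  variance — baseline-sd units) plus a per-(site, region) constant offset
  (sd 0.5), the "scanner effect".
- **Sites:** subjects assigned round-robin to sites (default 3); each
  site draws its own run length uniformly from 96-128 timepoints, a
  scaled-down version of typical resting-state runs.
- **Imbalance:** default 80 vs 20 subjects, the 4:1 ratio characteristic
  of the clinical population that motivates margin-based training.
- **Group signal:** class-1 subjects receive, in a small planted region
  set, a sinusoid at 0.08 cycles/timepoint with one random phase per
  subject and region-specific amplitudes `a ~ Normal(effect, effect/4)`
  (default effect 2.0). The signal lives in oscillation *amplitude*, not
  in the mean, so detection requires temporal feature extraction — a mean
  detector finds nothing, and per-region z-scoring (the default
  preprocessing) removes means and offsets anyway.
- **Symptom link:** the "rrb" domain score is the subject's amplitude at
  one designated planted region plus Normal(0, 0.5) noise, for class-1
  subjects only; "social" and "communication" scores are pure noise for
  everyone. This mirrors a single-group, single-domain brain-behaviour
  association.

Transfer cohorts follow the identical law with a fresh seed stream and a
disjoint site vocabulary; the signal-free control cohort sets the effect
to zero with the training site names.

What these cohorts do **not** contain: hemodynamic response shapes,
spatial covariance between regions, motion artifacts, site x class
interactions, or heavy-tailed noise. Passing benchmarks here demonstrates that the
implementation is correct and that the framework recovers planted
structure under its own assumptions — not that comparable accuracies
would be reached on real imaging data.

## Problem sizes and numerical choices

Tests and the acceptance script run deliberately scaled-down studies: the
classification benchmark uses the default 100-subject, 30-region cohort
with 5 planted regions; the imbalance comparison uses 96 vs 12 subjects,
16 regions and threefold CV over 10 seeds; the association benchmark uses
60 + 60 subjects and 12 regions over repeated studies — the 60-per-group
size was set by a power analysis of the association stage: after
z-scoring, amplitude variation survives only as the oscillation's
variance *fraction*, capping the attainable score-symptom correlation
near rho 0.5, which at 20 subjects cannot reliably outrank 11 null
regions (the band-power oracle itself recovers the planted region only
~65% of the time there) but separates cleanly at 60.

Other numerical conventions: z-scoring uses the population sd and maps
constant rows to zeros (never NaN), making it idempotent; cohort TSVs are
written at %.17g so save/load round-trips are bit-exact; fold assignment,
training, generation and the pipeline's per-stage seeds all derive
deterministically from explicit seeds (the pipeline fans a single master
seed out through a fixed `SeedSequence` rule, so stages are independently
re-runnable); model files are single `.npz` containers with the JSON
config embedded.
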