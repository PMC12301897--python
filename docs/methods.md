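# Methods

This note documents the models, the synthetic data, the numerical choices,
and what the test suite does and does not establish.

## Synthetic cohort model

The generator (`eegage.synthetic`) produces longitudinal clinical-EEG
cohorts with known latent structure. Per subject: sex (female with
probability `sex_ratio`, default 0.55), a first-recording age uniform on
`age_range` (default 18–86 y), a **trait offset** drawn once from
N(0, `trait_sd`²) (default 3 y), and a recording count from a shifted
Poisson, 1 + Pois(mean − 1), with mean 2.5 — matching the skewed
recordings-per-subject counts typical of clinical archives. Intervals
between recordings are lognormal with configurable mean (default 12 months,
σ_log = 0.6), giving the month-to-year gaps that make change-rate
denominators meaningful. A `transition_fraction` of subjects (default 0.1)
flips pathology label exactly once, direction split 50/50 and flip position
uniform; all other subjects keep a constant label (pathological with
probability `pathology_fraction`).

The **effective age** that drives signal synthesis for a recording is

```
effective_age = chronological_age + trait_offset + state_effect · 1[pathological]
```

so `state_effect = 0` *is* the trait-only world and a nonzero `state_effect`
the state world; the two acceptance cohorts differ only in these knobs.

Each signal is pink noise (1/f power, 10 µV RMS) plus an alpha oscillation
with peak frequency `11.0 − 0.03 · effective_age` Hz, amplitude 20 µV
weighted by electrode site (occipital 1.0, parietal 0.7, temporal 0.55,
central 0.4, frontal 0.25). Pathological recordings get one delta and one
theta component (+50 % of the background RMS each) and 30 % alpha
attenuation — classic diffuse slowing. These coefficients are deliberate
stand-ins: the corpus the analysis targets provides no generative spectral
model, so the generator encodes age and pathology in well-understood EEG
features; every coefficient is a config field. Two age sources are written
per recording; a configurable fraction (default 5 %) disagree by a uniform
1–5 years, exercising the >1-year consistency filter. Reports are template
text; a fraction of subjects carry a condition keyword (schizo/depress/
stroke variants, mixed capitalization) for the subgroup search.

What the generator does **not** emulate: artifacts, sleep, epileptiform
activity, nonstationarity, realistic spatial covariance, or the corpus's
file naming. Passing tests therefore demonstrate that the *analysis
machinery* is correct and sensitive under its own assumptions, not that any
clinical effect size is reproduced.

## Preprocessing

The chain is applied in the order listed (the order is part of the
contract): channel selection to the configured 10-20 subset → amplitude
clipping to ±800 µV → common average reference → polyphase resampling
(Kaiser window, `scipy.signal.resample_poly`) to 100 Hz → dropping the
first 60 s. Clipping before re-referencing means a pathological outlier
also perturbs the common average at that sample; with the clinical bound
the re-referenced signal stays inside ±800 µV, making the chain idempotent
in practice (asserted in tests at realistic amplitudes; a much tighter clip
would break idempotence because projection operators do not commute).
Channel labels accept the clinical dialects `EEG <name>-REF`, `-LE`, and
bare names, case-insensitively, plus the T7/T8/P7/P8 synonyms.
Standardization statistics (per-channel pooled mean/SD) and the min-max
age scaling are computed on the training split only and carry a provenance
tag; ages outside the training range clamp to [0, 1] with a logged warning
rather than erroring, since evaluation cohorts may exceed the training
range.

Desk-scale studies shorten the head-drop to 10 s: synthetic recordings are
60–120 s, stationary, and artifact-free, so the 60 s clinical drop would
discard half the data for no benefit. The clinical values remain defaults
of `PreprocConfig`.

## Age regressor

A temporal convolutional network: `n_blocks` residual blocks (default 4),
each two dilated convolutions (kernel 5, dilation 2^i, valid/unpadded) with
ReLU and dropout 0.1, a skip path (1×1 projection on channel change,
left-trimmed for causal alignment), then a 1×1 convolution and a sigmoid.
The receptive field — 121 samples = 1.21 s at 100 Hz for the default — is
the crop length, so one crop yields exactly one output, and running the
unpadded network over a full recording emits the outputs of *all* maximally
overlapping one-sample-stride crops in a single pass (verified against
materialized crops to float precision). The per-recording brain age is the
unweighted mean of per-crop sigmoid outputs, mapped to years by the
training-split age range without clamping.

Training: L1 loss on scaled targets, AdamW (lr 2e-3, weight decay 1e-4),
cosine-annealed learning rate, batch 128, channel-dropout augmentation
(p = 0.1) applied to crops at training time only. Each epoch samples 16
random crops per recording rather than enumerating all crops — with ~6 000
crops per recording, full enumeration is redundant at desk scale; the
paper-scale epoch count (35) remains the default while desk studies use
8–10, which the loss curves show is past convergence on the synthetic
task. Only non-pathological recordings enter training; pathological ones
are inference-only. The implementation is plain numpy with hand-written
backward passes, which also provides the exact input gradients the saliency
analysis needs. Determinism: everything derives from one integer seed;
"identical given seed" holds bit-for-bit here because numpy reductions are
deterministic on one thread, but tests still compare with tolerances to
stay robust to BLAS variation.

Cross-validation splits *subjects*, not recordings (shuffled round-robin,
fold sizes within one), so no subject leaks across folds; every recording
is predicted exactly once out-of-fold. Final evaluation trains on all
training subjects and predicts a disjoint held-out subject set, repeated
`fe_runs` times with different seeds and averaged per recording.

## Gap, bias correction, metrics

`gap_raw = BA − CA` exactly. Because decoding error interacts with the
target (regression to the mean), the expected gap is modeled as a quadratic
in CA, least-squares fit on the pooled cross-validation predictions of
non-pathological recordings, then frozen and subtracted from every gap
(CV, final-evaluation, pathological) before any statistic is computed.
On its own fit set the correction is an orthogonal projection: the
corrected gaps have zero mean and a refit quadratic has ~0 coefficients
(asserted to 1e-8). Subjects with several recordings contribute their
per-(subject, status) mean gap to group comparisons.

R² is reported as the standard 1 − SS_res/SS_tot. The explained-variance
ratio Σ(ŷ−ȳ)²/Σ(y−ȳ)² — an alternative convention that coincides for
least-squares-calibrated predictors — is available as
`explained_variance_ratio`. APE is printed rounded to integer percent in
reports, full precision retained.

## Biomarker and longitudinal statistics

The biomarker is a closed interval [lo, hi] on the corrected gap: inside →
non-pathological, outside → pathological. Candidates are midpoints between
consecutive sorted unique gaps plus ±∞, which exhausts all achievable
interval rules; the pair maximizing BACC wins, ties broken by the widest
non-pathological interval then the smallest lower bound (deterministic).
Boundary values count as inside, per the rule's "within the thresholds"
reading. Thresholds are fit per CV fold and applied frozen to final
evaluation with BACCs averaged; the pooled-CV pair is used as the single
fixed rule of the BACC permutation test. The age-threshold baseline uses
the same machinery restricted to one cut (older → pathological), i.e. the
pair (−∞, t).

Change rates: per (subject, status), same-day recordings are averaged,
consecutive-date slopes Δgap/Δt (years, 365.25 d) are averaged per subject.
The moment-of-transition rate uses only the flip-adjacent pair (same-day
averaging within each side); zero or multiple flips, or a flip pair sharing
a date, are pattern errors. TNPP and TPNP rate distributions are compared
with KS, Wilcoxon–Mann–Whitney, and Brunner–Munzel.

## Statistical tests

The permutation machinery is implemented in-package. Mean-difference test:
statistic mean(A) − mean(B), null by reshuffling pooled membership at fixed
group sizes, two-sided, p = (1 + #{|stat*| ≥ |stat|})/(n + 1); the +1
smoothing keeps p valid and sets the floor 1/(n+1) (with 100 000 samples,
1e-5 — the resolution of the smallest reportable p). Biomarker test:
BACC of the *fixed* threshold pair under label permutation, one-sided
(greater), since the question is "better than chance". Sidedness choices
are recorded on the result objects. The classical tests delegate to scipy.
Because the fixed-rule BACC is a discrete (hypergeometric) statistic, its
permutation p-values are super-uniform under the null — valid but
conservative; the calibration test asserts exactly that. Calibration of
the whole battery (rejection rate 3–7 % at α = 0.05 under the null over
1 000 replicates) and the power of the transition comparison (≥ 0.8 with a
10-year state effect, ~50 transition subjects, decoder-like noise of
σ = 5 y) are asserted in the acceptance suite using latent-truth gaps, so
they measure the statistics rather than the decoder.

## Saliency

A crop x is written as the inverse DFT of amplitudes A and phases φ; with
φ held fixed, ∂out/∂A_{c,f} follows from the time-domain input gradient g
by the chain rule, ∂out/∂A_{c,f} = s_f · Re[e^{iφ_{c,f}} · conj(rfft(g)_{c,f})]
with s_f = 2/N (1/N at DC and Nyquist, numpy rfft convention) — verified
against central finite differences to <1e-3 relative error. Signed bin
gradients are averaged into delta (0.5–4 Hz), theta (4–8), alpha (8–12),
beta (12–30), gamma (30–50) per channel, then aggregated crop → recording →
subject → group → run; the difference map is NP − P. Gradients are taken on
standardized inputs (the model's actual input space). For tractability
crops are subsampled at a regular stride (default ≤ 32 per recording);
since the map is a mean over crops this changes sampling density, not the
estimand. Output is a channel × band table; no head-diagram rendering.

## Problem sizes and runtime

Desk-scale defaults: 8 channels (Fp1, Fp2, C3, C4, T5, T6, O1, O2),
100 Hz, 60–120 s recordings; the full 21-electrode set and 15-minute
durations are config options. The acceptance studies use 100–110 subjects,
3 CV folds, 2 final-evaluation runs, 8 epochs, and 2 000 permutations;
the end-to-end recovery check uses 200 subjects. These sizes were chosen so
the complete suite runs on a single CPU core in well under half an hour
while every qualitative claim (decoder beats baseline by >40 %, trait
recovery r > 0.5, transition power ≥ 0.8, null calibration) has a wide
margin.

## Known limitations

* The spectral aging model is a stand-in; coefficients are not fit to any
  corpus, and pathology is a fixed additive slowing pattern.
* The quadratic is the only bias-correction scheme offered.
* No multiple-testing correction across analyses (uncorrected p at 0.05,
  matching the reporting convention of the analysis this reproduces).
* The numpy network is single-threaded and desk-scale; it is not intended
  for corpus-scale training.
* Report keyword search is substring-based by design and will match
  negated mentions ("no history of stroke").
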