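# eegage

Brain-age decoding from clinical EEG, and the statistics to decide whether
the brain-age gap behaves like a **state** (it moves when pathology is
acquired or resolves) or a **trait** (a stable, person-specific offset).

## The problem

A decoder trained to predict chronological age (CA) from the EEG of healthy
subjects yields, for any recording, a *brain age* (BA). The difference

```
BAG = BA − CA
```

is the brain-age gap: positive means the EEG "looks older" than the person
is. Clinically the interesting questions are (1) is the gap a usable
biomarker of EEG pathology, and (2) does it change within a person when
their pathology status changes — the state hypothesis — or is it a stable
individual characteristic — the trait hypothesis. Answering (2) requires
subjects with repeated recordings, grouped into four longitudinal cohorts:

* **RNP** — repeated recordings, all non-pathological
* **RP** — repeated recordings, all pathological
* **TNPP** — one transition, non-pathological recordings first
* **TPNP** — one transition, pathological recordings first

This package implements the full analysis as a tested library:

* a **synthetic cohort generator** with an age-dependent EEG spectrum
  (occipital alpha rhythm whose peak frequency falls linearly with age),
  per-subject trait offsets, an optional pathology-linked state shift,
  month-scale repeated recordings, single-flip label transitions, dual age
  sources, and keyword-bearing reports — so the entire pipeline is testable
  without access to gated clinical corpora;
* EDF I/O and the clinical **preprocessing chain** (21-channel 10-20
  selection, ±800 µV clipping, common average reference, 100 Hz resampling,
  first-minute drop);
* a **temporal convolutional age regressor** (dilated residual blocks,
  sigmoid output on min-max-scaled ages, L1 loss, AdamW + cosine annealing,
  channel-dropout augmentation) trained with **cropped decoding**:
  maximally overlapping receptive-field-length crops at one-sample stride,
  evaluated densely in a single unpadded convolution pass;
* subject-wise **cross-validation** and repeated final evaluation,
  **quadratic bias correction** of the gap, the **two-threshold gap
  biomarker** optimized for balanced accuracy (BACC), an age-threshold
  baseline, permutation tests (mean-gap difference and biomarker BACC),
  paired-t / Kolmogorov–Smirnov / Wilcoxon–Mann–Whitney / Brunner–Munzel
  comparisons, longitudinal **change rates** and the **moment-of-transition**
  statistic, and **amplitude-gradient saliency maps** per channel and
  frequency band.

The convolutional network and its backward pass are implemented directly in
numpy, so input gradients (needed for the saliency analysis) are exact and
the package has no deep-learning framework dependency.

## Worked example

`examples/longitudinal_transitions.py` plants a 10-year state effect and
runs the longitudinal analysis on generator ground truth plus decoder-like
noise:

```
derivative cohorts: {'RNP': 59, 'TNPP': 24, 'TPNP': 22, 'RP': 18}
within-status rates: RNP +0.59  RP -0.47 gap-years/year
moment of transition: TNPP +12.37 (n=24)   TPNP -14.98 (n=22) gap-years/year
TNPP vs TPNP Wilcoxon-Mann-Whitney p = 9.68e-08
```

The within-status change rates hover near zero, while the gap jumps by
roughly the planted +10 years across a non-pathological→pathological
transition (and −10 the other way): with a state effect present, the
moment-of-transition comparison detects it. Run with `state_effect=0` and
the same comparison stays null while per-subject mean gaps track the
planted trait offsets — the two signatures the analysis is built to
distinguish.

Other examples: `simulate_cohort.py` (cohort structure and the aging alpha
peak), `decode_age.py` (training the regressor and beating the
predict-the-mean baseline), `bias_and_biomarker.py` (quadratic bias removal
and threshold optimization), `saliency_table.py` (channel × band gradient
table).

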