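# Methods

## Problem and signal model

The task is binary tissue identification — trachea vs esophagus — from
diffuse reflectance spectra acquired by a fiber sensor at an
endotracheal tube cuff. The discriminating physics is oxyhemoglobin's
two visible Q-band absorptions, which imprint reflectance troughs near
543 and 578 nm around a local reflectance peak at 561 nm. Both tissues
carry the signature; it is substantially deeper in trachea. All
analysis happens inside the 535–585 nm band; the rest of the 470–850 nm
source range is carried through but never feeds a decision.

## Preprocessing

Raw counts are converted to reflectance with paired references,
`R = (raw − dark)/(white − dark)`, computed pointwise on the shared
grid. A non-positive `white − dark` is fatal inside the analysis band;
outside it the point is flagged NaN and any later lookup there raises
rather than silently interpolating through it.

Spectra are then normalized by the reflectance at 561 nm, and the
features are the normalized reflectance at 543 and 578 nm. All three
wavelengths are evaluated by **linear interpolation** between grid
points, not nearest pixel: spectrometer grids are instrument-specific,
and interpolation makes the features identical across grid pitches (the
test suite includes a jitter-free analytic bound: interpolation error of
a smooth trough is ≤ max|f″|·h²/8). Normalization and feature
extraction are scale-invariant (any positive rescaling of counts and
references cancels) and the normalized value at 561 nm equals 1 to
1e−12 relative by construction; both are enforced as properties.

No smoothing, baseline, scatter or derivative correction is applied —
the acquisition this emulates used none (BoxCar width 1, no averaging).

## Classifiers

**K-NN.** Minkowski distance of order `p ≥ 1` (default 2; `p` is a
knob) on the 2-D features, `k = 10` neighbors. Under resubstitution the
query is excluded from the neighbor search but casts its own vote, so
the voting set has `k + 1 = 11` members and the confidence is the
majority vote fraction (8/11 → 72.7%). Leave-one-out drops the
self-vote (k votes); an external query simply takes the k nearest.
Determinism: candidates are ordered by (distance, pair_id, organ,
acq_index), so distance ties at the k-th rank resolve
lexicographically; an even split is resolved by the single nearest
neighbor's label and flagged `tie_broken`. The implementation is
checked query-by-query against an exhaustive sort-everything oracle.

**LDA.** Two-class Fisher discriminant with equal priors (the cohort is
balanced 450/450 by design; an empirical-prior variant would only shift
`b`). Pooled within-class covariance uses the unbiased `n − 2`
denominator; the sign convention puts trachea on the negative side, and
an exactly zero discriminant is classified trachea (documented tie
rule). `d_max`, the largest perpendicular boundary distance on the
training set, anchors the confidence mapping

    u = min(d / d_max, 1),   conf = 100 · exp(κ (u − 1)),   κ = ln(100/63)

which is the minimal exponential through the two pinned endpoints: 63%
on the boundary, 100% at the furthest training point. Only the
endpoints are prescribed by the sensor's design intent; the exponential
form and κ are this package's choice and κ is a config knob. Points
beyond `d_max` saturate at 100%.

**Evaluation.** The per-spectrum error is the deviation of the assigned
true-class probability from the 0/1 truth: `1 − c` if correct, `c` if
wrong (confidence `c` as a fraction). `MSE` is the mean square of these
and `PSNR = 10·log₁₀(1/MSE)` with peak 1 on the probability scale; the
7.4×10⁻³ ↔ 21.3 dB pair pins this form exactly. A zero-MSE cohort
reports an infinite-PSNR sentinel (JSON renders it as null plus a
`psnr_perfect` flag). The error definition is a reconstruction — no
standard definition exists for confidence-weighted classification error
in this setting — and is documented as such rather than fitted to any
particular published value.

**Exact binomial bound.** `clopper_pearson_lower` returns the
Beta(x, n − x + 1) quantile at α/2 (closed form `(α/2)^(1/n)` for
x = n, 0 for x = 0), cross-checked against bisection on the exact
binomial tail sum for every (x, n) with n ≤ 50 to 1e−10. The bound
assumes independent observations; 50 spectra from one organ are not
independent, so every rendering of the bound carries a mandatory
caveat. No clustered interval is attempted.

## Synthetic cohort generator

One acquisition's underlying reflectance is

    R(λ) = B(λ) · [1 − d543·G(λ; 543, 9) − d578·G(λ; 578, 11)]

with unit-height Gaussian troughs centered exactly at the feature
wavelengths and a gentle linear baseline
`B(λ) = 1 + 0.02·(λ − 561)/380` (flat to ~1e−3 across the analysis
band, so a zero-depth tissue yields features (1, 1) to that order).
Depth realization: class mean (trachea 0.35/0.40, esophagus 0.12/0.15
at 543/578 nm) × a lognormal factor (σ = 0.10) drawn once per
(pair, organ) — organs differ, spectra within an organ share it — × a
per-spectrum lognormal jitter (σ = 0.02). Raw counts are
`dark + (white − dark)·R·(1 + ε)`, ε Gaussian with SD 0.01, clipped at
zero. References: dark = 100 ± 2 counts of read noise; white = dark +
a smooth two-Gaussian LED envelope peaking at 50 000 counts over
470–850 nm (0.5 nm default grid). The whole dataset is a pure function
of the config, including the seed.

Trough depths, widths, and noise levels are generator calibrations
chosen to reproduce the qualitative contrast of the real tissues
(pronounced vs less pronounced signature, visually clean class
separation in the feature plane); no published absolute depths exist to
pin them. The defaults make the cohort linearly separable —
deliberately, since the result being emulated is a fully separable
cohort — and `SimulationConfig.hard_mode()` provides an overlapping
preset for stress tests. The generator records ground-truth realized
depths per spectrum, and a closed-form inversion of the feature map
(a 2×2 linear solve) recovers them exactly at zero noise; class-mean
recovery is tested within 2 SE computed across organ means, the
clustered unit of variation.

What the generator does **not** model: photon transport and
source–detector-distance effects, contact-pressure artifacts, blood
contamination, wavelength-dependent detector response beyond the
envelope, and non-uniform spectrometer grids in the default (a jittered
grid is exercised only through the interpolation tests). Passing tests
therefore demonstrate the pipeline's correctness and its behavior under
the stated statistical structure, not performance on real tissue.

## Null condition

The no-signal check sets the two class depth means equal **and** the
between-organ depth SD to zero, then scores K-NN leave-one-out. Both
choices are needed for the null to be a null: with organ-level depth
factors retained, each (pair, organ) forms a tight cluster with a
constant label and K-NN memorizes cluster identity (accuracy ≫ 50%
with zero class signal); and under resubstitution the self-vote alone
lifts K-NN to P(Binom(10, ½) ≥ 5) ≈ 62% on pure noise. LDA, a global
2-parameter boundary, is scored under resubstitution, where its
overfit at n = 900 is negligible. The 20-seed sweep lands at 49.7%
(K-NN) and 51.4% (LDA) mean accuracy.

## Protocols, sizes, determinism

Resubstitution is the default cohort protocol (it mirrors the
self-vote worked example); leave-one-out is a flag for honest
generalization estimates (LDA is refitted without the held-out point).
Default problem sizes everywhere are the study design itself — 900
spectra, 761-point grid — which runs in well under a minute; property
sweeps use 200-point training sets and 20-seed nulls. CSVs are written
with 12 significant digits so round trips preserve values beyond the
documented 9-digit contract; reports are byte-identical under a fixed
seed. No vendor or repository-specific instrument formats are parsed:
ingest of an externally archived dataset would be a separate adapter
written against the actual files; the canonical CSV dialect is the
supported interchange format.
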