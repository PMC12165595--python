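# airwayspec

Spectral discrimination of tracheal from esophageal tissue, for an
optical sensor integrated into an endotracheal tube (ETT) cuff.
Unrecognized esophageal intubation is a rare but catastrophic airway
management failure; a reflectance sensor at the cuff can detect it at
the moment of placement. This package implements the analysis chain
that turns raw spectrometer counts into a tissue call with a
confidence, and a synthetic cohort generator so the whole chain is
testable end to end without instrument data.

## The method

Both tissues show the oxyhemoglobin *trough–peak–trough* signature —
two absorption troughs at 543 and 578 nm flanking a reflectance peak at
561 nm — but it is pronounced in trachea and much weaker in esophagus.
The pipeline is:

1. **Reference correction.** With paired dark and white-standard
   acquisitions, `R(λ) = (raw(λ) − dark(λ)) / (white(λ) − dark(λ))`.
2. **Peak normalization.** Divide by the interpolated reflectance at
   561 nm, so every spectrum has value 1 at the central peak and the
   between-tissue variance concentrates in the troughs.
3. **Feature extraction.** The normalized reflectance at the troughs,
   `x = (r543, r578)`, is the 2-D classification space.
4. **Classification.**
   - *K-NN* (Minkowski order *p* = 2, *k* = 10): majority vote of the
     neighborhood. Under resubstitution the query also votes for
     itself, so confidence = 100 · (majority votes)/(k + 1); e.g. 8
     tracheal votes out of 11 → trachea at 72.7%.
   - *LDA*: two-class Fisher discriminant with equal priors,
     `w = Σ⁻¹(μ_eso − μ_tra)`, `b = −w·(μ_eso + μ_tra)/2`; negative
     side is trachea. Confidence maps the perpendicular boundary
     distance `d` exponentially onto [63%, 100%]:
     `conf = 100·exp(κ(u − 1))` with `u = min(d/d_max, 1)` and
     `κ = ln(100/63)`, so a point on the boundary scores 63% and the
     furthest training point 100%.
5. **Evaluation.** Accuracy; a mean-square error on the assigned
   true-class probability (error `1 − c` when correct, `c` when wrong);
   `PSNR = 10·log₁₀(1/MSE)` in dB; and the exact (Clopper–Pearson)
   lower bound of the two-sided 95% binomial interval on the
   probability of correct identification — `(α/2)^(1/n)` when all *n*
   are correct, which is 99.6% at n = 900.

The synthetic generator emulates a 470–850 nm LED envelope recorded by
a spectrometer, Gaussian absorption troughs at 543/578 nm whose depths
are organ-specific (lognormal between-organ variation, per-spectrum
jitter, multiplicative detector noise), and the 9 pairs × 2 organs ×
50 acquisitions cohort design.

## Worked example

```sh
python analysis/01_simulate_cohort.py
python analysis/02_extract_features.py
python analysis/03_classify_and_evaluate.py
python analysis/04_null_check.py
```

prints (abridged):

```
wrote 900 spectra to .../results/cohort
             d543    d578
esophagus  0.1227  0.1535
trachea    0.3557  0.4072
tracheal 543 nm troughs are 2.9x deeper than esophageal ones

             r543            r578
             mean     std    mean     std
esophagus  0.9335  0.0153  0.9044  0.0183
trachea    0.7739  0.0178  0.7164  0.0198
r543 class gap (min esophagus - max trachea): +0.0613

KNN  accuracy 100.0% (900/900) | MSE 0 | PSNR inf | 95% CI lower bound 99.6%
LDA  accuracy 100.0% (900/900) | MSE 0.0288 | PSNR 15.4 dB | 95% CI lower bound 99.6%

mean K-NN accuracy 49.7%, mean LDA accuracy 51.4% -- both at chance
```

Reading this: tracheal spectra have markedly deeper troughs, the two
classes separate cleanly in the (r543, r578) plane, both classifiers
identify all 900 spectra (the K-NN MSE is 0 here because every
neighborhood is unanimous), and the exact binomial bound says that with
900/900 correct the correct-identification probability is at least
99.6% at 95% confidence — under an independence assumption the report
explicitly caveats. The null check (equal class depths, no organ-level
variation) confirms both classifiers fall to chance when the trough
contrast is removed.

The same pipeline is available as a CLI
(`airwayspec simulate|run|report`), e.g.
`airwayspec run --simulate --seed 42 --out results/report`.

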