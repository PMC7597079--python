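# usentropy

Ultrasound Shannon-entropy parametric imaging for grading hepatic steatosis.

Fat droplets accumulating in liver parenchyma act as acoustic scatterers: as
steatosis progresses, the scatterer number density rises and the statistics of
the backscattered envelope move from pre-Rayleigh toward fully developed
Rayleigh speckle. The Shannon entropy of the raw radiofrequency (RF) amplitude
distribution tracks this transition, so a local-entropy parametric map is a
physics-based, interpretable imaging biomarker for steatosis grade. This
package implements that pipeline end to end for quantitative-ultrasound
researchers:

- **RF speckle simulator** — delay-and-sum point-scatterer phantoms whose
  envelope SNR (mean/std) sweeps from pre-Rayleigh (< 1.91) to the Rayleigh
  limit √(π/(4−π)) ≈ 1.91 as density per resolution cell grows, plus labeled
  synthetic cohorts (default composition 79/74/35/17 subjects for
  normal/mild/moderate/severe, five scans each, SNR 20 dB).
- **B-mode preprocessing** — Hilbert-transform envelope detection,
  log compression at 40 dB dynamic range, linear/convex scan conversion.
- **Entropy imaging** — sliding physically-square window (side = one pulse
  length, 50 % overlap), per-window amplitude histogram (100 bins) and
  Shannon entropy `H = −Σ w(yᵢ) log₂ w(yᵢ)`, bilinear upsampling back to the
  RF grid, pseudocolor overlay rendering.
- **ROI features** — rectangular region-of-interest extraction and
  mean-entropy reduction per scan, aggregated per subject.
- **Diagnostics** — grading criteria (≥ mild / ≥ moderate / ≥ severe), 4:1
  stratified subject-level split, ROC cutoff at the point closest to (0, 1),
  confusion-matrix metrics, AUROC with DeLong variance / 95 % CI, and the
  paired DeLong test for comparing correlated AUROCs.

The transform- and classifier-shaped stages are scikit-learn estimators
(`SlidingWindowEntropy`, `ROCThresholdClassifier`) and compose with sklearn
pipelines; everything else is plain functions over small dataclasses.

## Worked example

```python
import usentropy as u

# a small synthetic cohort: 10 subjects per grade, 5 scans each
spec = u.CohortSpec(subjects_per_grade=(10, 10, 10, 10),
                    n_samples=768, n_lines=96, rng_seed=0)
features = u.cohort_feature_table(spec)          # one row per subject
print(features.groupby("grade", sort=False)["entropy_mean"].mean())

report = u.evaluate_pipeline(features, seed=0)
print(report[["criterion", "cutoff", "auroc", "accuracy"]])
```

Output (entropy in bits; densities 1/3/6/12 scatterers per resolution cell):

```
grade
normal      5.840942
mild        6.048216
moderate    6.080871
severe      6.104801
Name: entropy_mean, dtype: float64

    criterion    cutoff  auroc  accuracy
0      >=mild  6.032940    1.0     1.000
1  >=moderate  6.076407    1.0     0.875
2    >=severe  6.089984    1.0     1.000
```

Mean ROI entropy rises monotonically with grade because denser scatterer
fields push the backscattered statistics toward Rayleigh speckle, and the
fitted cutoffs for the three nested criteria are strictly increasing — the
same ordering a clinical entropy-imaging workflow exhibits. On such a
well-separated synthetic cohort, the test AUROCs are at or near 1; the small
test split (8 subjects here) quantizes accuracy.

A CLI mirrors the library (`usentropy simulate-cohort | bmode | entropy-map |
features | evaluate | run-all`), e.g.:

```bash
usentropy run-all --config cohort.json --out run/ --seed 3
```

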