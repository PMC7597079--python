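# Methods

## The measurement model

Liver parenchyma is modeled as a random medium of sub-resolution scatterers.
Each scan line of an RF frame is the superposition of delay-shifted,
amplitude-weighted replicas of the transmit pulse:

    s(t) = Σₖ aₖ · p(t − 2 zₖ / c)

with scatterer depths zₖ, amplitudes aₖ, sound speed c and pulse p. The pulse
is a Gaussian-modulated sinusoid; its envelope width is set so that the −6 dB
full width, mapped to depth by `length = duration · c / 2` (pulse-echo
convention), equals the nominal pulse length (2.3 mm by default at 3.5 MHz
center frequency, 30 MHz sampling). If a fractional bandwidth is given
explicitly it overrides the pulse-length-derived width; for a Gaussian pulse
the two parameterizations are redundant, and pulse length remains the nominal
value used for window sizing.

Scatterer positions are uniform i.i.d. over the phantom, counts Poisson with
mean `density × area / resolution cell`, where the resolution cell is
`pulse length × line spacing` — the operational definition that makes
"density per resolution cell" meaningful on a sampled, beamformed grid.
Fractional delays are evaluated analytically (the pulse is sampled at
`t − τₖ` per scatterer), so echo phases are continuous rather than quantized
to the sample grid; this matters for speckle statistics. Lateral spread is
nearest-line assignment by default; a Gaussian lateral point-spread is
available.

With few scatterers per cell the envelope amplitude distribution is
pre-Rayleigh (envelope SNR = mean/std < 1.91); as density grows it converges
to Rayleigh speckle with SNR → √(π/(4−π)) ≈ 1.913. At density 16/cell the
simulator sits at ≈ 1.88–1.89 — the expected finite-density residual below
the asymptote. This density-driven transition is the physical mechanism the
entropy statistic reads out, and the package's mechanism tests check it
directly. SNR is estimated as the mean of per-frame SNRs: pooling raw
envelopes across frames mixes between-frame brightness (Poisson count)
variation into the within-frame statistic and biases it low by ~2 %.

## Entropy imaging

The local statistic is the Shannon entropy of the amplitude histogram of a
sliding window of **raw RF** samples (an envelope mode exists behind a config
switch for comparison):

    H = − Σᵢ w(yᵢ) log₂ w(yᵢ),   0 ≤ H ≤ log₂ n_bins

Normalization is per-window: samples are divided by the window's max
|amplitude| and histogrammed into 100 equal-width bins over [−1, 1] (the
upper edge inclusive in the last bin). Per-window normalization makes the
estimator gain-invariant; frame-level normalization is available as an
alternative. `0 · log₂ 0 = 0` by the usual continuity convention.

The window is physically square — equal axial and lateral extent in mm —
because sample counts and line counts are incommensurate units. The side is
one pulse length by default: axially `round(side · 2 fs / c)` samples (90 at
the default constants; round-half-away-from-zero), laterally
`round(side / line spacing)` lines. The step is `floor(len · (1 − overlap))`
with 50 % default overlap (step 45 axially), minimum 1. Tiling starts at
(0, 0); partial windows at the far edges are discarded rather than fabricating
statistics from truncated windows. All-zero windows are flagged (0 or NaN,
configurable and counted).

The coarse map (one value per window) is upsampled to the RF grid by
separable bilinear interpolation anchored at window centers, with constant
extrapolation beyond the outermost centers, so the full map is bounded by the
coarse extrema. 1×N coarse grids fall back to 1-D interpolation.

## ROI features and the synthetic cohort

Per scan, the feature is the arithmetic mean entropy over a rectangular ROI
(sentinel/background pixels excluded); per subject, the mean of its scans'
means (median available). The clinical ROI is 3.5 × 3.5 cm placed by an
expert; the synthetic pipeline uses a deterministic centered ROI instead.
Note the 3.5 cm axial extent cannot fit a 1247-sample frame at 30 MHz
sampling (depth `1247 · c/(2 fs)` ≈ 3.2 cm), so synthetic configurations
either shrink the ROI or average the full map; feature values are insensitive
to this choice in homogeneous phantoms.

The cohort generator emulates the study design this package was built
around: 79/74/35/17 subjects for normal/mild/moderate/severe, five scans per
subject, acquisition SNR 20 dB (additive white Gaussian noise scaled to the
frame's own signal power). The grade → density mapping (1/3/6/12 scatterers
per resolution cell) is a **modeling stand-in, not a measured quantity**: it
spans the pre-Rayleigh-to-developed-speckle range so the mechanism is
exercised, but no quantitative grade-to-density calibration exists. Subject
densities get lognormal multiplicative jitter with 15 % relative sd (matched
mean), creating within-grade overlap so ROC analysis is non-degenerate.
Seeding uses one `SeedSequence` spawned per subject and scan, so frames are
reproducible and independent of consumption order.

What the generator does **not** model: diffraction and depth-dependent beam
width, frequency-dependent attenuation and time-gain compensation, vessels
and diaphragm, operator ROI placement, and inter-patient anatomical
variability. Passing tests therefore demonstrate that the algorithms recover
the scatterer-density mechanism under the stated statistical model — not
clinical performance on patient data; clinical AUROCs cannot be reproduced
without the (undeposited) patient dataset.

## Diagnostic evaluation

Grades are binarized at ≥ mild / ≥ moderate / ≥ severe. The split is
subject-level (all scans of a subject on one side), stratified, train:test =
4:1 — 164/41 subjects at the default cohort size. The ROC curve places one
vertex per distinct score (ties grouped); the trapezoidal AUROC then equals
the Mann–Whitney statistic with ties counted ½. The cutoff minimizes the
Euclidean distance of the ROC vertex to (0, 1), ties broken toward lower FPR,
then higher threshold; classification is "positive iff score ≥ cutoff"
(entropy increases with steatosis, fixing the direction). Confusion-matrix
ratios with zero denominators are reported as missing, never as 0; with a
single confusion matrix per criterion, recall ≡ sensitivity by definition
(clinical reports sometimes compute them on different units; this package
does not).

The AUROC variance uses DeLong placement values: `var = S₁₀/n₁ + S₀₁/n₀`
with sample variances of the per-positive and per-negative placements, and a
Wald 95 % CI clipped to [0, 1] (a bootstrap CI is a test-side cross-check,
not the default). The paired test uses the joint placement covariance;
a zero-variance difference (identical or perfectly concordant classifiers) is
flagged and reported as z = 0, p = 1. The implementation reproduces an
independent reference implementation (R pROC) to 10 decimal places on a fixed
fixture, and its type-I error under a correlated paired null is ≈ 0.05.

## Numerical choices and problem sizes

- Histogram binning: `floor((x − lo)/width)` clipped to the last bin, so the
  top edge is inclusive; identical rule in the vectorized map and the scalar
  reference used in tests (agreement to 1e−12).
- Window/step rounding: round-half-away-from-zero for window lengths, floor
  for steps, minimum 1 — deterministic tie-breaking.
- Scan conversion is bilinear (no overshoot); out-of-sector pixels carry a
  NaN sentinel excluded from statistics and rendered as background.
- Simulated frames in tests and the acceptance script are smaller than the
  clinical 1247 × 256 default: end-to-end cohort runs use 1024 × 128 frames
  (205 subjects, 1025 frames in ~2 min), mechanism checks use 1247 × 192
  homogeneous frames (20 per density point, enough independent speckle cells
  to resolve the ~0.03 SNR step between densities 8 and 16). Frame size is a
  sizing choice; cohort composition, densities, scan count and noise level
  are the study conditions and are not scaled.

## Known limitations

- The convolution phantom has no spatial impulse response; absolute echo
  amplitudes are arbitrary (entropy is gain-invariant, so this is benign for
  the statistic but makes B-mode brightness uncalibrated).
- At high densities the entropy–density curve saturates (Gaussian-limit
  amplitude statistics), so grade separation between moderate and severe
  rests on small entropy differences; the default cohort is sized and
  jittered such that the separation is still reliable.
- Wald CIs on the AUROC can degenerate (zero width) under perfect
  separation; flagged rather than patched.
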