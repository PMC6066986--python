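# Methods

This note records the models, defaults, and design choices behind nfbsim,
and what the synthetic validation does and does not demonstrate.

## Block design and scheduling

A run is 16 blocks: 8 neutral (30 s each, no music) and 4 + 4 emotion
blocks (46 s each, one distinct music-track identifier per block), totaling
608 s = 304 volumes at TR = 2 s; a session is 4 such runs (1,216 volumes),
plus 5 dummy volumes per run that are acquired but discarded. ROI runs
alternate emotions (`[N,E1,N,E2] × 4`); SVM runs group them
(`[N,E1] × 4, [N,E2] × 4`). These are the arrangements consistent with the
printed durations, the 304-volume run length, and the constraint that both
feedback definitions require a neutral block immediately before every
emotion block. Counterbalancing is implemented by alternating the leading
emotion across runs 1–4; the exact per-run permutations of the original
protocol are not published, so this is one consistent realization.

Volume labels are shifted by a configurable hemodynamic delay, default 2
volumes (4 s), a conventional figure for the BOLD lag at these block
durations. Shifting within a fixed-length run means the final block's last
`shift` volumes fall past the run end; analyses that require every block to
sample an identical window (e.g. the closed-loop monotonicity check) use
shift 0.

## Synthetic BOLD model

Voxel time series are generated as

```
y_v(t) = baseline · (1 + Σ_c psc_c(v) · [boxcar_c ∗ h](t)) + d(t) + ε_v(t)
```

- **HRF** `h`: canonical double-gamma (peak delay 6 s, undershoot delay
  16 s, dispersions 1, undershoot ratio 1/6), the field-standard choice.
  Block regressors are normalized to unit steady state, so a long block's
  plateau equals the planted PSC amplitude exactly — this is what makes the
  convolution model usable as an exact oracle.
- **Noise** `ε`: stationary Gaussian AR(1), default sd 20 on baseline
  1,000 with coefficient 0.3. A 2% planted effect (20 units) therefore has
  voxelwise CNR ≈ 1, a deliberately hard but realistic operating point.
- **Drift** `d`: linear ramp plus a sinusoid, default amplitude 10 units
  (1% of baseline) per run and period 300 s. The period is chosen below
  the high-pass cutoff frequencies (152 s ROI / 456 s SVM) because the
  drift term exists to emulate exactly the confound that filter removes; a
  faster drift would alias into the task band and no longer model scanner
  drift.
- **Planted effects**: the ROI phantom activates a random 10% of each
  1,000-voxel target ROI at 2% PSC for its target emotion; the SVM phantom
  activates two disjoint 60-voxel sets inside the feature mask, one per
  emotion, which makes the two conditions linearly separable by
  construction and the degree of separability controllable.
- **Geometry**: 16×16×10 grid (desk scale, < 1 s per run to generate) with
  box-shaped masks — a 1,000-voxel septo-hypothalamic stand-in, a 480-voxel
  right-amygdala stand-in, and a feature mask covering the grid minus a
  strip that stands in for the sensorimotor/visuospatial exclusion.
- **Motion**: a slow random-walk 6-parameter trace (not applied to the
  images) with optional injected spikes, used to exercise artifact
  flagging.

Generation is a pure function of the design and configuration (seeds
derive from `numpy.random.SeedSequence`), which the replay and closed-loop
reduction tests rely on.

What the phantom does **not** model: anatomy, susceptibility artifacts,
slice-timing effects, physiological noise, spatial autocorrelation, or
motion-induced intensity changes. Passing tests therefore demonstrate the
correctness of the engine's arithmetic and the statistical behavior of its
estimators under the stated noise model — not performance on scanner data.

## ROI feedback

The activation statistic is the per-voxel PSC of each target-emotion block
against its immediately preceding neutral block, averaged over the training
run's four target blocks. "Most active" is one-sided (largest positive
statistic), since both targets are activation hypotheses; ties break to the
lowest linear voxel index for determinism, and the selected count is
`ceil(fraction · |ROI|)` with fraction 0.10.

The baseline weighting uses `sig(k) = 1/(1+exp(−(k − B/2)))` over baseline
volume index k, renormalized to a weighted mean. The weighting's midpoint at
B/2 halves the influence of the first half of the neutral block, where the
previous emotion block's response is still decaying; the sigmoid's
parameters are this package's choice, and the normalization is the
standard weighted mean Σw·x/Σw. Weights are normalized before the dot
product so a single-volume baseline returns that volume's mean exactly.

## SVM feedback

Features are per-voxel PSC relative to the sigmoid-weighted per-voxel mean
of the previous neutral block, over the feature mask; no further
standardization is applied (PSC already equalizes per-voxel scale). The
classifier is a soft-margin linear SVM at C = 1, solved by libsvm
(scikit-learn `SVC`) at tolerance 1e−8; with fixed data the fit is
deterministic. Tenderness sits on the positive side of the hyperplane;
during anguish blocks the projection's sign is flipped so feedback always
grows with engagement of the current target. Cumulative training is batch
semantics — at each run boundary the model is refitted from scratch on all
stored examples — so incremental and batch training agree to solver
tolerance by construction. Neutral volumes are never training examples;
they define the baselines.

## Engine and color mapping

Feedback is computed once per TR during emotion blocks with no temporal
smoothing, and mapped to saturation by `clip(raw/f_max, 0, 1)`, optionally
quantized to n equal levels (continuous by default). `f_max` defaults to
0.02 (2% PSC saturates the display) for the ROI method and to twice the
median |projection| over the training examples for the SVM method, which
places typical well-classified volumes near mid-saturation. During neutral
blocks the interface stays at baseline hue (saturation 0) and the engine
only updates baselines; dummy volumes produce nothing. The log schema is
identical for both methods.

The closed-loop harness replaces the participant with a proportional
responder: the planted amplitude of each emotion block is scaled by
`1 + gain × (previous same-emotion block's mean saturation)`, fixed at
block onset. Because every block's HRF-convolved contribution is causal and
the accumulation order matches the open-loop generator's, gain 0 reproduces
the open-loop session bit-for-bit.

## Offline QC and GLM

Motion flagging reads "over 3 mm / 0.02 rad" as a strict inequality on the
per-volume absolute parameters (a frame-to-frame delta mode is available).
High-pass filtering regresses out a discrete-cosine basis up to
`K = floor(2·n·TR/cutoff)` components, preserving the series mean — the
same mechanism as SPM's filter; cutoffs are configuration constants (152 s
ROI, 456 s SVM). The GLM stacks HRF-convolved condition regressors, an
intercept, the DCT drift basis, demeaned motion covariates, and one
indicator column per flagged volume; rank deficiency is rejected with the
offending columns named. Condition amplitudes are reported as
`β_condition / β_intercept`, which equals the planted PSC fraction exactly
on noise-free data.

The t-statistics assume iid Gaussian errors, so the type-I-error
calibration runs on white-noise null phantoms; under AR(1) noise the
uncorrected OLS t is mildly anti-conservative for slow block designs, a
known limitation (no prewhitening is implemented).

## Problem sizes in the validation suite

The test and acceptance runs use the full 304-volume, 16×16×10 protocol
throughout; multi-seed performance checks use 20 phantoms (voxel-selection
recovery, held-out decoding) and 200 white-noise nulls at 8×8×4 for the
type-I calibration, sizes at which the binomial uncertainty of the
estimated rates is comfortably inside the asserted bands.
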