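# nfbsim

A simulator-backed real-time fMRI neurofeedback (NFB) engine. It implements
the full closed loop of an emotion-regulation NFB protocol — block-design
scheduling, per-volume feedback computation, and mapping of feedback to the
color saturation of a virtual-environment brain–computer interface — with a
synthetic BOLD generator standing in for the scanner, so every stage can be
developed and validated against known ground truth on a desk.

It is aimed at researchers prototyping real-time fMRI pipelines: the
feedback arithmetic, the incremental decoder, and the quality-control stage
are the real thing; only the participant and the scanner are simulated.

## The protocol and the two feedback methods

A session is four runs (one training run + three NFB runs) of 304 volumes
at TR = 2 s (1,216 volumes total, five dummy volumes discarded per run).
Each run interleaves eight 30-s *neutral* blocks with four 46-s *tenderness*
and four 46-s *anguish* blocks (music excerpts accompany the emotion
blocks). ROI sessions alternate the emotions; SVM sessions group each
emotion's blocks consecutively. Every emotion block is preceded by a
neutral block, which provides the feedback baseline.

**ROI method.** The training run maps, inside an a-priori anatomical ROI
(septo-hypothalamic area for tenderness, right amygdala for anguish), the
10% of voxels most activated by the target emotion relative to the
preceding neutral blocks. During NFB runs the feedback at each volume is
the percent signal change

$$f \;=\; \frac{\overline{ROI}_{curr} - m}{m},
\qquad m = \frac{\sum_{k=1}^{B} \mathrm{sig}(k)\,\overline{ROI}_k}
                 {\sum_{k=1}^{B} \mathrm{sig}(k)},$$

where $\overline{ROI}_k$ is the selected-voxel mean of the $k$-th volume of
the previous neutral block ($B$ volumes) and $\mathrm{sig}(k) =
1/(1+e^{-(k-B/2)})$ down-weights early baseline volumes still contaminated
by the previous block's hemodynamic decay.

**SVM method.** Each emotion-block volume becomes a feature vector
$x$ of per-voxel PSC relative to the previous neutral block, restricted to a
feature-selection mask. A linear soft-margin SVM separates tenderness from
anguish patterns, and feedback is the hyperplane projection $x \cdot w + b$,
oriented toward the current block's emotion. The model is *cumulatively*
retrained at every run boundary on all examples observed so far.

In both methods feedback is mapped to color saturation by
$s = \mathrm{clip}(f / f_{max},\, 0,\, 1)$ — orange hues for tenderness,
purple for anguish, baseline tones (saturation 0) for neutral.

The synthetic generator produces
`baseline × (1 + Σ psc·(boxcar ∗ HRF)) + drift + AR(1) noise` with a
canonical double-gamma HRF and planted per-voxel effects, and an offline QC
stage flags motion artifacts (> 3 mm translation / > 0.02 rad rotation),
high-pass filters with DCT regression (cutoffs 152 s ROI / 456 s SVM), and
fits a voxelwise GLM to verify the planted amplitudes are recovered.

## Worked example

```bash
python examples/03_roi_feedback.py
```

```
selected 100 voxels; 95/100 are truly active
546 feedback samples over runs 2-4 (one per TR during emotion blocks)
            raw_feedback  saturation
condition
anguish           0.0183      0.8111
tenderness        0.0187      0.8151
```

The training run selected the 100-voxel decile of the 1,000-voxel ROI and
found 95 of the 100 truly responsive voxels despite voxelwise CNR ≈ 1.
Across the three NFB runs the engine emitted one sample per TR during
emotion blocks (92 tenderness + 92 anguish volumes per run, minus the two
samples the hemodynamic shift pushes past each run's end). The mean raw
feedback of ≈ 0.018 approaches the planted 2% PSC (block on/offset
transients included), and the mean saturation of ≈ 0.81 is the color drive
sent to the interface, where 1.0 means "fully orange/purple".

The other examples cover scheduling (`01`), the phantom and its convolution
oracle (`02`), cumulative SVM decoding (`04`, held-out run-4 accuracy
1.000 on a separable phantom), the closed loop (`05`, saturation climbing
from 0.446 to 0.874 across a run's blocks at responder gain 1.5), and the
offline QC/GLM stage (`06`).

A thin CLI wraps the same workflow:
`nfbsim schedule|simulate|train|run|loop|analyze --help`.

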