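# Methods

## Overview

`ststp` implements a multi-modal pipeline for recognising involuntary
behavioural cues — eye blinking, eyebrow and body motion, hand gestures —
in short RGB clips of a speaking subject, and for classifying each clip as
LIE or TRUTH from those cues.  The pipeline runs in stages:

1. **Keyframe selection.**  Each frame receives a scalar signature
   `K_i` (its grayscale pixel sum, luma weights 0.299/0.587/0.114).  A
   data-derived threshold `T = (P/V) Σ |K_i − K_{i+1}|` (V frames, scale
   parameter P, default 1.0) keeps frame i iff its signature difference to
   its neighbour exceeds T; the first frame is always kept.  The rule is a
   cheap change detector: larger P keeps strictly fewer frames.  All
   downstream per-frame features are computed on the kept list.
2. **Optical flow (body motion).**  Shi–Tomasi corners (max 100 points,
   relative quality 0.3, min spacing 7 px, 7-px structure-tensor window)
   are detected on the first keyframe and tracked across successive
   keyframes with iterative pyramidal Lucas–Kanade (15-px window, up to 4
   pyramid levels).  The tracker solves the 2×2 structure-tensor system
   per point, coarse-to-fine, and flags points invalid when the tensor is
   near-singular (aperture problem) or the track leaves the frame.  When
   the valid fraction drops below 0.5 the corner set is re-detected (and
   logged) — otherwise long clips lose every point.  Each keyframe pair is
   summarised by six values: mean/median/max displacement magnitude, mean
   direction (cos, sin), and the valid fraction; the final row is zero
   padding so the block aligns with the kept list.
3. **Hand pose (gesture).**  Each frame carries up to two hands with 20
   retained joints (thumb t1–t3, index i1–i4, middle m1–m4, ring r1–r4,
   little p1–p4, wrist w; the extracted palm centre is dropped).  Frames
   are embedded in the uniform two-hand layout (2×40 coordinates plus the
   wrist–wrist distance σ = 81 values) with missing hands zeroed.  The
   pose block is reduced by the Karhunen–Loève transform
   `g = B (f − mean f)`: a mean-centred eigendecomposition of the pose
   covariance (10 components by default), with component signs fixed by
   making the largest-magnitude loading positive.  PCA is fitted on
   training folds only, never on test subjects.
4. **Eye aspect ratio (blink).**  From the six eye-contour landmarks,
   `EAR = (‖l2−l6‖ + ‖l3−l5‖) / (2‖l1−l4‖)` — translation-, rotation- and
   scale-invariant, collapsing toward 0 when the lids close.  Blinks are
   maximal runs of EAR below 0.2 lasting at least 2 keyframes (the
   threshold and run length follow the standard EAR blink literature and
   are configurable).  The per-keyframe eye block is (left EAR, right EAR,
   V1–V3 eyebrow offsets), the eyebrow offset being the signed distance of
   each brow point from the line through the outer eye corners —
   translation-invariant by construction.  A circular-Hough iris locator
   is provided for pixel-level eye analysis: the strongest circle in a
   configured radius band, with a null result (the blink signal) when the
   normalised accumulator peak falls below 0.65; a straight lid line can
   reach ~0.58 on a small circle, so the threshold sits above that.
5. **Fusion.**  The per-keyframe STSTP vector is the concatenation
   β = [CNN | OF | PCA | EAR] with recorded slice offsets; an absent
   modality contributes an exactly-zero slice (and serialises as literal
   zeros in the per-clip CSV), so all clips share one schema and no rows
   are dropped.
6. **Guided selection.**  Candidate columns are scored by the
   relevance-vs-redundancy merit
   `J(S) = Σ_{x∈S} rel(x) / sqrt(|S| + Σ_{l≠u} red(l,u))`, with relevance
   the R² of a straight-line fit of the class label on the column and
   redundancy the pairwise column R² ("confidence score") — columns that
   predict each other well are penalised.  The search is greedy forward
   selection with a floating drop step, deterministic with a
   lowest-column-index tie break, stopping when the merit gain falls below
   `tol`.  In the pipeline, selection statistics are computed on
   per-subject temporal means rather than raw keyframe rows: keyframe rows
   of one subject are pseudo-replicates, and pooling them inflates the
   apparent relevance of noise columns above genuinely informative ones.
   The pipeline default `tol = 0.01` keeps subsets small and stable on
   cohort-sized training folds; the function default is 1e-4.
7. **Classifier.**  A spatial encoder embeds each kept frame; the fused
   sequence feeds two stacked bidirectional LSTM layers (hidden size 100
   by default); the final forward/backward states are spliced,
   concatenated with the mean-pooled fused-feature summary, projected to
   two classes, and softmaxed.  Training is mini-batch SGD with momentum
   0.9 on the softmax cross-entropy, batch 32, dropout 0.2, weight decay
   5e-4, at most 64 epochs.  The entire network, including
   backpropagation-through-time, is implemented in NumPy; the analytic
   gradients are verified against finite differences in the test suite.
   Conv/pool geometry uses `out = floor((H + 2K − U)/D) + 1`, with
   "same" padding meaning `K = (U−1)/2`.  The desk-scale encoder is a
   small fixed-weight (seeded, He-initialised) convolutional stack — a
   random-projection feature extractor; the 152-layer residual schedule is
   expressible as an `EncoderConfig` for GPU-scale work but is not trained
   here.  An optional key-feature gate can zero fused features whose mean
   absolute value falls below a configurable fraction of the sequence-wide
   mean; it is off by default because standardised inputs rarely benefit.
   The learning rate is the package's choice (default 0.05 for
   `Hyperparams`, 0.1 in the desk-scale cohort settings): the recurrent
   training block specifies momentum, batch, dropout and epochs but no
   rate.
8. **Evaluation.**  Confusion entries a1 (true positive = LIE called LIE),
   a2, b1, b2 with Acc = (a1+a2)/n, TPR = a1/(a1+b2), TNR = a2/(a2+b1);
   zero-denominator metrics are reported as missing, never as 0.  ROC/AUC
   by the trapezoidal rule over the empirical curve (LIE positive).
   The protocol is subject-level stratified k-fold (k = 10 by default)
   with PCA and selection fitted inside training folds; fold scores are
   pooled for the ROC.  The ablation runner re-evaluates the pipeline on
   modality subsets (three singles, three pairs, and the full fusion with
   guided selection) by zeroing the excluded blocks, layout unchanged.

## Synthetic subjects

The generator renders deliberately cartoonish talking heads whose exact
geometry doubles as ground truth: a smoothly textured background
(trackable corners), a face disc, elliptical eyes whose contour collapses
vertically during blinks (open EAR ≈ 0.52, closed ≈ 0.04), an iris disc
that disappears while the eye is closed, eyebrow arcs that bob with a
per-subject amplitude, and an optional hand blob with 21 joint markers.
Blinks arrive as a homogeneous Poisson process (per-frame start
probability rate/(60·fps)) with a fixed closure duration (default 3
frames); body and hand translation follow mean-reverting random walks
whose per-frame innovation is the documented amplitude — mean reversion
keeps the face in frame without clipping, which would otherwise distort
the amplitude contract near the boundary.

Class structure: TRUTH subjects draw blink rate 20/min (SD 5), body
motion 0.8 px/frame (SD 0.25), eyebrow bob 0.5 px (SD 0.2), hand jiggle
0.3 px/frame (SD 0.1); LIE subjects are shifted by effect × (18/min,
0.8 px, 0.5 px, 0.2 px) respectively.  Standardised by the between-subject
SDs the contrasts order blink > body > eyebrow > hand, the qualitative
ordering the cue statistics reporting expects; the magnitudes themselves
are this package's choice, since no public numeric reference exists for
them.  Female subjects express every cue 10% more strongly — a simple
hook for the gender-stratified descriptive statistics.  80% of subjects
carry hands (one or two at random); hand-absent subjects exercise the
zero-padding path end to end.

What the generator does **not** emulate: real faces and photometric
variation, pose changes, occlusion, detector noise in the landmark
streams (streams are exact render geometry), camera motion distinct from
body motion, and any audio-visual context.  Passing tests therefore
demonstrate that the pipeline's machinery — geometry, tracking,
selection, training, evaluation protocol — behaves correctly and that
class-conditioned cue differences of the documented size are recoverable;
they say nothing about accuracy on real interrogation footage.

## Problem sizes

Cohort-level tests and the acceptance script run at the package's desk
scale, chosen once: 8-second clips at 12.5 fps (100 frames), 36×36 px
frames, a 36-px encoder input (no resize step), hidden size 16, batch 64,
12 training epochs at rate 0.1 (20 epochs for the small ablation
cohorts).  Halving the frame rate relative to typical video keeps blink
closures at a realistic ~240 ms while keeping sequences short.  The
end-to-end recovery study uses 60 + 60 subjects with 10-fold evaluation
over effect sizes {0, 0.5, 1.0}; ablations use 20 + 20 subjects with
5-fold evaluation on a blink-only contrast.

## Numerical choices and degenerate inputs

- Keyframe rule: strict inequality, so a constant clip keeps only the
  forced first frame; a single-frame clip has no differences and is
  rejected by `compute_threshold` (but `select_keyframes` returns the lone
  frame).
- Corner response: central-difference gradients with a Gaussian window
  (σ = block_size/6) localise an ideal square corner to < 1 px bias;
  textureless frames return an empty list, not an error.
- Lucas–Kanade: max 10 iterations per level, convergence step 0.01 px,
  minimum normalised tensor eigenvalue 1e-4; pyramid depth is clamped so
  the window always fits.
- PCA: eigendecomposition of the covariance via `eigh`; a constant pose
  matrix (zero covariance) is an error; sign fixed per component.
- Selection: constant columns are excluded with a warning; single-class
  labels are an error; ties break toward the lowest column index, making
  the search order-deterministic.
- Training: labels may be LIE/TRUTH strings or {0, 1}; a single-class
  training set is an error; feature standardisation statistics come from
  the training sequences only, with zero-variance columns left unscaled.
- Evaluation: `k` larger than the cohort is an error; undefined rates stay
  `None` so fold averages are honest.

## Known limitations

- The sparse Lucas–Kanade tracker recovers translations to sub-pixel
  accuracy on textured scenes but, like any local method, fails on large
  displacements relative to the window and pyramid depth.
- The fixed-weight encoder is a random projection: it preserves coarse
  pixel structure but learns nothing; on synthetic cohorts its slice is
  mostly ballast, and the ablation studies treat it as part of the full
  fusion rather than a modality of interest.
- Guided selection's relevance is a marginal, linear statistic; features
  informative only through interactions will be missed.
- Per-clip classification treats each clip as one subject; no
  subject-identity grouping across clips is modelled.
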