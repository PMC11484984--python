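# Methods

This note documents the models, conventions and design choices behind
`cacseg`, in the spirit of a methods appendix: what is computed, under which
assumptions, and where the genuinely open decisions were made.

## The segment diagram

The 13 adapted segment classes collapse the SCCT coronary segmentation scheme
(defined for contrast-enhanced CTA) to what is distinguishable on non-contrast
calcium-scoring CT. The canonical label order — p/m/d/s-RCA, LM, p/m/d/s-LAD,
p/m/d/s-LCX — is fixed package-wide so confusion matrices and label volumes
are comparable bit-for-bit. The SCCT mapping is: 1→p-RCA, 2→m-RCA,
3/4a/4b→d-RCA, RCA side branches→s-RCA, 5→LM, 6→p-LAD, 7→m-LAD, 8→d-LAD,
9/10/17→s-LAD, 11→p-LCX, 13→m-LCX, 15/16a/16b→d-LCX, 12/14→s-LCX.

*Adjacency* drives the disagreement weights of the segment-level weighted κ
(0.5 for adjoining pairs, 1.0 otherwise). We define adjoining as consecutive
segments along one vessel — (p,m), (m,d), (d,s) within RCA/LAD/LCX — plus the
left-main bifurcation pairs (LM, p-LAD) and (LM, p-LCX). Whether the
bifurcation pairs should count as adjoining is a judgment call; they are
anatomically contiguous, so we include them. The adjacency lives in one
shipped YAML file (`cacseg/data/segment_diagram.yaml`) and can be swapped
without touching code. Under this default adjacency the shipped 13×13
test-set matrix gives κ_w = 0.792; published analyses using a different
(unpublished) weighting matrix report values near 0.81, so the statistic is
sensitive at the ±0.02 level to the exact weighting.

## Agatston scoring

* Candidate voxels: attenuation ≥ 130 HU, boundary inclusive.
* Lesion identity: maximal 26-connected 3-D components. A calcification
  spanning slices must be one object for lesion counting and segment
  assignment; the in-plane areas entering the score are still computed per
  slice within the component.
* Minimum-size rule: per-slice contributions below 1 mm² score zero, and
  components with no qualifying slice are discarded entirely (noise specks).
* Density weight: per-slice peak attenuation, bins 130–199/200–299/300–399/
  ≥ 400 HU → 1/2/3/4. The weight is per slice, not per lesion.
* All areas and volumes use the voxel spacing carried by the volume, never
  raw voxel counts.
* Risk categories: I = {0}, II = (0, 100), III = [100, 300], IV = (300, ∞) AU.
  Published category definitions are ambiguous at exactly 100 and 300 AU;
  the boundaries are a configurable `RiskPolicy` with the above defaults.

## The synthetic phantom

The phantom generator is first-class code: it produces the study conditions
under which every other module is tested.

What it emulates: Hounsfield-valued cardiac volumes at calcium-scoring
acquisition settings (3.0 mm slices by default, 2.4–3.0 mm allowed, 0.7 mm
in-plane), a ~40 HU soft-tissue background with a 50 HU blood pool, additive
Gaussian image noise (σ = 10 HU default), 13 non-overlapping tubular segment
regions laid out as connected trees (RCA chain with a side branch; LM
bifurcating into LAD and LCX chains; piecewise-linear centerlines in a config
dict), and ellipsoidal calcified lesions of 180–900 HU placed on segment
centerlines — spanning all four Agatston density bins. Default six lesions
per case, assigned to segments cyclically in canonical order.

Construction guarantees used by tests: every calcified voxel is ≥ 130 HU
(lesion voxels are floored at the threshold after noise); lesions are mutually
separated so connected-component analysis recovers exactly the truth table;
each lesion lies inside its segment's tube with its majority region label
equal to its segment; lesions are the only ≥ 130 HU structures inside the
tubes, so thresholding restricted to the region mask reproduces the
ground-truth score. Tubes are rasterized by nearest-centerline assignment
(overlap is impossible by construction); centerlines of segments that share
no junction must keep two tube radii of separation or generation fails.

What it does **not** emulate: real cardiac anatomy and its variation, cardiac
and respiratory motion, metal and beam-hardening artifacts, bones, contrast,
vendor-specific HU calibration, or class imbalance across segments. Passing
the recovery tests therefore demonstrates that the pipeline's machinery is
correct and learnable at toy scale — not that the model generalizes to
clinical CT.

## The multi-task model

Input: five consecutive slices min-max normalized from [−2000, 1300] HU to
[0, 1] (edge slices replicated at volume borders) plus the binary candidate
mask of the center slice — six channels.

Architecture: a deliberately small fully-convolutional encoder-decoder in
numpy/BLAS (float32): two 3×3 conv+ReLU stages, 2×2 average pooling, a 3×3
bottleneck conv with dropout (p = 0.1), nearest-neighbour upsampling, a 1×1
mixing conv over [upsampled bottleneck, skip], and two 1×1 heads of 14
classes each (background + 13 segments). ~16k parameters at the default
width of 16 base channels. Because plain convolutions are
translation-equivariant while segment identity in the phantom is positional,
the network appends normalized (z, y, x) coordinate channels internally
(CoordConv-style); the public input contract stays six channels.

Losses: voxel-wise softmax cross-entropy for both heads. Calcified pixels are
rare (tens per slice out of 4096), so main-task foreground pixels are
up-weighted ×200 and auxiliary region pixels ×4; both weights are config.
The two tasks combine via learned homoscedastic-uncertainty weighting in the
log-variance parameterization, `exp(−s)·L + s` per task, which reduces to the
plain sum at s = 0 and is optimized by gradient steps alongside the network
(the ½ factors of the regression variant are absorbed into s). On slices
without region annotation the auxiliary loss is identically zero — the
auxiliary head receives exactly zero gradient — and s_aux is not updated when
a whole batch is unannotated.

Batches: 12 slices, stratified over (calcification × region annotation) with
expected proportions 12.5/12.5/37.5/37.5%. Integer parts of the stratum
counts are deterministic; fractional remainders are assigned by weighted
sampling, so expectations are exact for any batch size (batch 16 → always
(2,2,6,6); batch 12 → expectation (1.5, 1.5, 4.5, 4.5)).

Zero-CAC module: a logistic slice classifier trained after segmentation on
four pooled features of the image stack and the main head's foreground
probability map (max and mean foreground probability over candidates, log1p
candidate count, max center-slice attenuation). At inference, slices below
the decision threshold (0.5 default) have predicted calcium suppressed; a
patient is called zero-CAC when every slice empties. The filter can only
remove calcium, never add it.

Inference: per-voxel argmax of the main head after the zero-CAC filter,
restricted to candidate voxels (≥ 130 HU) — the Agatston convention only
scores above-threshold attenuation, and the restriction makes the predicted
mask directly scoreable.

Optimization: Adam (lr 5·10⁻³), seeded end-to-end; training aborts with a
diagnostic on non-finite loss. Default problem sizes are desk-scale: 20
training phantoms of 12×64×64 voxels (240 slices), 20 epochs ≈ 400 batches.

## Active learning

Uncertainty: mean per-voxel predictive entropy of the T-pass Monte-Carlo
dropout average (T = 10 default, T = 5 in the loop's tests), restricted to
candidate voxels for the main task (a slice with no candidates has main
uncertainty 0) and the whole slice for the auxiliary task. Top-k per task
with ties broken by pool order gives X_M and X_A.

Fisher scores: gradient of the log-likelihood of the model's own hard
predictions (pseudo-labels — unlabeled slices have no ground truth) with
respect to a designated parameter block θ_k, by default the bottleneck
convolution; configurable. i_F is the mean squared score norm of a sample set
(empirical Fisher), i_C the average scalar product between main-task scores
of X_M and auxiliary-task scores of the candidate batch, and
ρ_F = i_C / √(i_F·i_F) — bounded by 1 via Cauchy–Schwarz.

Selection is greedy: starting from an empty batch, repeatedly add the
candidate x ∈ X_A maximizing ρ_F(X_M, X_B ∪ {x}). One published formulation
writes the argmax over "X_B ∩ x"; intersecting a batch with a fresh sample is
vacuous, so union is the only reading that defines an iterative selection,
and that is what is implemented. Greedy selection equals the step-wise
exhaustive argmax by definition; it is not claimed globally optimal.

The loop (10 rounds by default) fine-tunes between rounds with a fresh
optimizer state each round, reveals ground-truth region labels for selected
slices in place of a human annotator, and retrains from scratch after the
last round to avoid warm-start overfitting.

## Evaluation statistics

* Lesion matching: a reference lesion is detected iff any of its voxels
  overlaps predicted foreground; its predicted segment is the majority
  predicted label over the overlap, ties toward the lower canonical index.
  Predicted components with no reference overlap are false positives. Both
  rules are the simplest defensible choices and are isolated behind one
  function.
* Micro metrics are computed over detected lesions only (missed lesions never
  enter the assignment matrix), which is why micro precision equals micro
  sensitivity equals the correct-assignment fraction on a single-label task.
  Per-class 0/0 ratios are reported as 0 with an `undefined` flag, mirroring
  the dash convention of reader-study tables.
* Weighted κ: κ_w = 1 − Σ W·p_obs / Σ W·p_exp with p_exp the outer product of
  marginals; all-ones off-diagonal W recovers unweighted κ (verified against
  scikit-learn to 1e-12 in tests). Linear ordinal weights |i−j|/(K−1) are
  used for the four risk categories.
* ICC: two-way random effects, single measure, absolute agreement — ICC(2,1)
  in the Shrout–Fleiss taxonomy — via the closed-form ANOVA decomposition,
  cross-checked against pingouin in tests. Returns NaN when both raters are
  constant.
* Bootstrap CIs: seeded percentile method, B = 2000 default; the resampling
  unit is the lesion for assignment metrics and the patient for risk-category
  agreement.

## Numerical and engineering choices

* Network arithmetic is float32 (memory-bandwidth bound); statistics are
  float64. Convolutions run as one large GEMM over an im2col layout.
* All random streams derive from explicit integer seeds; every public
  operation is deterministic given (config, seed).
* NIfTI I/O goes through nibabel with spacing in the affine; zooms are
  rounded at 5 decimals on read to undo float32 header storage.
* The `(1,100)`-style interval notation of published risk tables is resolved
  as described under Agatston scoring and kept behind `RiskPolicy`.

## Known limitations

* The phantom's geometric simplicity makes the segmentation task much easier
  than clinical data; recovery thresholds (≥ 80% segment assignment, ≥ 0.9
  voxel F1) are properties of the pipeline, not clinical performance claims.
* The zero-CAC classifier is a feature-pooled logistic model, adequate for
  phantom noise but not a substitute for the full image-level classifier a
  clinical system would use.
* ρ_F is computed from pseudo-label Fisher scores at one parameter block;
  other choices of θ_k change the selection and are exposed in config but not
  systematically compared.
* Interobserver machinery (second-reader comparison) reduces to running the
  same statistics on a second annotation set; no reader-study management
  tooling is included.
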