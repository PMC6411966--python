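# Methods

## Model

`gliotype` treats tissue classification as Bayesian inference with
non-parametric, spatially uninformed priors. The feature vector at each
voxel is X = (*p*, *q*, T2n, PDn): the isotropic and anisotropic scalar
decompositions of the diffusion tensor (mm² s⁻¹) and two intensity-
normalised structural channels. For each of the seven classes
{GM, WM, CSF, VO, GII, GIV, Ne} the class-conditional likelihood
*p*(X|*Cᵢ*) is a 4D histogram (50 bins per axis, unit integral) built from
labelled training voxels. The posterior is

P(*Cᵢ*|X) = P(*Cᵢ*) *p*(X|*Cᵢ*) / Σⱼ P(*Cⱼ*) *p*(X|*Cⱼ*),  with
P(*Cᵢ*) = *p*(X|*Cᵢ*) / Σⱼ *p*(X|*Cⱼ*).

Because the prior is itself the normalised likelihood, the posterior is
proportional to the squared likelihood. This is implemented literally as
the default (`prior="paper"`); whether a flat prior (posterior ∝
likelihood) was intended instead is not decidable from the method's
description, so a `prior="flat"` mode is provided for sensitivity analysis
but is never the default. Posteriors are invariant to any common rescaling
of all seven densities, which also makes the unit-integral-vs-unit-sum
ambiguity of histogram normalisation immaterial to classification; unit
integral (a true density) is used.

Key assumptions: the four channels are co-registered onto one voxel grid
(the package validates and refuses to resample); training ROIs are pure
samples of their class; intensities are exchangeable across subjects after
affine histogram normalisation; no spatial smoothness is imposed at the
voxel level (regularisation enters only through superpixel averaging).

## Histograms and numerical choices

* **Bin grid.** One global grid is shared by all classes — required so the
  cross-class likelihood ratio compares densities at the same X. Per
  channel the edges span the 0.5–99.5 percentile range of the pooled
  training samples, uniformly spaced; samples and query points outside the
  range are clipped into the edge bins. Moving an outside sample to the
  nearest edge-bin centre provably leaves the histogram unchanged.
* **Lookup** is piecewise constant (no interpolation): the density of the
  bin containing X.
* **Out-of-support voxels.** Where every class density is zero the
  posterior carries no information; such voxels get the uniform vector 1/7
  and an explicit mask, so superpixel averaging stays defined. With 10⁴
  training samples per class the default phantom shows ≈2 % out-of-support
  voxels — the intrinsic sparseness of a 50⁴-bin histogram.
* **Smoothing.** An optional Gaussian filter on the counts (σ in bins,
  `smoothing_sigma_bins`) is available for sparse training data; it is off
  by default because the canonical method uses raw histograms.
* **Intensity normalisation** fits I → aI + b (a > 0) minimising the L2
  distance between unit-sum histograms on the reference bin edges
  (256 bins over the reference's 0.1–99.9 percentile range). The objective
  is piecewise constant in (a, b), so the optimiser is moment-matching
  initialisation followed by six rounds of a shrinking 21×21 grid search
  rather than a gradient method. The reference histogram is a saved
  artifact, making normalisation reproducible. The whole skull-stripped
  mask (including CSF) feeds the histogram.

## Superpixels, lesion, colour

SLIC runs per axial slice (matching the 2D formulation of the source
superpixel implementation and the thick-slice acquisitions) on three
channels (PDn, FLAIR, *p*), each robustly rescaled to [0,1] by its 1–99
percentile span. Slices are upsampled in-plane ×4 (bilinear) before
clustering — e.g. 256² → 1024² — and labels return to the native grid by
block majority vote (ties broken to the smallest label; rare in-mask holes
filled from the nearest labelled pixel). The implementation is
scikit-image `slic` with `n_segments = ceil(H/g)·ceil(W/g)` for grid size
g = 30 and `compactness` equal to the regularisation value 0.2; channels
are not colour-converted. Superpixel ids are unique across slices.

Per-superpixel probabilities are the mean posterior over member voxels,
renormalised to unit sum (renormalisation precedes the lesion test, as the
procedure orders it; with in-mask voxels the mean already sums to 1, so
the order matters only where out-of-support voxels were averaged in). The
lesion is the union of superpixels with p(VO)+p(GII)+p(GIV)+p(Ne) strictly
greater than 0.5, reduced to the largest 3D-connected component under
26-connectivity (the method's "connected 3D component", with connectivity
chosen and fixed here). Colour: raw = (p(GIV), p(GII), p(Ne)); if nonzero,
rgb = raw/‖raw‖₂ · (p(GII)+p(GIV)+p(Ne)), clipped to [0,1]; pure oedema
and everything outside the lesion render black. High-grade volume counts
lesion superpixels with p(GIV) > 0.5 (strict).

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `bins` | 50 | – | histogram bins per feature axis |
| `mrsi_purity_threshold` | 0.90 | fraction | min tumour fraction for a training MRSI voxel |
| `necrosis_p_threshold` | 4×10⁻³ | mm² s⁻¹ | *p* above which GIV ROI voxels become Ne |
| `normal_prob_threshold` | 0.95 | fraction | segmentation probability behind the normal-tissue masks |
| `slic_grid_size` | 30 | pixels | SLIC seed spacing at upsampled resolution |
| `slic_regularisation` | 0.2 | – | SLIC compactness (channels in [0,1]) |
| `upsample_factor` | 4 | – | in-plane upsampling before SLIC |
| `lesion_threshold` | 0.5 | probability | abnormal-tissue inequality threshold |
| `highgrade_threshold` | 0.5 | probability | p(GIV) threshold for high-grade volume |
| `prior` | `paper` | – | PDD-derived prior (posterior ∝ L²) or `flat` |

## The phantom

The generator emulates the study conditions: a 7-class brain — WM
interior, GM shell, two CSF ventricles, and a nested tumour (necrotic
centre ⊂ GIV core ⊂ GII rim ⊂ oedema shell, spherical radii in mm) — at
192×192×20 voxels of 1.25×1.25×5 mm (240 mm field of view, thick slices).
Channel intensities are drawn per voxel from class mixture models (two
location-scale components for GII, GIV and Ne, mimicking multi-cluster
tumour densities; one component for GM/WM/CSF/VO) plus independent
per-channel acquisition noise. Component means are loosely anchored to
physiology — CSF free-water *p* ≈ 3×10⁻³ mm² s⁻¹, high WM *q*, elevated
*p* in oedema, and a necrosis *p* mixture straddling the 4×10⁻³ threshold
(70 % at 5.0×10⁻³, 30 % at 3.6×10⁻³) so the necrosis rule is exercised in
both directions. Every pair of classes is separated by ≥3 SD in at least
one classifier channel (asserted by a test): the phantom realises the
"well-separated classes" condition under which end-to-end recovery is
evaluated.

Training draws (`sample_training_set`) include the acquisition noise,
mirroring training intensities read off noisy images; they use an rng
stream independent of the voxel draws (seed+1). The phantom also emits a
synthetic MRSI geometry (4×4-voxel in-plane blocks over a 3-slice slab)
and a ground-truth fraction table (normal / GII / GIV, with necrosis
counted as GIV), so the MRSI evaluation runs end-to-end.

What the phantom does **not** model: partial-volume mixing at region
boundaries, bias fields, k-space/PSF effects, anatomical variability,
inter-subject intensity drift, or the heavy-tailed within-class
heterogeneity of real tumours. Passing recovery tests therefore
demonstrates correctness of the pipeline's computations under its own
assumptions — not clinical accuracy on patient data, where class overlap
is substantially larger.

## Evaluation battery

(i) Posteriors are block-averaged onto the MRSI grid, collapsed to
(normal = GM+WM+CSF+VO, low-grade = GII, high-grade = GIV+Ne) triples and
compared with the MRS-derived fractions by Székely's sample distance
correlation (the biased original form, computed by double-centering the
Euclidean distance matrices; an O(n²) loop implementation serves as the
test oracle). MRSI voxels used for training can be flagged and excluded;
voxels whose block carries < 0.5 posterior mass (mostly outside the brain)
are dropped. (ii) Manual-vs-automatic lesion volumes: two-sided Pearson
correlation plus Bland–Altman bias and 95 % limits (difference =
automatic − manual). (iii) Dice, Jaccard and Overlap
(Szymkiewicz–Simpson) coefficients between masks.

## Problem sizes and reproducibility

Tests and the acceptance script use the default phantom (≈283 k brain
voxels, 10⁴ training samples per class) and a coarser 64×64×10 phantom for
unit-level checks; these sizes give stable statistics while keeping a full
run under a minute on one CPU. All randomness flows through
`numpy.random.default_rng` seeded from one integer; rerunning any stage
with the same config and inputs is bit-identical.

## Known limitations

* The squared-likelihood posterior sharpens decisions relative to a flat
  prior; with well-separated classes the argmax rarely differs, but
  borderline partial-volume voxels are pushed toward the locally dominant
  class.
* Histogram likelihoods need dense training sampling; rare classes with
  few ROI voxels produce sparse PDDs and more out-of-support voxels
  (mitigable with `smoothing_sigma_bins`).
* Registration, reslicing, skull stripping, the spectral decomposition of
  MRSI data and the control-cohort segmentation behind the normal-tissue
  masks are out of scope: the package consumes their outputs.
* Superpixel granularity is set by the physical in-plane resolution;
  structures thinner than one superpixel (~7 mm at 0.94 mm voxels ×4
  upsampling) cannot be isolated by the averaging stage.
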