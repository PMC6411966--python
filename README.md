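# gliotype

Nosologic tissue-type mapping of glial brain tumours from multimodal MRI.

Gliomas are heterogeneous: a single lesion can contain cellular high-grade
tumour, low-grade or infiltrated tissue, necrosis and vasogenic oedema, and
conventional MRI does not delineate these components or the infiltration
margin. `gliotype` implements a non-parametric Bayesian classification
scheme that maps every brain voxel to one of seven tissue classes — grey
matter (GM), white matter (WM), CSF, vasogenic oedema (VO), grade II glioma
(GII), grade IV glioma (GIV) and necrosis (Ne) — from four co-registered
image channels: isotropic diffusion *p*, anisotropic diffusion *q*, and
intensity-normalised T2-weighted (T2n) and proton-density-weighted (PDn)
images. It is aimed at researchers in quantitative neuro-oncology imaging
who want probabilistic tissue maps, automatic lesion segmentation and
high-grade tumour volumes without Gaussian assumptions or spatial priors.

## Method

Each tissue class *Cᵢ* gets a class-conditional likelihood *p*(X|*Cᵢ*)
estimated as a 4D histogram over X = (*p*, *q*, T2n, PDn), 50 bins per
axis, normalised to unit integral, built from high-confidence training
regions (MRSI voxels with >90 % pure tumour spectra, necrosis split from
GIV at *p* > 4×10⁻³ mm² s⁻¹, normal-tissue and oedema masks). Posteriors
follow Bayes' theorem,

    P(Cᵢ|X) = P(Cᵢ) p(X|Cᵢ) / Σⱼ P(Cⱼ) p(X|Cⱼ),

with the prior itself taken from the histograms,
P(*Cᵢ*) = *p*(X|*Cᵢ*) / Σⱼ *p*(X|*Cⱼ*), so no spatial prior enters. The
voxelwise maps are averaged within SLIC superpixels (computed per slice on
PDn/FLAIR/*p* at ×4 upsampling, grid size 30, regularisation 0.2) and
renormalised; the whole lesion is segmented by the inequality
p(VO)+p(GII)+p(GIV)+p(Ne) > 0.5 (largest 3D-connected component), and
rendered as an RGB nosologic map with Red = p(GIV), Green = p(GII),
Blue = p(Ne), unit-length normalised and intensity-modulated by
p(GII)+p(GIV)+p(Ne) so pure oedema appears black. High-grade tumour volume
is the total volume of lesion superpixels with p(GIV) > 0.5.

A synthetic phantom module generates 7-class brains with per-class
non-Gaussian (mixture) channel models and nested tumour geometry, plus an
MRSI grid with ground-truth tissue fractions, so the whole pipeline is
testable without patient data.

## Worked example

```python
from gliotype import phantom, TissueTypeModel

spec = phantom.PhantomSpec(seed=7)                       # synthetic GIV glioma
volume, truth, volumes = phantom.generate_phantom(spec)
train = phantom.sample_training_set(spec, n_per_class=10_000)

model = TissueTypeModel.from_training_samples(volume, train,
                                              brain_mask=truth.labels > 0)
results = model.fit()
print(results.summary())
```

prints

```
Tissue-type mapping results
===========================
volume shape (192, 192, 20), voxel (1.25, 1.25, 5.0) mm
prior mode: paper; bins: 50; SLIC grid 30, reg 0.2, upsample x4
superpixels: 12905
out-of-support voxel fraction: 0.0180
lesion components considered: 21
lesion volume: 91.8 ml
high-grade volume (p(GIV) > 0.5): 14.5 ml

probability-weighted lesion composition (ml):
    GM:      0.5
    WM:      0.8
   CSF:      0.6
    VO:     46.0
   GII:     26.3
   GIV:     16.1
    Ne:      1.5
```

The automatic lesion volume (91.8 ml) recovers the phantom's ground-truth
abnormal volume (91.7 ml); the probability-weighted GIV estimate (16.1 ml)
matches the 16.3 ml of simulated grade-IV tissue, and the high-grade volume
(14.5 ml) counts only superpixels whose averaged p(GIV) exceeds 0.5.
`results.save(dir)` writes the posterior maps, superpixel table, lesion
mask and RGB colour map as NIfTI/CSV; `results.save_overlays(dir)` writes
per-slice PNG overlays on FLAIR.

The same stages are available from the shell:

```bash
gliotype simulate --seed 7 --out phantom/
gliotype run --seed 7 --out mapped/          # end-to-end phantom pipeline
gliotype normalize --channel T2 --ref ref_t2.tsv --volume t2.nii.gz --out t2n.nii.gz
```

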