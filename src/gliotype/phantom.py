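"""Synthetic multimodal brain phantoms with ground-truth tissue labels.

The phantom emulates the study conditions the pipeline was designed for: a
7-class brain (GM shell, WM interior, CSF ventricles, and a nested tumour
with a necrotic centre, GIV core, GII infiltration rim and vasogenic oedema
shell) imaged in five channels (p, q, T2n, PDn, FLAIR).  Per-class channel
intensities are drawn from location-scale mixture models — two components
for the tumour classes, mimicking the multi-cluster, non-Gaussian densities
seen in real glioma tissue — plus independent per-channel acquisition
noise.  Channel units: p and q in 10⁻³ mm² s⁻¹-scale diffusivities (stored
in mm² s⁻¹); T2n/PDn/FLAIR in normalised intensity units.

Default component means are loosely anchored to physiology (CSF free-water
p ≈ 3×10⁻³ mm² s⁻¹; WM anisotropy q high; oedema and necrosis p elevated,
with 70% of the necrosis mixture above the 4×10⁻³ mm² s⁻¹ threshold so the
necrosis ROI rule is exercised in both directions) and are pairwise
separated by ≥3 SD in the 4D classifier space.

The phantom also emits a synthetic MRSI geometry plus tissue-fraction table
(block-averaged ground-truth labels mapped to normal/GII/GIV fractions) so
the MRSI-based evaluation runs end-to-end without patient data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classes import CLASSES, CLASS_BY_NAME, CLASSIFIER_CHANNELS, TissueClass
from .io_volumes import LabelVolume, MultimodalVolume, save_multimodal, save_volume
from .mrsi import MRSIGeometry, save_fractions

ALL_CHANNELS = ("p", "q", "T2n", "PDn", "FLAIR")


@dataclass(frozen=True)
class MixtureComponent:
    """One multivariate location-scale component over the 5 channels."""

    mean: tuple[float, float, float, float, float]
    sd: tuple[float, float, float, float, float]
    weight: float = 1.0


@dataclass(frozen=True)
class TumourGeometry:
    """Concentric spherical tumour regions, radii in mm (Ne ⊂ GIV ⊂ GII ⊂ VO)."""

    center_mm: tuple[float, float, float] = (72.0, 92.0, 50.0)
    r_ne: float = 6.0
    r_giv: float = 16.0
    r_gii: float = 22.0
    r_vo: float = 28.0

    def __post_init__(self):
        radii = [r for r in (self.r_ne, self.r_giv, self.r_gii, self.r_vo) if r > 0]
        if radii != sorted(radii):
            raise ValueError("tumour radii must be nested: r_ne <= r_giv <= r_gii <= r_vo")


@dataclass(frozen=True)
class BrainGeometry:
    """Elliptical brain with a GM shell and two ventricles; mm units."""

    center_mm: tuple[float, float, float] = (120.0, 120.0, 50.0)
    semi_axes_mm: tuple[float, float, float] = (105.0, 105.0, 48.0)
    gm_shell_rho: float = 0.88            # normalised radius where WM ends
    ventricle_offset_mm: float = 15.0
    ventricle_semi_axes_mm: tuple[float, float, float] = (12.0, 30.0, 12.0)


def _c(p, q, t2, pd_, fl):
    return (p * 1e-3, q * 1e-3, t2, pd_, fl)


def _s(p, q, t2, pd_, fl):
    return (p * 1e-3, q * 1e-3, t2, pd_, fl)


#: Default class mixture models.  Diffusivities given in 10⁻³ mm² s⁻¹.
#: Component means of every class pair are separated by at least 3 SD in at
#: least one classifier channel, so the phantom realises the "well-separated
#: classes" study condition; spreads are compact relative to the intensity
#: dynamic range, as in the tight per-tissue clusters the phantom emulates.
DEFAULT_CLASS_MODELS: dict[str, tuple[MixtureComponent, ...]] = {
    "GM": (MixtureComponent(_c(0.85, 0.30, 100, 150, 130), _s(0.04, 0.02, 5, 5, 6)),),
    "WM": (MixtureComponent(_c(0.70, 0.70, 85, 120, 105), _s(0.04, 0.02, 5, 5, 6)),),
    "CSF": (MixtureComponent(_c(3.00, 0.15, 400, 200, 30), _s(0.05, 0.02, 8, 5, 6)),),
    "VO": (MixtureComponent(_c(1.70, 0.45, 260, 180, 230), _s(0.04, 0.02, 5, 5, 6)),),
    "GII": (
        MixtureComponent(_c(1.10, 0.22, 200, 205, 185), _s(0.04, 0.02, 5, 5, 6), 0.5),
        MixtureComponent(_c(1.25, 0.22, 230, 220, 185), _s(0.04, 0.02, 5, 5, 6), 0.5),
    ),
    "GIV": (
        MixtureComponent(_c(1.00, 0.40, 150, 245, 185), _s(0.04, 0.02, 5, 5, 6), 0.6),
        MixtureComponent(_c(1.30, 0.40, 170, 260, 185), _s(0.04, 0.02, 5, 5, 6), 0.4),
    ),
    "Ne": (
        MixtureComponent(_c(5.00, 0.18, 320, 190, 120), _s(0.05, 0.02, 6, 5, 6), 0.7),
        MixtureComponent(_c(3.60, 0.18, 300, 190, 120), _s(0.05, 0.02, 6, 5, 6), 0.3),
    ),
}

#: Independent per-channel acquisition noise SD (same units as the channels).
DEFAULT_NOISE_SD = {"p": 0.01e-3, "q": 0.005e-3, "T2n": 1.5, "PDn": 1.5, "FLAIR": 2.0}


@dataclass
class PhantomSpec:
    """Full description of a synthetic phantom (deterministic given `seed`)."""

    shape: tuple[int, int, int] = (192, 192, 20)
    voxel_size: tuple[float, float, float] = (1.25, 1.25, 5.0)
    brain: BrainGeometry = field(default_factory=BrainGeometry)
    tumour: TumourGeometry = field(default_factory=TumourGeometry)
    class_models: dict[str, tuple[MixtureComponent, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MODELS)
    )
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    seed: int = 0

    def __post_init__(self):
        for name, comps in self.class_models.items():
            w = sum(c.weight for c in comps)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"mixture weights for {name} sum to {w}, not 1")
        if any(s <= 0 for s in self.shape) or any(v <= 0 for v in self.voxel_size):
            raise ValueError("degenerate phantom geometry")


def pure_lowgrade_spec(seed: int = 0, **kwargs) -> PhantomSpec:
    """A phantom containing only low-grade tumour tissue (no GIV, no necrosis)."""
    tum = TumourGeometry(r_ne=0.0, r_giv=0.0, r_gii=14.0, r_vo=22.0)
    return PhantomSpec(tumour=tum, seed=seed, **kwargs)


def _coord_grids(spec: PhantomSpec):
    ax = [
        (np.arange(n) + 0.5) * v
        for n, v in zip(spec.shape, spec.voxel_size)
    ]
    return np.meshgrid(*ax, indexing="ij")


def ground_truth_labels(spec: PhantomSpec) -> LabelVolume:
    """Exact class labels from the nested geometry (later regions override)."""
    X, Y, Z = _coord_grids(spec)
    b = spec.brain
    rho = np.sqrt(
        ((X - b.center_mm[0]) / b.semi_axes_mm[0]) ** 2
        + ((Y - b.center_mm[1]) / b.semi_axes_mm[1]) ** 2
        + ((Z - b.center_mm[2]) / b.semi_axes_mm[2]) ** 2
    )
    labels = np.zeros(spec.shape, dtype=np.int32)
    labels[rho <= 1.0] = CLASS_BY_NAME["GM"].index
    labels[rho <= b.gm_shell_rho] = CLASS_BY_NAME["WM"].index
    for sgn in (-1.0, 1.0):
        cx = b.center_mm[0] + sgn * b.ventricle_offset_mm
        rv = np.sqrt(
            ((X - cx) / b.ventricle_semi_axes_mm[0]) ** 2
            + ((Y - b.center_mm[1]) / b.ventricle_semi_axes_mm[1]) ** 2
            + ((Z - b.center_mm[2]) / b.ventricle_semi_axes_mm[2]) ** 2
        )
        labels[(rv <= 1.0) & (labels > 0)] = CLASS_BY_NAME["CSF"].index
    t = spec.tumour
    r = np.sqrt(
        (X - t.center_mm[0]) ** 2 + (Y - t.center_mm[1]) ** 2 + (Z - t.center_mm[2]) ** 2
    )
    inside = labels > 0
    for radius, name in ((t.r_vo, "VO"), (t.r_gii, "GII"), (t.r_giv, "GIV"), (t.r_ne, "Ne")):
        if radius > 0:
            labels[(r <= radius) & inside] = CLASS_BY_NAME[name].index
    return LabelVolume(labels, {c.index: c for c in CLASSES})


def _draw_mixture(
    comps: tuple[MixtureComponent, ...],
    n: int,
    rng: np.random.Generator,
    channels: tuple[str, ...],
) -> np.ndarray:
    """n draws from the class mixture, restricted to the named channels."""
    ch_idx = [ALL_CHANNELS.index(c) for c in channels]
    weights = np.array([c.weight for c in comps])
    which = rng.choice(len(comps), size=n, p=weights)
    out = np.empty((n, len(ch_idx)))
    for k, comp in enumerate(comps):
        m = which == k
        nk = int(m.sum())
        if nk == 0:
            continue
        mean = np.array([comp.mean[i] for i in ch_idx])
        sd = np.array([comp.sd[i] for i in ch_idx])
        out[m] = rng.normal(mean, sd, size=(nk, len(ch_idx)))
    return out


def _add_noise(samples: np.ndarray, spec: PhantomSpec, rng: np.random.Generator,
               channels: tuple[str, ...]) -> np.ndarray:
    noise_sd = np.array([spec.noise_sd[c] for c in channels])
    return samples + rng.normal(0.0, noise_sd, size=samples.shape)


def _clip_nonneg(samples: np.ndarray, channels: tuple[str, ...]) -> np.ndarray:
    for k, c in enumerate(channels):
        if c in ("p", "q"):
            samples[..., k] = np.maximum(samples[..., k], 0.0)
    return samples


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[MultimodalVolume, LabelVolume, dict[str, float]]:
    """Render the phantom: channels, ground-truth labels, per-class volumes (ml).

    Deterministic for a fixed ``spec.seed``.  Outside the brain every
    channel is 0.
    """
    rng = np.random.default_rng(spec.seed)
    truth = ground_truth_labels(spec)
    vox_ml = float(np.prod(spec.voxel_size)) / 1000.0
    data = np.zeros(spec.shape + (len(ALL_CHANNELS),))
    for cls in CLASSES:
        m = truth.labels == cls.index
        n = int(m.sum())
        if n == 0:
            continue
        samples = _draw_mixture(spec.class_models[cls.name], n, rng, ALL_CHANNELS)
        samples = _add_noise(samples, spec, rng, ALL_CHANNELS)
        data[m] = _clip_nonneg(samples, ALL_CHANNELS)
    channels = {name: data[..., k] for k, name in enumerate(ALL_CHANNELS)}
    volume = MultimodalVolume(channels, voxel_size=spec.voxel_size)
    volumes_ml = {c.name: float(np.count_nonzero(truth.labels == c.index)) * vox_ml
                  for c in CLASSES}
    return volume, truth, volumes_ml


def sample_training_set(
    spec: PhantomSpec,
    n_per_class: int,
    seed: int | None = None,
) -> dict[TissueClass, np.ndarray]:
    """i.i.d. classifier-channel training draws per class (seeded).

    Draws come from the class mixture plus the per-channel acquisition
    noise — mirroring training intensities read off noisy images.  The seed
    defaults to ``spec.seed + 1`` so training draws are independent of the
    phantom's voxel draws.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    out: dict[TissueClass, np.ndarray] = {}
    for cls in CLASSES:
        s = _draw_mixture(spec.class_models[cls.name], n_per_class, rng, CLASSIFIER_CHANNELS)
        s = _add_noise(s, spec, rng, CLASSIFIER_CHANNELS)
        out[cls] = _clip_nonneg(s, CLASSIFIER_CHANNELS)
    return out


def abnormal_mask(truth: LabelVolume) -> np.ndarray:
    """Ground-truth lesion mask: VO + GII + GIV + Ne."""
    out = np.zeros(truth.labels.shape, dtype=bool)
    for name in ("VO", "GII", "GIV", "Ne"):
        out |= truth.mask(name)
    return out


def default_mrsi_geometry(spec: PhantomSpec) -> MRSIGeometry:
    """A coarse MRSI grid over the central slab, 4×4 in-plane voxels per cell."""
    block = (4, 4)
    ni = spec.shape[0] // block[0] - 2
    nj = spec.shape[1] // block[1] - 2
    origin = (block[0], block[1])
    z_mid = spec.shape[2] // 2
    return MRSIGeometry(
        origin=origin, block_size=block, z_start=max(z_mid - 1, 0),
        n_slices=3, grid_shape=(ni, nj),
    )


def mrsi_fraction_table(
    truth: LabelVolume,
    geometry: MRSIGeometry,
) -> pd.DataFrame:
    """Ground-truth MRS tissue fractions per MRSI voxel.

    Labels collapse to normal = {GM, WM, CSF, VO}, GII, and GIV = {GIV, Ne}
    (necrotic tissue arises within grade IV tumour); out-of-brain voxels in
    a block count as normal.
    """
    geometry.validate_bounds(truth.labels.shape)
    gii = CLASS_BY_NAME["GII"].index
    giv = CLASS_BY_NAME["GIV"].index
    ne = CLASS_BY_NAME["Ne"].index
    rows = []
    for i in range(geometry.grid_shape[0]):
        for j in range(geometry.grid_shape[1]):
            sx, sy, sz = geometry.block(i, j)
            block = truth.labels[sx, sy, sz]
            n = block.size
            f_gii = float(np.count_nonzero(block == gii)) / n
            f_giv = float(np.count_nonzero((block == giv) | (block == ne))) / n
            rows.append({
                "i": i, "j": j,
                "fraction_normal": 1.0 - f_gii - f_giv,
                "fraction_GII": f_gii,
                "fraction_GIV": f_giv,
            })
    return pd.DataFrame(rows)


def write_phantom(spec: PhantomSpec, out_dir: str | Path) -> dict:
    """Generate and write channel NIfTIs, labels, MRSI CSV + geometry, truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    volume, truth, volumes_ml = generate_phantom(spec)
    paths = save_multimodal(volume, out_dir)
    save_volume(truth.labels, spec.voxel_size, out_dir / "labels.nii.gz")
    geom = default_mrsi_geometry(spec)
    geom.save(out_dir / "mrsi_geometry.json")
    save_fractions(mrsi_fraction_table(truth, geom), out_dir / "mrsi_fractions.csv")
    info = {
        "seed": spec.seed,
        "shape": list(spec.shape),
        "voxel_size_mm": list(spec.voxel_size),
        "class_volumes_ml": volumes_ml,
        "abnormal_volume_ml": float(sum(volumes_ml[n] for n in ("VO", "GII", "GIV", "Ne"))),
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(info, fh, indent=2)
    return {"paths": {k: str(v) for k, v in paths.items()}, **info}
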