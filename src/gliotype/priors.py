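"""Tissue ROI derivation and per-class 4D probability density distributions.

The class-conditional likelihoods p(X|C_i) are non-parametric: each tissue
class gets a 4D histogram over the classifier feature space (p, q, T2n,
PDn), 50 bins per axis by default, normalised to unit integral.  All seven
classes share one global bin-edge set so that densities of different
classes are comparable at the same feature vector X.

Training ROIs follow fixed rules:

* tumour ROIs come from MRSI voxels whose spectrum decomposes into >90%
  grade II (GII patients) or >90% grade IV (GIV patients) tumour tissue;
* within GIV ROIs, voxels with isotropic diffusivity p above
  4×10⁻³ mm² s⁻¹ are relabelled necrosis (free water dominates there);
* normal-tissue ROIs (GM/WM/CSF segmented at probability ≥ 0.95) and
  manually drawn oedema ROIs are consumed as precomputed masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .classes import CLASSES, CLASS_BY_NAME, CLASSIFIER_CHANNELS, TissueClass
from .io_volumes import LabelVolume, MultimodalVolume
from .mrsi import MRSIGeometry, validate_fractions

DEFAULT_BINS = 50
#: Percentile span (over pooled training samples) covered by the bin grid.
GRID_PCT_RANGE = (0.5, 99.5)


@dataclass(frozen=True)
class ROIRuleSet:
    """Thresholds of the training-ROI derivation rules."""

    mrsi_purity_threshold: float = 0.90
    necrosis_p_threshold: float = 4e-3      # mm² s⁻¹
    normal_prob_threshold: float = 0.95

    def __post_init__(self):
        if not 0 < self.mrsi_purity_threshold <= 1:
            raise ValueError("mrsi_purity_threshold must be in (0, 1]")
        if self.necrosis_p_threshold <= 0:
            raise ValueError("necrosis_p_threshold must be positive")
        if not 0 < self.normal_prob_threshold <= 1:
            raise ValueError("normal_prob_threshold must be in (0, 1]")


@dataclass
class BinGrid4D:
    """Shared uniform bin edges over the (p, q, T2n, PDn) feature space."""

    edges: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    bins: int = DEFAULT_BINS

    def __post_init__(self):
        if len(self.edges) != 4:
            raise ValueError("need one edge vector per classifier channel")
        edges = []
        for k, e in enumerate(self.edges):
            e = np.asarray(e, dtype=float)
            if e.shape != (self.bins + 1,):
                raise ValueError(
                    f"edge vector {k} has length {e.shape[0]}, expected {self.bins + 1}"
                )
            if np.any(np.diff(e) <= 0):
                raise ValueError(f"edge vector {k} is not strictly increasing")
            edges.append(e)
        self.edges = tuple(edges)

    @property
    def bin_volume(self) -> float:
        """Hypervolume of one bin (uniform per axis)."""
        return float(np.prod([(e[-1] - e[0]) / self.bins for e in self.edges]))

    def bin_indices(self, x: np.ndarray) -> tuple[np.ndarray, ...]:
        """Per-axis bin index of points `x` (..., 4); out-of-grid clipped."""
        x = np.asarray(x, dtype=float)
        idx = []
        for k in range(4):
            i = np.searchsorted(self.edges[k], x[..., k], side="right") - 1
            idx.append(np.clip(i, 0, self.bins - 1))
        return tuple(idx)


@dataclass
class PDD4D:
    """Per-class 4D probability density distribution (unit integral)."""

    tissue: TissueClass
    grid: BinGrid4D
    density: np.ndarray
    n_samples: int

    def __post_init__(self):
        b = self.grid.bins
        if self.density.shape != (b, b, b, b):
            raise ValueError(f"density shape {self.density.shape} != {(b,) * 4}")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    @property
    def integral(self) -> float:
        return float(self.density.sum()) * self.grid.bin_volume


def derive_tumour_rois(
    mrsi_fractions: pd.DataFrame,
    mrsi_geometry: MRSIGeometry,
    rules: ROIRuleSet,
    grade_of_patient: str,
    image_shape: tuple[int, int, int],
) -> LabelVolume:
    """Label image voxels inside "pure tumour" MRSI voxels.

    An MRSI voxel is pure when its tumour fraction of the patient's own
    grade strictly exceeds ``rules.mrsi_purity_threshold``; its whole image
    block is then labelled GII (GII patients) or GIV (GIV patients).
    """
    if grade_of_patient not in ("GII", "GIV"):
        raise ValueError("grade_of_patient must be 'GII' or 'GIV'")
    validate_fractions(mrsi_fractions)
    mrsi_geometry.validate_bounds(image_shape)
    cls = CLASS_BY_NAME[grade_of_patient]
    col = f"fraction_{grade_of_patient}"
    labels = np.zeros(image_shape, dtype=np.int32)
    for _, row in mrsi_fractions.iterrows():
        if row[col] > rules.mrsi_purity_threshold:
            sx, sy, sz = mrsi_geometry.block(int(row["i"]), int(row["j"]))
            labels[sx, sy, sz] = cls.index
    return LabelVolume(labels, {cls.index: cls})


def split_necrosis(
    giv_roi: LabelVolume,
    p_channel: np.ndarray,
    rules: ROIRuleSet = ROIRuleSet(),
) -> LabelVolume:
    """Relabel GIV ROI voxels with p above the necrosis threshold as Ne."""
    giv = CLASS_BY_NAME["GIV"]
    ne = CLASS_BY_NAME["Ne"]
    present = set(np.unique(giv_roi.labels)) - {0}
    if present - {giv.index}:
        raise ValueError("split_necrosis expects a GIV-only ROI volume")
    labels = giv_roi.labels.copy()
    hot = (labels == giv.index) & (p_channel > rules.necrosis_p_threshold)
    labels[hot] = ne.index
    return LabelVolume(labels, {giv.index: giv, ne.index: ne})


def extract_samples(
    volume: MultimodalVolume,
    rois: LabelVolume,
) -> dict[TissueClass, np.ndarray]:
    """Pull (p, q, T2n, PDn) 4-vectors out of the volume for every ROI class."""
    if rois.labels.shape != volume.shape:
        raise ValueError("ROI volume shape does not match the multimodal volume")
    feats = volume.stack(CLASSIFIER_CHANNELS)
    out: dict[TissueClass, np.ndarray] = {}
    for k, cls in rois.class_map.items():
        m = rois.labels == k
        if m.any():
            s = feats[m]
            out[cls] = np.vstack([out[cls], s]) if cls in out else s
    return out


def fit_bin_grid(
    samples_by_class: Mapping[TissueClass, np.ndarray],
    bins: int = DEFAULT_BINS,
) -> BinGrid4D:
    """Global uniform bin edges from the pooled 0.5–99.5 percentile span.

    Pooling over classes guarantees one grid shared by every PDD, which the
    cross-class prior ratio requires.
    """
    arrays = [np.asarray(s, dtype=float).reshape(-1, 4) for s in samples_by_class.values()]
    if not arrays or sum(a.shape[0] for a in arrays) == 0:
        raise ValueError("no training samples to fit a bin grid")
    pooled = np.vstack(arrays)
    if pooled.shape[0] < bins:
        raise ValueError(f"need at least {bins} pooled samples, got {pooled.shape[0]}")
    edges = []
    for k in range(4):
        lo, hi = np.percentile(pooled[:, k], GRID_PCT_RANGE)
        if hi <= lo:  # constant channel: pad so the grid stays valid
            pad = max(abs(lo), 1.0) * 1e-6
            lo, hi = lo - pad, hi + pad
        edges.append(np.linspace(lo, hi, bins + 1))
    return BinGrid4D(tuple(edges), bins=bins)


def build_pdd(
    samples: np.ndarray,
    grid: BinGrid4D,
    tissue: TissueClass,
    smoothing_sigma_bins: float = 0.0,
) -> PDD4D:
    """Histogram the class samples on the shared grid, unit-integral normalised.

    Samples outside the grid are clipped into the edge bins.  Optional
    Gaussian smoothing (``smoothing_sigma_bins`` > 0, in bin units) is
    applied to the counts before normalisation; it is off by default.
    """
    samples = np.asarray(samples, dtype=float).reshape(-1, 4)
    n = samples.shape[0]
    if n == 0:
        raise ValueError(f"no samples for class {tissue.name}")
    idx = grid.bin_indices(samples)
    b = grid.bins
    flat = np.ravel_multi_index(idx, (b, b, b, b))
    counts = np.bincount(flat, minlength=b ** 4).astype(np.float64).reshape(b, b, b, b)
    if smoothing_sigma_bins > 0:
        counts = ndimage.gaussian_filter(counts, sigma=smoothing_sigma_bins, mode="constant")
    density = counts / (counts.sum() * grid.bin_volume)
    return PDD4D(tissue=tissue, grid=grid, density=density, n_samples=n)


def lookup_density(pdd: PDD4D, x: np.ndarray) -> np.ndarray | float:
    """Piecewise-constant density of the bin(s) containing x (..., 4)."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    idx = pdd.grid.bin_indices(np.atleast_2d(x))
    vals = pdd.density[idx]
    return float(vals[0]) if scalar else vals


def build_all_pdds(
    samples_by_class: Mapping[TissueClass, np.ndarray],
    bins: int = DEFAULT_BINS,
    smoothing_sigma_bins: float = 0.0,
) -> dict[TissueClass, PDD4D]:
    """Fit the shared grid, then one PDD per class (all seven required)."""
    missing = [c.name for c in CLASSES if c not in samples_by_class]
    if missing:
        raise ValueError(f"missing training samples for classes {missing}")
    grid = fit_bin_grid(samples_by_class, bins=bins)
    return {
        cls: build_pdd(samples_by_class[cls], grid, cls, smoothing_sigma_bins)
        for cls in CLASSES
    }


def save_pdds(pdds: Mapping[TissueClass, PDD4D], path: str | Path) -> None:
    """Serialise a class set of PDDs (edges + densities + metadata) to .npz."""
    first = next(iter(pdds.values()))
    arrays: dict[str, np.ndarray] = {
        f"edges_{k}": first.grid.edges[k] for k in range(4)
    }
    names, nsamp = [], []
    for cls, pdd in pdds.items():
        if pdd.grid.bins != first.grid.bins or any(
            not np.array_equal(pdd.grid.edges[k], first.grid.edges[k]) for k in range(4)
        ):
            raise ValueError("all PDDs must share one bin grid")
        arrays[f"density_{cls.name}"] = pdd.density
        names.append(cls.name)
        nsamp.append(pdd.n_samples)
    arrays["class_names"] = np.array(names)
    arrays["n_samples"] = np.array(nsamp)
    np.savez_compressed(str(path), **arrays)


def load_pdds(path: str | Path) -> dict[TissueClass, PDD4D]:
    with np.load(str(path), allow_pickle=False) as z:
        edges = tuple(z[f"edges_{k}"] for k in range(4))
        grid = BinGrid4D(edges, bins=len(edges[0]) - 1)
        out = {}
        for name, n in zip(z["class_names"], z["n_samples"]):
            cls = CLASS_BY_NAME[str(name)]
            out[cls] = PDD4D(cls, grid, z[f"density_{name}"], int(n))
    return out
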