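"""Top-level modelling interface: TissueTypeModel -> TissueTypeResults.

The model bundles a co-registered multimodal volume with the per-class 4D
intensity priors (built from labelled training samples or loaded from
disk); ``fit()`` runs Bayesian voxel classification, superpixel averaging,
automatic lesion extraction and nosologic colour rendering, returning a
results object that carries the posterior maps, the lesion segmentation,
derived volumes and a text summary.

Example
-------
>>> from gliotype import phantom, TissueTypeModel
>>> spec = phantom.PhantomSpec(seed=7)
>>> volume, truth, volumes = phantom.generate_phantom(spec)
>>> train = phantom.sample_training_set(spec, n_per_class=10_000)
>>> res = TissueTypeModel.from_training_samples(volume, train,
...                                             brain_mask=truth.labels > 0).fit()
>>> print(res.summary())                                   # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .classes import CLASSES, TissueClass
from .config import PipelineConfig
from .io_volumes import MultimodalVolume, save_volume
from .bayes import PosteriorMap, classify_volume
from .priors import PDD4D, build_all_pdds, load_pdds, save_pdds
from .superpixels import (
    LesionSegmentation,
    SuperpixelMap,
    TissueColourMap,
    average_probabilities,
    compute_superpixels,
    extract_lesion,
    highgrade_volume,
    probability_weighted_volume,
    render_colour_map,
    superpixel_table,
)


class TissueTypeModel:
    """Tissue-type mapping model for one subject.

    Parameters
    ----------
    volume
        Co-registered multimodal volume; must contain the classifier
        channels (p, q, T2n, PDn) and, for superpixel mapping, FLAIR.
    pdds
        The seven class-conditional 4D densities on one shared bin grid.
    brain_mask
        Boolean brain mask; defaults to voxels where any channel is
        non-zero.
    config
        Pipeline parameters (defaults are the canonical values).
    """

    def __init__(
        self,
        volume: MultimodalVolume,
        pdds: Mapping[TissueClass, PDD4D],
        brain_mask: np.ndarray | None = None,
        config: PipelineConfig | None = None,
    ):
        self.volume = volume
        self.pdds = dict(pdds)
        self.config = config or PipelineConfig()
        if brain_mask is None:
            stack = np.stack(list(volume.channels.values()), axis=-1)
            brain_mask = np.any(stack != 0, axis=-1)
        self.brain_mask = np.asarray(brain_mask, dtype=bool)

    @classmethod
    def from_training_samples(
        cls,
        volume: MultimodalVolume,
        samples_by_class: Mapping[TissueClass, np.ndarray],
        brain_mask: np.ndarray | None = None,
        config: PipelineConfig | None = None,
    ) -> "TissueTypeModel":
        """Build the class PDDs from labelled (p, q, T2n, PDn) samples."""
        config = config or PipelineConfig()
        pdds = build_all_pdds(
            samples_by_class,
            bins=config.bins,
            smoothing_sigma_bins=config.smoothing_sigma_bins,
        )
        return cls(volume, pdds, brain_mask=brain_mask, config=config)

    @classmethod
    def from_pdd_file(
        cls,
        volume: MultimodalVolume,
        path: str | Path,
        brain_mask: np.ndarray | None = None,
        config: PipelineConfig | None = None,
    ) -> "TissueTypeModel":
        return cls(volume, load_pdds(path), brain_mask=brain_mask, config=config)

    def fit(self) -> "TissueTypeResults":
        """Run classification, superpixel averaging, lesion extraction and
        colour rendering; deterministic given inputs and config."""
        cfg = self.config
        posterior = classify_volume(
            self.volume, self.pdds, brain_mask=self.brain_mask, prior=cfg.prior
        )
        sp_labels = compute_superpixels(
            self.volume,
            self.brain_mask,
            grid_size=cfg.slic_grid_size,
            regularisation=cfg.slic_regularisation,
            upsample_factor=cfg.upsample_factor,
        )
        spmap = average_probabilities(posterior, sp_labels)
        lesion = extract_lesion(spmap, self.volume.voxel_size, threshold=cfg.lesion_threshold)
        colour = render_colour_map(spmap, lesion)
        return TissueTypeResults(
            model=self,
            posterior=posterior,
            superpixels=spmap,
            lesion=lesion,
            colour_map=colour,
        )


@dataclass
class TissueTypeResults:
    """Fitted tissue-type map and everything derived from it."""

    model: TissueTypeModel
    posterior: PosteriorMap
    superpixels: SuperpixelMap
    lesion: LesionSegmentation
    colour_map: TissueColourMap
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def config(self) -> PipelineConfig:
        return self.model.config

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.model.volume.voxel_size

    @property
    def lesion_volume_ml(self) -> float:
        return self.lesion.lesion_volume_ml

    @property
    def highgrade_volume_ml(self) -> float:
        """Volume of lesion superpixels with p(GIV) > the high-grade threshold."""
        return highgrade_volume(
            self.superpixels, self.lesion, self.voxel_size,
            threshold=self.config.highgrade_threshold,
        )

    def class_volume_ml(self, *names: str) -> float:
        """Probability-weighted volume of the named classes over the lesion."""
        return probability_weighted_volume(
            self.superpixels, self.lesion, self.voxel_size, names
        )

    @property
    def out_of_support_fraction(self) -> float:
        m = self.posterior.brain_mask
        return float(self.posterior.out_of_support[m].mean()) if m.any() else 0.0

    def argmax_labels(self) -> np.ndarray:
        return self.posterior.argmax_labels()

    def accuracy_against(self, truth_labels: np.ndarray) -> float:
        """Voxelwise argmax accuracy against a ground-truth label volume
        (evaluated over in-mask voxels with a non-zero truth label)."""
        m = self.posterior.brain_mask & (truth_labels > 0)
        return float(np.mean(self.argmax_labels()[m] == truth_labels[m]))

    def summary(self) -> str:
        """Human-readable run summary."""
        cfg = self.config
        vol = self.model.volume
        lines = [
            "Tissue-type mapping results",
            "===========================",
            f"volume shape {vol.shape}, voxel {vol.voxel_size} mm",
            f"prior mode: {cfg.prior}; bins: {cfg.bins}; "
            f"SLIC grid {cfg.slic_grid_size}, reg {cfg.slic_regularisation}, "
            f"upsample x{cfg.upsample_factor}",
            f"superpixels: {len(self.superpixels.sp_probs)}",
            f"out-of-support voxel fraction: {self.out_of_support_fraction:.4f}",
            f"lesion components considered: {self.lesion.component_count_considered}",
            f"lesion volume: {self.lesion_volume_ml:.1f} ml",
            f"high-grade volume (p(GIV) > {cfg.highgrade_threshold:g}): "
            f"{self.highgrade_volume_ml:.1f} ml",
            "",
            "probability-weighted lesion composition (ml):",
        ]
        for c in CLASSES:
            lines.append(f"  {c.name:>4}: {self.class_volume_ml(c.name):8.1f}")
        return "\n".join(lines)

    def save(self, directory: str | Path) -> None:
        """Write posterior NIfTIs, superpixel labels + table, lesion mask,
        colour map and a JSON run record."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        vs = self.voxel_size
        self.posterior.save(directory)
        save_volume(self.superpixels.labels, vs, directory / "superpixels.nii.gz")
        save_volume(self.lesion.lesion_mask.astype(np.uint8), vs, directory / "lesion_mask.nii.gz")
        save_volume(self.colour_map.rgb, vs, directory / "colour_map.nii.gz")
        superpixel_table(self.superpixels, self.lesion).to_csv(
            directory / "superpixels.csv", index=False
        )
        save_pdds(self.model.pdds, directory / "pdds.npz")
        record = {
            "config": self.config.to_dict(),
            "lesion_volume_ml": self.lesion_volume_ml,
            "highgrade_volume_ml": self.highgrade_volume_ml,
            "out_of_support_fraction": self.out_of_support_fraction,
            "n_superpixels": len(self.superpixels.sp_probs),
        }
        with open(directory / "results.json", "w") as fh:
            json.dump(record, fh, indent=2)

    def save_overlays(self, directory: str | Path, background: str = "FLAIR") -> list[Path]:
        """Per-slice PNGs of the colour map blended onto a background channel."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        bg = self.model.volume.channels[background]
        lo, hi = np.percentile(bg[self.posterior.brain_mask], (1, 99)) if \
            self.posterior.brain_mask.any() else (0, 1)
        span = hi - lo if hi > lo else 1.0
        written = []
        for z in range(bg.shape[2]):
            base = np.clip((bg[:, :, z] - lo) / span, 0, 1)
            img = np.stack([base] * 3, axis=-1)
            rgb = self.colour_map.rgb[:, :, z]
            on = rgb.sum(axis=-1) > 0
            img[on] = 0.4 * img[on] + 0.6 * rgb[on]
            path = directory / f"overlay_z{z:03d}.png"
            plt.imsave(path, np.transpose(img, (1, 0, 2)), origin="lower")
            written.append(path)
        return written
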