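"""NIfTI volume I/O and aligned multimodal channel stacks.

All volumes are indexed (x, y, z), with z the slice axis used for per-slice
superpixel segmentation.  Inputs must be pre-co-registered onto one voxel
grid: this module validates alignment and fails loudly on any mismatch, it
never resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .classes import CLASS_BY_INDEX, TissueClass

#: Channel names recognised in a multimodal stack.
KNOWN_CHANNELS = ("p", "q", "T2n", "PDn", "FLAIR")


class AlignmentError(ValueError):
    """Raised when channel volumes do not share one voxel grid."""


@dataclass
class MultimodalVolume:
    """Aligned stack of named 3D channels on one voxel grid.

    Parameters
    ----------
    channels
        Map channel-name -> 3D float array.  Names are drawn from
        ``{p, q, T2n, PDn, FLAIR}``; p and q are diffusivities in mm²/s and
        must be non-negative.
    voxel_size
        Physical voxel dimensions (mm) along (x, y, z).
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self.channels:
            raise ValueError("at least one channel is required")
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        ref_name, ref_shape = next(iter(shapes.items()))
        for name, shp in shapes.items():
            if len(shp) != 3:
                raise AlignmentError(f"channel {name!r} is not 3D (shape {shp})")
            if shp != ref_shape:
                raise AlignmentError(
                    f"channel {name!r} has shape {shp}, expected {ref_shape} "
                    f"(channel {ref_name!r})"
                )
        for name in ("p", "q"):
            if name in self.channels and np.any(self.channels[name] < 0):
                raise ValueError(f"diffusivity channel {name!r} has negative values")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm³)."""
        return float(np.prod(self.voxel_size)) / 1000.0

    def stack(self, names: tuple[str, ...]) -> np.ndarray:
        """Stack the named channels along a trailing axis -> (x, y, z, len(names))."""
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(f"missing channels {missing}; have {sorted(self.channels)}")
        return np.stack([self.channels[n] for n in names], axis=-1)


@dataclass
class LabelVolume:
    """3D integer label volume (0 = unlabelled) with a class map.

    Every non-zero label value must have an entry in ``class_map``.
    """

    labels: np.ndarray
    class_map: dict[int, TissueClass]

    def __post_init__(self):
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        present = {int(v) for v in np.unique(self.labels)} - {0}
        missing = sorted(present - set(self.class_map))
        if missing:
            raise ValueError(f"labels {missing} have no class_map entry")

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of voxels labelled with the class called `name`."""
        idx = [k for k, c in self.class_map.items() if c.name == name]
        out = np.zeros(self.labels.shape, dtype=bool)
        for k in idx:
            out |= self.labels == k
        return out

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for k, cls in self.class_map.items():
            out[cls.name] = out.get(cls.name, 0) + int(np.count_nonzero(self.labels == k))
        return out


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise AlignmentError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms, np.asarray(img.affine)


def load_multimodal(paths: Mapping[str, str | Path]) -> MultimodalVolume:
    """Load co-registered channel NIfTIs into one :class:`MultimodalVolume`.

    Fails with :class:`AlignmentError` (naming the offending channel) on any
    shape or voxel-size mismatch; no resampling is attempted.
    """
    channels: dict[str, np.ndarray] = {}
    ref: tuple | None = None
    affine = None
    for name, path in paths.items():
        data, zooms, aff = _load_nifti(path)
        if ref is None:
            ref = (name, data.shape, zooms)
            affine = aff
        else:
            if data.shape != ref[1]:
                raise AlignmentError(
                    f"channel {name!r} shape {data.shape} != {ref[1]} of {ref[0]!r}"
                )
            if not np.allclose(zooms, ref[2], rtol=1e-4):
                raise AlignmentError(
                    f"channel {name!r} voxel size {zooms} != {ref[2]} of {ref[0]!r}"
                )
        channels[name] = np.asarray(data, dtype=np.float64)
    assert ref is not None
    return MultimodalVolume(channels, voxel_size=ref[2], affine=affine)


def load_labels(path: str | Path, class_map: Mapping[int, TissueClass] | None = None) -> LabelVolume:
    """Load an integer NIfTI label volume and validate it against `class_map`.

    With `class_map` omitted, the canonical 1..7 class indexing is assumed.
    """
    data, _, _ = _load_nifti(path)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path}: label volume contains non-integer values")
    labels = np.asarray(np.round(data), dtype=np.int32)
    cmap = dict(class_map) if class_map is not None else dict(CLASS_BY_INDEX)
    return LabelVolume(labels, cmap)


def save_volume(array: np.ndarray, voxel_size, path: str | Path, affine=None) -> None:
    """Write a 3D (or 4D) array as NIfTI with the given voxel size."""
    if affine is None:
        affine = np.diag([*(float(v) for v in voxel_size), 1.0])
    img = nib.Nifti1Image(np.asarray(array), affine)
    img.header.set_zooms(tuple(voxel_size) + (1.0,) * (array.ndim - 3))
    nib.save(img, str(path))


def save_multimodal(volume: MultimodalVolume, out_dir: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write each channel as `<prefix><name>.nii.gz`; returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in volume.channels.items():
        p = out_dir / f"{prefix}{name}.nii.gz"
        save_volume(arr, volume.voxel_size, p, affine=volume.affine)
        paths[name] = p
    return paths
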