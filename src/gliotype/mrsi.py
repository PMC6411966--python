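"""MRSI grid geometry and per-voxel tissue-fraction tables.

MRSI acquires a coarse in-plane grid of spectroscopy voxels over one thick
slab.  Spectral decomposition (performed upstream, e.g. with LCModel) turns
each spectrum into fractions of normal brain, grade II and grade IV tumour
tissue.  Here the grid is described by a simple block geometry: MRSI voxel
(i, j) covers the image-voxel block

    x in [origin_x + i·block_x, origin_x + (i+1)·block_x)
    y in [origin_y + j·block_y, origin_y + (j+1)·block_y)
    z in [z_start, z_start + n_slices)

Fractions travel as a CSV with columns (i, j, fraction_normal, fraction_GII,
fraction_GIV) and the geometry as a small JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

FRACTION_COLUMNS = ["i", "j", "fraction_normal", "fraction_GII", "fraction_GIV"]


@dataclass(frozen=True)
class MRSIGeometry:
    """Block mapping from an MRSI grid onto the image voxel grid."""

    origin: tuple[int, int]        # image-voxel (x, y) of MRSI voxel (0, 0)
    block_size: tuple[int, int]    # image voxels per MRSI voxel, in-plane
    z_start: int                   # first image slice covered by the slab
    n_slices: int                  # slab thickness in image slices
    grid_shape: tuple[int, int]    # (n_i, n_j) MRSI voxels

    def block(self, i: int, j: int) -> tuple[slice, slice, slice]:
        """Image-array slices covered by MRSI voxel (i, j)."""
        if not (0 <= i < self.grid_shape[0] and 0 <= j < self.grid_shape[1]):
            raise IndexError(f"MRSI voxel ({i}, {j}) outside grid {self.grid_shape}")
        x0 = self.origin[0] + i * self.block_size[0]
        y0 = self.origin[1] + j * self.block_size[1]
        return (
            slice(x0, x0 + self.block_size[0]),
            slice(y0, y0 + self.block_size[1]),
            slice(self.z_start, self.z_start + self.n_slices),
        )

    def validate_bounds(self, shape: tuple[int, int, int]) -> None:
        """Raise if any MRSI voxel block falls outside an image of `shape`."""
        ni, nj = self.grid_shape
        x_end = self.origin[0] + ni * self.block_size[0]
        y_end = self.origin[1] + nj * self.block_size[1]
        z_end = self.z_start + self.n_slices
        if (self.origin[0] < 0 or self.origin[1] < 0 or self.z_start < 0
                or x_end > shape[0] or y_end > shape[1] or z_end > shape[2]):
            raise ValueError(
                f"MRSI geometry block extent (({self.origin[0]},{x_end}), "
                f"({self.origin[1]},{y_end}), ({self.z_start},{z_end})) exceeds "
                f"image shape {shape}"
            )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "MRSIGeometry":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            origin=tuple(d["origin"]),
            block_size=tuple(d["block_size"]),
            z_start=int(d["z_start"]),
            n_slices=int(d["n_slices"]),
            grid_shape=tuple(d["grid_shape"]),
        )


def validate_fractions(table: pd.DataFrame, atol: float = 1e-6) -> pd.DataFrame:
    """Check column presence and per-voxel unit-sum of the fraction triple."""
    missing = [c for c in FRACTION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"fractions table missing columns {missing}")
    sums = table[FRACTION_COLUMNS[2:]].sum(axis=1)
    bad = (np.abs(sums - 1.0) > atol).to_numpy()
    if bad.any():
        k = int(np.argmax(bad))
        raise ValueError(
            f"fractions do not sum to 1 at row {k} (sum {sums.iloc[k]:.8f})"
        )
    return table


def load_fractions(path: str | Path) -> pd.DataFrame:
    return validate_fractions(pd.read_csv(path))


def save_fractions(table: pd.DataFrame, path: str | Path) -> None:
    validate_fractions(table)[FRACTION_COLUMNS].to_csv(path, index=False)
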