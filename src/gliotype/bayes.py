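"""Voxelwise Bayesian tissue classification from the 4D class PDDs.

For a feature vector X = (p, q, T2n, PDn) the posterior of tissue class C_i
is

    P(C_i | X) = P(C_i) p(X|C_i) / Σ_j P(C_j) p(X|C_j)

with the prior itself taken from the PDDs,

    P(C_i) = p(X|C_i) / Σ_j p(X|C_j),

so the posterior is proportional to the squared likelihood.  This prior
choice is deliberately data-driven and spatially uninformed; a ``flat``
prior mode (posterior ∝ likelihood) is available for sensitivity analysis.

Voxels falling in a bin where every class density is zero carry no
information; they receive the uniform posterior 1/7 and are flagged in an
explicit out-of-support mask so downstream averaging stays defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .classes import CLASSES, CLASSIFIER_CHANNELS, N_CLASSES, TissueClass
from .io_volumes import MultimodalVolume, save_volume
from .priors import PDD4D


@dataclass
class PosteriorMap:
    """Per-voxel posterior probability vectors over the 7 ordered classes."""

    probs: np.ndarray                 # (x, y, z, 7) float32
    out_of_support: np.ndarray        # (x, y, z) bool
    class_order: tuple[TissueClass, ...] = CLASSES
    brain_mask: np.ndarray | None = None
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.probs.ndim != 4 or self.probs.shape[-1] != N_CLASSES:
            raise ValueError(f"probs must be (x, y, z, {N_CLASSES})")
        if self.out_of_support.shape != self.probs.shape[:3]:
            raise ValueError("out_of_support shape mismatch")
        if self.brain_mask is None:
            self.brain_mask = self.probs.sum(axis=-1) > 0.5

    def argmax_labels(self) -> np.ndarray:
        """1-based hard labels inside the brain mask, 0 outside."""
        lab = np.argmax(self.probs, axis=-1).astype(np.int32) + 1
        lab[~self.brain_mask] = 0
        return lab

    def class_prob(self, name: str) -> np.ndarray:
        k = [i for i, c in enumerate(self.class_order) if c.name == name]
        return self.probs[..., k[0]]

    def save(self, directory: str | Path, prefix: str = "posterior") -> None:
        """Write probs as one 4D NIfTI (4th dim = class, canonical order) plus
        the out-of-support mask."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_volume(self.probs.astype(np.float32), self.voxel_size,
                    directory / f"{prefix}.nii.gz")
        save_volume(self.out_of_support.astype(np.uint8), self.voxel_size,
                    directory / f"{prefix}_out_of_support.nii.gz")


def posterior_vector(likelihoods: np.ndarray, prior: str = "paper") -> tuple[np.ndarray, bool]:
    """Posterior over the 7 classes from a 7-vector of class densities.

    With the PDD-derived prior the posterior reduces to L_i² / Σ_j L_j²;
    with ``prior="flat"`` it is L_i / Σ_j L_j.  An all-zero likelihood
    vector yields the uniform posterior and an out-of-support flag.

    Returns ``(posterior, out_of_support)``.
    """
    L = np.asarray(likelihoods, dtype=float)
    if L.shape != (N_CLASSES,):
        raise ValueError(f"expected {N_CLASSES} likelihoods, got shape {L.shape}")
    if np.any(L < 0):
        raise ValueError("likelihoods must be non-negative")
    if prior == "paper":
        w = L * L
    elif prior == "flat":
        w = L
    else:
        raise ValueError("prior must be 'paper' or 'flat'")
    s = w.sum()
    if s == 0:
        return np.full(N_CLASSES, 1.0 / N_CLASSES), True
    return w / s, False


def classify_volume(
    volume: MultimodalVolume,
    pdds: Mapping[TissueClass, PDD4D],
    brain_mask: np.ndarray | None = None,
    prior: str = "paper",
) -> PosteriorMap:
    """Posterior map for every in-mask voxel of a multimodal volume.

    Streams slice-by-slice; the result is independent of the partitioning.
    All PDDs must share one bin grid.
    """
    if prior not in ("paper", "flat"):
        raise ValueError("prior must be 'paper' or 'flat'")
    missing = [c.name for c in CLASSES if c not in pdds]
    if missing:
        raise ValueError(f"missing PDDs for classes {missing}")
    grid = pdds[CLASSES[0]].grid
    for cls in CLASSES:
        g = pdds[cls].grid
        if g.bins != grid.bins or any(
            not np.array_equal(g.edges[k], grid.edges[k]) for k in range(4)
        ):
            raise ValueError(f"PDD for {cls.name} is on a different bin grid")

    shape = volume.shape
    if brain_mask is None:
        brain_mask = np.ones(shape, dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != shape:
        raise ValueError("brain_mask shape mismatch")

    feats = volume.stack(CLASSIFIER_CHANNELS)
    probs = np.zeros(shape + (N_CLASSES,), dtype=np.float32)
    oos = np.zeros(shape, dtype=bool)

    for z in range(shape[2]):
        m = brain_mask[:, :, z]
        if not m.any():
            continue
        x = feats[:, :, z][m]                      # (n, 4)
        idx = grid.bin_indices(x)
        L = np.empty((x.shape[0], N_CLASSES))
        for i, cls in enumerate(CLASSES):
            L[:, i] = pdds[cls].density[idx]
        w = L * L if prior == "paper" else L
        s = w.sum(axis=1)
        zero = s == 0
        post = np.empty_like(w)
        np.divide(w, s[:, None], out=post, where=~zero[:, None])
        post[zero] = 1.0 / N_CLASSES
        sl = np.zeros(m.shape + (N_CLASSES,), dtype=np.float32)
        sl[m] = post
        probs[:, :, z] = sl
        oz = np.zeros(m.shape, dtype=bool)
        oz[m] = zero
        oos[:, :, z] = oz

    return PosteriorMap(
        probs=probs,
        out_of_support=oos,
        brain_mask=brain_mask,
        voxel_size=volume.voxel_size,
    )
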