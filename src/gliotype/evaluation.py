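"""Evaluation battery: MRSI-grid comparison, volume agreement, overlap metrics.

Three complementary checks of a tissue-type map:

i.   per-MRSI-voxel comparison of imaging-derived tissue fractions (grouped
     into normal / low-grade / high-grade triples) with the MRS-derived
     fractions, quantified by Székely's distance correlation between the
     two 3D spaces, after excluding the MRSI voxels used for training;
ii.  manual-vs-automatic lesion volume agreement: Pearson correlation plus
     Bland–Altman bias and 95% limits of agreement;
iii. mask overlap: Dice, Jaccard and Overlap (Szymkiewicz–Simpson)
     coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .classes import class_index
from .bayes import PosteriorMap
from .mrsi import MRSIGeometry

#: class-name groups of the 3-class comparison space
GROUPS = {
    "normal": ("GM", "WM", "CSF", "VO"),
    "low_grade": ("GII",),
    "high_grade": ("GIV", "Ne"),
}


def resample_to_mrsi(posterior: PosteriorMap, geometry: MRSIGeometry) -> np.ndarray:
    """Block-mean posterior per MRSI voxel -> array (n_i, n_j, 7)."""
    geometry.validate_bounds(posterior.probs.shape[:3])
    ni, nj = geometry.grid_shape
    out = np.zeros((ni, nj, posterior.probs.shape[-1]))
    for i in range(ni):
        for j in range(nj):
            sx, sy, sz = geometry.block(i, j)
            out[i, j] = posterior.probs[sx, sy, sz].reshape(-1, out.shape[-1]).mean(axis=0)
    return out


def group_fractions(seven: np.ndarray) -> np.ndarray:
    """Collapse 7-class probability vectors (..., 7) into renormalised
    (normal, low_grade, high_grade) triples (..., 3)."""
    seven = np.asarray(seven, dtype=float)
    triples = np.stack(
        [seven[..., [class_index(n) for n in names]].sum(axis=-1)
         for names in GROUPS.values()],
        axis=-1,
    )
    s = triples.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(s > 0, triples / s, triples)
    return out


@dataclass
class GroupedFractions:
    """Paired imaging- and MRS-derived (normal, low, high) triples per MRSI voxel."""

    imaging: np.ndarray      # (n, 3)
    mrs: np.ndarray          # (n, 3)
    train_flag: np.ndarray   # (n,) bool — voxels used to build the tumour PDDs

    def __post_init__(self):
        self.imaging = np.atleast_2d(np.asarray(self.imaging, dtype=float))
        self.mrs = np.atleast_2d(np.asarray(self.mrs, dtype=float))
        self.train_flag = np.asarray(self.train_flag, dtype=bool)
        if self.imaging.shape != self.mrs.shape or self.imaging.shape[1] != 3:
            raise ValueError("imaging and mrs must be matching (n, 3) arrays")
        if self.train_flag.shape[0] != self.imaging.shape[0]:
            raise ValueError("train_flag length mismatch")
        for name, arr in (("imaging", self.imaging), ("mrs", self.mrs)):
            if np.any(np.abs(arr.sum(axis=1) - 1.0) > 1e-3):
                raise ValueError(f"{name} triples must sum to 1 (±1e-3)")

    def held_out(self) -> tuple[np.ndarray, np.ndarray]:
        """The voxel pairs with training voxels removed."""
        keep = ~self.train_flag
        return self.imaging[keep], self.mrs[keep]


def paired_mrsi_fractions(
    posterior: PosteriorMap,
    geometry: MRSIGeometry,
    table: pd.DataFrame,
    train_flag: np.ndarray | None = None,
    min_mass: float = 0.5,
) -> GroupedFractions:
    """Pair imaging-derived with MRS-derived 3-class fractions per MRSI voxel.

    The posterior is block-averaged onto the MRSI grid and collapsed into
    (normal, low-grade, high-grade) triples.  MRSI voxels whose image block
    carries less than ``min_mass`` posterior mass (i.e. lies mostly outside
    the brain mask) are excluded, mirroring the restriction to spectroscopy
    voxels with adequate brain coverage.
    """
    seven = resample_to_mrsi(posterior, geometry)
    ii = table["i"].to_numpy(dtype=int)
    jj = table["j"].to_numpy(dtype=int)
    raw = seven[ii, jj]
    keep = raw.sum(axis=1) >= min_mass
    imaging = group_fractions(raw[keep])
    mrs = table[["fraction_normal", "fraction_GII", "fraction_GIV"]].to_numpy()[keep]
    if train_flag is None:
        train_flag = np.zeros(len(table), dtype=bool)
    return GroupedFractions(imaging, mrs, np.asarray(train_flag, dtype=bool)[keep])


def distance_correlation(xs: np.ndarray, ys: np.ndarray) -> float:
    """Székely's (biased) sample distance correlation between two samples.

    Both inputs are (n, d) matrices of paired observations.  Computed from
    double-centred Euclidean distance matrices; symmetric in its arguments,
    invariant under affine maps of either side, in [0, 1].
    """
    xs = np.atleast_2d(np.asarray(xs, dtype=float))
    ys = np.atleast_2d(np.asarray(ys, dtype=float))
    if xs.ndim == 2 and xs.shape[0] == 1:
        xs, ys = xs.T, ys.T
    if xs.shape[0] != ys.shape[0]:
        raise ValueError("xs and ys must have the same number of rows")
    n = xs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    a = cdist(xs, xs)
    b = cdist(ys, ys)
    if a.max() == 0 or b.max() == 0:
        raise ValueError("constant input: distance correlation undefined")
    A = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    B = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    dcov2 = float((A * B).mean())
    dvar_x = float((A * A).mean())
    dvar_y = float((B * B).mean())
    denom = np.sqrt(dvar_x * dvar_y)
    if denom == 0:
        raise ValueError("zero distance variance: distance correlation undefined")
    return float(np.sqrt(max(dcov2, 0.0) / denom))


def overlap_metrics(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """(Dice, Jaccard, Overlap) between two boolean masks of equal shape."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise ValueError("both masks empty: overlap undefined")
    inter = int(np.count_nonzero(a & b))
    union = na + nb - inter
    dice = 2.0 * inter / (na + nb)
    jaccard = inter / union if union else 0.0
    overlap = inter / min(na, nb) if min(na, nb) else 0.0
    return dice, jaccard, overlap


@dataclass
class VolumeAgreement:
    pearson_r: float
    p_value: float
    mean_diff: float
    loa_low: float
    loa_high: float


def volume_agreement(manual_ml: np.ndarray, auto_ml: np.ndarray) -> VolumeAgreement:
    """Pearson correlation (two-sided) plus Bland–Altman bias and 95% limits.

    The Bland–Altman difference is automatic − manual, so a positive bias
    means automatic segmentation yields larger volumes.
    """
    manual = np.asarray(manual_ml, dtype=float)
    auto = np.asarray(auto_ml, dtype=float)
    if manual.shape != auto.shape or manual.ndim != 1 or manual.size < 3:
        raise ValueError("need two equal-length 1D vectors with n >= 3")
    if manual.std() == 0 or auto.std() == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    r, p = stats.pearsonr(manual, auto)
    diff = auto - manual
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return VolumeAgreement(
        pearson_r=float(r),
        p_value=float(p),
        mean_diff=mean_diff,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
    )


def evaluation_report(
    grouped: GroupedFractions | None = None,
    manual_ml: np.ndarray | None = None,
    auto_ml: np.ndarray | None = None,
    mask_pairs: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> dict:
    """Assemble the metric battery into one JSON-serialisable dict."""
    report: dict = {}
    if grouped is not None:
        report["dcor_all"] = distance_correlation(grouped.imaging, grouped.mrs)
        im, mr = grouped.held_out()
        if im.shape[0] >= 2:
            report["dcor_excl_training"] = distance_correlation(im, mr)
        report["n_mrsi_voxels"] = int(grouped.imaging.shape[0])
        report["n_training_excluded"] = int(grouped.train_flag.sum())
    if manual_ml is not None and auto_ml is not None:
        va = volume_agreement(manual_ml, auto_ml)
        report["volume_agreement"] = {
            "pearson_r": va.pearson_r, "p_value": va.p_value,
            "mean_diff_ml": va.mean_diff,
            "loa_ml": [va.loa_low, va.loa_high],
        }
    if mask_pairs:
        rows = [overlap_metrics(a, b) for a, b in mask_pairs]
        arr = np.array(rows)
        report["overlap"] = {
            "dice_mean": float(arr[:, 0].mean()), "dice_sd": float(arr[:, 0].std(ddof=0)),
            "jaccard_mean": float(arr[:, 1].mean()), "jaccard_sd": float(arr[:, 1].std(ddof=0)),
            "overlap_mean": float(arr[:, 2].mean()), "overlap_sd": float(arr[:, 2].std(ddof=0)),
            "per_case": [list(map(float, r)) for r in rows],
        }
    return report
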