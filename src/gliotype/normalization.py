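"""Histogram-matching intensity normalisation for T2w and PDw volumes.

T2w and PDw intensities are only semi-quantitative: scanner gain puts each
acquisition on its own arbitrary scale.  To make intensities comparable
across subjects, each volume's within-brain intensity histogram is
translated and scaled (I -> a·I + b, a > 0) to minimise the L2 norm of the
difference to a fixed cohort reference histogram.  Both histograms are
compared as unit-sum vectors on the reference bin edges.

The reference is an explicit artifact (built once from a chosen subject and
saved to disk) so that normalisation is reproducible.  The objective is
piecewise constant in (a, b) because of binning, so the optimiser is a
moment-matched initial guess followed by an iteratively shrinking grid
search rather than a gradient method.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Default number of histogram bins for normalisation.
DEFAULT_BINS = 256
#: Percentile span of the reference intensities covered by the bin range.
REF_PCT_RANGE = (0.1, 99.9)


@dataclass
class ReferenceHistogram:
    """A fixed intensity histogram against which volumes are normalised."""

    bin_edges: np.ndarray
    counts: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != self.bin_edges.shape[0] - 1:
            raise ValueError("counts length must be len(bin_edges) - 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def density(self) -> np.ndarray:
        """Counts normalised to unit sum."""
        total = self.counts.sum()
        if total <= 0:
            raise ValueError("reference histogram is empty")
        return self.counts / total

    def moments(self) -> tuple[float, float]:
        """Mean and standard deviation of the binned reference distribution."""
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        w = self.density
        mean = float(np.sum(w * centers))
        var = float(np.sum(w * (centers - mean) ** 2))
        return mean, np.sqrt(max(var, 0.0))

    def save(self, path: str | Path) -> None:
        """Write as a two-column (edge, count) tab-delimited text file.

        The file has ``bins + 1`` rows; the count column of the final edge
        row is empty.
        """
        with open(path, "w") as fh:
            fh.write(f"# reference histogram: {self.source_id}\n")
            for i, edge in enumerate(self.bin_edges):
                c = f"{self.counts[i]:.10g}" if i < len(self.counts) else ""
                fh.write(f"{edge:.10g}\t{c}\n")

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceHistogram":
        edges, counts = [], []
        source = ""
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    source = line.lstrip("# ").partition(":")[2].strip()
                    continue
                parts = line.split("\t")
                edges.append(float(parts[0]))
                if len(parts) > 1 and parts[1]:
                    counts.append(float(parts[1]))
        return cls(np.array(edges), np.array(counts), source_id=source)


def _masked(volume: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    values = np.asarray(volume, dtype=float)
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool)]
    else:
        values = values.ravel()
    if values.size == 0:
        raise ValueError("empty mask: no voxels to normalise")
    return values


def build_reference_histogram(
    volume: np.ndarray,
    mask: np.ndarray | None = None,
    bins: int = DEFAULT_BINS,
    source_id: str = "",
) -> ReferenceHistogram:
    """Build the cohort reference from one (skull-stripped) volume.

    Bins span the 0.1–99.9 percentile range of the masked intensities.
    """
    values = _masked(volume, mask)
    lo, hi = np.percentile(values, REF_PCT_RANGE)
    if hi <= lo:
        raise ValueError("degenerate intensities: percentile range is empty")
    edges = np.linspace(lo, hi, bins + 1)
    counts = _clipped_histogram(values, edges)
    return ReferenceHistogram(edges, counts, source_id=source_id)


def _clipped_histogram(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Histogram with out-of-range values clipped into the end bins."""
    idx = np.searchsorted(edges, values, side="right") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    return np.bincount(idx, minlength=len(edges) - 1).astype(float)


def _objective(values: np.ndarray, ref_density: np.ndarray, edges: np.ndarray,
               a: float, b: float) -> float:
    h = _clipped_histogram(a * values + b, edges)
    h /= h.sum()
    return float(np.linalg.norm(h - ref_density))


def fit_affine_intensity_map(
    volume: np.ndarray,
    ref: ReferenceHistogram,
    mask: np.ndarray | None = None,
    grid_points: int = 21,
    levels: int = 6,
) -> tuple[float, float, float]:
    """Fit I -> a·I + b (a > 0) minimising the histogram L2 distance to `ref`.

    Returns ``(scale, shift, residual_l2)`` where residual_l2 is the L2 norm
    between the unit-sum histogram of the mapped intensities (on the
    reference bin edges, out-of-range values clipped into end bins) and the
    unit-sum reference histogram.

    The search starts from the moment-matching guess
    ``a0 = sd_ref / sd_vol, b0 = mean_ref − a0·mean_vol`` and refines it with
    `levels` rounds of a `grid_points`² grid search whose span shrinks by
    ×0.25 each round.
    """
    values = _masked(volume, mask)
    sd_vol = float(values.std())
    if sd_vol == 0:
        raise ValueError("degenerate (constant) intensities in mask")
    ref_density = ref.density
    edges = ref.bin_edges
    mean_ref, sd_ref = ref.moments()
    if sd_ref == 0:
        raise ValueError("degenerate reference histogram")

    a0 = sd_ref / sd_vol
    b0 = mean_ref - a0 * float(values.mean())
    span_a = 0.5 * a0
    span_b = 0.25 * (edges[-1] - edges[0])

    best = (a0, b0, _objective(values, ref_density, edges, a0, b0))
    for _ in range(levels):
        a_grid = np.linspace(best[0] - span_a, best[0] + span_a, grid_points)
        a_grid = a_grid[a_grid > 0]
        b_grid = np.linspace(best[1] - span_b, best[1] + span_b, grid_points)
        for a in a_grid:
            mapped = a * values
            for b in b_grid:
                r = _objective(mapped, ref_density, edges, 1.0, b)
                if r < best[2]:
                    best = (float(a), float(b), r)
        span_a *= 0.25
        span_b *= 0.25
    return best


def apply_intensity_map(volume: np.ndarray, scale: float, shift: float) -> np.ndarray:
    """Apply I -> scale·I + shift elementwise."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return scale * np.asarray(volume, dtype=float) + shift


def normalize_volume(
    volume: np.ndarray,
    ref: ReferenceHistogram,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float, float]:
    """Fit and apply the affine intensity map; returns (normalised, a, b, residual)."""
    a, b, r = fit_affine_intensity_map(volume, ref, mask=mask)
    return apply_intensity_map(volume, a, b), a, b, r
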