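"""Sliding-window functional connectivity density (FCD) and its variability.

FCD of a voxel in a time window is the number of other masked voxels whose
Pearson correlation with it over that window exceeds a threshold (strict
``r > r_threshold``; only positive correlations count by default, since
global-signal regression makes negative correlations hard to interpret).
The dynamic-FCD (dFCD) variability map is the per-voxel standard deviation
of FCD across windows, optionally z-normalised over the mask.

The voxel×voxel correlation is evaluated blockwise (memory stays O(block ×
n_voxels)) but is numerically identical to the naive double loop: each
voxel's windowed series is centred and scaled to unit norm once, so every
pairwise r is the same inner product either way.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .imaging_io import AtlasParcellation, BoldSeries, check_alignment

_BLOCK = 2048


@dataclasses.dataclass(frozen=True)
class FCDParams:
    """Sliding-window parameters.

    window_width and step are in TRs; r_threshold is the correlation cutoff
    (connectivity requires r strictly greater). With positive_only=False,
    |r| > r_threshold counts. weighted=True sums suprathreshold r values
    instead of counting them (non-default variant).
    """

    window_width: int = 50
    step: int = 10
    r_threshold: float = 0.2
    positive_only: bool = True
    normalize: bool = True
    weighted: bool = False
    ddof: int = 1  # sample SD across windows

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window_width):
            raise ValueError("need 0 < step <= window_width")
        if not (0 <= self.r_threshold < 1):
            raise ValueError("need 0 <= r_threshold < 1")


@dataclasses.dataclass
class DFCDMap:
    """Per-voxel SD of windowed FCD, restricted to a mask."""

    values: np.ndarray          # (n_masked_voxels,)
    mask: np.ndarray            # 3D boolean
    affine: np.ndarray
    n_windows: int
    normalized: bool
    subject_id: str = ""

    def to_volume(self, background: float = 0.0) -> np.ndarray:
        vol = np.full(self.mask.shape, background, dtype=np.float64)
        vol[self.mask] = self.values
        return vol


def sliding_windows(n_timepoints: int, params: FCDParams) -> list[tuple[int, int]]:
    """Ordered [start, end) windows; a trailing partial window is dropped."""
    width, step = params.window_width, params.step
    if n_timepoints < width:
        raise ValueError(
            f"series length {n_timepoints} shorter than window width {width}"
        )
    n = (n_timepoints - width) // step + 1
    return [(i * step, i * step + width) for i in range(n)]


def analysis_mask(bold: BoldSeries, atlas: AtlasParcellation) -> np.ndarray:
    """Atlas-nonzero voxels with nonzero temporal variance over the series."""
    check_alignment(bold, atlas)
    variance = bold.data.var(axis=3)
    return (atlas.labels != 0) & (variance > 0)


def _unit_rows(window_data: np.ndarray) -> np.ndarray:
    """Centre each row and scale to unit norm; zero-variance rows become 0."""
    centred = window_data - window_data.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", centred, centred))
    out = np.zeros_like(centred)
    nz = norms > 0
    out[nz] = centred[nz] / norms[nz, None]
    return out


def window_fcd(series: np.ndarray, window: tuple[int, int],
               params: FCDParams) -> np.ndarray:
    """FCD map for one window over a (n_voxels, T) series matrix.

    degree(v) = #{u != v : r(v, u) > r_threshold} (strict). Voxels with zero
    variance in the window have r defined as 0 with everything, hence degree 0.
    Returns integer counts, or float sums of suprathreshold r if weighted.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 2 or series.shape[0] < 2:
        raise ValueError("need a 2D (n_voxels >= 2, T) series matrix")
    start, end = window
    if not (0 <= start < end <= series.shape[1]):
        raise ValueError(f"window {window} outside series of length {series.shape[1]}")
    unit = _unit_rows(series[:, start:end])
    if not unit.any():
        warnings.warn("all-constant window: FCD map is all zero", stacklevel=2)
    n = unit.shape[0]
    degree = np.zeros(n, dtype=np.float64 if params.weighted else np.int64)
    for lo in range(0, n, _BLOCK):
        hi = min(lo + _BLOCK, n)
        r_block = unit[lo:hi] @ unit.T
        # remove self-correlation from each row of the block
        r_block[np.arange(hi - lo), np.arange(lo, hi)] = 0.0
        above = r_block > params.r_threshold
        if not params.positive_only:
            above |= r_block < -params.r_threshold
        if params.weighted:
            degree[lo:hi] = np.where(above, np.abs(r_block), 0.0).sum(axis=1)
        else:
            degree[lo:hi] = above.sum(axis=1)
    return degree


def fcd_window_maps(series: np.ndarray, params: FCDParams) -> np.ndarray:
    """Stack of FCD maps, shape (n_windows, n_voxels)."""
    windows = sliding_windows(series.shape[1], params)
    return np.stack([window_fcd(series, w, params) for w in windows])


def dfcd_variability(bold: BoldSeries, atlas: AtlasParcellation,
                     params: FCDParams = FCDParams()) -> DFCDMap:
    """Per-voxel SD of FCD across sliding windows for one subject.

    With normalize=True the SD map is z-scored across the mask (mean 0, SD 1)
    before group statistics; raw-SD mode keeps the native scale.
    """
    mask = analysis_mask(bold, atlas)
    if mask.sum() < 2:
        raise ValueError("analysis mask has fewer than 2 voxels")
    series = bold.data[mask]
    windows = sliding_windows(series.shape[1], params)
    if len(windows) < 2:
        raise ValueError(
            "at least 2 windows required for an SD across windows "
            f"(got {len(windows)}; series length {series.shape[1]}, "
            f"width {params.window_width}, step {params.step})"
        )
    maps = fcd_window_maps(series, params)
    sd = maps.std(axis=0, ddof=params.ddof)
    if params.normalize:
        scale = sd.std(ddof=1)
        if scale == 0:
            raise ValueError("dFCD map is constant; cannot z-normalise")
        sd = (sd - sd.mean()) / scale
    return DFCDMap(values=sd, mask=mask, affine=bold.affine,
                   n_windows=len(windows), normalized=params.normalize,
                   subject_id=bold.subject_id)
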