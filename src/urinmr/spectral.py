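"""Spectral post-processing: referencing, alignment, binning, integration.

Turns a set of 1D spectra into an aligned, binned, region-filtered
feature matrix.  Steps: translate each ppm axis so the reference (TSP)
apex sits at 0.00; pick the most representative spectrum as alignment
reference; recursive segment-wise peak alignment (integer-gridpoint
cross-correlation shifts, recursively refined on sub-segments split at
reference troughs); dynamic adaptive binning of the mean spectrum
(boundaries at smoothed local minima, narrow bins merged, sub-noise
runs collapsed); exclusion of the water/urea regions; trapezoidal bin
integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FeatureMatrix, Spectrum

logger = logging.getLogger(__name__)

#: default excluded ppm regions (standard urine-NMR practice)
DEFAULT_EXCLUDED_REGIONS = [(4.70, 5.00), (5.40, 6.00)]


@dataclass
class AlignmentParams:
    max_shift: float = 0.02  # ppm
    min_segment_points: int = 32
    recursion_depth: int = 6
    correlation_floor: float = 0.1

    def __post_init__(self) -> None:
        if self.max_shift <= 0:
            raise ValueError("max_shift must be > 0")
        if self.min_segment_points < 8:
            raise ValueError("min_segment_points must be >= 8")


@dataclass
class BinDefinition:
    left: float  # ppm, left > right
    right: float
    center: float
    excluded: bool = False
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.left > self.right:
            raise ValueError("bin needs left > right (descending ppm)")
        if not (self.right < self.center < self.left):
            raise ValueError("bin center must lie inside (right, left)")


def bins_to_frame(bins: Sequence[BinDefinition]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"left": b.left, "right": b.right, "center": b.center,
             "excluded": b.excluded, "label": b.label}
            for b in bins
        ],
        columns=["left", "right", "center", "excluded", "label"],
    )


# ---------------------------------------------------------------------------
# referencing

def reference_to_tsp(
    spectrum: Spectrum, search_window: tuple[float, float] = (-0.2, 0.2)
) -> Spectrum:
    """Translate the ppm axis so the tallest peak in the window sits at 0.00 ppm."""
    lo, hi = min(search_window), max(search_window)
    mask = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    if not mask.any():
        raise ValueError(f"search window {search_window} contains no points")
    idx = np.flatnonzero(mask)[np.argmax(spectrum.intensity[mask])]
    shift = spectrum.ppm[idx]
    if shift == 0.0:
        return spectrum
    return Spectrum(ppm=spectrum.ppm - shift, intensity=spectrum.intensity.copy())


def interpolate_to_grid(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation onto a common descending ppm grid (edge-padded)."""
    # np.interp needs ascending x
    y = np.interp(grid[::-1], spectrum.ppm[::-1], spectrum.intensity[::-1])[::-1]
    return Spectrum(ppm=grid.copy(), intensity=y)


# ---------------------------------------------------------------------------
# reference spectrum choice and alignment

def _check_common_grid(spectra: Sequence[Spectrum]) -> np.ndarray:
    grid = spectra[0].ppm
    for s in spectra[1:]:
        if len(s) != len(grid) or not np.allclose(s.ppm, grid):
            raise ValueError("spectra are not on a common ppm grid")
    return grid


def select_reference_spectrum(spectra: Sequence[Spectrum]) -> int:
    """Index of the spectrum maximizing mean Pearson correlation to the others.

    Ties resolve to the lowest index.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra")
    _check_common_grid(spectra)
    mat = np.vstack([s.intensity for s in spectra])
    corr = np.corrcoef(mat)
    np.fill_diagonal(corr, np.nan)
    mean_corr = np.nanmean(corr, axis=1)
    best = np.max(mean_corr)
    return int(np.flatnonzero(mean_corr >= best - 1e-12)[0])


def _best_lag(ref_seg: np.ndarray, seg: np.ndarray, max_lag: int) -> tuple[int, float]:
    """Integer lag in [-max_lag, max_lag] maximizing Pearson correlation of the
    overlapping parts; ties resolve to the smallest |lag| (then negative first)."""
    best_lag, best_corr = 0, -np.inf
    n = len(seg)
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l)):
        if lag >= 0:
            a, b = ref_seg[lag:], seg[: n - lag]
        else:
            a, b = ref_seg[:lag], seg[-lag:]
        if len(a) < 4:
            continue
        sa, sb = np.std(a), np.std(b)
        if sa == 0 or sb == 0:
            continue
        c = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
        if c > best_corr + 1e-12:
            best_lag, best_corr = lag, c
    return best_lag, best_corr


def _shift_segment(seg: np.ndarray, lag: int) -> np.ndarray:
    """Translate right by ``lag`` gridpoints (left if negative), padding with
    the segment's edge values.

    ``_best_lag`` matches seg[i] to ref[i + lag], so applying a
    positive lag moves the segment's features to higher indices.
    """
    if lag == 0:
        return seg
    out = np.empty_like(seg)
    if lag > 0:
        out[lag:] = seg[:-lag]
        out[:lag] = seg[0]
    else:
        out[:lag] = seg[-lag:]
        out[lag:] = seg[-1]
    return out


def _align_recursive(
    work: np.ndarray,
    ref: np.ndarray,
    lo: int,
    hi: int,
    depth: int,
    params: AlignmentParams,
    max_lag: int,
) -> None:
    n = hi - lo
    if n < params.min_segment_points:
        return
    lag, corr = _best_lag(ref[lo:hi], work[lo:hi], min(max_lag, n - 4))
    if corr >= params.correlation_floor and lag != 0:
        work[lo:hi] = _shift_segment(work[lo:hi], lag)
    if depth >= params.recursion_depth or n < 2 * params.min_segment_points:
        return
    # split at the lowest-intensity trough of the reference near the midpoint
    third = max(n // 6, 1)
    mid_lo, mid_hi = lo + n // 2 - third, lo + n // 2 + third
    split = mid_lo + int(np.argmin(ref[mid_lo:mid_hi]))
    if split - lo < params.min_segment_points or hi - split < params.min_segment_points:
        return
    _align_recursive(work, ref, lo, split, depth + 1, params, max_lag)
    _align_recursive(work, ref, split, hi, depth + 1, params, max_lag)


def align_rspa(
    spectra: Sequence[Spectrum],
    reference_index: int,
    params: AlignmentParams | None = None,
) -> list[Spectrum]:
    """Recursive segment-wise peak alignment against the chosen reference.

    Each spectrum is shifted region-by-region by the best integer-lag
    cross-correlation shift within ``max_shift``, then the region is
    split at a reference trough near its midpoint and each half refined
    recursively.  Segments that correlate with the reference below
    ``correlation_floor`` are left untouched.  Shifts pad with the
    local segment-edge value, so total intensity is preserved up to the
    padding contribution.
    """
    params = params or AlignmentParams()
    grid = _check_common_grid(spectra)
    if not 0 <= reference_index < len(spectra):
        raise ValueError("reference index out of range")
    step = abs(float(np.mean(np.diff(grid))))
    max_lag = max(1, int(round(params.max_shift / step)))
    ref = spectra[reference_index].intensity
    out = []
    for i, s in enumerate(spectra):
        if i == reference_index:
            out.append(Spectrum(ppm=grid.copy(), intensity=s.intensity.copy()))
            continue
        work = s.intensity.copy()
        _align_recursive(work, ref, 0, len(work), 0, params, max_lag)
        out.append(Spectrum(ppm=grid.copy(), intensity=work))
    return out


# ---------------------------------------------------------------------------
# binning

def mean_spectrum(spectra: Sequence[Spectrum]) -> Spectrum:
    grid = _check_common_grid(spectra)
    return Spectrum(ppm=grid.copy(),
                    intensity=np.mean([s.intensity for s in spectra], axis=0))


def dynamic_adaptive_bins(
    mean_spec: Spectrum,
    min_bin_width: float = 0.01,
    noise_floor: float = 0.0,
    smoothing_points: int = 5,
) -> list[BinDefinition]:
    """Bin boundaries at local minima of the smoothed mean spectrum.

    Adjacent bins are merged (removing the shallower of the two
    boundaries first) until every bin is at least ``min_bin_width``
    wide; maximal runs of bins whose smoothed maximum stays below
    ``noise_floor`` collapse into single noise bins.  The returned bins
    partition the window exactly.  Bin centers sit at the apex of the
    mean spectrum within each bin.
    """
    ppm, y = mean_spec.ppm, mean_spec.intensity
    if len(ppm) == 0:
        raise ValueError("empty spectrum")
    if min_bin_width >= ppm[0] - ppm[-1]:
        raise ValueError("min_bin_width larger than the spectral window")
    if smoothing_points > 1:
        kernel = np.ones(smoothing_points) / smoothing_points
        smooth = np.convolve(y, kernel, mode="same")
    else:
        smooth = y.copy()

    interior = np.flatnonzero(
        (smooth[1:-1] <= smooth[:-2]) & (smooth[1:-1] < smooth[2:])
    ) + 1
    boundaries = [0, *interior.tolist(), len(ppm) - 1]
    boundaries = sorted(set(boundaries))

    # merge narrow bins: drop the boundary with the higher smoothed intensity
    def width(i: int) -> float:
        return ppm[boundaries[i]] - ppm[boundaries[i + 1]]

    changed = True
    while changed and len(boundaries) > 2:
        changed = False
        for i in range(len(boundaries) - 1):
            if width(i) < min_bin_width:
                if i == 0:
                    drop = 1
                elif i == len(boundaries) - 2:
                    drop = len(boundaries) - 2
                else:
                    drop = i if smooth[boundaries[i]] >= smooth[boundaries[i + 1]] else i + 1
                    drop = max(1, min(drop, len(boundaries) - 2))
                del boundaries[drop]
                changed = True
                break

    # collapse maximal runs of sub-noise bins into single bins
    if noise_floor > 0 and len(boundaries) > 2:
        is_noise = [
            bool(np.max(smooth[boundaries[i]: boundaries[i + 1] + 1]) < noise_floor)
            for i in range(len(boundaries) - 1)
        ]
        keep = [boundaries[0]]
        for i in range(1, len(boundaries) - 1):
            if is_noise[i - 1] and is_noise[i]:
                continue
            keep.append(boundaries[i])
        keep.append(boundaries[-1])
        boundaries = keep

    bins = []
    for i in range(len(boundaries) - 1):
        a, b = boundaries[i], boundaries[i + 1]
        apex = a + int(np.argmax(y[a: b + 1]))
        center = float(ppm[apex])
        left, right = float(ppm[a]), float(ppm[b])
        if not (right < center < left):  # apex on a boundary -> midpoint
            center = (left + right) / 2.0
        bins.append(BinDefinition(left=left, right=right, center=center))
    logger.info("dynamic binning produced %d bins", len(bins))
    return bins


def exclude_regions(
    bins: Sequence[BinDefinition],
    regions: Sequence[tuple[float, float]] = DEFAULT_EXCLUDED_REGIONS,
) -> list[BinDefinition]:
    """Mark any bin overlapping any ppm region as excluded (manifest retained)."""
    out = []
    n_excluded = 0
    for b in bins:
        excluded = b.excluded
        for r in regions:
            lo, hi = min(r), max(r)
            if b.right < hi and b.left > lo:
                excluded = True
        n_excluded += excluded and not b.excluded
        out.append(BinDefinition(left=b.left, right=b.right, center=b.center,
                                 excluded=excluded, label=b.label))
    logger.info("excluded %d bins overlapping %d regions", n_excluded, len(regions))
    return out


def integrate_bins(
    spectra: dict[str, Spectrum] | Sequence[Spectrum],
    bins: Sequence[BinDefinition],
) -> FeatureMatrix:
    """Trapezoidal integral of each spectrum over each non-excluded bin.

    Negative integrals (possible after baseline work) are floored at 0
    with a logged count.  Bin edges snap to the closest grid points, so
    the sum of bin integrals over a full partition equals the
    whole-window integral exactly.
    """
    if isinstance(spectra, dict):
        ids = list(spectra.keys())
        specs = list(spectra.values())
    else:
        specs = list(spectra)
        ids = [f"sample_{i}" for i in range(len(specs))]
    grid = _check_common_grid(specs)
    active = [b for b in bins if not b.excluded]
    if not active:
        raise ValueError("no non-excluded bins to integrate")
    asc = grid[::-1]
    n_floored = 0
    values = np.zeros((len(specs), len(active)))
    for j, b in enumerate(active):
        i_left = len(grid) - 1 - int(np.searchsorted(asc, b.left, side="left"))
        i_right = len(grid) - 1 - int(np.searchsorted(asc, b.right, side="left"))
        i_left = max(0, min(i_left, len(grid) - 2))
        i_right = max(i_left + 1, min(i_right, len(grid) - 1))
        x = grid[i_left: i_right + 1]
        for i, s in enumerate(specs):
            v = -np.trapezoid(s.intensity[i_left: i_right + 1], x)  # descending x
            if v < 0:
                n_floored += 1
                v = 0.0
            values[i, j] = v
    if n_floored:
        logger.info("floored %d negative bin integrals at 0", n_floored)
    manifest = bins_to_frame(bins)
    active_idx = manifest.index[~manifest["excluded"]]
    vals = pd.DataFrame(values, index=pd.Index(ids, name="sample_id"), columns=active_idx)
    return FeatureMatrix(values=vals, bins=manifest)
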