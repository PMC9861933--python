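"""Noise estimation, S/N >= 5 peak picking and peak-cluster extraction.

Peaks are picked on the total mean spectrum of the processed data set.
Local noise is a sliding-window median absolute deviation (scaled by
1.4826 to be consistent with a Gaussian SD); a local maximum is a peak if
its apex intensity divided by the local noise reaches the S/N threshold
and it is separated from any taller accepted peak by at least one FWHM.
Each mean-spectrum peak defines a cluster window within which per-sample
intensities are read (windowed maximum by default, trapezoid area
optionally) to form the samples x clusters feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import argrelmin, find_peaks

from .preprocess import Spectrum, SpectraSet

#: Relative noise floor (fraction of max intensity) guarding S/N division.
NOISE_FLOOR_FRAC = 1e-12

#: Consistency factor turning a median absolute deviation into a Gaussian SD.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class Peak:
    """A picked peak on the total mean spectrum."""

    mz: float  # parabolically refined apex position, Da
    index: int  # apex grid index
    intensity: float
    snr: float
    left_mz: float
    right_mz: float
    fwhm: float

    def __post_init__(self) -> None:
        if not (self.left_mz <= self.mz <= self.right_mz):
            raise ValueError("integration bounds must bracket the apex")


@dataclass(frozen=True)
class PeakCluster:
    """An m/z window centred on a mean-spectrum peak."""

    center: float
    low: float
    high: float


@dataclass
class PeakClusterMatrix:
    """Samples x peak-clusters intensity matrix with class labels."""

    intensities: pd.DataFrame  # index: sample ids, columns: cluster centers
    clusters: list[PeakCluster]
    labels: pd.Series  # per-sample class label

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("cluster intensities must be >= 0")

    @property
    def centers(self) -> np.ndarray:
        return np.array([c.center for c in self.clusters])


def estimate_noise(spectrum: Spectrum, window_da: float = 250.0) -> np.ndarray:
    """Per-point noise SD: sliding-window MAD x 1.4826.

    The window must cover at least 31 grid points.
    """
    size = int(round(window_da / spectrum.step_da))
    if size % 2 == 0:
        size += 1
    if size < 31:
        raise ValueError(
            f"noise window of {window_da} Da covers only {size} points (< 31)"
        )
    intensity = spectrum.intensity
    med = median_filter(intensity, size=size, mode="nearest")
    mad = median_filter(np.abs(intensity - med), size=size, mode="nearest")
    return MAD_SCALE * mad


def estimate_background(spectrum: Spectrum, window_da: float = 250.0) -> np.ndarray:
    """Sliding-window median: the residual noise pedestal under the peaks.

    Top-hat subtraction leaves noisy spectra sitting on a small positive
    pedestal (noise minus its lower envelope); the local median estimates
    it so that S/N can rate apexes by their height *above* local background.
    """
    size = int(round(window_da / spectrum.step_da))
    if size % 2 == 0:
        size += 1
    if size < 31:
        raise ValueError(
            f"background window of {window_da} Da covers only {size} points (< 31)"
        )
    return median_filter(spectrum.intensity, size=size, mode="nearest")


def _half_crossing(y: np.ndarray, i: int, half: float, step: float,
                   direction: int) -> float:
    """Distance (Da) from apex ``i`` to the half-maximum crossing."""
    j = i
    while 0 < j < y.size - 1 and y[j + direction] < y[j] and y[j + direction] > half:
        j += direction
    nxt = j + direction
    if nxt < 0 or nxt >= y.size or y[nxt] >= y[j]:
        return abs(j - i) * step
    # linear interpolation between the last point above half and the first below
    frac = (y[j] - half) / (y[j] - y[nxt]) if y[j] > y[nxt] else 0.0
    return (abs(j - i) + frac) * step


def measure_fwhm(spectrum: Spectrum, i: int) -> float:
    """Full width at half maximum of the peak with apex at grid index ``i``."""
    y = spectrum.intensity
    half = y[i] / 2.0
    step = spectrum.step_da
    left = _half_crossing(y, i, half, step, -1)
    right = _half_crossing(y, i, half, step, +1)
    return max(left + right, step)


def _refine_apex(spectrum: Spectrum, i: int) -> float:
    y = spectrum.intensity
    if i == 0 or i == y.size - 1:
        return float(spectrum.mz[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom >= 0:
        return float(spectrum.mz[i])
    shift = float(np.clip(0.5 * (y[i - 1] - y[i + 1]) / denom, -0.5, 0.5))
    return float(spectrum.mz[i] + shift * spectrum.step_da)


def pick_peaks(
    spectrum: Spectrum,
    noise: np.ndarray,
    snr_min: float = 5.0,
    background: np.ndarray | None = None,
) -> list[Peak]:
    """Pick S/N-thresholded local maxima on the (total mean) spectrum.

    S/N is the apex intensity above the local ``background`` (zero when not
    given) divided by the local noise.  A retained peak must be the tallest
    local maximum within one FWHM (the larger of any pair), a rule applied
    before the S/N filter so that raising ``snr_min`` can only remove
    peaks; integration bounds are set at the nearest local minima.  An
    empty list is a valid result.
    """
    intensity = spectrum.intensity
    if noise.shape != intensity.shape:
        raise ValueError("noise trace must share the spectrum axis")
    if background is None:
        background = np.zeros_like(intensity)
    elif background.shape != intensity.shape:
        raise ValueError("background trace must share the spectrum axis")
    peak_max = float(intensity.max(initial=0.0))
    eff_noise = np.maximum(noise, NOISE_FLOOR_FRAC * max(peak_max, 1.0))
    signal = intensity - background
    candidates, _ = find_peaks(intensity)
    if candidates.size == 0:
        return []

    fwhms = {int(i): measure_fwhm(spectrum, int(i)) for i in candidates}
    max_fwhm = max(fwhms.values())
    accepted: list[int] = []
    for k, c in enumerate(candidates):
        c = int(c)
        suppressed = False
        # scan neighbours within the widest possible separation window
        for j in range(k - 1, -1, -1):
            other = int(candidates[j])
            if spectrum.mz[c] - spectrum.mz[other] >= max_fwhm:
                break
            sep = max(fwhms[c], fwhms[other])
            if (spectrum.mz[c] - spectrum.mz[other] < sep
                    and intensity[other] > intensity[c]):
                suppressed = True
                break
        if not suppressed:
            for j in range(k + 1, candidates.size):
                other = int(candidates[j])
                if spectrum.mz[other] - spectrum.mz[c] >= max_fwhm:
                    break
                sep = max(fwhms[c], fwhms[other])
                if (spectrum.mz[other] - spectrum.mz[c] < sep
                        and intensity[other] > intensity[c]):
                    suppressed = True
                    break
        if not suppressed and signal[c] / eff_noise[c] >= snr_min:
            accepted.append(c)

    minima = argrelmin(intensity)[0]
    peaks = []
    for i in sorted(accepted):
        below = minima[minima < i]
        above = minima[minima > i]
        left = spectrum.mz[below[-1]] if below.size else spectrum.mz[0]
        right = spectrum.mz[above[0]] if above.size else spectrum.mz[-1]
        peaks.append(
            Peak(
                mz=_refine_apex(spectrum, i),
                index=i,
                intensity=float(intensity[i]),
                snr=float(signal[i] / eff_noise[i]),
                left_mz=float(left),
                right_mz=float(right),
                fwhm=fwhms[i],
            )
        )
    return peaks


def build_clusters(
    peaks: list[Peak], tolerance_frac: float = 0.001
) -> list[PeakCluster]:
    """One cluster per mean-spectrum peak.

    The window width is max(peak FWHM, tolerance in Da at that m/z);
    overlapping windows are split at the midpoint between the two apexes,
    so cluster windows never overlap.
    """
    if not peaks:
        return []
    peaks = sorted(peaks, key=lambda p: p.mz)
    lows, highs = [], []
    for p in peaks:
        width = max(p.fwhm, tolerance_frac * p.mz)
        lows.append(p.mz - width / 2)
        highs.append(p.mz + width / 2)
    for i in range(len(peaks) - 1):
        if highs[i] > lows[i + 1]:
            mid = 0.5 * (peaks[i].mz + peaks[i + 1].mz)
            highs[i] = mid
            lows[i + 1] = mid
    return [
        PeakCluster(center=p.mz, low=lo, high=hi)
        for p, lo, hi in zip(peaks, lows, highs)
    ]


def extract_matrix(
    sset: SpectraSet,
    clusters: list[PeakCluster],
    mode: str = "max",
) -> PeakClusterMatrix:
    """Read per-sample intensities within each cluster window.

    ``mode='max'`` takes the windowed maximum (peak-intensity semantics);
    ``mode='area'`` the trapezoid integral.  Clusters outside the shared
    axis are rejected.
    """
    if mode not in ("max", "area"):
        raise ValueError(f"unknown extraction mode {mode!r}")
    axis = sset.axis
    selections = []
    for c in clusters:
        if c.high < axis[0] or c.low > axis[-1]:
            raise ValueError(
                f"cluster at {c.center:.2f} Da lies outside the spectrum axis"
            )
        sel = np.flatnonzero((axis >= c.low) & (axis <= c.high))
        if sel.size == 0:
            raise ValueError(f"cluster at {c.center:.2f} Da contains no grid point")
        selections.append(sel)

    rows, ids, labels = [], [], []
    for s in sset:
        values = []
        for sel in selections:
            if mode == "max":
                values.append(float(s.intensity[sel].max()))
            else:
                values.append(float(np.trapezoid(s.intensity[sel], axis[sel])))
        rows.append(values)
        ids.append(s.sample_id)
        labels.append(s.label)
    frame = pd.DataFrame(
        rows,
        index=pd.Index(ids, name="sample_id"),
        columns=[round(c.center, 4) for c in clusters],
    )
    return PeakClusterMatrix(
        intensities=frame,
        clusters=list(clusters),
        labels=pd.Series(labels, index=frame.index, name="label"),
    )
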