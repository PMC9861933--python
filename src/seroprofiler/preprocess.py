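"""Linear-mode MALDI-TOF spectrum processing chain.

Implements the standard serum-profiling preparation applied before peak
statistics: resampling to a common 1000-10,000 Da axis, recalibration
against prominent peaks shared across spectra, total-ion-current (TIC)
normalization, Savitzky-Golay smoothing, morphological top-hat baseline
subtraction (flat structuring element, default width 10% of the processed
m/z span), grouping of technical replicates into one biological replica,
and the total mean spectrum used for peak picking.

Every step appends its name and parameters to the spectrum's processing
history, and the canonical step order (recalibration -> normalization ->
smoothing -> baseline) is enforced by :func:`standard_pipeline` unless the
caller explicitly overrides it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "Spectrum",
    "SpectraSet",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "smooth",
    "tophat_baseline",
    "tic_normalize",
    "recalibrate",
    "group_replicates",
    "total_mean_spectrum",
    "standard_pipeline",
]

#: Minimum number of points accepted for a spectrum.
MIN_POINTS = 16

#: Canonical processing order of the per-spectrum steps.
CANONICAL_ORDER = ("recalibrate", "tic_normalize", "smooth", "tophat_baseline")


@dataclass
class Spectrum:
    """An m/z-sorted intensity trace with sample/replicate metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str | None = None
    replicate: int | None = None
    label: str | None = None
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z axis must be strictly ascending")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def evolve(self, intensity: np.ndarray, step: str, mz: np.ndarray | None = None
               ) -> "Spectrum":
        """Copy with new intensities (and optionally axis), history appended."""
        return Spectrum(
            mz=self.mz if mz is None else mz,
            intensity=intensity,
            sample_id=self.sample_id,
            replicate=self.replicate,
            label=self.label,
            history=self.history + [step],
        )

    @property
    def step_da(self) -> float:
        return float(np.median(np.diff(self.mz)))


@dataclass
class SpectraSet:
    """A collection of spectra, on a shared axis after :func:`resample`."""

    spectra: list[Spectrum]

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("empty spectra set")

    @property
    def axis(self) -> np.ndarray:
        ref = self.spectra[0].mz
        for s in self.spectra[1:]:
            if s.mz.shape != ref.shape or not np.array_equal(s.mz, ref):
                raise ValueError("spectra are not on a shared axis; resample first")
        return ref

    def intensity_matrix(self) -> np.ndarray:
        axis = self.axis  # validates
        del axis
        return np.vstack([s.intensity for s in self.spectra])

    def groups(self) -> dict[str, list[int]]:
        """Map sample id -> indices of its (replicate) spectra."""
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.spectra):
            out.setdefault(s.sample_id or f"spectrum_{i}", []).append(i)
        return out

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)


# ---------------------------------------------------------------------------
# I/O


def read_spectrum(path: str | Path, **metadata) -> Spectrum:
    """Read a spectrum from mzML or two-column delimited text.

    Unsorted axes are sorted ascending with a warning; fewer than
    ``MIN_POINTS`` points, non-numeric rows or empty files are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        from pyteomics import mzml

        with mzml.MzML(str(path)) as reader:
            try:
                entry = next(iter(reader))
            except StopIteration:
                raise ValueError(f"{path}: no spectra in mzML file") from None
        mz = np.asarray(entry["m/z array"], dtype=float)
        intensity = np.asarray(entry["intensity array"], dtype=float)
    else:
        try:
            table = np.loadtxt(path, ndmin=2, delimiter=None)
        except ValueError:
            try:
                table = np.loadtxt(path, ndmin=2, delimiter=",")
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric or malformed rows") from exc
        if table.size == 0:
            raise ValueError(f"{path}: empty spectrum file")
        if table.shape[1] != 2:
            raise ValueError(f"{path}: expected two columns, got {table.shape[1]}")
        mz, intensity = table[:, 0], table[:, 1]

    if mz.size < MIN_POINTS:
        raise ValueError(f"{path}: spectrum has {mz.size} points, minimum {MIN_POINTS}")
    if np.any(np.diff(mz) <= 0):
        warnings.warn(f"{path}: m/z axis not ascending, sorting", stacklevel=2)
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
    return Spectrum(mz=mz, intensity=intensity, history=[f"read({path.name})"],
                    **metadata)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write as two-column whitespace-delimited text (m/z, intensity)."""
    out = np.column_stack([spectrum.mz, spectrum.intensity])
    np.savetxt(path, out, fmt="%.12g")


# ---------------------------------------------------------------------------
# Per-spectrum steps


def resample(
    spectra: list[Spectrum] | SpectraSet,
    mz_range: tuple[float, float] = (1000.0, 10000.0),
    step: float = 1.0,
) -> SpectraSet:
    """Linear interpolation of every spectrum onto a common grid.

    Data outside the range are discarded; grid points outside a spectrum's
    support get zero intensity.  A spectrum that does not overlap the range
    is rejected by name.
    """
    lo, hi = mz_range
    if not (hi > lo):
        raise ValueError("m/z range must be ascending")
    if not step > 0:
        raise ValueError("step must be > 0")
    grid = lo + step * np.arange(int(np.floor((hi - lo) / step)) + 1)
    out = []
    items = spectra.spectra if isinstance(spectra, SpectraSet) else spectra
    for s in items:
        if s.mz[-1] < lo or s.mz[0] > hi:
            raise ValueError(
                f"spectrum {s.sample_id or '<unnamed>'} "
                f"({s.mz[0]:.1f}-{s.mz[-1]:.1f} Da) does not overlap "
                f"range {lo}-{hi} Da"
            )
        intensity = np.interp(grid, s.mz, s.intensity, left=0.0, right=0.0)
        out.append(
            s.evolve(intensity, f"resample(range=({lo},{hi}),step={step})", mz=grid)
        )
    return SpectraSet(out)


def smooth(
    spectrum: Spectrum,
    window_points: int = 5,
    polyorder: int = 2,
    method: str = "savgol",
) -> Spectrum:
    """Smooth a spectrum (Savitzky-Golay default, moving average optional).

    The window must be odd and at least ``polyorder + 2`` points; edges are
    handled by a polynomial fit on the truncated window (``mode='interp'``).
    """
    n = spectrum.intensity.size
    if window_points > n:
        raise ValueError(f"smoothing window {window_points} exceeds {n} points")
    if method == "savgol":
        if window_points % 2 == 0 or window_points < polyorder + 2:
            raise ValueError("window must be odd and >= polyorder + 2")
        sm = savgol_filter(spectrum.intensity, window_points, polyorder,
                           mode="interp")
    elif method == "moving_average":
        sm = uniform_filter1d(spectrum.intensity, window_points, mode="nearest")
    else:
        raise ValueError(f"unknown smoothing method {method!r}")
    return spectrum.evolve(sm, f"smooth({method},window={window_points})")


def _element_points(spectrum: Spectrum, min_width_frac: float) -> int:
    span = spectrum.mz[-1] - spectrum.mz[0]
    size = int(round(min_width_frac * span / spectrum.step_da))
    if size % 2 == 0:
        size += 1
    return max(size, 3)


def grey_opening(intensity: np.ndarray, size: int) -> np.ndarray:
    """Morphological opening with a flat element: erosion then dilation."""
    eroded = minimum_filter1d(intensity, size, mode="nearest")
    return maximum_filter1d(eroded, size, mode="nearest")


def tophat_baseline(spectrum: Spectrum, min_width_frac: float = 0.10) -> Spectrum:
    """Top-hat baseline subtraction: input minus its greyscale opening.

    The flat structuring element spans ``min_width_frac`` of the processed
    m/z range (the "minimum baseline width"); the result is pointwise >= 0.
    """
    if not (0 < min_width_frac < 1):
        raise ValueError("min_width_frac must be in (0, 1)")
    size = _element_points(spectrum, min_width_frac)
    if size > spectrum.intensity.size:
        raise ValueError(
            f"structuring element ({size} points) wider than spectrum "
            f"({spectrum.intensity.size} points)"
        )
    opened = grey_opening(spectrum.intensity, size)
    return spectrum.evolve(
        np.maximum(spectrum.intensity - opened, 0.0),
        f"tophat_baseline(min_width_frac={min_width_frac})",
    )


def tic_normalize(spectrum: Spectrum) -> Spectrum:
    """Divide intensities by the total ion current so that they sum to 1."""
    total = float(spectrum.intensity.sum())
    if not total > 0:
        raise ValueError("cannot TIC-normalize an all-zero spectrum")
    return spectrum.evolve(spectrum.intensity / total, "tic_normalize()")


# ---------------------------------------------------------------------------
# Set-level steps


def _prominent_positions(spectrum: Spectrum, top_n: int) -> np.ndarray:
    """m/z of the ``top_n`` tallest local maxima, parabolically refined."""
    min_dist = max(3, int(round(5.0 / spectrum.step_da)))
    idx, _ = find_peaks(spectrum.intensity, distance=min_dist)
    if idx.size == 0:
        return np.empty(0)
    order = np.argsort(spectrum.intensity[idx])[::-1][:top_n]
    picked = np.sort(idx[order])
    return np.array([_refine_apex(spectrum, i) for i in picked])


def _refine_apex(spectrum: Spectrum, i: int) -> float:
    """Sub-grid apex position via a parabola through three points."""
    y = spectrum.intensity
    if i == 0 or i == y.size - 1:
        return float(spectrum.mz[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom >= 0:
        return float(spectrum.mz[i])
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    return float(spectrum.mz[i] + shift * spectrum.step_da)


def recalibrate(
    sset: SpectraSet,
    max_shift_da: float = 3.0,
    top_n: int = 15,
    quorum: float = 0.8,
    coarse_tol_frac: float = 0.002,
) -> SpectraSet:
    """Linear per-spectrum m/z correction to prominent common peaks.

    The ``top_n`` most prominent peaks of each spectrum are pooled and
    clustered within a coarse relative tolerance; consensus positions shared
    by at least ``quorum`` of the spectra define reference masses.  Each
    spectrum gets a least-squares linear axis correction towards them.
    Spectra whose implied shift exceeds ``max_shift_da`` are flagged and
    left uncorrected; with fewer than 3 consensus peaks recalibration is
    skipped with a warning.
    """
    if len(sset) < 2:
        warnings.warn("recalibration needs >= 2 spectra; skipped", stacklevel=2)
        return SpectraSet(
            [s.evolve(s.intensity, "recalibrate(skipped: <2 spectra)")
             for s in sset]
        )
    axis = sset.axis
    per_spectrum = [_prominent_positions(s, top_n) for s in sset]

    pooled = sorted(
        (pos, i) for i, positions in enumerate(per_spectrum) for pos in positions
    )
    consensus: list[float] = []
    members: list[dict[int, float]] = []
    group: list[tuple[float, int]] = []

    def _close(group: list[tuple[float, int]]) -> None:
        owners = {i: pos for pos, i in group}
        if len(owners) >= quorum * len(sset):
            consensus.append(float(np.median([pos for pos, _ in group])))
            members.append(owners)

    for pos, i in pooled:
        if group and pos - group[-1][0] > coarse_tol_frac * pos:
            _close(group)
            group = []
        group.append((pos, i))
    if group:
        _close(group)

    if len(consensus) < 3:
        warnings.warn(
            f"only {len(consensus)} common prominent peaks; recalibration skipped",
            stacklevel=2,
        )
        return SpectraSet(
            [s.evolve(s.intensity, "recalibrate(skipped: <3 common peaks)")
             for s in sset]
        )

    out = []
    for i, s in enumerate(sset):
        own = np.array([m[i] for m in members if i in m])
        ref = np.array([c for c, m in zip(consensus, members) if i in m])
        if own.size < 2:
            out.append(s.evolve(s.intensity, "recalibrate(flagged: <2 anchors)"))
            continue
        design = np.column_stack([own, np.ones_like(own)])
        (a, b), *_ = np.linalg.lstsq(design, ref, rcond=None)
        shift = max(abs(a * axis[0] + b - axis[0]), abs(a * axis[-1] + b - axis[-1]))
        if shift > max_shift_da:
            out.append(
                s.evolve(s.intensity, f"recalibrate(flagged: shift {shift:.2f} Da)")
            )
            continue
        corrected_axis = a * axis + b
        # edge-value extension: the warp is at most a few Da
        intensity = np.interp(axis, corrected_axis, s.intensity)
        out.append(
            s.evolve(intensity, f"recalibrate(a={a:.8f},b={b:.4f})")
        )
    return SpectraSet(out)


def group_replicates(sset: SpectraSet) -> SpectraSet:
    """Average the technical replicates of each sample into one spectrum."""
    axis = sset.axis
    out = []
    for sample_id, idx in sset.groups().items():
        if not idx:
            raise ValueError(f"sample {sample_id} has no replicates")
        stack = np.vstack([sset.spectra[i].intensity for i in idx])
        template = sset.spectra[idx[0]]
        out.append(
            Spectrum(
                mz=axis,
                intensity=stack.mean(axis=0),
                sample_id=sample_id,
                replicate=None,
                label=template.label,
                history=template.history
                + [f"group_replicates(n={len(idx)})"],
            )
        )
    return SpectraSet(out)


def total_mean_spectrum(sset: SpectraSet) -> Spectrum:
    """Pointwise mean over all (per-sample) spectra."""
    axis = sset.axis
    mean = sset.intensity_matrix().mean(axis=0)
    return Spectrum(
        mz=axis,
        intensity=mean,
        sample_id="__total_mean__",
        history=[f"total_mean_spectrum(n={len(sset)})"],
    )


def standard_pipeline(
    spectra: list[Spectrum] | SpectraSet,
    mz_range: tuple[float, float] = (1000.0, 10000.0),
    step: float = 1.0,
    do_recalibrate: bool = True,
    max_shift_da: float = 3.0,
    smooth_window: int = 5,
    smooth_polyorder: int = 2,
    tophat_frac: float = 0.10,
    group: bool = True,
    order: tuple[str, ...] | None = None,
    allow_reorder: bool = False,
) -> tuple[SpectraSet, Spectrum]:
    """Run the full processing chain and return (per-sample set, mean spectrum).

    The per-spectrum step order defaults to the canonical
    recalibration -> TIC normalization -> smoothing -> top-hat baseline;
    a different ``order`` requires ``allow_reorder=True``.
    """
    if order is None:
        order = CANONICAL_ORDER
    elif tuple(order) != CANONICAL_ORDER and not allow_reorder:
        raise ValueError(
            "non-canonical step order requires allow_reorder=True; "
            f"canonical order is {CANONICAL_ORDER}"
        )
    sset = resample(spectra, mz_range=mz_range, step=step)
    for name in order:
        if name == "recalibrate":
            if do_recalibrate:
                sset = recalibrate(sset, max_shift_da=max_shift_da)
        elif name == "tic_normalize":
            sset = SpectraSet([tic_normalize(s) for s in sset])
        elif name == "smooth":
            sset = SpectraSet(
                [smooth(s, smooth_window, smooth_polyorder) for s in sset]
            )
        elif name == "tophat_baseline":
            sset = SpectraSet([tophat_baseline(s, tophat_frac) for s in sset])
        else:
            raise ValueError(f"unknown pipeline step {name!r}")
    if group:
        sset = group_replicates(sset)
    return sset, total_mean_spectrum(sset)
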