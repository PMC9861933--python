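"""Synthetic cohorts and synthetic linear-mode MALDI-TOF spectra.

The generator defines the study conditions used throughout the test suite:
a 76-child atopic cohort in which 22 patients carry IgE-mediated allergy to
at least one plant storage protein (19 to 2S albumins, 15 to vicilins,
10 to legumins, 1 to cereal prolamins, with 9 patients positive to all of
Ara h 1/2/3), and serum peptidome spectra over 1000-10,000 Da acquired in
triplicate, with class-discriminant peaks planted at the published
genetic-algorithm peak positions at a 2:1 amplitude ratio.

Concentrations for positive calls are log-normal, truncated at the
positivity threshold, with per-component location/scale chosen to match the
reported allergy-group median and mean; negative calls sit at the assay
detection floor (0.1 kUA/L).  Every stochastic operation takes an explicit
seed; there is no hidden global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .panel import (
    DEFAULT_THRESHOLD,
    FAMILIES,
    AllergenComponent,
    SIgEPanel,
    load_catalog,
)
from .preprocess import Spectrum, SpectraSet

#: Discriminant peak positions (Da) reported by the genetic-algorithm model.
GA_DISCRIMINANT_MZ = (
    1077.88, 1219.27, 1419.92, 1897.85, 2661.39, 3159.56, 3198.01, 3689.35,
    4287.68, 4396.62, 4645.8, 4964.58, 7922.04, 8126.66, 8866.89,
)

#: Discriminant peak positions (Da) reported by the quick-classifier model.
QC_DISCRIMINANT_MZ = (
    1277.39, 1773.08, 1795.39, 1945.54, 2012.59, 2016.56, 2144.89, 2269.28,
    2474.89, 2601.66, 2726.71, 3689.35, 4964.58, 5004.83, 5017.61, 5044.33,
    6065.66, 8866.89,
)

#: Discriminant peak positions (Da) reported by the supervised-neural-network model.
SNN_DISCRIMINANT_MZ = (
    1450.43, 1795.39, 4151.16, 5352.47, 5905.01, 6221.79, 8601.73, 9135.64,
)

#: Per-component defaults: (positive count of 76, allergy-group median, mean).
#: Components reported as not measured carry a zero count.
DEFAULT_COMPONENT_PARAMS: dict[str, tuple[int, float | None, float | None]] = {
    "nAra h 1": (14, 3.165, 10.93),
    "nCor a 11": (2, 1.6, 1.592),
    "nJug r 6": (2, 0.705, 0.838),
    "nJug r 2": (3, 2.43, 2.223),
    "nPis v 3": (1, 0.44, 0.44),
    "rGly m 5": (0, None, None),
    "nAra h 3": (9, 3.59, 9.038),
    "nCor a 9": (6, 2.695, 3.157),
    "nJug r 4": (3, 1.47, 1.662),
    "rGly m 6": (2, 4.455, 5.623),
    "rAna o 2": (0, None, None),
    "nPis v 2": (0, None, None),
    "nAra h 2": (13, 9.81, 14.434),
    "nAra h 6": (12, 7.975, 14.513),
    "nCor a 14": (4, 2.21, 2.767),
    "nSes i 1": (3, 1.19, 1.56),
    "nSin a 1": (2, 3.65, 5.047),
    "nJug r 1": (4, 2.38, 8.287),
    "rAna o 3": (3, 0.53, 1.127),
    "nMac i": (2, 1.94, 1.94),
    "nBer e 1": (1, 0.64, 0.64),
    "rPis v 1": (1, 1.67, 1.67),
    "nPap s": (1, 0.64, 0.64),
    "nFag e 2": (0, None, None),
    "rGly m 8": (0, None, None),
    "rTri a 19": (1, 0.4, 0.4),
}

#: Family-positivity counts of the emulated 76-patient cohort.
DEFAULT_FAMILY_COUNTS = {
    "2S albumins": 19,
    "vicilins": 15,
    "legumins": 10,
    "cereal prolamins": 1,
}

ALLERGY_LABEL = "storage-protein allergy"
CONTROL_LABEL = "atopic control"


def lognormal_params_from_summary(
    median: float, mean: float, fallback_sigma: float = 0.3
) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and mean.

    mu = ln(median); sigma from mean/median = exp(sigma^2 / 2).  When the
    printed mean does not exceed the median (small-n rounding), a small
    fallback sigma is used.
    """
    if not median > 0:
        raise ValueError("median must be > 0")
    mu = math.log(median)
    if mean > median:
        sigma = math.sqrt(2.0 * math.log(mean / median))
    else:
        sigma = fallback_sigma
    return mu, sigma


def truncated_lognormal_mean(mu: float, sigma: float, lower: float) -> float:
    """E[X | X >= lower] for X ~ LogNormal(mu, sigma)."""
    z = (math.log(lower) - mu) / sigma
    tail = norm.sf(z)
    if tail <= 0:
        raise ValueError("truncation point is beyond the distribution")
    return math.exp(mu + 0.5 * sigma**2) * norm.sf(z - sigma) / tail


@dataclass
class CohortSimConfig:
    """Configuration of the synthetic sIgE cohort generator.

    Two modes: count mode (default) plants exact family-positivity counts
    and a fixed number of Ara h 1/2/3 triple-positive patients; probability
    mode (``component_probs`` set) draws independent Bernoulli positives.
    """

    n: int = 76
    allergic_count: int = 22
    family_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_COUNTS)
    )
    component_counts: dict[str, int] = field(
        default_factory=lambda: {
            code: cnt for code, (cnt, _, _) in DEFAULT_COMPONENT_PARAMS.items()
        }
    )
    arah_triple_count: int = 9
    component_probs: dict[str, float] | None = None
    arah_triple_prob: float = 9 / 17
    lognormal_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    floor: float = 0.1
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.floor > 0:
            raise ValueError("detection floor must be > 0")
        if self.component_probs is not None:
            bad = {k: v for k, v in self.component_probs.items()
                   if not 0 <= v <= 1}
            if bad:
                raise ValueError(f"probabilities outside [0, 1]: {bad}")
        for code, (cnt, median, mean) in DEFAULT_COMPONENT_PARAMS.items():
            if code not in self.lognormal_params:
                if median is None:
                    self.lognormal_params[code] = (math.log(1.0), 0.5)
                else:
                    self.lognormal_params[code] = lognormal_params_from_summary(
                        median, mean
                    )


def _validate_counts(cfg: CohortSimConfig, catalog: list[AllergenComponent]) -> None:
    if cfg.allergic_count > cfg.n:
        raise ValueError("allergic_count exceeds cohort size")
    by_family: dict[str, list[str]] = {f: [] for f in FAMILIES}
    for c in catalog:
        by_family[c.family].append(c.code)
    total_slots = 0
    for fam, fam_count in cfg.family_counts.items():
        if fam_count > cfg.allergic_count:
            raise ValueError(f"family count for {fam} exceeds allergic_count")
        comp_total = sum(cfg.component_counts.get(code, 0) for code in by_family[fam])
        if comp_total < fam_count:
            raise ValueError(
                f"component counts in {fam} ({comp_total}) cannot cover "
                f"{fam_count} family positives"
            )
        for code in by_family[fam]:
            if cfg.component_counts.get(code, 0) > fam_count:
                raise ValueError(
                    f"count for {code} exceeds family count for {fam}"
                )
        total_slots += fam_count
    if total_slots < cfg.allergic_count:
        raise ValueError("family counts cannot cover every allergic patient")
    triple = cfg.arah_triple_count
    if triple:
        majors = ("vicilins", "legumins", "2S albumins")
        for fam in majors:
            if triple > cfg.family_counts.get(fam, 0):
                raise ValueError("arah_triple_count exceeds a family count")
        for code in ("nAra h 1", "nAra h 2", "nAra h 3"):
            if triple > cfg.component_counts.get(code, 0):
                raise ValueError(f"arah_triple_count exceeds count for {code}")


def _assign_families(
    cfg: CohortSimConfig, allergic: np.ndarray, rng: np.random.Generator
) -> tuple[dict[str, set[int]], set[int]]:
    """Choose family members among allergic patients, hitting counts exactly."""
    triple = set(
        rng.choice(allergic, size=cfg.arah_triple_count, replace=False).tolist()
        if cfg.arah_triple_count
        else []
    )
    members: dict[str, set[int]] = {f: set() for f in FAMILIES}
    for fam in ("vicilins", "legumins", "2S albumins"):
        members[fam] |= triple
    remaining = {
        fam: cfg.family_counts.get(fam, 0) - len(members[fam])
        for fam in FAMILIES
    }
    pool = [p for p in allergic.tolist() if p not in triple]
    rng.shuffle(pool)
    if sum(max(r, 0) for r in remaining.values()) < len(pool):
        raise ValueError("not enough family slots to cover allergic patients")
    # coverage pass: every allergic patient joins at least one family
    for p in pool:
        open_fams = [f for f in FAMILIES if remaining[f] > 0]
        weights = np.array([remaining[f] for f in open_fams], dtype=float)
        fam = open_fams[rng.choice(len(open_fams), p=weights / weights.sum())]
        members[fam].add(p)
        remaining[fam] -= 1
    # fill pass: leftover slots among allergic patients not yet in the family
    for fam in FAMILIES:
        if remaining[fam] > 0:
            candidates = [p for p in allergic.tolist() if p not in members[fam]]
            extra = rng.choice(candidates, size=remaining[fam], replace=False)
            members[fam] |= set(extra.tolist())
    return members, triple


def _assign_components(
    cfg: CohortSimConfig,
    catalog: list[AllergenComponent],
    members: dict[str, set[int]],
    triple: set[int],
    rng: np.random.Generator,
) -> dict[str, set[int]]:
    """Distribute component positives within each family's members."""
    triple_codes = ("nAra h 1", "nAra h 2", "nAra h 3")
    arah_patients = set(triple) if cfg.arah_triple_count else set()
    positives: dict[str, set[int]] = {}
    for fam in FAMILIES:
        fam_members = list(members[fam])
        codes = [c.code for c in catalog if c.family == fam]
        remaining = {}
        covered: set[int] = set()
        for code in codes:
            positives[code] = set()
            cnt = cfg.component_counts.get(code, 0)
            if code in triple_codes and cfg.arah_triple_count:
                positives[code] |= arah_patients
                cnt -= len(arah_patients)
                covered |= arah_patients
            remaining[code] = max(cnt, 0)
        uncovered = [p for p in fam_members if p not in covered]
        rng.shuffle(uncovered)
        for p in uncovered:
            open_codes = [c for c in codes if remaining[c] > 0
                          and p not in positives[c]]
            if not open_codes:  # pragma: no cover - blocked by validation
                raise ValueError(f"cannot cover patient {p} in family {fam}")
            weights = np.array([remaining[c] for c in open_codes], dtype=float)
            code = open_codes[rng.choice(len(open_codes), p=weights / weights.sum())]
            positives[code].add(p)
            remaining[code] -= 1
        for code in codes:
            if remaining[code] > 0:
                candidates = [p for p in fam_members if p not in positives[code]]
                take = min(remaining[code], len(candidates))
                if take:
                    extra = rng.choice(candidates, size=take, replace=False)
                    positives[code] |= set(extra.tolist())
    return positives


def _draw_positive(
    cfg: CohortSimConfig, code: str, rng: np.random.Generator
) -> float:
    """Log-normal concentration truncated below the positivity threshold."""
    mu, sigma = cfg.lognormal_params[code]
    for _ in range(1000):
        value = float(rng.lognormal(mu, sigma))
        if value >= cfg.threshold:
            return value
    return cfg.threshold


def simulate_cohort(cfg: CohortSimConfig | None = None) -> SIgEPanel:
    """Generate a synthetic sIgE panel; reproducible given ``cfg.seed``."""
    if cfg is None:
        cfg = CohortSimConfig()
    catalog = load_catalog()
    rng = np.random.default_rng(cfg.seed)
    codes = [c.code for c in catalog]
    ids = [f"P{i + 1:03d}" for i in range(cfg.n)]
    data = pd.DataFrame(
        np.full((cfg.n, len(codes)), cfg.floor),
        index=pd.Index(ids, name="patient_id"),
        columns=codes,
    )

    if cfg.component_probs is not None:
        for code, prob in cfg.component_probs.items():
            if code not in data.columns:
                raise ValueError(f"unknown component code {code!r}")
            hits = np.flatnonzero(rng.random(cfg.n) < prob)
            for i in hits:
                data.iloc[i, data.columns.get_loc(code)] = _draw_positive(
                    cfg, code, rng
                )
        # co-sensitisation coupling: peanut-positive patients may react to
        # all three major peanut storage proteins
        arah = ["nAra h 1", "nAra h 2", "nAra h 3"]
        peanut_pos = np.flatnonzero(
            (data[arah] >= cfg.threshold).any(axis=1).to_numpy()
        )
        for i in peanut_pos:
            if rng.random() < cfg.arah_triple_prob:
                for code in arah:
                    if data.iloc[i, data.columns.get_loc(code)] < cfg.threshold:
                        data.iloc[i, data.columns.get_loc(code)] = _draw_positive(
                            cfg, code, rng
                        )
    else:
        _validate_counts(cfg, catalog)
        allergic = rng.choice(cfg.n, size=cfg.allergic_count, replace=False)
        members, triple = _assign_families(cfg, allergic, rng)
        positives = _assign_components(cfg, catalog, members, triple, rng)
        for code, patients in positives.items():
            col = data.columns.get_loc(code)
            for p in sorted(patients):
                data.iloc[p, col] = _draw_positive(cfg, code, rng)

    positive_any = (data >= cfg.threshold).any(axis=1)
    labels = pd.Series(
        np.where(positive_any, ALLERGY_LABEL, CONTROL_LABEL),
        index=data.index,
        name="clinical_label",
    )
    return SIgEPanel(data=data, clinical_labels=labels)


# ---------------------------------------------------------------------------
# Spectra


@dataclass(frozen=True)
class PeakTemplate:
    """A Gaussian peak: center (Da) and class-conditional mean amplitude."""

    center: float
    amplitude: float | dict[str, float]

    def amplitude_for(self, label: str | None) -> float:
        if isinstance(self.amplitude, dict):
            if label not in self.amplitude:
                raise KeyError(f"no amplitude for class {label!r} at "
                               f"{self.center} Da")
            return self.amplitude[label]
        return float(self.amplitude)

    @property
    def discriminant(self) -> bool:
        return isinstance(self.amplitude, dict) and len(set(
            self.amplitude.values())) > 1


#: Class-shared background peaks of the synthetic serum profile (Da).
DEFAULT_BACKGROUND_MZ = (
    1180.0, 1465.0, 2035.0, 2560.0, 2940.0, 3440.0, 4080.0, 4550.0,
    5250.0, 5680.0, 6450.0, 6900.0, 7450.0, 8350.0, 9300.0, 9650.0,
)

_BACKGROUND_AMPS = (20.0, 35.0, 50.0, 65.0, 80.0)


def default_peak_templates(
    planted_mz: tuple[float, ...] = GA_DISCRIMINANT_MZ,
    ratio: float = 2.0,
    planted_amplitude: float = 24.0,
    pos_label: str = "allergy",
    neg_label: str = "control",
) -> list[PeakTemplate]:
    """Background peaks plus class-discriminant peaks at ``planted_mz``."""
    templates = [
        PeakTemplate(mz, _BACKGROUND_AMPS[i % len(_BACKGROUND_AMPS)])
        for i, mz in enumerate(DEFAULT_BACKGROUND_MZ)
    ]
    templates += [
        PeakTemplate(
            mz,
            {pos_label: planted_amplitude * ratio, neg_label: planted_amplitude},
        )
        for mz in planted_mz
    ]
    return sorted(templates, key=lambda t: t.center)


@dataclass
class SpectrumSimConfig:
    """Configuration of the synthetic linear-mode spectrum generator."""

    mz_range: tuple[float, float] = (1000.0, 10000.0)
    step: float = 1.0
    baseline_amplitude: float = 30.0
    baseline_decay: float = 1200.0
    baseline_const: float = 2.0
    noise_sd: float = 1.0
    fwhm_intercept: float = 3.0
    fwhm_slope: float = 0.002
    peaks: list[PeakTemplate] = field(default_factory=default_peak_templates)
    biological_cv: float = 0.25
    replicate_cv: float = 0.08
    replicates: int = 3
    calib_slope_jitter: float = 5e-5
    calib_offset_jitter: float = 0.3

    def __post_init__(self) -> None:
        lo, hi = self.mz_range
        if not hi > lo:
            raise ValueError("m/z range must be ascending")
        if not self.step > 0:
            raise ValueError("step must be > 0")
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if self.fwhm_intercept <= 0 and self.fwhm_slope <= 0:
            raise ValueError("peak widths must be positive")

    def grid(self) -> np.ndarray:
        lo, hi = self.mz_range
        n = int(np.floor((hi - lo) / self.step)) + 1
        return lo + self.step * np.arange(n)

    def fwhm(self, mz: float) -> float:
        return self.fwhm_intercept + self.fwhm_slope * mz


def _signal(
    cfg: SpectrumSimConfig,
    grid: np.ndarray,
    amplitudes: np.ndarray,
    calib: tuple[float, float] = (1.0, 0.0),
) -> np.ndarray:
    """Baseline plus Gaussian peaks, evaluated on a (possibly warped) axis."""
    a, b = calib
    axis = a * grid + b
    lo = cfg.mz_range[0]
    out = (
        cfg.baseline_amplitude * np.exp(-(axis - lo) / cfg.baseline_decay)
        + cfg.baseline_const
    )
    for template, amp in zip(cfg.peaks, amplitudes):
        if amp == 0:
            continue
        sigma = cfg.fwhm(template.center) / 2.3548200450309493
        sel = slice(
            np.searchsorted(axis, template.center - 5 * sigma),
            np.searchsorted(axis, template.center + 5 * sigma),
        )
        out[sel] += amp * np.exp(
            -0.5 * ((axis[sel] - template.center) / sigma) ** 2
        )
    return out


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv**2)) if cv > 0 else 0.0


def simulate_spectrum(
    cfg: SpectrumSimConfig, class_label: str | None, seed: int
) -> Spectrum:
    """One spectrum: baseline + class-conditional peaks + noise, clipped at 0."""
    rng = np.random.default_rng(seed)
    grid = cfg.grid()
    sigma_bio = _lognormal_sigma(cfg.biological_cv)
    amps = np.array(
        [
            t.amplitude_for(class_label)
            * (rng.lognormal(0.0, sigma_bio) if sigma_bio else 1.0)
            for t in cfg.peaks
        ]
    )
    signal = _signal(cfg, grid, amps)
    noise = rng.normal(0.0, cfg.noise_sd, grid.size) if cfg.noise_sd else 0.0
    return Spectrum(
        mz=grid,
        intensity=np.maximum(signal + noise, 0.0),
        label=class_label,
        history=[f"simulate_spectrum(seed={seed})"],
    )


def simulate_profiling_dataset(
    cfg: SpectrumSimConfig,
    n_per_class: dict[str, int],
    seed: int = 0,
) -> SpectraSet:
    """Simulate a full profiling acquisition with technical replicates.

    Each biological sample draws per-peak amplitude multipliers and one
    additive-noise realisation shared by its replicates; replicates then
    differ by a multiplicative intensity jitter and a small linear m/z
    miscalibration.  Deterministic given ``seed``.
    """
    for label, count in n_per_class.items():
        if count < 2:
            raise ValueError(f"need >= 2 samples for class {label!r}")
    rng = np.random.default_rng(seed)
    grid = cfg.grid()
    sigma_bio = _lognormal_sigma(cfg.biological_cv)
    sigma_rep = _lognormal_sigma(cfg.replicate_cv)
    spectra = []
    sample_no = 0
    for label, count in n_per_class.items():
        for _ in range(count):
            sample_no += 1
            sample_id = f"S{sample_no:03d}"
            amps = np.array(
                [
                    t.amplitude_for(label)
                    * (rng.lognormal(0.0, sigma_bio) if sigma_bio else 1.0)
                    for t in cfg.peaks
                ]
            )
            noise = (
                rng.normal(0.0, cfg.noise_sd, grid.size)
                if cfg.noise_sd
                else np.zeros(grid.size)
            )
            for rep in range(cfg.replicates):
                mult = rng.lognormal(0.0, sigma_rep) if sigma_rep else 1.0
                a = 1.0 + (
                    rng.uniform(-cfg.calib_slope_jitter, cfg.calib_slope_jitter)
                    if cfg.calib_slope_jitter
                    else 0.0
                )
                b = (
                    rng.uniform(-cfg.calib_offset_jitter, cfg.calib_offset_jitter)
                    if cfg.calib_offset_jitter
                    else 0.0
                )
                intensity = np.maximum(
                    mult * _signal(cfg, grid, amps, calib=(a, b)) + noise, 0.0
                )
                spectra.append(
                    Spectrum(
                        mz=grid,
                        intensity=intensity,
                        sample_id=sample_id,
                        replicate=rep,
                        label=label,
                        history=[
                            f"simulate_profiling_dataset(seed={seed},"
                            f"sample={sample_id},rep={rep})"
                        ],
                    )
                )
    return SpectraSet(spectra)
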