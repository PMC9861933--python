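"""Theoretical peptide masses and matching of discriminant profiling peaks.

Computes [M+H]+ (monoisotopic or average) for peptide sequences as the sum
of residue masses plus water plus a proton, optionally with modifications
from a fixed dictionary, and matches observed peak m/z values against a
catalog of identified peptides within a ppm or Da tolerance (the search
setting for the reference identifications was +/- 50 ppm).

Observed linear-mode profiling masses need not equal the unmodified
theoretical masses of the identified sequences; the matcher therefore
searches candidate modifications and reports signed deltas rather than
asserting identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

#: Monoisotopic masses of water and the proton (Da).
WATER_MONO = 18.0105646863
PROTON = 1.007276466
WATER_AVG = 18.01528

#: Modification deltas: name -> (monoisotopic Da, average Da, target residues).
#: Targeted modifications apply once per matching residue; untargeted ones once.
MODIFICATIONS: dict[str, tuple[float, float, frozenset | None]] = {
    "carbamidomethyl": (57.02146, 57.0513, frozenset("C")),
    "acetyl": (42.01057, 42.0367, None),
    "oxidation": (15.99491, 15.9994, frozenset("MW")),
    "amidation": (-0.98402, -0.9847, None),
}

_FLANKED_RE = re.compile(r"^([A-Z]|-)\.([A-Z]+)\.([A-Z]|-)$")


def _load_residue_masses() -> dict[str, tuple[float, float]]:
    ref = resources.files("seroprofiler.data") / "residue_masses.tsv"
    with resources.as_file(ref) as p:
        frame = pd.read_csv(p, sep="\t")
    return {
        r.residue: (float(r.monoisotopic), float(r.average))
        for r in frame.itertuples(index=False)
    }


RESIDUE_MASSES = _load_residue_masses()


@dataclass(frozen=True)
class PeptideRecord:
    """An identified peptide with its reported precursor mass."""

    flanked: str
    sequence: str
    accession: str
    protein_name: str = ""
    reported_mz: float | None = None
    reported_p: float | None = None
    n_terminal: bool = False
    c_terminal: bool = False


def parse_flanked(
    mascot_string: str,
    accession: str = "",
    protein_name: str = "",
    reported_mz: float | None = None,
    reported_p: float | None = None,
) -> PeptideRecord:
    """Parse an X.PEPTIDE.Y flanked peptide string; "-" marks a terminus."""
    m = _FLANKED_RE.match(mascot_string.strip())
    if not m:
        raise ValueError(f"malformed flanked peptide string {mascot_string!r}")
    left, seq, right = m.groups()
    bad = sorted(set(seq) - set(RESIDUE_MASSES))
    if bad:
        raise ValueError(f"non-canonical residue(s) {bad} in {mascot_string!r}")
    return PeptideRecord(
        flanked=mascot_string.strip(),
        sequence=seq,
        accession=accession,
        protein_name=protein_name,
        reported_mz=reported_mz,
        reported_p=reported_p,
        n_terminal=left == "-",
        c_terminal=right == "-",
    )


def _mod_delta(sequence: str, name: str, mass_type: str) -> float:
    if name not in MODIFICATIONS:
        raise ValueError(f"unknown modification {name!r}")
    mono, avg, targets = MODIFICATIONS[name]
    delta = mono if mass_type == "monoisotopic" else avg
    if targets is None:
        return delta
    count = sum(1 for r in sequence if r in targets)
    if count == 0:
        raise ValueError(
            f"modification {name!r} targets {sorted(targets)} but "
            f"{sequence!r} has none"
        )
    return delta * count


def peptide_mh(
    sequence: str,
    modifications: tuple[str, ...] = (),
    mass_type: str = "monoisotopic",
) -> float:
    """[M+H]+ in Da: residue masses + water + proton (+ modification deltas).

    Targeted modifications (e.g. carbamidomethyl on C) apply once per
    matching residue; untargeted ones (e.g. acetyl) once per occurrence in
    ``modifications``.
    """
    if mass_type not in ("monoisotopic", "average"):
        raise ValueError(f"mass_type must be monoisotopic or average")
    if not sequence:
        raise ValueError("empty peptide sequence")
    idx = 0 if mass_type == "monoisotopic" else 1
    total = 0.0
    for r in sequence:
        if r not in RESIDUE_MASSES:
            raise ValueError(f"unknown residue {r!r} in {sequence!r}")
        total += RESIDUE_MASSES[r][idx]
    total += (WATER_MONO if mass_type == "monoisotopic" else WATER_AVG) + PROTON
    for name in modifications:
        total += _mod_delta(sequence, name, mass_type)
    return total


@dataclass(frozen=True)
class PeptideMatch:
    """A peak assigned to a peptide record under a modification set."""

    peak_mz: float
    record: PeptideRecord
    theoretical_mh: float
    delta_da: float
    delta_ppm: float
    modifications: tuple[str, ...]
    mass_type: str


def _applicable(record: PeptideRecord, name: str) -> bool:
    _, _, targets = MODIFICATIONS[name]
    return targets is None or any(r in targets for r in record.sequence)


def match_peaks(
    peak_mzs,
    records: list[PeptideRecord],
    tolerance_value: float = 50.0,
    tolerance_unit: str = "ppm",
    candidate_modifications: tuple[str, ...] = (),
    mass_type: str = "monoisotopic",
) -> tuple[list[PeptideMatch], list[float]]:
    """Assign each peak the record/modification pair minimising |delta|.

    Candidate modification sets are the empty set plus each applicable
    single modification.  Peaks with no combination inside the tolerance
    are returned in the unmatched list.
    """
    if not tolerance_value > 0:
        raise ValueError("tolerance must be > 0")
    if tolerance_unit not in ("ppm", "Da"):
        raise ValueError("tolerance_unit must be 'ppm' or 'Da'")
    matches: list[PeptideMatch] = []
    unmatched: list[float] = []
    for peak in peak_mzs:
        best: PeptideMatch | None = None
        for record in records:
            mod_sets: list[tuple[str, ...]] = [()]
            mod_sets += [
                (name,)
                for name in candidate_modifications
                if _applicable(record, name)
            ]
            for mods in mod_sets:
                mh = peptide_mh(record.sequence, mods, mass_type)
                delta = peak - mh
                ppm = delta / mh * 1e6
                within = (
                    abs(ppm) <= tolerance_value
                    if tolerance_unit == "ppm"
                    else abs(delta) <= tolerance_value
                )
                if within and (best is None or abs(delta) < abs(best.delta_da)):
                    best = PeptideMatch(
                        peak_mz=float(peak),
                        record=record,
                        theoretical_mh=mh,
                        delta_da=float(delta),
                        delta_ppm=float(ppm),
                        modifications=mods,
                        mass_type=mass_type,
                    )
        if best is None:
            unmatched.append(float(peak))
        else:
            matches.append(best)
    return matches, unmatched


def load_reference_peptides(path: str | Path | None = None) -> list[PeptideRecord]:
    """Load the packaged catalog of identified discriminant peptides."""
    if path is None:
        ref = resources.files("seroprofiler.data") / "discriminant_peptides.tsv"
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p, sep="\t")
    else:
        frame = pd.read_csv(path, sep="\t")
    return [
        parse_flanked(
            r.flanked_peptide,
            accession=r.accession,
            protein_name=r.protein_name,
            reported_mz=float(r.mz),
            reported_p=float(r.p_value),
        )
        for r in frame.itertuples(index=False)
    ]
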