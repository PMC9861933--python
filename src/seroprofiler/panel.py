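"""Component-resolved sIgE sensitisation profiling.

This module encodes the 26-component plant storage-protein panel of the
ALEX2 multiplex macroarray (vicilins/7S globulins, legumins/11S globulins,
2S albumins and cereal prolamins), applies the positivity rule
(sIgE concentration >= 0.35 kUA/L), derives family-level allergy calls and
the study-group assignment (storage-protein-allergic vs. atopic controls),
and computes per-component / per-family sensitisation summaries
(prevalence %, mean, SD, median in kUA/L).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical storage-protein family names.
FAMILIES = ("vicilins", "legumins", "2S albumins", "cereal prolamins")

#: Structural-superfamily membership of each storage-protein family.
FAMILY_SUPERFAMILY = {
    "vicilins": "Cupins",
    "legumins": "Cupins",
    "2S albumins": "Prolamins",
    "cereal prolamins": "Prolamins",
}

#: Column name for the "sensitised to at least one storage protein" call.
ANY_STORAGE = "any storage protein"

#: Default positivity threshold in kUA/L (inclusive).
DEFAULT_THRESHOLD = 0.35

#: Columns in a cohort table that are patient metadata, not components.
_META_COLUMNS = ("patient_id", "clinical_label")


@dataclass(frozen=True)
class AllergenComponent:
    """One molecular allergen of the storage-protein panel."""

    code: str
    source: str
    family: str
    superfamily: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown storage-protein family {self.family!r}")
        expected = FAMILY_SUPERFAMILY[self.family]
        if self.superfamily != expected:
            raise ValueError(
                f"{self.code}: family {self.family!r} belongs to superfamily "
                f"{expected!r}, got {self.superfamily!r}"
            )


def load_catalog(path: str | Path | None = None) -> list[AllergenComponent]:
    """Load the allergen-component catalog (packaged ALEX2 panel by default)."""
    if path is None:
        ref = resources.files("seroprofiler.data") / "alex2_storage_panel.csv"
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p)
    else:
        frame = pd.read_csv(path)
    catalog = [
        AllergenComponent(r.code, r.source, r.family, r.superfamily)
        for r in frame.itertuples(index=False)
    ]
    codes = [c.code for c in catalog]
    if len(set(codes)) != len(codes):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        raise ValueError(f"duplicate component codes in catalog: {dupes}")
    return catalog


def catalog_frame(catalog: list[AllergenComponent]) -> pd.DataFrame:
    """Catalog as a DataFrame indexed by component code."""
    return pd.DataFrame(
        {
            "source": [c.source for c in catalog],
            "family": [c.family for c in catalog],
            "superfamily": [c.superfamily for c in catalog],
        },
        index=pd.Index([c.code for c in catalog], name="code"),
    )


@dataclass
class SIgEPanel:
    """Patients x components sIgE concentration matrix (kUA/L).

    ``data`` is indexed by patient id with one column per component code.
    NaN marks a not-measured cell (printed as "-" in cohort tables); it is
    distinct from the assay detection floor and is excluded from summaries.
    """

    data: pd.DataFrame
    clinical_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValueError("panel needs at least one patient")
        values = self.data.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            raise ValueError("sIgE concentrations must be non-negative")
        if self.clinical_labels is not None:
            self.clinical_labels = self.clinical_labels.reindex(self.data.index)

    @property
    def patients(self) -> pd.Index:
        return self.data.index

    @property
    def components(self) -> pd.Index:
        return self.data.columns


@dataclass
class PositivityMatrix:
    """Boolean patients x components sensitisation calls at a threshold."""

    values: pd.DataFrame
    threshold: float


@dataclass
class StudyGroups:
    """Partition of the cohort into the allergy and control groups."""

    allergy: list[str]
    control: list[str]

    @property
    def n(self) -> int:
        return len(self.allergy) + len(self.control)


@dataclass
class SensitisationSummary:
    """Prevalence and concentration summaries per component and family."""

    component_summary: pd.DataFrame
    family_summary: pd.DataFrame
    n_patients: int
    threshold: float


def load_panel(
    path: str | Path,
    catalog: list[AllergenComponent] | None = None,
) -> SIgEPanel:
    """Read a delimited cohort table (comma for .csv, tab for .tsv/.txt).

    The table must have a ``patient_id`` column and one column per component
    code; "-" cells are treated as not measured.  Unknown component codes,
    missing patient ids, negative or non-numeric concentrations are rejected
    with row/column context.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "patient_id" not in raw.columns:
        raise ValueError(f"{path}: missing required 'patient_id' column")
    if (raw["patient_id"].str.strip() == "").any():
        rows = raw.index[raw["patient_id"].str.strip() == ""].tolist()
        raise ValueError(f"{path}: empty patient id in row(s) {rows}")

    if catalog is None:
        catalog = load_catalog()
    known = {c.code for c in catalog}
    comp_cols = [c for c in raw.columns if c not in _META_COLUMNS]
    unknown = [c for c in comp_cols if c not in known]
    if unknown:
        raise ValueError(f"{path}: unknown component code(s): {unknown}")

    data = pd.DataFrame(index=pd.Index(raw["patient_id"], name="patient_id"))
    for col in comp_cols:
        cells = raw[col].str.strip().replace({"-": None, "": None})
        numeric = pd.to_numeric(cells, errors="coerce")
        bad = cells.notna() & numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric concentration {cells.iloc[row]!r} "
                f"in column {col!r}, row {row}"
            )
        neg = numeric < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0])
            raise ValueError(
                f"{path}: negative concentration in column {col!r}, row {row}"
            )
        data[col] = numeric.to_numpy()

    labels = None
    if "clinical_label" in raw.columns:
        labels = pd.Series(
            raw["clinical_label"].to_numpy(), index=data.index, name="clinical_label"
        )
    return SIgEPanel(data=data, clinical_labels=labels)


def write_panel(panel: SIgEPanel, path: str | Path) -> None:
    """Write a panel as a delimited table; NaN cells become "-"."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    out = panel.data.copy()
    if panel.clinical_labels is not None:
        out.insert(0, "clinical_label", panel.clinical_labels)
    out.to_csv(path, sep=sep, na_rep="-", float_format="%.10g")


def call_positivity(
    panel: SIgEPanel, threshold: float = DEFAULT_THRESHOLD
) -> PositivityMatrix:
    """Apply the inclusive positivity rule: concentration >= threshold."""
    if not threshold > 0:
        raise ValueError("positivity threshold must be > 0")
    values = panel.data.ge(threshold).fillna(False).astype(bool)
    return PositivityMatrix(values=values, threshold=threshold)


def family_allergy_calls(
    pos: PositivityMatrix, catalog: list[AllergenComponent] | None = None
) -> pd.DataFrame:
    """Per-patient, per-family calls: positive to >= 1 component of the family.

    Adds an ``any storage protein`` column (positive to any panel component).
    """
    if catalog is None:
        catalog = load_catalog()
    by_code = {c.code: c.family for c in catalog}
    missing = [c for c in pos.values.columns if c not in by_code]
    if missing:
        raise ValueError(f"components not in catalog: {missing}")
    calls = pd.DataFrame(index=pos.values.index)
    for fam in FAMILIES:
        cols = [c for c in pos.values.columns if by_code[c] == fam]
        calls[fam] = pos.values[cols].any(axis=1) if cols else False
    calls[ANY_STORAGE] = pos.values.any(axis=1)
    return calls


def assign_groups(family_calls: pd.DataFrame) -> StudyGroups:
    """Allergy group = sensitised to at least one storage protein."""
    if len(family_calls) < 1:
        raise ValueError("need at least one patient")
    mask = family_calls[ANY_STORAGE].to_numpy(dtype=bool)
    allergy = list(family_calls.index[mask])
    control = list(family_calls.index[~mask])
    if not allergy:
        logger.warning("allergy group is empty")
    if not control:
        logger.warning("control group is empty")
    return StudyGroups(allergy=allergy, control=control)


def _stats(values: np.ndarray, ddof: int) -> tuple[float, float, float]:
    """(mean, SD, median) of measured values; NaN triple when empty."""
    values = values[~np.isnan(values)]
    if values.size == 0:
        return (np.nan, np.nan, np.nan)
    sd = float(np.std(values, ddof=ddof)) if values.size > ddof else 0.0
    return (float(np.mean(values)), sd, float(np.median(values)))


def summarize(
    panel: SIgEPanel,
    pos: PositivityMatrix,
    groups: StudyGroups,
    catalog: list[AllergenComponent] | None = None,
    ddof: int = 1,
) -> SensitisationSummary:
    """Per-component and per-family sensitisation summary.

    Prevalence = 100 * positives / n patients, reported to one decimal
    (full precision kept in ``prevalence_frac``).  Concentration statistics
    are given for the whole population and for the component-positive
    patients ("allergy group" columns of the standard report); not-measured
    cells are excluded, and empty groups yield NaN rather than zero.
    SD uses the sample (n - ddof) denominator, ddof=1 by default.
    """
    if catalog is None:
        catalog = load_catalog()
    n = len(panel.patients)
    by_code = {c.code: c for c in catalog}

    rows = []
    for code in panel.components:
        conc = panel.data[code].to_numpy(dtype=float)
        positive = pos.values[code].to_numpy(dtype=bool)
        count = int(positive.sum())
        pop = _stats(conc, ddof)
        grp = _stats(conc[positive], ddof)
        comp = by_code[code]
        rows.append(
            {
                "code": code,
                "source": comp.source,
                "family": comp.family,
                "superfamily": comp.superfamily,
                "n_measured": int(np.sum(~np.isnan(conc))),
                "n_positive": count,
                "prevalence_frac": count / n,
                "prevalence_pct": round(100.0 * count / n, 1),
                "pop_mean": pop[0],
                "pop_sd": pop[1],
                "pop_median": pop[2],
                "allergy_mean": grp[0],
                "allergy_sd": grp[1],
                "allergy_median": grp[2],
            }
        )
    component_summary = pd.DataFrame(rows).set_index("code")

    calls = family_allergy_calls(pos, catalog)
    fam_rows = []
    for fam in list(FAMILIES) + [ANY_STORAGE]:
        count = int(calls[fam].sum())
        fam_rows.append(
            {
                "family": fam,
                "n_positive": count,
                "prevalence_frac": count / n,
                "prevalence_pct": round(100.0 * count / n, 1),
            }
        )
    family_summary = pd.DataFrame(fam_rows).set_index("family")

    return SensitisationSummary(
        component_summary=component_summary,
        family_summary=family_summary,
        n_patients=n,
        threshold=pos.threshold,
    )
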