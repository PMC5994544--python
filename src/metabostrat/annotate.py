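"""Exact-mass peak annotation against a metabolite library.

Putative annotation of LC-MS peaks works by comparing each peak's
measured neutral monoisotopic mass against theoretical masses computed
from molecular formulas, accepting matches within a ppm window
(default +/-10 ppm, the tolerance used for HILIC-QTOF annotation).

Masses here are neutral-molecule monoisotopic masses: the measured
masses carried by the peak table are assumed to already be de-adducted
to the neutral species, so no proton/electron arithmetic is applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

#: IUPAC monoisotopic atomic masses (Da) for the supported elements.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.0030740,
    "O": 15.9949146,
    "P": 30.9737616,
    "S": 31.9720707,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(.)")


class FormulaError(ValueError):
    """Raised for malformed or unsupported molecular formulas."""


@dataclass(frozen=True)
class MetaboliteRecord:
    """A library metabolite: name, formula and external identifiers."""

    name: str
    formula: str
    kegg_id: str = ""
    compound_class: str = ""
    validation_level: int = 3

    def __post_init__(self) -> None:
        parse_formula(self.formula)  # raises on malformed input
        if self.validation_level not in (1, 2, 3):
            raise ValueError(
                f"validation_level must be 1, 2 or 3, got {self.validation_level}"
            )

    @property
    def theoretical_mass(self) -> float:
        return monoisotopic_mass(self.formula)


@dataclass(frozen=True)
class AnnotationMatch:
    """One peak-to-library match within the ppm tolerance."""

    peak_id: str
    metabolite: MetaboliteRecord
    theoretical_mass: float
    measured_mass: float
    ppm_error: float


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula like ``C4H7N3O`` into element counts.

    Only C, H, N, O, P, S are supported; any other token raises
    :class:`FormulaError` naming the offending text.
    """
    if not formula or not isinstance(formula, str):
        raise FormulaError(f"empty or non-string formula: {formula!r}")
    counts: dict[str, int] = {}
    for match in _FORMULA_TOKEN.finditer(formula):
        element, digits, bad = match.groups()
        if bad is not None:
            raise FormulaError(f"malformed token {bad!r} in formula {formula!r}")
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unsupported element {element!r} in formula {formula!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"nonpositive count for {element!r} in {formula!r}")
        counts[element] = counts.get(element, 0) + n
    if not counts:
        raise FormulaError(f"formula {formula!r} contains no elements")
    return counts


def monoisotopic_mass(formula: str) -> float:
    """Theoretical neutral monoisotopic mass (Da) of a molecular formula."""
    counts = parse_formula(formula)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items())


def ppm_error(measured: float, theoretical: float) -> float:
    """Relative mass error (measured - theoretical)/theoretical in ppm."""
    if theoretical <= 0:
        raise ValueError(f"theoretical mass must be positive, got {theoretical}")
    return (measured - theoretical) / theoretical * 1e6


def annotate_peaks(table, library: list[MetaboliteRecord], tol_ppm: float = 10.0):
    """Annotate every peak of ``table`` against ``library`` within ``tol_ppm``.

    Returns a list of :class:`AnnotationMatch`, all |ppm error| <=
    ``tol_ppm`` (inclusive boundary), sorted per peak by absolute ppm
    error; peaks with no match contribute nothing. Internal-standard
    channels are skipped.
    """
    if tol_ppm <= 0:
        raise ValueError(f"tol_ppm must be positive, got {tol_ppm}")
    if not library:
        raise ValueError("metabolite library is empty")
    theoretical = [(rec, rec.theoretical_mass) for rec in library]
    matches: list[AnnotationMatch] = []
    masses = table.peak_meta["measured_mass"]
    for peak_id in table.analyte_ids:
        measured = float(masses.loc[peak_id])
        peak_matches = []
        for rec, theo in theoretical:
            err = ppm_error(measured, theo)
            if abs(err) <= tol_ppm:
                peak_matches.append(
                    AnnotationMatch(
                        peak_id=str(peak_id),
                        metabolite=rec,
                        theoretical_mass=theo,
                        measured_mass=measured,
                        ppm_error=err,
                    )
                )
        peak_matches.sort(key=lambda m: abs(m.ppm_error))
        matches.extend(peak_matches)
    return matches


def matches_to_frame(matches: list[AnnotationMatch]) -> pd.DataFrame:
    rows = [
        {
            "peak_id": m.peak_id,
            "metabolite": m.metabolite.name,
            "formula": m.metabolite.formula,
            "kegg_id": m.metabolite.kegg_id,
            "theoretical_mass": m.theoretical_mass,
            "measured_mass": m.measured_mass,
            "ppm_error": round(m.ppm_error, 2),
        }
        for m in matches
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "peak_id",
            "metabolite",
            "formula",
            "kegg_id",
            "theoretical_mass",
            "measured_mass",
            "ppm_error",
        ],
    )


def read_library(path) -> list[MetaboliteRecord]:
    """Read a metabolite library TSV (name, formula, kegg_id, compound_class, validation_level)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"name", "formula"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"library file lacks columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            MetaboliteRecord(
                name=row["name"],
                formula=row["formula"],
                kegg_id=row.get("kegg_id", ""),
                compound_class=row.get("compound_class", ""),
                validation_level=int(row.get("validation_level", "3") or 3),
            )
        )
    return records


def marker_panel_table() -> pd.DataFrame:
    """The bundled 20-metabolite PPMS marker panel.

    Per metabolite: formula, reported neutral mass, KEGG id, compound
    class, validation level, the two cohort log2 fold changes
    (PPMS/HC) and the four per-component VIP scores from the two
    cross-sectional cohort models.
    """
    path = resources.files("metabostrat.data").joinpath("ppms_marker_panel.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    df["kegg_id"] = df["kegg_id"].fillna("")
    return df


def marker_panel_library() -> list[MetaboliteRecord]:
    """The bundled marker panel as annotation-library records."""
    df = marker_panel_table()
    return [
        MetaboliteRecord(
            name=row["name"],
            formula=row["formula"],
            kegg_id=row["kegg_id"],
            compound_class=row["compound_class"],
            validation_level=int(row["validation_level"]),
        )
        for _, row in df.iterrows()
    ]
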