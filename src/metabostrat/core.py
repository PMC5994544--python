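"""Core in-memory containers for annotated LC-MS peak tables.

The central object is :class:`PeakTable`: a samples x peaks intensity
matrix (raw peak heights, arbitrary instrument units) together with
per-peak metadata (measured neutral monoisotopic mass, ionization mode,
internal-standard flag) and per-sample metadata (analytical role plus
phenotype: group, cohort, sex, age, timepoint, batch).

Samples play one of three analytical roles:

``biological``
    a patient or control specimen, carrying a phenotype ``group``;
``qc``
    a pooled biological quality control injected periodically, used to
    gauge analytical reproducibility and to anchor inter-batch alignment;
``blank``
    an extraction-solvent-only injection used to flag contaminant peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = ("biological", "qc", "blank")

#: sample-metadata columns every PeakTable carries (missing ones are NA)
SAMPLE_META_COLUMNS = (
    "role",
    "group",
    "cohort",
    "sex",
    "age",
    "timepoint_months",
    "subject",
    "batch",
)

PEAK_META_COLUMNS = ("measured_mass", "ion_mode", "is_internal_standard")


class PeakTableError(ValueError):
    """Raised when a peak table violates its structural invariants."""


@dataclass
class PeakTable:
    """Samples x peaks intensity matrix with peak and sample metadata.

    Parameters
    ----------
    intensities
        DataFrame of nonnegative raw peak heights; rows indexed by
        sample id, columns by peak id.
    peak_meta
        DataFrame indexed by peak id with columns ``measured_mass`` (Da,
        neutral monoisotopic), ``ion_mode`` (``positive``/``negative``)
        and ``is_internal_standard`` (bool).
    sample_meta
        DataFrame indexed by sample id; must contain a ``role`` column,
        other columns from :data:`SAMPLE_META_COLUMNS` are optional.
    """

    intensities: pd.DataFrame
    peak_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.intensities.index.duplicated().any():
            dup = self.intensities.index[self.intensities.index.duplicated()]
            raise PeakTableError(f"duplicate sample ids: {sorted(set(dup))}")
        if self.intensities.columns.duplicated().any():
            dup = self.intensities.columns[self.intensities.columns.duplicated()]
            raise PeakTableError(f"duplicate peak ids: {sorted(set(dup))}")
        if not self.intensities.index.equals(self.sample_meta.index):
            raise PeakTableError("sample ids of intensities and sample_meta differ")
        if not self.intensities.columns.equals(self.peak_meta.index):
            raise PeakTableError("peak ids of intensities and peak_meta differ")
        if "role" not in self.sample_meta.columns:
            raise PeakTableError("sample_meta lacks a 'role' column")
        bad_roles = set(self.sample_meta["role"]) - set(ROLES)
        if bad_roles:
            raise PeakTableError(f"unknown sample roles: {sorted(bad_roles)}")
        vals = self.intensities.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise PeakTableError("intensities must be numeric")
        if (vals < 0).any():
            raise PeakTableError("intensities must be nonnegative")
        if (self.sample_meta["role"] == "biological").sum() == 0:
            raise PeakTableError("at least one biological sample is required")
        missing = set(PEAK_META_COLUMNS) - set(self.peak_meta.columns)
        if missing:
            raise PeakTableError(f"peak_meta lacks columns: {sorted(missing)}")

    # -- accessors ------------------------------------------------------
    @property
    def peak_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def n_peaks(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    def samples_with_role(self, role: str) -> pd.Index:
        return self.sample_meta.index[self.sample_meta["role"] == role]

    @property
    def biological_ids(self) -> pd.Index:
        return self.samples_with_role("biological")

    @property
    def qc_ids(self) -> pd.Index:
        return self.samples_with_role("qc")

    @property
    def blank_ids(self) -> pd.Index:
        return self.samples_with_role("blank")

    @property
    def internal_standard_ids(self) -> pd.Index:
        mask = self.peak_meta["is_internal_standard"].astype(bool)
        return self.peak_meta.index[mask]

    @property
    def analyte_ids(self) -> pd.Index:
        """Peak ids excluding internal-standard channels."""
        mask = ~self.peak_meta["is_internal_standard"].astype(bool)
        return self.peak_meta.index[mask]

    def biological(self) -> pd.DataFrame:
        return self.intensities.loc[self.biological_ids]

    def groups(self) -> dict[str, pd.Index]:
        """Biological sample ids keyed by phenotype group."""
        meta = self.sample_meta.loc[self.biological_ids]
        return {g: idx for g, idx in meta.groupby("group", sort=True).groups.items()}

    # -- manipulation ---------------------------------------------------
    def subset_peaks(self, peak_ids) -> "PeakTable":
        peak_ids = pd.Index(peak_ids)
        return PeakTable(
            intensities=self.intensities.loc[:, peak_ids].copy(),
            peak_meta=self.peak_meta.loc[peak_ids].copy(),
            sample_meta=self.sample_meta.copy(),
        )

    def subset_samples(self, sample_ids) -> "PeakTable":
        sample_ids = pd.Index(sample_ids)
        return PeakTable(
            intensities=self.intensities.loc[sample_ids].copy(),
            peak_meta=self.peak_meta.copy(),
            sample_meta=self.sample_meta.loc[sample_ids].copy(),
        )

    def copy(self) -> "PeakTable":
        return PeakTable(
            intensities=self.intensities.copy(),
            peak_meta=self.peak_meta.copy(),
            sample_meta=self.sample_meta.copy(),
        )

    def equals(self, other: "PeakTable") -> bool:
        return (
            self.intensities.equals(other.intensities)
            and self.peak_meta.equals(other.peak_meta)
            and self.sample_meta.equals(other.sample_meta)
        )


@dataclass
class FilterReport:
    """Bookkeeping for a peak-filtering stage."""

    stage: str
    n_input: int
    removed_ids: dict[str, list[str]] = field(default_factory=dict)
    skipped: bool = False

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed_ids.values())

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def validate(self) -> None:
        all_removed: list[str] = []
        for ids in self.removed_ids.values():
            all_removed.extend(ids)
        if len(all_removed) != len(set(all_removed)):
            raise PeakTableError("removed-id sets overlap between rules")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": self.stage, "rule": rule, "peak_id": pid}
            for rule, ids in self.removed_ids.items()
            for pid in ids
        ]
        return pd.DataFrame(rows, columns=["stage", "rule", "peak_id"])

    def __str__(self) -> str:  # human-readable log line
        if self.skipped:
            return f"[{self.stage}] skipped"
        per_rule = ", ".join(f"{r}={len(v)}" for r, v in self.removed_ids.items())
        return (
            f"[{self.stage}] input={self.n_input} removed={self.n_removed}"
            f" ({per_rule}) retained={self.n_retained}"
        )
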