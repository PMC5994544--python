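"""Synthetic untargeted plasma-metabolomics cohorts.

The patient-level data behind the PPMS stratification study are
access-restricted, so this module generates peak tables with the same
statistical structure the downstream analysis assumes:

* log-normal peak intensities with additive effects on the natural-log
  scale (the standard model for LC-MS peak heights);
* case/control cohorts of the study's sizes (13+13, 20+20, 10+10,
  40+20) with designed marker peaks whose log2 fold changes default to
  the reported panel effects (log2 FC ~ -0.07 .. -0.55);
* per-sample multiplicative handling effects shared by all channels of
  a sample, which internal-standard normalization is meant to remove;
* per-batch, per-peak run-day offsets, QC replicates of a pooled mean
  profile with technical noise only, and solvent blanks carrying only a
  small fraction of peaks at biological levels;
* a longitudinal arm (15 subjects x 3 visits) with subject random
  intercepts and exactly one designed declining marker.

Everything is driven by one master seed: peak-universe attributes
(masses, base abundances, marker positions) derive from the master seed
alone so cohorts share a peak panel, while each cohort draws samples
from its own fixed-offset substream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import PeakTable

LN2 = float(np.log(2.0))

#: log2 fold changes (case/control) of the 20-metabolite marker panel,
#: exploration-cohort column of the reported panel.
PANEL_LOG2FC = (
    -0.15, -0.21, -0.09, -0.55, -0.55, -0.40, -0.20, -0.23, -0.25, -0.25,
    -0.26, -0.31, -0.30, -0.24, -0.12, -0.07, -0.40, -0.13, -0.26, -0.36,
)

#: default cohort sizes (n_case, n_control) mirroring the study design
DEFAULT_COHORTS = {
    "A": (13, 13),
    "B": (20, 20),
    "RRMS": (10, 10),
    "PD": (40, 20),
}


def implied_marker_sigma_log2() -> tuple[float, ...]:
    """Per-marker biological SD (log2 scale) implied by the reported panel.

    Each marker's printed log2 fold change, raw Welch p-value and group
    size jointly pin down the per-group SD that makes the t statistic
    come out at the printed p:  sigma = |FC| * sqrt(2/n) / t_quantile.
    The two cross-sectional cohorts give one estimate each; their mean
    is used, so simulating at the default effect sizes reproduces the
    panel's reported univariate statistics in expectation.
    """
    from scipy import stats as sps

    from .annotate import marker_panel_table

    df = marker_panel_table()
    sigmas = []
    for (fc_col, p_col, n) in (("log2fc_a", "p_raw_a", 13), ("log2fc_b", "p_raw_b", 20)):
        t = sps.t.ppf(1 - df[p_col].to_numpy() / 2, 2 * n - 2)
        sigmas.append(np.abs(df[fc_col].to_numpy()) * np.sqrt(2 / n) / t)
    return tuple(np.round(np.mean(sigmas, axis=0), 4))


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation configurations."""


def _cv_to_log_sd(cv: float) -> float:
    """Standard deviation on the natural-log scale for a lognormal CV."""
    return float(np.sqrt(np.log1p(cv * cv)))


@dataclass(frozen=True)
class LongitudinalConfig:
    """Design of the longitudinal arm.

    ``declining_marker_fold_total`` is the expected ratio
    mean(baseline)/mean(last visit) of the single designed declining
    marker; 1.0 means no decline. ``within_subject_cv`` is the
    visit-to-visit biological variation around a subject's own level.
    """

    n_subjects: int = 15
    timepoints_months: tuple[int, ...] = (0, 12, 24)
    declining_marker_fold_total: float = 1.84
    within_subject_cv: float = 0.15


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study conditions: cohort sizes from the
    recruitment table, 534 annotated peaks, 20 designed markers at the
    reported panel log2 fold changes, periodic QCs whose replicate
    dispersion stays under the 10% median-RSD acceptance bound, blanks,
    internal standards, and two analytical batches.
    """

    cohorts: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_COHORTS)
    )
    n_peaks: int = 534
    marker_log2fc: tuple[float, ...] = PANEL_LOG2FC
    marker_sigma_log2: tuple[float, ...] | None = None  # None: panel-implied
    base_log_mean: float = 11.5
    peak_log_mean_sd: float = 1.0
    biological_cv: float = 0.30
    technical_cv: float = 0.06
    handling_cv: float = 0.15
    n_internal_standards: int = 5
    n_batches: int = 2
    batch_log_offset_sd: float = 0.10
    n_qc_per_batch: int = 3
    n_blanks: int = 3
    blank_fraction: float = 0.05
    missing_rate: float = 0.0
    longitudinal: LongitudinalConfig = field(default_factory=LongitudinalConfig)
    seed: int = 0

    @property
    def n_markers(self) -> int:
        return len(self.marker_log2fc)

    def __post_init__(self) -> None:
        if self.n_peaks <= 0:
            raise ConfigurationError("n_peaks must be positive")
        if self.n_markers > self.n_peaks:
            raise ConfigurationError(
                f"{self.n_markers} markers exceed {self.n_peaks} peaks"
            )
        for cv_name in ("biological_cv", "technical_cv", "handling_cv"):
            cv = getattr(self, cv_name)
            if not 0 < cv < 2:
                raise ConfigurationError(f"{cv_name} must lie in (0, 2), got {cv}")
        for cohort, sizes in self.cohorts.items():
            if len(sizes) != 2 or min(sizes) <= 0:
                raise ConfigurationError(
                    f"cohort {cohort!r} needs positive (n_case, n_control), got {sizes}"
                )
        if not 0 <= self.blank_fraction <= 1:
            raise ConfigurationError("blank_fraction must lie in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if (
            self.marker_sigma_log2 is not None
            and len(self.marker_sigma_log2) != self.n_markers
        ):
            raise ConfigurationError(
                "marker_sigma_log2 length must match marker_log2fc length"
            )

    def marker_sigma_nat(self) -> np.ndarray:
        """Per-marker biological SD on the natural-log scale.

        Defaults to the panel-implied values when the marker count
        matches the bundled 20-metabolite panel, else to the global
        biological CV.
        """
        if self.marker_sigma_log2 is not None:
            return np.asarray(self.marker_sigma_log2, dtype=float) * LN2
        if self.n_markers == len(PANEL_LOG2FC):
            return np.asarray(implied_marker_sigma_log2(), dtype=float) * LN2
        return np.full(self.n_markers, _cv_to_log_sd(self.biological_cv))

    # -- presets --------------------------------------------------------
    def with_effect_scale(self, factor: float) -> "SimConfig":
        """Scale every designed marker log2 FC by ``factor``."""
        return replace(
            self, marker_log2fc=tuple(f * factor for f in self.marker_log2fc)
        )

    def null(self) -> "SimConfig":
        """All designed effects set to zero (negative-control preset)."""
        return replace(
            self,
            marker_log2fc=tuple(0.0 for _ in self.marker_log2fc),
            longitudinal=replace(self.longitudinal, declining_marker_fold_total=1.0),
        )

    def boosted(self) -> "SimConfig":
        """|log2 FC| = 1.0 for every marker: the strong-separation preset."""
        return replace(
            self,
            marker_log2fc=tuple(-1.0 for _ in self.marker_log2fc),
        )


@dataclass
class SimOutput:
    """A generated dataset plus its design ground truth."""

    peak_table: PeakTable
    truth: dict[str, float]  # designed marker peak id -> true log2 FC
    cohort_id: str
    config: SimConfig

    def __post_init__(self) -> None:
        missing = set(self.truth) - set(map(str, self.peak_table.peak_ids))
        if missing:
            raise ConfigurationError(f"truth refers to unknown peaks: {sorted(missing)}")


def _substream(config: SimConfig, label: str) -> np.random.Generator:
    """Deterministic per-label stream derived from the master seed."""
    return np.random.default_rng([config.seed, zlib.crc32(label.encode())])


def _peak_universe(config: SimConfig):
    """Peak-level attributes shared by every cohort of one configuration.

    Returns (peak_meta, base_log_mean per peak, marker ids, blank-present
    ids). Derived from the master seed only, so all cohorts see the same
    peak panel and the same designed markers.
    """
    rng = _substream(config, "peaks")
    n = config.n_peaks
    n_is = config.n_internal_standards
    peak_ids = [f"P{i + 1:04d}" for i in range(n)]
    is_ids = [f"IS{i + 1:02d}" for i in range(n_is)]
    masses = np.round(rng.uniform(80.0, 900.0, size=n + n_is), 5)
    ion_mode = rng.choice(["positive", "negative"], size=n + n_is)
    peak_meta = pd.DataFrame(
        {
            "measured_mass": masses,
            "ion_mode": ion_mode,
            "is_internal_standard": [False] * n + [True] * n_is,
        },
        index=pd.Index(peak_ids + is_ids, name="peak_id"),
    )
    mu = config.base_log_mean + rng.normal(0.0, config.peak_log_mean_sd, size=n + n_is)
    marker_ids = [
        peak_ids[i]
        for i in sorted(rng.choice(n, size=config.n_markers, replace=False))
    ]
    if config.n_markers == len(PANEL_LOG2FC):
        # marker peaks carry the panel's reported neutral masses so that
        # exact-mass annotation recovers their metabolite identities
        from .annotate import marker_panel_table

        panel = marker_panel_table()
        pos = peak_meta.index.get_indexer(marker_ids)
        masses = peak_meta["measured_mass"].to_numpy().copy()
        masses[pos] = panel["reported_mass"].to_numpy()
        peak_meta["measured_mass"] = masses
    # blank-present (contaminant-like) peaks; designed markers are real
    # biological compounds and are never drawn as contaminants
    n_blank_present = int(round(config.blank_fraction * n))
    marker_set = set(marker_ids)
    candidates = [p for p in peak_ids if p not in marker_set]
    pick = rng.choice(len(candidates), size=min(n_blank_present, len(candidates)), replace=False)
    blank_ids = [candidates[i] for i in sorted(pick)]
    return peak_meta, mu, marker_ids, blank_ids


def _case_label(cohort_id: str) -> str:
    return cohort_id if cohort_id in ("RRMS", "PD") else "PPMS"


def generate_cohort(config: SimConfig, cohort_id: str) -> SimOutput:
    """Generate one cross-sectional case/control cohort.

    Case-group marker peaks are shifted by ``log2fc * ln 2`` on the log
    scale; every sample carries a multiplicative handling effect shared
    by all its channels (including internal standards); per-batch
    per-peak run-day offsets apply to all injections of a batch; QCs
    replicate the pooled mean profile with technical noise only; blanks
    carry only the configured fraction of peaks at biological levels.
    """
    if cohort_id not in config.cohorts:
        raise ConfigurationError(
            f"unknown cohort {cohort_id!r}; configured: {sorted(config.cohorts)}"
        )
    n_case, n_control = config.cohorts[cohort_id]
    peak_meta, mu, marker_ids, blank_present = _peak_universe(config)
    rng = _substream(config, f"cohort:{cohort_id}")

    n_total = len(peak_meta)
    analyte_mask = ~peak_meta["is_internal_standard"].to_numpy()
    marker_pos = peak_meta.index.get_indexer(marker_ids)
    effect = np.zeros(n_total)
    effect[marker_pos] = np.asarray(config.marker_log2fc) * LN2

    sigma_tech = _cv_to_log_sd(config.technical_cv)
    sigma_handle = _cv_to_log_sd(config.handling_cv)
    # per-peak biological SD: panel-calibrated for markers, global CV else
    bio_sd = np.full(n_total, _cv_to_log_sd(config.biological_cv))
    bio_sd[marker_pos] = config.marker_sigma_nat()

    # per-batch per-peak run-day offsets
    batch_offsets = rng.normal(
        0.0, config.batch_log_offset_sd, size=(config.n_batches, n_total)
    )

    case = _case_label(cohort_id)
    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []

    def add_sample(sid, role, group, log_mean, noise_sd, batch, handling):
        eps = rng.normal(0.0, noise_sd, size=n_total)
        log_x = log_mean + batch_offsets[batch] + handling + eps
        rows.append(np.exp(log_x))
        meta_rows.append(
            {
                "sample_id": sid,
                "role": role,
                "group": group,
                "cohort": cohort_id,
                "sex": "",
                "age": np.nan,
                "timepoint_months": np.nan,
                "subject": "",
                "batch": f"batch{batch + 1}",
            }
        )

    # biological samples, alternating batches
    pooled_shift = effect * n_case / (n_case + n_control)  # pooled-QC profile
    i_sample = 0
    for group, n_group, shifted in ((case, n_case, True), ("HC", n_control, False)):
        for k in range(n_group):
            sid = f"{cohort_id}_{group}_{k + 1:02d}"
            batch = i_sample % config.n_batches
            handling = rng.normal(0.0, sigma_handle)
            log_mean = mu + (effect if shifted else 0.0)
            # IS channels see only handling + technical noise, not
            # biological variation: split the draw per channel class
            eps_bio = rng.normal(0.0, 1.0, size=n_total) * bio_sd
            eps_tech = rng.normal(0.0, sigma_tech, size=n_total)
            eps = np.where(analyte_mask, eps_bio, eps_tech)
            log_x = log_mean + batch_offsets[batch] + handling + eps
            rows.append(np.exp(log_x))
            meta_rows.append(
                {
                    "sample_id": sid,
                    "role": "biological",
                    "group": group,
                    "cohort": cohort_id,
                    "sex": "F" if k % 2 == 0 else "M",
                    "age": float(np.round(rng.normal(52.0, 8.0), 1)),
                    "timepoint_months": np.nan,
                    "subject": "",
                    "batch": f"batch{batch + 1}",
                }
            )
            i_sample += 1

    # QC replicates: pooled mean profile + technical noise only
    for batch in range(config.n_batches):
        for k in range(config.n_qc_per_batch):
            add_sample(
                f"{cohort_id}_QC_b{batch + 1}_{k + 1:02d}",
                "qc",
                "QC",
                mu + pooled_shift,
                sigma_tech,
                batch,
                0.0,
            )

    # blanks: configured peak subset at biological level, rest near zero
    blank_mu = np.zeros(n_total)  # intensity ~ 1, far below any threshold
    present_pos = peak_meta.index.get_indexer(blank_present)
    blank_mu[present_pos] = mu[present_pos]
    for k in range(config.n_blanks):
        add_sample(
            f"{cohort_id}_BLANK_{k + 1:02d}",
            "blank",
            "BLANK",
            blank_mu,
            sigma_tech,
            k % config.n_batches,
            0.0,
        )

    sample_meta = pd.DataFrame(meta_rows).set_index("sample_id")
    intensities = pd.DataFrame(
        np.vstack(rows), index=sample_meta.index, columns=peak_meta.index
    )
    if config.missing_rate > 0:
        mask = rng.random(intensities.shape) < config.missing_rate
        intensities = intensities.mask(mask)
    table = PeakTable(intensities, peak_meta, sample_meta)
    truth = dict(zip(marker_ids, config.marker_log2fc))
    return SimOutput(table, truth, cohort_id, config)


def generate_longitudinal(config: SimConfig) -> SimOutput:
    """Generate the longitudinal arm: subjects sampled at fixed visits.

    Each subject carries per-peak random intercepts shared across
    timepoints; exactly one designed marker declines so that the
    expected ratio mean(baseline)/mean(last visit) equals
    ``declining_marker_fold_total``; all other peaks are stationary in
    expectation.
    """
    lconf = config.longitudinal
    months = tuple(lconf.timepoints_months)
    if len(months) < 2:
        raise ConfigurationError("longitudinal design needs at least 2 timepoints")
    peak_meta, mu, marker_ids, _ = _peak_universe(config)
    rng = _substream(config, "longitudinal")

    n_total = len(peak_meta)
    analyte_mask = ~peak_meta["is_internal_standard"].to_numpy()
    # the designed declining marker: first designed marker of the panel
    decline_id = marker_ids[0]
    decline_pos = int(peak_meta.index.get_indexer([decline_id])[0])
    total_dlog = float(np.log(lconf.declining_marker_fold_total))
    span = months[-1] - months[0]

    subj_sd = np.full(n_total, _cv_to_log_sd(config.biological_cv))
    marker_pos_all = peak_meta.index.get_indexer(marker_ids)
    subj_sd[marker_pos_all] = config.marker_sigma_nat()
    sigma_visit = _cv_to_log_sd(lconf.within_subject_cv)
    sigma_tech = _cv_to_log_sd(config.technical_cv)

    rows, meta_rows = [], []
    for s in range(lconf.n_subjects):
        subject = f"S{s + 1:02d}"
        intercept_bio = rng.normal(0.0, 1.0, size=n_total) * subj_sd
        handling_scale = _cv_to_log_sd(config.handling_cv)
        for m in months:
            drop = np.zeros(n_total)
            drop[decline_pos] = -total_dlog * (m - months[0]) / span
            handling = rng.normal(0.0, handling_scale)
            eps_visit = rng.normal(0.0, sigma_visit, size=n_total)
            eps_tech = rng.normal(0.0, sigma_tech, size=n_total)
            eps = np.where(analyte_mask, eps_visit, eps_tech)
            intercept = np.where(analyte_mask, intercept_bio, 0.0)
            log_x = mu + intercept + drop + handling + eps
            rows.append(np.exp(log_x))
            meta_rows.append(
                {
                    "sample_id": f"L_{subject}_m{m:02d}",
                    "role": "biological",
                    "group": "PPMS",
                    "cohort": "longitudinal",
                    "sex": "F" if s % 3 == 0 else "M",
                    "age": float(np.round(rng.normal(55.0, 7.0), 1)),
                    "timepoint_months": float(m),
                    "subject": subject,
                    "batch": "batch1",
                }
            )
    # periodic QCs for completeness of the analytical design
    for k in range(config.n_qc_per_batch):
        eps = rng.normal(0.0, sigma_tech, size=n_total)
        rows.append(np.exp(mu + eps))
        meta_rows.append(
            {
                "sample_id": f"L_QC_{k + 1:02d}",
                "role": "qc",
                "group": "QC",
                "cohort": "longitudinal",
                "sex": "",
                "age": np.nan,
                "timepoint_months": np.nan,
                "subject": "",
                "batch": "batch1",
            }
        )

    sample_meta = pd.DataFrame(meta_rows).set_index("sample_id")
    intensities = pd.DataFrame(
        np.vstack(rows), index=sample_meta.index, columns=peak_meta.index
    )
    table = PeakTable(intensities, peak_meta, sample_meta)
    truth = {decline_id: float(np.log2(lconf.declining_marker_fold_total))}
    return SimOutput(table, truth, "longitudinal", config)


def write_fixture(sim: SimOutput, path) -> dict[str, str]:
    """Write a SimOutput as TSV files (peak table, sample metadata, truth).

    Reading the files back reproduces the dataset bit-for-bit; two
    writes of the same seed produce byte-identical files.
    """
    from . import io as msio

    return msio.write_fixture(sim, path)
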