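"""Peak filtering, internal-standard normalization, and batch alignment.

The preprocessing chain mirrors common untargeted LC-MS practice:

1. drop peaks never reaching the minimum detectable intensity in any
   biological sample (default threshold 2000 instrument units);
2. drop contaminant peaks whose biological group medians all fall below
   the blank (solvent-only) median;
3. remove per-sample technical handling variation using spiked
   internal-standard channels (single-IS ratio, or the multi-IS
   regression schemes in the NOMIS/CCMN family);
4. align batches so QC means agree across run days for a chosen panel
   of peaks.

All normalization arithmetic happens on the natural-log scale and is
mapped back to raw intensities, preserving positivity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import FilterReport, PeakTable, PeakTableError

IS_METHODS = ("nomis", "ccmn", "single_is_ratio")


def filter_min_intensity(
    table: PeakTable, threshold: float = 2000.0
) -> tuple[PeakTable, FilterReport]:
    """Keep a peak iff its maximum over biological samples reaches ``threshold``.

    The max-over-samples rule keeps peaks detected in any biological
    sample; internal-standard channels are always retained.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be nonnegative, got {threshold}")
    if table.n_peaks == 0:
        raise PeakTableError("empty peak table")
    bio = table.biological()
    max_per_peak = bio.max(axis=0)
    is_mask = table.peak_meta["is_internal_standard"].astype(bool)
    keep = (max_per_peak >= threshold) | is_mask
    removed = [str(p) for p in table.peak_ids[~keep]]
    report = FilterReport(
        stage="min_intensity",
        n_input=table.n_peaks,
        removed_ids={"below_min_intensity": removed},
    )
    report.validate()
    return table.subset_peaks(table.peak_ids[keep]), report


def filter_blank(
    table: PeakTable, quantifier: str = "all"
) -> tuple[PeakTable, FilterReport]:
    """Drop peaks dominated by the extraction-solvent blank signal.

    With ``quantifier='all'`` (default, conservative) a peak is excluded
    only when *every* biological group's median intensity is strictly
    below the blank median; ``'any'`` excludes as soon as one group
    median falls below it. Internal standards are never removed.
    """
    if quantifier not in ("all", "any"):
        raise ValueError(f"quantifier must be 'all' or 'any', got {quantifier!r}")
    blanks = table.blank_ids
    if len(blanks) == 0:
        raise PeakTableError(
            "no blank samples present; skip the blank-filter stage explicitly"
        )
    groups = table.groups()
    if not groups:
        raise PeakTableError("no biological groups defined in sample metadata")
    blank_median = table.intensities.loc[blanks].median(axis=0)
    below = pd.DataFrame(
        {
            g: table.intensities.loc[ids].median(axis=0) < blank_median
            for g, ids in groups.items()
        }
    )
    exclude = below.all(axis=1) if quantifier == "all" else below.any(axis=1)
    exclude &= ~table.peak_meta["is_internal_standard"].astype(bool)
    removed = [str(p) for p in table.peak_ids[exclude]]
    report = FilterReport(
        stage="blank",
        n_input=table.n_peaks,
        removed_ids={f"blank_dominated_{quantifier}_groups": removed},
    )
    report.validate()
    return table.subset_peaks(table.peak_ids[~exclude]), report


def _log_is_matrix(table: PeakTable, rows) -> pd.DataFrame:
    is_ids = table.internal_standard_ids
    if len(is_ids) == 0:
        raise PeakTableError("no internal-standard channels in table")
    is_x = table.intensities.loc[rows, is_ids]
    if (is_x <= 0).any().any():
        raise PeakTableError("internal-standard intensities must be positive")
    if len(is_ids) >= len(rows):
        raise PeakTableError(
            f"{len(is_ids)} IS channels for {len(rows)} samples; "
            "normalization regression is underdetermined"
        )
    return np.log(is_x)


def normalize_is(table: PeakTable, method: str = "ccmn") -> PeakTable:
    """Remove IS-correlated technical variation from analyte channels.

    ``single_is_ratio``
        divide each sample by the geometric mean of its IS channels
        (rescaled by the grand IS level so units are preserved);
    ``nomis``
        per-peak least-squares regression of log intensity on the
        centered log IS panel; the IS-explained component is removed;
    ``ccmn``
        as ``nomis`` but the IS panel is first residualized against the
        biological group factor, so designed group differences cannot
        leak out of the data through the correction.

    The correction is estimated on, and applied to, biological and QC
    injections; solvent blanks carry no internal standards at working
    level and are left untouched. Output keeps all samples and peaks;
    IS channels stay flagged (and are excluded from downstream
    statistics by the callers).
    """
    if method not in IS_METHODS:
        raise ValueError(f"method must be one of {IS_METHODS}, got {method!r}")
    rows = table.sample_meta.index[table.sample_meta["role"].isin(["biological", "qc"])]
    log_is = _log_is_matrix(table, rows)
    out = table.copy()
    analytes = table.analyte_ids
    x = table.intensities.loc[rows, analytes]
    if (x <= 0).any().any():
        raise PeakTableError("normalization requires positive intensities")
    log_x = np.log(x.to_numpy())

    if method == "single_is_ratio":
        sample_factor = log_is.mean(axis=1)  # log geometric mean of IS
        corrected = log_x - (sample_factor.to_numpy() - sample_factor.mean())[:, None]
    else:
        z = log_is.to_numpy() - log_is.to_numpy().mean(axis=0, keepdims=True)
        if method == "ccmn":
            # project the group factor out of the IS panel first
            groups = table.sample_meta.loc[rows, "group"].astype(str)
            dummies = pd.get_dummies(groups, dtype=float).to_numpy()
            proj, *_ = np.linalg.lstsq(dummies, z, rcond=None)
            z = z - dummies @ proj
        y = log_x - log_x.mean(axis=0, keepdims=True)
        beta, *_ = np.linalg.lstsq(z, y, rcond=None)
        corrected = log_x - z @ beta

    out.intensities.loc[rows, analytes] = np.exp(corrected)
    return out


def align_batches(table: PeakTable, peaks=None) -> PeakTable:
    """Equalize per-batch QC means on the log scale for selected peaks.

    For each listed peak, the additive log-scale offset of each batch is
    chosen so every batch's QC mean equals the grand QC mean; all
    samples of the batch are shifted by that offset. Peaks outside
    ``peaks`` (default: the whole table) are left untouched.
    """
    qc_ids = table.qc_ids
    if len(qc_ids) == 0:
        raise PeakTableError("batch alignment requires QC samples")
    batches = table.sample_meta["batch"].astype(str)
    qc_batches = batches.loc[qc_ids]
    all_batches = sorted(batches.unique())
    missing_qc = sorted(set(all_batches) - set(qc_batches.unique()))
    if missing_qc:
        raise PeakTableError(f"batches without QC samples: {missing_qc}")

    peaks = table.peak_ids if peaks is None else pd.Index(peaks)
    out = table.copy()
    x = table.intensities.loc[:, peaks]
    if (x <= 0).any().any():
        raise PeakTableError("batch alignment requires positive intensities")
    log_x = np.log(x)
    qc_log = log_x.loc[qc_ids]
    grand = qc_log.mean(axis=0)
    corrected = log_x.copy()
    for b in all_batches:
        offset = qc_log.loc[qc_batches.index[qc_batches == b]].mean(axis=0) - grand
        corrected.loc[batches.index[batches == b]] -= offset
    out.intensities.loc[:, peaks] = np.exp(corrected)
    return out


def qc_rsd(table: PeakTable) -> pd.Series:
    """Per-peak relative standard deviation over QC replicates (fraction)."""
    qc = table.intensities.loc[table.qc_ids, table.analyte_ids]
    if qc.shape[0] < 2:
        raise PeakTableError("need at least 2 QC samples for RSD")
    return qc.std(axis=0, ddof=1) / qc.mean(axis=0)
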