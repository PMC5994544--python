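import numpy as np
import pandas as pd
import pytest

from metabostrat.core import PeakTable
from metabostrat.simdata import SimConfig, generate_cohort


def make_table(
    intensities: np.ndarray,
    roles: list[str],
    groups: list[str] | None = None,
    is_flags: list[bool] | None = None,
    batches: list[str] | None = None,
    masses: list[float] | None = None,
) -> PeakTable:
    """Construct a small PeakTable from raw arrays, for hand-built fixtures."""
    intensities = np.asarray(intensities, dtype=float)
    n_samples, n_peaks = intensities.shape
    sample_ids = [f"s{i}" for i in range(n_samples)]
    peak_ids = [f"p{j}" for j in range(n_peaks)]
    if groups is None:
        groups = ["case" if r == "biological" and i % 2 == 0 else
                  ("control" if r == "biological" else r.upper())
                  for i, r in enumerate(roles)]
    if is_flags is None:
        is_flags = [False] * n_peaks
    if batches is None:
        batches = ["batch1"] * n_samples
    peak_meta = pd.DataFrame(
        {
            "measured_mass": masses if masses is not None else np.linspace(100, 500, n_peaks),
            "ion_mode": ["positive"] * n_peaks,
            "is_internal_standard": is_flags,
        },
        index=pd.Index(peak_ids, name="peak_id"),
    )
    sample_meta = pd.DataFrame(
        {
            "role": roles,
            "group": groups,
            "cohort": ["T"] * n_samples,
            "sex": ["F"] * n_samples,
            "age": [50.0] * n_samples,
            "timepoint_months": [np.nan] * n_samples,
            "subject": [""] * n_samples,
            "batch": batches,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return PeakTable(
        pd.DataFrame(intensities, index=sample_meta.index, columns=peak_meta.index),
        peak_meta,
        sample_meta,
    )


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A compact simulated study: 60 peaks, 5 strong designed markers."""
    return SimConfig(
        cohorts={"A": (10, 10), "B": (12, 12)},
        n_peaks=60,
        marker_log2fc=(-1.0, -0.8, 1.0, -0.6, 0.9),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, "B")


def cohort_xy(sim):
    """Feature matrix (biological x analyte) and 0/1 labels of a SimOutput."""
    table = sim.peak_table
    x = table.biological().loc[:, table.analyte_ids]
    y = (table.sample_meta.loc[x.index, "group"] != "HC").astype(int).to_numpy()
    return x.to_numpy(), y, list(x.columns)
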