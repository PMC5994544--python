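"""File formats, run configuration, and the end-to-end pipeline.

The on-disk dialect is UTF-8 TSV with "." decimals. A dataset is two
files: a peak table (one row per peak: ``peak_id``, ``measured_mass``,
``ion_mode``, ``is_internal_standard``, then one intensity column per
sample) and a sample-metadata table (one row per sample). Floats are
written with shortest round-trip repr, so write -> read reproduces the
in-memory values bit-for-bit and identical runs produce byte-identical
files.

:func:`run_pipeline` ties the stages together in the study's order —
simulate (or load) -> filter -> normalize -> align -> annotate ->
model/validate -> markers -> longitudinal -> pathway — and writes every
artifact alongside a manifest recording input hashes, seeds and
versions.
"""

from __future__ import annotations

import copy
import csv
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import PeakTable, PeakTableError

logger = logging.getLogger("metabostrat")

PEAK_META_COLS = ["measured_mass", "ion_mode", "is_internal_standard"]


class ConfigError(ValueError):
    """Raised for invalid run configurations."""


# ---------------------------------------------------------------------------
# peak-table round trip
# ---------------------------------------------------------------------------

def write_peak_table(table: PeakTable, peaks_path, samples_path) -> None:
    """Write a PeakTable as the two-file TSV dialect."""
    df = table.peak_meta.copy()
    df.index.name = "peak_id"
    intens = table.intensities.T  # peaks x samples
    out = pd.concat([df, intens], axis=1)
    out.to_csv(peaks_path, sep="\t", lineterminator="\n")
    meta = table.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(samples_path, sep="\t", lineterminator="\n")


def _check_header(path) -> list[str]:
    with open(path, encoding="utf-8", newline="") as fh:
        header = next(csv.reader(fh, delimiter="\t"))
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise PeakTableError(f"duplicated column(s) in {path}: {dupes}")
    return header


def read_peak_table(peaks_path, samples_path) -> PeakTable:
    """Read the two-file TSV dialect back into a PeakTable.

    Duplicate peak ids or sample columns raise, and non-numeric
    intensity cells are reported with their row and column.
    """
    header = _check_header(peaks_path)
    missing = {"peak_id", *PEAK_META_COLS} - set(header)
    if missing:
        raise PeakTableError(f"{peaks_path} lacks columns: {sorted(missing)}")
    df = pd.read_csv(
        peaks_path, sep="\t", dtype={"peak_id": str}, float_precision="round_trip"
    )
    if df["peak_id"].duplicated().any():
        dupes = sorted(df.loc[df["peak_id"].duplicated(), "peak_id"])
        raise PeakTableError(f"duplicate peak_id in {peaks_path}: {dupes}")
    df = df.set_index("peak_id")
    sample_cols = [c for c in df.columns if c not in PEAK_META_COLS]
    for col in sample_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise PeakTableError(
                f"non-numeric intensity at peak {row!r}, sample column {col!r}"
            )
        df[col] = coerced
    peak_meta = df[PEAK_META_COLS].copy()
    peak_meta["is_internal_standard"] = peak_meta["is_internal_standard"].astype(bool)
    intensities = df[sample_cols].T
    intensities.index.name = "sample_id"

    sample_meta = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    if sample_meta["sample_id"].duplicated().any():
        raise PeakTableError(f"duplicate sample_id in {samples_path}")
    sample_meta = sample_meta.set_index("sample_id")
    for col in ("subject", "sex", "group", "cohort", "batch"):
        if col in sample_meta.columns:
            sample_meta[col] = sample_meta[col].fillna("").astype(str)
    sample_meta = sample_meta.reindex(intensities.index)
    if sample_meta["role"].isna().any():
        missing_ids = sorted(sample_meta.index[sample_meta["role"].isna()])
        raise PeakTableError(f"samples without metadata records: {missing_ids}")
    return PeakTable(intensities, peak_meta, sample_meta)


def write_fixture(sim, out_dir) -> dict[str, str]:
    """Write a simulated dataset (peak table, sample meta, truth sidecar)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "peak_table": str(out_dir / "peak_table.tsv"),
        "sample_meta": str(out_dir / "sample_meta.tsv"),
        "truth": str(out_dir / "truth.tsv"),
    }
    write_peak_table(sim.peak_table, paths["peak_table"], paths["sample_meta"])
    truth = pd.DataFrame(
        sorted(sim.truth.items()), columns=["peak_id", "true_log2fc"]
    )
    truth.to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
    return paths


def read_truth(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"peak_id": str})
    return dict(zip(df["peak_id"], df["true_log2fc"].astype(float)))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "schema_version": 1,
    "seed": 0,
    "out_dir": "metabostrat_run",
    "sim": {
        "cohort_a": "A",
        "cohort_b": "B",
        "effect_scale": 1.0,
        "boosted": False,
        "n_peaks": 534,
    },
    "preprocess": {
        "min_intensity": 2000.0,
        "blank_filter": True,
        "blank_quantifier": "all",
        "is_method": "ccmn",
        "align_batches": True,
    },
    "annotate": {"tol_ppm": 10.0},
    "model": {"n_components": 4, "n_iterations": 100, "train_fraction": 0.7},
    "markers": {"vip_threshold": 1.0, "auc_threshold": 0.60},
    "longitudinal": {"enabled": True, "pairs": [[0, 24], [12, 24]]},
    "pathway": {"enabled": True},
}


def _merge_validate(defaults: dict, given: dict, path: str = "") -> dict:
    out = {}
    unknown = set(given) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config key(s) at {path or 'top level'}: {sorted(unknown)}")
    for key, default in defaults.items():
        if isinstance(default, dict):
            sub = given.get(key, {})
            if not isinstance(sub, dict):
                raise ConfigError(f"config key {path}{key} must be a mapping")
            out[key] = _merge_validate(default, sub, f"{path}{key}.")
        else:
            out[key] = copy.deepcopy(given.get(key, default))
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    given: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            given = yaml.safe_load(fh) or {}
    config = _merge_validate(DEFAULT_CONFIG, given)
    if overrides:
        for key, value in overrides.items():
            section = config
            *parents, leaf = key.split(".")
            for part in parents:
                section = section[part]
            if leaf not in section:
                raise ConfigError(f"unknown config key {key!r}")
            section[leaf] = value
    return config


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# the end-to-end pipeline
# ---------------------------------------------------------------------------

def _preprocess_cohort(table, pconf, panel_peaks, log):
    from . import preprocess as pp

    table, rep1 = pp.filter_min_intensity(table, pconf["min_intensity"])
    log.append(str(rep1))
    if pconf["blank_filter"] and len(table.blank_ids) > 0:
        table, rep2 = pp.filter_blank(table, pconf["blank_quantifier"])
        log.append(str(rep2))
    else:
        log.append("[blank] skipped")
    table = pp.normalize_is(table, pconf["is_method"])
    log.append(f"[normalize_is] method={pconf['is_method']} n_peaks={table.n_peaks}")
    if pconf["align_batches"] and len(table.qc_ids) > 0:
        peaks = [p for p in panel_peaks if p in table.peak_ids] or None
        table = pp.align_batches(table, peaks)
        log.append(f"[align_batches] peaks={'panel' if peaks else 'all'}")
    else:
        log.append("[align_batches] skipped")
    return table


def _xy(table):
    """Biological-sample feature matrix (analyte peaks) and 0/1 labels."""
    bio = table.biological()
    x = bio.loc[:, table.analyte_ids.intersection(bio.columns)]
    groups = table.sample_meta.loc[bio.index, "group"]
    y = (groups != "HC").astype(int).to_numpy()
    return x, y


def run_pipeline(config: dict) -> dict:
    """Execute the full synthetic-cohort workflow described by ``config``.

    Returns the manifest dict (also written as ``manifest.json``).
    Every stage appends a log line with its input/output dimensions;
    identical (config, seed) pairs reproduce identical outputs.
    """
    from . import annotate as ann
    from . import pathway as pw
    from . import simdata
    from . import validate as val

    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    stage = "simulate"
    try:
        sim_conf = simdata.SimConfig(
            n_peaks=config["sim"]["n_peaks"], seed=config["seed"]
        )
        if config["sim"]["boosted"]:
            sim_conf = sim_conf.boosted()
        elif config["sim"]["effect_scale"] != 1.0:
            sim_conf = sim_conf.with_effect_scale(config["sim"]["effect_scale"])
        sim_a = simdata.generate_cohort(sim_conf, config["sim"]["cohort_a"])
        sim_b = simdata.generate_cohort(sim_conf, config["sim"]["cohort_b"])
        truth_peaks = sorted(sim_a.truth)
        log.append(
            f"[simulate] cohorts {config['sim']['cohort_a']}/{config['sim']['cohort_b']}"
            f" n_samples={sim_a.peak_table.n_samples}/{sim_b.peak_table.n_samples}"
            f" n_peaks={sim_a.peak_table.n_peaks}"
        )
        for label, sim in (("cohort_a", sim_a), ("cohort_b", sim_b)):
            write_fixture(sim, out_dir / label)

        stage = "preprocess"
        table_a = _preprocess_cohort(
            sim_a.peak_table, config["preprocess"], truth_peaks, log
        )
        table_b = _preprocess_cohort(
            sim_b.peak_table, config["preprocess"], truth_peaks, log
        )

        stage = "annotate"
        library = ann.marker_panel_library()
        matches = ann.annotate_peaks(table_a, library, config["annotate"]["tol_ppm"])
        ann.matches_to_frame(matches).to_csv(
            out_dir / "annotation.tsv", sep="\t", index=False, lineterminator="\n"
        )
        log.append(f"[annotate] n_matches={len(matches)}")

        stage = "validate"
        xa, ya = _xy(table_a)
        xb, yb = _xy(table_b)
        xa, xb = val.intersect_panels(xa, xb)
        mconf = config["model"]
        eval_rows = []
        for label, (x, y) in (("A", (xa, ya)), ("B", (xb, yb))):
            summary = val.repeated_split_eval(
                x.to_numpy(),
                y,
                n_components=mconf["n_components"],
                n_iterations=mconf["n_iterations"],
                train_fraction=mconf["train_fraction"],
                seed=config["seed"],
            )
            eval_rows.append(
                {
                    "cohort": label,
                    "mean_auc": summary.mean_auc,
                    "auc_ci_lo": summary.ci95["auc"][0],
                    "auc_ci_hi": summary.ci95["auc"][1],
                    "mean_ppv": summary.mean_ppv,
                    "mean_npv": summary.mean_npv,
                    "mean_accuracy": summary.mean_accuracy,
                }
            )
        cross = val.cross_cohort_predict(
            (xb.to_numpy(), yb), (xa.to_numpy(), ya), mconf["n_components"]
        )
        eval_df = pd.DataFrame(eval_rows)
        eval_df.to_csv(out_dir / "model_eval.tsv", sep="\t", index=False, lineterminator="\n")
        log.append(
            "[validate] mean AUC "
            + ", ".join(f"{r['cohort']}={r['mean_auc']:.3f}" for r in eval_rows)
            + f"; cross-cohort B->A AUC={cross.auc:.3f}"
        )

        stage = "markers"
        records = val.select_markers_from_cohorts(
            xa.to_numpy(),
            ya,
            xb.to_numpy(),
            yb,
            variable_names=list(xa.columns),
            n_components=max(2, mconf["n_components"]),
            vip_threshold=config["markers"]["vip_threshold"],
            auc_threshold=config["markers"]["auc_threshold"],
        )
        marker_df = val.markers_from_table(records)
        marker_df.to_csv(out_dir / "markers.tsv", sep="\t", index=False, lineterminator="\n")
        selected = [r.metabolite for r in records]
        recovered = sorted(set(selected) & set(truth_peaks))
        log.append(
            f"[markers] selected={len(selected)} designed={len(truth_peaks)}"
            f" recovered={len(recovered)}"
        )

        stage = "longitudinal"
        if config["longitudinal"]["enabled"]:
            sim_l = simdata.generate_longitudinal(sim_conf)
            bio = sim_l.peak_table.biological()
            long_df = pd.concat(
                [
                    sim_l.peak_table.sample_meta.loc[
                        bio.index, ["subject", "timepoint_months"]
                    ],
                    bio.loc[:, sim_l.peak_table.analyte_ids],
                ],
                axis=1,
            )
            pairs = [tuple(p) for p in config["longitudinal"]["pairs"]]
            long_res = val.longitudinal_tests(long_df, pairs)
            long_res.to_csv(
                out_dir / "longitudinal.tsv", sep="\t", index=False, lineterminator="\n"
            )
            marker_id = next(iter(sim_l.truth))
            marker_rows = long_res[long_res["variable"] == marker_id]
            log.append(
                f"[longitudinal] declining marker {marker_id}: "
                + ", ".join(
                    f"{int(r.earlier)}->{int(r.later)}mo fold={r.fold_change:.2f} p={r.p_raw:.4f}"
                    for r in marker_rows.itertuples()
                )
            )
        else:
            log.append("[longitudinal] skipped")

        stage = "pathway"
        if config["pathway"]["enabled"]:
            panel_df = ann.marker_panel_table()
            mass_by_peak = table_a.peak_meta["measured_mass"]
            kegg_ids = []
            for pid in selected:
                if pid not in mass_by_peak.index:
                    continue
                sub = [m for m in matches if m.peak_id == pid]
                kegg_ids.extend(
                    m.metabolite.kegg_id for m in sub if m.metabolite.kegg_id
                )
            if not kegg_ids:  # synthetic peak masses rarely hit the library
                kegg_ids = [k for k in panel_df["kegg_id"] if k]
            rows = pw.enrich_panel(kegg_ids, pw.bundled_pathways())
            pw.enrichment_to_frame(rows).to_csv(
                out_dir / "pathway_enrichment.tsv", sep="\t", index=False, lineterminator="\n"
            )
            log.append(
                f"[pathway] top={rows[0].pathway_id} p={rows[0].p_hyper:.4f}"
                f" impact={rows[0].impact:.3f}"
            )
        else:
            log.append("[pathway] skipped")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config["seed"],
        "config": config,
        "log": log,
        "outputs": {
            p.name: _sha256(p) for p in sorted(out_dir.rglob("*.tsv"))
        },
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for line in log:
        logger.info("%s", line)
    return manifest
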