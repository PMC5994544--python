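"""Inference scaffolding for the marker-discovery workflow.

Covers repeated stratified 70/30 split evaluation of PLS-DA models,
blinded cross-cohort prediction, label-shuffling permutation nulls
(for model metrics and for the two-cohort marker-overlap count),
two-cohort VIP/AUC marker selection, Welch tests with
Benjamini-Hochberg FDR, bootstrap AUC confidence intervals, one-way
ANOVA with Tukey post hoc comparisons, paired longitudinal tests, and
age/sex confounder checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import train_test_split
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .chemometrics import (
    BinaryMetrics,
    ModelError,
    PLSModel,
    auc_mann_whitney,
    binary_metrics,
    fit_plsda,
    predict_scores,
)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class EvalSummary:
    """Aggregate of repeated train/test split evaluations."""

    per_iteration: list[BinaryMetrics]
    train_fraction: float
    seed: int
    mean_auc: float = field(init=False)
    mean_ppv: float = field(init=False)
    mean_npv: float = field(init=False)
    mean_accuracy: float = field(init=False)
    ci95: dict[str, tuple[float, float]] = field(init=False)

    def __post_init__(self) -> None:
        arrays = {
            "auc": np.array([m.auc for m in self.per_iteration]),
            "ppv": np.array([m.ppv for m in self.per_iteration]),
            "npv": np.array([m.npv for m in self.per_iteration]),
            "accuracy": np.array([m.accuracy for m in self.per_iteration]),
        }
        self.ci95 = {}
        means = {}
        for name, vals in arrays.items():
            vals = vals[~np.isnan(vals)]
            means[name] = float(vals.mean())
            if vals.size > 1 and vals.std(ddof=1) > 0:
                lo, hi = sps.t.interval(
                    0.95, vals.size - 1, loc=vals.mean(), scale=sps.sem(vals)
                )
            else:
                lo = hi = means[name]
            self.ci95[name] = (float(lo), float(hi))
        self.mean_auc = means["auc"]
        self.mean_ppv = means["ppv"]
        self.mean_npv = means["npv"]
        self.mean_accuracy = means["accuracy"]

    @property
    def n_iterations(self) -> int:
        return len(self.per_iteration)


@dataclass
class MarkerRecord:
    """Per-metabolite evidence across the two cross-sectional cohorts."""

    metabolite: str
    vip_c1_a: float
    vip_c2_a: float
    vip_c1_b: float
    vip_c2_b: float
    univ_auc: float
    log2fc_a: float = float("nan")
    log2fc_b: float = float("nan")
    p_raw_a: float = float("nan")
    p_fdr_a: float = float("nan")
    p_raw_b: float = float("nan")
    p_fdr_b: float = float("nan")


@dataclass
class PermutationResult:
    """Observed statistic against a label-shuffling null distribution."""

    observed: float
    null_values: np.ndarray
    n_permutations: int
    seed: int
    empirical_p: float = field(init=False)

    def __post_init__(self) -> None:
        b = self.n_permutations
        self.empirical_p = float(
            (1 + int(np.sum(np.asarray(self.null_values) >= self.observed))) / (b + 1)
        )


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def _drop_constant(X_train, X_test):
    keep = X_train.std(axis=0, ddof=1) > 0
    return X_train[:, keep], X_test[:, keep]


def repeated_split_eval(
    X,
    y,
    n_components: int = 4,
    n_iterations: int = 100,
    train_fraction: float = 0.7,
    seed: int = 0,
    threshold: float = 0.5,
) -> EvalSummary:
    """Repeated stratified train/test split evaluation of PLS-DA.

    Per iteration: stratified split, autoscaling estimated on the
    training part only, model fit, blinded prediction of the test part,
    and AUC/PPV/NPV/accuracy of the predicted responses. The summary
    reports per-metric means with t-based 95% confidence intervals.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    if min(np.bincount(y)) < 2:
        raise ModelError("both classes need >= 2 samples for stratified splits")
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_iterations):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X,
            y,
            train_size=train_fraction,
            stratify=y,
            random_state=int(rng.integers(2**31 - 1)),
        )
        X_tr, X_te = _drop_constant(X_tr, X_te)
        k = min(n_components, len(y_tr) - 1, X_tr.shape[1])
        model = fit_plsda(X_tr, y_tr, k)
        results.append(binary_metrics(predict_scores(model, X_te), y_te, threshold))
    return EvalSummary(results, train_fraction=train_fraction, seed=seed)


def cross_cohort_predict(
    train: tuple[np.ndarray, np.ndarray],
    test_blinded: tuple[np.ndarray, np.ndarray],
    n_components: int = 4,
    threshold: float = 0.5,
) -> BinaryMetrics:
    """Train on all subjects of one cohort, evaluate once on the other.

    The feature panels must already be intersected and ordered
    identically (see :func:`intersect_panels`).
    """
    X_tr, y_tr = train
    X_te, y_te = test_blinded
    X_tr = np.asarray(X_tr, dtype=float)
    X_te = np.asarray(X_te, dtype=float)
    if X_tr.shape[1] != X_te.shape[1]:
        raise ModelError("train and test cohorts disagree on the variable panel")
    if X_tr.shape[1] < 2:
        raise ModelError("fewer than 2 shared variables after intersection")
    X_tr, X_te = _drop_constant(X_tr, X_te)
    model = fit_plsda(X_tr, np.asarray(y_tr).astype(int), n_components)
    return binary_metrics(predict_scores(model, X_te), np.asarray(y_te).astype(int), threshold)


def intersect_panels(a: pd.DataFrame, b: pd.DataFrame):
    """Restrict two feature tables to their shared, identically ordered columns."""
    shared = a.columns.intersection(b.columns)
    if len(shared) < 2:
        raise ModelError("fewer than 2 shared variables between cohorts")
    return a.loc[:, shared], b.loc[:, shared]


def permutation_null(metric_fn, X, y, B: int = 100, seed: int = 0) -> PermutationResult:
    """Empirical p-value of ``metric_fn(X, y)`` under label shuffling.

    The estimator p = (1 + #{null >= observed}) / (B + 1) avoids zero
    p-values and is exact under exchangeability.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(y)
    observed = float(metric_fn(X, y))
    rng = np.random.default_rng(seed)
    null_values = np.empty(B)
    for b in range(B):
        try:
            null_values[b] = float(metric_fn(X, rng.permutation(y)))
        except Exception as exc:  # noqa: BLE001 - annotate origin, then re-raise
            raise RuntimeError(f"metric failed on permutation {b}") from exc
    return PermutationResult(observed, null_values, n_permutations=B, seed=seed)


# ---------------------------------------------------------------------------
# marker selection
# ---------------------------------------------------------------------------

def select_markers_from_vips(
    v1a,
    v2a,
    v1b,
    v2b,
    univariate_aucs,
    variable_names=None,
    vip_threshold: float = 1.0,
    auc_threshold: float = 0.60,
    extra: pd.DataFrame | None = None,
) -> list[MarkerRecord]:
    """Marker selection from precomputed VIP columns and univariate AUCs.

    A variable is a marker iff all four VIP values (components 1 and 2
    in both cohorts) reach ``vip_threshold`` AND its univariate AUC
    reaches ``auc_threshold``.
    """
    v1a, v2a, v1b, v2b = (np.asarray(v, dtype=float) for v in (v1a, v2a, v1b, v2b))
    p = v1a.shape[0]
    names = (
        [str(v) for v in variable_names]
        if variable_names is not None
        else [f"var{i}" for i in range(p)]
    )
    aucs = np.asarray(univariate_aucs, dtype=float)
    if aucs.shape[0] != p:
        raise ModelError("univariate AUC vector does not match the panel size")
    selected = (
        (v1a >= vip_threshold)
        & (v2a >= vip_threshold)
        & (v1b >= vip_threshold)
        & (v2b >= vip_threshold)
        & (aucs >= auc_threshold)
    )
    records = []
    for j in np.flatnonzero(selected):
        rec = MarkerRecord(
            metabolite=names[j],
            vip_c1_a=float(v1a[j]),
            vip_c2_a=float(v2a[j]),
            vip_c1_b=float(v1b[j]),
            vip_c2_b=float(v2b[j]),
            univ_auc=float(aucs[j]),
        )
        if extra is not None and names[j] in extra.index:
            for col in extra.columns:
                if hasattr(rec, col):
                    setattr(rec, col, float(extra.loc[names[j], col]))
        records.append(rec)
    return records


def select_markers(
    model_a: PLSModel,
    model_b: PLSModel,
    univariate_aucs,
    variable_names=None,
    vip_threshold: float = 1.0,
    auc_threshold: float = 0.60,
    extra: pd.DataFrame | None = None,
) -> list[MarkerRecord]:
    """Two-cohort reproducible marker selection from fitted models.

    VIP columns are the cumulative scores through components 1 and 2
    (the convention of the PLS toolchains that report one VIP column
    per component count); a variable is a marker iff all four reach
    ``vip_threshold`` in both cohort models and its univariate AUC
    reaches ``auc_threshold``.
    """
    if model_a.n_variables != model_b.n_variables:
        raise ModelError("cohort models disagree on the variable panel")
    if model_a.n_components < 2 or model_b.n_components < 2:
        raise ModelError("marker selection needs at least 2 components per model")
    from .chemometrics import vip_scores

    return select_markers_from_vips(
        vip_scores(model_a, 1),
        vip_scores(model_a, 2),
        vip_scores(model_b, 1),
        vip_scores(model_b, 2),
        univariate_aucs,
        variable_names=variable_names,
        vip_threshold=vip_threshold,
        auc_threshold=auc_threshold,
        extra=extra,
    )


def markers_from_table(records: list[MarkerRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def discriminative_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Direction-free univariate AUC: max(AUC, 1 - AUC).

    A metabolite informative in either direction (elevated or
    diminished in cases) scores above 0.5.
    """
    auc = auc_mann_whitney(values, labels)
    return max(auc, 1.0 - auc)


def univariate_auc_panel(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column direction-free AUC for a feature matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = sps.rankdata(X, axis=0)
    r_pos = ranks[y == 1].sum(axis=0)
    auc = (r_pos - n1 * (n1 + 1) / 2) / (n1 * n0)
    return np.maximum(auc, 1.0 - auc)


def _selection_pipeline(Xa, ya, Xb, yb, n_components, vip_threshold, auc_threshold):
    model_a = fit_plsda(Xa, ya, n_components)
    model_b = fit_plsda(Xb, yb, n_components)
    pooled_auc = univariate_auc_panel(
        np.vstack([Xa, Xb]), np.concatenate([ya, yb])
    )
    return select_markers(
        model_a,
        model_b,
        pooled_auc,
        vip_threshold=vip_threshold,
        auc_threshold=auc_threshold,
    )


def select_markers_from_cohorts(
    Xa,
    ya,
    Xb,
    yb,
    variable_names=None,
    n_components: int = 4,
    vip_threshold: float = 1.0,
    auc_threshold: float = 0.60,
) -> list[MarkerRecord]:
    """Fit both cohort models and select the reproducible marker panel.

    The univariate AUC is the direction-free AUC on the pooled cohorts.
    """
    Xa = np.asarray(Xa, dtype=float)
    Xb = np.asarray(Xb, dtype=float)
    ya = np.asarray(ya).astype(int).ravel()
    yb = np.asarray(yb).astype(int).ravel()
    model_a = fit_plsda(Xa, ya, n_components)
    model_b = fit_plsda(Xb, yb, n_components)
    pooled_auc = univariate_auc_panel(np.vstack([Xa, Xb]), np.concatenate([ya, yb]))
    return select_markers(
        model_a,
        model_b,
        pooled_auc,
        variable_names=variable_names,
        vip_threshold=vip_threshold,
        auc_threshold=auc_threshold,
    )


def overlap_permutation_p(
    Xa,
    ya,
    Xb,
    yb,
    B: int = 100,
    seed: int = 0,
    n_components: int = 4,
    vip_threshold: float = 1.0,
    auc_threshold: float = 0.60,
) -> PermutationResult:
    """Permutation p-value for the size of the selected marker panel.

    Observed statistic: the number of variables passing the two-cohort
    selection under the true labels. Null: labels shuffled independently
    within each cohort, models refitted, selection re-run.
    """
    Xa = np.asarray(Xa, dtype=float)
    Xb = np.asarray(Xb, dtype=float)
    ya = np.asarray(ya).astype(int).ravel()
    yb = np.asarray(yb).astype(int).ravel()

    def count(ya_, yb_):
        return float(
            len(
                _selection_pipeline(
                    Xa, ya_, Xb, yb_, n_components, vip_threshold, auc_threshold
                )
            )
        )

    observed = count(ya, yb)
    rng = np.random.default_rng(seed)
    null_values = np.empty(B)
    for b in range(B):
        null_values[b] = count(rng.permutation(ya), rng.permutation(yb))
    return PermutationResult(observed, null_values, n_permutations=B, seed=seed)


# ---------------------------------------------------------------------------
# univariate statistics
# ---------------------------------------------------------------------------

def welch_fdr(group1: np.ndarray, group2: np.ndarray):
    """Per-variable Welch t-test with Benjamini-Hochberg FDR.

    ``group1``/``group2`` are (samples x variables) matrices. Variables
    with zero variance in both groups and equal means get t = 0, p = 1
    by convention. Returns (t, p_raw, p_fdr) arrays.
    """
    g1 = np.atleast_2d(np.asarray(group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(group2, dtype=float))
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples")
    t, p = sps.ttest_ind(g1, g2, axis=0, equal_var=False)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    degenerate = np.isnan(p) & np.isclose(g1.mean(axis=0), g2.mean(axis=0))
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    _, p_fdr, _, _ = multipletests(p, method="fdr_bh")
    return t, p, p_fdr


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    _, p_fdr, _, _ = multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")
    return p_fdr


def univariate_auc_ci(
    values, labels, n_boot: int = 500, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Point AUC with a stratified percentile-bootstrap 95% CI."""
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    point = auc_mann_whitney(values, labels)
    rng = np.random.default_rng(seed)
    pos = values[labels == 1]
    neg = values[labels == 0]
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        boot[b] = auc_mann_whitney(
            np.concatenate([bp, bn]),
            np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)]),
        )
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return float(point), (float(lo), float(hi))


def anova_tukey(values, group_labels):
    """One-way ANOVA plus Tukey HSD adjusted pairwise comparisons.

    Returns (F, p_anova, pairwise DataFrame). Tukey comparisons use the
    Tukey-Kramer variant, valid for unequal group sizes.
    """
    values = np.asarray(values, dtype=float).ravel()
    group_labels = np.asarray(group_labels).astype(str).ravel()
    groups = [values[group_labels == g] for g in np.unique(group_labels)]
    if len(groups) < 3:
        raise ValueError("need at least 3 groups for ANOVA with post hoc test")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    if all(np.allclose(g, groups[0].mean()) for g in groups):
        f_stat, p_anova = 0.0, 1.0
    else:
        f_stat, p_anova = sps.f_oneway(*groups)
    tukey = pairwise_tukeyhsd(values, group_labels)
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return float(f_stat), float(p_anova), pairwise


def longitudinal_tests(
    long_df: pd.DataFrame,
    timepoint_pairs,
    value_columns=None,
):
    """Paired t-tests and fold changes between visit pairs.

    ``long_df`` is long-format with columns ``subject``,
    ``timepoint_months`` and one column per variable. For each variable
    and each (earlier, later) pair: paired t on per-subject differences
    over complete pairs only, fold change mean(earlier)/mean(later), and
    BH-FDR across variables within the pair. Returns a tidy DataFrame.
    """
    required = {"subject", "timepoint_months"}
    if missing := required - set(long_df.columns):
        raise ValueError(f"long_df lacks columns: {sorted(missing)}")
    if value_columns is None:
        value_columns = [c for c in long_df.columns if c not in required]
    rows = []
    for earlier, later in timepoint_pairs:
        a = long_df[long_df["timepoint_months"] == earlier].set_index("subject")
        b = long_df[long_df["timepoint_months"] == later].set_index("subject")
        shared = a.index.intersection(b.index)
        if len(shared) < 3:
            raise ValueError(
                f"fewer than 3 complete pairs for visits ({earlier}, {later})"
            )
        for var in value_columns:
            x = a.loc[shared, var].to_numpy(dtype=float)
            y = b.loc[shared, var].to_numpy(dtype=float)
            d = x - y
            if np.allclose(d.std(ddof=1), 0.0):
                # all subjects moved identically: treat a nonzero shared
                # shift as a certain change, a zero shift as no change
                t_stat = float("inf") * np.sign(d.mean()) if d.mean() != 0 else 0.0
                p_val = 0.0 if d.mean() != 0 else 1.0
            else:
                t_stat, p_val = sps.ttest_rel(x, y)
            rows.append(
                {
                    "variable": var,
                    "earlier": earlier,
                    "later": later,
                    "n_pairs": len(shared),
                    "t": float(t_stat),
                    "p_raw": float(p_val),
                    "fold_change": float(x.mean() / y.mean()),
                }
            )
    result = pd.DataFrame(rows)
    result["p_fdr"] = np.nan
    for (_, _), idx in result.groupby(["earlier", "later"]).groups.items():
        result.loc[idx, "p_fdr"] = bh_fdr(result.loc[idx, "p_raw"].to_numpy())
    return result


def confounder_checks(meta: pd.DataFrame, values: pd.DataFrame) -> dict:
    """Sex/age confounder screen for a marker panel.

    * chi-square (no continuity correction) on the sex x group
      contingency of biological samples;
    * one-way ANOVA of age across cohorts;
    * per-metabolite ordinary least-squares slope of intensity vs age
      with its p-value.

    ``values`` is (samples x metabolites) aligned with ``meta``.
    """
    for col in ("sex", "group", "age", "cohort"):
        if col not in meta.columns:
            raise ValueError(f"sample metadata lacks required field {col!r}")
    contingency = pd.crosstab(meta["sex"], meta["group"])
    if (contingency.to_numpy().sum(axis=1) > 0).all() and contingency.shape[0] > 1:
        chi2, chi2_p, _, _ = sps.chi2_contingency(contingency, correction=False)
    else:
        chi2, chi2_p = 0.0, 1.0
    cohorts = [g["age"].dropna().to_numpy() for _, g in meta.groupby("cohort")]
    if len(cohorts) >= 2:
        f_stat, anova_p = sps.f_oneway(*cohorts)
    else:
        f_stat, anova_p = 0.0, 1.0
    age = meta["age"].to_numpy(dtype=float)
    slopes = {}
    for col in values.columns:
        res = sps.linregress(age, values[col].to_numpy(dtype=float))
        slopes[col] = {"slope": float(res.slope), "p": float(res.pvalue)}
    return {
        "sex_chi2": float(chi2),
        "sex_p": float(chi2_p),
        "age_anova_f": float(f_stat),
        "age_anova_p": float(anova_p),
        "age_slopes": slopes,
    }
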