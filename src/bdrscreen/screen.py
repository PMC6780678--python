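"""Metabolome-wide age-by-metabolite interaction screens.

One model per metabolite feature: BDR regressed on covariates, age, the
(preprocessed) metabolite level and the age x metabolite product.  The
longitudinal screen fits a subject-level random-intercept mixed model with
a normal-reference Wald test on the interaction; the cross-sectional
screen fits per-feature OLS with t-based inference.  Benjamini-Hochberg
q-values are computed across all features tested in one invocation.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError
from .lcms import FeatureMatrix
from .lmm import LMMSpec, fit_random_intercept, wald_test

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("race", "sex", "clinic", "treatment")
TERM_METABOLITE = "metabolite"
TERM_INTERACTION = "age:metabolite"

RESULT_COLUMNS = [
    "feature_id", "beta", "se", "p", "q",
    "n_obs", "n_subjects", "model", "stratum", "status",
]


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR-adjusted p-values.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1 and mapped back to
    the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DomainError("pvalues must be a nonempty 1-D vector")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def percent_significant(results: pd.DataFrame, alpha: float = 0.05) -> float:
    """Percentage of successfully tested features with p below alpha."""
    ok = results.loc[results["status"] == "ok", "p"]
    if len(ok) == 0:
        raise DomainError("no successfully tested features")
    return 100.0 * float((ok < alpha).mean())


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _features_by_sample(features: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(features, FeatureMatrix):
        return features.study_frame()
    return features


def build_base_design(cohort: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Intercept + dummy-coded covariates + age.

    Categorical levels are ordered lexicographically with the first level
    as the reference; single-level covariates are dropped with a log line
    (e.g. race in a single-race cohort).  Numeric covariate columns such as
    ancestry components pass through unchanged.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(cohort))}
    for cov in covariates:
        if cov in ("age", "age_years"):
            continue
        series = cohort[cov]
        if pd.api.types.is_numeric_dtype(series):
            cols[cov] = series.to_numpy(dtype=float)
            continue
        levels = sorted(series.astype(str).unique())
        if len(levels) < 2:
            logger.info("covariate %r has a single level (%s); dropped from design",
                        cov, levels)
            continue
        for lvl in levels[1:]:
            cols[f"{cov}[{lvl}]"] = (series.astype(str) == lvl).to_numpy(dtype=float)
    cols["age"] = cohort["age_years"].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=cohort.index)


def _aligned_inputs(
    cohort: pd.DataFrame, features: FeatureMatrix | pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    z = _features_by_sample(features)
    usable = cohort["sample_id"].isin(z.columns) & cohort["bdr"].notna()
    dropped = int((~usable).sum())
    if dropped:
        logger.info("screen: %d cohort row(s) without matched sample or BDR excluded", dropped)
    sub = cohort.loc[usable].reset_index(drop=True)
    return sub, z.loc[:, sub["sample_id"]]


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def run_longitudinal_screen(
    cohort: pd.DataFrame,
    features: FeatureMatrix | pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    stratum: str = "all",
) -> pd.DataFrame:
    """One random-intercept LMM per feature; Wald z on the interaction.

    Returns one row per feature sorted by ascending p, with BH q-values
    computed across all successfully tested features.  Zero-variance
    features are skipped and model failures recorded as failed rows, so
    the denominator stays auditable.
    """
    sub, z = _aligned_inputs(cohort, features)
    x0 = build_base_design(sub, covariates)
    base = x0.to_numpy(dtype=float)
    base_cols = list(x0.columns)
    age = sub["age_years"].to_numpy(dtype=float)
    groups = sub["subject_id"].to_numpy()
    y = sub["bdr"].to_numpy(dtype=float)
    n_subjects = sub["subject_id"].nunique()

    rows = []
    for fid in z.index:
        zf = z.loc[fid].to_numpy(dtype=float)
        row = {
            "feature_id": fid, "beta": np.nan, "se": np.nan, "p": np.nan,
            "n_obs": len(sub), "n_subjects": n_subjects,
            "model": "longitudinal", "stratum": stratum, "status": "ok",
        }
        if np.nanstd(zf) == 0 or np.isnan(zf).all():
            row["status"] = "skipped_zero_variance"
            logger.info("feature %s skipped: zero variance after preprocessing", fid)
            rows.append(row)
            continue
        X = np.column_stack([base, zf, age * zf])
        spec = LMMSpec(y=y, X=X, columns=base_cols + [TERM_METABOLITE, TERM_INTERACTION],
                       groups=groups)
        try:
            fit = fit_random_intercept(spec)
            w = wald_test(fit, TERM_INTERACTION)
        except Exception as exc:  # model failure recorded, screen continues
            row["status"] = "failed"
            logger.warning("feature %s: model failure: %s", fid, exc)
            rows.append(row)
            continue
        row.update(beta=w.beta, se=w.se, p=w.p)
        rows.append(row)
    return _finalize(rows)


def run_cross_sectional_screen(
    cohort: pd.DataFrame,
    features: FeatureMatrix | pd.DataFrame,
    covariates: Sequence[str] = ("race", "sex"),
    stratum: str = "all",
) -> pd.DataFrame:
    """Per-feature OLS of BDR on covariates, age, metabolite and age x
    metabolite; Wald t p-values with residual degrees of freedom."""
    sub, z = _aligned_inputs(cohort, features)
    x0 = build_base_design(sub, covariates)
    base = x0.to_numpy(dtype=float)
    age = sub["age_years"].to_numpy(dtype=float)
    y = sub["bdr"].to_numpy(dtype=float)
    n_subjects = sub["subject_id"].nunique()

    rows = []
    for fid in z.index:
        zf = z.loc[fid].to_numpy(dtype=float)
        row = {
            "feature_id": fid, "beta": np.nan, "se": np.nan, "p": np.nan,
            "n_obs": len(sub), "n_subjects": n_subjects,
            "model": "cross-sectional", "stratum": stratum, "status": "ok",
        }
        if np.nanstd(zf) == 0 or np.isnan(zf).all():
            row["status"] = "skipped_zero_variance"
            rows.append(row)
            continue
        X = np.column_stack([base, zf, age * zf])
        try:
            res = sm.OLS(y, X).fit()
            j = X.shape[1] - 1
            row.update(beta=float(res.params[j]), se=float(res.bse[j]),
                       p=float(res.pvalues[j]))
        except Exception as exc:
            row["status"] = "failed"
            logger.warning("feature %s: OLS failure: %s", fid, exc)
        rows.append(row)
    return _finalize(rows)


def _finalize(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    ok = df["status"] == "ok"
    if ok.any():
        df.loc[ok, "q"] = bh_adjust(df.loc[ok, "p"].to_numpy())
    df = df.sort_values(["p", "feature_id"], na_position="last", kind="stable")
    return df.reset_index(drop=True)[RESULT_COLUMNS]


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

TIER_REPLICATED = "replicated"
TIER_NOMINAL = "nominal"
TIER_NOT_REPLICATED = "not_replicated"
TIER_UNTESTED = "untested"


def replication_report(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    alpha: float = 0.05,
    nominal_p: float = 0.10,
) -> pd.DataFrame:
    """Cross-cohort replication tiers with direction-of-effect consistency.

    replicated: discovery p < alpha, replication p < alpha, same sign;
    nominal: discovery p < alpha, replication p < nominal_p, same sign;
    untested: feature absent from the replication screen;
    not_replicated: everything else.  Features are harmonized by exact
    name match.
    """
    rep = replication.set_index("feature_id")
    rows = []
    for _, d in discovery.iterrows():
        fid = d["feature_id"]
        entry = {
            "feature_id": fid,
            "discovery_beta": d["beta"], "discovery_p": d["p"],
            "replication_beta": np.nan, "replication_p": np.nan,
            "direction_consistent": False, "tier": TIER_UNTESTED,
        }
        if fid in rep.index:
            r = rep.loc[fid]
            consistent = bool(np.sign(d["beta"]) == np.sign(r["beta"])) and d["beta"] != 0
            entry.update(
                replication_beta=r["beta"], replication_p=r["p"],
                direction_consistent=consistent,
            )
            if d["p"] < alpha and consistent and r["p"] < alpha:
                entry["tier"] = TIER_REPLICATED
            elif d["p"] < alpha and consistent and r["p"] < nominal_p:
                entry["tier"] = TIER_NOMINAL
            else:
                entry["tier"] = TIER_NOT_REPLICATED
        rows.append(entry)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stratified screens, trends, QQ
# ---------------------------------------------------------------------------

def stratified_screen(
    cohort: pd.DataFrame,
    features: FeatureMatrix | pd.DataFrame,
    strata_var: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    model: str = "longitudinal",
    min_samples: int = 30,
) -> tuple[pd.DataFrame, list[str]]:
    """Independent screens per stratum of `strata_var` (e.g. sex or race).

    Strata with fewer than `min_samples` rows are skipped (returned in the
    second element).  The stratifying variable is removed from the
    covariate list automatically.
    """
    covs = [c for c in covariates if c != strata_var]
    runner = run_longitudinal_screen if model == "longitudinal" else run_cross_sectional_screen
    parts, skipped = [], []
    for level in sorted(cohort[strata_var].astype(str).unique()):
        sub = cohort.loc[cohort[strata_var].astype(str) == level]
        if len(sub) < min_samples:
            skipped.append(level)
            logger.info("stratum %s=%s skipped: only %d samples (min %d)",
                        strata_var, level, len(sub), min_samples)
            continue
        parts.append(runner(sub, features, covariates=covs, stratum=level))
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=RESULT_COLUMNS)
    return out, skipped


def metabolite_age_trend(
    cohort: pd.DataFrame,
    features: FeatureMatrix | pd.DataFrame,
    visit: str,
    feature_ids: Sequence[str] | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Per-visit OLS of each preprocessed metabolite on age + covariates.

    Returns the age coefficient with its t-based 95% CI and p-value, plus
    BH q across the features tested in this call.
    """
    z = _features_by_sample(features)
    sub = cohort.loc[(cohort["visit"] == visit) & cohort["sample_id"].isin(z.columns)]
    if len(sub) == 0:
        raise DomainError(f"no samples for visit {visit!r}")
    sub = sub.reset_index(drop=True)
    zmat = z.loc[:, sub["sample_id"]]
    if feature_ids is None:
        feature_ids = list(zmat.index)
    for fid in feature_ids:
        if fid not in zmat.index:
            raise KeyError(f"feature {fid!r} not present in the feature matrix")

    X = build_base_design(sub, covariates).to_numpy(dtype=float)
    j = X.shape[1] - 1  # age is the last base column
    rows = []
    for fid in feature_ids:
        res = sm.OLS(zmat.loc[fid].to_numpy(dtype=float), X).fit()
        lo, hi = res.conf_int()[j]
        rows.append({
            "feature_id": fid, "visit": visit, "beta": float(res.params[j]),
            "ci_low": float(lo), "ci_high": float(hi), "p": float(res.pvalues[j]),
            "n_obs": len(sub),
        })
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def qq_points(pvalues: Sequence[float]) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ diagnostic.

    Expected quantiles are (i - 0.5)/m; observed p of exactly 0 are
    clamped to the smallest positive normal double with a warning.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise DomainError("empty p-value vector")
    if np.any(p == 0):
        logger.warning("qq_points: %d zero p-value(s) clamped", int((p == 0).sum()))
        p = np.where(p == 0, np.finfo(float).tiny, p)
    p_sorted = np.sort(p)
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(p_sorted)
    return pd.DataFrame({"expected_neglog10_p": expected, "observed_neglog10_p": observed})
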