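"""LC-MS feature-matrix preprocessing.

Implements the pooled-reference drift standardization, the QC filter
cascade (instrument signal-to-noise, per-feature missingness among study
samples, pooled-reference coefficient of variation), median imputation, and
the log10 + pareto transform used before modeling.

The canonical pipeline order is fixed:

    standardize -> SNR filter -> missingness filter -> impute
                -> CV filter -> log10 -> pareto

The CV filter is evaluated on RAW pooled-reference values (standardization
forces pool ratios toward 1 and would mask technical variance), and pools
are never imputed, so its outcome does not depend on the imputation step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

ROLE_STUDY = "study"
ROLE_POOL = "pooled_reference"

STATUS_RETAINED = "retained"
STATUS_DROPPED_SNR = "dropped_snr"
STATUS_DROPPED_MISSING = "dropped_missing"
STATUS_DROPPED_CV = "dropped_cv"


@dataclass
class FeatureMatrix:
    """A metabolite-feature x injection peak-area matrix.

    Attributes
    ----------
    values
        DataFrame indexed by feature id with one column per injection id;
        entries are nonnegative peak areas or NaN for missing.
    injections
        Sidecar table indexed by injection id with columns
        ``injection_order`` (1..n permutation), ``role`` (``study`` or
        ``pooled_reference``) and ``sample_id`` (NA for pools).
    snr
        Per-feature signal-to-noise ratio as reported by instrument
        software (consumed as metadata, never computed from spectra).
    """

    values: pd.DataFrame
    injections: pd.DataFrame
    snr: pd.Series | None = None

    def __post_init__(self) -> None:
        inj = self.injections
        for col in ("injection_order", "role", "sample_id"):
            if col not in inj.columns:
                raise FormatError(f"injections table is missing column {col!r}")
        if set(self.values.columns) != set(inj.index):
            raise FormatError("values columns and injections index do not match")
        order = np.sort(inj["injection_order"].to_numpy())
        if not np.array_equal(order, np.arange(1, len(inj) + 1)):
            raise FormatError("injection_order must be a permutation of 1..n_injections")
        bad_roles = set(inj["role"]) - {ROLE_STUDY, ROLE_POOL}
        if bad_roles:
            raise FormatError(f"unknown injection role(s): {sorted(bad_roles)}")
        study = inj.loc[inj["role"] == ROLE_STUDY, "sample_id"]
        if study.isna().any():
            raise FormatError("every study injection must carry a sample_id")
        if study.duplicated().any():
            raise FormatError("study injections map to duplicate sample ids")
        # keep columns in injection order for positional work
        ordered = inj.sort_values("injection_order").index
        self.injections = inj.loc[ordered]
        self.values = self.values.loc[:, ordered]
        if self.snr is not None:
            self.snr = self.snr.reindex(self.values.index)

    # -- convenience views -------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def study_ids(self) -> pd.Index:
        return self.injections.index[self.injections["role"] == ROLE_STUDY]

    @property
    def pool_ids(self) -> pd.Index:
        return self.injections.index[self.injections["role"] == ROLE_POOL]

    def study_values(self) -> pd.DataFrame:
        return self.values.loc[:, self.study_ids]

    def pool_values(self) -> pd.DataFrame:
        return self.values.loc[:, self.pool_ids]

    def study_frame(self) -> pd.DataFrame:
        """Study values with columns relabeled by sample id."""
        out = self.study_values().copy()
        out.columns = self.injections.loc[self.study_ids, "sample_id"].to_numpy()
        return out

    def subset_features(self, ids) -> "FeatureMatrix":
        snr = None if self.snr is None else self.snr.loc[ids]
        return FeatureMatrix(self.values.loc[ids].copy(), self.injections.copy(), snr)

    def copy(self) -> "FeatureMatrix":
        snr = None if self.snr is None else self.snr.copy()
        return FeatureMatrix(self.values.copy(), self.injections.copy(), snr)


@dataclass
class QCReport:
    """Per-feature QC dispositions with telescoping stage counts."""

    table: pd.DataFrame  # columns: status, snr, missing_frac, pool_cv
    counts: dict = field(default_factory=dict)

    def retained_ids(self) -> pd.Index:
        return self.table.index[self.table["status"] == STATUS_RETAINED]


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize_to_reference(m: FeatureMatrix) -> FeatureMatrix:
    """Drift-correct every injection against its nearest pooled reference.

    For feature *f* and injection *i*::

        out[f, i] = raw[f, i] / raw[f, nearest_ref(i)] * median_f

    where ``median_f`` is the median of the feature's nonmissing reference
    values and nearest is by absolute injection-order difference, ties
    broken toward the earlier injection.  If the nearest reference value is
    missing or zero the next nearest positive reference is used.  Missing
    inputs stay missing; a feature with no usable reference at all comes
    back all-missing (it is caught by the missingness filter downstream).
    """
    vals = m.values.to_numpy(dtype=float)
    orders = m.injections["injection_order"].to_numpy()
    pool_pos = np.flatnonzero((m.injections["role"] == ROLE_POOL).to_numpy())
    n_feat, n_inj = vals.shape

    if pool_pos.size == 0:
        raise FormatError("no pooled-reference injections present")

    pool_orders = orders[pool_pos]
    # ranking of pools per injection by (distance, earlier order)
    dist = np.abs(orders[:, None] - pool_orders[None, :])  # (n_inj, n_pool)
    key = dist * (orders.max() + 1) + pool_orders[None, :]
    ranking = np.argsort(key, axis=1, kind="stable")  # pool indices, best first

    pool_vals = vals[:, pool_pos]  # (n_feat, n_pool)
    valid = np.isfinite(pool_vals) & (pool_vals > 0)

    medians = np.full(n_feat, np.nan)
    for f in range(n_feat):
        pv = pool_vals[f][np.isfinite(pool_vals[f])]
        if pv.size:
            medians[f] = np.median(pv)

    out = np.full_like(vals, np.nan)
    all_valid = valid.all(axis=1)

    # fast path: every pool usable -> nearest pool is ranking[:, 0] for all
    if all_valid.any():
        nearest = ranking[:, 0]  # (n_inj,)
        ref = pool_vals[np.ix_(all_valid, nearest)]  # rows x n_inj
        out[all_valid] = vals[all_valid] / ref * medians[all_valid, None]

    for f in np.flatnonzero(~all_valid):
        if not valid[f].any():
            logger.warning(
                "feature %s has no usable pooled reference; values set missing",
                m.feature_ids[f],
            )
            continue
        # first valid pool in each injection's ranking
        valid_sorted = valid[f][ranking]  # (n_inj, n_pool)
        first = np.argmax(valid_sorted, axis=1)
        chosen = ranking[np.arange(n_inj), first]
        out[f] = vals[f] / pool_vals[f, chosen] * medians[f]

    res = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return FeatureMatrix(res, m.injections.copy(), None if m.snr is None else m.snr.copy())


# ---------------------------------------------------------------------------
# QC statistics and filters
# ---------------------------------------------------------------------------

def qc_feature_stats(m: FeatureMatrix, raw_for_cv: FeatureMatrix | None = None) -> pd.DataFrame:
    """Per-feature missing fraction (study samples only), pool CV and SNR.

    The pool CV = SD/mean (SD with the n-1 denominator) is computed from
    ``raw_for_cv`` when given (raw values, the default policy) and from
    ``m`` otherwise.
    """
    study = m.study_values().to_numpy(dtype=float)
    missing_frac = np.isnan(study).mean(axis=1)

    src = raw_for_cv if raw_for_cv is not None else m
    pools = src.pool_values().reindex(m.feature_ids).to_numpy(dtype=float)
    cv = np.full(len(m.feature_ids), np.nan)
    for f in range(pools.shape[0]):
        pv = pools[f][np.isfinite(pools[f])]
        if pv.size >= 2 and pv.mean() != 0:
            cv[f] = pv.std(ddof=1) / pv.mean()

    snr = (
        m.snr.to_numpy(dtype=float)
        if m.snr is not None
        else np.full(len(m.feature_ids), np.nan)
    )
    return pd.DataFrame(
        {"snr": snr, "missing_frac": missing_frac, "pool_cv": cv},
        index=m.feature_ids,
    )


def filter_features(
    m: FeatureMatrix,
    snr_min: float = 10.0,
    max_missing: float = 0.10,
    cv_max: float = 0.25,
    raw_for_cv: FeatureMatrix | None = None,
) -> tuple[FeatureMatrix, QCReport]:
    """Apply the QC cascade: SNR < snr_min, then study-sample missing
    fraction > max_missing, then pooled-reference CV > cv_max.

    All thresholds follow the strict inequalities of the stated rules:
    SNR exactly 10 is retained, missing fraction exactly 0.10 is retained,
    CV exactly 0.25 is retained.  The CV never depends on imputed values
    (pools are never imputed), so running this cascade in one pass is
    equivalent to interleaving imputation before the CV stage.
    """
    stats = qc_feature_stats(m, raw_for_cv=raw_for_cv)
    status = pd.Series(STATUS_RETAINED, index=m.feature_ids, dtype=object)

    snr_bad = stats["snr"] < snr_min
    # features with unknown SNR are treated as failing the SNR gate
    snr_bad |= stats["snr"].isna()
    status[snr_bad] = STATUS_DROPPED_SNR

    miss_bad = (stats["missing_frac"] > max_missing) & (status == STATUS_RETAINED)
    status[miss_bad] = STATUS_DROPPED_MISSING

    cv_bad = (stats["pool_cv"] > cv_max) & (status == STATUS_RETAINED)
    status[cv_bad] = STATUS_DROPPED_CV

    table = stats.copy()
    table.insert(0, "status", status)
    counts = {
        "n_input": len(status),
        "n_retained": int((status == STATUS_RETAINED).sum()),
        "n_dropped_snr": int((status == STATUS_DROPPED_SNR).sum()),
        "n_dropped_missing": int((status == STATUS_DROPPED_MISSING).sum()),
        "n_dropped_cv": int((status == STATUS_DROPPED_CV).sum()),
    }
    report = QCReport(table=table, counts=counts)
    kept = m.subset_features(status.index[status == STATUS_RETAINED])
    logger.info("filter_features: %s", counts)
    return kept, report


def impute_median(m: FeatureMatrix) -> FeatureMatrix:
    """Replace missing study values by the feature's observed study median.

    Pooled-reference values are never imputed.  Runs after the SNR and
    missingness filters, so an all-missing feature cannot occur here.
    """
    out = m.copy()
    study_ids = m.study_ids
    study = out.values.loc[:, study_ids].to_numpy(dtype=float)
    for f in range(study.shape[0]):
        row = study[f]
        mask = np.isnan(row)
        if not mask.any():
            continue
        observed = row[~mask]
        assert observed.size > 0, "all-missing feature survived the missingness filter"
        row[mask] = np.median(observed)
    out.values.loc[:, study_ids] = study
    return out


def log10_pareto(m: FeatureMatrix) -> FeatureMatrix:
    """log10-transform then pareto-scale each feature over study samples.

    Pareto scaling centers and divides by the square root of the standard
    deviation (n-1 denominator): z = (log10 x - mean) / sqrt(SD).  Zero or
    negative values at this stage are replaced by half the feature's
    smallest positive study value (logged); constant features (SD = 0)
    are dropped with a logged reason.  The returned matrix contains study
    injections only (pools play no further role in modeling).
    """
    study_ids = m.study_ids
    study = m.values.loc[:, study_ids].to_numpy(dtype=float).copy()

    n_clamped = 0
    keep = np.ones(study.shape[0], dtype=bool)
    for f in range(study.shape[0]):
        row = study[f]
        nonpos = row <= 0
        if nonpos.any():
            positive = row[row > 0]
            if positive.size == 0:
                keep[f] = False
                logger.warning("feature %s has no positive study value; dropped", m.feature_ids[f])
                continue
            row[nonpos] = positive.min() / 2.0
            n_clamped += int(nonpos.sum())
        logged = np.log10(row)
        sd = logged.std(ddof=1)
        if sd == 0:
            keep[f] = False
            logger.warning("feature %s is constant after log10; dropped", m.feature_ids[f])
            continue
        study[f] = (logged - logged.mean()) / np.sqrt(sd)
    if n_clamped:
        logger.info("log10_pareto: clamped %d nonpositive value(s) to half-minimum", n_clamped)

    ids = m.feature_ids[keep]
    values = pd.DataFrame(study[keep], index=ids, columns=study_ids)
    injections = m.injections.loc[study_ids].copy()
    injections["injection_order"] = (
        injections["injection_order"].rank(method="first").astype(int)
    )
    snr = None if m.snr is None else m.snr.loc[ids]
    return FeatureMatrix(values, injections, snr)


def preprocess(
    raw: FeatureMatrix,
    snr_min: float = 10.0,
    max_missing: float = 0.10,
    cv_max: float = 0.25,
) -> tuple[FeatureMatrix, QCReport]:
    """Full preprocessing pipeline in the canonical order.

    standardize -> SNR filter -> missingness filter -> impute -> CV filter
    -> log10 -> pareto.  Returns the analysis-ready (study-only) matrix and
    the QC report.
    """
    std = standardize_to_reference(raw)
    s1, rep1 = filter_features(
        std, snr_min=snr_min, max_missing=max_missing, cv_max=np.inf, raw_for_cv=raw
    )
    imputed = impute_median(s1)
    s2, rep2 = filter_features(
        imputed, snr_min=-np.inf, max_missing=1.0, cv_max=cv_max, raw_for_cv=raw
    )
    out = log10_pareto(s2)

    table = rep1.table.copy()
    cv_dropped = rep2.table.index[rep2.table["status"] == STATUS_DROPPED_CV]
    table.loc[cv_dropped, "status"] = STATUS_DROPPED_CV
    table["pool_cv"] = rep2.table["pool_cv"].reindex(table.index).fillna(table["pool_cv"])
    status = table["status"]
    counts = {
        "n_input": len(table),
        "n_retained": int((status == STATUS_RETAINED).sum()),
        "n_dropped_snr": int((status == STATUS_DROPPED_SNR).sum()),
        "n_dropped_missing": int((status == STATUS_DROPPED_MISSING).sum()),
        "n_dropped_cv": int((status == STATUS_DROPPED_CV).sum()),
    }
    return out, QCReport(table=table, counts=counts)
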