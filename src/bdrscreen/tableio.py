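"""TSV interchange for every pipeline artifact.

All tables are tab-separated UTF-8 with a header row and "NA" for missing
values; floats are written with 12 significant digits so write -> read
round-trips to full practical precision.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .lcms import FeatureMatrix

FLOAT_FORMAT = "%.12g"
NA_REP = "NA"


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", na_rep=NA_REP, float_format=FLOAT_FORMAT, index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_REP], index_col=index_col)


# -- cohort -----------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    write_table(cohort, path)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return read_table(path)


# -- feature matrix ---------------------------------------------------------

def write_feature_matrix(fm: FeatureMatrix, features_path: str | Path,
                         injections_path: str | Path) -> None:
    """Features TSV: feature_id, optional snr, one column per injection id.
    Injections sidecar TSV: injection_id, injection_order, role, sample_id."""
    values = fm.values.copy()
    if fm.snr is not None:
        values.insert(0, "snr", fm.snr)
    values.index.name = "feature_id"
    write_table(values, features_path, index=True)
    inj = fm.injections.copy()
    inj.index.name = "injection_id"
    write_table(inj, injections_path, index=True)


def read_feature_matrix(features_path: str | Path,
                        injections_path: str | Path) -> FeatureMatrix:
    values = read_table(features_path, index_col="feature_id")
    snr = None
    if "snr" in values.columns:
        snr = values.pop("snr")
    injections = read_table(injections_path, index_col="injection_id")
    return FeatureMatrix(values, injections, snr)


# -- processed (study-only) feature values ----------------------------------

def write_processed_features(fm: FeatureMatrix, path: str | Path) -> None:
    """Analysis-ready matrix keyed by sample id (pools already dropped)."""
    frame = fm.study_frame()
    frame.index.name = "feature_id"
    write_table(frame, path, index=True)


def read_processed_features(path: str | Path) -> pd.DataFrame:
    return read_table(path, index_col="feature_id")


# -- simulation truth -------------------------------------------------------

def write_truth(truth, feature_path: str | Path, subject_path: str | Path) -> None:
    write_table(truth.feature_table, feature_path, index=True)
    subj = truth.subject_intercepts.to_frame("random_intercept")
    write_table(subj, subject_path, index=True)
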