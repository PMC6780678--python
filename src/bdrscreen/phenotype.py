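"""Bronchodilator response (BDR) phenotype computation and cohort assembly.

BDR is defined as (best post-bronchodilator FEV1 - pre-bronchodilator FEV1)
/ pre-bronchodilator FEV1, where "best" is the maximum over the recorded
post-bronchodilator maneuvers.  BDR is carried internally as a dimensionless
fraction (0.11, not 11%); reporting layers multiply by 100 for display.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, MissingDataError

logger = logging.getLogger(__name__)

#: Columns every long-format cohort table must provide.
REQUIRED_COLUMNS = (
    "subject_id",
    "visit",
    "age_years",
    "sex",
    "race",
    "clinic",
    "treatment",
    "pre_fev1_l",
    "post_fev1_l",
)

#: Separator for multiple post-bronchodilator maneuvers in one TSV cell.
MANEUVER_SEP = ";"


def compute_bdr(pre_fev1: float, post_fev1: Sequence[float]) -> float:
    """Bronchodilator response as a fraction of the pre-bronchodilator FEV1.

    Parameters
    ----------
    pre_fev1
        Pre-bronchodilator FEV1 in liters; must be positive.
    post_fev1
        One or more post-bronchodilator FEV1 maneuvers in liters; the best
        (maximum) maneuver is used.

    Returns
    -------
    float
        ``(max(post_fev1) - pre_fev1) / pre_fev1``.  Negative values are
        permitted (paradoxical response).
    """
    post = list(post_fev1)
    if len(post) == 0:
        raise MissingDataError("at least one post-bronchodilator maneuver is required")
    if not np.isfinite(pre_fev1) or pre_fev1 <= 0:
        raise DomainError(f"pre_fev1 must be positive, got {pre_fev1!r}")
    best = max(post)
    return (best - pre_fev1) / pre_fev1


def parse_maneuvers(cell: object) -> list[float]:
    """Parse a semicolon-joined post-FEV1 cell into a list of floats."""
    if isinstance(cell, (list, tuple, np.ndarray)):
        return [float(v) for v in cell]
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    text = str(cell).strip()
    if not text or text.upper() == "NA":
        return []
    return [float(part) for part in text.split(MANEUVER_SEP) if part.strip()]


def format_maneuvers(values: Sequence[float]) -> str:
    return MANEUVER_SEP.join(f"{v:.12g}" for v in values)


def assemble_cohort(samples: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Validate a long-format phenotype table and populate the BDR column.

    Rows lacking usable spirometry (non-positive pre-FEV1, no post maneuver)
    are excluded from the returned table with a logged reason; duplicate
    (subject, visit) pairs or missing required columns raise
    :class:`FormatError`.
    """
    if isinstance(samples, (str, Path)):
        samples = pd.read_csv(samples, sep="\t", na_values=["NA"], keep_default_na=True)
    df = samples.copy()

    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"cohort table is missing required column(s): {missing_cols}")

    dup = df.duplicated(subset=["subject_id", "visit"])
    if dup.any():
        pairs = df.loc[dup, ["subject_id", "visit"]].to_records(index=False).tolist()
        raise FormatError(f"duplicate (subject, visit) rows: {pairs[:5]}")

    bdr = np.full(len(df), np.nan)
    keep = np.ones(len(df), dtype=bool)
    for i, (pre, post_cell, age) in enumerate(
        zip(df["pre_fev1_l"], df["post_fev1_l"], df["age_years"])
    ):
        post = parse_maneuvers(post_cell)
        if pd.isna(age):
            keep[i] = False
            logger.warning("row %d excluded: missing age", i)
            continue
        try:
            bdr[i] = compute_bdr(float(pre), post) if pd.notna(pre) else np.nan
        except (DomainError, MissingDataError) as exc:
            keep[i] = False
            logger.warning("row %d excluded from modeling: %s", i, exc)
            continue
        if np.isnan(bdr[i]):
            keep[i] = False
            logger.warning("row %d excluded: no spirometry", i)

    df["bdr"] = bdr
    if "sample_id" not in df.columns:
        df["sample_id"] = pd.NA
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("assemble_cohort: excluded %d row(s) without usable spirometry", n_dropped)
    return df.loc[keep].reset_index(drop=True)
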