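"""Predicted BDR-versus-age curves at metabolite percentiles, plus plotting.

For a fitted interaction model, the predicted BDR at age a and metabolite
level m* is x(a, m*, profile)' beta-hat, a straight line in age with slope
beta_age + beta_int * m*.  Curves are evaluated at the 25th/50th/75th
empirical percentiles of the metabolite by default, with categorical
covariates held at their reference level (or at their sample mean via
``profile="mean"``).
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EstimabilityError
from .lmm import LMMFit, LMMSpec
from .screen import TERM_INTERACTION, TERM_METABOLITE

DEFAULT_PROBS = (0.25, 0.50, 0.75)


def percentile_levels(values: Sequence[float], probs: Sequence[float] = DEFAULT_PROBS) -> np.ndarray:
    """Empirical percentiles by linear interpolation between order statistics
    (numpy's ``linear`` convention: quantile q sits at index q*(n-1))."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise DomainError("cannot take percentiles of an empty vector")
    return np.quantile(v, probs, method="linear")


def predicted_curves(
    fit: LMMFit,
    spec: LMMSpec,
    feature_values: Sequence[float],
    age_range: tuple[float, float] = (5.0, 25.0),
    profile: str = "reference",
    probs: Sequence[float] = DEFAULT_PROBS,
    n_ages: int = 41,
    feature_id: str = "",
) -> pd.DataFrame:
    """Tidy grid of predicted BDR over age x metabolite-percentile.

    Parameters
    ----------
    fit, spec
        The fitted interaction model and the spec it was fitted on (the
        spec supplies column means for the ``"mean"`` covariate profile).
    feature_values
        The metabolite's preprocessed values in the fitting cohort, from
        which the percentile levels are taken.
    profile
        ``"reference"`` holds every categorical dummy at 0 (reference
        level); ``"mean"`` holds each design column at its sample mean
        (population-average profile).
    """
    if profile not in ("reference", "mean"):
        raise EstimabilityError(f"unknown covariate profile {profile!r}")
    cols = fit.columns
    for needed in ("age", TERM_METABOLITE, TERM_INTERACTION):
        if needed not in cols:
            raise EstimabilityError(f"fit lacks required term {needed!r}")
    levels = percentile_levels(feature_values, probs)
    ages = np.linspace(age_range[0], age_range[1], n_ages)

    base = np.zeros(len(cols))
    if profile == "reference":
        if "intercept" in cols:
            base[cols.index("intercept")] = 1.0
    else:
        base = spec.X.mean(axis=0).copy()
    i_age = cols.index("age")
    i_met = cols.index(TERM_METABOLITE)
    i_int = cols.index(TERM_INTERACTION)

    rows = []
    for prob, mstar in zip(probs, levels):
        for a in ages:
            x = base.copy()
            x[i_age] = a
            x[i_met] = mstar
            x[i_int] = a * mstar
            rows.append({
                "feature_id": feature_id,
                "percentile": int(round(100 * prob)),
                "metabolite_value": float(mstar),
                "age": float(a),
                "bdr_pred": float(x @ fit.beta),
                "profile": profile,
            })
    return pd.DataFrame(rows)


def age_slope(fit: LMMFit, metabolite_value: float) -> float:
    """d(predicted BDR)/d(age) at a fixed metabolite level:
    beta_age + beta_int * m*."""
    return fit.coef("age") + fit.coef(TERM_INTERACTION) * metabolite_value


# ---------------------------------------------------------------------------
# plotting (matplotlib, optional outputs)
# ---------------------------------------------------------------------------

def plot_effect_curves(grid: pd.DataFrame, path: str | None = None):
    """Line plot of predicted BDR vs age, one line per percentile."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for pctl, part in grid.groupby("percentile"):
        ax.plot(part["age"], 100 * part["bdr_pred"], label=f"{pctl}th pctl")
    ax.set_xlabel("Age (years)")
    ax.set_ylabel("Predicted BDR (%)")
    fid = grid["feature_id"].iloc[0] if len(grid) else ""
    ax.set_title(str(fid))
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_qq(qq: pd.DataFrame, path: str | None = None):
    """QQ plot of observed vs expected -log10 p with the identity line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(qq["expected_neglog10_p"], qq["observed_neglog10_p"], s=8, alpha=0.6)
    lim = max(qq["expected_neglog10_p"].max(), qq["observed_neglog10_p"].max())
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    ax.set_xlabel("Expected $-\\log_{10} p$")
    ax.set_ylabel("Observed $-\\log_{10} p$")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig
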