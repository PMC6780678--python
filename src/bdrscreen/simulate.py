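"""Synthetic longitudinal and cross-sectional asthma cohorts with an LC-MS layer.

The generator produces the statistical structure the downstream analysis
assumes: a long-format cohort table (subject, visit, age, categorical
covariates, spirometry, BDR), a raw metabolite feature x injection matrix
with pooled-reference injections, multiplicative injection-order drift and
missingness, and a ground-truth record for parameter-recovery tests.

Data-generating model for the bronchodilator response (a fraction):

    bdr = intercept + covariate effects + beta_age * age
          + sum over active features f of
              [ beta_metab * z_f + beta_int * (age - mean age) * z_f ]
          + subject intercept + residual

where z_f is the feature's metabolite level on the preprocessed
(log10 + pareto) scale.  Centering age inside the interaction term is a
pure reparameterization -- the interaction coefficient recovered by the
uncentered fitted model is still exactly ``beta_int_active`` -- but keeps
each active feature's variance contribution to BDR at a realistic
magnitude (~0.015 BDR units rather than ~0.05).

Pre-bronchodilator FEV1 is drawn log-normal around 2.0 L and the single
post maneuver is back-computed as pre * (1 + bdr), so `compute_bdr`
reproduces the latent BDR to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .lcms import ROLE_POOL, ROLE_STUDY, FeatureMatrix

__all__ = ["VisitSpec", "LcmsSpec", "SimConfig", "SimTruth",
           "simulate_cohort", "simulate_cross_sectional"]


@dataclass(frozen=True)
class VisitSpec:
    """One study visit: label, age distribution and sampling weight."""

    label: str
    age_mean: float
    age_sd: float
    weight: float = 1.0


@dataclass(frozen=True)
class LcmsSpec:
    """Parameters of the raw LC-MS layer.

    Peak areas are log-normal: a feature's clean study value is
    exp(loc_f + scale * z_latent) with loc_f ~ N(log_loc_mean, log_loc_sd).
    Drift is smooth and multiplicative, exp(a_f sin(2 pi o / period) + s o)
    with feature-specific amplitude a_f ~ U(0, drift_amplitude) and shared
    slope s; pooled references are injected after every ``pool_interval``
    study samples.  Missingness is value-independent (MCAR) on study
    values.  SNR is per-feature log-normal instrument metadata.
    """

    log_loc_mean: float = math.log(1.0e6)
    log_loc_sd: float = 1.0
    log_scale: float = 0.4
    drift_amplitude: float = 0.08
    drift_slope: float = 1e-4
    drift_period: float = 150.0
    pool_interval: int = 20
    missing_rate: float = 0.02
    snr_log_mean: float = math.log(40.0)
    snr_log_sd: float = 0.7
    tech_sigma: float = 0.05


def _camp_visits() -> tuple[VisitSpec, ...]:
    return (
        VisitSpec("baseline", 8.8, 2.1, 0.45),
        VisitSpec("end", 12.8, 2.2, 0.45),
        VisitSpec("followup", 16.8, 2.9, 0.10),
    )


def _camp_covariates() -> dict[str, dict[str, float]]:
    return {
        "sex": {"Male": 0.64, "Female": 0.36},
        "race": {"White": 0.705, "Black": 0.146, "Hispanic": 0.100, "Other": 0.049},
        "clinic": {f"clinic{i}": 0.125 for i in range(1, 9)},
        "treatment": {"budesonide": 0.27, "nedocromil": 0.305, "placebo": 0.425},
    }


@dataclass(frozen=True)
class SimConfig:
    """Complete configuration of one synthetic cohort."""

    n_subjects: int = 565
    visit_spec: tuple[VisitSpec, ...] = field(default_factory=_camp_visits)
    #: P(subject has 3, 2, 1 of the visits); longitudinal designs only.
    visit_pattern: tuple[float, ...] = (294 / 565, 265 / 565, 6 / 565)
    covariate_spec: dict[str, dict[str, float]] = field(default_factory=_camp_covariates)
    n_features: int = 500
    frac_active: float = 0.01
    beta_int_active: float = 0.004
    beta_age: float = -0.004
    beta_metab: float = 0.005
    covariate_betas: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"sex": {"Female": -0.005}, "treatment": {"placebo": 0.01}}
    )
    intercept: float = 0.145
    sigma_subject: float = 0.04
    sigma_resid: float = 0.07
    lcms: LcmsSpec = field(default_factory=LcmsSpec)
    #: explicit feature ids (met_0001, ...) to make active; overrides the
    #: random choice so the same drivers can be planted in two cohorts
    active_features: tuple[str, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise InvalidConfigError(f"n_subjects must be positive, got {self.n_subjects}")
        if self.n_features <= 0:
            raise InvalidConfigError(f"n_features must be positive, got {self.n_features}")
        if not 0.0 <= self.frac_active <= 1.0:
            raise InvalidConfigError("frac_active must lie in [0, 1]")
        if self.sigma_subject < 0 or self.sigma_resid < 0:
            raise InvalidConfigError("variance components must be nonnegative")
        if self.lcms.pool_interval < 1:
            raise InvalidConfigError("pool interval must be >= 1")
        if len(self.visit_spec) == 0:
            raise InvalidConfigError("at least one visit is required")
        for cov, freqs in self.covariate_spec.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-8:
                raise InvalidConfigError(f"frequencies for {cov!r} sum to {total}, not 1")
        k = len(self.visit_pattern)
        if k > len(self.visit_spec) or abs(sum(self.visit_pattern) - 1.0) > 1e-8:
            raise InvalidConfigError("visit_pattern must sum to 1 with <= n_visits entries")

    # -- canned study designs ---------------------------------------------
    @classmethod
    def camp_like(cls, **overrides) -> "SimConfig":
        """Three-visit longitudinal design mirroring the discovery cohort."""
        return replace(cls(), **overrides)

    @classmethod
    def gacrs_like(cls, **overrides) -> "SimConfig":
        """Single-visit cross-sectional design mirroring the replication
        cohort: 320 Hispanic children, mean age 9.1 y, mean BDR 5%."""
        base = cls(
            n_subjects=320,
            visit_spec=(VisitSpec("enrollment", 9.1, 1.8, 1.0),),
            visit_pattern=(1.0,),
            covariate_spec={
                "sex": {"Male": 0.60, "Female": 0.40},
                "race": {"Hispanic": 1.0},
                "clinic": {"sanjose": 1.0},
                "treatment": {"none": 1.0},
            },
            covariate_betas={"sex": {"Female": -0.005}},
            n_features=615,
            intercept=0.05 - (-0.004) * 9.1,
            sigma_subject=0.0,
            sigma_resid=0.07,
        )
        return replace(base, **overrides)


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort, for recovery tests."""

    feature_table: pd.DataFrame   # index feature_id: active, beta_int, snr, log_loc
    subject_intercepts: pd.Series  # index subject_id
    latent_scaled: pd.DataFrame   # preprocessed-scale metabolite, feature x sample
    age_center: float             # mean age used to center the interaction term


# ---------------------------------------------------------------------------


def _pareto_log10(raw: np.ndarray) -> np.ndarray:
    """log10 then pareto scale each row; mirrors the preprocessing transform."""
    logged = np.log10(raw)
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd == 0, np.nan, sd)
    return (logged - mean) / np.sqrt(sd)


def _simulate(config: SimConfig, longitudinal: bool) -> tuple[pd.DataFrame, FeatureMatrix, SimTruth]:
    config.validate()
    rng = np.random.default_rng(config.seed)
    lc = config.lcms
    n_sub, n_feat = config.n_subjects, config.n_features
    visits = config.visit_spec

    subject_ids = [f"S{i + 1:04d}" for i in range(n_sub)]

    # categorical covariates per subject
    cov_draws: dict[str, np.ndarray] = {}
    for cov, freqs in config.covariate_spec.items():
        levels = list(freqs.keys())
        probs = np.array([freqs[l] for l in levels], dtype=float)
        cov_draws[cov] = rng.choice(levels, size=n_sub, p=probs / probs.sum())

    # visit availability
    if longitudinal:
        counts = np.arange(len(config.visit_pattern), 0, -1)  # e.g. 3, 2, 1
        k_visits = rng.choice(counts, size=n_sub, p=np.asarray(config.visit_pattern))
    else:
        k_visits = np.ones(n_sub, dtype=int)
    weights = np.array([v.weight for v in visits], dtype=float)
    weights = weights / weights.sum()

    rows = []
    for i, sid in enumerate(subject_ids):
        chosen = rng.choice(len(visits), size=int(k_visits[i]), replace=False, p=weights)
        for vi in sorted(chosen):
            v = visits[vi]
            rows.append({
                "subject_id": sid,
                "visit": v.label,
                "age_years": rng.normal(v.age_mean, v.age_sd),
                **{cov: cov_draws[cov][i] for cov in config.covariate_spec},
            })
    cohort = pd.DataFrame(rows)
    n_samples = len(cohort)
    cohort["sample_id"] = [f"SMP{i + 1:05d}" for i in range(n_samples)]

    if longitudinal:
        b_subj = rng.normal(0.0, config.sigma_subject, size=n_sub)
        resid_sd = config.sigma_resid
    else:
        # single sample per subject: the subject effect is absorbed into the residual
        b_subj = np.zeros(n_sub)
        resid_sd = math.hypot(config.sigma_subject, config.sigma_resid)
    subj_index = {sid: i for i, sid in enumerate(subject_ids)}

    # features and latent metabolite levels
    feature_ids = [f"met_{j + 1:04d}" for j in range(n_feat)]
    loc_f = rng.normal(lc.log_loc_mean, lc.log_loc_sd, size=n_feat)
    if config.active_features is not None:
        id_pos = {fid: j for j, fid in enumerate(feature_ids)}
        try:
            active_idx = np.array([id_pos[f] for f in config.active_features], dtype=int)
        except KeyError as exc:
            raise InvalidConfigError(f"unknown active feature id: {exc}") from exc
    else:
        n_active = int(round(config.frac_active * n_feat))
        active_idx = (rng.choice(n_feat, size=n_active, replace=False)
                      if n_active else np.array([], dtype=int))
    active = np.zeros(n_feat, dtype=bool)
    active[active_idx] = True
    snr = rng.lognormal(lc.snr_log_mean, lc.snr_log_sd, size=n_feat)

    latent = rng.standard_normal((n_feat, n_samples))
    clean_study = np.exp(loc_f[:, None] + lc.log_scale * latent)
    if n_samples >= 2:
        z = _pareto_log10(clean_study)
    else:
        z = np.zeros_like(clean_study)

    # bronchodilator response
    age = cohort["age_years"].to_numpy()
    age_center = float(age.mean())
    bdr = np.full(n_samples, config.intercept, dtype=float)
    bdr += config.beta_age * age
    for cov, betas in config.covariate_betas.items():
        vals = cohort[cov].to_numpy()
        for level, beta in betas.items():
            bdr += beta * (vals == level)
    for j in active_idx:
        bdr += config.beta_metab * z[j] + config.beta_int_active * (age - age_center) * z[j]
    bdr += np.array([b_subj[subj_index[s]] for s in cohort["subject_id"]])
    bdr += rng.normal(0.0, resid_sd, size=n_samples)

    pre = rng.lognormal(math.log(2.0), 0.15, size=n_samples)
    post = pre * (1.0 + bdr)
    cohort["pre_fev1_l"] = pre
    cohort["post_fev1_l"] = [f"{v:.17g}" for v in post]
    cohort["bdr"] = bdr

    # injection queue: study samples in randomized order, a pooled reference
    # after every `pool_interval` study injections
    study_perm = rng.permutation(n_samples)
    inj_rows = []
    n_pools = 0
    for k, sample_pos in enumerate(study_perm, start=1):
        inj_rows.append((ROLE_STUDY, cohort["sample_id"].iloc[sample_pos], sample_pos))
        if k % lc.pool_interval == 0:
            n_pools += 1
            inj_rows.append((ROLE_POOL, None, -1))
    inj_ids = [f"I{k + 1:05d}" for k in range(len(inj_rows))]
    injections = pd.DataFrame(
        {
            "injection_order": np.arange(1, len(inj_rows) + 1),
            "role": [r[0] for r in inj_rows],
            "sample_id": [r[1] for r in inj_rows],
        },
        index=pd.Index(inj_ids, name="injection_id"),
    )

    # raw peak areas with drift + technical noise
    n_inj = len(inj_rows)
    clean = np.empty((n_feat, n_inj))
    study_cols = []
    for c, (role, _, sample_pos) in enumerate(inj_rows):
        if role == ROLE_STUDY:
            clean[:, c] = clean_study[:, sample_pos]
            study_cols.append(c)
        else:
            clean[:, c] = np.exp(loc_f)  # pool = population-average material

    orders = injections["injection_order"].to_numpy()
    amp = rng.uniform(0.0, lc.drift_amplitude, size=n_feat)
    # slope enters scaled by the feature amplitude so drift_amplitude = 0
    # switches the drift layer off entirely
    drift = np.exp(
        amp[:, None]
        * (np.sin(2 * np.pi * orders[None, :] / lc.drift_period)
           + lc.drift_slope * orders[None, :])
    )
    tech = (
        np.exp(rng.normal(0.0, lc.tech_sigma, size=(n_feat, n_inj)))
        if lc.tech_sigma > 0
        else 1.0
    )
    raw = clean * drift * tech

    if lc.missing_rate > 0:
        mask = rng.random((n_feat, len(study_cols))) < lc.missing_rate
        raw[:, study_cols] = np.where(mask, np.nan, raw[:, study_cols])

    values = pd.DataFrame(raw, index=pd.Index(feature_ids, name="feature_id"),
                          columns=injections.index)
    fm = FeatureMatrix(values, injections, pd.Series(snr, index=feature_ids, name="snr"))

    truth = SimTruth(
        feature_table=pd.DataFrame(
            {
                "active": active,
                "beta_int": np.where(active, config.beta_int_active, 0.0),
                "snr": snr,
                "log_loc": loc_f,
            },
            index=pd.Index(feature_ids, name="feature_id"),
        ),
        subject_intercepts=pd.Series(b_subj, index=pd.Index(subject_ids, name="subject_id")),
        latent_scaled=pd.DataFrame(z, index=feature_ids, columns=cohort["sample_id"]),
        age_center=age_center,
    )
    return cohort, fm, truth


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, FeatureMatrix, SimTruth]:
    """Simulate a longitudinal (repeated-measures) cohort.

    Identical config (including seed) yields bit-identical outputs.
    """
    return _simulate(config, longitudinal=True)


def simulate_cross_sectional(config: SimConfig) -> tuple[pd.DataFrame, FeatureMatrix, SimTruth]:
    """Simulate a single-visit cohort (one sample per subject; the subject
    random effect is absorbed into the residual)."""
    if len(config.visit_spec) != 1:
        raise InvalidConfigError(
            f"cross-sectional design requires exactly one visit, got {len(config.visit_spec)}"
        )
    return _simulate(config, longitudinal=False)
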