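"""Normative limits for dark-adaptation outcomes from healthy volunteers.

For each outcome (CT, FT, RIT) a linear mixed-effects model is fitted to
the healthy cohort:

    outcome ~ intercept + age_decades + eccentricity (categorical, 2 deg ref)
              + subject random intercept + residual

by REML (statsmodels ``MixedLM``).  A 95% prediction interval for a *new*
subject at a *new* locus has half-width

    z(0.975) * sqrt(between_subject_var + residual_var)

around the fixed-effect prediction.  Observed outcomes of test eyes are
then expressed relative to these normative limits: thresholds as
``predicted - observed`` (negative = sensitivity loss) and RIT as the
delay ``observed - predicted`` (positive = slowed rod recovery); a locus
is flagged abnormal when the observation falls outside the interval.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import norm

from .exceptions import (
    ConfigurationError,
    DegenerateDesignError,
    InsufficientDataError,
    StateError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NormativeModel",
    "fit_normative_model",
    "predict_interval",
    "compute_deviations",
    "OUTCOME_NAMES",
]

OUTCOME_NAMES = ("CT", "FT", "RIT")

#: Eccentricity used as the categorical reference level, degrees.
REF_ECC = 2.0


@dataclass
class NormativeModel:
    """Fitted age/eccentricity normative model for one outcome.

    ``age_slope`` is per decade of age.  ``ecc_offsets`` maps each
    non-reference eccentricity (as float degrees) to its additive offset
    relative to the 2-degree reference.  Variance components are SDs.
    """

    outcome_name: str
    intercept: float = np.nan
    age_slope: float = np.nan
    ecc_offsets: dict = field(default_factory=dict)
    between_sd: float = np.nan
    residual_sd: float = np.nan
    n_subjects: int = 0
    n_loci: int = 0
    age_range: tuple = (np.nan, np.nan)
    age_slope_se: float = np.nan
    backend: str = "reml"
    fitted: bool = False

    def to_dict(self) -> dict:
        d = {
            "outcome_name": self.outcome_name,
            "intercept": self.intercept,
            "age_slope": self.age_slope,
            "ecc_offsets": {str(k): v for k, v in self.ecc_offsets.items()},
            "between_sd": self.between_sd,
            "residual_sd": self.residual_sd,
            "n_subjects": self.n_subjects,
            "n_loci": self.n_loci,
            "age_range": list(self.age_range),
            "age_slope_se": self.age_slope_se,
            "backend": self.backend,
            "fitted": self.fitted,
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeModel":
        d = dict(d)
        d["ecc_offsets"] = {float(k): float(v) for k, v in d.get("ecc_offsets", {}).items()}
        d["age_range"] = tuple(d.get("age_range", (np.nan, np.nan)))
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "NormativeModel":
        return cls.from_dict(json.loads(s))


def fit_normative_model(
    healthy_outcomes: pd.DataFrame,
    outcome_name: str,
    exclude_censored: bool = False,
) -> NormativeModel:
    """Fit the healthy-cohort mixed model for one outcome by REML.

    Parameters
    ----------
    healthy_outcomes : DataFrame
        One row per locus with columns ``subject_id, age,
        eccentricity_deg`` and the outcome column.  At least 10 subjects.
    outcome_name : {"CT", "FT", "RIT"}
    exclude_censored : bool
        Drop censored RIT rows (``rit_censored``) from the normative fit.
        Censored values are rare in healthy eyes and are included
        untransformed by default, matching how the recorded value is used
        downstream.

    Notes
    -----
    Age enters in decades for numerical conditioning.  If the data hold a
    single eccentricity the categorical term is dropped and the model
    remains valid for that stratum.  An exactly collinear or variation-free
    design raises :class:`DegenerateDesignError`.  In the zero-noise limit
    the mixed model is singular; the fit then falls back to exact OLS with
    null variance components.
    """
    if outcome_name not in healthy_outcomes.columns:
        raise ConfigurationError(f"outcome column {outcome_name!r} missing")
    df = healthy_outcomes.copy()
    if exclude_censored and outcome_name == "RIT" and "rit_censored" in df.columns:
        df = df[~df["rit_censored"].astype(bool)]
    df = df.dropna(subset=[outcome_name, "age", "eccentricity_deg", "subject_id"])
    n_subj = df["subject_id"].nunique()
    if n_subj < 10:
        raise InsufficientDataError(
            f"normative fit needs >= 10 healthy subjects, got {n_subj}"
        )
    df["age_dec"] = df["age"].astype(float) / 10.0
    df["ecc"] = df["eccentricity_deg"].astype(float)
    ecc_levels = sorted(df["ecc"].unique())
    multi_ecc = len(ecc_levels) > 1

    if df["age_dec"].nunique() == 1 and not multi_ecc:
        raise DegenerateDesignError(
            "constant age and a single eccentricity: fixed effects unidentifiable"
        )

    formula = f"{outcome_name} ~ age_dec"
    if multi_ecc:
        formula += " + C(ecc, Treatment(reference=%r))" % REF_ECC

    model = NormativeModel(outcome_name=outcome_name)
    model.n_subjects = int(n_subj)
    model.n_loci = int(len(df))
    model.age_range = (float(df["age"].min()), float(df["age"].max()))

    # zero-noise guard: if OLS interpolates exactly, variance components are
    # null and MixedLM would be singular
    ols = smf.ols(formula, data=df).fit()
    if float(np.var(ols.resid)) < 1e-18:
        _store_fixed(model, ols.params, ecc_levels, multi_ecc)
        model.age_slope_se = float(ols.bse.get("age_dec", np.nan))
        model.between_sd = 0.0
        model.residual_sd = 0.0
        model.fitted = True
        return model

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mlm = smf.mixedlm(formula, data=df, groups=df["subject_id"])
        try:
            res = mlm.fit(reml=True)
        except Exception as exc:  # singular fits fall back to OLS
            logger.warning("MixedLM failed (%s); falling back to OLS", exc)
            res = None

    if res is None:
        _store_fixed(model, ols.params, ecc_levels, multi_ecc)
        model.age_slope_se = float(ols.bse.get("age_dec", np.nan))
        model.between_sd = 0.0
        model.residual_sd = float(np.std(ols.resid, ddof=int(ols.df_model) + 1))
    else:
        _store_fixed(model, res.fe_params, ecc_levels, multi_ecc)
        model.age_slope_se = float(res.bse_fe.get("age_dec", np.nan))
        model.between_sd = float(np.sqrt(max(res.cov_re.iloc[0, 0], 0.0)))
        model.residual_sd = float(np.sqrt(max(res.scale, 0.0)))
    model.fitted = True
    return model


def _store_fixed(model: NormativeModel, params: pd.Series, ecc_levels, multi_ecc):
    model.intercept = float(params["Intercept"])
    model.age_slope = float(params.get("age_dec", 0.0))
    offsets = {}
    if multi_ecc:
        for ecc in ecc_levels:
            if ecc == REF_ECC:
                continue
            key = f"C(ecc, Treatment(reference={REF_ECC!r}))[T.{ecc}]"
            if key in params.index:
                offsets[float(ecc)] = float(params[key])
    model.ecc_offsets = offsets


def predict_interval(
    model: NormativeModel,
    age: float,
    eccentricity_deg: float,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Normative prediction interval for a new subject at a new locus.

    Returns ``(pi_low, predicted_median, pi_high)``.  The median is the
    fixed-effect prediction; the half-width combines between-subject and
    residual variability at the requested coverage.  Ages more than 10
    years outside the training range trigger an extrapolation warning log.
    """
    if not model.fitted:
        raise StateError("normative model is not fitted")
    lo_age, hi_age = model.age_range
    if np.isfinite(lo_age) and (age < lo_age - 10 or age > hi_age + 10):
        logger.warning(
            "age %.1f extrapolates beyond training range [%.1f, %.1f]",
            age,
            lo_age,
            hi_age,
        )
    ecc = float(eccentricity_deg)
    offset = 0.0 if ecc == REF_ECC else model.ecc_offsets.get(ecc, 0.0)
    if ecc != REF_ECC and ecc not in model.ecc_offsets and model.ecc_offsets:
        logger.warning("eccentricity %s not in training data; using reference level", ecc)
    median = model.intercept + model.age_slope * (age / 10.0) + offset
    z = norm.ppf(0.5 + level / 2.0)
    half = z * float(np.sqrt(model.between_sd**2 + model.residual_sd**2))
    return median - half, median, median + half


def compute_deviations(
    outcomes: pd.DataFrame,
    models: dict,
    level: float = 0.95,
) -> pd.DataFrame:
    """Express observed outcomes relative to normative limits.

    Parameters
    ----------
    outcomes : DataFrame
        Locus outcomes (any mix of groups) with columns ``subject_id, age,
        eccentricity_deg, CT, FT, RIT`` and optionally ``rit_censored``.
    models : dict
        Mapping outcome name -> fitted :class:`NormativeModel`; every
        outcome present in ``models`` is evaluated.

    Returns
    -------
    DataFrame
        One row per subject x eccentricity x outcome with observed value,
        predicted median, interval bounds, signed deviation, abnormality
        flag and censoring flag.  Deviation signs: thresholds use
        ``predicted - observed`` (negative = loss), RIT uses ``observed -
        predicted`` (positive = delay; a censored 60 yields a lower bound
        on the true delay).
    """
    for name in models:
        m = models[name]
        if not isinstance(m, NormativeModel) or not m.fitted:
            raise ConfigurationError(f"model for outcome {name!r} missing or unfitted")
    rows = []
    for _, rec in outcomes.iterrows():
        for name, model in models.items():
            if name not in rec or pd.isna(rec[name]):
                continue
            observed = float(rec[name])
            lo, med, hi = predict_interval(
                model, float(rec["age"]), float(rec["eccentricity_deg"]), level
            )
            if name == "RIT":
                deviation = observed - med
                censored = bool(rec.get("rit_censored", False))
            else:
                deviation = med - observed
                censored = False
            rows.append(
                {
                    "subject_id": rec["subject_id"],
                    "group": rec.get("group", ""),
                    "age": float(rec["age"]),
                    "eccentricity_deg": float(rec["eccentricity_deg"]),
                    "outcome_name": name,
                    "observed": observed,
                    "predicted_median": med,
                    "pi_low": lo,
                    "pi_high": hi,
                    "deviation": deviation,
                    "abnormal": bool(observed < lo or observed > hi),
                    "censored": censored,
                }
            )
    return pd.DataFrame(rows)
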