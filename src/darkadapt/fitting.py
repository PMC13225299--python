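"""From raw staircase presentations to per-locus dark-adaptation outcomes.

The measurement chain implemented here is:

1. :func:`extract_threshold_points` — every *seen* presentation of the
   5-up/1-down staircase yields one timestamped threshold datum, converted
   from instrument dB attenuation to logUnits with :func:`db_to_log`.
2. :func:`detect_rod_function` — rod-mediated detection of the cyan
   (505 nm) stimulus implies late-session separation between cyan and red
   (627 nm) thresholds; absence of separation marks a locus with no
   measurable cone–rod break.
3. :func:`fit_curve` — the biphasic curve is fitted to the cyan points by
   penalized maximum likelihood (truncated-normal priors over a broad
   physiological box) or by MCMC.
4. :func:`derive_outcome` — cone threshold (CT), final rod threshold (FT)
   and rod intercept time (RIT, censored at 60 min) for the locus; loci
   without rod function are assigned a cone-mediated FT (= CT) and a
   censored RIT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import (
    DomainError,
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
    RangeError,
)
from .model import (
    RIT_CRITERION,
    SESSION_CAP_MIN,
    DACurveParams,
    evaluate_curve,
    rod_intercept_time,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DB_MAX",
    "db_to_log",
    "extract_threshold_points",
    "detect_rod_function",
    "ParameterBox",
    "DEFAULT_BOX",
    "FitSummary",
    "fit_curve",
    "LocusOutcome",
    "derive_outcome",
    "fit_locus",
    "fit_all_loci",
]

#: Instrument dynamic range, dB attenuation from the device maximum.
DB_MAX: float = 36.0

#: Default calibration constant: logUnits at 0 dB attenuation.
CAL_CONST: float = 2.0

PRESENTATION_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "eccentricity_deg",
    "color",
    "t_min",
    "level_db",
    "seen",
]


def db_to_log(level_db, cal_const: float = CAL_CONST):
    """Convert stimulus attenuation (dB) to log-threshold units.

    10 dB of attenuation is one log unit down from the device maximum, so
    ``threshold = cal_const - level_db / 10``.  The instrument plots "log
    threshold"; the calibration constant anchors 0 dB at ``cal_const``
    logUnits (2.0 by default), placing the 36 dB floor at -1.6 logUnits —
    just below the -1.4 RIT criterion, so the criterion is measurable
    within the dynamic range.
    """
    arr = np.asarray(level_db, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > DB_MAX):
        raise RangeError(f"level_db outside [0, {DB_MAX}]: {level_db!r}")
    out = cal_const - arr / 10.0
    return float(out) if np.ndim(level_db) == 0 else out


def extract_threshold_points(
    presentations: pd.DataFrame, cal_const: float = CAL_CONST
) -> pd.DataFrame:
    """One threshold point per *seen* presentation.

    The 5-up/1-down staircase yields a threshold datum at each seen
    response, timestamped at that presentation; misses carry no threshold
    information on their own and contribute no point.

    Parameters
    ----------
    presentations : DataFrame
        Columns ``eccentricity_deg, color, t_min, level_db, seen`` (extra
        columns pass through).  Expected sorted by ``t_min``; unsorted
        input is sorted internally with a warning.

    Returns
    -------
    DataFrame
        Columns ``eccentricity_deg, color, t_min, threshold, at_floor``.
        ``at_floor`` flags points at the instrument's 36 dB floor, whose
        thresholds are left-censored by the dynamic range.
    """
    cols = ["eccentricity_deg", "color", "t_min", "threshold", "at_floor"]
    if len(presentations) == 0:
        return pd.DataFrame(columns=cols)
    df = presentations
    if not df["t_min"].is_monotonic_increasing:
        logger.warning("presentations not sorted by t_min; sorting internally")
        df = df.sort_values("t_min", kind="stable")
    seen = df[df["seen"].astype(bool)]
    out = pd.DataFrame(
        {
            "eccentricity_deg": seen["eccentricity_deg"].to_numpy(),
            "color": seen["color"].to_numpy(),
            "t_min": seen["t_min"].to_numpy(dtype=float),
            "threshold": db_to_log(seen["level_db"].to_numpy(dtype=float), cal_const),
            "at_floor": seen["level_db"].to_numpy(dtype=float) >= DB_MAX,
        }
    )
    return out.reset_index(drop=True)


def detect_rod_function(
    cyan_points: pd.DataFrame,
    red_points: pd.DataFrame,
    margin: float = 0.3,
    window: float = 10.0,
) -> bool:
    """Decide whether a locus shows rod-mediated (cyan) detection.

    True iff, over the final ``window`` minutes of the session, the median
    cyan threshold lies more than ``margin`` logUnits *below* the median
    red threshold.  Rods do not detect the 627 nm stimulus at these light
    levels, so cyan–red separation late in the session is the signature of
    a cone–rod break; without separation the locus is treated as
    cone-mediated throughout.  Degenerate inputs (either list empty in the
    window) return False.
    """
    if len(cyan_points) == 0 or len(red_points) == 0:
        logger.warning("empty cyan or red point list; cannot establish separation")
        return False
    t_end = max(cyan_points["t_min"].max(), red_points["t_min"].max())
    t_cut = t_end - window
    cyan_w = cyan_points.loc[cyan_points["t_min"] >= t_cut, "threshold"]
    red_w = red_points.loc[red_points["t_min"] >= t_cut, "threshold"]
    if len(cyan_w) == 0 or len(red_w) == 0:
        return False
    return float(cyan_w.median()) < float(red_w.median()) - margin


# ---------------------------------------------------------------------------
# Curve fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterBox:
    """Physiological parameter box used as bounds and prior support.

    Priors are truncated normals centered mid-box with SD equal to the box
    half-width — broad enough to constrain fits to realistic limits
    without meaningfully influencing well-determined solutions.  ``t0`` and
    ``tf`` have data-dependent boxes ``[ct, t0_max]`` and ``[tf_min, ct]``.
    """

    ct: tuple = (-1.5, 1.5)
    t0_max: float = 4.5
    tau: tuple = (1e-3, 10.0)
    S2: tuple = (-1.0, -0.01)
    CRB: tuple = (1.0, 45.0)
    tf_min: float = -3.5


DEFAULT_BOX = ParameterBox()

# internal optimization coordinates: (ct, d0, tau, S2, CRB, df) with
# t0 = ct + d0 and tf = ct - df, so the order constraints are box bounds
_X_LO = np.array([-1.5, 0.0, 1e-3, -1.0, 1.0, 0.0])
_X_HI = np.array([1.5, 6.0, 10.0, -0.01, 45.0, 5.0])


def _x_to_params(x) -> DACurveParams:
    ct, d0, tau, s2, crb, df = x
    return DACurveParams(
        ct=float(ct),
        t0=float(ct + d0),
        tau=float(tau),
        S2=float(s2),
        CRB=float(crb),
        tf=float(ct - df),
    )


def _prior_residuals(x, box: ParameterBox, sigma: float) -> np.ndarray:
    """Truncated-normal log-prior expressed as pseudo-residuals.

    Each natural parameter contributes ``sigma * (theta - mid) / halfwidth``
    so that the summed squared residuals divided by ``2 sigma**2`` equal the
    Gaussian prior exponent with SD = box half-width.  Soft barriers keep
    ``t0`` and ``tf`` inside their absolute caps.
    """
    ct, d0, tau, s2, crb, df = x
    t0 = ct + d0
    tf = ct - df
    res = []
    for val, (lo, hi) in (
        (ct, box.ct),
        (t0, (ct, box.t0_max)),
        (tau, box.tau),
        (s2, box.S2),
        (crb, box.CRB),
        (tf, (box.tf_min, ct)),
    ):
        mid = 0.5 * (lo + hi)
        hw = max(0.5 * (hi - lo), 1e-6)
        res.append(sigma * (val - mid) / hw)
    # barriers for the absolute caps not representable as fixed box bounds
    res.append(10.0 * max(0.0, t0 - box.t0_max))
    res.append(10.0 * max(0.0, box.tf_min - tf))
    return np.asarray(res)


def _heuristic_starts(t: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Data-driven initial guesses in optimization coordinates."""
    y_min, y_max = float(np.min(y)), float(np.max(y))
    late = y[t >= np.percentile(t, 70)]
    tf0 = float(np.median(late)) if late.size else y_min
    # cone plateau: middle of the observed range unless the series is flat
    ct0 = np.clip(float(np.median(y[(t > 3) & (t < 14)])) if np.any((t > 3) & (t < 14)) else y_max, -1.5, 1.5)
    starts = []
    for crb0 in (8.0, 14.0, 22.0):
        d00 = np.clip(y_max - ct0 + 0.5, 0.0, 6.0)
        df0 = np.clip(ct0 - tf0, 0.0, 5.0)
        starts.append(np.array([ct0, d00, 1.0, -0.24, crb0, max(df0, 0.2)]))
    return starts


@dataclass
class FitSummary:
    """Point estimate metadata and per-parameter uncertainty for one fit."""

    mode: str
    seed: int
    n_points: int
    residual_sd: float
    param_sd: dict = field(default_factory=dict)
    n_starts: int = 0
    cost: float = float("nan")
    converged: bool = True


def _objective_factory(t, y, box, sigma):
    def resid(x):
        params = _x_to_params(x)
        r = y - evaluate_curve(params, t)
        return np.concatenate([r, _prior_residuals(x, box, sigma)])

    return resid


def _map_fit(t, y, box, seed, n_starts):
    rng = np.random.default_rng(seed)
    starts = _heuristic_starts(t, y)
    while len(starts) < n_starts:
        starts.append(_X_LO + rng.random(6) * (_X_HI - _X_LO))
    sigma = 0.1  # provisional noise scale; profiled below
    best = None
    for x0 in starts:
        x0 = np.clip(x0, _X_LO + 1e-9, _X_HI - 1e-9)
        try:
            sol = least_squares(
                _objective_factory(t, y, box, sigma),
                x0,
                bounds=(_X_LO, _X_HI),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=4000,
            )
        except Exception:  # singular jacobian etc.; try next start
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitFailureError("all optimizer starts failed", {"n_starts": n_starts})
    # profile sigma: re-estimate the noise SD from data residuals and refit
    # once so the prior weight matches the likelihood scale; floored so the
    # noiseless limit reduces to interpolation
    n = len(t)
    for _ in range(2):
        data_res = best.fun[:n]
        sigma = max(float(np.sqrt(np.mean(data_res**2))), 1e-3)
        sol = least_squares(
            _objective_factory(t, y, box, sigma),
            best.x,
            bounds=(_X_LO, _X_HI),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=4000,
        )
        if sol.cost <= best.cost or True:
            best = sol
    return best, sigma


def _laplace_sd(best, n):
    """Approximate per-parameter SDs from the Gauss-Newton Hessian."""
    try:
        J = best.jac
        cov = np.linalg.pinv(J.T @ J)
        sd = np.sqrt(np.clip(np.diag(cov), 0, None))
        data_res = best.fun[:n]
        s = np.sqrt(np.mean(data_res**2)) if n else 1.0
        return sd * max(s, 1e-3)
    except Exception:
        return np.full(6, np.nan)


def _log_posterior_factory(t, y, box):
    def log_post(theta):
        x, log_sigma = theta[:6], theta[6]
        if np.any(x < _X_LO) or np.any(x > _X_HI) or not (-4.0 < log_sigma < 0.7):
            return -np.inf
        sigma = np.exp(log_sigma)
        params = _x_to_params(x)
        r = y - evaluate_curve(params, t)
        loglik = -len(t) * log_sigma - 0.5 * np.sum(r**2) / sigma**2
        pr = _prior_residuals(x, box, 1.0)
        logprior = -0.5 * np.sum(pr**2)
        return loglik + logprior

    return log_post


def _mcmc_fit(t, y, box, seed, n_walkers=32, n_steps=1200, n_burn=400):
    import emcee

    best, sigma = _map_fit(t, y, box, seed, n_starts=10)
    rng = np.random.default_rng(seed + 1)
    center = np.concatenate([best.x, [np.log(max(sigma, 1e-2))]])
    p0 = center + 1e-3 * rng.standard_normal((n_walkers, 7))
    p0[:, :6] = np.clip(p0[:, :6], _X_LO + 1e-9, _X_HI - 1e-9)
    p0[:, 6] = np.clip(p0[:, 6], -3.9, 0.6)
    sampler = emcee.EnsembleSampler(n_walkers, 7, _log_posterior_factory(t, y, box))
    state = sampler.run_mcmc(p0, n_steps, progress=False, rstate0=None, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=n_burn, flat=True)
    med = np.median(chain[:, :6], axis=0)
    sd = np.std(chain[:, :6], axis=0)
    # project the componentwise median back into the constraint set
    med = np.clip(med, _X_LO, _X_HI)
    return med, sd, float(np.exp(np.median(chain[:, 6])))


def fit_curve(
    points: pd.DataFrame,
    box: ParameterBox = DEFAULT_BOX,
    mode: str = "map_penalized",
    seed: int = 0,
    n_starts: int = 12,
) -> tuple[DACurveParams, FitSummary]:
    """Fit the biphasic curve to cyan threshold points.

    Parameters
    ----------
    points : DataFrame
        Cyan threshold points with columns ``t_min`` and ``threshold``;
        at least 8 points spanning at least 15 minutes.
    box : ParameterBox
        Bounds and prior support; identical for every locus.
    mode : {"map_penalized", "mcmc"}
        ``map_penalized`` maximizes the Gaussian likelihood times the
        truncated-normal priors by seeded multistart bounded least squares
        (best objective wins); ``mcmc`` samples the same posterior with an
        affine-invariant ensemble sampler and reports posterior medians.
    seed : int
        Seed for start placement / sampler initialization.

    Returns
    -------
    (DACurveParams, FitSummary)
        Point estimate and per-parameter uncertainty summary.
    """
    t = np.asarray(points["t_min"], dtype=float)
    y = np.asarray(points["threshold"], dtype=float)
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    if len(t) < 8 or (len(t) and (t.max() - t.min()) < 15.0):
        raise InsufficientDataError(
            f"need >= 8 cyan points spanning >= 15 min, got {len(t)} points "
            f"spanning {0.0 if len(t) == 0 else t.max() - t.min():.1f} min"
        )
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise InvalidInputError("non-finite threshold point")

    if mode == "map_penalized":
        best, sigma = _map_fit(t, y, box, seed, n_starts)
        params = _x_to_params(best.x)
        sd = _laplace_sd(best, len(t))
        resid = y - evaluate_curve(params, t)
        summary = FitSummary(
            mode=mode,
            seed=seed,
            n_points=len(t),
            residual_sd=float(np.sqrt(np.mean(resid**2))),
            param_sd=dict(zip(("ct", "d0", "tau", "S2", "CRB", "df"), sd)),
            n_starts=n_starts,
            cost=float(best.cost),
            converged=bool(best.success),
        )
        return params, summary
    elif mode == "mcmc":
        med, sd, sigma = _mcmc_fit(t, y, box, seed)
        params = _x_to_params(med)
        resid = y - evaluate_curve(params, t)
        summary = FitSummary(
            mode=mode,
            seed=seed,
            n_points=len(t),
            residual_sd=float(np.sqrt(np.mean(resid**2))),
            param_sd=dict(zip(("ct", "d0", "tau", "S2", "CRB", "df"), sd)),
        )
        return params, summary
    raise InvalidInputError(f"unknown fit mode {mode!r}")


# ---------------------------------------------------------------------------
# Locus outcomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusOutcome:
    """Derived dark-adaptation outcomes for one locus of one eye."""

    subject_id: str
    eccentricity_deg: float
    CT: float
    FT: float
    RIT: float
    rit_censored: bool
    rod_function_present: bool
    fit_quality: float

    def __post_init__(self):
        if not self.rod_function_present:
            if not (self.rit_censored and self.RIT == SESSION_CAP_MIN and self.FT == self.CT):
                raise InvalidInputError(
                    "locus without rod function must have censored RIT at session "
                    "cap and cone-mediated FT (= CT)"
                )


def derive_outcome(
    fit: DACurveParams,
    rod_function: bool,
    subject_id: str = "",
    eccentricity_deg: float = np.nan,
    fit_quality: float = np.nan,
    criterion: float = RIT_CRITERION,
    t_max: float = SESSION_CAP_MIN,
) -> LocusOutcome:
    """Combine a curve fit with the rod-function decision into a LocusOutcome.

    Without rod function the FT is cone-mediated (FT = CT) and RIT is
    recorded as the censored session cap; otherwise FT is the fitted rod
    plateau and RIT comes from :func:`rod_intercept_time` (still censored
    when the rod plateau never crosses the criterion).
    """
    ct = fit.ct
    if rod_function:
        res = rod_intercept_time(fit, criterion=criterion, t_max=t_max)
        return LocusOutcome(
            subject_id, eccentricity_deg, ct, fit.tf, res.rit, res.censored, True, fit_quality
        )
    return LocusOutcome(
        subject_id, eccentricity_deg, ct, ct, t_max, True, False, fit_quality
    )


def fit_locus(
    presentations: pd.DataFrame,
    mode: str = "map_penalized",
    seed: int = 0,
    cal_const: float = CAL_CONST,
    criterion: float = RIT_CRITERION,
    t_max: float = SESSION_CAP_MIN,
    margin: float = 0.3,
    window: float = 10.0,
) -> LocusOutcome:
    """Full per-locus chain: extract points, detect rod function, fit, derive."""
    points = extract_threshold_points(presentations, cal_const)
    cyan = points[points["color"] == "cyan505"]
    red = points[points["color"] == "red627"]
    rod = detect_rod_function(cyan, red, margin=margin, window=window)
    params, summary = fit_curve(cyan, mode=mode, seed=seed)
    sid = str(presentations["subject_id"].iloc[0]) if "subject_id" in presentations else ""
    ecc = float(presentations["eccentricity_deg"].iloc[0])
    return derive_outcome(
        params,
        rod,
        subject_id=sid,
        eccentricity_deg=ecc,
        fit_quality=summary.residual_sd,
        criterion=criterion,
        t_max=t_max,
    )


def fit_all_loci(
    presentations: pd.DataFrame,
    mode: str = "map_penalized",
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Fit every (subject, eccentricity) locus in a presentations table.

    Returns one row per locus with LocusOutcome fields plus the subject's
    group and age carried through for downstream modeling.  Loci whose fit
    fails are logged and skipped.
    """
    rows = []
    for i, ((sid, ecc), grp) in enumerate(
        presentations.groupby(["subject_id", "eccentricity_deg"], sort=True)
    ):
        try:
            out = fit_locus(grp, mode=mode, seed=seed + i, **kwargs)
        except (InsufficientDataError, FitFailureError, DomainError) as exc:
            logger.warning("skipping locus (%s, %s): %s", sid, ecc, exc)
            continue
        rows.append(
            {
                "subject_id": out.subject_id,
                "group": grp["group"].iloc[0],
                "age": float(grp["age"].iloc[0]),
                "eccentricity_deg": out.eccentricity_deg,
                "CT": out.CT,
                "FT": out.FT,
                "RIT": out.RIT,
                "rit_censored": out.rit_censored,
                "rod_function_present": out.rod_function_present,
                "fit_quality": out.fit_quality,
            }
        )
    return pd.DataFrame(rows)
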