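"""Synthetic dark-adaptometry cohorts and staircase session simulation.

No public dataset exists for fundus-controlled dark adaptometry, so this
module generates cohorts with the statistical structure the analysis
assumes, then simulates the full two-color, three-locus adaptive
staircase session an S-MAIA-style device would record:

* :func:`generate_cohort` draws healthy and AMD subjects (ages, disease
  severity, subretinal drusenoid deposits) and builds a ground-truth
  biphasic recovery curve per locus whose cone threshold, rod plateau and
  rod intercept time reflect additive age, eccentricity, severity and SDD
  effects plus between-subject and locus-level variability.  The cone–rod
  break and rod slope are solved so the implied RIT matches its target;
  targets at or beyond the 60-min cap yield naturally censored curves.
* :func:`simulate_session` runs the psychophysics: cyan (505 nm) and red
  (627 nm) Goldmann III stimuli interleaved at 2/4/6 degrees temporal,
  5 dB dimmer after a seen response and 1 dB brighter after a miss over a
  0–36 dB range, locus rotation after each seen response, and a
  probabilistic observer whose detection follows a cumulative-normal
  psychometric function (with lapse and guess rates) around the
  ground-truth threshold at the presentation time.  Red detection remains
  cone-mediated, so rod-intact loci develop the late cyan–red separation
  the analysis keys on.

All randomness flows from explicit seeds; equal seeds give identical
cohorts and sessions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fitting import CAL_CONST, DB_MAX, db_to_log
from .model import (
    RIT_CRITERION,
    SESSION_CAP_MIN,
    DACurveParams,
    cone_branch,
    evaluate_curve,
    rod_intercept_time,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "ProtocolSpec",
    "SubjectTruth",
    "generate_cohort",
    "cohort_truth_frame",
    "simulate_session",
    "simulate_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Cohort structure and effect sizes for the synthetic study.

    Defaults mirror a 35 + 35 cross-sectional design: healthy volunteers
    over a broad age range, AMD patients skewed older, ~29% of patients
    with subretinal drusenoid deposits, and study-eye severity dominated
    by intermediate AMD.  RIT effects are in minutes (age slope per
    decade), threshold effects in logUnits.  Disease effects on RIT are
    graded across eccentricity (parafovea worst); the SDD effect is
    macula-wide and enters ungraded.
    """

    n_healthy: int = 35
    n_amd: int = 35
    age_range_healthy: tuple = (22.0, 82.0)
    age_range_amd: tuple = (47.0, 86.0)
    prop_sdd: float = 10 / 35
    severity_study: dict = field(
        default_factory=lambda: {"eAMD": 11 / 35, "iAMD": 20 / 35, "lateAMD": 4 / 35}
    )
    # a small unilateral-disease fraction keeps study-eye and fellow-eye
    # severity terms jointly identifiable in the structure-function model
    severity_fellow: dict = field(
        default_factory=lambda: {
            "none": 3 / 35,
            "eAMD": 9 / 35,
            "iAMD": 15 / 35,
            "lateAMD": 8 / 35,
        }
    )

    # RIT structure (minutes)
    rit_intercept: float = 10.0
    rit_age_slope: float = 2.0
    rit_ecc_offsets: dict = field(default_factory=lambda: {2.0: 0.0, 4.0: -0.5, 6.0: -1.0})
    rit_disease_effects: dict = field(
        default_factory=lambda: {"eAMD": 10.0, "iAMD": 30.0, "lateAMD": 28.0}
    )
    rit_ecc_disease_scale: dict = field(
        default_factory=lambda: {2.0: 1.0, 4.0: 0.6, 6.0: 0.35}
    )
    rit_sdd_effect: float = 20.0
    rit_between_sd: float = 2.5
    rit_residual_sd: float = 1.5

    # cone threshold structure (logUnits)
    ct_intercept: float = -0.85
    ct_age_slope: float = 0.025
    ct_disease_shifts: dict = field(
        default_factory=lambda: {"eAMD": 0.02, "iAMD": 0.10, "lateAMD": 0.15}
    )
    ct_sdd_shift: float = 0.05
    ct_between_sd: float = 0.12
    ct_residual_sd: float = 0.08

    # final rod threshold structure (logUnits)
    ft_intercept: float = -2.35
    ft_age_slope: float = 0.025
    ft_disease_shifts: dict = field(
        default_factory=lambda: {"eAMD": 0.10, "iAMD": 0.50, "lateAMD": 0.70}
    )
    ft_sdd_shift: float = 0.40
    ft_between_sd: float = 0.15
    ft_residual_sd: float = 0.10

    # fixed curve-shape anchors
    t0_elevation: float = 3.0  # initial threshold above ct, logUnits (capped at 4.5)
    tau: float = 1.0  # cone time constant, minutes
    s2_default: float = -0.24  # rod slope, logUnits/min

    # observer psychometrics
    psychometric_slope: float = 0.1  # logUnits
    lapse_rate: float = 0.02
    guess_rate: float = 0.01

    seed: int = 17

    def __post_init__(self):
        for p in (self.prop_sdd, self.lapse_rate, self.guess_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion {p} outside [0, 1]")
        for d in (self.severity_study, self.severity_fellow):
            if abs(sum(d.values()) - 1.0) > 1e-9:
                raise ValueError(f"severity proportions must sum to 1: {d}")
        for sd in (
            self.rit_between_sd,
            self.rit_residual_sd,
            self.ct_between_sd,
            self.ct_residual_sd,
            self.ft_between_sd,
            self.ft_residual_sd,
        ):
            if sd < 0:
                raise ValueError("SDs must be >= 0")


@dataclass(frozen=True)
class ProtocolSpec:
    """Two-color multi-locus staircase protocol.

    5-up/1-down: 5 dB dimmer after a seen response, 1 dB brighter after a
    miss, clamped to the 0–36 dB range.  Loci are visited in ascending
    eccentricity with colors interleaved; the scheduler advances to the
    next (locus, color) staircase after each seen response, with an
    anti-starvation override after 10 consecutive misses.  The session
    ends at the cap or earlier once every cyan staircase is steady (last
    5 thresholds within 1 dB).
    """

    eccentricities: tuple = (2.0, 4.0, 6.0)
    colors: tuple = ("cyan505", "red627")
    step_down_db: float = 5.0
    step_up_db: float = 1.0
    db_range: tuple = (0.0, DB_MAX)
    session_cap_min: float = SESSION_CAP_MIN
    interval_s: float = 4.0
    stimulus_duration_ms: float = 200.0  # metadata only
    anti_starvation: int = 10
    steady_n: int = 5
    steady_span_db: float = 1.0

    def __post_init__(self):
        if self.step_down_db <= 0 or self.step_up_db <= 0:
            raise ValueError("staircase step sizes must be positive")
        if self.session_cap_min > 60.0:
            raise ValueError("session cap must be <= 60 min")


@dataclass
class SubjectTruth:
    """Ground truth for one simulated subject (study eye).

    ``params`` maps eccentricity to the true :class:`DACurveParams`;
    ``rod_present`` marks loci with measurable rod function; ``true_*``
    hold the implied outcomes (``true_RIT`` recomputed from the params via
    the same root-finder the analysis uses, so truth and analysis share
    one definition).
    """

    subject_id: str
    group: str
    age: float
    SDD: bool
    study_dx: str
    fellow_dx: str
    params: dict = field(default_factory=dict)
    rod_present: dict = field(default_factory=dict)
    true_CT: dict = field(default_factory=dict)
    true_FT: dict = field(default_factory=dict)
    true_RIT: dict = field(default_factory=dict)
    true_rit_censored: dict = field(default_factory=dict)
    rit_target: dict = field(default_factory=dict)  # pre-censoring target, min


def _solve_curve_for_targets(
    ct: float,
    ft: float,
    rit_target: float,
    spec: CohortSpec,
    criterion: float = RIT_CRITERION,
    t_max: float = SESSION_CAP_MIN,
) -> tuple[DACurveParams, bool]:
    """Build DACurveParams hitting the target CT/FT/RIT.

    Solves the cone–rod break for the default rod slope from the exact
    crossing condition evaluate_curve(RIT) == criterion; when the break
    would leave its physiological box the break is clamped and the slope
    re-solved, and when neither can reach the target the parameters are
    clamped with a logged warning.  Returns (params, rod_present).
    """
    ct = float(np.clip(ct, -1.45, 1.45))
    t0 = min(ct + spec.t0_elevation, 4.5)
    tau = spec.tau
    if ft > ct - 0.05:
        # rod plateau at/above cone plateau: no measurable rod function
        return (
            DACurveParams(ct=ct, t0=t0, tau=tau, S2=spec.s2_default, CRB=20.0, tf=ct),
            False,
        )
    ft = float(np.clip(ft, -3.5, ct - 0.05))
    s2 = spec.s2_default
    if ft >= criterion - 0.02:
        # rod plateau never crosses the criterion: censored by construction
        return DACurveParams(ct=ct, t0=t0, tau=tau, S2=s2, CRB=15.0, tf=ft), True

    rit_target = max(rit_target, 5.0)  # physiological floor for the crossing
    cone_decay = (t0 - ct) * math.exp(-rit_target / tau)
    a = criterion - ct - cone_decay
    inner = 10.0**a - 10.0 ** (ft - ct)
    if inner <= 0:
        # criterion unreachable once the cone decay is accounted for
        return DACurveParams(ct=ct, t0=t0, tau=tau, S2=s2, CRB=15.0, tf=ft), True
    log_inner = math.log10(inner)
    crb = rit_target - log_inner / s2
    # cone recovery after a strong bleach takes minutes: keep the break
    # late enough that the cone plateau is expressed in the data
    if not 2.5 <= crb <= 45.0:
        crb = float(np.clip(crb, 2.5, 45.0))
        if rit_target - crb > 0.1:
            s2 = log_inner / (rit_target - crb)
        if not -1.0 <= s2 <= -0.01:
            s2 = float(np.clip(s2, -1.0, -0.01))
            logger.warning(
                "target RIT %.1f min unattainable within parameter bounds; clamped",
                rit_target,
            )
    return DACurveParams(ct=ct, t0=t0, tau=tau, S2=s2, CRB=crb, tf=ft), True


def generate_cohort(spec: CohortSpec) -> list[SubjectTruth]:
    """Draw a cohort of SubjectTruth records under the spec.

    Ages are uniform within each group's range.  Per locus, each outcome
    target is built additively: intercept + age slope x decades +
    eccentricity offset + severity effect (RIT effects scaled by the
    eccentricity grading) + SDD effect + subject random intercept +
    locus-level noise.  Reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    eccs = sorted(spec.rit_ecc_offsets)
    subjects = []
    sev_levels = list(spec.severity_study)
    sev_p = np.array([spec.severity_study[k] for k in sev_levels])
    fel_levels = list(spec.severity_fellow)
    fel_p = np.array([spec.severity_fellow[k] for k in fel_levels])

    for i in range(spec.n_healthy + spec.n_amd):
        healthy = i < spec.n_healthy
        group = "healthy" if healthy else "AMD"
        lo, hi = spec.age_range_healthy if healthy else spec.age_range_amd
        age = float(rng.uniform(lo, hi))
        if healthy:
            sdd, study_dx, fellow_dx = False, "none", "none"
        else:
            sdd = bool(rng.random() < spec.prop_sdd)
            study_dx = str(rng.choice(sev_levels, p=sev_p))
            fellow_dx = str(rng.choice(fel_levels, p=fel_p))
        subj = SubjectTruth(
            subject_id=f"S{i:03d}",
            group=group,
            age=age,
            SDD=sdd,
            study_dx=study_dx,
            fellow_dx=fellow_dx,
        )
        age_dec = age / 10.0
        b_rit = rng.normal(0.0, spec.rit_between_sd)
        b_ct = rng.normal(0.0, spec.ct_between_sd)
        b_ft = rng.normal(0.0, spec.ft_between_sd)
        for ecc in eccs:
            scale = spec.rit_ecc_disease_scale[ecc]
            dis_rit = dis_ct = dis_ft = 0.0
            if not healthy:
                dis_rit = spec.rit_disease_effects[study_dx] * scale
                dis_ct = spec.ct_disease_shifts[study_dx]
                dis_ft = spec.ft_disease_shifts[study_dx]
                if sdd:
                    dis_rit += spec.rit_sdd_effect
                    dis_ct += spec.ct_sdd_shift
                    dis_ft += spec.ft_sdd_shift
            rit_t = (
                spec.rit_intercept
                + spec.rit_age_slope * age_dec
                + spec.rit_ecc_offsets[ecc]
                + dis_rit
                + b_rit
                + rng.normal(0.0, spec.rit_residual_sd)
            )
            ct_t = (
                spec.ct_intercept
                + spec.ct_age_slope * age_dec
                + dis_ct
                + b_ct
                + rng.normal(0.0, spec.ct_residual_sd)
            )
            ft_t = (
                spec.ft_intercept
                + spec.ft_age_slope * age_dec
                + dis_ft
                + b_ft
                + rng.normal(0.0, spec.ft_residual_sd)
            )
            params, rod = _solve_curve_for_targets(ct_t, ft_t, rit_t, spec)
            subj.params[ecc] = params
            subj.rod_present[ecc] = rod
            subj.rit_target[ecc] = rit_t
            subj.true_CT[ecc] = params.ct
            if rod:
                res = rod_intercept_time(params)
                if res.censored and params.tf < RIT_CRITERION - 0.02:
                    # break too late for the rod plateau to be expressed in
                    # session: the measurable FT is cone-mediated, matching
                    # the derivation rule applied to observed sessions
                    subj.true_FT[ecc] = params.ct
                else:
                    subj.true_FT[ecc] = params.tf
                subj.true_RIT[ecc] = res.rit
                subj.true_rit_censored[ecc] = res.censored
            else:
                subj.true_FT[ecc] = params.ct
                subj.true_RIT[ecc] = SESSION_CAP_MIN
                subj.true_rit_censored[ecc] = True
        subjects.append(subj)
    return subjects


def cohort_truth_frame(subjects: list[SubjectTruth]) -> pd.DataFrame:
    """Flatten SubjectTruth records to one row per subject x eccentricity."""
    rows = []
    for s in subjects:
        for ecc, p in s.params.items():
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "age": s.age,
                    "SDD": int(s.SDD),
                    "study_dx": s.study_dx,
                    "fellow_dx": s.fellow_dx,
                    "eccentricity_deg": ecc,
                    "ct": p.ct,
                    "t0": p.t0,
                    "tau": p.tau,
                    "S2": p.S2,
                    "CRB": p.CRB,
                    "tf": p.tf,
                    "rod_present": int(s.rod_present[ecc]),
                    "rit_target": s.rit_target[ecc],
                    "true_CT": s.true_CT[ecc],
                    "true_FT": s.true_FT[ecc],
                    "true_RIT": s.true_RIT[ecc],
                    "true_rit_censored": int(s.true_rit_censored[ecc]),
                }
            )
    return pd.DataFrame(rows)


def _p_seen(
    stim_log: float, thr_log: float, slope: float, guess: float, lapse: float
) -> float:
    """Cumulative-normal psychometric function with guess and lapse rates.

    A stimulus brighter than the momentary threshold (``stim_log >
    thr_log``) is seen with probability approaching ``1 - lapse``; slope 0
    degenerates to an ideal step observer.
    """
    if slope <= 0:
        core = 1.0 if stim_log >= thr_log else 0.0
    else:
        core = 0.5 * (1.0 + math.erf((stim_log - thr_log) / (slope * math.sqrt(2.0))))
    return guess + (1.0 - guess - lapse) * core


@dataclass
class _Staircase:
    level: float = 0.0
    misses: int = 0
    seen_levels: list = field(default_factory=list)


def simulate_session(
    truth: SubjectTruth,
    protocol: ProtocolSpec = ProtocolSpec(),
    seed: int = 0,
    spec: CohortSpec | None = None,
) -> pd.DataFrame:
    """Simulate one full dark-adaptometry session for a subject.

    Returns a presentations table (one row per stimulus presentation) in
    the shared schema: ``subject_id, group, age, eccentricity_deg, color,
    t_min, level_db, seen``.  The observer's detection probability uses
    the biphasic truth curve for cyan stimuli and the cone-only branch for
    red stimuli (627 nm detection stays cone-mediated at these levels).

    Psychometric settings are taken from ``spec`` (slope, guess, lapse);
    a default :class:`CohortSpec` is used when none is given.
    """
    spec = spec or CohortSpec()
    for ecc in protocol.eccentricities:
        if ecc not in truth.params:
            raise ValueError(f"truth lacks parameters for eccentricity {ecc}")
    rng = np.random.default_rng(seed)
    keys = [(e, c) for e in protocol.eccentricities for c in protocol.colors]
    stair = {k: _Staircase(level=protocol.db_range[0]) for k in keys}
    lo_db, hi_db = protocol.db_range
    dt_min = protocol.interval_s / 60.0
    rows = []
    t = dt_min
    idx = 0
    while t <= protocol.session_cap_min:
        ecc, color = keys[idx % len(keys)]
        st = stair[(ecc, color)]
        p = truth.params[ecc]
        if color == "cyan505" and truth.rod_present[ecc]:
            thr = float(evaluate_curve(p, t))
        else:
            thr = float(cone_branch(p, t))
        stim = db_to_log(st.level)
        seen = rng.random() < _p_seen(
            stim, thr, spec.psychometric_slope, spec.guess_rate, spec.lapse_rate
        )
        rows.append(
            {
                "subject_id": truth.subject_id,
                "group": truth.group,
                "age": truth.age,
                "eccentricity_deg": ecc,
                "color": color,
                "t_min": round(t, 6),
                "level_db": st.level,
                "seen": int(seen),
            }
        )
        if seen:
            st.seen_levels.append(st.level)
            st.level = min(st.level + protocol.step_down_db, hi_db)
            st.misses = 0
            idx += 1
        else:
            st.level = max(st.level - protocol.step_up_db, lo_db)
            st.misses += 1
            if st.misses >= protocol.anti_starvation:
                st.misses = 0
                idx += 1
        t += dt_min
        # early termination: steady-state rod thresholds at every cyan locus
        steady = True
        for e in protocol.eccentricities:
            lv = stair[(e, "cyan505")].seen_levels
            if len(lv) < protocol.steady_n or (
                max(lv[-protocol.steady_n :]) - min(lv[-protocol.steady_n :])
                >= protocol.steady_span_db
            ):
                steady = False
                break
        if steady and t > 20.0:
            break
    return pd.DataFrame(rows)


def simulate_cohort(
    subjects: list[SubjectTruth],
    protocol: ProtocolSpec = ProtocolSpec(),
    seed: int = 0,
    spec: CohortSpec | None = None,
) -> pd.DataFrame:
    """Simulate sessions for a whole cohort; one child seed per subject."""
    frames = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(subjects))
    for subj, child in zip(subjects, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        frames.append(simulate_session(subj, protocol, seed=sub_seed, spec=spec))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
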