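"""End-to-end pipeline: presentations -> fits -> normative -> diagnostics.

``run_pipeline`` executes the full analysis on either a presentations CSV
or a freshly simulated synthetic cohort, and writes every artifact of a
run — locus outcomes, normative models, deviations, AROC curves,
structure-function regression tables, figures and a run-metadata JSON
whose seed/config hash make the run bit-for-bit reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import covariate_adjusted_roc, structure_function_fit
from .exceptions import DarkAdaptError
from .fitting import fit_all_loci
from .io import RunConfig, read_presentations, save_models, write_outcomes, write_presentations
from .normative import OUTCOME_NAMES, compute_deviations, fit_normative_model
from .simulate import CohortSpec, ProtocolSpec, cohort_truth_frame, generate_cohort, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except DarkAdaptError as exc:
                raise DarkAdaptError(f"[stage {name}] {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis described by ``config``.

    Returns a bundle dict with the in-memory artifacts (outcomes,
    deviations, AROC results, regression results, truth table when
    simulated) after writing all CSV/JSON outputs and figures to
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    # --- inputs ---------------------------------------------------------
    truth_df = None
    if config.presentations_path is not None:
        pres, report = read_presentations(config.presentations_path)
        if report:
            (out / "rejected_rows.txt").write_text("\n".join(report) + "\n")
    else:
        spec = CohortSpec(seed=config.seed, **config.cohort_overrides)
        subjects = generate_cohort(spec)
        truth_df = cohort_truth_frame(subjects)
        truth_df.to_csv(out / "cohort_truth.csv", index=False)
        pres = simulate_cohort(subjects, ProtocolSpec(), seed=config.seed + 1, spec=spec)
        write_presentations(pres, out / "presentations.csv")
        bundle["truth"] = truth_df

    # --- stage: curve fitting ------------------------------------------
    outcomes = _stage("fit")(fit_all_loci)(
        pres,
        mode=config.fit_mode,
        seed=config.seed,
        cal_const=config.cal_const,
        criterion=config.criterion,
        t_max=config.t_max,
    )
    if truth_df is not None:
        meta = truth_df[["subject_id", "eccentricity_deg", "SDD", "study_dx", "fellow_dx"]]
        outcomes = outcomes.merge(meta, on=["subject_id", "eccentricity_deg"], how="left")
    write_outcomes(outcomes, out / "locus_outcomes.csv")
    bundle["outcomes"] = outcomes

    # --- stage: normative ----------------------------------------------
    healthy = outcomes[outcomes["group"] == "healthy"]
    models = {}
    for name in OUTCOME_NAMES:
        models[name] = _stage("normative")(fit_normative_model)(
            healthy, name, exclude_censored=config.exclude_censored_normative
        )
    save_models(models, out / "normative_models.json")
    deviations = _stage("normative")(compute_deviations)(outcomes, models)
    deviations.to_csv(out / "deviations.csv", index=False)
    bundle["models"] = models
    bundle["deviations"] = deviations

    # --- stage: diagnostics --------------------------------------------
    aroc_results = []
    rows = []
    for name in config.markers:
        for ecc, grp in outcomes.groupby("eccentricity_deg"):
            r = _stage("roc")(covariate_adjusted_roc)(
                grp[name],
                grp["group"] == "AMD",
                grp["age"],
                direction="higher_is_diseased",
                n_boot=config.n_boot,
                seed=config.seed,
                marker_name=name,
                eccentricity_deg=float(ecc),
            )
            aroc_results.append(r)
            rows.append(
                {
                    "marker_name": name,
                    "eccentricity_deg": ecc,
                    "aauc": r.aauc,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "n_healthy": r.n_healthy,
                    "n_diseased": r.n_diseased,
                    "n_boot": r.n_boot,
                }
            )
    pd.DataFrame(rows).to_csv(out / "aroc_results.csv", index=False)
    with open(out / "aroc_curves.json", "w") as fh:
        json.dump([r.to_dict() for r in aroc_results], fh)
    bundle["aroc"] = aroc_results

    regression = None
    if {"SDD", "study_dx", "fellow_dx"}.issubset(outcomes.columns):
        sf = outcomes.copy()
        sf["SDD"] = sf["SDD"].fillna(0).astype(int)
        for c in ("study_dx", "fellow_dx"):
            sf[c] = sf[c].fillna("none")
        regression = _stage("structfun")(structure_function_fit)(sf, outcome="RIT")
        reg_rows = []
        for ecc, res in regression.items():
            tab = res.table.copy()
            tab.insert(0, "eccentricity_deg", ecc)
            tab["r2"] = res.r2
            tab["r2_adj"] = res.r2_adj
            tab["n"] = res.n
            reg_rows.append(tab)
        pd.concat(reg_rows, ignore_index=True).to_csv(
            out / "regression_results.csv", index=False
        )
    bundle["regression"] = regression

    # --- figures --------------------------------------------------------
    if config.make_plots:
        from . import plots

        plots.plot_outcomes_vs_age(outcomes, models, out / "outcomes_vs_age.png")
        plots.plot_aroc_curves(aroc_results, out / "aroc_curves.png")
        plots.plot_deviation_pairs(deviations, out / "deviation_pairs.png")

    # --- run metadata ----------------------------------------------------
    meta = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_loci": int(len(outcomes)),
        "numpy_version": np.__version__,
    }
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    bundle["metadata"] = meta
    return bundle
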