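"""End-to-end pipeline: generate/load -> screen -> metrics -> stats ->
classify -> access, with CSV reports and a JSON run summary."""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .access import EvalProtocol, access_table
from .artifacts import calibrate_box, screen_stream
from .bandstats import build_trial_matrix, effect_directions
from .classify import FeatureVector, kfold_cv
from .core import Session
from .io import RunConfig, read_session_csv, write_session_csv
from .metrics import subject_summary, trial_average_features
from .synthetic import (
    SimConfig,
    demo_profiles,
    generate_cohort,
    generate_labeled_epochs,
    session_epochs,
    subject_seed,
)

log = logging.getLogger("attnaccess")

REPORT_FILES = (
    "trial_metrics.csv",
    "band_pvalues.csv",
    "effect_directions.csv",
    "classification.csv",
    "access.csv",
    "summary.json",
)


def _cohort_from_config(config: RunConfig) -> dict[str, list[Session]]:
    if config.input_csv is not None:
        sessions = read_session_csv(config.input_csv)
        cohort: dict[str, list[Session]] = {}
        for s in sessions:
            cohort.setdefault(s.subject_id, []).append(s)
        log.info("loaded %d subjects from %s", len(cohort), config.input_csv)
        return cohort
    sim = SimConfig(seed=config.seed, n_bands=config.n_bands)
    cohort = generate_cohort(demo_profiles(config.n_bands), sim)
    log.info("generated demo cohort: %d subjects", len(cohort))
    return cohort


def _screen_cohort(
    cohort: dict[str, list[Session]], config: RunConfig
) -> tuple[dict[str, list[Session]], dict]:
    """Raw-epoch screening of a generated cohort (synthetic epochs)."""
    sim = SimConfig(seed=config.seed, n_bands=config.n_bands)
    box = calibrate_box(generate_labeled_epochs(sim, config.seed + 7919, 100))
    profiles = {p.subject_id: p for p in demo_profiles(config.n_bands)}
    screened: dict[str, list[Session]] = {}
    n_invalid = 0
    for sid, sessions in cohort.items():
        profile = profiles.get(sid)
        if profile is None:
            screened[sid] = sessions
            continue
        out = []
        for session in sessions:
            epochs, _ = session_epochs(
                profile, sim, session, subject_seed(config.seed, sid)
            )
            s2, report = screen_stream(session, epochs, box)
            n_invalid += int((~report["valid"]).sum())
            out.append(s2)
        screened[sid] = out
    log.info("screening flagged %d invalid seconds", n_invalid)
    return screened, {"invalid_seconds": n_invalid}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``out_dir``.

    Returns the JSON-serializable run summary.  Any stage failure aborts
    with the stage name and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "version": __version__, "stages": {}}

    stage = "generate"
    try:
        cohort = _cohort_from_config(config)
        if config.input_csv is None:
            write_session_csv(
                [s for ss in cohort.values() for s in ss], out / "sessions.csv"
            )
        summary["stages"][stage] = {"subjects": sorted(cohort)}

        stage = "screen"
        if config.screen_epochs and config.input_csv is None:
            cohort, screen_info = _screen_cohort(cohort, config)
            summary["stages"][stage] = screen_info

        stage = "metrics"
        rows = []
        for sid, sessions in cohort.items():
            df = subject_summary(sessions, config.threshold).reset_index()
            df.insert(0, "subject_id", sid)
            rows.append(df)
        metrics_df = pd.concat(rows, ignore_index=True)
        metrics_df.to_csv(out / "trial_metrics.csv", index=False)
        summary["stages"][stage] = {"rows": len(metrics_df)}

        stage = "stats"
        pv_rows, dir_rows = [], []
        for sid, sessions in cohort.items():
            matrix = build_trial_matrix(sessions)
            table = effect_directions(matrix, config.alpha)
            t = table.reset_index()
            t.insert(0, "subject_id", sid)
            pv_rows.append(t[["subject_id", "variable", "p_value", "significant"]])
            dir_rows.append(t[["subject_id", "variable", "direction"]])
        pd.concat(pv_rows, ignore_index=True).to_csv(
            out / "band_pvalues.csv", index=False
        )
        pd.concat(dir_rows, ignore_index=True).to_csv(
            out / "effect_directions.csv", index=False
        )
        summary["stages"][stage] = {"subjects": len(pv_rows)}

        stage = "classify"
        cls_rows = []
        for sid, sessions in cohort.items():
            for fset in config.feature_sets:
                fvs = []
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    for session in sessions:
                        for trial in session.trials:
                            feats = trial_average_features(trial, fset)
                            if feats is not None and not np.any(np.isnan(feats)):
                                fvs.append(FeatureVector(feats, trial.trial_type))
                res = kfold_cv(fvs, k=config.k_folds, seed=config.seed)
                cls_rows.append(
                    {
                        "subject_id": sid,
                        "feature_set": fset,
                        "accuracy_pct": res.accuracy_pct,
                        "auc": res.auc,
                        "n_trials": len(fvs),
                    }
                )
        cls_df = pd.DataFrame(cls_rows)
        cls_df.to_csv(out / "classification.csv", index=False)
        summary["stages"][stage] = {"rows": len(cls_df)}

        stage = "access"
        protocol = EvalProtocol(
            n_train=config.protocol.n_train,
            n_validation=config.protocol.n_validation,
            n_test=config.protocol.n_test,
            repeats=config.protocol.repeats,
            t_w_grid=config.protocol.t_w_grid,
            seed=config.seed,
        )
        acc_df = access_table(
            cohort, config.feature_sets, config.n_icons, protocol
        )
        acc_df.to_csv(out / "access.csv", index=False)
        infeasible = acc_df["t_w_opt"].isna().sum()
        summary["stages"][stage] = {
            "rows": len(acc_df),
            "infeasible": int(infeasible),
        }
        log.info("%d infeasible subject/set combinations", infeasible)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
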