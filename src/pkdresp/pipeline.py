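"""End-to-end orchestration: simulate -> screen -> fit -> classify -> stats ->
eGFR slopes -> power, with stable file contracts and a run manifest.

Every stage reads and writes delimited text tables (UTF-8, comma, header row)
or schema-versioned JSON under one output directory; a single master seed
funnels all randomness.  On stage failure the run halts with the stage name
and cause, and files the failing stage had already written are renamed with a
``.partial`` suffix.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import classify_cohort
from .config import CohortConfig
from .egfr import add_delta_column, fit_group_slopes
from .errors import PipelineError
from .growth import (PatientFlags, apply_eligibility_filters, fit_cohort_growth,
                     scans_frame_to_records)
from .mayo import add_mic_columns
from .power import PowerSpec, power_report
from .simulate import simulate_cohort, write_cohort_tables
from .stats import (compare_groups_univariate, comparisons_to_frame,
                    fit_logistic_response_model, stepwise_aic_select)

log = logging.getLogger("pkdresp")

SCHEMA_VERSION = 1
FLAG_COLUMNS = ("interruption_gt_1_month", "non_adherence", "cyst_event")

#: univariate battery mirroring the baseline characteristics table
BATTERY = {
    "treatment_start_age": "continuous",
    "sex": "categorical",
    "height_m": "continuous",
    "weight_kg": "continuous",
    "bmi": "continuous",
    "tkv_at_start_ml": "continuous",
    "httkv": "continuous",
    "mic_class": "categorical",
    "egfr_baseline": "continuous",
    "uosm_baseline": "continuous",
    "pre_rate": "continuous",
}


@dataclass
class RunManifest:
    seed: int
    config: dict
    version: str = __version__
    outputs: dict = field(default_factory=dict)   # stage -> {name: path}
    counts: dict = field(default_factory=dict)    # stage -> records

    def to_json(self, path: str | Path) -> str:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return str(path)


class _Stage:
    """Tracks files written by one stage so failures leave .partial markers."""

    def __init__(self, manifest: RunManifest, name: str):
        self.manifest = manifest
        self.name = name
        self.manifest.outputs.setdefault(name, {})

    def __enter__(self):
        log.info("stage %s: start", self.name)
        return self

    def add(self, key: str, path: str | Path):
        self.manifest.outputs[self.name][key] = str(path)

    def __exit__(self, exc_type, exc, tb):
        if exc is None:
            log.info("stage %s: done", self.name)
            return False
        for key, path in self.manifest.outputs[self.name].items():
            p = Path(path)
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
                self.manifest.outputs[self.name][key] = str(p) + ".partial"
        if isinstance(exc, PipelineError):
            return False
        raise PipelineError(self.name, "STAGE_FAILURE", f"{type(exc).__name__}: {exc}") from exc


def _flags_from_row(row: pd.Series) -> PatientFlags:
    return PatientFlags(**{c: bool(row[c]) if c in row else False
                           for c in FLAG_COLUMNS})


def run_full_pipeline(config: CohortConfig | str | Path | None = None,
                      outdir: str | Path = "pkdresp_run",
                      seed: int | None = None,
                      make_plots: bool = True) -> RunManifest:
    """Run the whole analysis on a simulated cohort; returns the manifest.

    ``config`` may be a :class:`CohortConfig`, a YAML path, or None for the
    defaults; ``seed`` overrides the config seed.  Idempotent given the seed.
    """
    if config is None:
        config = CohortConfig()
    elif isinstance(config, (str, Path)):
        config = CohortConfig.from_yaml(config)
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, config=config.to_dict())

    # --- simulate ---------------------------------------------------------
    with _Stage(manifest, "simulate") as st:
        patients = simulate_cohort(config)
        paths = write_cohort_tables(patients, config, outdir)
        for k, v in paths.items():
            st.add(k, v)
        manifest.counts["simulate"] = len(patients)
    scans_df = pd.read_csv(outdir / "scans.csv")
    patients_df = pd.read_csv(outdir / "patients.csv")
    labs_df = pd.read_csv(outdir / "labs.csv")

    # --- eligibility ------------------------------------------------------
    with _Stage(manifest, "screen") as st:
        records = scans_frame_to_records(scans_df)
        roster = {row.patient_id: (records.get(row.patient_id, []),
                                   float(row.treatment_start_age),
                                   _flags_from_row(pd.Series(row._asdict())))
                  for row in patients_df.itertuples()}
        decisions = apply_eligibility_filters(roster)
        elig = pd.DataFrame([{"patient_id": d.patient_id, "eligible": d.eligible,
                              "reasons": ";".join(d.reasons)} for d in decisions])
        path = outdir / "eligibility.csv"
        elig.to_csv(path, index=False)
        st.add("eligibility", path)
        manifest.counts["screen"] = int(elig["eligible"].sum())
    eligible_ids = set(elig.loc[elig["eligible"], "patient_id"])

    # --- growth fits ------------------------------------------------------
    with _Stage(manifest, "fit") as st:
        sub_scans = scans_df[scans_df["patient_id"].isin(eligible_ids)]
        sub_pats = patients_df[patients_df["patient_id"].isin(eligible_ids)]
        fits = fit_cohort_growth(sub_scans, sub_pats) if eligible_ids else \
            pd.DataFrame(columns=["patient_id", "window", "annual_rate",
                                  "tkv_at_ref_age", "ref_age", "n_points",
                                  "log_residual_rms"])
        path = outdir / "growth_fits.csv"
        fits.to_csv(path, index=False, float_format="%.10g")
        st.add("growth_fits", path)
        manifest.counts["fit"] = int(fits["patient_id"].nunique())

    # --- responder classification ----------------------------------------
    with _Stage(manifest, "classify") as st:
        if fits.empty:
            raise PipelineError("classify", "ELIGIBILITY_EMPTY",
                                "no eligible patients reached classification")
        result, calls = classify_cohort(fits)
        path = outdir / "responder_calls.csv"
        calls.to_csv(path, index=False, float_format="%.10g")
        st.add("responder_calls", path)
        summary = {"schema_version": SCHEMA_VERSION,
                   "split_value": result.split_value,
                   "cluster_means": list(result.cluster_means),
                   "within_ss": result.within_ss,
                   "gap": [result.low_max, result.high_min],
                   "n_responders": int((calls["label"] == "responder").sum()),
                   "n_non_responders": int((calls["label"] == "non-responder").sum())}
        spath = outdir / "cluster_summary.json"
        spath.write_text(json.dumps(summary, indent=2))
        st.add("cluster_summary", spath)
        if make_plots:
            from .plots import plot_delta_clusters
            st.add("cluster_plot", plot_delta_clusters(
                calls, result.split_value, outdir / "clusters.png"))
        manifest.counts["classify"] = len(calls)
    labels = calls.set_index("patient_id")["label"]

    # --- statistics -------------------------------------------------------
    with _Stage(manifest, "stats") as st:
        table = add_mic_columns(sub_pats).merge(
            calls[["patient_id", "pre_rate"]], on="patient_id").set_index("patient_id")
        lab = labels.loc[table.index]
        comparisons = compare_groups_univariate(table, lab, BATTERY)
        t1 = comparisons_to_frame(comparisons)
        path = outdir / "table1_replica.csv"
        t1.to_csv(path, index=False, float_format="%.6g")
        st.add("table1_replica", path)

        # model: univariate raw p < 0.05 plus age and sex, then stepwise AIC
        sig = [c.variable for c in comparisons
               if c.p_raw < 0.05 and c.kind == "continuous"
               and c.variable != "treatment_start_age"]
        data = table.copy()
        data["sex_male"] = (data["sex"] == "M").astype(float)
        candidates = list(dict.fromkeys(sig + ["treatment_start_age", "sex_male"]))
        selected, trail = stepwise_aic_select(lab, data, candidates)
        model = fit_logistic_response_model(lab, data[selected]) if selected else None
        report = {"schema_version": SCHEMA_VERSION,
                  "outcome_coding": "non-responder=1",
                  "candidates": candidates,
                  "selected": selected,
                  "aic_trail": trail,
                  "terms": [dataclasses.asdict(t) for t in model.terms] if model else [],
                  "aic": model.aic if model else trail[-1]["aic"],
                  "separation_flag": bool(model.separation_flag) if model else False}
        mpath = outdir / "model_table.json"
        mpath.write_text(json.dumps(report, indent=2))
        st.add("model_table", mpath)
        manifest.counts["stats"] = len(comparisons)

    # --- eGFR trajectory --------------------------------------------------
    with _Stage(manifest, "egfr") as st:
        sub_labs = labs_df[labs_df["patient_id"].isin(labels.index)]
        sub_labs = add_delta_column(sub_labs)
        comparison = fit_group_slopes(sub_labs, labels)
        out = {"schema_version": SCHEMA_VERSION,
               "slopes": {g: {"slope_per_year": gs.slope, "se": gs.se,
                              "ci95": list(gs.ci), "n_points": gs.n_points}
                          for g, gs in comparison.slopes.items()},
               "interaction_p": comparison.interaction_p,
               "excess_percent": comparison.excess_percent}
        path = outdir / "egfr_slopes.json"
        path.write_text(json.dumps(out, indent=2))
        st.add("egfr_slopes", path)
        if make_plots:
            from .plots import plot_egfr_trajectories
            st.add("egfr_plot", plot_egfr_trajectories(
                sub_labs, labels, comparison, outdir / "egfr_trajectory.png"))
        manifest.counts["egfr"] = int(len(sub_labs))

    # --- power ------------------------------------------------------------
    with _Stage(manifest, "power") as st:
        report = power_report(PowerSpec(), seed=config.seed)
        path = outdir / "power.json"
        path.write_text(json.dumps({"schema_version": SCHEMA_VERSION, **report},
                                   indent=2))
        st.add("power", path)
        manifest.counts["power"] = report["n_required"]

    manifest.to_json(outdir / "manifest.json")
    return manifest
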