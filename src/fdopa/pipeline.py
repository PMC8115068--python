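"""End-to-end driver: simulate -> quantify -> reliability -> discrimination ->
voxel classification -> economics, all reproducible from one master seed."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ModelSpec, extract_feature_matrix, loocv_evaluate
from .core import FrameSchedule
from .econ import EconScenario, breakeven_sensitivity, econ_outcome, savings_surface
from .io import write_cohort, write_config, write_label_map, write_schedule
from .patlak import parametric_map, roi_ki
from .reliability import PairedMeasurements, gated_correlation, icc_two_way, percent_var
from .roc import LabelledScores, cohens_d, roc_curve
from .suvr import compute_snr, compute_suvrc, static_frame
from .synthetic import CohortDesign, make_mask, simulate_cohort, simulate_test_retest

__all__ = ["RunConfig", "RunReport", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = (
    "simulate", "patlak", "suvr", "reliability", "correlation",
    "effect_roc", "classify", "econ",
)
REGIONS = ("striatum", "limbic", "associative", "sensorimotor")


@dataclass(frozen=True)
class RunConfig:
    out_dir: str
    master_seed: int = 0
    schedule: str = "dataset1"
    design: CohortDesign = field(default_factory=CohortDesign)
    stages: tuple = ALL_STAGES
    t_star_min: float = 30.0
    fit_weights: str = "uniform"
    suvr_window_starts_min: tuple = (60.0, 75.0, 90.0)
    suvr_window_length_min: float = 10.0
    snr_window_start_min: float = 75.0
    snr_window_lengths_min: tuple = (5.0, 10.0, 15.0)
    classifier_families: tuple = ("bernoulli_logistic", "linear_svm", "random_forest")
    classifier_seeds: int = 5
    econ_scenario: EconScenario = field(default_factory=EconScenario)
    write_volumes: bool = False

    def resolve_schedule(self) -> FrameSchedule:
        if self.schedule == "dataset1":
            return FrameSchedule.dataset1()
        if self.schedule == "dataset2":
            return FrameSchedule.dataset2()
        raise ValueError("schedule must be 'dataset1' or 'dataset2'")


@dataclass
class RunReport:
    config_hash: str
    master_seed: int
    version: str
    outputs: dict = field(default_factory=dict)  # stage -> list of file names
    timings_s: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "master_seed": self.master_seed,
                "version": self.version,
                "outputs": self.outputs,
                "timings_s": self.timings_s,
            },
            indent=2,
        )


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False, float_format="%.10g")
    return path.name


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages in order, writing one CSV per result
    table under ``config.out_dir``. Deterministic given the master seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(_config_hash(config), config.master_seed, __version__)
    schedule = config.resolve_schedule()
    mask = make_mask()
    seeds = np.random.SeedSequence(config.master_seed).spawn(3)
    design = replace(config.design, seed=config.master_seed)

    stages = tuple(config.stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    scans = pairs = None
    ki_df = suvr_df = None
    maps = {}

    def _stage(name):
        return name in stages

    needs_scans = bool(set(stages) & set(ALL_STAGES[:-1]))

    # ---- simulate ------------------------------------------------------
    if needs_scans:
        t0 = time.perf_counter()
        scans = simulate_cohort(design, schedule, mask, np.random.default_rng(seeds[0]))
        pairs = simulate_test_retest(design, schedule, mask, np.random.default_rng(seeds[1]))
        files = []
        if _stage("simulate"):
            if config.write_volumes:
                files.append(write_cohort(scans, out / "cohort").name)
            files.append(_write(write_truth_table(scans), out / "cohort_truth.csv"))
            files.append(write_schedule(schedule, out / "frames.csv").name)
            files.append(write_label_map(out / "mask_labels.txt").name)
        report.outputs["simulate"] = files
        report.timings_s["simulate"] = round(time.perf_counter() - t0, 3)

    # ---- patlak --------------------------------------------------------
    if _stage("patlak") or _stage("correlation") or _stage("effect_roc") or _stage("classify"):
        t0 = time.perf_counter()
        rows = []
        for scan in scans:
            for region in REGIONS:
                fit = roi_ki(scan, region, config.t_star_min, config.fit_weights)
                rows.append(
                    {"subject_id": scan.subject_id, "group": scan.group,
                     "region": region, "ki_cer_per_min": fit.ki_cer,
                     "intercept": fit.intercept, "r_squared": fit.r_squared,
                     "t_star_min": fit.t_star}
                )
        ki_df = pd.DataFrame(rows)
        if _stage("patlak"):
            report.outputs["patlak"] = [_write(ki_df, out / "roi_ki.csv")]
            report.timings_s["patlak"] = round(time.perf_counter() - t0, 3)

    # ---- suvr ----------------------------------------------------------
    if _stage("suvr") or _stage("correlation") or _stage("effect_roc"):
        t0 = time.perf_counter()
        rows, snr_rows = [], []
        for scan in scans:
            for start in config.suvr_window_starts_min:
                # late windows are truncated at scan end (e.g. a 10-min window
                # at 90 min on a 95-min acquisition); the effective length is
                # recorded in the output
                length = min(config.suvr_window_length_min, schedule.total_min - start)
                for region in REGIONS:
                    res = compute_suvrc(scan, region, start, length)
                    rows.append(
                        {"subject_id": scan.subject_id, "group": scan.group,
                         "region": region, "window_start_min": start,
                         "window_length_min": res.window_length_min,
                         "suvrc": res.suvrc}
                    )
            for length in config.snr_window_lengths_min:
                vol = static_frame(scan, config.snr_window_start_min, length)
                snr = compute_snr(vol, scan.mask, config.snr_window_start_min, length)
                snr_rows.append(
                    {"subject_id": scan.subject_id,
                     "window_start_min": snr.window_start_min,
                     "window_length_min": snr.window_length_min, "snr": snr.snr}
                )
        suvr_df = pd.DataFrame(rows)
        if _stage("suvr"):
            report.outputs["suvr"] = [
                _write(suvr_df, out / "suvrc.csv"),
                _write(pd.DataFrame(snr_rows), out / "snr.csv"),
            ]
            report.timings_s["suvr"] = round(time.perf_counter() - t0, 3)

    # ---- reliability ---------------------------------------------------
    if _stage("reliability"):
        t0 = time.perf_counter()
        rows = []
        for metric in ("ki_cer_per_min", "suvrc"):
            for region in REGIONS:
                ids, test_vals, retest_vals = [], [], []
                for test, retest in pairs:
                    if metric == "ki_cer_per_min":
                        tv = roi_ki(test, region, config.t_star_min, config.fit_weights).ki_cer
                        rv = roi_ki(retest, region, config.t_star_min, config.fit_weights).ki_cer
                    else:
                        tv = compute_suvrc(test, region, 75.0,
                                           config.suvr_window_length_min).suvrc
                        rv = compute_suvrc(retest, region, 75.0,
                                           config.suvr_window_length_min).suvrc
                    ids.append(test.subject_id)
                    test_vals.append(tv)
                    retest_vals.append(rv)
                pm = PairedMeasurements(ids, test_vals, retest_vals)
                icc = icc_two_way(pm)
                var = percent_var(pm)
                rows.append(
                    {"metric": metric, "region": region,
                     "icc_consistency": icc.icc_consistency,
                     "icc_absolute": icc.icc_absolute,
                     "var_subjects": icc.var_subjects,
                     "var_sessions": icc.var_sessions,
                     "var_residual": icc.var_residual,
                     "mean_percent_var": var.mean}
                )
        report.outputs["reliability"] = [_write(pd.DataFrame(rows), out / "reliability.csv")]
        report.timings_s["reliability"] = round(time.perf_counter() - t0, 3)

    # ---- correlation ---------------------------------------------------
    if _stage("correlation"):
        t0 = time.perf_counter()
        rows = []
        for region in REGIONS:
            ki_vals = ki_df[ki_df.region == region].set_index("subject_id")["ki_cer_per_min"]
            for start in config.suvr_window_starts_min:
                sub = suvr_df[(suvr_df.region == region)
                              & (suvr_df.window_start_min == start)]
                sv = sub.set_index("subject_id")["suvrc"].reindex(ki_vals.index)
                corr = gated_correlation(sv.to_numpy(), ki_vals.to_numpy())
                rows.append(
                    {"region": region, "window_start_min": start,
                     "coefficient": corr.coefficient, "method": corr.method,
                     "p_value": corr.p}
                )
        report.outputs["correlation"] = [
            _write(pd.DataFrame(rows), out / "suvrc_ki_correlation.csv")
        ]
        report.timings_s["correlation"] = round(time.perf_counter() - t0, 3)

    # ---- effect sizes + ROC -------------------------------------------
    if _stage("effect_roc"):
        t0 = time.perf_counter()
        rows = []
        groups = {scan.subject_id: scan.group for scan in scans}
        metric_tables = {"ki_cer_per_min": ki_df}
        if suvr_df is not None:
            m75 = suvr_df[suvr_df.window_start_min == 75.0]
            metric_tables["suvrc_75min"] = m75.rename(columns={"suvrc": "value"})
        ki_named = ki_df.rename(columns={"ki_cer_per_min": "value"})
        metric_tables["ki_cer_per_min"] = ki_named
        for metric, table in metric_tables.items():
            for region in REGIONS:
                sub = table[table.region == region]
                vals = {sid: v for sid, v in zip(sub.subject_id, sub.value)}
                nr = [v for sid, v in vals.items() if groups[sid] == "non_responder"]
                resp = [v for sid, v in vals.items() if groups[sid] == "responder"]
                d = cohens_d(resp, nr)
                res = roc_curve(LabelledScores.from_groups(nr, resp))
                rows.append(
                    {"metric": metric, "region": region,
                     "cohens_d_responder_minus_nonresponder": d.cohens_d,
                     "auc": res.auc, "p_value_vs_chance": res.p_value,
                     "sens_at_100pct_spec": res.sens_at_full_spec,
                     "low_is_positive": res.low_is_positive}
                )
        report.outputs["effect_roc"] = [_write(pd.DataFrame(rows), out / "stratification.csv")]
        report.timings_s["effect_roc"] = round(time.perf_counter() - t0, 3)

    # ---- voxel classification -----------------------------------------
    if _stage("classify"):
        t0 = time.perf_counter()
        patients = [s for s in scans if s.group in ("responder", "non_responder")]
        for scan in patients:
            maps[scan.subject_id] = parametric_map(scan, config.t_star_min, config.fit_weights)
        features = extract_feature_matrix(
            [maps[s.subject_id] for s in patients],
            [s.group for s in patients],
            mask,
            [s.subject_id for s in patients],
        )
        rows = []
        for family in config.classifier_families:
            spec = ModelSpec(family=family)
            n_seeds = config.classifier_seeds if spec.stochastic else 1
            base = config.master_seed * 10_000
            cv = loocv_evaluate(spec, features, seeds=range(base, base + n_seeds))
            rows.append(
                {"model": family, "mean_auc": cv.mean_auc, "sd_auc": cv.sd_auc,
                 "n_seeds": cv.n_seeds, "n_failed_folds": cv.n_failed_folds}
            )
        report.outputs["classify"] = [_write(pd.DataFrame(rows), out / "classification.csv")]
        report.timings_s["classify"] = round(time.perf_counter() - t0, 3)

    # ---- economics -----------------------------------------------------
    if _stage("econ"):
        t0 = time.perf_counter()
        scn = config.econ_scenario
        outcome = econ_outcome(scn)
        try:
            brk = breakeven_sensitivity(scn, scn.specificity)
        except ValueError:
            brk = None
        out_row = {**asdict(outcome), "breakeven_sensitivity": brk,
                   "sensitivity": scn.sensitivity, "specificity": scn.specificity}
        surface = savings_surface(scn)
        files = [
            _write(pd.DataFrame([out_row]), out / "econ_outcome.csv"),
            _write(surface, out / "econ_surface.csv"),
            write_config(asdict(scn), out / "econ_scenario_echo.cfg").name,
        ]
        report.outputs["econ"] = files
        report.timings_s["econ"] = round(time.perf_counter() - t0, 3)

    (out / "run_report.json").write_text(report.to_json(), encoding="utf-8")
    return report


def write_truth_table(scans) -> pd.DataFrame:
    """Subject-level mean true Ki per striatal region (one row per scan)."""
    rows = []
    for scan in scans:
        row = {"subject_id": scan.subject_id, "group": scan.group,
               "session": scan.session}
        for region in REGIONS:
            idx = scan.mask.region_indices(region)
            row[f"true_ki_{region}_per_min"] = float(scan.truth_ki.ravel()[idx].mean())
        rows.append(row)
    return pd.DataFrame(rows)
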