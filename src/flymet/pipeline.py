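"""End-to-end pipeline: simulate -> respirometry -> survival -> stats.

Each stage reads/writes delimited text under an output directory and the
resolved configuration is always serialized alongside, so identical
(config, seed) reruns produce byte-identical numerical outputs.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path

import pandas as pd

from . import phenostats, respirometry, simulate, survival
from .config import PipelineConfig
from .io import atomic_write, read_survival_table, read_trace, write_survival_table, write_trace

__all__ = ["run_pipeline", "simulate_stage", "respire_stage", "survive_stage", "stats_stage"]

log = logging.getLogger("flymet")


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    with atomic_write(path) as fh:
        frame.to_csv(fh, index=False)


def simulate_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    """Generate traces per genotype, a survival cohort, and climbing trials."""
    outdir = Path(outdir)
    tracedir = outdir / "traces"
    trace_paths = []
    for gi, (genotype, coupling) in enumerate(sorted(cfg.sim_couplings.items())):
        for age_i, age in enumerate(("young", "old")):
            for k in range(cfg.sim_n_flies):
                spec = simulate.RespSynthSpec(
                    duration_s=cfg.sim_duration_s,
                    smr_uW=cfg.sim_smr_uW,
                    activity_coupling_uW=coupling,
                    noise_sd_ppm=cfg.sim_noise_sd_ppm,
                    mass_mg=cfg.sim_mass_mg,
                    flow_ml_min=cfg.sim_flow_ml_min,
                    fly_id=f"{genotype}_{age}_{k:02d}",
                    genotype=genotype,
                    age_class=age,
                    seed=cfg.seed + 1000 * gi + 100 * age_i + k,
                )
                trace = simulate.gen_resp_trace(spec)
                trace_paths.append(write_trace(trace, tracedir / f"{spec.fly_id}.csv"))
    cohort = simulate.gen_cohort(simulate.CohortSynthSpec(
        groups={g: tuple(ab) for g, ab in cfg.sim_gompertz.items()},
        n_per_group=cfg.sim_cohort_n,
        censor_prob=cfg.sim_censor_prob,
        time_unit=cfg.time_unit,
        seed=cfg.seed + 7,
    ))
    cohort_path = write_survival_table(cohort, outdir / "cohort.csv")
    climbing = []
    for gi, (genotype, mean) in enumerate(sorted(cfg.sim_climbing_means.items())):
        trials = simulate.gen_climbing_trials(
            cfg.sim_climbing_n_flies, mean, cfg.sim_climbing_sd, seed=cfg.seed + 31 + gi)
        trials.insert(0, "genotype", genotype)
        climbing.append(trials)
    climbing_path = outdir / "climbing.csv"
    _write_csv(pd.concat(climbing, ignore_index=True), climbing_path)
    log.info("simulated %d traces, cohort of %d, climbing trials",
             len(trace_paths), len(cohort))
    return {"traces": trace_paths, "cohort": cohort_path, "climbing": climbing_path}


def respire_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    """Process every trace into segments, SMR, and homeostasis verdicts."""
    outdir = Path(outdir)
    tracedir = outdir / "traces"
    seg_frames, smr_rows = [], []
    for path in sorted(tracedir.glob("*.csv")):
        trace = read_trace(path)
        seg_frames.append(respirometry.segment_metrics(
            trace, segment_s=cfg.segment_s, rq=cfg.rq,
            mass_exponent=cfg.mass_exponent, drift_method=cfg.drift_method))
        est = respirometry.standard_metabolic_rate(
            trace, window_s=cfg.smr_window_s, quiescence_quantile=cfg.smr_quantile,
            rq=cfg.rq, mass_exponent=cfg.mass_exponent, drift_method=cfg.drift_method)
        smr_rows.append({"fly_id": trace.fly_id, "genotype": trace.genotype,
                         "age_class": trace.age_class, "smr": est.smr,
                         "used_fallback": est.used_fallback})
    segments = pd.concat(seg_frames, ignore_index=True)
    _write_csv(segments, outdir / "segments.csv")
    _write_csv(pd.DataFrame(smr_rows), outdir / "smr.csv")
    reports = []
    for (genotype, age), sub in segments.groupby(["genotype", "age_class"]):
        res = respirometry.homeostasis_regression(sub, f"{genotype}/{age}", alpha=cfg.alpha)
        reports.append(res.to_dict())
    _write_csv(pd.DataFrame(reports), outdir / "homeostasis.csv")
    log.info("respirometry: %d segments, %d groups", len(segments), len(reports))
    return {"segments": outdir / "segments.csv", "smr": outdir / "smr.csv",
            "homeostasis": outdir / "homeostasis.csv"}


def survive_stage(cfg: PipelineConfig, outdir: Path,
                  table_path: Path | None = None) -> dict:
    """KM curves, corrected pairwise rank tests, and lifespan summaries."""
    outdir = Path(outdir)
    table = read_survival_table(table_path or outdir / "cohort.csv")
    groups = list(table["genotype"].unique())
    km_rows = []
    for g in groups:
        curve = survival.km_estimate(table, g)
        km_rows.append(pd.DataFrame({
            "group": g, "time": curve.times, "survival": curve.survival,
            "at_risk": curve.at_risk, "observed": curve.observed,
        }))
    _write_csv(pd.concat(km_rows, ignore_index=True), outdir / "km_curves.csv")
    pairs = list(itertools.combinations(groups, 2))
    results = survival.multi_compare(table, pairs, method=cfg.correction_method)
    _write_csv(pd.DataFrame([r.to_dict() for r in results]), outdir / "survival_tests.csv")
    summary = survival.lifespan_summary(table, groups, cfg.max_lifespan_definition)
    _write_csv(summary, outdir / "lifespan_summary.csv")
    log.info("survival: %d groups, %d pairwise tests", len(groups), len(pairs))
    return {"km": outdir / "km_curves.csv", "tests": outdir / "survival_tests.csv",
            "summary": outdir / "lifespan_summary.csv"}


def stats_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    """Gated comparisons of SMR and climbing scores across genotypes."""
    outdir = Path(outdir)
    results = []
    smr = pd.read_csv(outdir / "smr.csv")
    for age, sub in smr.groupby("age_class"):
        ms = sub.rename(columns={"genotype": "group", "smr": "value"})
        res = phenostats.dispatch_test(ms, alpha_norm=cfg.alpha)
        results.append({"measure": f"smr[{age}]", **res.to_dict()})
    climbing = pd.read_csv(outdir / "climbing.csv")
    scores = {g: phenostats.climbing_score(sub)
              for g, sub in climbing.groupby("genotype")}
    _write_csv(pd.DataFrame([{"genotype": g, "score": s} for g, s in scores.items()]),
               outdir / "climbing_scores.csv")
    _write_csv(pd.DataFrame(results), outdir / "stats.csv")
    log.info("stats: %d dispatch results", len(results))
    return {"stats": outdir / "stats.csv", "climbing_scores": outdir / "climbing_scores.csv"}


def run_pipeline(cfg: PipelineConfig, outdir: str | Path,
                 stages: tuple[str, ...] = ("simulate", "respire", "survive", "stats"),
                 ) -> dict:
    """Run the requested stages in order; always emits the resolved config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "resolved_config.yaml")
    artifacts: dict = {}
    runners = {"simulate": simulate_stage, "respire": respire_stage,
               "survive": survive_stage, "stats": stats_stage}
    for stage in stages:
        if stage not in runners:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            artifacts.update(runners[stage](cfg, outdir))
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return artifacts
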