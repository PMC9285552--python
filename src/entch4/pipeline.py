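"""End-to-end orchestration of simulate -> process -> fit -> evaluate.

A single :class:`RunConfig` (usually loaded from YAML) drives a
reproducible run: simulate a feeding trial (cows in Latin-square
groups on three diets, AMS visit traces, head-box measurements,
activity logs), process the traces with the sniffer and head-box
stages, fit the time-after-eating mixed model, adjust AMS ratios to
0 h, predict daily CH4 by the regression equation and the HPU
CO2-tracer route, and compare predictions against the head-box
"observed" emissions with through-origin regressions. Outputs are
CSV tables plus a JSON run log carrying the seed and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import headbox as hb
from . import models, sniffer, synthdata
from .formulas import (
    CH4_ENERGY_KJ_PER_L,
    compute_hpu,
    load_equations,
    predict_ch4_hpu,
)

logger = logging.getLogger("entch4")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for one reproducible pipeline run."""

    seed: int = synthdata.DEFAULT_SEED
    out_dir: str = "run_out"
    # simulation scale
    n_squares: int = 2
    cows_per_square: int = 3
    visits_per_cow_diet: int = 4
    visit_duration_s: int = 420
    headbox_reps: int = 4
    # processing parameters
    co2_threshold_ppm: float = sniffer.DEFAULT_CO2_THRESHOLD_PPM
    min_retained_s: int = sniffer.DEFAULT_MIN_RETAINED_S
    background_window_s: int = sniffer.DEFAULT_BACKGROUND_S
    background_rule: str = "pre"  # pre | post | both
    peak_distance_s: int = sniffer.DEFAULT_PEAK_DISTANCE_S
    peak_prominence: float | None = None
    # prediction
    equation: str = "eq2"
    recovery_correction: bool = False
    recovery_factor: float = 1.0
    ch4_energy_kj_per_l: float = CH4_ENERGY_KJ_PER_L
    # optional pre-existing inputs (skip simulation when set)
    traces_dir: str | None = None
    activity_file: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML mapping; unknown keys are rejected."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    bad = set(raw) - known
    if bad:
        raise ValueError(f"unknown config key(s) {sorted(bad)}")
    return RunConfig(**raw)


def _simulate_trial(cfg: RunConfig) -> dict:
    """Simulate the feeding trial: per-visit AMS traces with known
    latent ratios, per-cow head-box measurements, and cow records."""
    rng = np.random.default_rng(cfg.seed)
    tcfg = synthdata.TraceConfig(visit_duration_s=cfg.visit_duration_s, seed=cfg.seed)
    visits = []
    cows = []
    headbox_rows = []
    for s in range(cfg.n_squares):
        for c in range(cfg.cows_per_square):
            cow_id = f"sq{s}_cow{c}"
            lw = float(rng.normal(680.0, 30.0))
            ecm = float(rng.normal(35.0, 3.0))
            cow_shift = float(rng.normal(0.0, 0.005))
            cows.append(
                {"cow_id": cow_id, "square": f"sq{s}", "live_weight": lw, "ecm": ecm,
                 "cow_ratio_shift": cow_shift}
            )
            for diet in ("LF", "MF", "HF"):
                # head-box reference: measured right after eating (t ~ 0.1 h)
                latent0 = (
                    tcfg.base_ratio + tcfg.diet_offsets[diet] + cow_shift
                    + tcfg.ratio_time_slope * 0.1
                )
                hpu = compute_hpu(lw, ecm, 0.0)
                true_daily = predict_ch4_hpu(max(latent0, 1e-4), hpu.hpu)
                for rep in range(cfg.headbox_reps):
                    trace = synthdata.gen_headbox_measurement(
                        true_daily, ratio=max(latent0, 1e-4), conc_noise_sd=5.0, rng=rng
                    )
                    flux = hb.compute_flux(
                        trace,
                        sniffer.Background(ch4=20.0, co2=600.0),
                        recovery_factor=cfg.recovery_factor if cfg.recovery_correction else 1.0,
                    )
                    headbox_rows.append(
                        {
                            "cow_id": cow_id,
                            "diet": diet,
                            "rep": rep,
                            "ch4_daily": flux.ch4_daily,
                            "ratio": flux.ratio,
                            "true_daily": true_daily,
                        }
                    )
                for v in range(cfg.visits_per_cow_diet):
                    tae = float(rng.uniform(0.0, 8.0))
                    trace, truth = synthdata.gen_ams_visit(
                        tcfg, time_after_eating_h=tae, diet=diet,
                        cow_ratio_shift=cow_shift, rng=rng,
                    )
                    bg = sniffer.Background(ch4=tcfg.bg_ch4, co2=tcfg.bg_co2)
                    summary = sniffer.summarize_visit(
                        trace,
                        bg,
                        visit_id=f"{cow_id}_{diet}_v{v}",
                        cow_id=cow_id,
                        diet=diet,
                        co2_threshold=cfg.co2_threshold_ppm,
                        min_retained=cfg.min_retained_s,
                        peak_distance_s=cfg.peak_distance_s,
                        peak_prominence=cfg.peak_prominence,
                    )
                    row = vars(summary).copy()
                    row.update(
                        square=f"sq{s}",
                        time=tae,
                        latent_ratio=truth["latent_ratio"],
                    )
                    visits.append(row)
    return {
        "visits": pd.DataFrame(visits),
        "cows": pd.DataFrame(cows),
        "headbox": pd.DataFrame(headbox_rows),
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write outputs under ``out_dir``.

    Returns a dict with the visit table, head-box table, mixed fit,
    prediction table and agreement table. Every stage failure is
    re-raised as :class:`PipelineError` naming the stage.
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.traces_dir is not None and not Path(cfg.traces_dir).exists():
        raise PipelineError("inputs", f"trace directory {cfg.traces_dir!r} does not exist")

    try:
        sim = _simulate_trial(cfg)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", str(e)) from e
    visits = sim["visits"]
    headbox_df = sim["headbox"]
    logger.info("simulated %d visits, %d head-box measurements", len(visits), len(headbox_df))

    try:
        valid = visits[visits["valid"]].copy()
        fit = models.fit_time_model(valid, response="ratio")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("fit", str(e)) from e

    try:
        valid["ratio_adj0"] = [
            sniffer.adjust_ratio_to_zero(r, t, d, fit)
            for r, t, d in zip(valid["ratio"], valid["time"], valid["diet"])
        ]
        per_cow_diet = (
            valid.groupby(["cow_id", "diet"], as_index=False)
            .agg(ratio=("ratio", "mean"), ratio_adj0=("ratio_adj0", "mean"))
        )
        hb_mean = (
            headbox_df.groupby(["cow_id", "diet"], as_index=False)
            .agg(ch4_obs=("ch4_daily", "mean"), hb_ratio=("ratio", "mean"))
        )
        merged = per_cow_diet.merge(hb_mean, on=["cow_id", "diet"])
        merged = merged.merge(sim["cows"][["cow_id", "live_weight", "ecm"]], on="cow_id")
        eq = load_equations()[cfg.equation]
        preds = {}
        for label, ratio_col in (
            ("equation_ams", "ratio"),
            ("equation_ams_adj0", "ratio_adj0"),
            ("equation_headbox", "hb_ratio"),
        ):
            preds[label] = np.array(
                [
                    eq({"LW": lw, "ECM": ecm, "CH4CO2": r})
                    for lw, ecm, r in zip(merged["live_weight"], merged["ecm"], merged[ratio_col])
                ]
            )
        hpus = [compute_hpu(lw, ecm, 0.0).hpu for lw, ecm in zip(merged["live_weight"], merged["ecm"])]
        for label, ratio_col in (("hpu_ams", "ratio"), ("hpu_ams_adj0", "ratio_adj0"), ("hpu_headbox", "hb_ratio")):
            preds[label] = np.array(
                [predict_ch4_hpu(max(r, 0.0), h) for r, h in zip(merged[ratio_col], hpus)]
            )
        for label, arr in preds.items():
            merged[f"pred_{label}"] = arr
    except Exception as e:  # noqa: BLE001
        raise PipelineError("predict", str(e)) from e

    try:
        agreement = models.evaluate_predictions(merged["ch4_obs"].to_numpy(), preds)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("evaluate", str(e)) from e

    try:
        float_fmt = "%.10g"
        visits.drop(columns=["start_time"], errors="ignore").to_csv(
            out / "visits.csv", index=False, float_format=float_fmt
        )
        headbox_df.to_csv(out / "headbox.csv", index=False, float_format=float_fmt)
        merged.to_csv(out / "predictions.csv", index=False, float_format=float_fmt)
        agreement.to_csv(out / "agreement.csv", float_format=float_fmt)
        fit.fixed.to_csv(out / "time_model_fixed.csv", float_format=float_fmt)
        log = {
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "n_visits": int(len(visits)),
            "n_valid_visits": int(visits["valid"].sum()),
            "n_headbox": int(len(headbox_df)),
            "time_slope": fit.coef("time"),
            "elapsed_s": round(time.time() - t0, 2),
        }
        with open(out / "run_log.json", "w", encoding="utf-8") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("report", str(e)) from e

    return {
        "visits": visits,
        "headbox": headbox_df,
        "time_model": fit,
        "predictions": merged,
        "agreement": agreement,
        "log": log,
    }
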