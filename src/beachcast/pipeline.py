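"""End-to-end orchestration: simulate -> qpcr -> preprocess -> fit ->
evaluate -> correlate -> influence.

Every stage reads and writes the package's plain-text formats (CSV with "."
decimals, ISO-8601 dates, "ND" for undetected Ct, "NA" for unavailable
covariates) and all randomness flows from named seeds in the config.  The
run finishes by writing a manifest listing every produced file with its
SHA-256 content hash, so two runs of the same config are hash-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from beachcast import __version__
from beachcast.correlate import correlation_matrix
from beachcast.evaluate import build_board, score_frame
from beachcast.influence import (
    coefficient_table,
    full_data_coefficients,
    heatmap_matrix,
    influence_scores,
    write_heatmap_csv,
)
from beachcast.lars import lars_fit, select_min_cp
from beachcast.preprocess import BeachSeason, build_model_frame
from beachcast.qpcr import QPCRRun, ddct_quantify, fit_composite_curve, run_qc
from beachcast.simulate import DEFAULT_INDICATOR_TRUTHS, QPCRSimConfig, simulate_qpcr_run, simulate_season

logger = logging.getLogger("beachcast.pipeline")

ALL_STAGES = ("simulate", "qpcr", "preprocess", "fit", "evaluate", "correlate", "influence")

INFLUENCE_GROUPS = {
    "rainfall": ["rain_24h", "rain_72h"],
    "wind": ["wind_a", "wind_o"],
}


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 0
    n_events: int = 65
    site: str = "synthetic_beach"
    k_folds: int = 10
    n_reps: int = 100
    collinearity_threshold: float = 0.8
    exclude: list[str] = field(default_factory=lambda: ["uv254", "rain_48h"])
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    indicators: list[str] | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        known = set(DEFAULT_INDICATOR_TRUTHS)
        if self.indicators is not None:
            bad = set(self.indicators) - known
            if bad:
                raise ValueError(f"unknown indicator(s): {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValueError(f"invalid config field: {exc}") from exc


def _season_limits_transforms(truth: dict) -> tuple[dict, dict]:
    limits = {k: v["censor_limit"] for k, v in truth["indicators"].items()}
    transforms = {k: v["response_transform"] for k, v in truth["indicators"].items()}
    return limits, transforms


def run_pipeline(config: PipelineConfig, dry_run: bool = False) -> dict:
    """Execute the requested stages in order; returns the artifact manifest.

    ``dry_run`` validates the whole config (including stage order and
    indicator names) without computing anything.
    """
    if dry_run:
        return {"dry_run": True, "config_valid": True, "stages": list(config.stages)}
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []
    timings: dict[str, float] = {}

    def track(path: Path) -> Path:
        produced.append(path)
        return path

    truths = DEFAULT_INDICATOR_TRUTHS
    if config.indicators is not None:
        truths = {k: truths[k] for k in config.indicators}

    season_df = truth = None
    if "simulate" in config.stages:
        t = time.time()
        season_df, truth = simulate_season(
            seed=config.seed, n_events=config.n_events, site=config.site,
            indicator_truths=truths,
        )
        season_df.to_csv(track(out / "season.csv"), index=False)
        (track(out / "truth.json")).write_text(json.dumps(truth, indent=1))
        qrun = simulate_qpcr_run(QPCRSimConfig(seed=config.seed))
        qrun.to_csv(track(out / "qpcr_run.csv"))
        timings["simulate"] = time.time() - t
        logger.info("simulate: %d events, %d indicators", config.n_events, len(truths))

    if "qpcr" in config.stages:
        t = time.time()
        qrun = QPCRRun.from_csv(out / "qpcr_run.csv")
        # the simulator's gate reference windows travel in the truth file,
        # not the plate CSV; re-derive them for QC
        qrun.gate_thresholds = simulate_qpcr_run(QPCRSimConfig(seed=config.seed)).gate_thresholds
        std = qrun.subset("standard", "target")
        curve = fit_composite_curve(std["log10_copies"], std["ct"])
        (track(out / "standard_curve.json")).write_text(json.dumps({
            "slope": curve.slope, "intercept": curve.intercept,
            "efficiency": curve.efficiency, "amp_base": curve.amp_base,
            "llq_copies_per_reaction": curve.llq_copies_per_reaction,
            "llq_ct": curve.llq_ct,
        }, indent=1))
        report = run_qc(qrun, curve=curve)
        report.gates.to_csv(track(out / "qc_report.csv"), index=False)
        quant_rows = []
        tests = qrun.subset("test")
        for sid, grp in tests.groupby("sample_id"):
            tct = grp.loc[grp["assay"] == "target", "ct"].mean()
            sct = grp.loc[grp["assay"] == "Sketa22", "ct"].mean()
            res = ddct_quantify(tct, sct, qrun, curve)
            quant_rows.append({
                "sample_id": sid, "copies_per_100ml": res.copies_per_100ml,
                "log10_value": res.log10_value, "below_llq": res.below_llq,
                "method": res.method,
            })
        pd.DataFrame(quant_rows).to_csv(track(out / "quant_results.csv"), index=False)
        timings["qpcr"] = time.time() - t
        logger.info("qpcr: curve slope %.3f, overall QC pass=%s", curve.slope, report.overall_pass)

    frames = {}
    if {"preprocess", "fit", "evaluate", "correlate", "influence"} & set(config.stages):
        season_df = pd.read_csv(out / "season.csv")
        truth = json.loads((out / "truth.json").read_text())
        limits, transforms = _season_limits_transforms(truth)
        season = BeachSeason(
            site=config.site, events=season_df, limits=limits, transforms=transforms
        )

    if "preprocess" in config.stages:
        t = time.time()
        (out / "frames").mkdir(exist_ok=True)
        for ind in season.indicators:
            frame = build_model_frame(
                season, ind,
                collinearity_threshold=config.collinearity_threshold,
                exclude=config.exclude,
            )
            frame.to_csv(track(out / "frames" / f"{ind}.csv"))
            track(out / "frames" / f"{ind}.json")
            frames[ind] = frame
        timings["preprocess"] = time.time() - t
        logger.info("preprocess: %d model frames", len(frames))

    def _load_frames() -> dict:
        from beachcast.preprocess import ModelFrame
        return {
            p.stem: ModelFrame.from_csv(p) for p in sorted((out / "frames").glob("*.csv"))
        }

    if "fit" in config.stages:
        t = time.time()
        frames = frames or _load_frames()
        (out / "fits").mkdir(exist_ok=True)
        for ind, frame in frames.items():
            path = lars_fit(frame.X, frame.y)
            path.to_frame().to_csv(track(out / "fits" / f"{ind}_path.csv"), index=False)
            model = select_min_cp(path)
            (track(out / "fits" / f"{ind}_selected.json")).write_text(json.dumps({
                "intercept": model.intercept,
                "coefficients": {k: float(v) for k, v in model.coefficients.items()},
                "active_set": model.active_set,
                "selected_step": path.selected_step,
            }, indent=1))
        timings["fit"] = time.time() - t
        logger.info("fit: %d LARS paths", len(frames))

    if "evaluate" in config.stages:
        t = time.time()
        frames = frames or _load_frames()
        (out / "cv").mkdir(exist_ok=True)
        rows = []
        for ind, frame in frames.items():
            score = score_frame(frame, k=config.k_folds, seed=config.seed)
            score.pop("cv").table.to_csv(track(out / "cv" / f"{ind}.csv"), index=False)
            rows.append(score)
        board = build_board(pd.DataFrame(rows))
        board.to_csv(track(out / "performance_board.csv"), index=False)
        timings["evaluate"] = time.time() - t
        logger.info("evaluate: board of %d models, best %s (%.2f)",
                    len(board), board.loc[board["overall_performance"].idxmax(), "indicator"],
                    board["overall_performance"].max())

    if "correlate" in config.stages:
        t = time.time()
        limits, transforms = _season_limits_transforms(truth)
        conc = season_df[[f"{i}_conc" for i in limits]].rename(
            columns=lambda c: c[: -len("_conc")]
        )
        cens = season_df[[f"{i}_censored" for i in limits]].rename(
            columns=lambda c: c[: -len("_censored")]
        )
        mean_r, sd_r, p = correlation_matrix(
            conc, cens, limits, transforms, n_reps=config.n_reps, seed=config.seed
        )
        mean_r.to_csv(track(out / "correlation_mean_r.csv"))
        sd_r.to_csv(track(out / "correlation_sd_r.csv"))
        p.to_csv(track(out / "correlation_p.csv"))
        timings["correlate"] = time.time() - t
        logger.info("correlate: %d indicator pairs", len(mean_r) * (len(mean_r) - 1) // 2)

    if "influence" in config.stages:
        t = time.time()
        frames = frames or _load_frames()
        models = {
            (config.site, ind): full_data_coefficients(frame) for ind, frame in frames.items()
        }
        table = coefficient_table(models)
        scores = influence_scores(
            table, groups={g: m for g, m in INFLUENCE_GROUPS.items()
                           if set(m) <= set(table.columns)}
        )
        scores.to_csv(track(out / "influence_table.csv"))
        heat = heatmap_matrix({ind: coefs for (_, ind), coefs in models.items()})
        write_heatmap_csv(heat, track(out / f"heatmap_{config.site}.csv"))
        timings["influence"] = time.time() - t
        logger.info("influence: top covariate %s", scores.index[0])

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "files": {
            str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(set(produced))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline finished in %.1fs; %d artifacts", time.time() - t0,
                len(manifest["files"]))
    return manifest
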