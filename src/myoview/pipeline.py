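"""End-to-end pipeline: simulate → featurize → train → evaluate → clinstats.

One YAML config and one global seed drive a whole run; every stage derives
its own seed as ``(global_seed XOR crc32(stage_name)) mod 2**31``, so stages
are decorrelated but fully reproducible.  The pipeline writes a manifest of
every produced file with content hashes; a failing stage halts the run with
the stage name after persisting the partial manifest.
"""

from __future__ import annotations

import json
import sys
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .clinical import compare_groups, hb_summary
from .networks import NetworkSpec, build_network
from .presets import (
    COMPLEMENTARY_VIEW_IDS,
    DEFAULT_NOISE_RMS,
    complementary_classes,
)
from .synth import (
    GestureClassParams,
    default_cohort_params,
    simulate_cohort,
    simulate_semg,
)
from .training import MultiViewDataset, TrainConfig, evaluate_result, train
from .views import VIEWS, build_multiview, segment


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (one YAML file)."""

    seed: int = 0
    out_dir: str = "run"
    n_trials_per_class: int = 20
    trial_len: float = 1.0
    fs: float = 1000.0
    noise_rms: float = DEFAULT_NOISE_RMS
    view_ids: tuple[int, ...] = COMPLEMENTARY_VIEW_IDS
    window_ms: float = 200.0
    overlap: float = 0.5
    conv_channels: int = 8
    fc_units: int = 32
    epochs: int = 40
    patience: int = 8
    classes: list[dict] = field(default_factory=list)
    version: str = "0.1.0"

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        cfg = RunConfig(**d)
        cfg.view_ids = tuple(cfg.view_ids)
        return cfg

    def gesture_classes(self) -> list[GestureClassParams]:
        if not self.classes:
            return complementary_classes()
        return [
            GestureClassParams(
                class_id=int(c["class_id"]),
                amplitude_uv=tuple(np.atleast_1d(c["amplitude_uv"]).tolist()),
                passband_hz=tuple(c["passband_hz"]),
                duty_cycle=float(c.get("duty_cycle", 1.0)),
            )
            for c in self.classes
        ]


def stage_seed(global_seed: int, stage: str) -> int:
    """Documented derivation rule: global seed XOR crc32(stage), mod 2³¹."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _log(msg: str, **extra) -> None:
    print(json.dumps({"msg": msg, **extra}), file=sys.stderr)


def run_pipeline(cfg: RunConfig) -> mio.Manifest:
    """Execute all stages in order and return the verified manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = mio.Manifest(stage="init", config=cfg.__dict__ | {
        "view_ids": list(cfg.view_ids)})
    manifest_path = out / "manifest.json"

    def run_stage(name, fn):
        manifest.stage = name
        _log(f"stage {name}", seed=stage_seed(cfg.seed, name))
        try:
            return fn()
        except Exception as e:
            manifest.write(manifest_path)
            raise PipelineError(name, e) from e

    def _simulate():
        rec = simulate_semg(
            cfg.gesture_classes(), cfg.n_trials_per_class, cfg.trial_len,
            fs=cfg.fs, seed=stage_seed(cfg.seed, "simulate"),
            noise_rms=cfg.noise_rms,
        )
        p = mio.write_recording(rec, out / "recording", fmt="npz")
        manifest.add(p, out)
        return rec

    rec = run_stage("simulate", _simulate)

    def _featurize():
        window = int(round(cfg.window_ms / 1000 * cfg.fs))
        step = max(1, int(round(window * (1 - cfg.overlap))))
        windows = segment(rec, window, step)
        samples = build_multiview(windows, [VIEWS[v] for v in cfg.view_ids])
        ds = MultiViewDataset.from_samples(samples, cfg.view_ids)
        p = mio.write_dataset(ds, out / "features")
        manifest.add(p, out)
        manifest.add(p.with_suffix("").with_suffix(".manifest.json"), out)
        return ds

    ds = run_stage("featurize", _featurize)

    def _train():
        spec = NetworkSpec.small(ds.n_classes, ds.view_shapes,
                                 conv_channels=cfg.conv_channels,
                                 fc_units=cfg.fc_units)
        model = build_network(spec, seed=stage_seed(cfg.seed, "train"))
        tcfg = TrainConfig(epochs=cfg.epochs, patience=cfg.patience,
                           seed=stage_seed(cfg.seed, "train"))
        res = train(model, ds, tcfg)
        p = mio.save_model(model, out / "model", view_ids=cfg.view_ids)
        manifest.add(p, out)
        manifest.add(p.with_suffix(".json"), out)
        return res

    res = run_stage("train", _train)

    def _evaluate():
        rep = evaluate_result(res)
        p = out / "evaluation.json"
        p.write_text(json.dumps({
            "arch": rep.arch,
            "accuracy": rep.accuracy,
            "confusion": rep.confusion.tolist(),
            "n_test": int(rep.confusion.sum()),
        }, indent=1))
        manifest.add(p, out)
        return rep

    run_stage("evaluate", _evaluate)

    def _cohort():
        records = simulate_cohort(default_cohort_params(),
                                  seed=stage_seed(cfg.seed, "simulate-cohort"))
        p = mio.write_cohort(records, out / "cohort.csv")
        manifest.add(p, out)
        return records

    records = run_stage("simulate-cohort", _cohort)

    def _clinstats():
        report = clinical_report(records)
        p = out / "clinstats.json"
        p.write_text(json.dumps(report, indent=1))
        manifest.add(p, out)
        return report

    run_stage("clinstats", _clinstats)

    manifest.stage = "done"
    manifest.write(manifest_path)
    return manifest


def clinical_report(records, alpha: float = 0.05) -> dict:
    """H-B summaries, the effective-rate chi-square and per-parameter
    post-treatment t-tests for a two-arm cohort."""
    ctrl = hb_summary(records, "control")
    trt = hb_summary(records, "treatment")
    rate_test = compare_groups(ctrl, trt, kind="rate", alpha=alpha)
    out = {
        "control": {"counts": list(ctrl.counts), "n": ctrl.n,
                    "effective_rate": ctrl.effective_rate},
        "treatment": {"counts": list(trt.counts), "n": trt.n,
                      "effective_rate": trt.effective_rate},
        "rate_test": {"statistic": rate_test.statistic, "df": rate_test.df,
                      "p_value": rate_test.p_value,
                      "significant": rate_test.significant},
        "mean_tests": {},
    }
    muscles = sorted({m for r in records for (m, _t) in r.params.keys()})
    for muscle in muscles:
        for param in ("rms", "mf", "mpf"):
            a = [getattr(r.params[(muscle, "post")], param)
                 for r in records if r.group == "control"
                 and (muscle, "post") in r.params]
            b = [getattr(r.params[(muscle, "post")], param)
                 for r in records if r.group == "treatment"
                 and (muscle, "post") in r.params]
            if len(a) < 2 or len(b) < 2:
                continue
            t = compare_groups(a, b, kind="mean", alpha=alpha)
            out["mean_tests"][f"{muscle}_{param}_post"] = {
                "statistic": t.statistic, "df": t.df, "p_value": t.p_value,
                "significant": t.significant,
                "control_mean": float(np.mean(a)),
                "treatment_mean": float(np.mean(b)),
            }
    return out
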