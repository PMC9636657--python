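"""End-to-end reproducible run: simulate -> summarize -> fit -> rank -> optimize.

One global seed derives every stage seed by a fixed offset, so a stage can be
re-run in isolation and a full re-run with the same config produces
byte-identical artifacts.  Every artifact's sha256 is recorded in a run
manifest alongside the config and derived seeds.

The raw and summary CSVs carry the canonical as-written speed (day/mm);
surrogate speed models and the GA's speed objective use the desirability
scale (mm/day, larger = faster growth), recorded as such in the reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .design import summarize_conditions
from .ga import GAConfig, brute_force_optimum, decode_chromosome, optimize
from .metrics import evaluate_model, sensitivity_analysis
from .mlp import MLPConfig, split_train_test, train_mlp
from .rbf import RBFConfig, fit_rbf
from .simulate import GeneratorConfig, simulate_experiment

log = logging.getLogger("callusopt")

# fixed per-stage seed offsets from the global seed
_STAGE_OFFSETS = {"generator": 0, "mlp": 1, "rbf": 2, "ga": 3, "split": 4}
_SEED_MOD = 2**31 - 1


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) + _STAGE_OFFSETS[stage]) % _SEED_MOD


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "callusopt_run"
    n_replicates: int = 24
    n_subsets: int = 3
    subset_effect_sd: float = 0.3
    train_fraction: float = 0.9
    mlp: dict = field(default_factory=dict)
    rbf: dict = field(default_factory=dict)
    ga: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns the run report (also written to disk)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    report: dict = {"seeds": {s: stage_seed(cfg.seed, s) for s in _STAGE_OFFSETS}}
    t_start = time.time()

    def stage(name):
        log.info("stage %s (t=%.1fs)", name, time.time() - t_start)

    try:
        stage("simulate")
        gen = GeneratorConfig(
            seed=stage_seed(cfg.seed, "generator"),
            n_replicates=cfg.n_replicates,
            n_subsets=cfg.n_subsets,
            subset_effect_sd=cfg.subset_effect_sd,
        )
        raw = simulate_experiment(gen)
        raw.to_csv(out / "raw.csv", index=False)
        artifacts["raw"] = out / "raw.csv"
    except Exception as exc:  # noqa: BLE001 - stage name is the diagnostic
        raise StageError("simulate", exc) from exc

    try:
        stage("summarize")
        summaries = summarize_conditions(raw, speed_mode="as_written")
        summaries.to_csv(out / "summaries.csv", index=False)
        artifacts["summaries"] = out / "summaries.csv"
        # desirability-scale speed (mm/day) for modelling and optimisation
        summaries_desir = summarize_conditions(raw, speed_mode="inverted")
    except Exception as exc:
        raise StageError("summarize", exc) from exc

    try:
        stage("train")
        split_seed = stage_seed(cfg.seed, "split")
        mlp_cfg = MLPConfig(seed=stage_seed(cfg.seed, "mlp"),
                            train_fraction=cfg.train_fraction, **cfg.mlp)
        rbf_cfg = RBFConfig(seed=stage_seed(cfg.seed, "rbf"), **cfg.rbf)
        models, metrics = {}, {}
        for target, table in (("percentage", summaries), ("speed", summaries_desir)):
            train, test = split_train_test(table, cfg.train_fraction, split_seed)
            m_mlp = train_mlp(train, target, mlp_cfg)
            m_rbf = fit_rbf(train, target, rbf_cfg)
            models[("mlp", target)] = m_mlp
            models[("rbf", target)] = m_rbf
            for family, model in (("mlp", m_mlp), ("rbf", m_rbf)):
                for split_name, tab in (("train", train), ("test", test)):
                    rep = evaluate_model(model, tab, target, split_name)
                    metrics[f"{family}_{target}_{split_name}"] = {
                        "rmse": rep.rmse, "r2": rep.r2, "n": rep.n,
                    }
                path = out / f"model_{family}_{target}.json"
                model.save(path)
                artifacts[f"model_{family}_{target}"] = path
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
        artifacts["metrics"] = out / "metrics.json"
        report["metrics"] = metrics
    except Exception as exc:
        raise StageError("train", exc) from exc

    try:
        stage("sensitivity")
        sens = {}
        for target, table in (("percentage", summaries), ("speed", summaries_desir)):
            rep = sensitivity_analysis(
                table, target, "mlp", mlp_cfg, seed=stage_seed(cfg.seed, "mlp")
            )
            rep.insert(0, "target", target)
            sens[target] = rep
        sens_table = pd.concat(sens.values(), ignore_index=True)
        sens_table.to_csv(out / "sensitivity.csv", index=False)
        artifacts["sensitivity"] = out / "sensitivity.csv"
        report["sensitivity"] = {
            t: r[["group", "vse", "vsr", "rank"]].to_dict("records")
            for t, r in sens.items()
        }
    except Exception as exc:
        raise StageError("sensitivity", exc) from exc

    try:
        stage("optimize")
        # optimisation surrogates are refit on the full summary table
        opt_pct = train_mlp(summaries, "percentage", mlp_cfg)
        opt_speed = train_mlp(summaries_desir, "speed", mlp_cfg)
        ga_seed = stage_seed(cfg.seed, "ga")
        opt_report = {}
        for objectives in ("percentage", "speed", "both"):
            ga_cfg = GAConfig(seed=ga_seed, objectives=objectives, **cfg.ga)
            res = optimize(opt_pct, opt_speed, ga_cfg)
            oracle = brute_force_optimum(opt_pct, opt_speed, objectives)
            opt_report[objectives] = {
                "best_chromosome": list(res.best_chromosome),
                "best_condition": res.best_condition.as_tuple(),
                "best_objectives": res.best_objectives,
                "matches_exhaustive": res.best_chromosome == oracle.best_chromosome,
                "history_first_last": [res.history[0], res.history[-1]],
                "front": [
                    {"chromosome": list(c), "condition": decode_chromosome(c).as_tuple(),
                     "percentage": p, "speed": s}
                    for c, p, s in res.front
                ],
                "selected_solution": list(res.selected_solution)
                if res.selected_solution else None,
                "selection_rule": res.selection_rule,
            }
        with open(out / "optimization.json", "w") as fh:
            json.dump(opt_report, fh, indent=2, sort_keys=True)
        artifacts["optimization"] = out / "optimization.json"
        report["optimization"] = opt_report
    except Exception as exc:
        raise StageError("optimize", exc) from exc

    manifest = {
        "config": cfg.to_dict(),
        "seeds": report["seeds"],
        "artifacts": {k: {"path": str(p.name), "sha256": _sha256(p)}
                      for k, p in sorted(artifacts.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    report["manifest"] = manifest
    return report
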