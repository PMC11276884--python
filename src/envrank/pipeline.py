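"""End-to-end driver: data -> filter -> screen -> model -> importance -> curves.

The pipeline wires the stages together in the canonical order:

1. load a CSV table or generate a synthetic one;
2. optionally STL-filter the features (trend emphasis);
3. screen multicollinearity and keep one representative per cluster;
4. split train/test, tune a random forest, report test performance;
5. compute PFI, Shapley and kappa-ALE importances with normalisation;
6. evaluate incremental configurations per distinct ranking and select the
   best ranking by curve comparison.

All randomness is derived from one user seed: each stage hashes its name
together with the seed, so re-running a config reproduces every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .forest import default_grid, performance_indices, predict, split_train_test, tune_forest
from .importance import PfiConfig, kappa_ale, normalize_importance, pfi, shapley_importance
from .incremental import compare_rankings, evaluate_configurations
from .io import read_feature_table, write_feature_table
from .preprocess import apply_trend_filter, correlation_matrix, screen_collinearity
from .synthetic import default_spec, generate_environmental_table
from .tables import FeatureTable

__all__ = ["PipelineConfig", "stage_seed", "run_pipeline"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the config seed."""
    digest = hashlib.blake2s(f"{seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible pipeline run."""

    seed: int
    input_path: str | None = None  # CSV; mutually exclusive with synthetic
    synthetic: bool = True
    n_days: int = 1500
    target: str = "CVD"
    # preprocessing
    stl_mode: str = "trend_only"  # trend_only | deseasonalized | none
    stl_period: int = 365
    filter_targets: bool = False
    collinearity_threshold: float = 0.8
    screen_policy: str = "max_target_corr"  # or user_pin / first
    pins: list[str] = field(default_factory=list)
    # split and tuning
    train_fraction: float = 0.8
    split_mode: str = "random"
    grid: list[tuple[int, int]] | None = None
    k_folds: int = 5
    # importance settings
    pfi_loss: str = "squared_error"
    pfi_n_repeats: int = 30
    shap_background: int = 50
    shap_n_explain: int = 100
    ale_K: int = 40
    normalization: str = "sum_to_one"
    zero_policy: str = "exclude"
    importance_on: str = "train"  # or test
    output_dir: str | None = None

    def validate(self) -> None:
        if self.input_path is None and not self.synthetic:
            raise ValueError("either input_path or synthetic must be set")
        if self.stl_mode not in ("trend_only", "deseasonalized", "none"):
            raise ValueError(f"unknown stl_mode {self.stl_mode!r}")
        if self.importance_on not in ("train", "test"):
            raise ValueError(f"importance_on must be train or test")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "grid" in raw and raw["grid"] is not None:
            raw["grid"] = [tuple(p) for p in raw["grid"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _dump(payload: dict, path: Path) -> None:
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; return (and optionally write) the report."""
    cfg.validate()
    report: dict = {"config": cfg.to_dict(), "version": __version__}

    # -- load / generate --------------------------------------------------
    stage = "load"
    try:
        ground_truth = None
        if cfg.input_path is not None:
            table = read_feature_table(cfg.input_path)
        else:
            spec = default_spec(n_days=cfg.n_days, seed=stage_seed(cfg.seed, "generate"))
            table, truths = generate_environmental_table(spec)
            ground_truth = truths.get(cfg.target)
        if cfg.target not in table.target_names:
            raise ValueError(
                f"target {cfg.target!r} not among {table.target_names}"
            )

        stage = "stl_filter"
        filtered = apply_trend_filter(
            table,
            mode=cfg.stl_mode,
            period=cfg.stl_period,
            include_targets=cfg.filter_targets,
        )

        stage = "collinearity_screen"
        corr = correlation_matrix(filtered)
        y = filtered.targets[cfg.target].to_numpy(dtype=float)
        target_corr = {
            c: float(np.corrcoef(filtered.features[c].to_numpy(dtype=float), y)[0, 1])
            for c in filtered.feature_names
        }
        screen = screen_collinearity(
            corr,
            threshold=cfg.collinearity_threshold,
            policy=cfg.screen_policy,
            target_corr=target_corr,
            pins=cfg.pins or None,
        )
        screened = filtered.select_features(screen.kept)

        stage = "split"
        train, test = split_train_test(
            screened, cfg.train_fraction, cfg.split_mode, stage_seed(cfg.seed, "split")
        )

        stage = "tune"
        grid = cfg.grid or default_grid(screened.d)
        forest = tune_forest(
            train, grid=grid, k=cfg.k_folds,
            seed=stage_seed(cfg.seed, "forest"), target=cfg.target,
        )

        stage = "evaluate"
        yhat = predict(forest, test.features)
        perf = performance_indices(
            test.targets[cfg.target].to_numpy(dtype=float), yhat,
            zero_policy=cfg.zero_policy,
        )

        stage = "importance"
        imp_table = train if cfg.importance_on == "train" else test
        est_pfi = pfi(
            forest, imp_table,
            PfiConfig(loss=cfg.pfi_loss, n_repeats=cfg.pfi_n_repeats,
                      seed=stage_seed(cfg.seed, "pfi")),
            target=cfg.target,
        )
        bg_seed = stage_seed(cfg.seed, "shap")
        rng = np.random.default_rng(bg_seed)
        Xtr = imp_table.features.to_numpy(dtype=float)
        take = min(cfg.shap_background, len(Xtr))
        background = Xtr[rng.choice(len(Xtr), size=take, replace=False)]
        est_shap = shapley_importance(
            forest, imp_table, background=background,
            mode="exact" if screened.d <= 15 else "sampled",
            n_explain=cfg.shap_n_explain, seed=bg_seed,
        )
        est_kale = kappa_ale(forest, imp_table, K=cfg.ale_K, target=cfg.target)
        estimates = {
            e.measure: normalize_importance(e, cfg.normalization)
            for e in (est_pfi, est_shap, est_kale)
        }

        stage = "incremental"
        rankings: dict[str, tuple[str, ...]] = {
            m: tuple(e.ranking) for m, e in estimates.items()
        }
        # identical rankings are evaluated once under a joint label
        by_ranking: dict[tuple[str, ...], list[str]] = {}
        for measure, ranking in rankings.items():
            by_ranking.setdefault(ranking, []).append(measure)
        curves = []
        for ranking, measures in by_ranking.items():
            curves.append(
                evaluate_configurations(
                    screened, list(ranking), grid=grid, k_folds=cfg.k_folds,
                    seed=stage_seed(cfg.seed, "incremental"), target=cfg.target,
                    train_fraction=cfg.train_fraction, split_mode=cfg.split_mode,
                    ranking_id="+".join(sorted(measures)),
                    zero_policy=cfg.zero_policy,
                )
            )
        comparison = compare_rankings(curves)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report.update(
        {
            "table": table,
            "ground_truth": ground_truth,
            "screen": screen,
            "forest": forest,
            "performance": perf,
            "importance": estimates,
            "rankings": {m: list(r) for m, r in rankings.items()},
            "curves": {c.ranking_id: c for c in curves},
            "comparison": comparison,
        }
    )

    if cfg.output_dir is not None:
        _write_artifacts(cfg, report)
    return report


def _write_artifacts(cfg: PipelineConfig, report: dict) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_feature_table(report["table"], out / "table.csv")
    _dump(report["screen"].to_dict(), out / "screen.json")
    _dump(report["forest"].summary(), out / "model.json")
    _dump(
        {**report["performance"].to_dict(),
         "zero_policy": report["performance"].zero_policy},
        out / "performance.json",
    )
    records = [
        r for est in report["importance"].values() for r in est.to_records()
    ]
    pd.DataFrame(records).to_csv(out / "importance.csv", index=False)
    _dump(
        {
            m: {"raw": e.raw, "normalized": e.normalized, "ranking": e.ranking}
            for m, e in report["importance"].items()
        },
        out / "importance.json",
    )
    curve_rows = [r for c in report["curves"].values() for r in c.to_records()]
    pd.DataFrame(curve_rows).to_csv(out / "curves.csv", index=False)
    _dump(report["comparison"].to_dict(), out / "comparison.json")
    if report["ground_truth"] is not None:
        gt = report["ground_truth"]
        _dump(
            {"target": gt.target, "effect_variances": gt.effect_variances,
             "signal_features": gt.signal_features},
            out / "ground_truth.json",
        )
    _dump(
        {
            "config": report["config"],
            "version": report["version"],
            "stage_seeds": {
                s: stage_seed(cfg.seed, s)
                for s in ("generate", "split", "forest", "pfi", "shap", "incremental")
            },
            "decisions": {
                "zero_policy": cfg.zero_policy,
                "stl_mode": cfg.stl_mode,
                "ale_K": cfg.ale_K,
                "normalization": cfg.normalization,
                "importance_on": cfg.importance_on,
            },
        },
        out / "log.json",
    )
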