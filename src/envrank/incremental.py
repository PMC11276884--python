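"""Incremental model configurations and ranking comparison.

Given a feature-importance ranking, ``conf_k`` is the forest using only the
top-k features.  Tracing (MAE, MARE, R^2) on a fixed held-out test set as k
grows shows how quickly the ranking concentrates predictive power: a good
ranking makes the error curves fall fast and plateau once the informative
features are in.  Competing rankings are compared by the trapezoidal area
under each index curve (lower is better for MAE/MARE, higher for R^2), with
a two-of-three majority deciding the preferred ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forest import (
    PerformanceTriple,
    performance_indices,
    predict,
    split_train_test,
    tune_forest,
)
from .tables import FeatureTable

__all__ = [
    "ConfigCurve",
    "RankingComparison",
    "build_configurations",
    "evaluate_configurations",
    "compare_rankings",
]


def build_configurations(ranking: list[str]) -> list[list[str]]:
    """Nested top-k subsets of a ranking: [r1], [r1, r2], ..."""
    if not ranking:
        raise ValueError("ranking is empty")
    if len(set(ranking)) != len(ranking):
        raise ValueError(f"ranking contains duplicates: {ranking}")
    return [list(ranking[: k + 1]) for k in range(len(ranking))]


@dataclass
class ConfigCurve:
    """Test-set performance of the nested configurations of one ranking."""

    ranking_id: str
    configurations: list[list[str]]
    per_config: list[PerformanceTriple]
    full_model_reference: PerformanceTriple

    def index_values(self, index: str) -> np.ndarray:
        return np.array([getattr(t, index) for t in self.per_config])

    def to_records(self) -> list[dict]:
        return [
            {
                "ranking_id": self.ranking_id,
                "k": k + 1,
                "features": ",".join(conf),
                **triple.to_dict(),
            }
            for k, (conf, triple) in enumerate(
                zip(self.configurations, self.per_config)
            )
        ]


def evaluate_configurations(
    table: FeatureTable,
    ranking: list[str],
    grid: list[tuple[int, int]] | None = None,
    k_folds: int = 5,
    seed: int = 0,
    target: str | None = None,
    train_fraction: float = 0.8,
    split_mode: str = "random",
    ranking_id: str | None = None,
    zero_policy: str = "exclude",
) -> ConfigCurve:
    """Train one tuned forest per nested configuration on a shared split.

    Every configuration reuses the same train/test partition and the same
    seed; the hyperparameter grid is adapted per configuration by capping
    ``mtry`` at the subset size (so each configuration is tuned in its own
    right rather than inheriting the full model's hyperparameters).
    """
    configurations = build_configurations(ranking)
    train, test = split_train_test(table, train_fraction, split_mode, seed)
    target = target or table.target_names[0]
    y_test = test.targets[target].to_numpy(dtype=float)

    per_config: list[PerformanceTriple] = []
    for conf in configurations:
        sub_train = train.select_features(conf)
        sub_grid = None
        if grid is not None:
            sub_grid = sorted({(t, min(m, len(conf))) for t, m in grid})
        forest = tune_forest(sub_train, grid=sub_grid, k=k_folds, seed=seed, target=target)
        yhat = predict(forest, test.features[conf])
        per_config.append(performance_indices(y_test, yhat, zero_policy=zero_policy))

    return ConfigCurve(
        ranking_id=ranking_id or "+".join(ranking[:1]) + f"_d{len(ranking)}",
        configurations=configurations,
        per_config=per_config,
        full_model_reference=per_config[-1],
    )


@dataclass
class RankingComparison:
    """Area-under-curve summary and winner across competing rankings."""

    curves: dict[str, ConfigCurve]
    summary: dict[str, dict[str, float]]
    selected: str  # ranking_id or "tie"
    wins: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "summary": self.summary,
            "wins": self.wins,
            "selected": self.selected,
        }


def _auc(values: np.ndarray) -> float:
    """Trapezoidal area under the performance curve over k = 1..d."""
    return float(np.trapezoid(values, dx=1.0)) if len(values) > 1 else float(values[0])


def compare_rankings(curves: list[ConfigCurve]) -> RankingComparison:
    """Select the ranking whose curves decay fastest.

    For each index the curve with the strictly best AUC (minimal for MAE and
    MARE, maximal for R^2) scores a win; the selected ranking is the one with
    wins on at least two of the three indices, otherwise ``"tie"``.
    """
    if not curves:
        raise ValueError("no curves to compare")
    lengths = {len(c.per_config) for c in curves}
    if len(lengths) != 1:
        raise ValueError(f"curves have mismatched configuration counts: {lengths}")
    by_id = {c.ranking_id: c for c in curves}
    if len(by_id) != len(curves):
        raise ValueError("duplicate ranking_id among curves")

    summary = {
        rid: {
            "mae_auc": _auc(c.index_values("mae")),
            "mare_auc": _auc(c.index_values("mare")),
            "r2_auc": _auc(c.index_values("r2")),
        }
        for rid, c in sorted(by_id.items())
    }
    wins = {rid: 0 for rid in by_id}
    for index, better in (("mae_auc", min), ("mare_auc", min), ("r2_auc", max)):
        best = better(s[index] for s in summary.values())
        winners = [rid for rid, s in summary.items() if s[index] == best]
        if len(winners) == 1:
            wins[winners[0]] += 1
    leaders = [rid for rid, w in wins.items() if w >= 2]
    selected = leaders[0] if len(leaders) == 1 else "tie"
    return RankingComparison(by_id, summary, selected, wins)
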