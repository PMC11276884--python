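"""Model-agnostic global feature-importance measures.

Three measures, all operating on a fitted prediction function f-hat and a
data sample, none relying on model internals:

PFI (permutation feature importance)
    The rise in expected loss when one feature column is randomly permuted,
    estimated as mean permuted loss minus baseline loss.

Shapley-based importance
    Per-observation Shapley values with the interventional (marginal) value
    function: a coalition's worth is the model output with the coalition's
    features fixed at the observation and the rest replaced by background
    rows, averaged over the background.  The global score per feature is
    the mean absolute Shapley value across observations.  The strict
    game-theoretic definition uses a conditional expectation; the
    interventional average is the tractable standard estimator and is what
    is implemented here.

kappa-ALE (derivative-based importance)
    Built from the accumulated-local-effects (ALE) construction: split the
    feature's support into K quantile intervals, average the prediction
    difference between the interval's endpoints over the observations inside
    it ("local effects"), divide by the interval width (a Newton ratio), and
    average the squared ratios over intervals.  Scaling by the feature/target
    variance ratio makes the score comparable across features:

        kappa_j = (1/K) * sum_k (mean local effect_k / width_k)^2
                  * var(x_j) / var(y)

    For a linear response beta * x_j with independent features this reduces
    to beta^2 var(x_j) / var(y), the share of target variance the feature
    explains.

Raw scores are normalised (sum-to-one by default) for cross-measure
comparison, and each measure yields a descending feature ranking.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import FeatureTable

__all__ = [
    "PfiConfig",
    "AleGrid",
    "ImportanceEstimate",
    "pfi",
    "shapley_importance",
    "ale_curve",
    "kappa_ale",
    "normalize_importance",
    "rank_features",
]

EXACT_SHAPLEY_MAX_D = 15  # 2^15 coalitions; beyond this use sampled mode


# --------------------------------------------------------------------------
# shared containers
# --------------------------------------------------------------------------

@dataclass
class ImportanceEstimate:
    """Raw scores, optional normalised scores and ranking for one measure."""

    measure: str
    raw: dict[str, float]
    normalized: dict[str, float] | None
    ranking: list[str]
    metadata: dict = field(default_factory=dict)

    def to_records(self) -> list[dict]:
        """Tidy rows: measure, feature, raw, normalized, rank."""
        rank_of = {f: i + 1 for i, f in enumerate(self.ranking)}
        return [
            {
                "measure": self.measure,
                "feature": f,
                "raw": self.raw[f],
                "normalized": None if self.normalized is None else self.normalized[f],
                "rank": rank_of[f],
            }
            for f in self.ranking
        ]


def _descending(raw: dict[str, float]) -> tuple[list[str], list[str]]:
    """Descending sort with lexicographic tie-break; returns (order, tied)."""
    order = [f for f, _ in sorted(raw.items(), key=lambda kv: (-kv[1], kv[0]))]
    seen: dict[float, list[str]] = {}
    for f, v in raw.items():
        seen.setdefault(v, []).append(f)
    tied = sorted(f for group in seen.values() if len(group) > 1 for f in group)
    return order, tied


def _make_estimate(measure: str, raw: dict[str, float], metadata: dict) -> ImportanceEstimate:
    ranking, tied = _descending(raw)
    metadata = dict(metadata)
    metadata["ties"] = tied
    return ImportanceEstimate(measure, raw, None, ranking, metadata)


def rank_features(est: ImportanceEstimate) -> list[str]:
    """Descending order of raw score; ties lexicographic, flagged in metadata."""
    if not est.raw:
        raise ValueError("estimate has no raw scores")
    ranking, tied = _descending(est.raw)
    est.metadata["ties"] = tied
    est.ranking = ranking
    return ranking


def normalize_importance(
    est: ImportanceEstimate, scheme: str = "sum_to_one"
) -> ImportanceEstimate:
    """Rescale raw scores for cross-measure comparison (ranking unchanged)."""
    if scheme not in ("sum_to_one", "max_to_one"):
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    values = np.array(list(est.raw.values()), dtype=float)
    denom = values.sum() if scheme == "sum_to_one" else values.max()
    if denom <= 0:
        raise ValueError("all raw scores are zero; nothing to normalize")
    normalized = {f: v / denom for f, v in est.raw.items()}
    meta = dict(est.metadata)
    meta["normalization"] = scheme
    return ImportanceEstimate(est.measure, dict(est.raw), normalized, list(est.ranking), meta)


def _resolve(model, table: FeatureTable, target: str | None) -> tuple[pd.DataFrame, np.ndarray]:
    names = list(model.feature_names)
    X = table.features[names]
    target = target or getattr(model, "target", None) or table.target_names[0]
    y = table.targets[target].to_numpy(dtype=float)
    return X, y


# --------------------------------------------------------------------------
# permutation feature importance
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PfiConfig:
    """Settings for permutation importance."""

    loss: str = "squared_error"  # or absolute_error
    n_repeats: int = 30
    seed: int = 0
    exhaustive: bool = False  # average over all n! permutations (tiny n only)

    def loss_fn(self):
        if self.loss == "squared_error":
            return lambda y, f: float(np.mean((y - f) ** 2))
        if self.loss == "absolute_error":
            return lambda y, f: float(np.mean(np.abs(y - f)))
        raise ValueError(f"unknown loss {self.loss!r}")


def pfi(
    model,
    table: FeatureTable,
    cfg: PfiConfig = PfiConfig(),
    target: str | None = None,
) -> ImportanceEstimate:
    """Permutation importance: mean permuted-column loss minus baseline loss.

    Negative raw values (possible through sampling noise) are clipped at 0;
    the pre-clip means and their Monte-Carlo standard errors are kept in the
    metadata.
    """
    if table.n < 2:
        raise ValueError("permutation importance needs at least 2 rows")
    loss = cfg.loss_fn()
    Xdf, y = _resolve(model, table, target)
    X = Xdf.to_numpy(dtype=float)
    n = len(y)
    baseline = loss(y, model.predict(X))

    if cfg.exhaustive and n > 8:
        raise ValueError(f"exhaustive permutations infeasible for n={n} (> 8)")
    perms: list[np.ndarray] | None = None
    if cfg.exhaustive:
        perms = [np.array(p) for p in itertools.permutations(range(n))]

    rng = np.random.default_rng(cfg.seed)
    raw_preclip: dict[str, float] = {}
    se: dict[str, float] = {}
    for j, name in enumerate(model.feature_names):
        diffs = []
        iters = perms if perms is not None else range(cfg.n_repeats)
        for it in iters:
            perm = it if perms is not None else rng.permutation(n)
            Xp = X.copy()
            Xp[:, j] = X[perm, j]
            diffs.append(loss(y, model.predict(Xp)) - baseline)
        diffs = np.asarray(diffs)
        raw_preclip[name] = float(diffs.mean())
        se[name] = (
            float(diffs.std(ddof=1) / math.sqrt(len(diffs))) if len(diffs) > 1 else 0.0
        )

    raw = {f: max(v, 0.0) for f, v in raw_preclip.items()}
    meta = {
        "loss": cfg.loss,
        "n_repeats": len(perms) if perms is not None else cfg.n_repeats,
        "exhaustive": cfg.exhaustive,
        "seed": cfg.seed,
        "baseline_loss": baseline,
        "raw_preclip": raw_preclip,
        "mc_se": se,
    }
    return _make_estimate("PFI", raw, meta)


# --------------------------------------------------------------------------
# Shapley-based importance
# --------------------------------------------------------------------------

def _coalition_values(model, X: np.ndarray, bg: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Interventional value matrix V[i, c] = mean_b f(x_i on mask_c, bg_b off).

    Batched over coalitions in chunks to bound memory.
    """
    n_e, d = X.shape
    n_bg = bg.shape[0]
    n_c = masks.shape[0]
    V = np.empty((n_e, n_c))
    chunk = max(1, int(2e6 // max(1, n_e * n_bg)))  # rows per predict call
    for start in range(0, n_c, chunk):
        sub = masks[start : start + chunk]
        blocks = []
        for mask in sub:
            arr = np.broadcast_to(bg, (n_e, n_bg, d)).copy()
            cols = np.flatnonzero(mask)
            if len(cols):
                arr[:, :, cols] = X[:, None, cols]
            blocks.append(arr.reshape(n_e * n_bg, d))
        preds = model.predict(np.concatenate(blocks, axis=0))
        preds = preds.reshape(len(sub), n_e, n_bg)
        V[:, start : start + len(sub)] = preds.mean(axis=2).T
    return V


def _exact_shapley(model, X: np.ndarray, bg: np.ndarray) -> np.ndarray:
    """Per-observation Shapley values by full coalition enumeration."""
    n_e, d = X.shape
    n_c = 1 << d
    ints = np.arange(n_c)
    masks = ((ints[:, None] >> np.arange(d)) & 1).astype(bool)
    V = _coalition_values(model, X, bg, masks)
    sizes = masks.sum(axis=1)
    fact = np.array([math.factorial(s) for s in range(d + 1)], dtype=float)
    # weight of adding player j to coalition of size s: s!(d-s-1)!/d!
    w = fact[np.arange(d)] * fact[d - 1 - np.arange(d)] / fact[d]
    phi = np.zeros((n_e, d))
    for j in range(d):
        without = np.flatnonzero(~masks[:, j])
        with_j = without | (1 << j)
        weights = w[sizes[without]]
        phi[:, j] = (V[:, with_j] - V[:, without]) @ weights
    return phi


def _sampled_shapley(
    model, X: np.ndarray, bg: np.ndarray, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo permutation estimate of the Shapley values."""
    n_e, d = X.shape
    phi = np.zeros((n_e, d))
    for _ in range(n_samples):
        perm = rng.permutation(d)
        mask = np.zeros(d, dtype=bool)
        prev = _coalition_values(model, X, bg, mask[None, :])[:, 0]
        for j in perm:
            mask[j] = True
            cur = _coalition_values(model, X, bg, mask[None, :])[:, 0]
            phi[:, j] += cur - prev
            prev = cur
    return phi / n_samples


def shapley_importance(
    model,
    table: FeatureTable,
    background: FeatureTable | pd.DataFrame | np.ndarray | None = None,
    mode: str = "exact",
    n_explain: int | None = None,
    n_samples: int = 200,
    seed: int = 0,
) -> ImportanceEstimate:
    """Global Shapley importance: mean absolute Shapley value per feature.

    Parameters
    ----------
    background
        Rows defining the off-coalition reference distribution; defaults to
        (up to) 100 rows sampled from ``table``.
    mode
        ``exact`` enumerates all 2^d coalitions (d <= 15);
        ``sampled`` uses ``n_samples`` random feature permutations.
    n_explain
        Number of observations to attribute (seeded subsample); all rows
        by default.
    """
    names = list(model.feature_names)
    d = len(names)
    if mode not in ("exact", "sampled"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "exact" and d > EXACT_SHAPLEY_MAX_D:
        raise ValueError(
            f"exact mode enumerates 2^{d} coalitions; use mode='sampled' for d > "
            f"{EXACT_SHAPLEY_MAX_D}"
        )
    rng = np.random.default_rng(seed)

    Xdf, _ = _resolve(model, table, None)
    X = Xdf.to_numpy(dtype=float)
    if background is None:
        take = min(100, len(X))
        bg = X[rng.choice(len(X), size=take, replace=False)]
    elif isinstance(background, FeatureTable):
        bg = background.features[names].to_numpy(dtype=float)
    elif isinstance(background, pd.DataFrame):
        bg = background[names].to_numpy(dtype=float)
    else:
        bg = np.asarray(background, dtype=float)
    if bg.ndim != 2 or bg.shape[1] != d or bg.shape[0] == 0:
        raise ValueError("background must be a non-empty m x d matrix")

    explain_idx = np.arange(len(X))
    if n_explain is not None and n_explain < len(X):
        explain_idx = np.sort(rng.choice(len(X), size=n_explain, replace=False))
    Xe = X[explain_idx]

    if mode == "exact":
        phi = _exact_shapley(model, Xe, bg)
    else:
        phi = _sampled_shapley(model, Xe, bg, n_samples, rng)

    raw = {name: float(np.mean(np.abs(phi[:, j]))) for j, name in enumerate(names)}
    v_empty = float(np.mean(model.predict(bg)))
    meta = {
        "mode": mode,
        "background_size": int(bg.shape[0]),
        "n_explain": int(len(Xe)),
        "explained_rows": explain_idx.tolist(),
        "seed": seed,
        "phi": phi,
        "v_empty": v_empty,
        "fx": model.predict(Xe),
    }
    return _make_estimate("SHAP", raw, meta)


# --------------------------------------------------------------------------
# ALE and the derivative-based importance
# --------------------------------------------------------------------------

@dataclass
class AleGrid:
    """Quantile-interval grid and accumulated local effects for one feature."""

    feature: str
    breakpoints: np.ndarray  # z_0 ... z_K, strictly increasing
    counts: np.ndarray  # observations per interval, sums to n
    effects: np.ndarray  # accumulated effect at each breakpoint; effects[0] = 0
    local_effects: np.ndarray  # mean prediction difference per interval

    @property
    def n_intervals(self) -> int:
        return len(self.breakpoints) - 1


def _ale_intervals(model, Xdf: pd.DataFrame, feature: str, K: int):
    """Quantile breakpoints, interval assignment and mean local effects.

    Breakpoints are empirical quantiles of the feature; duplicate
    breakpoints (heavily tied data) are collapsed and intervals left empty
    by quantile interpolation are merged into their left neighbour, so every
    retained interval contains at least one observation.
    """
    x = Xdf[feature].to_numpy(dtype=float)
    distinct = np.unique(x)
    if len(distinct) < 2:
        raise ValueError(f"feature {feature!r} is constant; no ALE grid")
    K = min(K, len(distinct) - 1)
    if K < 1:
        raise ValueError(f"feature {feature!r}: cannot build any interval")
    z = np.unique(np.quantile(x, np.linspace(0.0, 1.0, K + 1)))
    # interval k = (z_{k-1}, z_k], first interval closed at z_0
    idx = np.clip(np.searchsorted(z, x, side="left"), 1, len(z) - 1)
    counts = np.bincount(idx, minlength=len(z))[1:]
    while np.any(counts == 0):
        k = int(np.flatnonzero(counts == 0)[0])  # interval k+1 in 1-based terms
        # merge with the left neighbour by removing the shared breakpoint;
        # an empty first interval merges rightwards instead
        drop = k if k > 0 else 1
        z = np.delete(z, drop)
        idx = np.clip(np.searchsorted(z, x, side="left"), 1, len(z) - 1)
        counts = np.bincount(idx, minlength=len(z))[1:]

    n_int = len(z) - 1
    names = list(Xdf.columns)
    j = names.index(feature)
    X = Xdf.to_numpy(dtype=float)
    hi = X.copy()
    lo = X.copy()
    hi[:, j] = z[idx]
    lo[:, j] = z[idx - 1]
    deltas = model.predict(hi) - model.predict(lo)
    sums = np.bincount(idx - 1, weights=deltas, minlength=n_int)
    local = sums / counts
    return z, idx, counts, local


def ale_curve(model, table: FeatureTable, feature: str, K: int = 40) -> AleGrid:
    """Accumulated-local-effects curve for one feature.

    The accumulated effect at breakpoint z_k is the running sum of the
    per-interval mean prediction differences up to k, anchored at 0 at the
    lowest breakpoint.
    """
    Xdf, _ = _resolve(model, table, None)
    z, _idx, counts, local = _ale_intervals(model, Xdf, feature, K)
    effects = np.concatenate([[0.0], np.cumsum(local)])
    return AleGrid(feature, z, counts, effects, local)


def kappa_ale(
    model,
    table: FeatureTable,
    K: int = 40,
    target: str | None = None,
    features: list[str] | None = None,
) -> ImportanceEstimate:
    """Derivative-based importance from the ALE construction.

    For each feature: the mean of squared interval Newton ratios
    (mean local effect / interval width), scaled by the ratio of the
    feature's sample variance to the target's sample variance (both with
    denominator n-1).
    """
    Xdf, y = _resolve(model, table, target)
    var_y = float(np.var(y, ddof=1))
    if var_y == 0:
        raise ValueError("target has zero variance; importance undefined")
    features = features or list(model.feature_names)
    raw: dict[str, float] = {}
    grids: dict[str, int] = {}
    for name in features:
        z, _idx, _counts, local = _ale_intervals(model, Xdf, name, K)
        widths = np.diff(z)
        ratios = local / widths
        var_x = float(np.var(Xdf[name].to_numpy(dtype=float), ddof=1))
        raw[name] = float(np.mean(ratios**2) * var_x / var_y)
        grids[name] = len(widths)
    meta = {"K_requested": K, "K_effective": grids, "target_variance": var_y}
    return _make_estimate("kALE", raw, meta)
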