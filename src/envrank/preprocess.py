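"""Seasonal-trend decomposition and multicollinearity screening.

Daily environmental series mix a slow trend, an annual cycle and
day-to-day noise.  The additive decomposition

    Y_v = T_v + S_v + R_v

(estimated with STL, i.e. LOESS-based seasonal-trend decomposition) lets the
pipeline emphasise the trend component of each feature before modelling.
Highly inter-correlated features (the temperature block in particular) are
collapsed to one representative via connected components of the thresholded
Pearson-correlation graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.tsa.seasonal import STL

from .tables import FeatureTable

__all__ = [
    "StlDecomposition",
    "CollinearityReport",
    "stl_decompose",
    "apply_trend_filter",
    "correlation_matrix",
    "screen_collinearity",
]

DEFAULT_PERIOD = 365  # annual cycle on daily data
DEFAULT_THRESHOLD = 0.8  # |r| at or above which two features are redundant


@dataclass
class StlDecomposition:
    """Additive trend/seasonal/residual split of one series."""

    trend: np.ndarray
    seasonal: np.ndarray
    residual: np.ndarray
    period: int

    def reconstruct(self) -> np.ndarray:
        return self.trend + self.seasonal + self.residual


def stl_decompose(
    series: np.ndarray,
    period: int = DEFAULT_PERIOD,
    seasonal: int = 7,
    robust: bool = False,
) -> StlDecomposition:
    """Decompose one series into trend + seasonal + residual via STL.

    Parameters
    ----------
    series
        Length-``n`` numeric vector with ``n >= 2 * period``.
    period
        Length of the seasonal cycle in observations (365 for annual
        cycles on daily data).
    seasonal
        Odd LOESS window for the seasonal smoother (statsmodels default 7).
    robust
        Use robustness iterations (downweights outliers).

    The residual is defined as ``series - trend - seasonal``, so additive
    reconstruction is exact to round-off.
    """
    y = np.asarray(series, dtype=float)
    if period < 2:
        raise ValueError(f"period must be >= 2, got {period}")
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    if len(y) < 2 * period:
        raise ValueError(
            f"series of length {len(y)} is shorter than two periods "
            f"({2 * period})"
        )
    res = STL(y, period=period, seasonal=seasonal, robust=robust).fit()
    return StlDecomposition(
        trend=np.asarray(res.trend),
        seasonal=np.asarray(res.seasonal),
        residual=np.asarray(res.resid),
        period=period,
    )


def apply_trend_filter(
    table: FeatureTable,
    mode: str = "trend_only",
    period: int = DEFAULT_PERIOD,
    seasonal: int = 7,
    robust: bool = False,
    include_targets: bool = False,
) -> FeatureTable:
    """Replace each feature by an STL-filtered version.

    mode
        ``trend_only``     — keep the trend component only (removes the
        seasonal cycle and the irregular noise);
        ``deseasonalized`` — keep trend + residual;
        ``none``           — identity.
    include_targets
        Also filter the target columns.  Off by default: admission counts
        stay raw so the model is evaluated against observed counts.
    """
    if mode not in ("trend_only", "deseasonalized", "none"):
        raise ValueError(f"unknown filter mode {mode!r}")
    if mode == "none":
        return FeatureTable(table.dates, table.features.copy(), table.targets.copy())

    def _filter(col: str, values: np.ndarray) -> np.ndarray:
        try:
            dec = stl_decompose(values, period=period, seasonal=seasonal, robust=robust)
        except ValueError as exc:
            raise ValueError(f"STL failed for column {col!r}: {exc}") from exc
        if mode == "trend_only":
            return dec.trend
        return dec.trend + dec.residual

    features = pd.DataFrame(
        {c: _filter(c, table.features[c].to_numpy()) for c in table.features.columns}
    )
    targets = table.targets.copy()
    if include_targets:
        filtered = {
            c: _filter(c, table.targets[c].to_numpy(dtype=float))
            for c in targets.columns
        }
        targets = pd.DataFrame(filtered)
        # filtered counts are no longer integers; keep them as floats in a
        # plain frame and bypass the integer-count validation
        out = FeatureTable(table.dates, features, targets, validate_on_init=False)
        return out
    return FeatureTable(table.dates, features, targets)


def correlation_matrix(table: FeatureTable) -> pd.DataFrame:
    """Pearson correlation of all feature pairs (diagonal exactly 1)."""
    for col in table.features.columns:
        if float(np.std(table.features[col].to_numpy())) == 0.0:
            raise ValueError(f"feature {col!r} has zero variance")
    corr = table.features.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class CollinearityReport:
    """Outcome of the redundancy screen."""

    correlation: pd.DataFrame
    threshold: float
    kept: list[str]
    dropped: list[str]
    groups: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "kept": self.kept,
            "dropped": self.dropped,
            "groups": self.groups,
        }


def screen_collinearity(
    corr: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    policy: str = "max_target_corr",
    target_corr: dict[str, float] | None = None,
    pins: list[str] | None = None,
) -> CollinearityReport:
    """Collapse clusters of mutually correlated features to one member each.

    Clusters are the connected components of the graph whose edges join
    feature pairs with ``|r| >= threshold``.  The representative of each
    multi-member cluster is chosen by ``policy``:

    - ``user_pin``        — the member listed in ``pins`` (a cluster with no
      pinned member falls back to ``max_target_corr`` if target correlations
      are given, else to ``first``);
    - ``max_target_corr`` — the member with the largest ``|r|`` against the
      target (requires ``target_corr``), ties broken lexicographically;
    - ``first``           — the lexicographically first member.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if policy not in ("user_pin", "max_target_corr", "first"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "max_target_corr" and target_corr is None:
        raise ValueError("policy 'max_target_corr' requires target_corr")
    if policy == "user_pin" and not pins:
        raise ValueError("policy 'user_pin' requires a non-empty pins list")

    names = list(corr.columns)
    absr = np.abs(corr.to_numpy())
    adj = (absr >= threshold).astype(int)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    kept: list[str] = []
    dropped: list[str] = []
    groups: list[dict] = []
    pinset = set(pins or [])

    for comp in range(n_comp):
        members = sorted(names[i] for i in np.flatnonzero(labels == comp))
        if len(members) == 1:
            kept.append(members[0])
            continue
        rep = None
        how = policy
        if policy == "user_pin":
            pinned = [m for m in members if m in pinset]
            if pinned:
                rep = pinned[0]
            elif target_corr is not None:
                how = "max_target_corr"
            else:
                how = "first"
        if rep is None and how == "max_target_corr":
            rep = max(members, key=lambda m: (abs(target_corr[m]), m))
            # lexicographic tie-break: max() prefers the later name on exact
            # ties of |r|, so resolve explicitly
            best = max(abs(target_corr[m]) for m in members)
            tied = [m for m in members if abs(target_corr[m]) == best]
            rep = sorted(tied)[0]
        if rep is None:
            rep = members[0]
        kept.append(rep)
        dropped.extend(m for m in members if m != rep)
        groups.append({"members": members, "representative": rep, "rule": how})

    kept = [n for n in names if n in set(kept)]  # preserve input order
    dropped = [n for n in names if n in set(dropped)]
    return CollinearityReport(corr, threshold, kept, dropped, groups)
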