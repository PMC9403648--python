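"""Robustness battery for predictive weight maps.

Three probes of whether an interpreted weight map reflects a stable signal
rather than one fold's noise: (1) pairwise inter-correlation of the fold-level
maps from repeated cross-validation; (2) a subject-level bootstrap of the
full-data model; (3) re-running prediction restricted to each network pair's
edges, comparing the 36 restricted models with the whole-brain model and
relating restricted accuracy to network-pair size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import Atlas
from .exceptions import InsufficientDataError, InvalidParameterError
from .interpretation import WeightMap
from .prediction import ConnectomePLS, simpls_path

__all__ = [
    "StabilityReport",
    "bootstrap_weights",
    "network_restricted_cv",
    "weight_intercorrelation",
]


@dataclass
class StabilityReport:
    """Bundle of the stability analyses for one target."""

    intercorrelation_mean: float
    intercorrelation_sd: float
    bootstrap_map: WeightMap
    bootstrap_sd: np.ndarray
    network_restricted: pd.DataFrame
    whole_brain_r: float
    size_vs_accuracy_corr: float


def weight_intercorrelation(
    fold_maps, max_pairs: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Mean and SD of Pearson correlations between distinct fold maps.

    All map pairs are used when there are at most ``max_pairs`` of them;
    otherwise ``max_pairs`` distinct pairs are sampled without replacement.
    """
    maps = np.atleast_2d(np.asarray(fold_maps, dtype=float))
    n = maps.shape[0]
    if n < 2:
        raise InsufficientDataError("need at least 2 maps")
    centered = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    total = n * (n - 1) // 2
    if total <= max_pairs:
        ii, jj = np.triu_indices(n, k=1)
    else:
        rng = np.random.default_rng(seed)
        flat = rng.choice(total, size=max_pairs, replace=False)
        # invert the row-major upper-triangle enumeration
        ii = (
            n - 2 - np.floor(
                np.sqrt(-8.0 * flat + 4.0 * n * (n - 1) - 7.0) / 2.0 - 0.5
            )
        ).astype(int)
        jj = (flat + ii + 1 - ii * (2 * n - ii - 1) // 2).astype(int)
    r = np.einsum("ij,ij->i", centered[ii], centered[jj]) / (norms[ii] * norms[jj])
    return float(r.mean()), float(r.std(ddof=1)) if r.size > 1 else 0.0


def bootstrap_weights(
    X,
    y,
    *,
    n_boot: int = 5000,
    n_components: int = 5,
    seed: int = 0,
) -> tuple[WeightMap, np.ndarray, int]:
    """Bootstrap the full-data weight map by resampling subjects.

    Each of ``n_boot`` resamples (with replacement) refits the model with the
    same component rule; the averaged coefficient vector and the per-edge
    bootstrap SD are returned, together with the count of degenerate
    resamples (constant target) that had to be redrawn.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if n < 10:
        raise InsufficientDataError("need at least 10 subjects to bootstrap")
    rng = np.random.default_rng(seed)
    maps = np.empty((n_boot, X.shape[1]))
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.ptp(y[idx]) > 0.0:
                break
            n_redrawn += 1
        a = min(n_components, X.shape[1], n - 1)
        coefs, _, n_eff = simpls_path(X[idx], y[idx], a)
        maps[b] = coefs[:, n_eff - 1]
    wmap = WeightMap(
        level="connection",
        values=maps.mean(axis=0),
        n_models_averaged=n_boot,
        source={"method": "bootstrap", "n_boot": n_boot, "seed": seed},
    )
    sd = maps.std(axis=0, ddof=1) if n_boot > 1 else np.zeros(X.shape[1])
    return wmap, sd, n_redrawn


def network_restricted_cv(
    X,
    y,
    atlas: Atlas,
    *,
    folds: int = 10,
    reps: int = 10,
    n_components: int = 5,
    seed: int = 0,
    target_name: str = "target",
) -> tuple[pd.DataFrame, float, float]:
    """Prediction accuracy from each network pair's edges alone.

    Runs the repeated-CV engine once per network pair (restricted to that
    pair's edges) and once on all edges, then Spearman-correlates each pair's
    edge count with its mean accuracy.  Pairs with fewer than 2 edges are
    skipped with a warning.

    Returns a table with one row per pair (``net_a, net_b, n_edges, mean_r,
    sd_r``), plus the whole-brain accuracy and the size–accuracy correlation,
    wrapped in a partial :class:`StabilityReport` namespace.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != atlas.n_nodes * (atlas.n_nodes - 1) // 2:
        raise InvalidParameterError("edge matrix does not match atlas")
    eclass = atlas.edge_class_index()
    rows = []
    for pair_idx, (net_a, net_b) in enumerate(atlas.network_pairs):
        cols = np.flatnonzero(eclass == pair_idx)
        if cols.size < 2:
            warnings.warn(
                f"network pair ({net_a}, {net_b}) has {cols.size} edge(s); skipped",
                stacklevel=2,
            )
            continue
        model = ConnectomePLS(y, X[:, cols], target_name=target_name)
        cv = model.fit_repeated_cv(
            folds=folds,
            reps=reps,
            n_components=min(n_components, cols.size),
            seed=seed + pair_idx,
        )
        rows.append(
            {
                "net_a": net_a,
                "net_b": net_b,
                "n_edges": int(cols.size),
                "mean_r": cv.mean_r,
                "sd_r": float(cv.rep_r.std(ddof=1)) if reps > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    whole = ConnectomePLS(y, X, target_name=target_name).fit_repeated_cv(
        folds=folds, reps=reps, n_components=n_components, seed=seed
    )
    if len(table) >= 2:
        rho = float(
            stats.spearmanr(table["n_edges"], table["mean_r"]).statistic
        )
    else:
        rho = float("nan")
    return table, whole.mean_r, rho
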