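"""Per-edge mediation of the age → cognition association.

For each candidate edge the standard three-regression decomposition is fit by
ordinary least squares (age as independent variable, a cognitive score as the
outcome, the edge as mediator, optional covariates such as gender and mean
framewise displacement):

    a       : slope of the mediator on age           (m ~ x + C)
    b, c'   : slopes of the outcome on mediator/age  (y ~ x + m + C)
    c       : total effect of age on the outcome     (y ~ x + C)

The indirect effect is ``a·b``; with identical covariate sets the OLS
identity ``a·b + c' = c`` holds exactly.  Significance of the indirect effect
comes from subject-level bootstrap resampling (percentile interval, add-one
two-sided p).  The proportion mediated is ``a·b / c``, reported only when the
total effect is bounded away from zero.

Across the top-k edges of a weight map, Benjamini–Hochberg FDR is applied
within the k-edge family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import CollinearityError, InvalidParameterError

__all__ = [
    "MediationRecord",
    "MediationTable",
    "mediate_edge",
    "mediate_topk",
]

#: |c_total| below this is treated as a null total effect: the proportion
#: mediated is then undefined and reported as NaN
C_TOTAL_TOL = 1e-10


@dataclass(frozen=True)
class MediationRecord:
    """All paths and bootstrap inference for one edge."""

    edge_id: int
    a_path: float
    b_path: float
    c_total: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    p_boot: float
    proportion_mediated: float  # NaN when undefined
    proportion_defined: bool


@dataclass(frozen=True)
class MediationTable:
    """Mediation results over a top-k edge family with BH-FDR."""

    records: pd.DataFrame  # one row per edge, q_value column included
    k: int
    alpha: float

    @property
    def n_significant(self) -> int:
        return int((self.records["q_value"] < self.alpha).sum())

    def proportion_range(self) -> tuple[float, float]:
        """Min–max proportion mediated among significant edges (NaN-safe)."""
        sig = self.records[
            (self.records["q_value"] < self.alpha)
            & self.records["proportion_defined"]
        ]
        if sig.empty:
            return (float("nan"), float("nan"))
        return (
            float(sig["proportion_mediated"].min()),
            float(sig["proportion_mediated"].max()),
        )


def _design(x: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(x), x]
    if covariates is not None:
        cols.append(covariates)
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("mediation design matrix is rank deficient")
    return design


def _paths(x, m, y, covariates):
    """Point estimates (a, b, c_total, c_prime) by OLS."""
    d_x = _design(x, covariates)
    a = float(np.linalg.lstsq(d_x, m, rcond=None)[0][1])
    c_total = float(np.linalg.lstsq(d_x, y, rcond=None)[0][1])
    d_xm = np.column_stack([d_x, m])
    if np.linalg.matrix_rank(d_xm) < d_xm.shape[1]:
        raise CollinearityError("mediator is collinear with the design")
    beta = np.linalg.lstsq(d_xm, y, rcond=None)[0]
    c_prime = float(beta[1])
    b = float(beta[-1])
    return a, b, c_total, c_prime


def mediate_edge(
    x,
    m,
    y,
    covariates=None,
    *,
    n_boot: int = 10000,
    seed: int = 0,
    ci_level: float = 0.95,
    edge_id: int = 0,
) -> MediationRecord:
    """Mediation of ``x → y`` through a single edge ``m``.

    Bootstrap resamples subjects jointly across all variables; the indirect
    effect's percentile CI at ``ci_level`` and a two-sided add-one p-value
    are derived from the resampled ``a·b`` distribution.
    """
    x = np.asarray(x, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if not (m.shape[0] == y.shape[0] == n) or n < 10:
        raise InvalidParameterError("need aligned vectors with at least 10 subjects")
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise InvalidParameterError("covariates have wrong length")
    if n_boot < 1:
        raise InvalidParameterError("n_boot must be >= 1")

    a, b, c_total, c_prime = _paths(x, m, y, cov)
    indirect = a * b

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        cb = cov[idx] if cov is not None else None
        try:
            ab, bb, *_ = _paths(x[idx], m[idx], y[idx], cb)
        except CollinearityError:
            boot[k] = np.nan
            continue
        boot[k] = ab * bb
    boot = boot[np.isfinite(boot)]
    lo_q = (1.0 - ci_level) / 2.0
    ci_low, ci_high = np.quantile(boot, [lo_q, 1.0 - lo_q])
    n_eff = boot.size
    p_le = (1 + int(np.sum(boot <= 0.0))) / (1 + n_eff)
    p_ge = (1 + int(np.sum(boot >= 0.0))) / (1 + n_eff)
    p_boot = min(1.0, 2.0 * min(p_le, p_ge))

    defined = abs(c_total) > C_TOTAL_TOL
    proportion = indirect / c_total if defined else float("nan")
    return MediationRecord(
        edge_id=edge_id,
        a_path=a,
        b_path=b,
        c_total=c_total,
        c_prime=c_prime,
        indirect=indirect,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_boot=float(p_boot),
        proportion_mediated=float(proportion),
        proportion_defined=bool(defined),
    )


def select_topk_edges(weights: np.ndarray, k: int, sign: str) -> np.ndarray:
    """Indices of the k most positive (or most negative) weights.

    Ties are broken by edge index (lower index first); the returned indices
    are sorted by decreasing |weight| priority then index.
    """
    weights = np.asarray(weights, dtype=float).ravel()
    if not 1 <= k <= weights.shape[0]:
        raise InvalidParameterError(
            f"k must be in [1, {weights.shape[0]}], got {k}"
        )
    if sign not in ("positive", "negative"):
        raise InvalidParameterError("sign must be 'positive' or 'negative'")
    key = -weights if sign == "positive" else weights
    order = np.lexsort((np.arange(weights.shape[0]), key))
    return order[:k]


def mediate_topk(
    weight_map,
    X,
    x,
    y,
    covariates=None,
    *,
    k: int = 100,
    sign: str = "positive",
    n_boot: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
) -> MediationTable:
    """Per-edge mediation over the top-k weighted edges with BH-FDR.

    ``weight_map`` may be a raw vector or a connection-level
    :class:`~connpredict.interpretation.WeightMap`.  Exactly ``k`` tests form
    the FDR family.
    """
    weights = getattr(weight_map, "values", weight_map)
    weights = np.asarray(weights, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.shape[1] != weights.shape[0]:
        raise InvalidParameterError("weight map is not aligned to the edge matrix")
    edge_ids = select_topk_edges(weights, k, sign)
    rng = np.random.default_rng(seed)
    rows = []
    for e in edge_ids:
        rec = mediate_edge(
            x,
            X[:, e],
            y,
            covariates,
            n_boot=n_boot,
            seed=int(rng.integers(2**31)),
            edge_id=int(e),
        )
        rows.append(
            {
                "edge_id": rec.edge_id,
                "weight": weights[e],
                "a_path": rec.a_path,
                "b_path": rec.b_path,
                "c_total": rec.c_total,
                "c_prime": rec.c_prime,
                "indirect": rec.indirect,
                "ci_low": rec.ci_low,
                "ci_high": rec.ci_high,
                "p_boot": rec.p_boot,
                "proportion_mediated": rec.proportion_mediated,
                "proportion_defined": rec.proportion_defined,
            }
        )
    table = pd.DataFrame(rows)
    _, q, *_ = multipletests(table["p_boot"].to_numpy(), method="fdr_bh")
    table["q_value"] = q
    return MediationTable(records=table, k=k, alpha=alpha)
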