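"""Scoring of connectivity recovery, time-series fit, and model comparison.

Connectivity recovery is scored with MAPE over the permitted edges, skipping
ground-truth values in (-0.1, 0.1) where the relative error is unstable.
Time-series fit uses NRMSE (RMSE over the ground-truth range, per region) and
the coefficient of determination.  Model comparison uses a penalized Gaussian
log-likelihood (a BIC-style accuracy-minus-complexity score), an
approximation to the variational log-evidence used in the DCM literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import BOLDTimeSeries
from .graph import NetworkGraph

__all__ = [
    "MetricReport",
    "mape",
    "nrmse",
    "r_squared",
    "log_evidence",
    "log_evidence_difference",
    "score_fit",
]

#: ground-truth connectivity magnitudes below this are excluded from MAPE
MAPE_EXCLUSION = 0.1

#: floor on the residual-variance MLE inside log_evidence
RESIDUAL_VAR_FLOOR = 1e-12


@dataclass
class MetricReport:
    mape: float
    n_excluded: int
    nrmse_per_region: np.ndarray
    nrmse: float
    r2_per_region: np.ndarray
    r2: float
    log_evidence: float | None = None

    def to_dict(self) -> dict:
        d = {
            "mape": float(self.mape),
            "n_excluded": int(self.n_excluded),
            "nrmse": float(self.nrmse),
            "nrmse_per_region": [float(x) for x in self.nrmse_per_region],
            "r2": float(self.r2),
            "r2_per_region": [float(x) for x in self.r2_per_region],
        }
        if self.log_evidence is not None:
            d["log_evidence"] = float(self.log_evidence)
        return d


def _as_matrix(x):
    return x.Y if isinstance(x, BOLDTimeSeries) else np.asarray(x, dtype=float)


def mape(
    a_true: np.ndarray,
    a_pred: np.ndarray,
    graph: NetworkGraph | None = None,
    exclusion: float = MAPE_EXCLUSION,
    return_n_excluded: bool = False,
):
    """Mean absolute percentage error over permitted connectivity edges.

    Edges whose true magnitude is below ``exclusion`` are skipped (their
    relative error is uninformative); the number skipped is reported when
    ``return_n_excluded`` is set.
    """
    a_true = np.asarray(a_true, dtype=float)
    a_pred = np.asarray(a_pred, dtype=float)
    if a_true.shape != a_pred.shape:
        raise ValueError("connectivity matrices must have identical shapes")
    if graph is not None:
        sel = graph.a_mask.astype(bool)
        t, p = a_true[sel], a_pred[sel]
    else:
        t, p = a_true.ravel(), a_pred.ravel()
    keep = np.abs(t) >= exclusion
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("all edges excluded by the magnitude rule: MAPE undefined")
    value = 100.0 * float(np.mean(np.abs(p[keep] - t[keep]) / np.abs(t[keep])))
    if return_n_excluded:
        return value, n_excluded
    return value


def nrmse(y_true, y_pred, mean_only: bool = False):
    """Normalized RMSE in percent: 100 * RMSE / (max - min of the truth),
    per region, plus the mean across regions."""
    yt, yp = _as_matrix(y_true), _as_matrix(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("series must have identical shapes")
    rng = yt.max(axis=0) - yt.min(axis=0)
    if np.any(rng == 0):
        raise ValueError("zero-range ground-truth region: NRMSE undefined")
    rmse = np.sqrt(np.mean((yp - yt) ** 2, axis=0))
    per_region = 100.0 * rmse / rng
    if mean_only:
        return float(per_region.mean())
    return per_region, float(per_region.mean())


def r_squared(y_obs, y_pred, mean_only: bool = False):
    """Coefficient of determination per region: 1 - SS_res / SS_tot."""
    yo, yp = _as_matrix(y_obs), _as_matrix(y_pred)
    if yo.shape != yp.shape:
        raise ValueError("series must have identical shapes")
    ss_tot = np.sum((yo - yo.mean(axis=0)) ** 2, axis=0)
    if np.any(ss_tot == 0):
        raise ValueError("zero-variance observation region: R^2 undefined")
    ss_res = np.sum((yo - yp) ** 2, axis=0)
    per_region = 1.0 - ss_res / ss_tot
    if mean_only:
        return float(per_region.mean())
    return per_region, float(per_region.mean())


def log_evidence(y_obs, y_pred, k_params: int) -> float:
    """Penalized Gaussian log-likelihood (BIC-style log-evidence proxy).

    Log-likelihood is evaluated at the residual-variance MLE (floored at
    ``RESIDUAL_VAR_FLOOR``); the complexity penalty is (k/2) ln n.
    """
    if k_params < 1:
        raise ValueError("k_params must be >= 1")
    yo, yp = _as_matrix(y_obs), _as_matrix(y_pred)
    if yo.shape != yp.shape:
        raise ValueError("series must have identical shapes")
    n = yo.size
    sigma2 = max(float(np.mean((yo - yp) ** 2)), RESIDUAL_VAR_FLOOR)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return float(loglik - 0.5 * k_params * np.log(n))


def log_evidence_difference(score_a: float, score_b: float) -> float:
    """Evidence of model a relative to model b (antisymmetric)."""
    return float(score_a - score_b)


def score_fit(
    a_true: np.ndarray,
    a_pred: np.ndarray,
    y_true,
    y_pred,
    graph: NetworkGraph | None = None,
    k_params: int | None = None,
) -> MetricReport:
    """Bundle all recovery metrics into one report."""
    m, n_exc = mape(a_true, a_pred, graph, return_n_excluded=True)
    nr_per, nr_mean = nrmse(y_true, y_pred)
    r2_per, r2_mean = r_squared(y_true, y_pred)
    le = log_evidence(y_true, y_pred, k_params) if k_params else None
    return MetricReport(
        mape=m,
        n_excluded=n_exc,
        nrmse_per_region=nr_per,
        nrmse=nr_mean,
        r2_per_region=r2_per,
        r2=r2_mean,
        log_evidence=le,
    )
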