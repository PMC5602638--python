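"""Time-lagged correlation of motif score series with cluster expression.

The motif raw-score series lives on the ChIP-seq time grid (0, 1, 2,
4 h); the cluster-median expression is measured on its own grid (0, 2,
4, 12 h) and linearly interpolated.  The lagged correlation R_tau is
the Pearson correlation between the motif scores and the expression
evaluated at the signal times shifted by +tau, with tau in [0, 2] h:
TF binding is expected to lead the expression response.

Three lag policies are supported: no lag (tau = 0), one fixed lag per
cluster (maximizing the sum of squared R_tau over the cluster's
retained motifs), and an optimal lag per motif (maximizing |R_tau|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from valleytf.expression import interpolate
from valleytf.motifscan import MotifScoreSeries


@dataclass(frozen=True)
class LagPolicy:
    mode: str = "optimal_per_motif"  # none | fixed_per_cluster | optimal_per_motif
    lag_min: float = 0.0
    lag_max: float = 2.0
    grid_step: float = 1e-3

    def __post_init__(self) -> None:
        if self.mode not in ("none", "fixed_per_cluster", "optimal_per_motif"):
            raise ValueError(f"unknown lag policy mode {self.mode!r}")
        if self.lag_max < self.lag_min or self.grid_step <= 0:
            raise ValueError("invalid lag range or grid step")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.lag_max - self.lag_min) / self.grid_step))
        return self.lag_min + self.grid_step * np.arange(n + 1)


@dataclass(frozen=True)
class LagCorrResult:
    motif_id: str
    cluster: str
    tau: float
    r: float
    policy: str


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return float("nan")
    return float((xc * yc).sum() / denom)


def lagged_r(
    scores: np.ndarray,
    signal_times: np.ndarray,
    median_profile: np.ndarray,
    expr_times: np.ndarray,
    tau: float,
) -> float:
    """Pearson R between motif scores and expression at signal times + tau.

    nan when either series has zero variance (undefined, not 0).
    """
    scores = np.asarray(scores, dtype=float)
    signal_times = np.asarray(signal_times, dtype=float)
    expr = interpolate(expr_times, median_profile, signal_times + tau)
    return _pearson(scores, np.asarray(expr))


def r_curve(
    scores: np.ndarray,
    signal_times: np.ndarray,
    median_profile: np.ndarray,
    expr_times: np.ndarray,
    policy: LagPolicy,
) -> np.ndarray:
    """R_tau over the whole lag grid (vectorized; nan if variance is zero)."""
    scores = np.asarray(scores, dtype=float)
    signal_times = np.asarray(signal_times, dtype=float)
    grid = policy.grid
    queries = signal_times[:, None] + grid[None, :]
    expr = np.asarray(interpolate(expr_times, median_profile, queries.ravel())).reshape(
        queries.shape
    )  # (n_times, n_lags)
    xc = scores - scores.mean()
    sx = np.sqrt((xc**2).sum())
    yc = expr - expr.mean(axis=0, keepdims=True)
    sy = np.sqrt((yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    return r


def _valid_scores(series: MotifScoreSeries) -> tuple[np.ndarray, np.ndarray]:
    ok = ~np.isnan(series.raw_scores)
    return series.raw_scores[ok], series.times[ok]


def fixed_cluster_lag(
    series_list: list[MotifScoreSeries],
    median_profile: np.ndarray,
    expr_times: np.ndarray,
    policy: LagPolicy | None = None,
) -> float:
    """One lag per cluster: argmax over the grid of sum of squared R_tau.

    The sum runs over the cluster's retained motifs; ties break toward
    the smallest tau (first grid argmax).
    """
    policy = policy or LagPolicy(mode="fixed_per_cluster")
    retained = [s for s in series_list if s.retained]
    if not retained:
        raise ValueError("no retained motif series for this cluster")
    total = np.zeros(len(policy.grid))
    n_valid = 0
    for s in retained:
        scores, times = _valid_scores(s)
        if len(scores) < 2 or np.std(scores) == 0:
            continue
        r = r_curve(scores, times, median_profile, expr_times, policy)
        if np.isnan(r).all():
            continue
        total += np.nan_to_num(r) ** 2
        n_valid += 1
    if n_valid == 0:
        raise ValueError("R is undefined for every retained motif (constant series)")
    return float(policy.grid[int(np.argmax(total))])


def optimal_motif_lag(
    series: MotifScoreSeries,
    median_profile: np.ndarray,
    expr_times: np.ndarray,
    policy: LagPolicy | None = None,
) -> tuple[float, float]:
    """Per-motif lag maximizing |R_tau|; returns (tau, signed R at tau).

    Ties break toward the smallest tau.
    """
    policy = policy or LagPolicy()
    scores, times = _valid_scores(series)
    if len(scores) < 2:
        raise ValueError(f"{series.motif_id}: fewer than 2 defined scores")
    r = r_curve(scores, times, median_profile, expr_times, policy)
    if np.isnan(r).all():
        raise ValueError(f"{series.motif_id}: R undefined at every lag (zero variance)")
    i = int(np.nanargmax(np.abs(r)))
    return float(policy.grid[i]), float(r[i])


def report_associations(
    series_by_cluster: dict[str, list[MotifScoreSeries]],
    medians: dict[str, np.ndarray],
    expr_times: np.ndarray,
    policy: LagPolicy | None = None,
) -> pd.DataFrame:
    """Association table over all (motif, cluster) pairs and lag policies.

    Columns: per-time raw scores and p-values, retained flag, R at no
    lag, at the cluster's fixed lag, and at the motif's optimal lag,
    the putative role (activator if optimal-lag R > 0, repressor if
    < 0), and the rank of retained motifs by score range within each
    cluster.
    """
    policy = policy or LagPolicy()
    rows = []
    for cluster, series_list in series_by_cluster.items():
        med = np.asarray(medians[cluster], dtype=float)
        try:
            tau_fixed = fixed_cluster_lag(series_list, med, expr_times, policy)
        except ValueError:
            tau_fixed = float("nan")
        retained = [s for s in series_list if s.retained]
        ranks = {
            s.motif_id: i + 1
            for i, s in enumerate(
                sorted(retained, key=lambda s: (-s.score_range, s.motif_id))
            )
        }
        for s in series_list:
            scores, times = _valid_scores(s)
            row: dict = {"motif_id": s.motif_id, "cluster": cluster, "retained": s.retained}
            for t, raw, p in zip(s.times, s.raw_scores, s.p_values):
                row[f"score_{t:g}h"] = raw
                row[f"p_{t:g}h"] = p
            if len(scores) >= 2 and np.std(scores) > 0:
                row["r_no_lag"] = lagged_r(scores, times, med, expr_times, 0.0)
                row["tau_fixed"] = tau_fixed
                row["r_fixed_lag"] = (
                    lagged_r(scores, times, med, expr_times, tau_fixed)
                    if not np.isnan(tau_fixed)
                    else float("nan")
                )
                tau_opt, r_opt = optimal_motif_lag(s, med, expr_times, policy)
                row["tau_optimal"] = tau_opt
                row["r_optimal"] = r_opt
                if not np.isnan(r_opt):
                    row["role"] = "activator" if r_opt > 0 else "repressor"
            else:
                row.update(
                    r_no_lag=float("nan"), tau_fixed=tau_fixed, r_fixed_lag=float("nan"),
                    tau_optimal=float("nan"), r_optimal=float("nan"), role=None,
                )
            row["rank_score_range"] = ranks.get(s.motif_id)
            row["score_range"] = s.score_range
            rows.append(row)
    return pd.DataFrame(rows)
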