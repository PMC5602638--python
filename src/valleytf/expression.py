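"""Expression filtering, differential-expression selection, temporal clustering.

The input is a gene x sample matrix of log2 intensities over a
stimulation time course with replicates.  Genes passing an intensity
floor form the "expressed" background universe; differentially
expressed genes (ANOVA permutation q and fold-change cuts) are split
into up- and down-regulated sets and clustered separately by k-means
under the correlation distance 1 - r.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEParams:
    min_log2_intensity: float = 6.0  # intensity >= 64
    q_cut: float = 0.01
    fc_cut: float = 5.0  # linear fold change
    n_permutations: int = 1000

    def __post_init__(self) -> None:
        if self.fc_cut < 1:
            raise ValueError("fc_cut must be >= 1")
        if not 0 < self.q_cut < 1:
            raise ValueError("q_cut must be in (0,1)")


@dataclass
class Cluster:
    label: str  # e.g. UC1..UC5 / DC1..DC3
    direction: str  # "up" or "down"
    members: list[str]
    median_profile: pd.Series  # fold change (log2) per time point
    iqr: pd.Series


@dataclass
class ClusterSet:
    clusters: list[Cluster]

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)

    def __getitem__(self, label: str) -> Cluster:
        for c in self.clusters:
            if c.label == label:
                return c
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.clusters]


def parse_sample_times(columns) -> np.ndarray:
    """Times (h) from sample labels of the form 't<time>_r<rep>' or '<time>h_r<rep>'."""
    times = []
    for c in columns:
        tok = str(c).split("_")[0].lstrip("t").rstrip("h")
        times.append(float(tok))
    return np.array(times)


def filter_expressed(matrix: pd.DataFrame, params: DEParams | None = None) -> pd.DataFrame:
    """Keep genes whose maximum log2 intensity reaches the floor.

    The retained set defines the expressed-gene background universe.
    """
    params = params or DEParams()
    keep = matrix.max(axis=1) >= params.min_log2_intensity
    if not keep.any():
        raise ValueError("no genes pass the intensity filter")
    return matrix.loc[keep]


def fold_changes(matrix: pd.DataFrame, times: np.ndarray) -> pd.DataFrame:
    """Per-gene log2 fold change vs the 0 h baseline, one column per time point.

    Replicates at each time are averaged first (values are log2, so the
    difference of means is a log2 fold change).
    """
    times = np.asarray(times, dtype=float)
    uniq = np.unique(times)
    if 0.0 not in uniq:
        raise ValueError("expression matrix must include the 0 h baseline")
    means = {t: matrix.loc[:, times == t].mean(axis=1) for t in uniq}
    fc = pd.DataFrame({t: means[t] - means[0.0] for t in uniq})
    fc.columns = [float(t) for t in fc.columns]
    return fc


def _f_statistic(values: np.ndarray, group_idx: np.ndarray, n_groups: int) -> np.ndarray:
    """Vectorized one-way ANOVA F across columns grouped by group_idx.

    values: genes x samples.  Returns one F per gene (nan -> 0/0 guarded).
    """
    n = values.shape[1]
    counts = np.bincount(group_idx, minlength=n_groups).astype(float)
    grand = values.mean(axis=1, keepdims=True)
    sums = np.zeros((values.shape[0], n_groups))
    np.add.at(sums.T, group_idx, values.T)
    gmeans = sums / counts
    ss_between = (counts * (gmeans - grand) ** 2).sum(axis=1)
    ss_total = ((values - grand) ** 2).sum(axis=1)
    ss_within = ss_total - ss_between
    df_b, df_w = n_groups - 1, n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    # zero within-group variance: F is infinite if between-variance > 0
    f = np.where(np.isnan(f), 0.0, f)
    return f


def anova_permutation_q(
    matrix: pd.DataFrame,
    times: np.ndarray,
    params: DEParams | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """One-way ANOVA across time points with a balanced-permutation null.

    Balanced permutations shuffle sample labels while preserving group
    sizes (a uniform random permutation of columns); each permutation is
    applied to all genes, and the pooled null F distribution yields an
    empirical FDR q per gene:

        q(F) = (mean null exceedances per permutation) / (observed exceedances)

    monotonized to be nonincreasing in F.  The permutation p-value is
    floored at 1/(B+1).
    """
    params = params or DEParams()
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    uniq, group_idx = np.unique(times, return_inverse=True)
    n_groups = len(uniq)
    counts = np.bincount(group_idx)
    if counts.min() < 2:
        warnings.warn(
            "fewer than 2 replicates in some group: ANOVA F is unstable; "
            "consider fold-change-only selection",
            stacklevel=2,
        )
    b = params.n_permutations
    if b < 100:
        warnings.warn(f"only {b} permutations: q-values will be coarse", stacklevel=2)

    values = matrix.to_numpy(dtype=float)
    f_obs = _f_statistic(values, group_idx, n_groups)

    n_samples = values.shape[1]
    null_f = np.empty((b, values.shape[0]))
    for i in range(b):
        perm = rng.permutation(n_samples)
        null_f[i] = _f_statistic(values[:, perm], group_idx, n_groups)
    null_pool = np.sort(null_f.ravel())

    # permutation p: fraction of pooled null F >= observed (floored)
    exceed = len(null_pool) - np.searchsorted(null_pool, f_obs, side="left")
    p = (1 + exceed / values.shape[0]) / (b + 1)
    p = np.minimum(p, 1.0)

    # empirical FDR q
    order = np.argsort(f_obs)
    f_sorted = f_obs[order]
    obs_exceed = len(f_obs) - np.searchsorted(f_sorted, f_obs, side="left")
    q_raw = (exceed / b) / obs_exceed
    q_raw = np.minimum(q_raw, 1.0)
    # monotonize: each gene takes the min raw q among genes with F >= its own
    q = np.empty_like(q_raw)
    q[order] = np.minimum.accumulate(q_raw[order][::-1])[::-1]

    return pd.DataFrame({"F": f_obs, "p": p, "q": q}, index=matrix.index)


def select_de(
    fc: pd.DataFrame, de_stats: pd.DataFrame, params: DEParams | None = None
) -> tuple[list[str], list[str]]:
    """Select DE genes (q and fold-change cuts) and split by direction.

    A gene is kept iff q <= q_cut and the max |log2 FC| over stimulated
    time points reaches log2(fc_cut); its direction is the sign of the
    max-magnitude fold change.
    """
    params = params or DEParams()
    stim = [t for t in fc.columns if t > 0]
    fc_stim = fc[stim]
    peak_idx = fc_stim.abs().to_numpy().argmax(axis=1)
    peak_fc = fc_stim.to_numpy()[np.arange(len(fc_stim)), peak_idx]
    passes = (de_stats.loc[fc.index, "q"] <= params.q_cut).to_numpy() & (
        np.abs(peak_fc) >= np.log2(params.fc_cut)
    )
    up = [g for g, keep, v in zip(fc.index, passes, peak_fc) if keep and v > 0]
    down = [g for g, keep, v in zip(fc.index, passes, peak_fc) if keep and v < 0]
    return up, down


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return (x - mu) / sd


def correlation_kmeans(
    profiles: np.ndarray,
    k: int,
    seed: int | np.random.Generator = 0,
    n_init: int = 10,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd k-means under the correlation distance d(x,y) = 1 - Pearson(x,y).

    Profiles are z-scored per row, centroids are member means
    re-standardized, and the best of ``n_init`` seeded restarts (by
    total within-cluster distance) is returned as (labels, centroids,
    objective).  Zero-variance profiles are rejected.
    """
    profiles = np.asarray(profiles, dtype=float)
    n, _ = profiles.shape
    if k > n:
        raise ValueError(f"k={k} exceeds number of profiles ({n})")
    sd = profiles.std(axis=1)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance profiles at rows {bad.tolist()}")
    z = _zscore_rows(profiles)
    m = z.shape[1]
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_init):
        centroids = z[rng.choice(n, size=k, replace=False)]
        labels = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            # Pearson(x, c) = dot(z_x, z_c)/m for z-scored rows
            corr = z @ centroids.T / m
            new_labels = corr.argmax(axis=1)
            for j in range(k):  # re-seed empty clusters
                if not (new_labels == j).any():
                    new_labels[rng.integers(n)] = j
            if (new_labels == labels).all() and _ > 0:
                break
            labels = new_labels
            for j in range(k):
                mean = z[labels == j].mean(axis=0)
                s = mean.std()
                centroids[j] = (mean - mean.mean()) / s if s > 0 else mean - mean.mean()
        corr = z @ centroids.T / m
        obj = float((1 - corr[np.arange(n), labels]).sum())
        if best is None or obj < best[0]:
            best = (obj, labels.copy(), centroids.copy())
    assert best is not None
    return best[1], best[2], best[0]


def median_profile(fc: pd.DataFrame, members: list[str]) -> tuple[pd.Series, pd.Series]:
    """Per-time-point median and interquartile range of member fold changes."""
    if not members:
        raise ValueError("empty cluster")
    sub = fc.loc[members]
    med = sub.median(axis=0)
    iqr = sub.quantile(0.75, axis=0) - sub.quantile(0.25, axis=0)
    return med, iqr


def cluster_profiles(
    fc: pd.DataFrame,
    up: list[str],
    down: list[str],
    k_up: int = 5,
    k_down: int = 3,
    seed: int | np.random.Generator = 0,
) -> ClusterSet:
    """Cluster up- and down-regulated genes independently (1 - r distance).

    Cluster labels UCi/DCi are ordered by cluster size (largest first)
    for determinism.
    """
    rng = np.random.default_rng(seed)
    clusters: list[Cluster] = []
    for direction, ids, k, prefix in (("up", up, k_up, "UC"), ("down", down, k_down, "DC")):
        if not ids:
            continue
        k_eff = min(k, len(ids))
        if k_eff < k:
            logger.warning("%s set has %d genes < k=%d; using k=%d", direction, len(ids), k, k_eff)
        labels, _, _ = correlation_kmeans(fc.loc[ids].to_numpy(), k_eff, rng)
        order = np.argsort([-np.sum(labels == j) for j in range(k_eff)], kind="stable")
        for rank, j in enumerate(order, start=1):
            members = [g for g, lab in zip(ids, labels) if lab == j]
            med, iqr = median_profile(fc, members)
            clusters.append(Cluster(f"{prefix}{rank}", direction, members, med, iqr))
    if not clusters:
        raise ValueError("no DE genes to cluster")
    return ClusterSet(clusters)


def interpolate(times: np.ndarray, values: np.ndarray, t_query) -> np.ndarray | float:
    """Piecewise-linear interpolation; extrapolation is an error."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    tq = np.asarray(t_query, dtype=float)
    if np.any(tq < times.min() - 1e-12) or np.any(tq > times.max() + 1e-12):
        raise ValueError(
            f"query time(s) outside [{times.min()}, {times.max()}]: extrapolation refused"
        )
    out = np.interp(tq, times, values)
    return float(out) if np.isscalar(t_query) else out
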