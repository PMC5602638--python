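"""Validation of motif -> cluster predictions against TF ChIP-seq reads.

For each TF, time point and cluster, reads overlapping the -2000/+500
promoter windows of the cluster genes are summed and compared to a null
built from 1000 random expressed-gene sets of equal size: the
log2-transformed summed counts over the random sets give a background
mean and standard deviation, the observed cluster gets a z-score, a
two-tailed normal p-value, and a Benjamini-Hochberg q-value across all
tests in the run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from valleytf.annotation import PROMOTER_CHIP, GeneModel, WindowSpec, promoter_window
from valleytf.coverage import ValleyCall, validate_reads


@dataclass
class NullDistribution:
    tf_id: str
    time_point: float
    cluster: str
    mu: float
    sd: float
    n_sets: int

    @property
    def degenerate(self) -> bool:
        return self.sd == 0


@dataclass
class EnrichmentResult:
    tf_id: str
    time_point: float
    cluster: str
    observed_log2_count: float
    z: float  # nan when the null is degenerate
    p: float


def count_promoter_reads(
    reads: pd.DataFrame,
    genes: Sequence[GeneModel],
    window: WindowSpec = PROMOTER_CHIP,
) -> pd.Series:
    """Reads overlapping each gene's strand-aware promoter window.

    Overlap is any shared bp of the half-open intervals.
    """
    validate_reads(reads)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in reads.groupby("chrom"):
        by_chrom[str(chrom)] = (
            np.sort(grp["start"].to_numpy()),
            np.sort(grp["end"].to_numpy()),
        )
    counts = {}
    for g in genes:
        chrom, start, end = promoter_window(g, window)
        if chrom not in by_chrom:
            counts[g.gene_id] = 0
            continue
        starts, ends = by_chrom[chrom]
        # read [s,e) overlaps [start,end) iff s < end and e > start
        counts[g.gene_id] = int(
            np.searchsorted(starts, end, side="left") - np.searchsorted(ends, start, side="right")
        )
    return pd.Series(counts, name="count")


def count_valley_reads(
    reads: pd.DataFrame,
    aprs: Mapping[str, list[tuple[float, ValleyCall]]],
    time_point: float,
) -> pd.Series:
    """Reads overlapping each gene's HAc-valley APRs at one time point.

    Region-provider alternative to the promoter window: counts are
    summed over the gene's valley intervals.
    """
    validate_reads(reads)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in reads.groupby("chrom"):
        by_chrom[str(chrom)] = (
            np.sort(grp["start"].to_numpy()),
            np.sort(grp["end"].to_numpy()),
        )
    counts = {}
    for gid, items in aprs.items():
        total = 0
        for t, v in items:
            if t != time_point or v.chrom not in by_chrom:
                continue
            starts, ends = by_chrom[v.chrom]
            total += int(
                np.searchsorted(starts, v.end, side="left")
                - np.searchsorted(ends, v.start, side="right")
            )
        counts[gid] = total
    return pd.Series(counts, name="count")


def _log2_sum(counts: np.ndarray) -> float:
    # pseudocount of 1 guards empty random sets
    return float(np.log2(1 + counts.sum()))


def build_null(
    counts: pd.Series,
    universe: Sequence[str],
    cluster_size: int,
    n_sets: int = 1000,
    seed: int | np.random.Generator = 0,
    tf_id: str = "",
    time_point: float = 0.0,
    cluster: str = "",
) -> NullDistribution:
    """Null of log2 summed counts over random expressed-gene sets.

    Sets are drawn without replacement from the universe; the statistic
    per set is log2(1 + sum of counts).
    """
    universe = list(universe)
    if len(universe) < cluster_size:
        raise ValueError(
            f"universe ({len(universe)}) smaller than cluster size ({cluster_size})"
        )
    if n_sets < 2:
        raise ValueError("n_sets must be >= 2")
    rng = np.random.default_rng(seed)
    if cluster_size == 0:
        return NullDistribution(tf_id, time_point, cluster, 0.0, 0.0, n_sets)
    vals = counts.loc[universe].to_numpy(dtype=float)
    # vectorized sampling without replacement: keep the k smallest random keys
    keys = rng.random((n_sets, len(vals)))
    idx = np.argpartition(keys, cluster_size - 1, axis=1)[:, :cluster_size]
    draws = np.log2(1 + vals[idx].sum(axis=1))
    return NullDistribution(
        tf_id, time_point, cluster, float(draws.mean()), float(draws.std(ddof=1)), n_sets
    )


def enrichment_z(
    cluster_genes: Sequence[str], counts: pd.Series, null: NullDistribution
) -> EnrichmentResult:
    """z-score of the observed cluster statistic and two-tailed normal p.

    p = 2 * (1 - Phi(|z|)).  A degenerate null (sd = 0) yields nan z/p;
    such results are excluded from the FDR family.
    """
    obs = _log2_sum(counts.loc[list(cluster_genes)].to_numpy(dtype=float))
    if null.degenerate:
        return EnrichmentResult(null.tf_id, null.time_point, null.cluster, obs,
                                float("nan"), float("nan"))
    z = (obs - null.mu) / null.sd
    p = float(2 * norm.sf(abs(z)))
    p = max(p, np.finfo(float).tiny)  # keep p in (0, 1]
    return EnrichmentResult(null.tf_id, null.time_point, null.cluster, obs, float(z), p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_i = min over j with p_j >= p_i of min(1, p_j * m / rank_j).
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def validate_predictions(
    tf_reads: Mapping[str, Mapping[float, pd.DataFrame]],
    genes: Sequence[GeneModel],
    clusters: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    predictions: Mapping[tuple[str, str], bool] | None = None,
    n_sets: int = 1000,
    seed: int | np.random.Generator = 0,
    window: WindowSpec = PROMOTER_CHIP,
) -> pd.DataFrame:
    """Run the full random-gene-set enrichment test for every TF/time/cluster.

    ``tf_reads`` maps tf_id -> time_point -> read table;
    ``predictions`` optionally maps (tf_id, cluster) -> predicted flag
    (motif retention).  Returns a table with observed log2 counts, mu,
    sd, z, p and BH q over all non-degenerate tests in the run.
    """
    rng = np.random.default_rng(seed)
    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    for tf_id in sorted(tf_reads):
        for time_point in sorted(tf_reads[tf_id]):
            reads = tf_reads[tf_id][time_point]
            counts = count_promoter_reads(reads, genes, window)
            for cluster in sorted(clusters):
                members = [g for g in clusters[cluster] if g in gene_by_id]
                null = build_null(
                    counts, universe, len(members), n_sets, rng, tf_id, time_point, cluster
                )
                res = enrichment_z(members, counts, null)
                rows.append(
                    {
                        "tf": tf_id,
                        "time": time_point,
                        "cluster": cluster,
                        "n_genes": len(members),
                        "observed_log2_count": res.observed_log2_count,
                        "mu": null.mu,
                        "sd": null.sd,
                        "z": res.z,
                        "p": res.p,
                        "predicted": (
                            predictions.get((tf_id, cluster)) if predictions else None
                        ),
                    }
                )
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    ok = table["p"].notna()
    if ok.any():
        table.loc[ok, "q"] = bh_adjust(table.loc[ok, "p"].to_numpy())
    return table


def concordance_report(
    validation: pd.DataFrame,
    clover_scores: pd.DataFrame,
    q_threshold: float = 0.05,
) -> dict:
    """Concordance of motif predictions with ChIP-seq enrichment outcomes.

    ``clover_scores`` must have columns tf, time, cluster, score.  The
    report crosses predicted flags with q < threshold outcomes and
    gives the Pearson correlation between Clover scores and observed
    log2 counts over (cluster, time) cells, split by predicted status.
    """
    merged = validation.merge(clover_scores, on=["tf", "time", "cluster"], how="inner")
    merged["significant"] = merged["q"] < q_threshold
    table = merged.groupby(["predicted", "significant"]).size().rename("n").reset_index()

    def _corr(sub: pd.DataFrame) -> float:
        if len(sub) < 2:
            return float("nan")
        x = sub["score"].to_numpy(dtype=float)
        y = sub["observed_log2_count"].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    return {
        "contingency": table,
        "r_predicted": _corr(merged[merged["predicted"] == True]),  # noqa: E712
        "r_not_predicted": _corr(merged[merged["predicted"] == False]),  # noqa: E712
        "n_cells": len(merged),
    }
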