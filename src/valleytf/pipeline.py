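"""End-to-end orchestration: coverage -> APRs -> expression -> motifs ->
time-lagged correlation -> ChIP-seq validation.

`RunConfig` collects every stage parameter (defaults are the published
analysis values: 10 bp grid, sigma 40 bp, 50-500 bp flanks, 70% rule,
+-5 kbp APR radius, -1500/+500 and -2000/+500 promoter windows,
p <= 0.01 motif retention, q <= 0.01 and FC >= 5 DE cuts, lags 0-2 h,
1000 background draws and random gene sets, 122 bp read extension).
`run_pipeline` works on in-memory inputs; the CLI wires files to it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from valleytf import __version__
from valleytf.annotation import (
    APR_RADIUS,
    PROMOTER_CHIP,
    PROMOTER_MOTIF,
    GeneModel,
    WindowSpec,
    apr_sequences,
    assign_aprs,
    promoter_sequences,
)
from valleytf.chipvalidate import validate_predictions
from valleytf.coverage import (
    CoverageTrack,
    SmoothingParams,
    ValleyParams,
    call_valleys,
    smooth,
)
from valleytf.expression import (
    ClusterSet,
    DEParams,
    anova_permutation_q,
    cluster_profiles,
    filter_expressed,
    fold_changes,
    parse_sample_times,
    select_de,
)
from valleytf.lagcorr import LagPolicy, report_associations
from valleytf.motifscan import PWM, Background, MotifScoreSeries, score_series

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    step: int = 10
    sigma: float = 40.0
    near: int = 50
    far: int = 500
    dip_fraction: float = 0.70
    read_extension: int = 122
    valley_min_score: float = 0.0  # enriched-region hook; 0 disables
    apr_radius: int = APR_RADIUS
    promoter_upstream: int = PROMOTER_MOTIF.upstream
    promoter_downstream: int = PROMOTER_MOTIF.downstream
    chip_upstream: int = PROMOTER_CHIP.upstream
    chip_downstream: int = PROMOTER_CHIP.downstream
    min_log2_intensity: float = 6.0
    q_cut: float = 0.01
    fc_cut: float = 5.0
    n_permutations: int = 1000
    k_up: int = 5
    k_down: int = 3
    retention_p: float = 0.01
    n_draws: int = 1000
    n_random_sets: int = 1000
    lag_min: float = 0.0
    lag_max: float = 2.0
    lag_grid_step: float = 1e-3

    @property
    def valley_params(self) -> ValleyParams:
        return ValleyParams(self.near, self.far, self.dip_fraction)

    @property
    def smoothing_params(self) -> SmoothingParams:
        return SmoothingParams(self.sigma)

    @property
    def de_params(self) -> DEParams:
        return DEParams(self.min_log2_intensity, self.q_cut, self.fc_cut, self.n_permutations)

    @property
    def lag_policy(self) -> LagPolicy:
        return LagPolicy("optimal_per_motif", self.lag_min, self.lag_max, self.lag_grid_step)

    def parameter_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PipelineResult:
    valleys_by_time: dict
    aprs: dict
    clusters: ClusterSet
    expressed_genes: list[str]
    series_by_cluster: dict[str, list[MotifScoreSeries]]
    associations: pd.DataFrame
    validation: pd.DataFrame | None
    manifest: dict


def run_pipeline(
    hac_tracks: dict[float, dict[str, CoverageTrack]],
    genes: list[GeneModel],
    genome,
    expression: pd.DataFrame,
    motifs: list[PWM],
    cfg: RunConfig | None = None,
    tf_reads: dict[str, dict[float, pd.DataFrame]] | None = None,
    tf_of_motif: dict[str, str] | None = None,
) -> PipelineResult:
    """Execute all stages on in-memory inputs and return every product.

    ``hac_tracks`` holds raw (unsmoothed) coverage per time point and
    chromosome.  ``tf_reads`` (optional) triggers the ChIP-seq
    validation stage; ``tf_of_motif`` maps motif IDs to TF read sets so
    motif retention can be used as the predicted flag.
    """
    cfg = cfg or RunConfig()
    rng = np.random.default_rng(cfg.seed)
    timings: dict[str, float] = {}

    def _stage(name):
        timings[name] = _time.perf_counter()
        logger.info("stage: %s", name)

    def _done(name):
        timings[name] = round(_time.perf_counter() - timings[name], 3)

    # --- coverage: smooth and call valleys per time point
    _stage("valleys")
    valleys_by_time: dict[float, list] = {}
    for t in sorted(hac_tracks):
        calls = []
        for chrom in sorted(hac_tracks[t]):
            sm = smooth(hac_tracks[t][chrom], cfg.smoothing_params)
            calls.extend(
                call_valleys(sm, cfg.valley_params, time_point=t, min_score=cfg.valley_min_score)
            )
        valleys_by_time[t] = calls
    _done("valleys")

    # --- expression: filter, DE, cluster
    _stage("expression")
    times = parse_sample_times(expression.columns)
    expressed = filter_expressed(expression, cfg.de_params)
    expressed_ids = list(expressed.index)
    de_stats = anova_permutation_q(expressed, times, cfg.de_params, rng)
    fc = fold_changes(expressed, times)
    up, down = select_de(fc, de_stats, cfg.de_params)
    clusters = cluster_profiles(fc, up, down, cfg.k_up, cfg.k_down, rng)
    _done("expression")

    # --- annotation: APRs restricted to expressed genes
    _stage("aprs")
    gene_by_id = {g.gene_id: g for g in genes}
    expressed_genes = [gene_by_id[g] for g in expressed_ids if g in gene_by_id]
    aprs = assign_aprs(valleys_by_time, expressed_genes, cfg.apr_radius)
    _done("aprs")

    # --- motif scan per cluster per time point
    _stage("motifscan")
    bg_seqs = [
        s
        for _, s in promoter_sequences(
            expressed_genes, genome, WindowSpec(cfg.promoter_upstream, cfg.promoter_downstream)
        )
    ]
    background = Background(bg_seqs)
    times_sig = sorted(valleys_by_time)
    series_by_cluster: dict[str, list[MotifScoreSeries]] = {}
    for cluster in clusters:
        seqs_by_time = {
            t: [s for _, s in apr_sequences(aprs, genome, t, cluster.members)]
            for t in times_sig
        }
        series_by_cluster[cluster.label] = [
            score_series(
                pwm,
                seqs_by_time,
                background,
                cluster=cluster.label,
                n_draws=cfg.n_draws,
                seed=rng,
                retention_p=cfg.retention_p,
            )
            for pwm in motifs
        ]
    _done("motifscan")

    # --- time-lagged correlation and association report
    _stage("lagcorr")
    expr_times = np.unique(times)
    medians = {c.label: c.median_profile.to_numpy() for c in clusters}
    associations = report_associations(
        series_by_cluster, medians, expr_times, cfg.lag_policy
    )
    _done("lagcorr")

    # --- ChIP-seq validation
    validation = None
    if tf_reads:
        _stage("chipvalidate")
        predictions = None
        if tf_of_motif:
            predictions = {}
            for label, series_list in series_by_cluster.items():
                for s in series_list:
                    tf = tf_of_motif.get(s.motif_id)
                    if tf is not None:
                        predictions[(tf, label)] = s.retained
        validation = validate_predictions(
            tf_reads,
            genes,
            {c.label: c.members for c in clusters},
            expressed_ids,
            predictions,
            n_sets=cfg.n_random_sets,
            seed=rng,
            window=WindowSpec(cfg.chip_upstream, cfg.chip_downstream),
        )
        _done("chipvalidate")

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "parameter_hash": cfg.parameter_hash(),
        "parameters": asdict(cfg),
        "n_genes": len(genes),
        "n_expressed": len(expressed_ids),
        "n_de_up": len(up),
        "n_de_down": len(down),
        "n_valleys": {str(t): len(v) for t, v in valleys_by_time.items()},
        "clusters": {c.label: len(c.members) for c in clusters},
        "timings_s": timings,
    }
    return PipelineResult(
        valleys_by_time, aprs, clusters, expressed_ids, series_by_cluster,
        associations, validation, manifest,
    )


def write_results(result: PipelineResult, outdir) -> None:
    """Serialize association/validation tables and the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.associations.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    if result.validation is not None:
        result.validation.to_csv(outdir / "validation.tsv", sep="\t", index=False)
    rows = []
    for c in result.clusters:
        for g in c.members:
            rows.append({"gene_id": g, "cluster": c.label, "direction": c.direction})
    pd.DataFrame(rows).to_csv(outdir / "cluster_members.tsv", sep="\t", index=False)
    from valleytf.io import write_valleys_bed

    for t, calls in result.valleys_by_time.items():
        write_valleys_bed(calls, outdir / f"valleys_t{t:g}h.bed")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1)


def evaluate_recovery(result: PipelineResult, truth) -> dict:
    """Compare pipeline output with synthetic ground truth.

    Maps each found cluster to the planted cluster sharing the most
    members, then checks whether the planted regulator motif ranks #1
    by score range among retained motifs and whether the sign of the
    optimal-lag R matches the planted role (activator > 0, repressor
    < 0).
    """
    assoc = result.associations
    per_cluster = {}
    for c in result.clusters:
        overlaps = {
            lab: len(set(c.members) & set(ct.members))
            for lab, ct in truth.clusters.items()
        }
        best = max(overlaps, key=lambda k: overlaps[k])
        ct = truth.clusters[best]
        sub = assoc[(assoc["cluster"] == c.label) & (assoc["retained"])]
        top = sub.sort_values(["rank_score_range"]).head(1)
        rank1_id = top["motif_id"].iloc[0] if len(top) else None
        row = sub[sub["motif_id"] == ct.motif_id]
        r_opt = float(row["r_optimal"].iloc[0]) if len(row) else float("nan")
        expected_sign = 1.0 if ct.role == "activator" else -1.0
        per_cluster[c.label] = {
            "mapped_truth": best,
            "overlap": overlaps[best],
            "n_members": len(c.members),
            "regulator": ct.motif_id,
            "rank1_motif": rank1_id,
            "rank1_correct": rank1_id == ct.motif_id,
            "r_optimal": r_opt,
            "sign_correct": bool(np.sign(r_opt) == expected_sign),
        }
    all_ok = all(v["rank1_correct"] and v["sign_correct"] for v in per_cluster.values())
    return {"clusters": per_cluster, "all_recovered": all_ok}
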