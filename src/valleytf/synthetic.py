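"""Fully in-silico datasets with known ground truth.

The generator emulates the statistical structure the pipeline assumes:

* a random genome with genes whose +-5 kbp TSS windows are disjoint;
* per-promoter histone-acetylation plateaus with Gaussian-shaped dips
  (valleys); each DE gene carries one always-open neutral dip and three
  motif-rich dips that open when the gene's cluster activity crosses a
  per-site threshold, so motif content of the open-valley sequence set
  tracks cluster activity over time (the genome sequence itself is
  fixed);
* consensus instances of each cluster's regulator motif embedded inside
  the motif-rich dips (outside the background promoter window), plus
  ubiquitous motifs planted in every neutral dip, plus unplanted decoys;
* expression profiles whose cluster medians follow the cluster activity
  shifted by a planted lag (activators positively, repressors
  negatively), with flat filler genes;
* TF ChIP-seq reads uniform over the genome plus an activity-scaled
  enrichment over target-cluster promoters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from valleytf.annotation import GeneModel
from valleytf.coverage import CoverageTrack
from valleytf.motifscan import PWM

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic dataset (defaults = test scale)."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 200
    genes_per_cluster: int = 25
    n_clusters_up: int = 2
    n_clusters_down: int = 2
    signal_times: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0)
    expr_times: tuple[float, ...] = (0.0, 2.0, 4.0, 12.0)
    n_replicates: int = 3
    step: int = 10
    base_frequencies: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    # HAc signal shape
    baseline: float = 2.0
    plateau_height: float = 50.0
    plateau_halfwidth: int = 4000
    dip_depth: float = 0.85  # fraction of plateau removed at the dip bottom
    dip_sigma: float = 60.0  # bp
    signal_noise_sd: float = 5.0  # 10% of plateau height
    # dip sites (bp relative to TSS, strand-aware); B sites open when
    # cluster activity >= threshold; the neutral site is always open
    neutral_site_offset: int = -1200
    site_offsets: tuple[int, ...] = (-3000, -2200, 1200)
    site_thresholds: tuple[float, ...] = (0.25, 0.6, 0.9)
    # motifs
    n_motifs: int = 20
    motif_width: int = 8
    n_ubiquitous: int = 2
    motif_copies_per_site: int = 2
    consensus_count: float = 18.0
    offconsensus_count: float = 0.5
    # expression
    expr_effect: float = 4.0  # log2 swing of the cluster drive
    expr_noise_sd: float = 0.15
    activator_baseline: float = 7.0
    repressor_baseline: float = 11.0
    planted_lags: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5)
    # TF ChIP-seq
    tf_reads_per_time: int = 20000
    tf_enrichment: float = 3.0
    read_length: int = 36

    @property
    def n_clusters(self) -> int:
        return self.n_clusters_up + self.n_clusters_down

    @property
    def genome_length(self) -> int:
        return self.n_chroms * self.chrom_length


@dataclass
class ClusterTruth:
    label: str
    direction: str  # up / down
    role: str  # activator / repressor
    activity: np.ndarray  # per signal time, in [0, 1]
    lag: float  # h, expression lags motif activity by this much
    motif_id: str
    tf_id: str
    members: list[str]


@dataclass
class GroundTruth:
    clusters: dict[str, ClusterTruth]
    cluster_of_gene: dict[str, str]  # DE genes only
    filler_genes: list[str]
    dip_sites: dict[str, list[dict]]  # gene_id -> site records
    valleys_by_time: dict[float, list[tuple[str, int, int]]]  # planted open dips
    regulator_motifs: list[str]
    ubiquitous_motifs: list[str]
    decoy_motifs: list[str]

    def to_manifest(self) -> dict:
        return {
            "clusters": {
                lab: {
                    "direction": c.direction,
                    "role": c.role,
                    "activity": c.activity.tolist(),
                    "lag": c.lag,
                    "motif_id": c.motif_id,
                    "tf_id": c.tf_id,
                    "members": c.members,
                }
                for lab, c in self.clusters.items()
            },
            "cluster_of_gene": self.cluster_of_gene,
            "filler_genes": self.filler_genes,
            "regulator_motifs": self.regulator_motifs,
            "ubiquitous_motifs": self.ubiquitous_motifs,
            "decoy_motifs": self.decoy_motifs,
            "valleys_by_time": {
                str(t): [[c, int(s), int(e)] for c, s, e in v]
                for t, v in self.valleys_by_time.items()
            },
        }


@dataclass
class SimData:
    config: SimConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    truth: GroundTruth
    hac: dict[float, dict[str, CoverageTrack]]  # raw (noisy, unsmoothed) signal
    expression: pd.DataFrame
    motifs: list[PWM]
    tf_reads: dict[str, dict[float, pd.DataFrame]]


# Activity-profile templates cycled over clusters: (role, profile on 0/1/2/4 h).
# Within each direction one program is transient and one sustained, so the
# induced expression shapes are linearly separable under the 1-r distance
# (mirroring the distinct temporal programs real LPS clusters show).
_UP_TEMPLATES = [
    ("activator", (0.1, 0.8, 1.0, 0.15)),  # transient induction
    ("repressor", (1.0, 0.85, 0.4, 0.05)),  # sustained de-repression
]
_DOWN_TEMPLATES = [
    ("activator", (1.0, 0.8, 0.4, 0.05)),  # sustained shut-down
    ("repressor", (0.05, 0.8, 1.0, 0.25)),  # transient repression
]


def _activity_at(times, activity, t):
    """Piecewise-linear cluster activity, clamped outside the signal grid."""
    return np.interp(np.asarray(t, dtype=float), times, activity)


def simulate_genome(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], list[GeneModel]]:
    """Random background genome plus gene models with disjoint +-5 kbp windows."""
    margin = cfg.plateau_halfwidth + 2000
    per_chrom = cfg.n_genes // cfg.n_chroms
    spacing = (cfg.chrom_length - 2 * margin) // per_chrom
    if spacing < 12_000:
        raise ValueError(
            f"genome too small for {cfg.n_genes} genes with disjoint +-5 kbp windows"
        )
    freqs = np.asarray(cfg.base_frequencies)
    genome: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        genome[chrom] = rng.choice(4, size=cfg.chrom_length, p=freqs).astype(np.uint8)
        for gi in range(per_chrom):
            tss = margin + gi * spacing + int(rng.integers(-500, 501))
            strand = "+" if (gi % 2 == 0) else "-"
            genes.append(GeneModel(f"g{ci * per_chrom + gi:04d}", chrom, tss, strand))
    return genome, genes


def _make_pwms(cfg: SimConfig, rng: np.random.Generator) -> tuple[list[PWM], list[str]]:
    """Random consensus-dominated PWMs; returns (pwms, consensus strings)."""
    pwms, consensi = [], []
    for i in range(cfg.n_motifs):
        cons_idx = rng.integers(0, 4, size=cfg.motif_width)
        counts = np.full((cfg.motif_width, 4), cfg.offconsensus_count)
        counts[np.arange(cfg.motif_width), cons_idx] = cfg.consensus_count
        pwms.append(PWM(f"V$SYN{i:02d}", counts))
        consensi.append("".join(_BASES[cons_idx]))
    return pwms, consensi


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _site_center(gene: GeneModel, offset: int) -> int:
    return gene.tss + offset if gene.strand == "+" else gene.tss - offset


def _plant(genome: dict[str, np.ndarray], chrom: str, pos: int, seq: str) -> None:
    enc = np.array(["ACGT".index(b) for b in seq], dtype=np.uint8)
    genome[chrom][pos : pos + len(enc)] = enc


def simulate_motifs_and_sequence(
    cfg: SimConfig,
    genome: dict[str, np.ndarray],
    genes: list[GeneModel],
    rng: np.random.Generator,
) -> tuple[list[PWM], GroundTruth]:
    """Assign clusters/motifs, embed motif instances, and build ground truth.

    Regulator consensus instances go inside the motif-rich dip sites of
    member genes; ubiquitous motifs get one copy in every gene's neutral
    dip.  Embedded instances never cross a dip-region boundary.
    """
    pwms, consensi = _make_pwms(cfg, rng)
    labels = [f"UC{i + 1}" for i in range(cfg.n_clusters_up)] + [
        f"DC{i + 1}" for i in range(cfg.n_clusters_down)
    ]
    regulators = [pwms[i].motif_id for i in range(cfg.n_clusters)]
    ubiquitous = [
        pwms[cfg.n_clusters + i].motif_id for i in range(cfg.n_ubiquitous)
    ]
    decoys = [p.motif_id for p in pwms if p.motif_id not in regulators + ubiquitous]

    n_de = cfg.n_clusters * cfg.genes_per_cluster
    if n_de > len(genes):
        raise ValueError("not enough genes for the requested clusters")
    order = rng.permutation(len(genes))
    times = np.asarray(cfg.signal_times)

    clusters: dict[str, ClusterTruth] = {}
    cluster_of_gene: dict[str, str] = {}
    dip_sites: dict[str, list[dict]] = {g.gene_id: [] for g in genes}

    for k, label in enumerate(labels):
        direction = "up" if label.startswith("UC") else "down"
        templates = _UP_TEMPLATES if direction == "up" else _DOWN_TEMPLATES
        role, profile = templates[k % len(templates)]
        members_idx = order[k * cfg.genes_per_cluster : (k + 1) * cfg.genes_per_cluster]
        members = [genes[i].gene_id for i in members_idx]
        clusters[label] = ClusterTruth(
            label=label,
            direction=direction,
            role=role,
            activity=np.asarray(profile, dtype=float),
            lag=cfg.planted_lags[k % len(cfg.planted_lags)],
            motif_id=regulators[k],
            tf_id=f"TF_{label}",
            members=members,
        )
        for gid in members:
            cluster_of_gene[gid] = label

    filler = [genes[i].gene_id for i in order[n_de:]]
    gene_by_id = {g.gene_id: g for g in genes}
    cons_by_id = dict(zip([p.motif_id for p in pwms], consensi))
    w = cfg.motif_width

    for g in genes:
        # neutral always-open site, with one copy of each ubiquitous motif
        center = _site_center(g, cfg.neutral_site_offset)
        dip_sites[g.gene_id].append(
            {"center": center, "kind": "neutral", "threshold": 0.0}
        )
        for j, mid in enumerate(ubiquitous):
            pos = center - w // 2 + (j - len(ubiquitous) // 2) * (w + 4)
            seq = cons_by_id[mid]
            _plant(genome, g.chrom, pos, seq if rng.random() < 0.5 else _revcomp(seq))

    for label, ct in clusters.items():
        seq0 = cons_by_id[ct.motif_id]
        for gid in ct.members:
            g = gene_by_id[gid]
            for offset, thr in zip(cfg.site_offsets, cfg.site_thresholds):
                center = _site_center(g, offset)
                dip_sites[gid].append(
                    {"center": center, "kind": "motif", "threshold": thr}
                )
                for c in range(cfg.motif_copies_per_site):
                    pos = center - w // 2 + (c - cfg.motif_copies_per_site // 2) * (w + 6)
                    seq = seq0 if rng.random() < 0.5 else _revcomp(seq0)
                    _plant(genome, g.chrom, pos, seq)

    # planted open-dip intervals per time point (the recall/precision truth)
    valleys_by_time: dict[float, list[tuple[str, int, int]]] = {}
    halfwidth = int(2.5 * cfg.dip_sigma)
    for ti, t in enumerate(times):
        items = []
        for g in genes:
            label = cluster_of_gene.get(g.gene_id)
            act = float(clusters[label].activity[ti]) if label else 0.0
            for site in dip_sites[g.gene_id]:
                if site["kind"] == "neutral" or act >= site["threshold"]:
                    items.append((g.chrom, site["center"] - halfwidth, site["center"] + halfwidth))
        valleys_by_time[float(t)] = items

    truth = GroundTruth(
        clusters=clusters,
        cluster_of_gene=cluster_of_gene,
        filler_genes=filler,
        dip_sites=dip_sites,
        valleys_by_time=valleys_by_time,
        regulator_motifs=regulators,
        ubiquitous_motifs=ubiquitous,
        decoy_motifs=decoys,
    )
    return pwms, truth


def simulate_hac(
    cfg: SimConfig,
    genes: list[GeneModel],
    truth: GroundTruth,
    rng: np.random.Generator,
    noise_sd: float | None = None,
) -> dict[float, dict[str, CoverageTrack]]:
    """Noisy HAc coverage per time point: promoter plateaus with open dips."""
    noise_sd = cfg.signal_noise_sd if noise_sd is None else noise_sd
    step = cfg.step
    n_bins = cfg.chrom_length // step
    times = np.asarray(cfg.signal_times)
    out: dict[float, dict[str, CoverageTrack]] = {}
    gene_by_id = {g.gene_id: g for g in genes}
    for ti, t in enumerate(times):
        tracks: dict[str, np.ndarray] = {
            f"chr{c + 1}": np.full(n_bins, cfg.baseline) for c in range(cfg.n_chroms)
        }
        for g in genes:
            arr = tracks[g.chrom]
            lo, hi = (g.tss - cfg.plateau_halfwidth) // step, (g.tss + cfg.plateau_halfwidth) // step
            arr[max(0, lo) : hi] += cfg.plateau_height
            label = truth.cluster_of_gene.get(g.gene_id)
            act = float(truth.clusters[label].activity[ti]) if label else 0.0
            for site in truth.dip_sites[g.gene_id]:
                if site["kind"] != "neutral" and act < site["threshold"]:
                    continue
                c_bin = site["center"] // step
                half = int(4 * cfg.dip_sigma) // step
                idx = np.arange(c_bin - half, c_bin + half + 1)
                x = idx * step - site["center"]
                dip = cfg.plateau_height * cfg.dip_depth * np.exp(
                    -(x**2) / (2 * cfg.dip_sigma**2)
                )
                arr[idx[0] : idx[-1] + 1] -= dip
        result: dict[str, CoverageTrack] = {}
        for chrom, arr in tracks.items():
            if noise_sd > 0:
                arr = arr + rng.normal(0.0, noise_sd, size=arr.shape)
            result[chrom] = CoverageTrack(chrom, 0, step, np.clip(arr, 0.0, None))
        out[float(t)] = result
    return out


def simulate_expression(
    cfg: SimConfig, genes: list[GeneModel], truth: GroundTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """log2 expression matrix: cluster medians track activity shifted by the lag.

    Activators drive expression positively, repressors negatively;
    filler genes are flat (about half below the intensity floor).
    """
    times = np.asarray(cfg.signal_times)
    expr_t = np.asarray(cfg.expr_times)
    cols = [f"t{t:g}_r{r + 1}" for t in expr_t for r in range(cfg.n_replicates)]
    col_times = np.repeat(expr_t, cfg.n_replicates)
    rows = {}
    for g in genes:
        label = truth.cluster_of_gene.get(g.gene_id)
        if label is None:
            low = rng.random() < 0.5
            base = rng.uniform(4.0, 5.5) if low else rng.uniform(6.5, 10.5)
            rows[g.gene_id] = base + rng.normal(0, cfg.expr_noise_sd, len(cols))
            continue
        ct = truth.clusters[label]
        sign = 1.0 if ct.role == "activator" else -1.0
        base = cfg.activator_baseline if sign > 0 else cfg.repressor_baseline
        gene_base = base + rng.normal(0, 0.3)
        gene_scale = cfg.expr_effect * rng.uniform(0.85, 1.2)
        drive = sign * _activity_at(times, ct.activity, col_times - ct.lag)
        rows[g.gene_id] = gene_base + gene_scale * drive + rng.normal(
            0, cfg.expr_noise_sd, len(cols)
        )
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).sort_index()


def simulate_tf_reads(
    cfg: SimConfig, genes: list[GeneModel], truth: GroundTruth, rng: np.random.Generator
) -> dict[str, dict[float, pd.DataFrame]]:
    """Per TF per time: uniform background reads + promoter enrichment.

    The enrichment factor over the -2000/+500 windows of the TF's
    target-cluster genes scales with cluster activity at that time.
    """
    times = np.asarray(cfg.signal_times)
    gene_by_id = {g.gene_id: g for g in genes}
    chroms = [f"chr{c + 1}" for c in range(cfg.n_chroms)]
    density = cfg.tf_reads_per_time / cfg.genome_length
    window = 2500  # -2000/+500
    out: dict[str, dict[float, pd.DataFrame]] = {}
    for label, ct in truth.clusters.items():
        out[ct.tf_id] = {}
        for ti, t in enumerate(times):
            parts = []
            n_bg = rng.poisson(cfg.tf_reads_per_time)
            chrom_idx = rng.integers(0, cfg.n_chroms, size=n_bg)
            starts = rng.integers(0, cfg.chrom_length - cfg.read_length, size=n_bg)
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": np.array(chroms)[chrom_idx],
                        "start": starts,
                        "end": starts + cfg.read_length,
                        "strand": np.where(rng.random(n_bg) < 0.5, "+", "-"),
                    }
                )
            )
            factor = 1 + (cfg.tf_enrichment - 1) * float(ct.activity[ti])
            extra_per_window = (factor - 1) * density * window
            for gid in ct.members:
                g = gene_by_id[gid]
                n_extra = rng.poisson(extra_per_window)
                if n_extra == 0:
                    continue
                if g.strand == "+":
                    lo, hi = g.tss - 2000, g.tss + 500
                else:
                    lo, hi = g.tss - 500, g.tss + 2000
                s = rng.integers(max(0, lo), hi - cfg.read_length, size=n_extra)
                parts.append(
                    pd.DataFrame(
                        {
                            "chrom": g.chrom,
                            "start": s,
                            "end": s + cfg.read_length,
                            "strand": np.where(rng.random(n_extra) < 0.5, "+", "-"),
                        }
                    )
                )
            df = pd.concat(parts, ignore_index=True)
            out[ct.tf_id][float(t)] = df.sort_values(["chrom", "start"]).reset_index(
                drop=True
            )
    return out


def simulate(cfg: SimConfig | None = None) -> SimData:
    """Run the full generator under the config's master seed."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    genome_arr, genes = simulate_genome(cfg, rng)
    pwms, truth = simulate_motifs_and_sequence(cfg, genome_arr, genes, rng)
    hac = simulate_hac(cfg, genes, truth, rng)
    expression = simulate_expression(cfg, genes, truth, rng)
    tf_reads = simulate_tf_reads(cfg, genes, truth, rng)
    genome = {c: "".join(_BASES[a]) for c, a in genome_arr.items()}
    return SimData(cfg, genome, genes, truth, hac, expression, pwms, tf_reads)


def run_config_for(cfg: SimConfig, seed: int | None = None, **overrides):
    """A pipeline RunConfig matched to a synthetic dataset.

    Sets the cluster counts to the planted truth, a valley-score floor
    of 30% of the plateau height (the enriched-region proxy: planted
    plateaus are acetylated regions, the noisy inter-gene baseline is
    not), and a permutation count sized to the synthetic gene count.
    """
    from valleytf.pipeline import RunConfig

    defaults = dict(
        seed=cfg.seed if seed is None else seed,
        k_up=cfg.n_clusters_up,
        k_down=cfg.n_clusters_down,
        valley_min_score=0.3 * cfg.plateau_height,
        n_permutations=300,
    )
    defaults.update(overrides)
    return RunConfig(**defaults)


def simulate_lag_series(
    lag: float,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
    signal_times: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0),
    expr_times: tuple[float, ...] = (0.0, 2.0, 4.0, 12.0),
) -> tuple[np.ndarray, np.ndarray]:
    """A (motif-score series, cluster-median profile) pair with a planted lag.

    The median profile is a randomly placed and scaled response pulse
    (Gaussian bump in time, random sign and amplitude), the non-affine
    shape temporal expression clusters show; the score series is that
    curve evaluated at signal times + lag (TF activity leads
    expression), plus optional Gaussian noise with SD equal to
    ``noise_sd`` times the score series' range.
    """
    expr_times = np.asarray(expr_times)
    sig = np.asarray(signal_times)
    while True:
        peak = rng.uniform(1.0, 6.0)
        width = rng.uniform(1.0, 3.0)
        median = np.exp(-((expr_times - peak) ** 2) / (2 * width**2))
        median = median * rng.choice([-1.0, 1.0]) * rng.uniform(2.0, 5.0) + rng.normal(0, 1)
        scores = np.interp(sig + lag, expr_times, median)
        if np.std(scores) > 1e-6 and np.std(median) > 1e-6:
            break
    if noise_sd > 0:
        scale = noise_sd * (scores.max() - scores.min())
        scores = scores + rng.normal(0, scale, size=len(scores))
    return scores, median


def write_outputs(sim: SimData, outdir) -> None:
    """Emit the exact plain-text formats the pipeline consumes."""
    from valleytf import io as vio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vio.write_fasta(sim.genome, outdir / "genome.fa")
    vio.write_genes_bed(sim.genes, outdir / "genes.bed")
    for t, tracks in sim.hac.items():
        path = outdir / f"hac_t{t:g}h.bedgraph"
        if path.exists():
            path.unlink()
        for chrom in sorted(tracks):
            vio.write_bedgraph(tracks[chrom], path, mode="a")
    vio.write_expression_tsv(sim.expression, outdir / "expression.tsv")
    from valleytf.motifscan import write_motifs_transfac

    write_motifs_transfac(sim.motifs, outdir / "motifs.transfac")
    for tf, by_time in sim.tf_reads.items():
        for t, reads in by_time.items():
            vio.write_bed_reads(reads, outdir / f"{tf}_t{t:g}h.bed")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(sim.truth.to_manifest(), fh, indent=1)
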