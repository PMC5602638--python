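"""Ground-truth generator: determinism, planted structure, calibration."""

import numpy as np
import pandas as pd
import pytest

from valleytf.annotation import assign_aprs, apr_sequences, promoter_sequences
from valleytf.coverage import call_valleys, smooth
from valleytf.expression import (
    DEParams,
    anova_permutation_q,
    filter_expressed,
    fold_changes,
    parse_sample_times,
    select_de,
)
from valleytf.motifscan import Background, raw_score
from valleytf.synthetic import (
    SimConfig,
    simulate,
    simulate_expression,
    simulate_genome,
    simulate_hac,
    simulate_motifs_and_sequence,
    simulate_tf_reads,
    write_outputs,
)

# a reduced scale for unit tests; statistical structure is unchanged
SMALL = SimConfig(
    seed=5,
    n_chroms=1,
    chrom_length=600_000,
    n_genes=40,
    genes_per_cluster=6,
    tf_reads_per_time=6000,
)


@pytest.fixture(scope="module")
def small_sim():
    return simulate(SMALL)


class TestSimulateGenome:
    def test_base_frequencies_within_multinomial_bounds(self, rng):
        cfg = SimConfig(seed=1, n_chroms=1, chrom_length=200_000, n_genes=10)
        genome, _ = simulate_genome(cfg, np.random.default_rng(1))
        counts = np.bincount(genome["chr1"], minlength=4)
        n = counts.sum()
        for c in counts:
            sd = np.sqrt(n * 0.25 * 0.75)
            assert abs(c - n * 0.25) < 3 * sd

    def test_tss_windows_are_disjoint(self):
        _, genes = simulate_genome(SMALL, np.random.default_rng(2))
        tss = sorted(g.tss for g in genes)
        assert all(b - a >= 10_000 for a, b in zip(tss, tss[1:]))

    def test_same_seed_same_genome(self):
        g1, _ = simulate_genome(SMALL, np.random.default_rng(3))
        g2, _ = simulate_genome(SMALL, np.random.default_rng(3))
        assert np.array_equal(g1["chr1"], g2["chr1"])

    def test_too_small_genome_rejected(self):
        cfg = SimConfig(n_chroms=1, chrom_length=100_000, n_genes=50)
        with pytest.raises(ValueError):
            simulate_genome(cfg, np.random.default_rng(0))


class TestSimulateHac:
    def _valleys(self, cfg, genes, truth, noise_sd):
        hac = simulate_hac(cfg, genes, truth, np.random.default_rng(77), noise_sd=noise_sd)
        found = {}
        for t, tracks in hac.items():
            calls = []
            for chrom, tr in tracks.items():
                calls.extend(call_valleys(smooth(tr), time_point=t,
                                          min_score=0.3 * cfg.plateau_height))
            found[t] = calls
        return found

    def _recall_precision(self, truth, found, t):
        planted = truth.valleys_by_time[t]
        calls = found[t]
        hit = sum(
            1
            for chrom, s, e in planted
            if any(c.chrom == chrom and c.start < e and c.end > s for c in calls)
        )
        matched_calls = sum(
            1
            for c in calls
            if any(c.chrom == chrom and c.start < e and c.end > s
                   for chrom, s, e in planted)
        )
        recall = hit / len(planted)
        precision = matched_calls / len(calls) if calls else 1.0
        return recall, precision

    def test_noiseless_recovery_is_perfect(self):
        rng = np.random.default_rng(8)
        genome, genes = simulate_genome(SMALL, rng)
        _, truth = simulate_motifs_and_sequence(SMALL, genome, genes, rng)
        found = self._valleys(SMALL, genes, truth, noise_sd=0.0)
        for t in found:
            recall, precision = self._recall_precision(truth, found, t)
            assert recall == 1.0 and precision == 1.0

    def test_noisy_recall_stays_high(self):
        rng = np.random.default_rng(9)
        genome, genes = simulate_genome(SMALL, rng)
        _, truth = simulate_motifs_and_sequence(SMALL, genome, genes, rng)
        found = self._valleys(SMALL, genes, truth, noise_sd=5.0)  # 10% of plateau
        for t in found:
            recall, _ = self._recall_precision(truth, found, t)
            assert recall >= 0.9

    def test_signal_nonnegative(self, small_sim):
        for tracks in small_sim.hac.values():
            for tr in tracks.values():
                assert (tr.values >= 0).all()


class TestSimulateMotifsAndSequence:
    def test_target_cluster_scores_track_activity(self, small_sim):
        sim = small_sim
        valleys = {}
        for t, tracks in sim.hac.items():
            calls = []
            for chrom, tr in tracks.items():
                calls.extend(call_valleys(smooth(tr), time_point=t, min_score=15.0))
            valleys[t] = calls
        aprs = assign_aprs(valleys, sim.genes)
        bg = Background([s for _, s in promoter_sequences(sim.genes, sim.genome)])
        pwm_by_id = {p.motif_id: p for p in sim.motifs}
        for ct in sim.truth.clusters.values():
            pwm = pwm_by_id[ct.motif_id]
            hi_t = float(ct.activity.argmax())  # activity index == time order
            times = sorted(sim.hac)
            t_hi = times[int(ct.activity.argmax())]
            t_lo = times[int(ct.activity.argmin())]
            seq_hi = [s for _, s in apr_sequences(aprs, sim.genome, t_hi, ct.members)]
            seq_lo = [s for _, s in apr_sequences(aprs, sim.genome, t_lo, ct.members)]
            assert raw_score(pwm, seq_hi, bg) > raw_score(pwm, seq_lo, bg) + 0.5

    def test_instances_inside_dip_regions(self, small_sim):
        sim = small_sim
        w = sim.config.motif_width
        cons = {p.motif_id: p for p in sim.motifs}
        for ct in sim.truth.clusters.values():
            pwm = cons[ct.motif_id]
            consensus = "".join("ACGT"[i] for i in pwm.counts.argmax(axis=1))
            for gid in ct.members[:3]:
                sites = [s for s in sim.truth.dip_sites[gid] if s["kind"] == "motif"]
                g = next(g for g in sim.genes if g.gene_id == gid)
                for site in sites:
                    region = sim.genome[g.chrom][site["center"] - 100 : site["center"] + 100]
                    from conftest import revcomp

                    assert consensus in region or revcomp(consensus) in region


class TestSimulateExpression:
    def test_de_selection_recovers_planted_genes(self, small_sim):
        sim = small_sim
        params = DEParams(n_permutations=200)
        times = parse_sample_times(sim.expression.columns)
        expressed = filter_expressed(sim.expression, params)
        stats = anova_permutation_q(expressed, times, params, seed=4)
        fc = fold_changes(expressed, times)
        up, down = select_de(fc, stats, params)
        de = set(up) | set(down)
        planted = set(sim.truth.cluster_of_gene)
        sensitivity = len(de & planted) / len(planted)
        assert sensitivity >= 0.95
        # filler genes rarely pass
        fillers = set(sim.truth.filler_genes) & set(expressed.index)
        assert len(de & fillers) <= max(1, 0.01 * len(fillers))

    def test_directions_match_truth(self, small_sim):
        sim = small_sim
        times = parse_sample_times(sim.expression.columns)
        fc = fold_changes(sim.expression, times)
        for gid, label in sim.truth.cluster_of_gene.items():
            ct = sim.truth.clusters[label]
            peak = fc.loc[gid].iloc[1:].to_numpy()
            extreme = peak[np.abs(peak).argmax()]
            assert (extreme > 0) == (ct.direction == "up")


class TestSimulateTfReads:
    def test_read_counts_poisson_dispersed(self, small_sim):
        sim = small_sim
        cfg = sim.config
        n = [len(df) for by_t in sim.tf_reads.values() for df in by_t.values()]
        lo = cfg.tf_reads_per_time - 5 * np.sqrt(cfg.tf_reads_per_time)
        assert all(v >= lo for v in n)

    def test_uniform_tf_gives_no_enrichment(self):
        # enrichment factor 1: the target cluster looks like background
        cfg = SimConfig(
            seed=6, n_chroms=1, chrom_length=600_000, n_genes=40,
            genes_per_cluster=6, tf_reads_per_time=6000, tf_enrichment=1.0,
        )
        sim = simulate(cfg)
        from valleytf.chipvalidate import validate_predictions

        universe = [g.gene_id for g in sim.genes]
        clusters = {lab: ct.members for lab, ct in sim.truth.clusters.items()}
        table = validate_predictions(sim.tf_reads, sim.genes, clusters, universe,
                                     n_sets=300, seed=3)
        assert (table["q"] < 0.01).mean() <= 0.05

    def test_enriched_tf_detected_in_target_cluster(self, small_sim):
        sim = small_sim
        from valleytf.chipvalidate import validate_predictions

        universe = [g.gene_id for g in sim.genes]
        clusters = {lab: ct.members for lab, ct in sim.truth.clusters.items()}
        table = validate_predictions(sim.tf_reads, sim.genes, clusters, universe,
                                     n_sets=500, seed=4)
        for lab, ct in sim.truth.clusters.items():
            t_hi = sorted(sim.hac)[int(ct.activity.argmax())]
            row = table[(table["tf"] == ct.tf_id) & (table["cluster"] == lab)
                        & (table["time"] == t_hi)].iloc[0]
            assert row["q"] < 0.01


class TestDeterminismAndOutputs:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(seed=12, n_chroms=1, chrom_length=400_000, n_genes=24,
                        genes_per_cluster=4, tf_reads_per_time=2000)
        for d in ("a", "b"):
            write_outputs(simulate(cfg), tmp_path / d)
        for name in ("genome.fa", "genes.bed", "expression.tsv", "motifs.transfac",
                     "hac_t0h.bedgraph", "ground_truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_emitted_files_are_consumable(self, tmp_path):
        from valleytf import io as vio
        from valleytf.motifscan import read_motifs

        cfg = SimConfig(seed=13, n_chroms=1, chrom_length=400_000, n_genes=24,
                        genes_per_cluster=4, tf_reads_per_time=2000)
        sim = simulate(cfg)
        write_outputs(sim, tmp_path)
        genome = vio.read_fasta(tmp_path / "genome.fa")
        assert genome.keys() == sim.genome.keys()
        assert genome["chr1"] == sim.genome["chr1"]
        genes = vio.read_genes_bed(tmp_path / "genes.bed")
        assert [g.gene_id for g in genes] == [g.gene_id for g in sim.genes]
        assert [g.tss for g in genes] == [g.tss for g in sim.genes]
        pwms = read_motifs(tmp_path / "motifs.transfac", "transfac")
        assert [p.motif_id for p in pwms] == [p.motif_id for p in sim.motifs]
        tracks = vio.read_bedgraph(tmp_path / "hac_t0h.bedgraph", step=10)
        orig = sim.hac[0.0]["chr1"]
        got = tracks["chr1"]
        i0 = (orig.positions >= got.origin).argmax()
        np.testing.assert_allclose(
            got.values[: 1000], orig.values[i0 : i0 + 1000], atol=1e-4
        )
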