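"""Simulator calibration against coalescent theory and truth-file coherence."""

import numpy as np
import pytest

from conftest import small_sim_config
from sexscan.io_core import MISSING
from sexscan.popgen import tajimas_d
from sexscan.simulate import (
    SimConfig,
    simulate_autosomal_block,
    simulate_cohort,
    simulate_depth,
    simulate_male_assembly_depth,
    simulate_reads,
    reference_sequences,
)


def _watterson_a1(n):
    return sum(1.0 / i for i in range(1, n))


class TestCoalescentBlock:
    def test_segregating_sites_match_watterson(self, rng):
        """E[S] = theta * a1; 600 reps at n=10, theta=5."""
        theta, n, reps = 5.0, 10, 600
        s = [
            simulate_autosomal_block(n, theta, rng)[0].shape[1] for _ in range(reps)
        ]
        expect = theta * _watterson_a1(n)  # 14.14
        # SD(S) ~ sqrt(theta*a1 + theta^2*a2) ~ 7.3
        assert abs(np.mean(s) - expect) < 3.5 * 7.3 / np.sqrt(reps)

    def test_pairwise_diversity_matches_theta(self, rng):
        theta, n, reps = 5.0, 10, 600
        pis = []
        for _ in range(reps):
            h, _ = simulate_autosomal_block(n, theta, rng)
            c = h.sum(axis=0)
            pis.append(np.sum(c * (n - c)) / (n * (n - 1) / 2))
        assert abs(np.mean(pis) - theta) < 0.4

    def test_same_seed_is_deterministic(self):
        h1, p1 = simulate_autosomal_block(8, 10.0, 42)
        h2, p2 = simulate_autosomal_block(8, 10.0, 42)
        assert np.array_equal(h1, h2) and np.array_equal(p1, p2)

    def test_equilibrium_tajimas_d_is_centered(self, rng):
        """Neutral equilibrium: |mean D| < 0.1 (n=20, theta=10)."""
        vals = []
        for _ in range(500):
            h, _ = simulate_autosomal_block(20, 10.0, rng)
            d = tajimas_d(h.sum(axis=0), 20)
            if np.isfinite(d):
                vals.append(d)
        assert abs(np.mean(vals)) < 0.1

    def test_matches_msprime_oracle(self):
        """Independent coalescent engine agrees on E[S] and E[pi]."""
        msprime = pytest.importorskip("msprime")
        theta, n, reps = 8.0, 12, 300
        s_mine, pi_mine, s_ms, pi_ms = [], [], [], []
        rng = np.random.default_rng(7)
        for _ in range(reps):
            h, _ = simulate_autosomal_block(n, theta, rng)
            c = h.sum(axis=0)
            s_mine.append(h.shape[1])
            pi_mine.append(np.sum(c * (n - c)) / (n * (n - 1) / 2))
        for i, ts in enumerate(
            msprime.sim_ancestry(
                samples=n, ploidy=1, population_size=0.5, num_replicates=reps,
                random_seed=99,
            )
        ):
            # at ploidy 1 and N=0.5 the expected pairwise branch length is 1,
            # so the per-genome rate theta gives E[pi] = theta, E[S] = theta*a1
            mts = msprime.sim_mutations(
                ts, rate=theta, discrete_genome=False, random_seed=17 + i
            )
            s_ms.append(mts.num_sites)
            pi_ms.append(mts.diversity(span_normalise=False))
        assert abs(np.mean(s_mine) - np.mean(s_ms)) < 1.5
        assert abs(np.mean(pi_mine) - np.mean(pi_ms)) < 0.6


class TestCohort:
    def test_truth_y_sites_are_male_het_female_hom(self, xy_cohort):
        m = xy_cohort.matrix
        males = m.sample_indices(xy_cohort.sheet.males())
        females = m.sample_indices(xy_cohort.sheet.females())
        sd_contig = xy_cohort.config.sd_region[0]
        pos_index = {
            (c, p): i
            for i, (c, p) in enumerate(zip(m.contig, m.positions))
        }
        assert xy_cohort.truth["y_sites"], "no Y sites simulated"
        assert not xy_cohort.truth["y_sites_fixed_on_y_only"]
        for p in xy_cohort.truth["y_sites"]:
            i = pos_index[(sd_contig, p)]
            assert (m.genotypes[i, males] == 1).all()
            assert np.isin(m.genotypes[i, females], (0, 2)).all()

    def test_y_sites_lie_inside_sd_region(self, xy_cohort):
        _, a, b = xy_cohort.config.sd_region
        pos = np.array(xy_cohort.truth["y_sites"])
        assert ((pos > a) & (pos <= b)).all()

    def test_no_y_sites_when_tau_zero(self):
        cfg = small_sim_config(seed=5, y_tau=0.0, y_internal_theta=0.0)
        res = simulate_cohort(cfg)
        assert res.truth["y_sites"] == []

    def test_y_site_count_matches_poisson_mean(self):
        """E[#Y sites] = tau * region length, averaged over replicates."""
        tau, region = 1e-3, 60_000
        counts = [
            len(
                simulate_cohort(
                    small_sim_config(seed=1000 + i, y_tau=tau, n_y_insertions=0)
                ).truth["y_sites"]
            )
            for i in range(40)
        ]
        expect = tau * region  # 60
        assert abs(np.mean(counts) - expect) < 3.5 * np.sqrt(expect / len(counts))

    def test_hardy_weinberg_at_autosomal_sites(self):
        """Observed/expected heterozygosity within 5% when aggregated over
        enough independent coalescent blocks (single blocks are dominated
        by their shared genealogy and fluctuate far more)."""
        obs = exp = 0.0
        for seed in range(60, 65):
            res = simulate_cohort(small_sim_config(seed=seed))
            for contig in ("c1", "c3"):
                g = res.matrix.for_contig(contig).genotypes
                n = g.shape[1]
                p = g.sum(axis=1) / (2 * n)
                obs += (g == 1).mean(axis=1).sum()
                exp += (2 * p * (1 - p) * (2 * n / (2 * n - 1))).sum()
        assert 0.95 < obs / exp < 1.05

    def test_bottleneck_population_has_positive_tajimas_d(self):
        cfg = small_sim_config(seed=21, n_populations=2)
        res = simulate_cohort(cfg)
        creek = [s for s in res.sheet.samples if res.sheet.population[s] == "creek"]
        idx = res.matrix.sample_indices(creek)
        vals = []
        for contig in ("c1", "c3"):
            sub = res.matrix.for_contig(contig)
            for w in range(10):
                lo, hi = np.searchsorted(
                    sub.positions, [w * 10_000 + 1, (w + 1) * 10_000 + 1]
                )
                g = sub.genotypes[lo:hi][:, idx]
                g = g[(g != MISSING).all(axis=1)]
                # restrict to sites polymorphic within the population
                tot = g.sum(axis=1)
                g = g[(tot > 0) & (tot < 2 * g.shape[1])]
                d = tajimas_d(g.sum(axis=1), 2 * len(idx))
                if np.isfinite(d):
                    vals.append(d)
        assert np.mean(vals) > 0

    def test_same_seed_reproduces_cohort(self):
        a = simulate_cohort(small_sim_config(seed=77))
        b = simulate_cohort(small_sim_config(seed=77))
        assert np.array_equal(a.matrix.genotypes, b.matrix.genotypes)
        assert a.truth["y_sites"] == b.truth["y_sites"]


class TestDepth:
    def test_dialect_contrast_in_differentiated_region(self, xy_cohort):
        cfg = xy_cohort.config
        males = [i for i, s in enumerate(xy_cohort.sheet.samples)
                 if xy_cohort.sheet.sex[s] == "M"]
        females = [i for i, s in enumerate(xy_cohort.sheet.samples)
                   if xy_cohort.sheet.sex[s] == "F"]
        region = slice(20_000, 80_000)
        perfect = simulate_depth(cfg, xy_cohort.truth, "perfect", full_sd_mask=True)
        allal = simulate_depth(cfg, xy_cohort.truth, "all")
        lam = cfg.depth_lambda
        assert abs(perfect["c2"].depth[males, region].mean() - lam / 2) < 0.2
        assert abs(perfect["c2"].depth[females, region].mean() - lam) < 0.2
        assert abs(allal["c2"].depth[males, region].mean() - lam) < 0.2
        # outside the sd region both sexes sit at lambda under either dialect
        assert abs(perfect["c1"].depth[males].mean() - lam) < 0.2

    def test_male_assembly_track_zeroes_females_on_insertions(self, xy_cohort):
        tr = simulate_male_assembly_depth(xy_cohort)
        f_rows = [i for i, s in enumerate(tr.samples)
                  if xy_cohort.sheet.sex[s] == "F"]
        m_rows = [i for i, s in enumerate(tr.samples)
                  if xy_cohort.sheet.sex[s] == "M"]
        for a, b in xy_cohort.truth["male_assembly"]["insertion_intervals"]:
            assert tr.depth[f_rows, a:b].sum() == 0
            assert abs(tr.depth[m_rows, a:b].mean()
                       - xy_cohort.config.depth_lambda / 2) < 0.6


@pytest.fixture(scope="module")
def read_sim(tmp_path_factory):
    cfg = SimConfig(
        seed=31,
        contigs={"c1": 40_000, "c2": 40_000},
        sd_region=("c2", 5_000, 35_000),
        n_y_insertions=2,
        y_insertion_length=800,
        read_depth=12.0,
    )
    res = simulate_cohort(cfg)
    outdir = tmp_path_factory.mktemp("reads")
    files = simulate_reads(res, outdir)
    return cfg, res, files


class TestReads:
    def test_per_base_coverage_identity(self, read_sim):
        cfg, res, files = read_sim
        total_bases = 0
        from sexscan.kmers import iter_fastq

        s = res.sheet.samples[0]
        for path in files[s]:
            for _, seq, _ in iter_fastq(path):
                total_bases += len(seq)
        genome = sum(cfg.contigs.values())
        cov = total_bases / genome
        assert abs(cov - cfg.read_depth) / cfg.read_depth < 0.1

    def test_female_reads_never_carry_insertion_sequence(self, read_sim):
        cfg, res, files = read_sim
        from sexscan.kmers import iter_fastq, revcomp

        probe = res.truth["y_insertions"][0]["sequence"][300:400]
        probes = (probe, revcomp(probe))
        for s in res.sheet.females():
            assert res.truth["y_insertion_read_pairs"][s] == []
            for path in files[s]:
                for _, seq, _ in iter_fastq(path):
                    assert probe[:37] not in seq and probes[1][:37] not in seq

    def test_reads_are_byte_identical_across_runs(self, read_sim, tmp_path):
        cfg, res, files = read_sim
        files2 = simulate_reads(res, tmp_path / "again")
        s = res.sheet.samples[3]
        assert files[s][0].read_bytes() == files2[s][0].read_bytes()
        assert files[s][1].read_bytes() == files2[s][1].read_bytes()
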