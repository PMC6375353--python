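"""XY-site detection, F_IS, F_IS-F_ST correlation, PCA, Ajk relatedness."""

import itertools

import numpy as np
import pytest

import oracles
from conftest import make_matrix, small_sim_config
from sexscan.popgen import window_statistics
from sexscan.sexsites import (
    ajk_relatedness,
    detect_sex_patterned_sites,
    fis_fst_correlation,
    individual_fis,
    normalized_fis_windows,
    pca_genotypes,
)
from sexscan.simulate import SimConfig, simulate_cohort


def _sexed_matrix(rows, n_m=5, n_f=5):
    m = make_matrix(rows)
    males = [f"s{i}" for i in range(n_m)]
    females = [f"s{i}" for i in range(n_m, n_m + n_f)]
    return m, males, females


class TestDetectSexPatternedSites:
    def test_all_males_het_all_females_hom_is_a_site(self):
        m, males, females = _sexed_matrix([[1] * 5 + [0] * 5])
        assert detect_sex_patterned_sites(m, males, females).n_sites == 1

    def test_single_homozygous_male_disqualifies(self):
        m, males, females = _sexed_matrix([[0] + [1] * 4 + [0] * 5])
        assert detect_sex_patterned_sites(m, males, females).n_sites == 0

    def test_females_may_be_homozygous_for_either_allele(self):
        m, males, females = _sexed_matrix([[1] * 5 + [0, 0, 2, 2, 0]])
        assert detect_sex_patterned_sites(m, males, females).n_sites == 1

    def test_zw_pattern_is_the_mirror(self):
        m, males, females = _sexed_matrix([[0] * 5 + [1] * 5])
        assert detect_sex_patterned_sites(m, males, females, pattern="ZW").n_sites == 1
        assert detect_sex_patterned_sites(m, males, females, pattern="XY").n_sites == 0

    def test_strict_mode_rejects_missing_lenient_evaluates_called(self):
        m, males, females = _sexed_matrix([[-1] + [1] * 4 + [0] * 5])
        assert detect_sex_patterned_sites(m, males, females, mode="strict").n_sites == 0
        assert (
            detect_sex_patterned_sites(
                m, males, females, mode="lenient", min_called=3
            ).n_sites
            == 1
        )

    def test_exhaustive_enumeration_three_v_three(self):
        """All 3^6 complete-call genotype configurations agree with the
        literal pattern rule."""
        rows = list(itertools.product((0, 1, 2), repeat=6))
        m, males, females = _sexed_matrix(rows, n_m=3, n_f=3)
        got = detect_sex_patterned_sites(m, males, females)
        got_pos = set(got.positions.tolist())
        for i, row in enumerate(rows):
            expect = oracles.xy_site_checker(row[:3], row[3:])
            assert ((m.positions[i] in got_pos) == expect), row

    def test_empty_sex_is_an_error(self):
        m, males, females = _sexed_matrix([[1] * 10])
        with pytest.raises(ValueError):
            detect_sex_patterned_sites(m, [], females)

    def test_recovers_truth_sites_and_concentrates_on_sd_contig(self, xy_cohort):
        males = xy_cohort.sheet.males()
        females = xy_cohort.sheet.females()
        got = detect_sex_patterned_sites(xy_cohort.matrix, males, females)
        sd_contig = xy_cohort.config.sd_region[0]
        truth = set(xy_cohort.truth["y_sites"])
        found = set(got.positions[got.contig == sd_contig].tolist())
        assert len(truth & found) / len(truth) >= 0.9
        assert (got.contig == sd_contig).mean() >= 0.8
        norm = got.contig_normalized_counts(xy_cohort.matrix)
        top = norm.sort_values("normalized", ascending=False).iloc[0]
        assert top["contig"] == sd_contig


class TestIndividualFis:
    def test_fully_homozygous_individual_scores_one(self):
        g = [[0, 0, 2], [2, 0, 0], [0, 2, 2]]
        f = individual_fis(make_matrix(g), ["s0", "s1", "s2"])
        assert f["s0"] == pytest.approx(1.0)

    def test_always_het_individual_approaches_minus_one(self):
        n = 50
        rows = [[1] + [0] * (n // 2 - 1) + [2] * (n // 2) for _ in range(40)]
        f = individual_fis(make_matrix(rows), [f"s{i}" for i in range(n)])
        assert f["s0"] == pytest.approx(-1.0, abs=0.05)

    def test_two_site_toy_matches_hand_computation(self):
        # 3 diploids, sites (0,1,2) and (1,2,0): p = 0.5 at both sites
        g = np.array([[0, 1, 2], [1, 2, 0]], dtype=np.int8)
        f = individual_fis(make_matrix(g), ["s0", "s1", "s2"])
        e_site = 1 - 2 * 0.5 * 0.5 * (6 / 5)  # 0.4 with the 2n/(2n-1) factor
        # s0: N=2 called sites, O_hom=1 -> (1 - 0.8)/(2 - 0.8)
        assert f["s0"] == pytest.approx((1 - 2 * e_site) / (2 - 2 * e_site), abs=1e-12)
        # s2: homozygous at both -> 1
        assert f["s2"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_literal_two_pass_oracle(self, rng):
        for _ in range(5):
            g = rng.integers(0, 3, size=(100, 6)).astype(np.int8)
            g[rng.random(g.shape) < 0.1] = -1
            samples = [f"s{i}" for i in range(6)]
            mine = individual_fis(make_matrix(g), samples)
            ref = oracles.individual_fis_literal(g, samples)
            for s in samples:
                if np.isnan(ref[s]):
                    assert np.isnan(mine[s])
                else:
                    assert mine[s] == pytest.approx(ref[s], abs=1e-12)


def _fis_cohort(seed):
    """A cohort with a 400 kb sd region: enough 10 kb windows that F_IS
    summaries are not dominated by single-genealogy noise (each window is
    one non-recombining block)."""
    cfg = SimConfig(
        seed=seed,
        contigs={"c1": 200_000, "c2": 600_000, "c3": 200_000},
        sd_region=("c2", 100_000, 500_000),
        n_y_insertions=0,
    )
    return simulate_cohort(cfg)


class TestNormalizedFisWindows:
    def test_sd_windows_show_male_excess_female_deficit(self):
        """Inside the sd region the heterogametic males trend to negative
        normalized F_IS and females to positive.  Per-window values carry
        the full genealogy noise of a non-recombining 10 kb block plus the
        block-shared Y haplotype, so the direction is asserted on pooled
        windows, not per window."""
        sd_m, sd_f = [], []
        for seed in (401, 402, 403):
            res = _fis_cohort(seed)
            sheet = res.sheet
            norm = normalized_fis_windows(
                res.matrix, sheet.males() + sheet.females(), sheet.sex,
                "c2", 600_000,
            )
            sd = norm[(norm.start >= 100_000) & (norm.end <= 500_000)]
            sd_m.extend(sd["norm_fis_m"])
            sd_f.extend(sd["norm_fis_f"])
        sd_m, sd_f = np.array(sd_m), np.array(sd_f)
        assert np.nanmean(sd_m) < -0.05
        assert np.nanmean(sd_f) > 0.0
        assert (sd_m < 0).mean() >= 0.7
        assert (sd_f > 0).mean() >= 0.55

    def test_autosomal_window_means_near_zero(self):
        vals = []
        for seed in (401, 402, 403):
            res = _fis_cohort(seed)
            sheet = res.sheet
            for contig in ("c1", "c3"):
                norm = normalized_fis_windows(
                    res.matrix, sheet.males() + sheet.females(), sheet.sex,
                    contig, 200_000,
                )
                vals.extend(norm["norm_fis_m"])
                vals.extend(norm["norm_fis_f"])
        assert abs(np.nanmean(vals)) < 0.15


class TestFisFstCorrelation:
    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        r, p = fis_fst_correlation(-x, x)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_gives_na(self):
        r, p = fis_fst_correlation(np.ones(5), np.arange(5.0))
        assert np.isnan(r)

    def test_sd_chromosome_signs_by_sex(self):
        """Heterogametic males: negative F_IS where sex F_ST is high;
        sign test concordant across seeded replicates."""
        for seed in (401, 402, 403, 404):
            res = _fis_cohort(seed)
            sheet = res.sheet
            subset = sheet.males() + sheet.females()
            norm = normalized_fis_windows(
                res.matrix, subset, sheet.sex, "c2", 600_000
            )
            stats = window_statistics(
                res.matrix, sheet.males(), sheet.females(), {"c2": 600_000}
            )
            rm, _ = fis_fst_correlation(norm["norm_fis_m"], stats["fst"])
            rf, _ = fis_fst_correlation(norm["norm_fis_f"], stats["fst"])
            assert rm < 0
            assert rf > 0

    def test_shuffled_windows_lose_the_correlation(self, rng):
        res = _fis_cohort(405)
        sheet = res.sheet
        subset = sheet.males() + sheet.females()
        norm = normalized_fis_windows(res.matrix, subset, sheet.sex, "c2", 600_000)
        stats = window_statistics(
            res.matrix, sheet.males(), sheet.females(), {"c2": 600_000}
        )
        x = norm["norm_fis_m"].to_numpy()
        y = stats["fst"].to_numpy()
        perm = [fis_fst_correlation(rng.permutation(x), y)[0] for _ in range(200)]
        assert abs(np.mean(perm)) < 0.1
        # permuted correlations spread around zero at the 1/sqrt(n) scale
        assert np.std(perm) < 2.5 / np.sqrt(len(x))


class TestPca:
    def test_two_clusters_separate_on_pc1(self):
        rows = [[0] * 4 + [2] * 4 for _ in range(30)] + [
            [0, 2] * 4 for _ in range(3)
        ]
        coords, expl = pca_genotypes(make_matrix(rows))
        pc1 = coords["PC1"].to_numpy()
        assert np.std(pc1[:4]) == pytest.approx(0, abs=1e-9)
        assert np.std(pc1[4:]) == pytest.approx(0, abs=1e-9)
        assert abs(pc1[:4].mean() - pc1[4:].mean()) > 1

    def test_sex_loads_on_a_pc_only_with_sd_contig(self):
        """A PCA on the sd contig shows a principal component tracking sex;
        dropping that contig removes the signal.  With ten samples the
        noise axes correlate substantially with any balanced binary vector
        by chance, so the contrast is asserted on means over seeds."""
        r_with, r_without = [], []
        for seed in (201, 202, 203, 204, 205):
            res = simulate_cohort(small_sim_config(seed=seed))
            sex = np.array(
                [1.0 if res.sheet.sex[s] == "M" else 0.0
                 for s in res.sheet.samples]
            )
            co, _ = pca_genotypes(res.matrix.for_contig("c2"), n_components=3)
            r_with.append(
                max(abs(np.corrcoef(co[c], sex)[0, 1]) for c in co.columns)
            )
            cex, _ = pca_genotypes(
                res.matrix, drop_contigs=("c2",), n_components=3
            )
            r_without.append(
                max(abs(np.corrcoef(cex[c], sex)[0, 1]) for c in cex.columns)
            )
        assert np.mean(r_with) > 0.7
        assert np.mean(r_without) < 0.55
        assert np.mean(r_with) - np.mean(r_without) > 0.15

    def test_distances_invariant_to_sign_flip(self, xy_cohort):
        coords, _ = pca_genotypes(xy_cohort.matrix, n_components=4)
        x = coords.to_numpy()
        d0 = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        x2 = x.copy()
        x2[:, 1] *= -1
        d1 = np.linalg.norm(x2[:, None] - x2[None, :], axis=2)
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_all_monomorphic_is_an_error(self):
        with pytest.raises(ValueError):
            pca_genotypes(make_matrix([[2, 2, 2], [0, 0, 0]]))


class TestAjk:
    def test_symmetry_and_duplicate_detection(self, rng):
        g = rng.integers(0, 3, size=(300, 6)).astype(np.int8)
        g = np.hstack([g, g[:, :1]])  # s6 duplicates s0
        a = ajk_relatedness(make_matrix(g))
        arr = a.to_numpy()
        np.testing.assert_array_equal(arr, arr.T)
        row = a.loc["s0"].drop("s0")
        assert row.idxmax() == "s6"

    def test_unrelated_individuals_center_near_zero(self):
        """Off-diagonal Ajk for unrelated samples carries only the
        -1/(n-1) small-sample centering bias; with 30 samples the mean is
        within 0.05 of zero."""
        res = simulate_cohort(
            small_sim_config(seed=51, n_males=15, n_females=15, sd_region=None,
                             n_y_insertions=0)
        )
        a = ajk_relatedness(res.matrix)
        off = a.to_numpy()[~np.eye(a.shape[0], dtype=bool)]
        assert abs(np.nanmean(off)) < 0.05
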