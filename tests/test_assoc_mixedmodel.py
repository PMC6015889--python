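import numpy as np
import pytest
from scipy import stats

from qtsmap.assoc_mixedmodel import (
    HendersonIII,
    ScanSettings,
    henderson3_f,
    permutation_threshold,
    permute_within_env,
    scan_candidates,
    screen_collinear_terms,
)
from qtsmap.datamodel import GeneticArchitecture, LocusEffect, PairEffect, build_design
from qtsmap.nam_simulator import SimConfig, simulate_genotypes, simulate_phenotypes
from qtsmap.presets import unlinked_map

from conftest import phenotypes_for, random_genotypes


def brute_force_partial_f(M_full, cols, y):
    """Independent two-regression RSS oracle for the partial F-test."""
    keep = [k for k in range(M_full.shape[1]) if k not in cols]

    def rss(A):
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        r = y - A @ beta
        return float(r @ r)

    rss_full, rss_red = rss(M_full), rss(M_full[:, keep])
    df1 = np.linalg.matrix_rank(M_full) - np.linalg.matrix_rank(M_full[:, keep])
    df2 = len(y) - np.linalg.matrix_rank(M_full)
    F = ((rss_red - rss_full) / df1) / (rss_full / df2)
    return F, df1, df2


@pytest.fixture
def fixed_only_design(rng):
    """n=60, 3 loci, single environment (so interaction blocks vanish)."""
    gm = random_genotypes(rng, 60, ("S1_100", "S1_200", "S2_100"))
    ph = phenotypes_for(gm, rng, n_env=1)
    return build_design(gm, ph, "trait", list(gm.marker_ids), [("S1_100", "S2_100")], "full")


class TestHendersonIII:
    def test_matches_ols_oracle_on_fixed_design(self, fixed_only_design):
        d = fixed_only_design
        M, groups, _ = d.full_matrix()
        tester = HendersonIII(d)
        for term, cols in groups.items():
            if tester.df1(term) == 0:
                continue
            F, df1, df2, _ = henderson3_f(d, term)
            F_o, df1_o, df2_o = brute_force_partial_f(M, cols, d.y)
            assert df1 == df1_o and df2 == df2_o
            assert F == pytest.approx(F_o, rel=1e-8)

    def test_response_in_base_span_gives_zero_f(self, fixed_only_design):
        d = fixed_only_design
        tester = HendersonIII(d)
        y0 = np.full(d.n_obs, 3.7)  # spanned by the intercept
        fs = tester.f_stats(y0)
        for term, v in fs.items():
            if tester.df1(term) > 0:
                assert v[0] == pytest.approx(0.0, abs=1e-16)

    def test_scale_and_shift_invariance(self, fixed_only_design):
        d = fixed_only_design
        tester = HendersonIII(d)
        base = tester.f_stats(d.y)
        shifted = tester.f_stats(7.3 * d.y + 100.0)
        for term in base:
            if np.isfinite(base[term][0]):
                assert shifted[term][0] == pytest.approx(base[term][0], rel=1e-9)

    def test_null_f_distribution_moments(self, rng):
        # 600 null replicates: empirical mean of F close to df2/(df2-2)
        gm = random_genotypes(rng, 40, ("S1_100", "S1_200"))
        ph = phenotypes_for(gm, rng, n_env=1)
        d = build_design(gm, ph, "trait", list(gm.marker_ids), [], "full")
        tester = HendersonIII(d)
        term = "a:S1_100"
        df1, df2 = tester.df1(term), tester.df2
        Y = rng.standard_normal((d.n_obs, 600))
        F = tester.f_stats(Y, [term])[term]
        expected_mean = df2 / (df2 - 2)
        se = np.sqrt(stats.f.var(df1, df2) / 600)
        assert abs(F.mean() - expected_mean) < 3 * se

    def test_degenerate_term_rejected(self, rng):
        gm = random_genotypes(rng, 30, ("S1_100",))
        # duplicate the locus column by testing it against itself:
        # constant-zero dominance column when no heterozygotes exist
        gm.calls[:, 0] = np.where(gm.calls[:, 0] == 1, 0, gm.calls[:, 0])
        ph = phenotypes_for(gm, rng, n_env=1)
        d = build_design(gm, ph, "trait", ["S1_100"], [], "full")
        with pytest.raises(ValueError, match="degenerate"):
            henderson3_f(d, "d:S1_100")


class TestPermutation:
    def test_preserves_multiset_within_environment(self, rng):
        y = rng.normal(size=20)
        env = np.repeat([1, 2], 10)
        Y = permute_within_env(y, env, 50, rng)
        for k in range(50):
            for e in (1, 2):
                assert sorted(Y[env == e, k]) == pytest.approx(sorted(y[env == e]))

    def test_seed_reproducible(self, fixed_only_design):
        d = fixed_only_design
        tester = HendersonIII(d)
        a = permutation_threshold(tester, n_perm=120, seed=5)
        b = permutation_threshold(tester, n_perm=120, seed=5)
        for k in a.maxima:
            np.testing.assert_array_equal(a.maxima[k], b.maxima[k])

    def test_single_term_matches_analytic_quantile(self, rng):
        gm = random_genotypes(rng, 80, ("S1_100",))
        ph = phenotypes_for(gm, rng, n_env=2)
        d = build_design(gm, ph, "trait", ["S1_100"], [], "additive")
        tester = HendersonIII(d)
        null = permutation_threshold(tester, ["a:S1_100"], n_perm=2000, seed=4)
        crit = null.critical_f(1)
        analytic = stats.f.ppf(0.95, 1, tester.df2)
        assert crit == pytest.approx(analytic, rel=0.25)

    def test_alpha_one_gives_min_of_maxima(self, fixed_only_design):
        tester = HendersonIII(fixed_only_design)
        null = permutation_threshold(tester, n_perm=150, seed=2)
        k = min(null.maxima)
        assert null.critical_f(k, alpha=1.0) == null.maxima[k].min()

    def test_p_ew_monotone_in_f(self, fixed_only_design):
        tester = HendersonIII(fixed_only_design)
        null = permutation_threshold(tester, n_perm=150, seed=3)
        k = min(null.maxima)
        fs = np.linspace(0, 20, 40)
        ps = [null.p_ew(k, f) for f in fs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_n_perm_floor(self, fixed_only_design):
        tester = HendersonIII(fixed_only_design)
        with pytest.raises(ValueError, match="below the floor"):
            permutation_threshold(tester, n_perm=50)

    def test_reject_iff_above_critical(self, fixed_only_design):
        tester = HendersonIII(fixed_only_design)
        null = permutation_threshold(tester, n_perm=200, alpha_ew=0.05, seed=9)
        k = min(null.maxima)
        crit = null.critical_f(k)
        for f in np.linspace(crit * 0.5, crit * 1.5, 21):
            assert (null.p_ew(k, f) <= 0.05) == (f > crit) or f == pytest.approx(crit)


def _sim_for_scan(arch_builder, seed=0, n_loci=12, lines=150, g=2):
    gmap = unlinked_map(n_loci)
    mids = [m.id for m in gmap.markers()]
    arch = arch_builder(mids)
    cfg = SimConfig(
        n_families=3, lines_per_family=lines // 3, genetic_map=gmap,
        selfing_generations=g, founder_poly=1.0, environments=2, env_sd=0.5,
        architecture=arch, seed=seed,
    )
    gm = simulate_genotypes(cfg)
    ph = simulate_phenotypes(gm, cfg)
    return gm, ph, mids


class TestScanCandidates:
    def test_recovers_strong_additive_loci(self):
        def arch(mids):
            return GeneticArchitecture(
                loci=[LocusEffect(mids[0], a=1.0), LocusEffect(mids[4], a=-0.9),
                      LocusEffect(mids[8], a=0.8)],
                residual_sd=1.0,
            )

        gm, ph, mids = _sim_for_scan(arch, seed=21)
        res = scan_candidates(
            gm, ph, "trait", list(gm.marker_ids), [], "full",
            ScanSettings(n_perm=150, seed=1),
        )
        truth = {mids[0], mids[4], mids[8]}
        assert truth <= set(res.selected_loci)
        false_pos = set(res.selected_loci) - truth
        assert len(false_pos) <= 2

    def test_null_truth_rarely_selects(self):
        gm, ph, _ = _sim_for_scan(lambda m: GeneticArchitecture(residual_sd=1.0), seed=22)
        res = scan_candidates(
            gm, ph, "trait", list(gm.marker_ids), [], "additive",
            ScanSettings(n_perm=150, seed=2),
        )
        assert len(res.selected_loci) <= 2  # experiment-wise control

    def test_additive_model_misses_pure_dd_truth(self):
        def arch(mids):
            return GeneticArchitecture(
                pairs=[PairEffect(mids[0], mids[1], dd=8.0)], residual_sd=1.0
            )

        gm, ph, mids = _sim_for_scan(arch, seed=23, lines=300, g=1)
        res_add = scan_candidates(
            gm, ph, "trait", list(gm.marker_ids), [], "additive",
            ScanSettings(n_perm=150, seed=3),
        )
        res_full = scan_candidates(
            gm, ph, "trait", [mids[0], mids[1]], [(mids[0], mids[1])], "full",
            ScanSettings(n_perm=150, seed=3),
        )
        dd_term = res_full.term(f"dd:{mids[0]}:{mids[1]}")
        assert dd_term.passes_ew  # full model sees the interaction
        assert len(res_add.selected_loci) <= 2  # additive model mostly blind to it

    def test_selected_terms_all_significant_after_pruning(self):
        def arch(mids):
            return GeneticArchitecture(loci=[LocusEffect(mids[0], a=1.2)], residual_sd=1.0)

        gm, ph, _ = _sim_for_scan(arch, seed=24, n_loci=6)
        res = scan_candidates(
            gm, ph, "trait", list(gm.marker_ids), [], "full", ScanSettings(n_perm=150, seed=4)
        )
        for t in res.selected_terms():
            assert t.p_ew <= res.settings.alpha_ew

    def test_neg_log10_capped_and_flagged(self):
        def arch(mids):
            return GeneticArchitecture(loci=[LocusEffect(mids[0], a=3.0)], residual_sd=0.3)

        gm, ph, mids = _sim_for_scan(arch, seed=25, n_loci=4)
        res = scan_candidates(
            gm, ph, "trait", list(gm.marker_ids), [], "additive",
            ScanSettings(n_perm=150, seed=5),
        )
        t = res.term(f"a:{mids[0]}")
        assert t.p_at_floor
        assert t.neg_log10_p_ew == pytest.approx(np.log10(151))

    def test_empty_candidates_rejected(self, tiny_gm, tiny_ph):
        with pytest.raises(ValueError, match="empty candidate"):
            scan_candidates(tiny_gm, tiny_ph, "trait", [], [])


class TestScreening:
    def test_duplicate_marker_column_screened(self, rng):
        # two markers with identical calls: the later one's terms add no rank
        gm = random_genotypes(rng, 50, ("S1_100", "S1_200"))
        gm.calls[:, 1] = gm.calls[:, 0]
        ph = phenotypes_for(gm, rng, n_env=1)
        d = build_design(gm, ph, "trait", ["S1_100", "S1_200"], [], "full")
        kept, dropped = screen_collinear_terms(d, gm)
        assert "a:S1_100" in kept and "d:S1_100" in kept
        assert "a:S1_200" in dropped and "d:S1_200" in dropped
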