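import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sleepsweep import afc
from sleepsweep.panel import AlleleCountPanel


def cmh_oracle(tables):
    """Independent direct evaluation of the Mantel-Haenszel formula."""
    num = den = 0.0
    for (a, b), (c, d) in tables:
        T = a + b + c + d
        if T <= 1:
            continue
        num += a - (a + b) * (a + c) / T
        den += (a + b) * (c + d) * (a + c) * (b + d) / (T ** 2 * (T - 1))
    stat = num ** 2 / den if den > 0 else 0.0
    return stat, stats.chi2.sf(stat, 1) if den > 0 else 1.0


def hpd_grid_oracle(minor, total, mass=0.95, grid=20001):
    """Brute-force shortest credible interval of the Jeffreys-Beta posterior."""
    post = stats.beta(0.5 + minor, 0.5 + total - minor)
    ts = np.linspace(0, 1 - mass, grid)
    lo = post.ppf(ts)
    hi = post.ppf(ts + mass)
    k = np.argmin(hi - lo)
    return lo[k], hi[k]


class TestDefineMinorAllele:
    def test_minor_is_lower_summed_count(self, toy_counts):
        asg = afc.define_minor_allele(toy_counts)
        # site 0: gen-0 sums ref=170 alt=30 -> alt minor
        assert asg.alt_is_minor[0]
        assert np.isclose(asg.minor_freq[0, 0], 10 / 100)

    def test_tie_goes_to_alt(self):
        sites = pd.DataFrame({"chrom": ["2L"], "pos": [1], "ref": ["A"],
                              "alt": ["T"]})
        samples = pd.DataFrame({"population": ["P"], "scheme": ["control"],
                                "replicate": [1], "sex": ["F"],
                                "generation": [0]})
        panel = AlleleCountPanel(sites, samples, np.array([[500]]),
                                 np.array([[500]]))
        assert afc.define_minor_allele(panel).alt_is_minor[0]

    def test_site_fixed_for_major(self, toy_counts):
        asg = afc.define_minor_allele(toy_counts)
        # site 2: alt (minor at gen 0) has counts 0 and 10
        assert asg.alt_is_minor[2]
        assert asg.minor_freq[2, 0] == 0.0

    def test_zero_coverage_deferred(self, toy_counts):
        p = toy_counts.copy()
        p.ref_count[1, [0, 1]] = 0
        p.alt_count[1, [0, 1]] = 0
        asg = afc.define_minor_allele(p)
        assert asg.deferred[1]
        assert not asg.deferred[0]


class TestCoverageFilter:
    @pytest.mark.parametrize("total,kept", [(9, False), (10, True),
                                            (2000, True), (2001, False)])
    def test_boundaries(self, total, kept):
        sites = pd.DataFrame({"chrom": ["2L"], "pos": [1], "ref": ["A"],
                              "alt": ["T"]})
        samples = pd.DataFrame({"population": ["P"], "scheme": ["long"],
                                "replicate": [1], "sex": ["F"],
                                "generation": [0]})
        panel = AlleleCountPanel(sites, samples, np.array([[total]]),
                                 np.array([[0]]))
        out = afc.coverage_filter(panel)
        assert out.valid[0, 0] == kept

    def test_counts_preserved(self, toy_counts):
        out = afc.coverage_filter(toy_counts)
        assert np.array_equal(out.ref_count, toy_counts.ref_count)


class TestHpdInterval:
    def test_boundary_modes(self):
        lo, hi = afc.allele_hpd_interval(0, 40)
        assert lo == 0.0 and 0 < hi < 0.2
        lo, hi = afc.allele_hpd_interval(40, 40)
        assert hi == 1.0 and lo > 0.8

    @pytest.mark.parametrize("minor,total", [(30, 100), (5, 50), (250, 500),
                                             (1, 12)])
    def test_matches_grid_search(self, minor, total):
        lo, hi = afc.allele_hpd_interval(minor, total)
        glo, ghi = hpd_grid_oracle(minor, total)
        assert abs(lo - glo) < 5e-4
        assert abs(hi - ghi) < 5e-4

    def test_interval_covers_mode(self):
        for minor, total in [(3, 10), (30, 100), (98, 100)]:
            lo, hi = afc.allele_hpd_interval(minor, total)
            mode = (0.5 + minor - 1) / (total - 1)  # Jeffreys posterior mode
            assert lo <= np.clip(mode, 0, 1) <= hi
            assert 0 <= lo <= hi <= 1

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            afc.allele_hpd_interval(0, 0)


class TestCmh:
    def test_no_association(self):
        stat, p = afc.cmh_test([[[10, 10], [90, 90]], [[5, 5], [45, 45]]])
        assert stat == 0.0 and p == 1.0

    def test_single_stratum_direct_formula(self):
        tables = [[[10, 90], [50, 50]]]
        stat, p = afc.cmh_test(tables)
        ostat, op = cmh_oracle(np.array(tables))
        assert abs(stat - ostat) < 1e-10
        assert abs(p - op) < 1e-12

    def test_oracle_agreement_random_tables(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            k = rng.integers(1, 5)
            tables = rng.integers(0, 200, size=(k, 2, 2))
            stat, p = afc.cmh_test(tables)
            ostat, op = cmh_oracle(tables)
            assert abs(stat - ostat) < 1e-10

    def test_doubling_counts_increases_statistic(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = rng.integers(1, 100, size=(2, 2, 2))
            s1, _ = afc.cmh_test(t)
            s2, _ = afc.cmh_test(2 * t)
            if s1 > 1e-12:
                assert s2 > s1

    def test_all_zero_strata_rejected(self):
        with pytest.raises(ValueError):
            afc.cmh_test(np.zeros((2, 2, 2)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            afc.cmh_test([[[1, -1], [2, 3]]])


def _two_gen_panel(ref0, alt0, ref1, alt1, population="L1", scheme="long"):
    """One site, one population, both sexes at generations 0 and 12."""
    sites = pd.DataFrame({"chrom": ["2L"], "pos": [1], "ref": ["A"],
                          "alt": ["T"]})
    samples = pd.DataFrame({
        "population": [population] * 4, "scheme": [scheme] * 4,
        "replicate": [1] * 4, "sex": ["F", "M", "F", "M"],
        "generation": [0, 0, 12, 12]})
    ref = np.array([[ref0, ref0, ref1, ref1]])
    alt = np.array([[alt0, alt0, alt1, alt1]])
    return AlleleCountPanel(sites, samples, ref, alt)


class TestScan:
    def test_big_change_is_significant(self):
        panel = _two_gen_panel(200, 0, 100, 100)
        asg = afc.define_minor_allele(panel)
        res = afc.scan(panel, asg, [(0, 12)], alpha=2.3e-8)
        assert res.significant["L1"] == {0}

    def test_no_change_not_significant(self):
        panel = _two_gen_panel(150, 50, 150, 50)
        asg = afc.define_minor_allele(panel)
        res = afc.scan(panel, asg, [(0, 12)], alpha=0.05)
        assert res.significant["L1"] == set()

    def test_coverage_failure_skips_pair_only(self):
        panel = _two_gen_panel(4, 0, 100, 100)  # gen-0 pools below 10 reads
        panel = afc.coverage_filter(panel)
        asg = afc.define_minor_allele(panel)
        res = afc.scan(panel, asg, [(0, 12)], alpha=0.05)
        assert np.isnan(res.p_values["L1"].iloc[0, 0])
        assert res.significant["L1"] == set()

    def test_missing_generation_warns_and_skips(self):
        panel = _two_gen_panel(100, 10, 90, 20)
        asg = afc.define_minor_allele(panel)
        with pytest.warns(UserWarning, match="incomplete"):
            res = afc.scan(panel, asg, [(0, 5), (0, 12)], alpha=0.05)
        assert list(res.p_values["L1"].columns) == ["0-12"]

    def test_null_family_wise_error_controlled(self):
        # pure-noise panel at constant frequency; Bonferroni alpha
        rng = np.random.default_rng(21)
        n_sites, fails = 200, 0
        n_reps = 40
        for _ in range(n_reps):
            cov = 100
            sites = pd.DataFrame({"chrom": "2L", "pos": np.arange(1, n_sites + 1),
                                  "ref": "A", "alt": "T"})
            samples = pd.DataFrame({
                "population": ["P"] * 4, "scheme": ["long"] * 4,
                "replicate": [1] * 4, "sex": ["F", "M", "F", "M"],
                "generation": [0, 0, 12, 12]})
            alt = rng.binomial(cov, 0.3, size=(n_sites, 4))
            panel = AlleleCountPanel(sites, samples,
                                     cov - alt, alt)
            asg = afc.define_minor_allele(panel)
            res = afc.scan(panel, asg, [(0, 12)], alpha=0.05 / n_sites)
            if res.significant["P"]:
                fails += 1
        assert fails <= 0.2 * n_reps  # FWER <= 0.05 nominally


class TestOverlapFilter:
    def test_rule(self):
        cands = afc.overlap_filter(
            sig_long={"L1": {1, 2}, "L2": {3}},
            sig_short={"S1": {2, 5}, "S2": {3, 7}},
            sig_control={"C1": {5}, "C2": {2}})
        # union(long)={1,2,3}; union(short)={2,3,5,7}; controls={2,5}
        assert cands == {3}

    def test_control_only_site_excluded(self):
        assert afc.overlap_filter({"L1": {1}}, {"S1": {1}}, {"C1": {1}}) == set()

    def test_intersection_variant(self):
        cands = afc.overlap_filter(
            sig_long={"L1": {1, 2}, "L2": {2, 3}},
            sig_short={"S1": {2}, "S2": {2}},
            sig_control={}, within_scheme="intersection")
        assert cands == {2}


def _trajectory_panel(p_long, p_short, gens=(0, 1, 2, 5, 8, 10, 12), cov=200):
    """Two populations (one long, one short), both sexes, deterministic
    counts following the given per-generation minor-allele frequencies."""
    sites = pd.DataFrame({"chrom": ["2L"], "pos": [1], "ref": ["A"],
                          "alt": ["T"]})
    rows, ref, alt = [], [], []
    for scheme, pops, traj in (("long", "L1", p_long), ("short", "S1", p_short)):
        for g, p in zip(gens, traj):
            for sex in ("F", "M"):
                rows.append({"population": pops, "scheme": scheme,
                             "replicate": 1, "sex": sex, "generation": g})
                a = int(round(p * cov))
                alt.append(a)
                ref.append(cov - a)
    samples = pd.DataFrame(rows)
    return AlleleCountPanel(sites, samples, np.array([ref]), np.array([alt]))


class TestLogisticFilter:
    def test_identical_trajectories_fail(self):
        traj = [0.3, 0.32, 0.35, 0.4, 0.45, 0.5, 0.55]
        panel = _trajectory_panel(traj, traj)
        asg = afc.define_minor_allele(panel)
        out = afc.logistic_filter(panel, asg, [0])
        assert not out.at[0, "passed"]
        assert out.at[0, "p_sel"] > 0.05

    def test_planted_divergent_site_passes(self):
        gens = np.array([0, 1, 2, 5, 8, 10, 12])
        p_long = 1 / (1 + np.exp(-(0.0 + 0.35 * gens)))
        p_short = 1 / (1 + np.exp(-(-0.4 - 0.35 * gens)))
        panel = _trajectory_panel(p_long, p_short)
        asg = afc.define_minor_allele(panel)
        out = afc.logistic_filter(panel, asg, [0])
        assert out.at[0, "passed"]
        assert out.at[0, "p_lack_of_fit"] >= 0.05

    def test_fixation_to_opposite_extremes_passes(self):
        # a low-frequency minor allele swept up in one scheme and lost in
        # the other: both level (Sel) and trend (Gen x Sel) separate
        p_short = [0.25, 0.45, 0.65, 0.9, 1.0, 1.0, 1.0]
        p_long = [0.25, 0.1, 0.02, 0.0, 0.0, 0.0, 0.0]
        panel = _trajectory_panel(p_long, p_short)
        asg = afc.define_minor_allele(panel)
        out = afc.logistic_filter(panel, asg, [0])
        assert out.at[0, "p_sel"] <= 0.05
        assert out.at[0, "p_gen_sel"] <= 0.05

    def test_complete_scheme_separation_triggers_fallback(self):
        # one scheme fixed for the minor allele, the other devoid of it, at
        # every generation: Sel separates the outcome perfectly
        panel = _trajectory_panel([1.0] * 7, [0.0] * 7)
        asg = afc.define_minor_allele(panel)
        out = afc.logistic_filter(panel, asg, [0])
        assert out.at[0, "separation"]
        assert np.isfinite(out.at[0, "p_sel"])

    def test_null_panel_rarely_passes(self):
        # proper scheme-null: one shared frequency path, independent
        # binomial read sampling per sample -> Sel effects are pure noise
        rng = np.random.default_rng(17)
        passed = 0
        n = 60
        cov = 200
        for _ in range(n):
            path = np.clip(rng.uniform(0.2, 0.5)
                           + rng.normal(0, 0.02, 7).cumsum(), 0.02, 0.98)
            sites = pd.DataFrame({"chrom": ["2L"], "pos": [1], "ref": ["A"],
                                  "alt": ["T"]})
            rows, ref, alt = [], [], []
            for scheme, pop in (("long", "L1"), ("short", "S1")):
                for g, p in zip((0, 1, 2, 5, 8, 10, 12), path):
                    for sex in ("F", "M"):
                        rows.append({"population": pop, "scheme": scheme,
                                     "replicate": 1, "sex": sex,
                                     "generation": g})
                        a = rng.binomial(cov, p)
                        alt.append(a)
                        ref.append(cov - a)
            panel = AlleleCountPanel(sites, pd.DataFrame(rows),
                                     np.array([ref]), np.array([alt]))
            asg = afc.define_minor_allele(panel)
            out = afc.logistic_filter(panel, asg, [0])
            passed += int(out.at[0, "passed"])
        assert passed / n < 0.05  # joint criteria are much stricter than 5%


class TestDirection:
    def test_minor_freq_direction(self):
        p_long = [0.5, 0.4, 0.3, 0.2, 0.1, 0.05, 0.0]
        p_short = [0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 1.0]
        panel = _trajectory_panel(p_long, p_short)
        asg = afc.define_minor_allele(panel)
        out = afc.minor_freq_direction(panel, asg, [0], generation=12)
        assert bool(out.at[0, "higher_in_short"])
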