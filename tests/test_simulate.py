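import numpy as np
import pytest
from scipy import stats

from sleepsweep import diallel, sleep
from sleepsweep.simulate import (ActivitySpec, ExperimentConfig, MafSpectrum,
                                 canonical_effects, generate_founder_panel,
                                 sample_pool_reads, simulate_activity,
                                 simulate_diallel)
from sleepsweep.simulate.experiment import simulate_experiment


class TestFounderPanel:
    def test_point_mass_half_gives_five_of_ten(self):
        panel = generate_founder_panel(10, 30, ["2L"],
                                       MafSpectrum("point", 0.5), seed=0)
        assert (panel.genotypes.sum(axis=0) == 5).all()

    def test_deterministic_given_seed(self):
        kw = dict(n_lines=8, n_sites_per_chrom=25, chrom_labels=["2L", "X"],
                  maf_spectrum=MafSpectrum("beta", 0.5, 0.5))
        a = generate_founder_panel(seed=42, **kw)
        b = generate_founder_panel(seed=42, **kw)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert a.sites.equals(b.sites)

    def test_all_sites_polymorphic(self, small_panel):
        assert small_panel.polymorphic_mask().all()

    def test_positions_strictly_increasing(self, small_panel):
        for _, grp in small_panel.sites.groupby("chrom"):
            assert (np.diff(grp["pos"]) > 0).all()

    def test_invalid_spectrum_rejected(self):
        with pytest.raises(ValueError):
            generate_founder_panel(10, 5, ["2L"], MafSpectrum("beta", -1, 2),
                                   seed=0)
        with pytest.raises(ValueError):
            generate_founder_panel(1, 5, ["2L"], seed=0)


class TestSamplePoolReads:
    def test_degenerate_frequencies(self):
        assert sample_pool_reads(0.0, 50, seed=1) == (50, 0)
        assert sample_pool_reads(1.0, 30, seed=1) == (0, 30)

    def test_binomial_moments(self):
        rng = np.random.default_rng(7)
        _, alt = sample_pool_reads(np.full(10_000, 0.3),
                                   np.full(10_000, 100), seed=rng)
        se = np.sqrt(100 * 0.3 * 0.7 / 10_000)
        assert abs(alt.mean() - 30.0) < 3 * se

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            sample_pool_reads(1.5, 10)
        with pytest.raises(ValueError):
            sample_pool_reads(0.5, -1)


def truncation_recursion(p, a, sigma, fraction, n_gens):
    """Deterministic single-locus oracle: expected allele frequency under
    truncation selection of the top ``fraction`` on genotype value + Normal
    noise, with Hardy-Weinberg genotype frequencies each generation."""
    freqs = [p]
    for _ in range(n_gens):
        w = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        means = np.array([0.0, a, 2 * a])

        def selected_fraction(c):
            return float(w @ stats.norm.sf(c, loc=means, scale=sigma))

        lo, hi = means.min() - 10 * sigma, means.max() + 10 * sigma
        for _ in range(200):  # bisect the truncation point
            mid = (lo + hi) / 2
            if selected_fraction(mid) > fraction:
                lo = mid
            else:
                hi = mid
        c = (lo + hi) / 2
        sel = w * stats.norm.sf(c, loc=means, scale=sigma)
        p = float((sel * np.array([0.0, 0.5, 1.0])).sum() / sel.sum())
        freqs.append(p)
    return np.array(freqs)


class TestSimulateExperiment:
    def test_generation_zero_shared_source(self, small_experiment):
        f0 = np.array([small_experiment.true_freq[p][0]
                       for p in small_experiment.true_freq])
        # across-population spread at generation 0 is founding noise only
        assert np.abs(f0 - f0.mean(axis=0)).max() < 0.35

    def test_no_genetic_variance_no_response(self, small_panel):
        cfg = ExperimentConfig(n_generations=6, n_measured_per_sex=40,
                               census=80, env_sd=50.0, qtl_effects=None,
                               schemes={"long": 1, "short": 1}, seed=9,
                               sequenced_generations=(0,))
        res = simulate_experiment(small_panel, cfg)
        final = res.summaries[res.summaries["generation"] == 6]
        gap = abs(final["mean"].iloc[0] - final["mean"].iloc[1])
        assert gap < 4 * 50.0 / np.sqrt(80)  # both are noise around baseline

    def test_single_locus_matches_truncation_recursion(self):
        # one strongly selected autosomal locus, many replicate populations
        a, sigma, frac, n_gens = 20.0, 50.0, 0.25, 5
        panel = generate_founder_panel(10, 1, ["2L"],
                                       MafSpectrum("point", 0.5), seed=1)
        oracle = truncation_recursion(0.5, a, sigma, frac, n_gens)
        finals = []
        for seed in range(40):
            cfg = ExperimentConfig(
                n_generations=n_gens, n_measured_per_sex=100, census=200,
                selection_fraction=frac, env_sd=sigma,
                qtl_effects={0: a}, schemes={"long": 1}, seed=seed,
                sequenced_generations=(0,))
            res = simulate_experiment(panel, cfg)
            finals.append(res.true_freq["L1"][n_gens, 0])
        # selection pushes the positive allele up, tracking the recursion
        assert abs(np.mean(finals) - oracle[-1]) < 0.04
        assert np.mean(finals) > 0.6

    def test_opposite_schemes_diverge(self, small_experiment):
        div = small_experiment.scheme_divergence(13)
        assert div[0] > 0.3  # planted locus
        assert div[small_experiment.sites.index[20]] < div[0]

    def test_selection_fraction_one_is_random_mating(self, small_panel):
        cfg = ExperimentConfig(n_generations=4, n_measured_per_sex=30,
                               census=60, selection_fraction=1.0,
                               qtl_effects={0: 50.0},
                               schemes={"long": 1, "short": 1}, seed=2,
                               sequenced_generations=(0,))
        res = simulate_experiment(small_panel, cfg)
        # everyone is a parent: S = 0 exactly every generation
        s_vals = res.summaries["S"] if "S" in res.summaries else (
            res.summaries["parent_mean"] - res.summaries["mean"])
        assert np.nanmax(np.abs(s_vals)) < 1e-9

    def test_deterministic_given_seed(self, small_panel):
        cfg = dict(n_generations=3, n_measured_per_sex=20, census=40,
                   sequenced_generations=(0, 2), seed=77)
        a = simulate_experiment(small_panel, ExperimentConfig(**cfg))
        b = simulate_experiment(small_panel, ExperimentConfig(**cfg))
        assert np.array_equal(a.counts.alt_count, b.counts.alt_count)
        for pop in a.true_freq:
            assert np.array_equal(a.true_freq[pop], b.true_freq[pop])

    def test_census_too_small_rejected(self, small_panel):
        with pytest.raises(ValueError):
            ExperimentConfig(census=20, n_measured_per_sex=50).validate(
                small_panel.n_sites)
        with pytest.raises(ValueError):
            ExperimentConfig(selection_fraction=0.001).validate(
                small_panel.n_sites)

    def test_pool_counts_track_true_frequency(self, small_experiment):
        res = small_experiment
        counts = res.counts
        xs, ys = [], []
        for j in range(counts.n_samples):
            pop = counts.samples.at[j, "population"]
            gen = counts.samples.at[j, "generation"]
            truth = res.true_freq[pop][gen]
            tot = counts.total[:, j]
            ok = tot > 0
            xs.append(truth[ok])
            ys.append(counts.alt_count[ok, j] / tot[ok])
        slope = stats.linregress(np.concatenate(xs), np.concatenate(ys)).slope
        assert 0.95 <= slope <= 1.05

    def test_x_hemizygosity_bounds(self, small_experiment):
        # X-site frequencies remain valid probabilities throughout
        for pop, freqs in small_experiment.true_freq.items():
            assert freqs.min() >= 0 and freqs.max() <= 1


class TestSimulateActivity:
    def test_single_full_night_block(self):
        tr = simulate_activity(720, 0, ActivitySpec(deterministic_totals=True,
                                                    mean_bout_length=720),
                               seed=3)
        t = sleep.score_traits(tr)
        assert t.night_sleep == 720
        assert t.night_bout_number == 1

    def test_zero_sleep_with_pauses(self):
        tr = simulate_activity(0, 0, ActivitySpec(n_pauses_per_phase=3), seed=4)
        t = sleep.score_traits(tr)
        assert t.night_sleep == 0 and t.day_sleep == 0
        states = sleep.classify_states(tr)
        assert (states == sleep.PAUSE).sum() > 0

    def test_population_mean_recovery(self):
        rng = np.random.default_rng(12)
        target = 400.0
        scored = [sleep.score_traits(simulate_activity(target, 100, seed=rng))
                  for _ in range(300)]
        vals = np.array([t.night_sleep for t in scored])
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - target) < 3 * max(se, 1.0)

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError):
            simulate_activity(800, 0, seed=0)


class TestSimulateDiallel:
    @staticmethod
    def random_effects(n, seed):
        rng = np.random.default_rng(seed)
        g = rng.normal(0, 5, n)
        s = rng.normal(0, 3, (n, n))
        r = rng.normal(0, 2, (n, n))
        return canonical_effects(g, (s + s.T) / 2, r)

    def test_zero_effects_zero_noise(self):
        n = 4
        tab = simulate_diallel(np.zeros(n), np.zeros((n, n)), np.zeros((n, n)),
                               grand_mean=250.0, noise_sd=0, n_per_cross=2,
                               seed=0)
        assert np.allclose(tab.cell_means(), 250.0)

    def test_noiseless_round_trip(self):
        g, s, r, _ = self.random_effects(5, seed=8)
        tab = simulate_diallel(g, s, r, 100.0, 0.0, 2, seed=1)
        Y = tab.cell_means()
        assert np.allclose(diallel.gca(Y), g)
        assert np.allclose(diallel.sca(Y), s)
        assert np.allclose(diallel.rec(Y), r)

    def test_symmetric_table_has_zero_rec(self):
        g, s, _, _ = self.random_effects(4, seed=3)
        tab = simulate_diallel(g, s, np.zeros((4, 4)), 50.0, 0.0, 1, seed=2)
        assert np.allclose(diallel.rec(tab.cell_means()), 0.0)

    def test_invalid_effects_rejected(self):
        with pytest.raises(ValueError):
            simulate_diallel([1.0, 1.0], np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            simulate_diallel([1.0, -1.0], np.ones((2, 2)) - np.eye(2) * 0,
                             np.zeros((2, 2)))
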