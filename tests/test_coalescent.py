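"""Coalescent simulators: neutral limits, split model, mutation dropping."""

import numpy as np
import pytest

from singletonmap import (
    count_singletons,
    drop_mutations,
    simulate_neutral_genealogy,
    simulate_structured_genealogy,
    theoretical_distribution,
)
from singletonmap.coalescent import (
    SplitModelParams,
    replicate_split_study,
    simulate_split_matrix,
    split_group_assignment,
)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


class TestNeutralGenealogy:
    def test_two_tip_height_and_external_length(self, rng):
        heights = []
        for _ in range(3000):
            t = simulate_neutral_genealogy(2, rng)
            heights.append(t.total_external_length())
        # n=2: tau1 = 2 * T2, E[T2] = 1 in coalescent units
        se = np.std(heights) / np.sqrt(len(heights))
        assert np.mean(heights) == pytest.approx(2.0, abs=3 * se)

    def test_mean_total_external_length_is_two(self, rng):
        taus = [
            simulate_neutral_genealogy(50, rng).total_external_length()
            for _ in range(2000)
        ]
        se = np.std(taus) / np.sqrt(len(taus))
        assert np.mean(taus) == pytest.approx(2.0, abs=3 * se)

    def test_single_external_branch_mean_two_over_n(self, rng):
        n = 30
        tips = []
        for _ in range(1500):
            tips.extend(
                simulate_neutral_genealogy(n, rng).external_branch_lengths()
            )
        tips = np.asarray(tips)
        se = tips.std() / np.sqrt(n * 1500)
        assert tips.mean() == pytest.approx(2.0 / n, abs=3 * se)

    def test_rejects_n_below_two(self, rng):
        with pytest.raises(ValueError):
            simulate_neutral_genealogy(1, rng)


class TestDropMutations:
    def test_zero_theta_zero_columns(self, rng):
        t = simulate_neutral_genealogy(5, rng)
        assert drop_mutations(t, 0.0, rng).n_loci == 0

    def test_expected_columns_match_poisson_oracle(self, rng):
        """On one fixed tree, mutation counts match a direct Poisson draw
        at rate theta/2 * total length."""
        t = simulate_neutral_genealogy(10, rng)
        theta = 4.0
        counts = [drop_mutations(t, theta, rng).n_loci for _ in range(4000)]
        lam = 0.5 * theta * t.total_length()
        se = np.sqrt(lam / len(counts))
        assert np.mean(counts) == pytest.approx(lam, abs=3.5 * se)

    def test_derived_carriers_match_subtree(self, rng):
        t = simulate_neutral_genealogy(6, rng)
        m = drop_mutations(t, 20.0, rng)
        # every column's carrier count must be between 1 and n-1 or n
        d = m.derived_counts()
        assert (d >= 1).all() and (d <= 6).all()

    def test_neutral_singleton_mean_equals_theta(self, rng):
        theta = 5.0
        total = 0
        reps = 2500
        per_locus = []
        for _ in range(reps):
            t = simulate_neutral_genealogy(20, rng)
            c = count_singletons(drop_mutations(t, theta, rng)).total
            per_locus.append(c)
        per_locus = np.asarray(per_locus)
        se = per_locus.std() / np.sqrt(reps)
        assert per_locus.mean() == pytest.approx(theta, abs=3 * se)
        del total


class TestStructuredGenealogy:
    def test_degenerate_limit_matches_neutral(self, rng):
        """s -> 1, t -> 0, no growth reduces to the panmictic coalescent."""
        from scipy.stats import ks_2samp

        params = SplitModelParams(
            N1=1000.0, NA=1000.0, shrink_rate=0.999,
            split_time_gens=1e-9, expansion_start_gens=1.0,
            sample_sizes=(10, 10), theta=5.0,
        )
        h_struct = [
            simulate_structured_genealogy(params, rng).total_external_length()
            for _ in range(800)
        ]
        h_neutral = [
            simulate_neutral_genealogy(20, rng).total_external_length()
            for _ in range(800)
        ]
        assert ks_2samp(h_struct, h_neutral).pvalue > 0.01

    def test_exchangeability_within_population(self, rng):
        params = SplitModelParams(sample_sizes=(10, 10), n_loci=0)
        taus = np.zeros(20)
        reps = 400
        for _ in range(reps):
            t = simulate_structured_genealogy(params.draw_scalars(rng), rng)
            taus += t.external_branch_lengths()
        taus /= reps
        # within each population, per-tip means agree within MC noise
        for block in (taus[:10], taus[10:]):
            assert block.std() / block.mean() < 0.2

    def test_population_one_has_longer_externals(self, rng):
        params = SplitModelParams(sample_sizes=(25, 25), n_loci=0)
        t1 = t2 = 0.0
        for _ in range(300):
            t = simulate_structured_genealogy(params.draw_scalars(rng), rng)
            tau = t.external_branch_lengths()
            t1 += tau[:25].sum()
            t2 += tau[25:].sum()
        assert t1 > t2

    def test_msprime_cross_oracle(self, rng):
        """Mean segregating sites and singletons agree with msprime on the
        identical split scenario within Monte-Carlo error."""
        msprime = pytest.importorskip("msprime")
        s, theta_w, tsplit_g = 0.33, 7.5, 5000.0
        params = SplitModelParams(
            shrink_rate=s, theta=theta_w, split_time_gens=tsplit_g,
            sample_sizes=(25, 25), n_loci=0,
        )
        L = 400
        own_S, own_xi = [], []
        for _ in range(L):
            t = simulate_structured_genealogy(params, rng)
            m = drop_mutations(t, 2.0 * theta_w, rng)
            own_S.append(m.n_loci)
            own_xi.append(count_singletons(m).total)

        beta = params.growth_rate
        t_exp = params.expansion_start_gens / (2 * params.N1)
        dem = msprime.Demography()
        dem.add_population(name="p1", initial_size=1.0, growth_rate=beta)
        dem.add_population(name="p2", initial_size=s)
        dem.add_mass_migration(
            time=tsplit_g / (2 * params.N1), source="p2", dest="p1",
            proportion=1.0,
        )
        dem.add_population_parameters_change(
            time=t_exp, population="p1",
            initial_size=params.NA / params.N1, growth_rate=0,
        )
        ms_S, ms_xi = [], []
        for ts in msprime.sim_ancestry(
            samples={"p1": 25, "p2": 25}, demography=dem, ploidy=1,
            num_replicates=L, random_seed=7,
        ):
            mts = msprime.sim_mutations(
                ts, rate=theta_w, random_seed=int(rng.integers(1, 2**31)),
                model=msprime.BinaryMutationModel(), discrete_genome=False,
            )
            G = mts.genotype_matrix()
            d = G.sum(axis=1)
            G = G[(d >= 1) & (d <= 49)]
            ms_S.append(G.shape[0])
            ms_xi.append(int((G.sum(axis=1) == 1).sum()))

        for ours, theirs in ((own_S, ms_S), (own_xi, ms_xi)):
            ours, theirs = np.asarray(ours), np.asarray(theirs)
            se = np.sqrt(ours.var() / L + theirs.var() / L)
            assert ours.mean() == pytest.approx(theirs.mean(), abs=3 * se)


class TestSplitStudy:
    def test_ratio_decreases_with_shrink_rate(self, rng):
        params_small = SplitModelParams(shrink_rate=0.05, n_loci=300)
        params_large = SplitModelParams(shrink_rate=0.5, n_loci=300)
        df_s = replicate_split_study(params_small, 8, rng)
        df_l = replicate_split_study(params_large, 8, rng)
        assert df_s.ratio.mean() > df_l.ratio.mean()
        assert df_s.ratio.mean() > 10

    def test_unbiasedness_empirical_vs_tree_prediction(self, rng):
        """Regression through the origin of p-hat on the tree-based p has
        slope 1: the empirical distribution is unbiased for its
        genealogical prediction."""
        params = SplitModelParams(n_loci=400)
        matrix, trees = simulate_split_matrix(params, rng)
        prof = count_singletons(matrix)
        p_hat = prof.proportions
        p_theo = theoretical_distribution(trees, order=matrix.chromosome_ids)
        slope = (p_hat @ p_theo) / (p_theo @ p_theo)
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_replicate_table_columns_and_polymorphic_counts(self, rng):
        df = replicate_split_study(
            SplitModelParams(n_loci=50), 3, rng, redraw=True
        )
        assert len(df) == 3
        assert {"pi_1", "pi_2", "ratio", "sd_1", "sd_2"} <= set(df.columns)
        assert (df.n_polymorphic > 0).all()
        # complementarity: group-size weighted means sum to 2/n * 50
        assert np.allclose(50 * df.pi_1 + 50 * df.pi_2, 1.0)

    def test_group_assignment_matches_tip_labels(self):
        params = SplitModelParams(sample_sizes=(3, 2))
        ga = split_group_assignment(params)
        assert len(ga.members(1)) == 3
        assert len(ga.members(2)) == 2
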