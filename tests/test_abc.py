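"""ABC machinery: priors, summary statistics, estimation, toy-model checks."""

import numpy as np
import pandas as pd
import pytest

from singletonmap import GroupAssignment, HaplotypeMatrix, SingletonProfile
from singletonmap.abc_origin import (
    PriorSpec,
    ReferenceTable,
    abc_estimate,
    mask_missing,
    sample_prior,
    singleton_histogram,
    spatial_kmeans,
)
from singletonmap.haplotypes import MISSING


class TestSpatialKmeans:
    def test_recovers_separated_clouds(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        pts = np.concatenate(
            [c + rng.normal(0, 0.3, size=(20, 2)) for c in centers]
        )
        ids = [f"c{i}" for i in range(60)]
        ga = spatial_kmeans(pts[:, 0], pts[:, 1], ids, 3, rng)
        labels = [ga.labels[i] for i in ids]
        # all chromosomes of a generating cloud share a cluster
        for block in (labels[:20], labels[20:40], labels[40:]):
            assert len(set(block)) == 1
        assert len({block[0] for block in
                    (labels[:20], labels[20:40], labels[40:])}) == 3

    def test_k_equals_one_and_n(self, rng):
        lons, lats = rng.uniform(0, 1, 6), rng.uniform(0, 1, 6)
        ids = list("abcdef")
        assert len(spatial_kmeans(lons, lats, ids, 1, rng).groups) == 1
        assert len(spatial_kmeans(lons, lats, ids, 6, rng).groups) == 6

    def test_infeasible_k_rejected(self, rng):
        with pytest.raises(ValueError):
            spatial_kmeans([0, 0], [0, 0], ["a", "b"], 2, rng)


class TestSingletonHistogram:
    def test_hand_example(self):
        prof = SingletonProfile(np.array([2, 4, 6, 8]), ["1", "2", "3", "4"])
        ga = GroupAssignment({"1": "A", "2": "A", "3": "B", "4": "B"})
        stat = singleton_histogram(prof, ga)
        assert stat == pytest.approx([3 / 20, 7 / 20])

    def test_uniform_counts_equal_entries(self):
        prof = SingletonProfile(np.array([5, 5, 5, 5]), list("abcd"))
        ga = GroupAssignment({"a": 1, "b": 1, "c": 2, "d": 2})
        stat = singleton_histogram(prof, ga)
        assert stat[0] == pytest.approx(stat[1])

    def test_equal_group_sizes_sum_identity(self, rng):
        """With equal group sizes, entries sum to n_groups / n."""
        n, k = 12, 4
        counts = rng.integers(1, 30, size=n)
        ids = [f"c{i}" for i in range(n)]
        ga = GroupAssignment(dict(zip(ids, np.repeat(np.arange(k), n // k))))
        stat = singleton_histogram(SingletonProfile(counts, ids), ga)
        assert stat.sum() == pytest.approx(k / n)

    def test_relabeling_within_group_invariant(self, rng):
        counts = rng.integers(0, 9, size=6)
        counts[0] += 1
        ids = list("abcdef")
        ga = GroupAssignment(dict(zip(ids, [1, 1, 1, 2, 2, 2])))
        base = singleton_histogram(SingletonProfile(counts, ids), ga)
        perm = [1, 2, 0, 5, 3, 4]  # permute within groups only
        stat = singleton_histogram(
            SingletonProfile(counts[perm], [ids[i] for i in perm]), ga
        )
        assert stat == pytest.approx(base)

    def test_zero_singletons_rejected(self):
        prof = SingletonProfile(np.zeros(4, dtype=int), list("abcd"))
        ga = GroupAssignment(dict(zip("abcd", [1, 1, 2, 2])))
        with pytest.raises(ValueError):
            singleton_histogram(prof, ga)


class TestMaskMissing:
    def test_zero_rate_identity(self, rng):
        m = HaplotypeMatrix(rng.integers(0, 2, (5, 50)).astype(np.int8))
        out = mask_missing(m, 0.0, rng)
        assert np.array_equal(out.alleles, m.alleles)

    def test_global_rate_within_binomial_error(self, rng):
        m = HaplotypeMatrix(np.zeros((100, 1000), dtype=np.int8))
        out = mask_missing(m, 0.2, rng)
        realized = (out.alleles == MISSING).mean()
        assert realized == pytest.approx(0.2, abs=0.004)

    def test_per_chromosome_rates(self, rng):
        m = HaplotypeMatrix(np.zeros((3, 20000), dtype=np.int8))
        rates = np.array([0.0, 0.1, 0.3])
        out = mask_missing(m, rates, rng)
        realized = (out.alleles == MISSING).mean(axis=1)
        assert realized == pytest.approx(rates, abs=0.01)

    def test_rate_one_rejected(self, rng):
        m = HaplotypeMatrix(np.zeros((2, 5), dtype=np.int8))
        with pytest.raises(ValueError):
            mask_missing(m, 1.0, rng)


class TestPrior:
    def test_untapered_rectangular_is_uniform(self, rng):
        from scipy.stats import chisquare

        spec = PriorSpec(lon_range=(0, 10), lat_range=(0, 10),
                         taper_fraction=0.0, grid=None)
        draws = np.array(
            [[sample_prior(spec, rng)[c] for c in ("lon", "lat")]
             for _ in range(10_000)]
        )
        for k in range(2):
            counts, _ = np.histogram(draws[:, k], bins=10, range=(0, 10))
            assert chisquare(counts).pvalue > 1e-3

    def test_bounds_always_respected(self, rng):
        spec = PriorSpec()
        for _ in range(500):
            d = sample_prior(spec, rng)
            assert -16 <= d["lon"] <= 40
            assert 5 <= d["lat"] <= 30

    def test_water_cells_never_drawn(self, rng, demo20):
        spec = PriorSpec(lon_range=(0.0, 20.0), lat_range=(0.0, 20.0),
                         taper_fraction=0.0, grid=demo20)
        for _ in range(2000):
            d = sample_prior(spec, rng)
            r, c = demo20.cell_of(d["lon"], d["lat"])
            assert demo20.is_habitable(r, c)

    def test_taper_downweights_edges(self, rng):
        spec = PriorSpec(lon_range=(0, 10), lat_range=(0, 10),
                         taper_fraction=0.2, grid=None)
        draws = np.array([sample_prior(spec, rng)["lon"] for _ in range(8000)])
        edge = ((draws < 1) | (draws > 9)).mean()
        core = ((draws > 4.5) & (draws < 5.5)).mean()
        assert edge < core


def toy_table(rng, n=2000, noise=1.0):
    """Tractable toy model: stat = (lon, lat) + Gaussian noise."""
    lon = rng.uniform(0, 10, n)
    lat = rng.uniform(0, 10, n)
    stats = np.column_stack([lon, lat]) + rng.normal(0, noise, (n, 2))
    params = pd.DataFrame({"lon": lon, "lat": lat})
    return ReferenceTable(params, stats, ["a", "b"])


class TestAbcEstimate:
    def test_self_match_concentrates(self, rng):
        table = toy_table(rng, n=500, noise=0.01)
        obs = table.stats[7]
        post = abc_estimate(obs, table, tolerance=0.05, method="rejection")
        truth = table.params.iloc[7]
        assert post.mean("lon") == pytest.approx(truth.lon, abs=0.3)
        assert post.mean("lat") == pytest.approx(truth.lat, abs=0.3)

    def test_regression_adjustment_shrinks_posterior(self, rng):
        """Local-linear adjustment never inflates posterior spread on the
        linear-Gaussian toy model."""
        table = toy_table(rng, n=2000, noise=1.0)
        obs = np.array([5.0, 5.0])
        rej = abc_estimate(obs, table, tolerance=0.3, method="rejection")
        adj = abc_estimate(obs, table, tolerance=0.3, method="local-linear")
        for coord in ("lon", "lat"):
            v_rej = np.average(
                (rej.samples[coord] - rej.mean(coord)) ** 2, weights=rej.weights
            )
            v_adj = np.average(
                (adj.samples[coord] - adj.mean(coord)) ** 2, weights=adj.weights
            )
            assert v_adj <= v_rej

    def test_coverage_of_equal_tailed_intervals(self, rng):
        """90% intervals cover the truth in about 90% of repetitions."""
        table = toy_table(rng, n=3000, noise=1.0)
        hits = 0
        reps = 100
        for _ in range(reps):
            lon, lat = rng.uniform(1, 9, 2)
            obs = np.array([lon, lat]) + rng.normal(0, 1.0, 2)
            post = abc_estimate(obs, table, tolerance=0.02,
                                method="rejection", grid_points=10,
                                ci_level=0.90)
            lo, hi = post.credible_intervals["lon"]
            hits += lo <= lon <= hi
        # binomial SE ~ 3%; generous 4-sigma band
        assert 0.78 <= hits / reps <= 0.99

    def test_nonlinear_regression_runs(self, rng):
        table = toy_table(rng, n=400, noise=0.5)
        post = abc_estimate(
            np.array([5.0, 5.0]), table, tolerance=0.3,
            method="nonlinear-regression", n_networks=4, rng=rng,
        )
        assert post.mean("lon") == pytest.approx(5.0, abs=1.5)

    def test_deterministic_for_deterministic_methods(self, rng):
        table = toy_table(rng, n=500, noise=0.5)
        obs = np.array([3.0, 7.0])
        a = abc_estimate(obs, table, tolerance=0.2, method="local-linear")
        b = abc_estimate(obs, table, tolerance=0.2, method="local-linear")
        assert np.array_equal(a.density, b.density)
        assert a.credible_intervals == b.credible_intervals

    def test_posterior_mass_respects_prior_support(self, rng, demo20):
        spec = PriorSpec(lon_range=(1.0, 19.0), lat_range=(1.0, 19.0),
                         taper_fraction=0.0, grid=demo20)
        table = toy_table(rng, n=800, noise=2.0)
        post = abc_estimate(np.array([0.0, 0.0]), table, tolerance=0.2,
                            method="local-linear", prior_spec=spec)
        assert post.samples["lon"].between(1, 19).all()
        assert post.samples["lat"].between(1, 19).all()
        # no density on sea cells
        for i, lat in enumerate(post.grid_lats):
            for j, lon in enumerate(post.grid_lons):
                if post.density[i, j] > 0:
                    r, c = demo20.cell_of(lon, lat)
                    assert demo20.is_habitable(r, c)

    def test_tiny_tolerance_rejected(self, rng):
        table = toy_table(rng, n=100)
        with pytest.raises(ValueError, match="tolerance"):
            abc_estimate(np.array([5.0, 5.0]), table, tolerance=0.01)


class TestReferenceTable:
    def test_csv_round_trip(self, tmp_path, rng):
        table = toy_table(rng, n=30)
        table.metadata["seeds"] = [1, 2, 3]
        table.to_csv(tmp_path / "t.csv")
        back = ReferenceTable.from_csv(tmp_path / "t.csv")
        assert np.allclose(back.stats, table.stats)
        assert list(back.params.columns) == ["lon", "lat"]
        assert back.metadata["seeds"] == [1, 2, 3]

    def test_build_is_seed_deterministic(self, rng, demo20, demo_history):
        from singletonmap.abc_origin import build_reference_table
        from singletonmap.expansion import draw_sampling_design

        sample = draw_sampling_design(demo_history, "population",
                                      np.random.default_rng(3), n_sites=6,
                                      haploids_per_site=4)
        groups = spatial_kmeans(sample.lons, sample.lats,
                                sample.chromosome_ids, 3,
                                np.random.default_rng(3))
        spec = PriorSpec(lon_range=(2.0, 18.0), lat_range=(2.0, 18.0),
                         grid=demo20,
                         nuisance_ranges={"migration_rate": (0.05, 0.1),
                                          "duration": (100, 200)})
        template = demo_history.scenario.with_params(n_loci=40)
        args = (2, spec, template, demo20, sample, groups)
        t1 = build_reference_table(*args, np.random.default_rng(9), n_loci=40)
        t2 = build_reference_table(*args, np.random.default_rng(9), n_loci=40)
        assert np.allclose(t1.stats, t2.stats)
        assert t1.params.equals(t2.params)
        assert t1.stats.shape[1] == len(groups.groups)


def test_choose_k_respects_group_size_floor(rng):
    from singletonmap.abc_origin import choose_k, spatial_kmeans

    lons = rng.uniform(0, 10, 40)
    lats = rng.uniform(0, 10, 40)
    k = choose_k(lons, lats, min_group_size=5, rng=rng, k_max=10)
    ga = spatial_kmeans(lons, lats, [str(i) for i in range(40)], k,
                        np.random.default_rng(0))
    assert min(len(ga.members(g)) for g in ga.groups) >= 1
    assert 1 <= k <= 8
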