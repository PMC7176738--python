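"""F3 population simulator: gametes, genotype frequencies, noise, determinism."""

import numpy as np
import pytest

from favamap import f3model, popsim


def two_marker_map(r=0.1):
    return popsim.TrueMap(
        groups=[popsim.TrueLinkageGroup("LG1", ["a", "b"], np.array([r]))]
    )


class TestSimulateGametes:
    def test_homozygous_parent_transmits_its_allele(self):
        parent = np.array([[1, 1, 1], [1, 1, 1]])
        g = popsim.simulate_gametes(parent, [0.3, 0.3], np.random.default_rng(0), n=50)
        assert np.all(g == 1)

    def test_zero_recombination_gives_intact_haplotypes(self):
        parent = np.array([[0, 0, 0, 0], [1, 1, 1, 1]])
        g = popsim.simulate_gametes(parent, [0.0, 0.0, 0.0], np.random.default_rng(1), n=200)
        assert set(map(tuple, g)) <= {(0, 0, 0, 0), (1, 1, 1, 1)}

    def test_recombinant_fraction_matches_r(self):
        parent = np.array([[0, 0], [1, 1]])
        n = 100_000
        g = popsim.simulate_gametes(parent, [0.2], np.random.default_rng(2), n=n)
        frac = (g[:, 0] != g[:, 1]).mean()
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(frac - 0.2) < 3 * se

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError):
            popsim.simulate_gametes(
                np.array([[0, 0], [1, 1]]), [0.5], np.random.default_rng(0)
            )


class TestConfigValidation:
    def test_bad_rates_and_size(self):
        with pytest.raises(ValueError):
            popsim.SimConfig(population_size=1)
        with pytest.raises(ValueError):
            popsim.SimConfig(population_size=10, missing_rate=1.5)

    def test_viability_weights_validated(self):
        with pytest.raises(ValueError):
            popsim.TrueMap(
                groups=[popsim.TrueLinkageGroup("LG1", ["a"], np.array([]))],
                viability={"a": (0.0, 0.0, 0.0)},
            )
        with pytest.raises(ValueError):
            popsim.TrueMap(
                groups=[popsim.TrueLinkageGroup("LG1", ["a"], np.array([]))],
                viability={"zzz": (1.0, 1.0, 1.0)},
            )


class TestF3Population:
    def test_single_locus_mendelian_frequencies(self):
        tm = popsim.TrueMap(groups=[popsim.TrueLinkageGroup("LG1", ["m"], np.array([]))])
        cfg = popsim.SimConfig(
            population_size=100_000, missing_rate=0.0, genotyping_error_rate=0.0, rng_seed=3
        )
        gm, _ = popsim.simulate_f3_population(tm, cfg)
        freqs = np.array([(gm.calls[0] == g).mean() for g in (0, 1, 2)])
        se = np.sqrt(f3model.F3_MARGINAL * (1 - f3model.F3_MARGINAL) / 100_000)
        assert np.all(np.abs(freqs - f3model.F3_MARGINAL) < 3 * se)

    def test_two_locus_frequencies_match_f3_joint(self):
        n = 10_000
        gm, _ = popsim.simulate_f3_population(
            two_marker_map(0.1),
            popsim.SimConfig(population_size=n, missing_rate=0.0,
                             genotyping_error_rate=0.0, rng_seed=4),
        )
        emp = np.zeros((3, 3))
        for i, j in zip(gm.calls[0], gm.calls[1]):
            emp[i, j] += 1
        emp /= n
        expected = f3model.f3_joint(0.1)
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(emp - expected) <= 3 * se + 1e-12)

    def test_error_model_perturbs_half_the_calls(self):
        tm = popsim.TrueMap(groups=[popsim.TrueLinkageGroup("LG1", ["m"], np.array([]))])
        cfg = popsim.SimConfig(
            population_size=20_000, missing_rate=0.0, genotyping_error_rate=0.5, rng_seed=5
        )
        gm, truth = popsim.simulate_f3_population(tm, cfg)
        perturbed = (gm.calls != truth.true_calls).mean()
        assert perturbed == pytest.approx(0.5, abs=0.02)
        assert not np.any(gm.calls == -1)

    def test_missingness_rate(self):
        gm, truth = popsim.simulate_f3_population(
            two_marker_map(),
            popsim.SimConfig(population_size=5000, missing_rate=0.2,
                             genotyping_error_rate=0.0, rng_seed=6),
        )
        assert (gm.calls == -1).mean() == pytest.approx(0.2, abs=0.02)
        assert not np.any(truth.true_calls == -1)  # truth is pre-noise

    def test_same_seed_is_bit_identical_different_seed_differs(self):
        cfg = popsim.SimConfig(population_size=200, rng_seed=7)
        a, _ = popsim.simulate_f3_population(two_marker_map(), cfg)
        b, _ = popsim.simulate_f3_population(two_marker_map(), cfg)
        c, _ = popsim.simulate_f3_population(
            two_marker_map(), popsim.SimConfig(population_size=200, rng_seed=8)
        )
        assert np.array_equal(a.calls, b.calls)
        assert not np.array_equal(a.calls, c.calls)

    def test_f2_stage_haplotypes_recover_true_r(self):
        tm = popsim.TrueMap(
            groups=[popsim.TrueLinkageGroup("LG1", list("abcd"), np.array([0.05, 0.2, 0.35]))]
        )
        n = 20_000
        _, truth = popsim.simulate_f3_population(
            tm, popsim.SimConfig(population_size=n, rng_seed=9)
        )
        g1, g2 = truth.f2_gametes["LG1"]
        for gam in (g1, g2):
            frac = (np.diff(gam.astype(int), axis=1) != 0).mean(axis=0)
            se = np.sqrt(tm.groups[0].r_adjacent * (1 - tm.groups[0].r_adjacent) / n)
            assert np.all(np.abs(frac - tm.groups[0].r_adjacent) < 4 * se)

    def test_viability_weights_distort_marginals(self):
        tm = popsim.TrueMap(
            groups=[popsim.TrueLinkageGroup("LG1", ["m"], np.array([]))],
            viability={"m": (0.25, 0.5, 1.0)},
        )
        gm, _ = popsim.simulate_f3_population(
            tm, popsim.SimConfig(population_size=20_000, missing_rate=0.0,
                                 genotyping_error_rate=0.0, rng_seed=10)
        )
        # expected post-selection frequencies: w * mendelian, renormalized
        w = np.array([0.25, 0.5, 1.0]) * f3model.F3_MARGINAL
        w /= w.sum()
        freqs = np.array([(gm.calls[0] == g).mean() for g in (0, 1, 2)])
        assert np.all(np.abs(freqs - w) < 0.02)

    def test_linked_neighbours_inherit_distortion(self):
        """Selection at one locus distorts tightly linked neighbours too."""
        tm = popsim.TrueMap(
            groups=[popsim.TrueLinkageGroup("LG1", ["sel", "near", "far"],
                                            np.array([0.02, 0.45]))],
            viability={"sel": (0.1, 0.4, 1.0)},
        )
        gm, _ = popsim.simulate_f3_population(
            tm, popsim.SimConfig(population_size=20_000, missing_rate=0.0,
                                 genotyping_error_rate=0.0, rng_seed=11)
        )
        bb_near = (gm.calls[1] == 2).mean()
        bb_far = (gm.calls[2] == 2).mean()
        assert bb_near > 0.5  # dragged by the selected locus
        assert abs(bb_far - 0.375) < 0.05  # nearly free of it


class TestTrueMapConstruction:
    def test_make_true_map_shape_and_validity(self):
        tm = popsim.make_true_map(n_markers=120, rng_seed=0)
        assert len(tm.groups) == 6
        assert tm.n_markers >= 120 - 6  # rounding to >= 2 per group
        for g in tm.groups:
            assert np.all(g.r_adjacent < 0.5)
            pos = g.positions_cM()
            assert pos[0] == 0.0 and np.all(np.diff(pos) >= 0)
        assert any(tm.viability)  # default carries a distortion region

    def test_distortion_region_optional(self):
        tm = popsim.make_true_map(n_markers=60, rng_seed=0, distortion_region=False)
        assert not tm.viability

    def test_duplicate_marker_ids_rejected(self):
        with pytest.raises(ValueError):
            popsim.TrueMap(
                groups=[
                    popsim.TrueLinkageGroup("LG1", ["x"], np.array([])),
                    popsim.TrueLinkageGroup("LG2", ["x"], np.array([])),
                ]
            )


def test_write_fixture_round_trips(tmp_path):
    gm, truth = popsim.simulate_f3_population(
        two_marker_map(), popsim.SimConfig(population_size=30, rng_seed=12,
                                           population_id="PopX")
    )
    paths = popsim.write_fixture(gm, truth, tmp_path)
    from favamap.io import read_genotypes

    back = read_genotypes(paths["genotypes"])
    assert back.markers == gm.markers
    assert back.individuals == gm.individuals
    assert np.array_equal(back.calls, gm.calls)
    assert paths["truth"].exists()
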