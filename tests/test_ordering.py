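"""Multipoint HMM likelihood and the scaffold/framework/bin ordering heuristic."""

import numpy as np
import pytest
from scipy import stats

from favamap import f3model, linkage, ordering, popsim
from favamap.io import GenotypeMatrix


def _true_positions(group):
    return dict(zip(group.markers, group.positions_cM()))


def _abs_tau(table, true_pos):
    return abs(
        stats.kendalltau(
            table["position_cM"], [true_pos[m] for m in table["marker_id"]]
        ).statistic
    )


class TestMultipointLikelihood:
    def test_two_marker_chain_equals_two_point_likelihood(self):
        tm = popsim.TrueMap(
            groups=[popsim.TrueLinkageGroup("LG1", ["a", "b"], np.array([0.15]))]
        )
        gm, _ = popsim.simulate_f3_population(
            tm, popsim.SimConfig(population_size=300, missing_rate=0.0,
                                 genotyping_error_rate=0.0, rng_seed=0)
        )
        ll_chain, r_chain = ordering.multipoint_loglik(
            ["a", "b"], gm, epsilon=0.0, tol=1e-8, max_iter=300
        )
        counts = np.zeros((3, 3))
        for i, j in zip(gm.calls[0], gm.calls[1]):
            counts[i, j] += 1
        r_hat, _ = linkage.twopoint_r(counts)
        ll_two_point = float(linkage._loglik(counts, np.array(r_hat)))
        assert r_chain[0] == pytest.approx(r_hat, abs=1e-4)
        assert ll_chain == pytest.approx(ll_two_point, abs=1e-3)

    def test_true_order_beats_every_wrong_order(self):
        tm = popsim.TrueMap(
            groups=[popsim.TrueLinkageGroup("LG1", ["a", "b", "c"], np.array([0.1, 0.1]))]
        )
        gm, _ = popsim.simulate_f3_population(
            tm, popsim.SimConfig(population_size=500, missing_rate=0.0,
                                 genotyping_error_rate=0.0, rng_seed=1)
        )
        # the 3 essentially distinct orders (reversal is a symmetry)
        lls = {
            order: ordering.multipoint_loglik(list(order), gm, epsilon=0.0)[0]
            for order in (("a", "b", "c"), ("b", "a", "c"), ("a", "c", "b"))
        }
        assert max(lls, key=lls.get) == ("a", "b", "c")

    def test_reversal_leaves_likelihood_unchanged(self, clean_group):
        gm = clean_group["genotypes"]
        order = list(gm.markers)
        ll_fwd, r_fwd = ordering.multipoint_loglik(order, gm, epsilon=0.005)
        ll_rev, _ = ordering.multipoint_loglik(
            order[::-1], gm, epsilon=0.005, r_init=r_fwd[::-1], max_iter=0
        )
        assert ll_rev == pytest.approx(ll_fwd, abs=1e-6)

    def test_all_missing_individual_is_uninformative(self):
        calls = np.array([[0, 1, -1], [2, 1, -1]], dtype=np.int8)
        gm = GenotypeMatrix(markers=["a", "b"], individuals=["i1", "i2", "blank"], calls=calls)
        with_blank, _ = ordering.fit_chain(gm.calls, 0.01, r_init=np.array([0.2]), max_iter=0)
        without, _ = ordering.fit_chain(gm.calls[:, :2], 0.01, r_init=np.array([0.2]), max_iter=0)
        assert with_blank == pytest.approx(without, abs=1e-12)

    def test_single_marker_group_flagged_trivial(self):
        calls = np.array([[0, 1, 2]], dtype=np.int8)
        ll, r = ordering.fit_chain(calls, 0.0)
        assert r.size == 0
        # unconditional single-locus F2 probabilities 1/4, 1/2, 1/4
        assert ll == pytest.approx(np.log(0.25) + np.log(0.5) + np.log(0.25), abs=1e-9)


class TestScaffold:
    def test_small_group_fully_in_scaffold(self):
        tm = popsim.TrueMap(
            groups=[popsim.TrueLinkageGroup("LG1", ["a", "b", "c"], np.array([0.25, 0.25]))]
        )
        gm, _ = popsim.simulate_f3_population(
            tm, popsim.SimConfig(population_size=300, missing_rate=0.0,
                                 genotyping_error_rate=0.0, rng_seed=2)
        )
        pairs = linkage.pairwise_linkage(gm)
        scaffold = ordering.build_scaffold(["a", "b", "c"], pairs, "b", min_spacing_cM=10)
        assert sorted(scaffold) == ["a", "b", "c"]

    def test_scaffold_spacing_respected(self, noisy_group):
        pairs = noisy_group["pairs"]
        members = list(noisy_group["genotypes"].markers)
        scaffold = ordering.build_scaffold(members, pairs, members[0], min_spacing_cM=10)
        idx = pairs.index_of()
        for a in scaffold:
            for b in scaffold:
                if a >= b:
                    continue
                r = pairs.r_hat[idx[a], idx[b]]
                assert f3model.haldane_cM(min(r, 0.49)) >= 10 - 1e-9

    def test_seed_replicates_agree_after_orientation(self, clean_group):
        pairs = clean_group["pairs"]
        members = list(clean_group["genotypes"].markers)
        rng = np.random.default_rng(3)
        seeds = rng.choice(members, size=10, replace=False)
        true_pos = _true_positions(clean_group["true_group"])
        taus = []
        for seed in seeds:
            scaffold = ordering.build_scaffold(members, pairs, seed, min_spacing_cM=10)
            tau = stats.kendalltau(
                range(len(scaffold)), [true_pos[m] for m in scaffold]
            ).statistic
            taus.append(abs(tau))
        assert min(taus) >= 0.95


class TestFrameworkAndBins:
    def test_cosegregating_duplicate_deferred_then_binned_at_same_position(self, clean_group):
        gm = clean_group["genotypes"]
        # append an exact duplicate of one mid-group marker
        dup_of = gm.markers[len(gm.markers) // 2]
        calls = np.vstack([gm.calls, gm.calls[gm.markers.index(dup_of)]])
        gm2 = GenotypeMatrix(
            markers=gm.markers + ["dup"], individuals=gm.individuals, calls=calls
        )
        pairs = linkage.pairwise_linkage(gm2)
        scaffold = ordering.build_scaffold(
            list(gm.markers), pairs, gm.markers[0], min_spacing_cM=10
        )
        framework, r, deferred = ordering.build_framework(
            scaffold, list(gm2.markers), gm2, pairs, epsilon=0.005
        )
        assert "dup" in deferred  # no interval is likelihood-preferred
        positions = np.concatenate([[0.0], np.cumsum(f3model.haldane_cM(r))])
        placed, unplaced = ordering.bin_map(framework, positions, deferred, pairs)
        assert not unplaced
        if dup_of in framework:
            assert placed["dup"] == pytest.approx(positions[framework.index(dup_of)])

    def test_order_group_recovers_truth_on_noisy_data(self, noisy_group):
        og = ordering.order_group(
            noisy_group["genotypes"],
            noisy_group["pairs"],
            list(noisy_group["genotypes"].markers),
            epsilon=0.005,
            coseg_bins=noisy_group["bins"],
            rng=np.random.default_rng(4),
        )
        true_pos = _true_positions(noisy_group["true_group"])
        assert _abs_tau(og.table, true_pos) >= 0.95
        assert set(og.scaffold) <= set(og.framework)
        assert np.all(np.diff(og.table["position_cM"]) >= 0)
        assert len(og.table) + len(og.unplaced) == len(noisy_group["truth"].markers)

    def test_binned_markers_near_truth(self):
        """Bin-mapped markers land within 5 cM of their true location.

        Uses a dense group so that many markers defer to bin-mapping.  The
        fitted map is aligned to the truth by least squares over all markers
        (orientation, offset and overall scale) before measuring binned-marker
        residuals: the small global length bias of the interval estimates is
        checked elsewhere and is not a binning property.
        """
        tm = popsim.make_true_map(
            n_markers=80, group_lengths_cM=(120.0,), rng_seed=106, distortion_region=False
        )
        gm, _ = popsim.simulate_f3_population(
            tm, popsim.SimConfig(population_size=150, missing_rate=0.05,
                                 genotyping_error_rate=0.005, rng_seed=107)
        )
        collapsed, bins = linkage.collapse_cosegregating(gm)
        pairs = linkage.pairwise_linkage(collapsed)
        og = ordering.order_group(
            collapsed, pairs, list(collapsed.markers), epsilon=0.005,
            coseg_bins=bins, rng=np.random.default_rng(5),
        )
        true_pos = _true_positions(tm.groups[0])
        table = og.table
        corrected = f3model.correct_map_positions(table["position_cM"].to_numpy())
        x = np.array([true_pos[m] for m in table["marker_id"]])
        A = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, corrected, rcond=None)
        predicted = A @ coef
        errors = np.abs(corrected - predicted) / abs(coef[0])
        binned_mask = (table["tier"] == "binned").to_numpy()
        assert binned_mask.sum() >= 10
        assert (errors[binned_mask] <= 5.0).mean() >= 0.95


class TestErrorRateHandling:
    def test_matched_epsilon_controls_map_inflation(self):
        """ε matched to the data keeps length near truth; ε=0 inflates it."""
        tm = popsim.make_true_map(
            n_markers=25, group_lengths_cM=(100.0,), rng_seed=104, distortion_region=False
        )
        gm, _ = popsim.simulate_f3_population(
            tm, popsim.SimConfig(population_size=200, missing_rate=0.0,
                                 genotyping_error_rate=0.01, rng_seed=105)
        )
        order = list(tm.groups[0].markers)  # fit at the true order
        _, r_matched = ordering.multipoint_loglik(order, gm, epsilon=0.01)
        _, r_zero = ordering.multipoint_loglik(order, gm, epsilon=0.0)
        to_len = lambda r: f3model.correct_map_positions(
            np.concatenate([[0.0], np.cumsum(f3model.haldane_cM(np.minimum(r, 0.4999)))])
        )[-1]
        true_len = tm.groups[0].positions_cM()[-1]
        assert to_len(r_matched) == pytest.approx(true_len, rel=0.10)
        assert to_len(r_zero) > to_len(r_matched) * 1.05
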