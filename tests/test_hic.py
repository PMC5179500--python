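"""Expected model, interaction calls vs a brute-force oracle, compartments,
TSS linking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import srftarget as st
from srftarget.hic import (
    CompartmentPCA,
    call_interactions,
    compartment_pca,
    fit_expected,
    link_tss,
)


def brute_force_calls(cmap, alpha=0.05, z_min=2.0, min_distance_bins=2,
                      smooth_above=20):
    """Independent pair-by-pair re-derivation of expected, Z, and p."""
    n = cmap.n_bins
    dense = cmap.to_dense()
    totals = dense.sum(axis=1)
    covered = totals > 0
    cov_mean = totals[covered].mean()
    c = {i: totals[i] / cov_mean for i in range(n) if covered[i]}

    # per-distance sums over covered pairs, then log2-band pooling
    sums, npairs = {}, {}
    for i in range(n):
        if not covered[i]:
            continue
        for j in range(i, n):
            if not covered[j]:
                continue
            d = j - i
            sums[d] = sums.get(d, 0.0) + dense[i, j]
            npairs[d] = npairs.get(d, 0) + 1

    def dmean(d):
        if d <= smooth_above:
            return sums.get(d, 0.0) / npairs[d]
        lo = smooth_above + 1
        while lo < n:
            hi = min(n, lo * 2)
            if lo <= d < hi:
                s = sum(sums.get(dd, 0.0) for dd in range(lo, hi))
                m = sum(npairs.get(dd, 0) for dd in range(lo, hi))
                return s / m
            lo = hi
        raise AssertionError

    rows = []
    for i, j, obs in zip(cmap.bins_i, cmap.bins_j, cmap.counts):
        i, j = int(i), int(j)
        if j - i < min_distance_bins or not (covered[i] and covered[j]):
            continue
        exp = dmean(j - i) * c[i] * c[j]
        if exp <= 0:
            continue
        z = (obs - exp) / np.sqrt(exp)
        p = float(stats.poisson.sf(obs - 1, exp))
        rows.append((i, j, int(obs), exp, z, p, p <= alpha and z >= z_min))
    return pd.DataFrame(rows, columns=["bin_i", "bin_j", "observed", "expected",
                                       "z", "p", "significant"])


class TestExpectedModel:
    def test_uniform_map(self, uniform_map):
        model = fit_expected(uniform_map)
        assert np.allclose(model.coverage, 1.0)
        assert np.allclose(model.raw_distance_means[:60], 8.0)
        calls = call_interactions(uniform_map, model)
        assert not calls["significant"].any()  # obs = exp everywhere

    def test_doubled_row_coverage_factor(self):
        n = 60
        iu, ju = np.triu_indices(n)
        counts = np.full(len(iu), 10)
        counts[(iu == 5) | (ju == 5)] = 20  # bin 5 at twice the depth
        cmap = st.ContactMap("chrT", 10_000, iu, ju, counts, n_bins=n)
        model = fit_expected(cmap)
        ratio = model.coverage[5] / np.mean(np.delete(model.coverage, 5))
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_masked_bin_excluded_everywhere(self):
        n = 60
        iu, ju = np.triu_indices(n)
        keep = (iu != 7) & (ju != 7)  # bin 7 has zero coverage
        cmap = st.ContactMap("chrT", 10_000, iu[keep], ju[keep],
                             np.full(keep.sum(), 5), n_bins=n)
        model = fit_expected(cmap)
        assert np.isnan(model.coverage[7])
        assert not model.covered[7]
        # distance means unaffected by the hole: still exactly 5
        assert np.allclose(model.raw_distance_means[:59][model.distance_pair_counts[:59] > 0], 5.0)

    def test_conservation_of_distance_sums(self):
        cfg = st.SimConfig(seed=2, n_bins=80, contact_depth=40.0)
        cmap, _ = st.simulate_contacts(cfg)
        model = fit_expected(cmap)
        dense = cmap.to_dense()
        for d in (0, 3, 11, 40):
            obs_sum = sum(dense[i, i + d] for i in range(80 - d))
            if d == 0:
                obs_sum = sum(dense[i, i] for i in range(80))
            assert model.raw_distance_means[d] * model.distance_pair_counts[d] == \
                pytest.approx(obs_sum)

    def test_too_few_covered_bins_rejected(self):
        cmap = st.ContactMap("chrT", 10_000, [0, 1], [1, 2], [3, 3], n_bins=10)
        with pytest.raises(ValueError):
            fit_expected(cmap)


class TestInteractionCalls:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        cfg = st.SimConfig(seed=seed, n_bins=70, contact_depth=50.0,
                           compartment_block_size=10,
                           loops=((5, 40), (12, 60)), loop_enrichment=8.0)
        cmap, _ = st.simulate_contacts(cfg)
        calls = st.InteractionCaller().fit(cmap).calls_
        oracle = brute_force_calls(cmap)
        merged = calls.merge(oracle, on=["bin_i", "bin_j"], suffixes=("", "_o"))
        assert len(merged) == len(calls) == len(oracle)
        assert (merged["significant"] == merged["significant_o"]).all()
        assert np.abs(merged["z"] - merged["z_o"]).max() < 1e-9
        assert np.abs(merged["p"] - merged["p_o"]).max() < 1e-9

    def test_planted_loop_called_significant(self):
        cfg = st.SimConfig(seed=5, n_bins=200, contact_depth=50.0,
                           compartment_block_size=None,
                           loops=((20, 120),), loop_enrichment=10.0)
        cmap, _ = st.simulate_contacts(cfg)
        calls = st.InteractionCaller().fit(cmap).calls_
        hit = calls[(calls["bin_i"] == 20) & (calls["bin_j"] == 120)]
        assert len(hit) == 1 and bool(hit["significant"].iloc[0])

    def test_short_range_pairs_excluded(self, uniform_map):
        calls = st.InteractionCaller(min_distance_bins=2).fit(uniform_map).calls_
        assert (calls["bin_j"] - calls["bin_i"]).min() >= 2

    def test_significance_flag_matches_thresholds(self):
        cfg = st.SimConfig(seed=8, n_bins=100, contact_depth=30.0)
        cmap, _ = st.simulate_contacts(cfg)
        calls = st.InteractionCaller().fit(cmap).calls_
        flag = (calls["p"] <= 0.05) & (calls["z"] >= 2.0)
        assert (calls["significant"] == flag).all()


class TestCompartments:
    def _study_map(self, seed):
        cfg = st.SimConfig(seed=seed, n_bins=500, compartment_block_size=20,
                           contact_depth=200.0)
        cmap, truth = st.simulate_contacts(cfg)
        rng = np.random.default_rng(seed + 999)
        track = np.where(truth.compartments == "A", 4.0, 1.0) + rng.poisson(1.0, 500)
        return cmap, truth, track

    def test_checkerboard_blocks_recovered(self):
        cmap, truth, track = self._study_map(0)
        comp = CompartmentPCA().fit(cmap, track)
        acc = (np.sign(comp.scores_) ==
               np.where(truth.compartments == "A", 1, -1)).mean()
        assert acc >= 0.95

    def test_orientation_reversal_swaps_labels_exactly(self):
        cmap, truth, track = self._study_map(1)
        model = fit_expected(cmap)
        fwd = compartment_pca(cmap, model, track)
        rev = compartment_pca(cmap, model, track.max() - track)
        assert np.allclose(fwd.scores, -rev.scores, equal_nan=True)
        swap = {"A": "B", "B": "A", ".": "."}
        assert [swap[l] for l in fwd.labels] == list(rev.labels)

    def test_structureless_map_mostly_unassigned(self):
        cfg = st.SimConfig(seed=2, n_bins=200, compartment_block_size=None,
                           contact_depth=100.0)
        cmap, _ = st.simulate_contacts(cfg)
        rng = np.random.default_rng(3)
        comp = CompartmentPCA().fit(cmap, rng.poisson(2.0, 200).astype(float))
        frac_unassigned = (np.abs(comp.scores_) <= 100).mean()
        assert frac_unassigned > 0.5

    def test_strong_blocks_assign_most_bins(self):
        """Signal-carrying scale: a well-compartmentalized map puts most bins
        beyond the +-100 unassigned band."""
        cmap, truth, track = self._study_map(4)
        comp = CompartmentPCA().fit(cmap, track)
        assert (np.abs(comp.scores_) > 100).mean() > 0.8


class TestLinkTSS:
    def test_hand_enumerated_linkage(self):
        """5 TSSs, 4 site bins, 3 significant calls."""
        tss = st.GenomicIntervalSet([
            st.GenomicInterval("chrS", 10 * 10_000 + 5, 10 * 10_000 + 6, name="gA"),
            st.GenomicInterval("chrS", 11 * 10_000 + 5, 11 * 10_000 + 6, name="gB"),
            st.GenomicInterval("chrS", 30 * 10_000 + 5, 30 * 10_000 + 6, name="gC"),
            st.GenomicInterval("chrS", 55 * 10_000 + 5, 55 * 10_000 + 6, name="gD"),
            st.GenomicInterval("chrS", 70 * 10_000 + 5, 70 * 10_000 + 6, name="gE"),
        ])
        sites = pd.DataFrame({
            "summit": [60 * 10_000 + 100, 62 * 10_000 + 100, 80 * 10_000 + 100,
                       90 * 10_000 + 100],
            "retained": [True, True, True, False],  # bin 90 not retained
        })
        calls = pd.DataFrame({
            "bin_i": [10, 30, 55, 70],
            "bin_j": [60, 62, 58, 90],
            "significant": [True, True, False, True],
        })
        links = link_tss(tss, sites, calls, bin_size=10_000)
        assert links["gA"] == [60]
        assert links["gB"] == []  # no call for bin 11
        assert links["gC"] == [62]
        assert links["gD"] == []  # call not significant
        assert links["gE"] == []  # partner bin 90 has no retained site
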