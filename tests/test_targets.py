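"""Direct/Indirect classification rules, enrichment, and the summary report."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

import srftarget as st
from srftarget.targets import (
    classify,
    hypergeom_enrichment,
    nearest_site_distance,
    percentage,
    summarize,
)


def _sites(*pairs):
    return st.GenomicIntervalSet(
        [st.GenomicInterval("chr1", s, e) for s, e in pairs]
    )


class TestNearestDistance:
    def test_containment_is_zero(self):
        tss = st.GenomicInterval("chr1", 5000, 5001)
        assert nearest_site_distance(tss, _sites((4000, 6000))) == 0

    def test_edge_gap(self):
        tss = st.GenomicInterval("chr1", 5000, 5001)
        assert nearest_site_distance(tss, _sites((15_000, 15_500))) == 10_000

    def test_no_sites_is_infinite(self):
        tss = st.GenomicInterval("chr1", 5000, 5001)
        assert nearest_site_distance(tss, _sites()) == math.inf

    def test_other_chromosome_ignored(self):
        tss = st.GenomicInterval("chr1", 5000, 5001)
        sites = st.GenomicIntervalSet([st.GenomicInterval("chr2", 5000, 5200)])
        assert nearest_site_distance(tss, sites) == math.inf


def _scenario(links=None):
    """Four induced+dependent genes covering every classification branch."""
    tss_map = {
        "prox": [st.GenomicInterval("chr1", 45_000, 45_001, name="prox")],
        "remote": [st.GenomicInterval("chr1", 700_000, 700_001, name="remote")],
        "gap": [st.GenomicInterval("chr1", 90_000, 90_001, name="gap")],
        "far": [st.GenomicInterval("chr1", 900_000, 900_001, name="far")],
    }
    sites = _sites((40_000, 40_200))  # single site at 40 kb
    genes = list(tss_map)
    induced = pd.Series("induced", index=genes)
    dependent = pd.Series("dependent", index=genes)
    if links is None:
        links = {"remote": [4]}  # only the remote gene has a Hi-C link
    return genes, tss_map, sites, links, induced, dependent


class TestClassify:
    def test_each_branch(self):
        res = classify(*_scenario())
        assert res.loc["prox", "target_class"] == "Direct"  # 4.8 kb away
        assert not res.loc["prox", "remote"]
        assert res.loc["remote", "target_class"] == "Direct"  # linked at 660 kb
        assert res.loc["remote", "remote"]
        assert res.loc["gap", "target_class"] == "Unassigned"  # 50 kb, no link
        assert res.loc["far", "target_class"] == "Indirect"  # 860 kb, no link

    def test_not_dependent_is_unassigned(self):
        genes, tss_map, sites, links, induced, dependent = _scenario()
        dependent["prox"] = "independent"
        res = classify(genes, tss_map, sites, links, induced, dependent)
        assert res.loc["prox", "target_class"] == "Unassigned"

    def test_missing_tss_is_unassigned(self):
        genes, tss_map, sites, links, induced, dependent = _scenario()
        del tss_map["far"]
        res = classify(genes, tss_map, sites, links, induced, dependent)
        assert res.loc["far", "target_class"] == "Unassigned"
        assert res.loc["far", "status"] == "no-TSS"

    def test_order_independent_and_exclusive(self):
        genes, tss_map, sites, links, induced, dependent = _scenario()
        a = classify(genes, tss_map, sites, links, induced, dependent)
        b = classify(genes[::-1], tss_map, sites, links, induced, dependent)
        assert a.sort_index().equals(b.sort_index())
        assert ((a["target_class"] == "Direct") & (a["target_class"] == "Indirect")).sum() == 0

    def test_multi_tss_gene_uses_best_tss(self):
        genes, tss_map, sites, links, induced, dependent = _scenario()
        tss_map["far"].append(st.GenomicInterval("chr1", 41_000, 41_001, name="far"))
        res = classify(genes, tss_map, sites, links, induced, dependent)
        assert res.loc["far", "target_class"] == "Direct"
        assert res.loc["far", "nearest_site_bp"] == 0 + 801  # gap to site end

    def test_link_shrinkage_monotonicity(self):
        """Removing links can demote Direct or promote Unassigned->Indirect,
        never Indirect->Direct."""
        genes, tss_map, sites, _, induced, dependent = _scenario()
        nested = [
            {"remote": [4], "far": [4]},
            {"remote": [4]},
            {},
        ]
        prev = None
        rank = {"Indirect": 0, "Unassigned": 1, "Direct": 2}
        for links in nested:
            res = classify(genes, tss_map, sites, links, induced, dependent)
            if prev is not None:
                for g in genes:
                    assert rank[res.loc[g, "target_class"]] <= rank[prev.loc[g, "target_class"]]
            prev = res


class TestEnrichment:
    def test_exact_enumeration_value(self):
        universe = [f"u{i}" for i in range(10)]
        query = universe[:5]
        res = hypergeom_enrichment(query, {"s": set(universe[:5])}, universe)
        assert res.loc["s", "p"] == pytest.approx(1 / comb(10, 5), rel=1e-12)
        assert res.loc["s", "overlap"] == 5

    def test_overlap_at_or_below_expectation(self):
        universe = [f"u{i}" for i in range(100)]
        query = universe[:10]
        # set of 50: expected overlap 5; observe exactly 5
        members = set(universe[5:55])
        res = hypergeom_enrichment(query, {"s": members}, universe)
        assert res.loc["s", "p"] >= 0.5

    def test_bonferroni_multiplies_by_set_count(self):
        universe = [f"u{i}" for i in range(20)]
        sets = {f"s{k}": set(universe[k:k + 5]) for k in range(5)}
        res = hypergeom_enrichment(universe[:5], sets, universe)
        for name in sets:
            expected = min(1.0, res.loc[name, "p"] * 5)
            assert res.loc[name, "p_bonferroni"] == pytest.approx(expected)

    def test_annotated_sets_intersected_with_universe(self):
        universe = ["a", "b", "c", "d"]
        res = hypergeom_enrichment(["a"], {"s": {"a", "zz"}}, universe)
        assert res.loc["s", "set_size"] == 1

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(["x"], {"s": {"x"}}, ["a", "b"])


class TestSummarize:
    def test_hand_labeled_fixture(self):
        cls = pd.DataFrame(
            {
                "target_class": ["Direct"] * 6 + ["Indirect"] * 4 + ["Unassigned"] * 10,
                "remote": [True, True, False, False, False, False] + [False] * 14,
            },
            index=[f"g{i}" for i in range(20)],
        )
        induction = pd.Series(["induced"] * 12 + ["downregulated"] * 3
                              + ["unchanged"] * 5, index=cls.index)
        dependence = pd.Series(["dependent"] * 10 + ["independent"] * 2,
                               index=cls.index[:12])
        coincidence = pd.Series(["SRF-associated"] * 3 + ["solo"] * 1)
        rep = summarize(cls, induction, dependence, coincidence)
        assert rep["n_induced"] == 12
        assert rep["n_downregulated"] == 3
        assert rep["n_dependent"] == 10
        assert rep["dependent_pct"] == pytest.approx(100 * 10 / 12)
        assert rep["n_direct"] == 6
        assert rep["n_indirect"] == 4
        assert rep["n_remote_direct"] == 2
        assert rep["remote_direct_pct"] == pytest.approx(100 * 2 / 6)
        assert rep["n_elk1_srf_associated"] == 3
        assert rep["elk1_srf_associated_pct"] == 75.0

    def test_empty_inputs_all_zero(self):
        rep = summarize()
        assert all(v == 0 for v in rep.values())

    def test_percentages_consistent_with_counts(self):
        rep = summarize()
        assert rep["dependent_pct"] == percentage(rep["n_dependent"], 0)

    def test_srf_sites_in_compartment_a(self):
        labels = np.array(["A"] * 5 + ["B"] * 5, dtype=object)
        sites = pd.DataFrame({"summit": [5_000, 25_000, 75_000],
                              "retained": [True, True, True]})
        rep = summarize(compartments=labels, srf_sites=sites, bin_size=10_000)
        assert rep["n_srf_sites"] == 3
        assert rep["n_srf_sites_in_A"] == 2
        assert rep["srf_sites_in_A_pct"] == pytest.approx(100 * 2 / 3)
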