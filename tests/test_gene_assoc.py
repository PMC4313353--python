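import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from regevo.gene_assoc import (associate_elements, build_regulatory_domains,
                               expression_ratio_profile,
                               geneset_enrichment_binomial, psg_enrichment,
                               tsps_and_liver_specific)
from regevo.intervals import GenomicInterval


def genes_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


class TestRegulatoryDomains:
    def test_isolated_plus_gene(self):
        gm = build_regulatory_domains(
            genes_frame([("g1", "c", 2_000_000, "+")]), {"c": 10_000_000})[0]
        assert (gm.basal_start, gm.basal_end) == (1_995_000, 2_001_000)
        # extension capped at 1 Mb beyond each basal edge
        assert (gm.domain_start, gm.domain_end) == (995_000, 3_001_000)

    def test_minus_strand_basal_mirrored(self):
        gm = build_regulatory_domains(
            genes_frame([("g1", "c", 2_000_000, "-")]), {"c": 10_000_000})[0]
        assert (gm.basal_start, gm.basal_end) == (1_999_000, 2_005_000)

    def test_extension_stops_at_neighbour_basal(self):
        gms = build_regulatory_domains(
            genes_frame([("g1", "c", 1_000_000, "+"),
                         ("g2", "c", 1_100_000, "+")]), {"c": 10_000_000})
        g1, g2 = gms
        assert g1.domain_end == g2.basal_start == 1_095_000
        assert g2.domain_start == g1.basal_end == 1_001_000

    def test_clipped_to_chromosome(self):
        gm = build_regulatory_domains(
            genes_frame([("g1", "c", 100_000, "+")]), {"c": 500_000})[0]
        assert gm.domain_start == 0
        assert gm.domain_end == 500_000

    def test_basal_inside_domain(self):
        gms = build_regulatory_domains(
            genes_frame([("g1", "c", 3_000_000, "+"),
                         ("g2", "c", 3_050_000, "-")]), {"c": 10_000_000})
        for gm in gms:
            assert gm.domain_start <= gm.basal_start < gm.basal_end <= gm.domain_end


class TestAssociation:
    def setup_method(self):
        self.models = build_regulatory_domains(
            genes_frame([("g1", "c", 1_000_000, "+"),
                         ("g2", "c", 1_100_000, "+")]), {"c": 10_000_000})

    def test_element_inside_one_domain(self):
        links = associate_elements(
            {"e1": GenomicInterval("h", "c", 1_050_000, 1_052_000)},
            self.models)
        # intergenic region is covered by both flanking regulatory domains
        assert set(links["gene_id"]) == {"g1", "g2"}

    def test_element_in_basal_of_one_gene(self):
        links = associate_elements(
            {"e1": GenomicInterval("h", "c", 996_000, 998_000)}, self.models)
        assert list(links["gene_id"]) == ["g1"]

    def test_gene_desert_beyond_caps_gives_no_links(self):
        links = associate_elements(
            {"e1": GenomicInterval("h", "c", 8_000_000, 8_002_000)},
            self.models)
        assert links.empty

    def test_signed_tss_distance_strand_aware(self):
        models = build_regulatory_domains(
            genes_frame([("g1", "c", 1_000_000, "-")]), {"c": 10_000_000})
        links = associate_elements(
            {"e1": GenomicInterval("h", "c", 1_010_000, 1_012_000)}, models)
        # downstream in genome = upstream for a minus-strand gene
        assert links.loc[0, "tss_distance"] == -(1_011_000 - 1_000_000)


class TestTsps:
    def expr(self, rows):
        return pd.DataFrame(rows, columns=["liver", "brain", "kidney"],
                            index=[f"g{i}" for i in range(len(rows))])

    def test_selected_when_all_conditions_hold(self):
        df = tsps_and_liver_specific(self.expr([[30.0, 10.0, 10.0]]))
        assert df.loc["g0", "tsps"] == pytest.approx(3.0)
        assert bool(df.loc["g0", "selected"])

    def test_low_tsps_not_selected(self):
        df = tsps_and_liver_specific(self.expr([[12.0, 10.0, 10.0]]))
        assert df.loc["g0", "tsps"] == pytest.approx(1.2)
        assert not df.loc["g0", "selected"]

    def test_argmax_condition_overrides_tsps(self):
        df = tsps_and_liver_specific(self.expr([[100.0, 200.0, 1.0]]))
        assert not df.loc["g0", "selected"]

    def test_rpkm_floor(self):
        df = tsps_and_liver_specific(self.expr([[8.0, 1.0, 1.0]]))
        assert df.loc["g0", "tsps"] > 1.5
        assert not df.loc["g0", "selected"]  # liver RPKM <= 10

    def test_all_zero_gene_never_selected(self):
        df = tsps_and_liver_specific(self.expr([[0.0, 0.0, 0.0]]))
        assert df.loc["g0", "tsps"] == 0.0
        assert not df.loc["g0", "selected"]

    def test_single_tissue_rejected(self):
        with pytest.raises(ValueError):
            tsps_and_liver_specific(pd.DataFrame({"liver": [1.0]}))


class TestGenesetBinomial:
    def test_equal_fractions_never_reported(self):
        fg = [f"g{i}" for i in range(10)]
        bg = [f"g{i}" for i in range(100)]
        sets = {"t1": [f"g{i}" for i in range(0, 100, 10)]}  # 10% everywhere
        df = geneset_enrichment_binomial(fg, bg, sets)
        assert df.loc[0, "fold"] == pytest.approx(1.0)
        assert not df.loc[0, "reported"]

    def test_enriched_term_counts_and_p(self):
        fg = [f"g{i}" for i in range(50)]
        bg = [f"g{i}" for i in range(500)]
        sets = {"t": [f"g{i}" for i in range(20)] +
                     [f"x{i}" for i in range(30)]}
        df = geneset_enrichment_binomial(fg, bg, sets)
        # fg hits 20/50 vs bg rate 20/500
        assert df.loc[0, "fold"] == pytest.approx((20 / 50) / (20 / 500))
        assert df.loc[0, "p"] == pytest.approx(
            float(st.binom.sf(19, 50, 0.04)))

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            geneset_enrichment_binomial(["g1"], [], {"t": ["g1"]})


class TestPsgTests:
    def _links(self, pairs):
        return pd.DataFrame(pairs, columns=["element_id", "gene_id"])

    def test_every_gene_psg_makes_gene_test_uninformative(self):
        universe = [f"g{i}" for i in range(6)]
        links_all = self._links([(f"e{i}", g) for i, g in enumerate(universe)])
        links_recent = self._links([("e0", "g0"), ("e1", "g1")])
        res = psg_enrichment(links_all, links_recent, universe, universe)
        gene_test = [r for r in res if r.name == "psgs_with_recent_enhancer"][0]
        assert gene_test.p == pytest.approx(1.0)

    def test_gene_level_hypergeometric_matches_enumeration(self):
        universe = [f"g{i}" for i in range(10)]
        psg = universe[:4]
        with_recent = universe[2:7]  # 5 genes, 2 of them PSGs
        links_all = self._links([(f"e{i}", g) for i, g in enumerate(universe)])
        links_recent = self._links(
            [(f"r{i}", g) for i, g in enumerate(with_recent)])
        res = psg_enrichment(links_all, links_recent, universe, psg)
        gene_test = [r for r in res if r.name == "psgs_with_recent_enhancer"][0]
        k, n, K, N = gene_test.counts
        assert (k, n, K, N) == (2, 5, 4, 10)
        # brute-force enumeration over all n-subsets of the universe
        total = hits = 0
        for subset in itertools.combinations(range(N), n):
            total += 1
            if len(set(subset) & set(range(K))) >= k:
                hits += 1
        assert gene_test.p == pytest.approx(hits / total)

    def test_empty_psg_list_rejected(self):
        links = self._links([("e0", "g0")])
        with pytest.raises(ValueError):
            psg_enrichment(links, links, ["g0"], [])

    def test_wilcoxon_detects_planted_proportion_shift(self):
        from regevo.simulate import simulate_psg_links
        data = simulate_psg_links(psg_fold=4.0, recent_rate=0.05, seed=3)
        res = psg_enrichment(data["links_all"], data["links_recent"],
                             data["universe"], data["psg"])
        wil = [r for r in res if "wilcoxon" in r.name][0]
        assert wil.p < 0.05


class TestExpressionRatio:
    def expr(self):
        return pd.DataFrame(
            {"liver": [10.0, 20.0, 30.0], "brain": [5.0, 5.0, 5.0]},
            index=["g0", "g1", "g2"])

    def test_set_equals_background_gives_ones(self):
        r = expression_ratio_profile(["g0", "g1"], ["g0", "g1"], self.expr())
        assert r["liver"] == pytest.approx(1.0)
        assert r["brain"] == pytest.approx(1.0)

    def test_single_tissue_difference(self):
        r = expression_ratio_profile(["g2"], ["g0", "g1"], self.expr())
        assert r["liver"] == pytest.approx(30.0 / 15.0)
        assert r["brain"] == pytest.approx(1.0)

    def test_unknown_genes_count_as_unexpressed(self):
        r = expression_ratio_profile(["zzz"], ["g0", "g1"], self.expr())
        assert r["liver"] == 0.0

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            expression_ratio_profile([], ["g0"], self.expr())
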