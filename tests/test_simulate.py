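import json
import math

import numpy as np
import pandas as pd
import pytest

from regevo import study
from regevo.intervals import MarkClass
from regevo.simulate import (SimConfig, emit_fixtures, load_fixtures,
                             simulate_psg_links, simulate_world)


def two_taxon_config(**kwargs):
    base = dict(
        seed=0, tree_newick="(a:50,b:50);", n_blocks=4000,
        n_root_elements={"promoter_dual": 0, "promoter_k4": 0,
                         "enhancer": 2000},
        birth_rate={"promoter_dual": 0, "promoter_k4": 0, "enhancer": 0},
        half_life={"promoter_dual": 900.0, "promoter_k4": 900.0,
                   "enhancer": 50.0},
        dna_half_life=1e12, replicate_overrides={}, n_genes=50, n_psg=5)
    base.update(kwargs)
    return SimConfig(**base)


class TestLossProcess:
    def test_no_loss_limit_every_element_everywhere(self):
        cfg = SimConfig(
            seed=1,
            half_life={"promoter_dual": math.inf, "promoter_k4": math.inf,
                       "enhancer": math.inf},
            birth_rate={"promoter_dual": 0, "promoter_k4": 0, "enhancer": 0},
            dna_half_life=math.inf,
            n_root_elements={"promoter_dual": 100, "promoter_k4": 50,
                             "enhancer": 150},
            n_blocks=1000,
        )
        world = simulate_world(cfg)
        assert world.presence.all().all()
        assert len(world.presence.columns) == 20

    def test_instant_loss_limit_nothing_shared(self):
        world = simulate_world(two_taxon_config(
            half_life={"promoter_dual": 1e-9, "promoter_k4": 1e-9,
                       "enhancer": 1e-9}))
        shared = world.presence["a"] & world.presence["b"]
        assert shared.sum() == 0

    def test_two_taxon_shared_fraction_matches_closed_form(self):
        # t = 50 Ma at half-life 50: both lineages retain with prob 0.5^2
        world = simulate_world(two_taxon_config())
        shared = (world.presence["a"] & world.presence["b"]).mean()
        se = math.sqrt(0.25 * 0.75 / 2000)
        assert abs(shared - 0.25) < 3 * se

    def test_degenerate_tree_rejected(self):
        with pytest.raises(ValueError):
            simulate_world(SimConfig(seed=0, tree_newick="(a:1);"))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(half_life={"enhancer": 0.0})
        with pytest.raises(ValueError):
            SimConfig(n_replicates=0)
        with pytest.raises(ValueError):
            SimConfig(peak_sensitivity=0.0)


class TestPeakEmulation:
    def test_perfect_sensitivity_recovers_truth_exactly(self):
        cfg = two_taxon_config(peak_sensitivity=1.0, false_positive_rate=0.0,
                               peak_jitter=0, half_life={
                                   "promoter_dual": 900, "promoter_k4": 900,
                                   "enhancer": 900})
        world = simulate_world(cfg)
        cons = study.species_consensus(world, "a")
        truth = world.element_intervals("a")
        got = {(c.interval.start, c.interval.end) for c in cons}
        want = {(iv.start, iv.end) for iv in truth.values()}
        assert got == want
        assert all(c.reproducibility == 1.0 for c in cons)

    def test_reproducible_fraction_matches_binomial_closed_form(self):
        # sensitivity 0.8, 3 replicates: P(>= 2 detections) = 0.896
        cfg = two_taxon_config(peak_sensitivity=0.8, false_positive_rate=0.0,
                               half_life={"promoter_dual": 900,
                                          "promoter_k4": 900,
                                          "enhancer": 1e12})
        world = simulate_world(cfg)
        cons = study.species_consensus(world, "a")
        n_true = int(world.presence["a"].sum())
        expected = 3 * 0.8 ** 2 * 0.2 + 0.8 ** 3
        se = math.sqrt(expected * (1 - expected) / n_true)
        assert abs(len(cons) / n_true - expected) < 3 * se

    def test_single_replicate_species_has_one_peak_file(self, default_world):
        assert default_world.n_replicates("whale") == 1
        assert len(default_world.replicate_peaks[("whale", "H3K4me3")]) == 1
        assert default_world.n_replicates("human") == 3

    def test_intensities_positive_and_lognormal_scale(self, default_world):
        el = default_world.elements
        assert (el["intensity"] > 0).all()
        assert 3 < el["intensity"].median() < 12


class TestWorldInvariants:
    def test_seed_determinism_byte_identical_fixtures(self, tmp_path):
        cfg = two_taxon_config(n_blocks=800, n_root_elements={
            "promoter_dual": 50, "promoter_k4": 20, "enhancer": 100})
        m1 = emit_fixtures(simulate_world(cfg), tmp_path / "run1")
        m2 = emit_fixtures(simulate_world(cfg), tmp_path / "run2")
        assert m1["files"] == m2["files"]
        m3 = emit_fixtures(simulate_world(
            two_taxon_config(seed=99, n_blocks=800, n_root_elements={
                "promoter_dual": 50, "promoter_k4": 20, "enhancer": 100})),
            tmp_path / "run3")
        assert m3["files"] != m1["files"]

    def test_orthology_round_trip_consistency(self, default_world):
        omap = default_world.orthology_map("human", "rat")
        rev = omap.reversed()
        ivs = list(default_world.element_intervals("human").values())[:200]
        for iv in ivs:
            fwd = omap.project(iv)
            if fwd.status != "unique":
                continue
            back = rev.project(fwd.target)
            assert back.status == "unique"
            assert (back.target.start, back.target.end) == (iv.start, iv.end)

    def test_shared_element_occupies_orthologous_blocks(self, default_world):
        w = default_world
        el = w.elements
        blocks = el["block"].to_numpy()
        both = (w.presence["human"] & w.presence["dog"]).to_numpy()
        assert both.any()
        ident_ok = (w.block_identity["human"][blocks[both]]
                    == w.block_identity["dog"][blocks[both]])
        assert ident_ok.all()

    def test_elements_born_on_branch_absent_outside_clade(self, default_world):
        w = default_world
        el = w.elements
        primate_clade = {"human", "macaque", "vervet", "marmoset"}
        stem = "node_" + "|".join(sorted(primate_clade))
        born = el["birth_node"] == stem
        if born.any():
            outside = [s for s in w.species if s not in primate_clade]
            assert not w.presence.loc[born, outside].any().any()

    def test_young_block_age_bounds_alignable_divergence(self, default_world):
        w = default_world
        ages = w.identity_birth_age
        rng = np.random.default_rng(0)
        hb = w.block_identity["human"]
        young = np.nonzero(ages[hb] < w.tree.depth)[0]
        for b in rng.choice(young, size=min(100, len(young)), replace=False):
            birth_age = ages[hb[b]]
            for s in w.species:
                if s != "human" and w.block_identity[s][b] == hb[b]:
                    assert w.tree.divergence_time("human", s) <= birth_age + 1e-9

    def test_per_species_elements_disjoint(self, default_world):
        for s in ("human", "whale"):
            ivs = sorted((iv.start, iv.end) for iv in
                         default_world.element_intervals(s).values())
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_truth_table_consistent_with_presence(self, default_world):
        tt = default_world.truth_table("human")
        assert (tt["n_species_present"]
                == default_world.presence.sum(axis=1)).all()
        assert set(tt["age_category"]) <= {"young", "mid", "ancestral"}


class TestFixtureFiles:
    def test_emit_and_load_round_trip(self, tmp_path):
        cfg = two_taxon_config(n_blocks=600, n_root_elements={
            "promoter_dual": 30, "promoter_k4": 10, "enhancer": 60})
        world = simulate_world(cfg)
        manifest = emit_fixtures(world, tmp_path / "fx")
        assert (tmp_path / "fx" / "manifest.json").exists()
        fx = load_fixtures(tmp_path / "fx")
        assert fx.tree.species == world.species
        pd.testing.assert_frame_equal(
            fx.presence, world.presence, check_names=False)
        key = ("a", "H3K27ac")
        pd.testing.assert_frame_equal(
            fx.replicate_peaks[key][0], world.replicate_peaks[key][0])
        om_w = world.orthology_map("a", "b").blocks
        om_f = fx.orthology[("a", "b")].blocks
        pd.testing.assert_frame_equal(om_f, om_w)
        pd.testing.assert_frame_equal(fx.expression, world.expression)
        assert fx.psg == world.psg


class TestPsgLinkGenerator:
    def test_null_and_planted_rates(self):
        null = simulate_psg_links(psg_fold=1.0, seed=0)
        planted = simulate_psg_links(psg_fold=3.0, recent_rate=0.08, seed=0)
        for d in (null, planted):
            assert set(d["links_recent"]["element_id"]) <= \
                set(d["links_all"]["element_id"])
            assert set(d["psg"]) <= set(d["universe"])
        pr = planted["links_recent"]["gene_id"].isin(planted["psg"]).mean()
        nr = null["links_recent"]["gene_id"].isin(null["psg"]).mean()
        assert pr > nr
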