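import numpy as np
import pandas as pd
import pytest

from regevo.conserved_sets import (MARKS, MarkCallTable, SpeciesPanel,
                                   classify_majority, find_highly_conserved,
                                   find_lineage_specific,
                                   find_recently_evolved,
                                   permutation_test_conserved_count)


def make_calls(k4: np.ndarray, k27: np.ndarray, species,
               alignable: np.ndarray | None = None) -> MarkCallTable:
    n = k4.shape[0]
    ids = pd.Index([f"e{i}" for i in range(n)])
    if alignable is None:
        alignable = k4 | k27 | True
    return MarkCallTable(
        {"H3K4me3": pd.DataFrame(k4, index=ids, columns=species),
         "H3K27ac": pd.DataFrame(k27, index=ids, columns=species)},
        pd.DataFrame(alignable, index=ids, columns=species),
    )


class TestMajorityRule:
    @pytest.mark.parametrize("states, expected", [
        (["dual"] * 8 + ["k27_only"] * 2, "promoter"),
        (["dual"] + ["k27_only"] * 9, "enhancer"),
        (["dual"] * 5 + ["k27_only"] * 5, "promoter"),   # tie -> promoter
        (["k4_only"] * 3, "promoter"),
        (["k27_only"], "enhancer"),
    ])
    def test_assignment(self, states, expected):
        assert classify_majority(states) == expected

    def test_all_none_rejected(self):
        with pytest.raises(ValueError):
            classify_majority(["none", "none"])


class TestHighlyConserved:
    SPECIES = [f"s{i}" for i in range(10)]

    def test_strict_all_of_rule(self):
        k4 = np.ones((2, 10), bool)
        k27 = np.ones((2, 10), bool)
        k4[0, 3] = k27[0, 3] = False  # element 0: 9 of 10 species
        calls = make_calls(k4, k27, self.SPECIES)
        panel = SpeciesPanel("ref", tuple(self.SPECIES), {})
        got = find_highly_conserved(calls, panel)
        assert [c.element_id for c in got] == ["e1"]
        assert got[0].assigned_class == "promoter"
        assert all(v == "dual" for v in got[0].states.values())

    def test_k27_only_element_classified_enhancer(self):
        k4 = np.zeros((1, 10), bool)
        k27 = np.ones((1, 10), bool)
        calls = make_calls(k4, k27, self.SPECIES)
        got = find_highly_conserved(
            calls, SpeciesPanel("ref", tuple(self.SPECIES), {}))
        assert got[0].assigned_class == "enhancer"

    def test_k4_only_everywhere_flagged_promoter(self):
        k4 = np.ones((1, 10), bool)
        k27 = np.zeros((1, 10), bool)
        got = find_highly_conserved(
            make_calls(k4, k27, self.SPECIES),
            SpeciesPanel("ref", tuple(self.SPECIES), {}))
        assert got[0].assigned_class == "promoter"
        assert got[0].k4_only_everywhere

    def test_enlarging_panel_shrinks_set(self):
        rng = np.random.default_rng(0)
        k4 = rng.random((300, 10)) < 0.7
        k27 = rng.random((300, 10)) < 0.7
        calls = make_calls(k4, k27, self.SPECIES)
        sizes = [
            len(find_highly_conserved(
                calls, SpeciesPanel("ref", tuple(self.SPECIES[:k]), {})))
            for k in (4, 6, 8, 10)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_no_loss_world_equals_alignable_panel(self, default_world,
                                                  anchor_calls):
        calls, _ = anchor_calls
        panel_species = ("macaque", "vervet", "marmoset", "mouse")
        panel = SpeciesPanel("human", panel_species, {})
        got = {c.element_id for c in find_highly_conserved(calls, panel)}
        anym = calls.any_mark()
        want = set(calls.elements[anym[list(panel_species)].all(axis=1)])
        assert got == want


class TestLineageAndRecent:
    SPECIES = ["mac", "ver", "mar", "dog", "cow"]

    def test_outside_conservation_disqualifies(self):
        k27 = np.array([[1, 1, 1, 1, 0],   # conserved in dog too -> excluded
                        [1, 1, 1, 0, 0]], bool)
        k4 = np.zeros_like(k27)
        calls = make_calls(k4, k27, self.SPECIES)
        got = find_lineage_specific(calls, ["mac", "ver", "mar"])
        assert [c.element_id for c in got] == ["e1"]
        assert got[0].assigned_class == "enhancer"

    def test_unalignable_outside_species_non_informative(self):
        k27 = np.array([[1, 1, 1, 0, 0]], bool)
        k4 = np.zeros_like(k27)
        align = np.array([[1, 1, 1, 0, 1]], bool)  # dog unalignable
        calls = make_calls(k4, k27, self.SPECIES, align)
        got = find_lineage_specific(calls, ["mac", "ver", "mar"])
        assert len(got) == 1

    def test_recent_excluded_by_single_conservation(self):
        k27 = np.array([[0, 0, 1, 0, 0], [0, 0, 0, 0, 0]], bool)
        k4 = np.zeros_like(k27)
        calls = make_calls(k4, k27, self.SPECIES)
        got = find_recently_evolved(
            calls, {"e0": "enhancer", "e1": "enhancer"})
        assert list(got.index) == ["e1"]

    def test_unalignable_everywhere_is_recent(self):
        k27 = np.zeros((1, 5), bool)
        k4 = np.zeros_like(k27)
        align = np.zeros((1, 5), bool)
        calls = make_calls(k4, k27, self.SPECIES, align)
        got = find_recently_evolved(calls, {"e0": "promoter_dual"})
        assert list(got.index) == ["e0"]
        assert got.loc["e0", "n_alignable"] == 0

    def test_set_disjointness_on_world(self, anchor_calls):
        calls, anchor_els = anchor_calls
        panel = SpeciesPanel(
            "human", ("macaque", "vervet", "marmoset", "mouse", "rat",
                      "rabbit", "cow", "pig", "dog", "cat"), {})
        hc = {c.element_id for c in find_highly_conserved(calls, panel)}
        recent = set(find_recently_evolved(
            calls, {e: anchor_els[e].mark_class.value
                    for e in calls.elements}).index)
        assert hc & recent == set()
        lin = {c.element_id
               for c in find_lineage_specific(calls,
                                              ["macaque", "vervet", "marmoset"])}
        assert lin & recent == set()


class TestPermutation:
    SPECIES = ["s1", "s2", "s3", "s4"]

    def test_zero_observed_gives_p_one(self):
        k4 = np.zeros((50, 4), bool)
        k27 = np.zeros((50, 4), bool)
        calls = make_calls(k4, k27, self.SPECIES)
        rep = permutation_test_conserved_count(
            calls, SpeciesPanel("ref", tuple(self.SPECIES), {}),
            n_iter=200, seed=0)
        assert rep.observed == 0
        assert rep.p_value == 1.0

    def test_planted_conservation_hits_lower_bound(self):
        rng = np.random.default_rng(1)
        k4 = rng.random((400, 4)) < 0.1
        k27 = rng.random((400, 4)) < 0.1
        k4[:80] = k27[:80] = True
        calls = make_calls(k4, k27, self.SPECIES)
        rep = permutation_test_conserved_count(
            calls, SpeciesPanel("ref", tuple(self.SPECIES), {}),
            n_iter=1000, seed=2)
        assert rep.p_value == pytest.approx(1 / 1001)
        assert rep.p_display.startswith("<")

    def test_null_counts_preserved_and_deterministic(self):
        rng = np.random.default_rng(3)
        k4 = rng.random((200, 4)) < 0.5
        k27 = rng.random((200, 4)) < 0.5
        calls = make_calls(k4, k27, self.SPECIES)
        panel = SpeciesPanel("ref", tuple(self.SPECIES), {})
        r1 = permutation_test_conserved_count(calls, panel, n_iter=300, seed=9)
        r2 = permutation_test_conserved_count(calls, panel, n_iter=300, seed=9)
        assert (r1.p_value, r1.null_mean) == (r2.p_value, r2.null_mean)
        # null preserves per-stratum conserved counts, so the mean count
        # stays near the independence expectation
        p_any = np.mean([(k4[:, j] | k27[:, j]).mean() for j in range(4)])
        expected = 200 * p_any ** 4
        assert abs(r1.null_mean - expected) < 15


class TestPanelValidation:
    def test_anchor_cannot_be_required(self):
        with pytest.raises(ValueError):
            SpeciesPanel("a", ("a", "b"), {})

    def test_clades_must_be_disjoint_with_member_reference(self):
        with pytest.raises(ValueError):
            SpeciesPanel("x", ("a",), {"c1": ("z", ["a", "b"])})
        with pytest.raises(ValueError):
            SpeciesPanel("x", ("q",),
                         {"c1": ("a", ["a", "b"]), "c2": ("b", ["b", "c"])})
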