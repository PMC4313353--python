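import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from regevo.intervals import GenomicInterval
from regevo.orthomap import ElementIndex, OrthologyMap
from regevo.turnover import (ConservationProfile, conservation_profile,
                             conservation_ratio, decay_points_from_matrix,
                             fit_decay_jackknife, fit_exponential_decay,
                             mean_lifetime, nj_tree)

LN2 = math.log(2.0)


class TestDecayFit:
    def test_noiseless_recovery_is_exact(self):
        t = np.array([10.0, 50.0, 90.0, 130.0, 170.0])
        r = np.exp(-t * LN2 / 100.0)
        fit = fit_exponential_decay(t, r)
        assert fit.half_life == pytest.approx(100.0, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-10)
        # zero residual scatter collapses the CI onto the point estimate
        assert fit.ci95_half_life[0] == pytest.approx(100.0)
        assert fit.ci95_half_life[1] == pytest.approx(100.0)

    def test_free_amplitude_absorbs_technical_floor(self):
        t = np.array([10.0, 50.0, 90.0, 130.0])
        r = 0.9 * np.exp(-t * LN2 / 200.0)
        fit = fit_exponential_decay(t, r)
        assert fit.amplitude == pytest.approx(0.9, rel=1e-9)
        assert fit.half_life == pytest.approx(200.0, rel=1e-9)
        constrained = fit_exponential_decay(t, r, fix_amplitude=True)
        assert constrained.amplitude == 1.0
        assert constrained.half_life < 200.0  # floor pushed into the slope

    def test_nonpositive_ratios_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            fit = fit_exponential_decay([10, 50, 90, 130], [0.9, 0.6, 0.0, 0.4])
        assert fit.n_points == 3

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_decay([10, 10, 10], [0.5, 0.4, 0.3])
        with pytest.raises(ValueError):
            fit_exponential_decay([1, 2], [0.9, 0.8])
        with pytest.raises(ValueError):  # increasing ratios: no decay
            fit_exponential_decay([10, 50, 90], [0.2, 0.5, 0.9])

    def test_ci_transform_is_monotone(self):
        rng = np.random.default_rng(0)
        t = np.linspace(10, 180, 30)
        r = np.exp(-t * LN2 / 300) * np.exp(rng.normal(0, 0.05, 30))
        fit = fit_exponential_decay(t, r)
        lo, hi = fit.ci95_half_life
        assert lo < fit.half_life < hi


class TestMeanLifetime:
    @pytest.mark.parametrize("half_life, expected", [
        (939.0, 1354.7), (296.0, 427.0), (LN2, 1.0),
    ])
    def test_values(self, half_life, expected):
        assert mean_lifetime(half_life) == pytest.approx(expected, abs=0.05)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mean_lifetime(0.0)


class TestConservationProfile:
    def _world(self):
        """Hand-built 3-species setup: anchor element alignable in two
        species, conserved in exactly one."""
        cols = ["species_a", "chrom_a", "start_a", "end_a", "strand_a",
                "species_b", "chrom_b", "start_b", "end_b", "strand_b"]
        map_b = OrthologyMap(pd.DataFrame(
            [("A", "c", 0, 10_000, "+", "B", "c", 0, 10_000, "+")], columns=cols))
        map_c = OrthologyMap(pd.DataFrame(
            [("A", "c", 0, 10_000, "+", "C", "c", 0, 10_000, "+")], columns=cols))
        anchor = {"e1": GenomicInterval("A", "c", 1000, 1500),
                  "e2": GenomicInterval("A", "c", 20_000, 20_500)}
        targets = {
            "B": ElementIndex([GenomicInterval("B", "c", 1000, 1500)]),
            "C": ElementIndex([]),
        }
        return anchor, {"B": map_b, "C": map_c}, targets

    def test_counts_and_calls(self):
        anchor, maps, targets = self._world()
        profiles = {p.element_id: p
                    for p in conservation_profile(anchor, maps, targets)}
        p1 = profiles["e1"]
        assert (p1.n_alignable, p1.n_conserved) == (2, 1)
        assert p1.calls == {"B": "conserved", "C": "absent"}
        p2 = profiles["e2"]  # outside every block
        assert (p2.n_alignable, p2.n_conserved) == (0, 0)

    def test_ratio(self):
        assert conservation_ratio(
            ConservationProfile("x", 10, 5)) == pytest.approx(0.5)
        assert conservation_ratio(
            ConservationProfile("x", 19, 19)) == pytest.approx(1.0)
        assert math.isnan(conservation_ratio(ConservationProfile("x", 0, 0)))

    def test_profile_bounds_on_world(self, default_world, anchor_calls):
        calls, _ = anchor_calls
        n_align = calls.alignable.sum(axis=1)
        n_cons = calls.any_mark().sum(axis=1)
        assert (n_cons <= n_align).all()
        assert (n_align <= len(default_world.species) - 1).all()


class TestRatioVsDivergence:
    def test_ratio_decreases_with_divergence(self, default_world,
                                             default_consensus):
        from regevo import study
        from regevo.intervals import MarkClass
        mat = study.class_ratio_matrix(default_world, default_consensus,
                                       MarkClass.enhancer)
        t, r = decay_points_from_matrix(mat, default_world.tree)
        rho = st.spearmanr(t, r).statistic
        assert rho < -0.9

    def test_total_branch_axis_doubles_divergence(self, fixture_tree):
        mat = pd.DataFrame(
            [[1.0, 0.5], [0.5, 1.0]],
            index=["human", "mouse"], columns=["human", "mouse"])
        t1, _ = decay_points_from_matrix(mat, fixture_tree, "divergence")
        t2, _ = decay_points_from_matrix(mat, fixture_tree, "total_branch")
        assert t2[0] == 2 * t1[0] == 180.0


class TestNJ:
    def test_additive_four_taxon_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4):0); additive distances
        d = {
            ("a", "b"): 3, ("a", "c"): 5, ("a", "d"): 6,
            ("b", "c"): 6, ("b", "d"): 7, ("c", "d"): 7,
        }
        taxa = ["a", "b", "c", "d"]
        mat = pd.DataFrame(0.0, index=taxa, columns=taxa)
        for (x, y), v in d.items():
            mat.loc[x, y] = mat.loc[y, x] = v
        newick = nj_tree(mat)
        from skbio import TreeNode
        import io
        tree = TreeNode.read(io.StringIO(newick))
        # additivity: leaf-to-leaf path lengths reproduce the input exactly
        for (x, y), v in d.items():
            assert tree.find(x).distance(tree.find(y)) == pytest.approx(v)

    def test_three_taxon_star_resolution(self):
        taxa = ["a", "b", "c"]
        mat = pd.DataFrame([[0, 2, 8], [2, 0, 8], [8, 8, 0]],
                           index=taxa, columns=taxa, dtype=float)
        newick = nj_tree(mat)
        assert set(t for t in taxa) <= set(newick.replace("(", " ").replace(
            ")", " ").replace(",", " ").replace(":", " ").split())

    def test_rejects_bad_matrices(self):
        taxa = ["a", "b"]
        mat = pd.DataFrame([[0, 1], [1, 0]], index=taxa, columns=taxa,
                           dtype=float)
        with pytest.raises(ValueError):
            nj_tree(mat)
        taxa = ["a", "b", "c"]
        asym = pd.DataFrame([[0, 1, 2], [9, 0, 3], [2, 3, 0]],
                            index=taxa, columns=taxa, dtype=float)
        with pytest.raises(ValueError):
            nj_tree(asym)

    def test_negative_branches_clamped(self):
        taxa = ["a", "b", "c", "d"]
        rng = np.random.default_rng(4)
        base = rng.uniform(0.4, 0.6, (4, 4))
        m = (base + base.T) / 2
        np.fill_diagonal(m, 0.0)
        newick = nj_tree(pd.DataFrame(m, index=taxa, columns=taxa))
        assert ":-" not in newick


class TestJackknife:
    def test_jackknife_ci_wider_than_ols(self, default_world,
                                         default_consensus):
        from regevo import study
        from regevo.intervals import MarkClass
        mat = study.class_ratio_matrix(default_world, default_consensus,
                                       MarkClass.enhancer)
        t, r = decay_points_from_matrix(mat, default_world.tree)
        ols = fit_exponential_decay(t, r)
        jack = fit_decay_jackknife(mat, default_world.tree)
        assert jack.half_life == pytest.approx(ols.half_life)
        ols_w = ols.ci95_half_life[1] - ols.ci95_half_life[0]
        jack_w = jack.ci95_half_life[1] - jack.ci95_half_life[0]
        assert jack_w > 0.5 * ols_w  # not degenerate
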