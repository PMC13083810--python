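"""Tissue simulators: packing constraints, heuristic annotation behavior,
hard-core point patterns and cluster infiltration."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

import nepscore as nep
from nepscore.errors import PackingError, ParameterError
from nepscore.simulate import (
    ClusterSpec,
    InfiltrationParams,
    SCENARIO_II_GREEN_SIZES,
    SCENARIO_PROPORTIONS,
    infiltration_scenario,
    simulate_infiltration,
)

SMALL = nep.SimParams(f=300.0, t=150.0, iterations=60, swaps=30)


@pytest.fixture(scope="module")
def small_scaffold():
    return nep.make_scaffold(SMALL, seed=21)


class TestPackCircles:
    def test_equal_radii_enforce_min_center_distance(self):
        pts, radii = nep.pack_circles(300, 10, 10, seed=1)
        assert len(pts) > 50
        assert pdist(pts).min() >= 20.0
        assert (radii == 10).all()

    def test_tiny_field_few_circles(self):
        pts, _ = nep.pack_circles(40, 10, 10, seed=2, retry_budget=2000)
        assert 1 <= len(pts) <= 4
        if len(pts) > 1:
            assert pdist(pts).min() >= 20.0

    def test_deterministic_under_seed(self):
        a, _ = nep.pack_circles(200, 10, 10, seed=3, retry_budget=2000)
        b, _ = nep.pack_circles(200, 10, 10, seed=3, retry_budget=2000)
        np.testing.assert_array_equal(a, b)

    def test_infeasible_radius_rejected(self):
        with pytest.raises(ParameterError):
            nep.pack_circles(15, 10, 10, seed=1)

    def test_mixed_radii_no_overlap(self):
        pts, radii = nep.pack_circles(200, 5, 15, seed=4, retry_budget=2000)
        d = pdist(pts)
        lim = radii[:, None] + radii[None, :]
        iu = np.triu_indices(len(pts), 1)
        assert (d >= lim[iu] - 1e-9).all()


def test_scaffold_graph_is_delaunay_of_centers(small_scaffold):
    direct = nep.build_delaunay(small_scaffold.points)
    np.testing.assert_array_equal(small_scaffold.graph.edges, direct.edges)


class TestAnnotateHeuristic:
    def test_every_node_labeled_once(self, small_scaffold):
        spec = nep.preset_spec("self", "weak")
        tis = nep.annotate_heuristic(small_scaffold, spec, SMALL, seed=5)
        assert tis.cells.n_cells == len(small_scaffold.points)
        assert set(tis.cells.df["cell_type"]) <= set(spec.type_names)
        assert (tis.cells.coordinates() >= 0).all()
        assert (tis.cells.coordinates() <= SMALL.f).all()

    def test_single_type_degenerate(self, small_scaffold):
        spec = nep.AdjacencySpec(p=[1.0], H=[[1.0]], cohort_label="mono")
        tis = nep.annotate_heuristic(small_scaffold, spec, SMALL, seed=6)
        assert set(tis.cells.df["cell_type"]) == {"type0"}

    def test_uniform_H_realizes_uniform_adjacency(self):
        """Flat H and p: realized directed adjacency fractions ~0.25 per
        pair, averaged over images."""
        spec = nep.preset_spec("self", "random")
        params = nep.SimParams(f=400.0, iterations=100, swaps=30)
        rows = []
        for i in range(6):
            sc = nep.make_scaffold(params, seed=100 + i)
            tis = nep.annotate_heuristic(sc, spec, params, seed=200 + i)
            rows.append(nep.adjacency_fractions(sc.graph, tis.cells.labels(), 4))
        mean_F = np.nanmean(rows, axis=0)
        assert np.abs(mean_F - 0.25).max() < 0.05

    def test_self_preference_raises_homotypic_adjacency(self, small_scaffold):
        """H with strong 0-0 preference versus flat H on the same
        scaffold: realized 0-0 fraction must be clearly higher."""
        rnd = nep.annotate_heuristic(
            small_scaffold, nep.preset_spec("self", "random"), SMALL, seed=7
        )
        strong = nep.annotate_heuristic(
            small_scaffold, nep.preset_spec("self", "strong"), SMALL, seed=7
        )
        f_rnd = nep.adjacency_fractions(small_scaffold.graph, rnd.cells.labels(), 4)
        f_str = nep.adjacency_fractions(small_scaffold.graph, strong.cells.labels(), 4)
        assert f_str[0, 0] > f_rnd[0, 0] + 0.1

    def test_refinement_conserves_cell_count(self, small_scaffold):
        spec = nep.preset_spec("self", "strong")
        tis = nep.annotate_heuristic(small_scaffold, spec, SMALL, seed=8)
        assert tis.cells.n_cells == len(small_scaffold.points)


class TestSimulateCohort:
    def test_deterministic_pair(self):
        spec = nep.preset_spec("self", "weak")
        a = nep.simulate_cohort(spec, 2, SMALL, seed=9)
        b = nep.simulate_cohort(spec, 2, SMALL, seed=9)
        for ta, tb in zip(a, b):
            assert ta.cells.df.equals(tb.cells.df)

    def test_shared_scaffolds_same_coords_different_labels(self):
        scaffolds = nep.make_scaffolds(2, SMALL, seed=10)
        a = nep.simulate_cohort(nep.preset_spec("self", "random"), 2, SMALL,
                                seed=10, scaffolds=scaffolds)
        b = nep.simulate_cohort(nep.preset_spec("self", "strong"), 2, SMALL,
                                seed=10, scaffolds=scaffolds)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.cells.coordinates(),
                                          tb.cells.coordinates())
            assert not (ta.cells.df["cell_type"] == tb.cells.df["cell_type"]).all()

    def test_realized_abundances_near_p(self):
        """Cohort-level abundances track p at equal target abundances;
        the heuristic tolerates modest drift."""
        spec = nep.preset_spec("self", "weak")
        tissues = nep.simulate_cohort(spec, 8, SMALL, seed=11)
        counts = np.zeros(4)
        total = 0
        for t in tissues:
            counts += np.bincount(t.cells.labels(), minlength=4)
            total += t.cells.n_cells
        assert np.abs(counts / total - spec.p).max() < 0.05


class TestInfiltration:
    def test_background_respects_hardcore_distance(self):
        params = InfiltrationParams(width=600, height=600, n_background=700,
                                    min_d=10.0)
        cells = simulate_infiltration(params, seed=12)
        assert cells.n_cells == 700
        assert pdist(cells.coordinates()).min() >= 10.0

    def test_packing_failure_is_informative(self):
        params = InfiltrationParams(width=100, height=100, n_background=500,
                                    min_d=10.0)
        with pytest.raises(PackingError, match="min_d"):
            simulate_infiltration(params, seed=13)

    @pytest.mark.parametrize("prop,expect", [(0.0, "pure"), (1.0, "full")])
    def test_infiltration_boundary_proportions(self, prop, expect):
        params = InfiltrationParams(
            width=600, height=600, n_background=700, min_d=10.0,
            clusters=(ClusterSpec("purple", 60, (300.0, 300.0),
                                  semi_axes=(150.0, 100.0),
                                  infiltration=prop, infiltrating_type="green"),),
        )
        cells = simulate_infiltration(params, seed=14)
        n_purple = (cells.df["cell_type"] == "purple").sum()
        n_green = (cells.df["cell_type"] == "green").sum()
        if expect == "pure":
            assert n_purple == 60 and n_green == 0
        else:
            assert n_purple == 0 and n_green == 60

    def test_scenario_ii_size_pairing(self):
        """Green-cluster size steps down 510..440 as purple infiltration
        rises, the stated counter-balance of the growing infiltrate."""
        sizes = dict(zip(SCENARIO_PROPORTIONS, SCENARIO_II_GREEN_SIZES))
        assert sizes[0.0] == 510 and sizes[0.7] == 440
        assert list(SCENARIO_II_GREEN_SIZES) == sorted(
            SCENARIO_II_GREEN_SIZES, reverse=True
        )
        cells = infiltration_scenario("II", 0.0, seed=15)
        counts = cells.df["cell_type"].value_counts()
        # at zero infiltration the two cluster totals differ by 10 cells
        assert counts["purple"] == 500
        assert counts["green"] == 510

    def test_scenario_iii_swaps_labels(self):
        ii = infiltration_scenario("II", 0.3, seed=16)
        iii = infiltration_scenario("III", 0.3, seed=16)
        ci = ii.df["cell_type"].value_counts()
        ciii = iii.df["cell_type"].value_counts()
        assert ci["purple"] == ciii["green"] and ci["green"] == ciii["purple"]
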