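import numpy as np
import pytest

from metachain import (
    SiteAtlas,
    TransitionMatrix,
    best_two_step,
    classify_sites,
    delta_distribution,
    one_step_probabilities,
    pathway_decomposition,
    propagate,
    self_seeding_ranking,
)
from metachain.classify import (
    FIRST_ORDER,
    SECOND_ORDER,
    CoverageError,
    EdgeStat,
    PathBudgetError,
    TwoStepResult,
)

from conftest import random_chain


class TestOneStep:
    def test_identity_matrix_self_edge_dominates(self, atlas3):
        edges = one_step_probabilities(TransitionMatrix(atlas3, np.eye(3)), 2)
        assert edges[0].to_site == 2 and edges[0].mean == 1.0
        assert all(e.mean == 0.0 for e in edges[1:])

    def test_means_from_one_row_sum_to_one(self):
        m = random_chain(6, 0)
        edges = one_step_probabilities(m, 3)
        assert sum(e.mean for e in edges) == pytest.approx(1.0)
        assert all(
            e1.mean >= e2.mean for e1, e2 in zip(edges, edges[1:])
        ), "edges must be sorted descending"

    def test_published_top_edge(self, fixtures):
        edges = one_step_probabilities(fixtures.one_step_stats(), fixtures.lung_site)
        assert edges[0].to_site == 24  # regional lymph nodes
        assert edges[0].mean == pytest.approx(0.15115)
        assert edges[0].std == pytest.approx(0.01821)

    def test_top_two_edges_carry_28_percent(self, fixtures):
        edges = one_step_probabilities(fixtures.one_step_stats(), fixtures.lung_site)
        assert edges[0].mean + edges[1].mean == pytest.approx(0.2828)


class TestBestTwoStep:
    def test_cycle_route_via_middle(self, cycle3):
        res = best_two_step(cycle3, 1, 3)
        assert res.best_intermediate == 2
        assert res.probability == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_enumeration(self, seed):
        m = random_chain(6, seed)
        for dest in (2, 5):
            res = best_two_step(m, 1, dest)
            brute = max(
                (m.a[0, k] * m.a[k, dest - 1], k + 1) for k in range(6)
            )
            assert res.probability == pytest.approx(brute[0])
            assert res.best_intermediate == brute[1]

    @pytest.mark.parametrize("seed", range(4))
    def test_bounded_by_full_two_step_mass(self, seed):
        m = random_chain(5, seed)
        sq = m.a @ m.a
        for dest in m.atlas.site_ids:
            res = best_two_step(m, 1, dest)
            assert res.probability <= sq[0, dest - 1] + 1e-12


class TestClassification:
    def test_strong_direct_edge_is_first_order(self):
        one = [EdgeStat(1, 2, 0.5, 0.0)]
        two = [TwoStepResult(2, 3, 0.1)]
        assert classify_sites(one, two)[0].label == FIRST_ORDER

    def test_two_step_within_one_std_is_second_order(self):
        one = [EdgeStat(1, 2, 0.00439, 0.00443)]  # skin-like edge
        two = [TwoStepResult(2, 3, 0.00203)]
        assert classify_sites(one, two)[0].label == SECOND_ORDER

    def test_published_tables_split_20_7(self, fixtures):
        labels = classify_sites(fixtures.one_step_stats(), fixtures.two_step_stats())
        assert sum(1 for l in labels if l.label == FIRST_ORDER) == 20
        assert sum(1 for l in labels if l.label == SECOND_ORDER) == 7
        # printed cut-off: Skeletal Muscle is the last first-order row and
        # Skin the first second-order row
        assert [l.label for l in labels[:20]] == [FIRST_ORDER] * 20
        assert [l.label for l in labels[20:]] == [SECOND_ORDER] * 7
        assert fixtures.atlas.name_of(labels[19].site) == "Skeletal Muscle"
        assert fixtures.atlas.name_of(labels[20].site) == "Skin"

    def test_mismatched_site_sets_rejected(self):
        with pytest.raises(CoverageError):
            classify_sites([EdgeStat(1, 2, 0.5)], [TwoStepResult(3, 4, 0.1)])


class TestSelfSeeding:
    def test_identity_all_ones(self, atlas3):
        ranking = self_seeding_ranking(TransitionMatrix(atlas3, np.eye(3)))
        assert [e.mean for e in ranking] == [1.0, 1.0, 1.0]

    def test_zero_diagonal(self, cycle3):
        ranking = self_seeding_ranking(cycle3)
        assert all(e.mean == 0.0 for e in ranking)

    def test_published_ranking_tops_with_regional_lymph_nodes(self, fixtures):
        ranked = sorted(
            fixtures.self_edge_stats(), key=lambda e: -e.mean
        )
        assert ranked[0].site == 24
        assert ranked[0].mean == pytest.approx(0.1865)

    def test_descending_order(self):
        m = random_chain(6, 3)
        ranking = self_seeding_ranking(m)
        assert all(a.mean >= b.mean for a, b in zip(ranking, ranking[1:]))


class TestPathways:
    def test_cycle_single_path(self, cycle3):
        paths = pathway_decomposition(cycle3, 1, 3, max_length=2)
        assert paths == [((1, 2, 3), 1.0)]

    def test_direct_path_probability_is_matrix_entry(self):
        m = random_chain(5, 7)
        paths = pathway_decomposition(m, 1, 4, max_length=1, prob_floor=0.0)
        assert len(paths) == 1
        assert paths[0] == ((1, 4), pytest.approx(m.a[0, 3]))

    @pytest.mark.parametrize("max_length", [1, 2, 3, 4])
    def test_total_mass_matches_absorbing_chain_oracle(self, max_length):
        """Summed first-passage path probabilities equal the cumulative
        first-passage probability from the absorbing-chain propagation."""
        m = random_chain(5, 11)
        dest = 4
        paths = pathway_decomposition(m, 1, dest, max_length=max_length,
                                      prob_floor=0.0, budget=10**6)
        total = sum(p for _, p in paths)

        absorbing = m.a.copy()
        absorbing[dest - 1] = 0.0
        absorbing[dest - 1, dest - 1] = 1.0
        m_abs = TransitionMatrix(m.atlas, absorbing)
        v = propagate(delta_distribution(m.atlas, 1), m_abs, max_length)
        assert total == pytest.approx(v[dest], abs=1e-12)

    def test_budget_exceeded_raises(self):
        m = random_chain(8, 0)
        with pytest.raises(PathBudgetError):
            pathway_decomposition(m, 1, 2, max_length=6, prob_floor=0.0, budget=100)

    def test_destination_not_revisited_internally(self):
        m = random_chain(4, 2)
        for path, _ in pathway_decomposition(m, 1, 3, max_length=3, prob_floor=0.0):
            assert path[-1] == 3
            assert 3 not in path[:-1]
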