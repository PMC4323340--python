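import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from groomstats import dominance as dom
from groomstats.errors import DataError
from groomstats.io import SociometricMatrix


def _matrix(values, ids=None):
    values = np.asarray(values, dtype=float)
    if ids is None:
        ids = [chr(ord("A") + i) for i in range(values.shape[0])]
    return SociometricMatrix(ids, values)


PERFECT3 = _matrix([[0, 2, 2], [0, 0, 2], [0, 0, 0]])  # A > B > C, all decided
CIRCULAR3 = _matrix([[0, 2, 0], [0, 0, 2], [2, 0, 0]])  # A>B, B>C, C>A


def _decided_dij3():
    """Fully decided Dij matrix (Dij = 1 for each dominant direction)."""
    dij = np.array([[0.0, 1.0, 1.0], [0.0, 0.0, 1.0], [0.0, 0.0, 0.0]])
    n_ij = np.full((3, 3), 2.0)
    np.fill_diagonal(n_ij, 0.0)
    return dom.DijMatrix(["A", "B", "C"], dij, n_ij)


@st.composite
def win_matrices(draw, min_n=3, max_n=6):
    n = draw(st.integers(min_n, max_n))
    vals = draw(
        st.lists(
            st.lists(st.integers(0, 8), min_size=n, max_size=n),
            min_size=n,
            max_size=n,
        )
    )
    m = np.array(vals, dtype=float)
    np.fill_diagonal(m, 0)
    return _matrix(m)


class TestDij:
    def test_hand_computed_eight_two(self):
        m = _matrix([[0, 8], [2, 0]])
        d = dom.dyadic_dominance_index(m)
        assert d.dij[0, 1] == pytest.approx(0.8 - 0.3 / 11)
        assert d.dij[1, 0] == pytest.approx(1 - (0.8 - 0.3 / 11))

    def test_even_split_gives_half(self):
        d = dom.dyadic_dominance_index(_matrix([[0, 1], [1, 0]]))
        assert d.dij[0, 1] == pytest.approx(0.5)

    def test_unknown_dyad_convention(self):
        d = dom.dyadic_dominance_index(_matrix([[0, 0], [0, 0]]))
        assert d.dij[0, 1] == 0.5 and d.dij[1, 0] == 0.5
        assert d.n_unknown_dyads == 1

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(win_matrices())
    def test_antisymmetry(self, m):
        d = dom.dyadic_dominance_index(m)
        off = ~np.eye(d.n, dtype=bool)
        np.testing.assert_allclose((d.dij + d.dij.T)[off], 1.0)


class TestDavidsScores:
    def test_perfect_three_individual_hierarchy(self):
        # oracle: direct summation over the fully decided 3x3 Dij matrix
        s = dom.davids_scores(_decided_dij3())
        np.testing.assert_allclose(s["DS"], [3, 0, -3])
        np.testing.assert_allclose(s["NDS"], [2, 1, 0])

    def test_uninformative_matrix_is_flat(self):
        d = dom.dyadic_dominance_index(_matrix(np.zeros((4, 4))))
        s = dom.davids_scores(d)
        np.testing.assert_allclose(s["DS"], 0.0, atol=1e-12)
        np.testing.assert_allclose(s["NDS"], 1.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(win_matrices())
    def test_zero_sum_and_nds_range(self, m):
        s = dom.davids_scores(dom.dyadic_dominance_index(m))
        assert s["DS"].sum() == pytest.approx(0.0, abs=1e-9)
        assert s["NDS"].mean() == pytest.approx((m.n - 1) / 2)
        assert (s["NDS"] >= -1e-9).all() and (s["NDS"] <= m.n - 1 + 1e-9).all()

    def test_rank_order_tie_flag_and_lexicographic(self):
        s = pd.DataFrame({"id": ["B", "A", "C"], "NDS": [1.0, 1.0, 2.0]})
        order, tied = dom.rank_order(s)
        assert order == ["C", "A", "B"]
        assert tied

    def test_rank_order_invariant_to_input_order(self):
        s1 = pd.DataFrame({"id": ["A", "B", "C"], "NDS": [0.0, 2.0, 1.0]})
        s2 = s1.iloc[::-1].reset_index(drop=True)
        assert dom.rank_order(s1)[0] == dom.rank_order(s2)[0] == ["B", "C", "A"]


class TestSteepness:
    def test_perfect_hierarchy_has_unit_steepness(self):
        res = dom.steepness(_decided_dij3(), n_randomizations=200, seed=1)
        assert res.steepness == pytest.approx(1.0)

    def test_flat_matrix_has_zero_steepness(self):
        d = dom.dyadic_dominance_index(_matrix(np.zeros((5, 5))))
        res = dom.steepness(d, n_randomizations=200, seed=1)
        assert res.steepness == pytest.approx(0.0)

    def test_seed_reproducible(self):
        d = dom.dyadic_dominance_index(_matrix([[0, 5, 1], [2, 0, 4], [0, 1, 0]]))
        p1 = dom.steepness(d, n_randomizations=500, seed=7).p_value
        p2 = dom.steepness(d, n_randomizations=500, seed=7).p_value
        assert p1 == p2

    def test_randomization_count_validation(self):
        d = _decided_dij3()
        with pytest.raises(ValueError):
            dom.steepness(d, n_randomizations=-1, seed=1)
        # zero means "skip the randomization test", not an error
        assert dom.steepness(d, n_randomizations=0, seed=1).p_value is None
        with pytest.warns(UserWarning, match="randomizations"):
            dom.steepness(d, n_randomizations=50, seed=1)


class TestLinearity:
    def test_perfect_order(self):
        res = dom.linearity(PERFECT3, n_randomizations=500, seed=1)
        assert res.h == pytest.approx(1.0)
        assert res.h_prime == pytest.approx(1.0)
        assert res.u == 0

    def test_circular_order(self):
        res = dom.linearity(CIRCULAR3, n_randomizations=500, seed=1)
        assert res.h == pytest.approx(0.0)
        assert res.h_prime == pytest.approx(0.0)

    def test_h_prime_equals_h_without_unknowns_or_ties(self):
        m = _matrix([[0, 5, 1, 4], [2, 0, 4, 1], [0, 1, 0, 3], [1, 0, 1, 0]])
        res = dom.linearity(m, n_randomizations=500, seed=1)
        assert res.u == 0
        assert res.h_prime == pytest.approx(res.h)

    @pytest.mark.parametrize(
        "values",
        [
            # N=4, one unknown dyad
            [[0, 3, 2, 0], [1, 0, 3, 2], [0, 1, 0, 3], [0, 0, 1, 0]],
            # N=5, two unknown dyads and one tie
            [
                [0, 3, 0, 2, 1],
                [1, 0, 3, 0, 2],
                [0, 1, 0, 3, 1],
                [0, 0, 1, 0, 2],
                [1, 1, 1, 0, 0],
            ],
        ],
    )
    def test_h_prime_matches_exhaustive_enumeration(self, values):
        """Oracle: enumerate every resolution of undecided dyads and average
        Landau's h; the randomized h' must agree within 3 Monte-Carlo SE."""
        m = _matrix(values)
        w = m.values
        n = m.n
        und = [
            (i, j)
            for i, j in itertools.combinations(range(n), 2)
            if w[i, j] == w[j, i]
        ]
        base_v = np.zeros(n)
        for i, j in itertools.combinations(range(n), 2):
            if w[i, j] > w[j, i]:
                base_v[i] += 1
            elif w[j, i] > w[i, j]:
                base_v[j] += 1
        hs = []
        for assign in itertools.product([0, 1], repeat=len(und)):
            v = base_v.copy()
            for (i, j), a in zip(und, assign):
                v[i if a else j] += 1
            hs.append(12.0 / (n**3 - n) * ((v - (n - 1) / 2) ** 2).sum())
        exact = np.mean(hs)
        nrand = 20_000
        res = dom.linearity(m, n_randomizations=nrand, seed=3)
        se = np.std(hs) / np.sqrt(nrand)
        assert abs(res.h_prime - exact) <= max(3 * se, 1e-12)


class TestDCI:
    def test_unidirectional_is_one(self):
        assert dom.directional_consistency(PERFECT3) == pytest.approx(1.0)

    def test_hand_computed_mixed_counts(self):
        m = _matrix([[0, 5, 3], [0, 0, 0], [1, 0, 0]])
        # dyads (5,0) and (3,1): (5+2)/(5+4) = 7/9
        assert dom.directional_consistency(m) == pytest.approx(7 / 9)

    def test_all_tied_is_zero(self):
        m = _matrix([[0, 2, 1], [2, 0, 3], [1, 3, 0]])
        assert dom.directional_consistency(m) == pytest.approx(0.0)

    def test_no_interactions_raises(self):
        with pytest.raises(DataError):
            dom.directional_consistency(_matrix(np.zeros((3, 3))))


class TestEquivariance:
    def test_relabeling_permutes_outputs_consistently(self):
        rng = np.random.default_rng(0)
        w = rng.integers(0, 6, size=(5, 5)).astype(float)
        np.fill_diagonal(w, 0)
        m = _matrix(w)
        perm = [3, 0, 4, 1, 2]
        ids_p = [m.ids[i] for i in perm]
        mp = SociometricMatrix(ids_p, w[np.ix_(perm, perm)])
        s = dom.davids_scores(dom.dyadic_dominance_index(m)).set_index("id")
        sp = dom.davids_scores(dom.dyadic_dominance_index(mp)).set_index("id")
        pd.testing.assert_frame_equal(s.sort_index(), sp.sort_index())
        assert dom.directional_consistency(m) == pytest.approx(
            dom.directional_consistency(mp)
        )


class TestDisplacementMatrix:
    def test_counts_and_season_filter(self):
        events = pd.DataFrame(
            {
                "season": ["1", "1", "1", "1", "2"],
                "session_id": ["s"] * 5,
                "focal_id": ["A"] * 5,
                "actor_id": ["A", "A", "A", "B", "A"],
                "recipient_id": ["B", "B", "B", "A", "B"],
                "behavior": ["displacement"] * 5,
                "start": [1.0, 2.0, 3.0, 4.0, 5.0],
                "end": [np.nan] * 5,
            }
        )
        m = dom.build_displacement_matrix(events, "1", ids=["A", "B"])
        assert m.values[0, 1] == 3 and m.values[1, 0] == 1

    def test_no_events_gives_zero_matrix(self):
        events = pd.DataFrame(
            columns=[
                "season", "session_id", "focal_id", "actor_id",
                "recipient_id", "behavior", "start", "end",
            ]
        )
        m = dom.build_displacement_matrix(events, "1", ids=["A", "B", "C"])
        assert (m.values == 0).all()
        assert dom.dyadic_dominance_index(m).n_unknown_dyads == 3

    def test_unknown_actor_raises(self):
        events = pd.DataFrame(
            {
                "season": ["1"],
                "session_id": ["s"],
                "focal_id": ["A"],
                "actor_id": ["Z"],
                "recipient_id": ["A"],
                "behavior": ["displacement"],
                "start": [0.0],
                "end": [np.nan],
            }
        )
        with pytest.raises(KeyError):
            dom.build_displacement_matrix(events, "1", ids=["A", "B"])


class TestRankRecovery:
    def test_dense_consistent_displacements_recover_latent_order(self):
        """With consistency ~1 and dense observation the NDS rank order
        equals the latent hierarchy."""
        from groomstats import EffectConfig, GroupConfig, generate_group, simulate_study

        cfg = GroupConfig(
            n_females=8, matriline_sizes=[3, 3, 2], seasons=1,
            focal_hours_per_female=15.0, seed=12,
        )
        roster, truth = generate_group(cfg)
        eff = EffectConfig(consistency=1.0, displacement_rate=0.5)
        ev, _, _ = simulate_study(roster, truth, eff, cfg)
        m = dom.build_displacement_matrix(ev, "1", roster=roster)
        summary = dom.summarize_dominance(m, n_randomizations=200, seed=0)
        assert summary.order == truth.latent_rank
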