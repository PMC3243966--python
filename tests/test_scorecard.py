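"""The eight similarity indices and scorecard ranking."""

import math

import pytest

from cscdecoder import build_database
from cscdecoder.evoprint import CSC
from cscdecoder.pairwise import PairAlignment, SharedElement
from cscdecoder.rps import Occurrence
from cscdecoder.scorecard import (
    ScoreRow,
    correlation_coefficient,
    rank,
    rps_balance_index,
    score_candidates,
    score_pair,
)
from cscdecoder.errors import CSCDecoderError
from cscdecoder.synth import make_related_pair, pair_to_cscs, random_plant_spec

from conftest import scores_close


def fabricate_pa(specs):
    """PairAlignment stub from (sequence, category, n_in, n_db) tuples."""
    dummy_csc = CSC(name="x", region_id="x", icr_cutoff=150, csbs=[],
                    text="")
    shared = [
        SharedElement(
            sequence=seq, category=cat,
            occurrences_input=[Occurrence(0, i, "+") for i in range(ni)],
            occurrences_db=[Occurrence(0, i, "+") for i in range(nd)])
        for seq, cat, ni, nd in specs
    ]
    return PairAlignment(input_csc=dummy_csc, db_csc=dummy_csc,
                         shared=shared)


class TestCorrelation:
    def test_hand_computed_pearson(self):
        # x=(3,1,2), y=(1,1,2): deviations (1,-1,0) and (-1/3,-1/3,2/3)
        # give zero cross-sum, hence r = 0 exactly
        pa = fabricate_pa([("AAAAAT", "repeat", 3, 1),
                           ("CCCCCG", "repeat", 1, 1),
                           ("GGGGGT", "repeat", 2, 2)])
        assert correlation_coefficient(pa) == pytest.approx(0.0)

    def test_equal_vectors_give_exactly_one(self):
        pa = fabricate_pa([("AAAAAT", "repeat", 2, 2),
                           ("CCCCCG", "repeat", 3, 3),
                           ("GGGGGT", "unique", 1, 1)])
        assert correlation_coefficient(pa) == 1.0

    def test_zero_variance_unequal_gives_zero(self):
        pa = fabricate_pa([("AAAAAT", "repeat", 2, 1),
                           ("CCCCCG", "repeat", 2, 3)])
        assert correlation_coefficient(pa) == 0.0

    def test_no_shared_elements_undefined(self):
        assert correlation_coefficient(fabricate_pa([])) is None


class TestBalanceIndex:
    def test_matched_30_unmatched_20_gives_1_5(self):
        # matched length mass: 10+8+12 = 30; unmatched: 11+9 = 20
        pa = fabricate_pa([
            ("A" * 10, "repeat", 2, 2),
            ("C" * 8, "repeat", 1, 1),
            ("G" * 12, "subrepeat", 3, 3),
            ("T" * 11, "repeat", 3, 1),
            ("AC" * 4 + "A", "repeat", 2, 3),
            ("GATTAC", "unique", 1, 5),  # unique types never counted
        ])
        assert rps_balance_index(pa) == pytest.approx(1.5)

    def test_all_matched_infinite(self):
        pa = fabricate_pa([("A" * 7, "repeat", 2, 2)])
        assert rps_balance_index(pa) == math.inf

    def test_no_shared_repeats_undefined(self):
        pa = fabricate_pa([("GATTAC", "unique", 1, 1)])
        assert rps_balance_index(pa) is None


class TestScoreCandidates:
    def test_self_row_dominates(self, tmp_path):
        a, b, _ = make_related_pair(random_plant_spec(11))
        A, B = pair_to_cscs(a, b)
        db = build_database([A, B], tmp_path / "t.db")
        rows = score_candidates(db, A, db.search(A))
        self_row = next(r for r in rows if r.cluster_name == A.name)
        assert self_row.correlation_coefficient == 1.0
        assert self_row.percent_coverage == 100.0
        assert self_row.rps_balance_index == math.inf
        assert self_row.conserved_bases == A.conserved_bases
        other = next(r for r in rows if r.cluster_name != A.name)
        assert other.correlation_coefficient <= 1.0
        assert other.percent_coverage < 100.0

    def test_empty_candidates_empty_scorecard(self, tmp_path):
        a, b, _ = make_related_pair(random_plant_spec(12))
        A, B = pair_to_cscs(a, b)
        db = build_database([B], tmp_path / "t.db")
        assert score_candidates(db, A, []) == []

    def test_matches_ground_truth_indices(self, tmp_path):
        spec = random_plant_spec(13)
        a, b, gt = make_related_pair(spec)
        A, B = pair_to_cscs(a, b)
        db = build_database([B], tmp_path / "t.db")
        (row,) = score_candidates(db, A, [B.name])
        for key, want in gt.scorecard.items():
            assert scores_close(getattr(row, key), want), (key, want)

    def test_required_elements_counted(self, tmp_path):
        from cscdecoder import SearchConstraint
        spec = random_plant_spec(14)
        a, b, gt = make_related_pair(spec)
        A, B = pair_to_cscs(a, b)
        db = build_database([B], tmp_path / "t.db")
        present = [d for d in gt.shared]
        cons = [SearchConstraint(present[0]["sequence"],
                                 min_copies=present[0]["copies_in_db"]),
                SearchConstraint("G" * 8, min_copies=1)]
        (row,) = score_candidates(db, A, [B.name], cons)
        assert row.required_elements == 1


def row(name, corr=0.5, balance=1.0):
    return ScoreRow(cluster_name=name, rps_balance_index=balance,
                    correlation_coefficient=corr, shared_repeats=1,
                    total_shared_elements=2, percent_coverage=50.0,
                    required_elements=0, longest_shared=8,
                    conserved_bases=100)


class TestRank:
    def test_descending_by_correlation_self_first(self):
        rows = [row("a", corr=0.3), row("self", corr=1.0),
                row("b", corr=0.7)]
        out = rank(rows, "correlation_coefficient")
        assert [r.cluster_name for r in out] == ["self", "b", "a"]

    def test_undefined_sorts_last(self):
        rows = [row("u", corr=None), row("a", corr=0.1)]
        out = rank(rows, "correlation_coefficient")
        assert [r.cluster_name for r in out] == ["a", "u"]

    def test_infinite_balance_sorts_first(self):
        rows = [row("fin", balance=3.0), row("inf", balance=math.inf),
                row("und", balance=None)]
        out = rank(rows, "rps_balance_index")
        assert [r.cluster_name for r in out] == ["inf", "fin", "und"]

    def test_natural_name_sort_groups_neighbors(self):
        rows = [row("vvl-43"), row("vvl-5"), row("vvl-41"), row("ac-2")]
        out = rank(rows, "cluster_name")
        assert [r.cluster_name for r in out] == \
            ["ac-2", "vvl-5", "vvl-41", "vvl-43"]

    def test_stability_on_ties(self):
        rows = [row("first", corr=0.5), row("second", corr=0.5)]
        out = rank(rows, "correlation_coefficient")
        assert [r.cluster_name for r in out] == ["first", "second"]

    def test_rank_invariant_under_permutation(self):
        rows = [row(n, corr=c) for n, c in
                [("a", 0.1), ("b", 0.9), ("c", 0.5), ("d", None)]]
        out1 = rank(rows, "correlation_coefficient")
        out2 = rank(rows[::-1], "correlation_coefficient")
        assert [r.cluster_name for r in out1] == \
            [r.cluster_name for r in out2]

    def test_unknown_key_lists_valid(self):
        with pytest.raises(CSCDecoderError, match="correlation_coefficient"):
            rank([], "nonsense")
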