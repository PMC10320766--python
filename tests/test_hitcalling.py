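import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cfscreen.hitcalling import (
    AmbiguousSignError,
    ConsistencyError,
    DataError,
    InteractionCall,
    ReplicateObservation,
    cascade_sensitivity,
    cascade_specificity,
    combined_hits,
    confirmed_interactions,
    primary_candidates,
    sign_of_pair,
)
from conftest import full_primary, obs_frame
from oracles import enumerate_cascade


def primary_grid(reg="r1", reporters=("p1",), calls=("none", "none", "none")):
    return full_primary({(reg, rep): list(calls) for rep in reporters})


class TestPrimaryCandidates:
    def test_two_of_three_triggers_candidacy(self):
        obs = obs_frame(primary_grid(calls=("decrease", "decrease", "none")))
        assert primary_candidates(obs) == {"r1"}

    def test_all_none_gives_empty_set(self):
        obs = obs_frame(primary_grid())
        assert primary_candidates(obs) == set()

    def test_direction_disagreement_still_counts(self):
        obs = obs_frame(primary_grid(calls=("decrease", "increase", "none")))
        assert primary_candidates(obs) == {"r1"}

    def test_one_of_three_on_many_pairs_is_not_candidacy(self):
        reporters = tuple(f"p{i}" for i in range(19))
        obs = obs_frame(primary_grid(reporters=reporters, calls=("decrease", "none", "none")))
        assert primary_candidates(obs) == set()

    def test_more_than_three_primary_observations_rejected(self):
        rows = primary_grid(calls=("none", "none", "none"))
        rows.append(("r1", "p1", "primary", 1, "none"))
        with pytest.raises(DataError):
            primary_candidates(obs_frame(rows))


class TestCombinedHits:
    @pytest.mark.parametrize(
        "prim,ret,passes",
        [
            (("decrease", "decrease", "none"), ("decrease", "none"), True),  # 2+1
            (("decrease", "none", "none"), ("decrease", "decrease"), True),  # 1+2
            (("decrease", "decrease", "none"), ("none", "none"), False),     # 2+0
            (("decrease", "decrease", "decrease"), ("none", "none"), True),  # 3+0
        ],
    )
    def test_three_of_five_rule(self, prim, ret, passes):
        # a second pair guarantees candidacy so the 1/3 pair is evaluated
        rows = full_primary(
            {("r1", "p1"): list(prim), ("r1", "p2"): ["decrease", "decrease", "decrease"]}
        )
        for i, c in enumerate(ret, 1):
            rows.append(("r1", "p1", "retest", i, c))
        for i in (1, 2):
            rows.append(("r1", "p2", "retest", i, "decrease"))
        hits = combined_hits(obs_frame(rows))
        assert (("r1", "p1") in hits) is passes
        assert ("r1", "p2") in hits

    def test_zero_of_three_pair_cannot_pass(self):
        rows = full_primary(
            {("r1", "p1"): ["none"] * 3, ("r1", "p2"): ["decrease"] * 3}
        )
        rows += [("r1", "p1", "retest", i, "decrease") for i in (1, 2)]
        rows += [("r1", "p2", "retest", i, "none") for i in (1, 2)]
        assert combined_hits(obs_frame(rows)) == {("r1", "p2")}

    def test_retest_of_non_candidate_rejected(self):
        rows = primary_grid(calls=("decrease", "none", "none"))
        rows.append(("r1", "p1", "retest", 1, "decrease"))
        with pytest.raises(ConsistencyError):
            combined_hits(obs_frame(rows))


class TestConfirmedInteractions:
    @staticmethod
    def _cascade_rows(imaging=("decrease", "none")):
        rows = full_primary({("r1", "p1"): ["decrease", "decrease", "none"]})
        rows += [("r1", "p1", "retest", 1, "decrease"), ("r1", "p1", "retest", 2, "none")]
        for i, c in enumerate(imaging, 1):
            rows.append(("r1", "p1", "imaging", i, c))
        return rows

    def test_one_of_two_photos_confirms(self):
        calls = confirmed_interactions(obs_frame(self._cascade_rows()))
        assert len(calls) == 1
        c = calls[0]
        assert c.final and c.sign == -1
        assert (c.n_primary_pos, c.n_retest_pos, c.n_photo_pos) == (2, 1, 1)

    def test_zero_photos_is_not_final(self):
        calls = confirmed_interactions(obs_frame(self._cascade_rows(("none", "none"))))
        assert len(calls) == 1 and not calls[0].final

    def test_noiseless_seven_replicate_increase(self):
        rows = full_primary({("r1", "p1"): ["increase"] * 3})
        rows += [("r1", "p1", "retest", i, "increase") for i in (1, 2)]
        rows += [("r1", "p1", "imaging", i, "increase") for i in (1, 2)]
        (c,) = confirmed_interactions(obs_frame(rows))
        assert c.final and c.sign == 1
        assert (c.n_primary_pos, c.n_retest_pos, c.n_photo_pos) == (3, 2, 2)

    def test_imaging_outside_combined_hits_rejected(self):
        rows = primary_grid(calls=("none", "none", "none"))
        rows.append(("r1", "p1", "imaging", 1, "decrease"))
        with pytest.raises(ConsistencyError):
            confirmed_interactions(obs_frame(rows))

    def test_excluded_regulator_never_final(self):
        calls = confirmed_interactions(
            obs_frame(self._cascade_rows()), exclude_regulators={"r1"}
        )
        assert len(calls) == 1 and not calls[0].final
        assert calls[0].n_photo_pos == 1  # evidence kept for reporting

    def test_final_call_invariants_enforced(self):
        with pytest.raises(ValueError, match="3/5"):
            InteractionCall("r", "p", -1, 1, 1, 1, final=True)
        with pytest.raises(ValueError, match="0/3"):
            InteractionCall("r", "p", -1, 0, 3, 1, final=True)

    def test_replicate_observation_tier_ranges(self):
        with pytest.raises(ValueError):
            ReplicateObservation("r", "p", "retest", 3, "none")
        with pytest.raises(ValueError):
            ReplicateObservation("r", "p", "primary", 4, "none")


class TestSignOfPair:
    def test_majority(self):
        assert sign_of_pair(["decrease"] * 4 + ["increase"]) == -1
        assert sign_of_pair(["decrease"]) == -1

    def test_tie_broken_by_imaging(self):
        assert sign_of_pair(
            ["decrease", "decrease", "increase", "increase", "decrease"][:4],
            imaging_calls=["decrease"],
        ) == -1

    def test_residual_tie_raises(self):
        with pytest.raises(AmbiguousSignError):
            sign_of_pair(["decrease", "increase"], imaging_calls=[])

    def test_all_none_rejected(self):
        with pytest.raises(ValueError, match="non-none"):
            sign_of_pair(["none", "none"])

    def test_ambiguous_pair_excluded_unless_kept(self):
        rows = full_primary({("r1", "p1"): ["decrease", "increase", "none"]})
        rows += [("r1", "p1", "retest", 1, "decrease"), ("r1", "p1", "retest", 2, "increase")]
        rows += [("r1", "p1", "imaging", 1, "decrease"), ("r1", "p1", "imaging", 2, "increase")]
        assert confirmed_interactions(obs_frame(rows)) == []
        kept = confirmed_interactions(obs_frame(rows), keep_ambiguous=True)
        assert len(kept) == 1 and kept[0].ambiguous and not kept[0].final


class TestCascadeProbabilities:
    def test_certain_detection(self):
        assert cascade_sensitivity(1, 1, 1) == pytest.approx(1.0)

    def test_zero_primary_means_zero(self):
        assert cascade_sensitivity(0, 0.9, 0.9) == 0.0

    def test_specificity_endpoints(self):
        assert cascade_specificity(0.0) == 0.0
        assert cascade_specificity(1.0) == pytest.approx(1.0)

    def test_half_probability_matches_enumeration(self):
        assert cascade_sensitivity(0.5, 0.5, 0.5) == pytest.approx(
            enumerate_cascade(0.5, 0.5, 0.5), abs=1e-12
        )

    def test_specificity_matches_enumeration(self):
        assert cascade_specificity(0.1) == pytest.approx(
            enumerate_cascade(0.1, 0.1, 0.1), abs=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cascade_sensitivity(1.2, 0.5, 0.5)

    def test_monotone_in_each_argument(self):
        grid = np.linspace(0.0, 1.0, 6)
        for fixed in (0.3, 0.8):
            s1 = [cascade_sensitivity(p, fixed, fixed) for p in grid]
            s2 = [cascade_sensitivity(fixed, p, fixed) for p in grid]
            s3 = [cascade_sensitivity(fixed, fixed, p) for p in grid]
            for s in (s1, s2, s3):
                assert all(a <= b + 1e-15 for a, b in zip(s, s[1:]))

    @given(
        st.tuples(
            st.floats(0, 1, allow_nan=False),
            st.floats(0, 1, allow_nan=False),
            st.floats(0, 1, allow_nan=False),
        )
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_closed_form_equals_enumeration_everywhere(self, probs):
        p1, p2, p3 = probs
        assert cascade_sensitivity(p1, p2, p3) == pytest.approx(
            enumerate_cascade(p1, p2, p3), abs=1e-12
        )
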