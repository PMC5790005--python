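"""Drug screening: clamp signatures, scores, HSA synergy, tiers, MoA."""

from __future__ import annotations

import math

import numpy as np
import pytest

from netscreen.model import PropagationModel, propagate
from netscreen.screen import (
    CombinationScore,
    PhenotypeSignature,
    ScreenConfig,
    Thresholds,
    adverse_score,
    drug_input_signature,
    efficacy_score,
    extract_moa,
    filter_candidates,
    ranking_key,
    score_singles,
    screen_combinations,
    synergy_score,
)
from netscreen.types import DrugSignature, Eligibility

ELIGIBLE = Eligibility(True, True, True, True)
INELIGIBLE = Eligibility(True, True, True, False)


@pytest.fixture
def convergent_model() -> PropagationModel:
    """a and b both activate read-out r; p is an untouched pain node."""
    return PropagationModel(
        nodes=["a", "b", "p", "r"],
        edge_src=np.array([0, 1]),
        edge_tgt=np.array([3, 3]),
        edge_sign=np.array([1, 1]),
        strengths=np.array([0.8, 0.8]),
        bias=np.zeros(4),
    )


def drug(drug_id: str, targets, eligibility=ELIGIBLE) -> DrugSignature:
    return DrugSignature(drug_id, tuple(targets), eligibility)


PROTECTION = PhenotypeSignature("protection", {"r": 1.0})
PAIN = PhenotypeSignature("pain", {"p": -1.0})
SIGS = {"protection": PROTECTION, "pain": PAIN}


class TestDrugInputSignature:
    def test_single_drug(self, convergent_model):
        sig, cov = drug_input_signature([drug("d", [("a", 1)])], convergent_model)
        assert sig == {"a": 1.0} and cov == 1.0

    def test_pair_union(self, convergent_model):
        sig, _ = drug_input_signature(
            [drug("d1", [("a", 1)]), drug("d2", [("b", -1)])], convergent_model
        )
        assert sig == {"a": 1.0, "b": -1.0}

    def test_shared_target_same_action_clips(self, convergent_model):
        sig, _ = drug_input_signature(
            [drug("d1", [("a", 1)]), drug("d2", [("a", 1)])], convergent_model
        )
        assert sig == {"a": 1.0}

    def test_shared_target_opposing_actions_cancel(self, convergent_model):
        sig, _ = drug_input_signature(
            [drug("d1", [("a", 1)]), drug("d2", [("a", -1)])], convergent_model
        )
        assert sig == {"a": 0.0}

    def test_off_map_targets_lower_coverage(self, convergent_model):
        sig, cov = drug_input_signature(
            [drug("d", [("a", 1), ("UNKNOWN", -1)])], convergent_model
        )
        assert sig == {"a": 1.0} and cov == 0.5

    def test_dose_scales_clamps(self, convergent_model):
        sig, _ = drug_input_signature([drug("d", [("a", -1)])], convergent_model, dose=0.25)
        assert sig == {"a": -0.25}

    def test_three_drugs_rejected(self, convergent_model):
        d = drug("d", [("a", 1)])
        with pytest.raises(ValueError, match="one or two"):
            drug_input_signature([d, d, d], convergent_model)


class TestElementaryScores:
    def test_exact_match_scores_100(self):
        sig = PhenotypeSignature("s", {"x": 0.5, "y": -0.5})
        assert efficacy_score({"x": 0.5, "y": -0.5}, sig) == pytest.approx(100.0)

    def test_overshoot_not_rewarded(self):
        sig = PhenotypeSignature("s", {"x": 0.5})
        assert efficacy_score({"x": 1.0}, sig) == pytest.approx(100.0)

    def test_opposite_direction_floors_at_zero(self):
        sig = PhenotypeSignature("s", {"x": 1.0})
        assert efficacy_score({"x": -0.8}, sig) == 0.0

    def test_weights_tilt_the_mean(self):
        sig = PhenotypeSignature("s", {"x": 1.0, "y": 1.0}, weights={"x": 3.0, "y": 1.0})
        # x fully hit, y untouched: (3*1 + 1*0) / 4
        assert efficacy_score({"x": 1.0, "y": 0.0}, sig) == pytest.approx(75.0)

    def test_adverse_uses_same_contract(self):
        sig = PhenotypeSignature("pain", {"p": -1.0})
        assert adverse_score({"p": -1.0}, sig) == pytest.approx(100.0)
        assert adverse_score({"p": 1.0}, sig) == 0.0

    def test_missing_protein_in_state_is_error(self):
        sig = PhenotypeSignature("s", {"zz": 1.0})
        with pytest.raises(KeyError, match="zz"):
            efficacy_score({"x": 1.0}, sig)

    def test_hsa_synergy_arithmetic(self):
        assert synergy_score(80.0, 50.0, 60.0) == pytest.approx(20.0)
        assert synergy_score(40.0, 50.0, 10.0) == pytest.approx(-10.0)  # kept, not clipped

    def test_zero_desired_state_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            PhenotypeSignature("s", {"x": 0.0})


class TestScreenCombinations:
    def library(self):
        return [
            drug("dA", [("a", 1)]),
            drug("dB", [("b", 1)]),
            drug("dN", []),  # null drug: no targets
        ]

    def test_pair_count_law(self, convergent_model):
        scores = screen_combinations(convergent_model, self.library(), SIGS)
        assert len(scores) == 3  # 3 drugs -> 3 unordered pairs

    def test_analytic_pair_efficacy_and_synergy(self, convergent_model):
        scores = {s.drugs: s for s in screen_combinations(convergent_model, self.library(), SIGS)}
        single = 100.0 * math.tanh(0.8)
        pair = scores[("dA", "dB")]
        assert pair.efficacy == pytest.approx(100.0 * math.tanh(1.6), abs=1e-6)
        assert pair.synergy == pytest.approx(100.0 * math.tanh(1.6) - single, abs=1e-6)
        assert pair.synergy > 0  # convergent activation is synergistic under HSA

    def test_null_drug_has_exactly_zero_synergy(self, convergent_model):
        scores = {s.drugs: s for s in screen_combinations(convergent_model, self.library(), SIGS)}
        # pairing with a no-target drug reproduces the single's state exactly
        assert scores[("dA", "dN")].synergy == 0.0
        assert scores[("dB", "dN")].synergy == 0.0

    def test_result_invariant_to_library_order(self, convergent_model):
        fwd = screen_combinations(convergent_model, self.library(), SIGS)
        rev = screen_combinations(convergent_model, list(reversed(self.library())), SIGS)
        assert fwd == rev

    def test_chunking_does_not_change_results(self, convergent_model):
        whole = screen_combinations(convergent_model, self.library(), SIGS)
        tiny = screen_combinations(
            convergent_model, self.library(), SIGS, ScreenConfig(chunk_size=1)
        )
        assert whole == tiny

    def test_singles_match_batch_scores(self, convergent_model):
        singles = score_singles(convergent_model, self.library(), PROTECTION, PAIN)
        state = propagate(convergent_model, {"a": 1.0})
        assert singles["dA"][0] == pytest.approx(efficacy_score(state, PROTECTION), abs=1e-9)
        assert singles["dN"] == (0.0, 0.0)

    def test_duplicate_drug_ids_rejected(self, convergent_model):
        lib = [drug("dA", [("a", 1)]), drug("dA", [("b", 1)])]
        with pytest.raises(ValueError, match="duplicate"):
            screen_combinations(convergent_model, lib, SIGS)

    def test_empty_library_rejected(self, convergent_model):
        with pytest.raises(ValueError, match="empty"):
            screen_combinations(convergent_model, [], SIGS)


class TestThresholds:
    T = Thresholds()

    @pytest.mark.parametrize(
        "eff,adv,syn,expected",
        [
            (23.0, 17.0, 20.1, True),   # pass boundaries inclusive on eff/adv
            (22.9999, 17.0, 25.0, False),
            (23.0, 17.0001, 25.0, False),
            (23.0, 17.0, 20.0, False),  # synergy boundary is strict
            (100.0, 0.0, 20.0001, True),
        ],
    )
    def test_pass_tier_boundaries(self, eff, adv, syn, expected):
        assert self.T.passes(eff, adv, syn) is expected

    @pytest.mark.parametrize(
        "eff,adv,expected",
        [
            (75.0, 1.0, False),   # top efficacy boundary is strict
            (75.0001, 1.0, True),
            (80.0, 2.5, False),   # top adverse boundary is strict
            (80.0, 2.4999, True),
        ],
    )
    def test_top_tier_boundaries(self, eff, adv, expected):
        assert self.T.tops(eff, adv) is expected


class TestFilterCandidates:
    def test_ineligible_pair_excluded_despite_scores(self):
        lib = [drug("dA", [("a", 1)]), drug("dX", [("b", 1)], INELIGIBLE)]
        scores = [CombinationScore(("dA", "dX"), 99.0, 0.0, 50.0)]
        passing, top = filter_candidates(scores, lib)
        assert passing == [] and top == []

    def test_top_is_subset_of_pass_with_flags_set(self):
        lib = [drug(d, [("a", 1)]) for d in ("d1", "d2", "d3")]
        scores = [
            CombinationScore(("d1", "d2"), 80.0, 1.0, 30.0),  # top tier
            CombinationScore(("d1", "d3"), 30.0, 5.0, 25.0),  # pass only
            CombinationScore(("d2", "d3"), 10.0, 5.0, 25.0),  # fails efficacy
        ]
        passing, top = filter_candidates(scores, lib)
        assert [s.drugs for s in passing] == [("d1", "d2"), ("d1", "d3")]
        assert [s.drugs for s in top] == [("d1", "d2")]
        assert passing[0].top_tier and passing[0].pass_tier and passing[0].eligible
        assert not passing[1].top_tier

    def test_ranking_order(self):
        a = CombinationScore(("x", "y"), 50.0, 1.0, 30.0)
        b = CombinationScore(("x", "z"), 50.0, 2.0, 40.0)
        c = CombinationScore(("y", "z"), 60.0, 9.0, 5.0)
        assert sorted([a, b, c], key=ranking_key) == [c, a, b]


class TestExtractMoa:
    def test_clamped_targets_excluded_and_order_invariant(self, convergent_model):
        dA, dB = drug("dA", [("a", 1)]), drug("dB", [("b", 1)])
        fwd = extract_moa(convergent_model, [dA, dB], PROTECTION)
        rev = extract_moa(convergent_model, [dB, dA], PROTECTION)
        assert fwd == rev
        proteins = {e.protein for e in fwd}
        assert "a" not in proteins and "b" not in proteins

    def test_contribution_is_pair_minus_dominant_single(self, convergent_model):
        dA, dB = drug("dA", [("a", 1)]), drug("dB", [("b", 1)])
        (r_entry,) = [e for e in extract_moa(convergent_model, [dA, dB], PROTECTION) if e.protein == "r"]
        expected = math.tanh(1.6) - math.tanh(0.8)
        assert r_entry.contribution == pytest.approx(expected, abs=1e-6)
        assert r_entry.pair_state == pytest.approx(math.tanh(1.6), abs=1e-6)

    def test_top_k_truncates(self, convergent_model):
        dA, dB = drug("dA", [("a", 1)]), drug("dB", [("b", 1)])
        assert len(extract_moa(convergent_model, [dA, dB], PROTECTION, top_k=1)) == 1

    def test_requires_exactly_two_drugs(self, convergent_model):
        with pytest.raises(ValueError, match="two drugs"):
            extract_moa(convergent_model, [drug("dA", [("a", 1)])], PROTECTION)
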