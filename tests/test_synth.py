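"""Synthetic benchmark generator: structure, determinism, planted truth."""

from __future__ import annotations

import numpy as np
import pytest

from netscreen.model import evaluate_restrictions, propagate, propagate_many
from netscreen.screen import efficacy_score, synergy_score
from netscreen.synth import (
    SyntheticScenario,
    generate_condition_seeds,
    generate_dataset,
    generate_drug_library,
    generate_ground_truth_model,
    generate_interactome,
    generate_restrictions,
)
from netscreen.utils import derive_seed


class TestDeriveSeed:
    def test_deterministic_and_label_sensitive(self):
        assert derive_seed(7, "x") == derive_seed(7, "x")
        assert derive_seed(7, "x") != derive_seed(7, "y")
        assert derive_seed(7, "x") != derive_seed(8, "x")

    def test_below_two_to_31(self):
        for lbl in ("a", "b", "interactome:0"):
            assert 0 <= derive_seed(123, lbl) < 2**31


class TestScenario:
    def test_defaults_are_valid(self):
        SyntheticScenario()

    def test_rejects_unknown_fields(self):
        with pytest.raises(Exception):
            SyntheticScenario(not_a_knob=1)

    def test_rejects_overdense_graph(self):
        with pytest.raises(ValueError, match="mean degree"):
            SyntheticScenario(n_nodes=10, mean_degree=10.0)

    def test_rejects_library_too_small_for_planted_roles(self):
        with pytest.raises(ValueError, match="cannot host"):
            SyntheticScenario(n_drugs=5)


class TestGenerateInteractome:
    def test_requested_shape(self):
        sc = SyntheticScenario(seed=4)
        net = generate_interactome(sc)
        assert net.n_nodes == sc.n_nodes
        # edge count is exact up to the few bridging edges
        want = round(sc.n_nodes * sc.mean_degree / 2)
        assert want <= net.n_edges <= want + 5

    def test_exact_inhibitory_count(self):
        sc = SyntheticScenario(seed=4)
        net = generate_interactome(sc)
        n_inhib = sum(1 for *_e, s, _w in net.edges if s == -1)
        assert n_inhib == round(sc.inhibitory_fraction * net.n_edges)

    def test_weights_within_range(self):
        sc = SyntheticScenario(seed=5, weight_range=(0.5, 0.8))
        net = generate_interactome(sc)
        assert all(0.5 <= w <= 0.8 for *_e, w in net.edges)

    def test_largest_component_covers_90_percent(self):
        import networkx as nx

        for seed in range(4):
            net = generate_interactome(SyntheticScenario(seed=seed))
            lwcc = max(nx.weakly_connected_components(net.graph), key=len)
            assert len(lwcc) >= 0.9 * net.n_nodes

    def test_deterministic_per_seed(self):
        a = generate_interactome(SyntheticScenario(seed=6))
        b = generate_interactome(SyntheticScenario(seed=6))
        c = generate_interactome(SyntheticScenario(seed=7))
        assert a == b and a != c


class TestConditionSeeds:
    def test_sizes_and_exact_overlap(self):
        sc = SyntheticScenario(seed=2)
        net = generate_interactome(sc)
        deg, prot = generate_condition_seeds(net, sc)
        size = sc.n_motives * sc.seeds_per_motive
        assert len(deg.proteins) == size and len(prot.proteins) == size
        assert len(deg.proteins & prot.proteins) == round(sc.seed_overlap * size)

    def test_motive_grouping(self):
        sc = SyntheticScenario(seed=2)
        net = generate_interactome(sc)
        deg, _ = generate_condition_seeds(net, sc)
        assert len(deg.motives) == sc.n_motives
        assert all(e.expected_state in (-1, 1) for e in deg.entries)

    def test_zero_disagreement_keeps_overlap_states(self):
        sc = SyntheticScenario(seed=2, disagreement_prob=0.0)
        net = generate_interactome(sc)
        deg, prot = generate_condition_seeds(net, sc)
        deg_state = {e.protein: e.expected_state for e in deg.entries}
        prot_state = {e.protein: e.expected_state for e in prot.entries}
        for p in deg.proteins & prot.proteins:
            assert deg_state[p] == prot_state[p]

    def test_infeasible_seed_count_is_error(self):
        sc = SyntheticScenario(seed=2, n_motives=5, seeds_per_motive=10, seed_overlap=0.0)
        net = generate_interactome(sc)
        with pytest.raises(ValueError, match="seeds per condition|overlap"):
            generate_condition_seeds(net, sc)


class TestGroundTruthAndRestrictions:
    def test_strengths_in_declared_range_and_zero_bias(self, default_dataset):
        gt = default_dataset.ground_truth
        lo, hi = default_dataset.scenario.strength_range
        mags = np.abs(gt.strengths)
        assert np.all((mags >= lo) & (mags <= hi))
        assert np.all(gt.edge_sign * gt.strengths >= 0)
        assert np.all(gt.bias == 0.0)

    def test_noiseless_table_satisfied_by_ground_truth(self, default_dataset):
        sat, _, obj = evaluate_restrictions(
            default_dataset.ground_truth, default_dataset.restrictions
        )
        assert sat == 1.0
        assert obj < 1e-12

    def test_restriction_shapes(self, default_dataset):
        sc = default_dataset.scenario
        table = default_dataset.restrictions
        readouts = set(default_dataset.readouts)
        assert len(table) == sc.n_restrictions
        lo, hi = sc.inputs_per_restriction
        for row in table.rows:
            assert lo <= len(row.inputs) <= hi
            assert not (set(row.inputs) & readouts)  # inputs never clamp read-outs
            assert set(row.outputs) == readouts
            assert row.tolerance == sc.restriction_tolerance
            assert not row.noisy

    def test_noise_flips_whole_rows(self):
        sc_clean = SyntheticScenario(seed=3, restriction_noise=0.0)
        sc_noisy = SyntheticScenario(seed=3, restriction_noise=0.5)
        net_map = generate_dataset(sc_clean).degeneration_map
        gt = generate_ground_truth_model(net_map, sc_clean)
        readouts = generate_dataset(sc_clean).readouts
        clean = generate_restrictions(gt, sc_clean, readouts)
        noisy = generate_restrictions(gt, sc_noisy, readouts)
        flagged = [r for r in noisy.rows if r.noisy]
        assert 0 < len(flagged) < len(noisy.rows)
        clean_by_id = {r.row_id: r for r in clean.rows}
        for row in noisy.rows:
            ref = clean_by_id[row.row_id]
            if row.noisy:
                assert row.outputs == {p: -v for p, v in ref.outputs.items()}
            else:
                assert row.outputs == ref.outputs


class TestDrugLibrary:
    def test_library_size_and_unique_ids(self, default_dataset):
        lib = default_dataset.library
        assert len(lib) == default_dataset.scenario.n_drugs
        assert len({d.drug_id for d in lib}) == len(lib)

    def test_labels_reference_real_drugs(self, default_dataset):
        ids = {d.drug_id for d in default_dataset.library}
        labels = default_dataset.labels
        for a, b in labels["planted_pairs"]:
            assert a in ids and b in ids
        assert set(labels["decoy_pair"]) <= ids
        assert set(labels["single_actives"]) <= ids
        assert set(labels["null_drugs"]) <= ids

    def test_planted_pair_members_fully_eligible(self, default_dataset):
        by_id = {d.drug_id: d for d in default_dataset.library}
        for a, b in default_dataset.labels["planted_pairs"]:
            assert by_id[a].eligibility.all_pass and by_id[b].eligibility.all_pass

    def test_decoy_fails_exactly_one_flag(self, default_dataset):
        by_id = {d.drug_id: d for d in default_dataset.library}
        a, b = default_dataset.labels["decoy_pair"]
        flags = [
            f
            for d in (by_id[a], by_id[b])
            for f in (
                d.eligibility.safe_profile,
                d.eligibility.no_pain_liability,
                d.eligibility.no_known_regen_effect,
                d.eligibility.crosses_bbb,
            )
        ]
        assert flags.count(False) == 1

    def test_null_drugs_target_low_influence_nodes(self, default_dataset):
        by_id = {d.drug_id: d for d in default_dataset.library}
        low = set(default_dataset.labels["low_influence_nodes"])
        for drug_id in default_dataset.labels["null_drugs"]:
            assert {t[0] for t in by_id[drug_id].targets} <= low

    def test_planted_pair_is_synergistic_on_ground_truth(self, default_dataset):
        """Re-verify the plant with the screening scorer, independently."""
        gt = default_dataset.ground_truth
        protection = default_dataset.signatures["protection"]
        by_id = {d.drug_id: d for d in default_dataset.library}
        a, b = default_dataset.labels["planted_pairs"][0]
        sig_a = {t[0]: float(t[1]) for t in by_id[a].targets}
        sig_b = {t[0]: float(t[1]) for t in by_id[b].targets}
        sig_ab = dict(sig_a) | dict(sig_b)
        eff = {
            k: efficacy_score(propagate(gt, s), protection)
            for k, s in (("a", sig_a), ("b", sig_b), ("ab", sig_ab))
        }
        sc = default_dataset.scenario
        assert eff["ab"] >= sc.min_pair_efficacy
        assert eff["a"] <= sc.single_cap and eff["b"] <= sc.single_cap
        assert synergy_score(eff["ab"], eff["a"], eff["b"]) >= sc.synergy_margin


class TestGenerateDataset:
    def test_fully_deterministic(self):
        a = generate_dataset(SyntheticScenario(seed=9))
        b = generate_dataset(SyntheticScenario(seed=9))
        assert a.interactome == b.interactome
        assert a.restrictions.rows == b.restrictions.rows
        assert a.library == b.library
        assert a.labels == b.labels

    def test_readouts_live_on_the_degeneration_map(self, default_dataset):
        nodes = set(default_dataset.degeneration_map.graph.nodes)
        assert set(default_dataset.readouts) <= nodes
        assert len(default_dataset.readouts) == default_dataset.scenario.n_readouts

    def test_signatures_nonempty_and_on_map(self, default_dataset):
        sigs = default_dataset.signatures
        nodes = set(default_dataset.degeneration_map.graph.nodes)
        assert set(sigs["protection"].desired) <= set(default_dataset.readouts)
        assert set(sigs["pain"].desired) <= nodes
        assert all(v in (-1.0, 1.0) for v in sigs["protection"].desired.values())
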