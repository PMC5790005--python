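"""Synthetic benchmark generator with planted ground truth.

Real screens of this kind run on a proprietary curated interactome, a
proteomics-derived truth table, and a curated drug-target library.  This
module emulates all three at desk scale so every downstream stage is
testable: a sparse signed interactome with heavy-tailed out-degree, two
overlapping motive-grouped seed sets, a hidden ground-truth propagation
model from which a (optionally noisy) restriction table is sampled, and
a drug library with planted null drugs, single actives, one or more
synergistic pairs, and an almost-eligible decoy pair.

Every generator is a pure function of its scenario: the same scenario
(including its seed) always produces byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .maps import ConditionMap, ExpansionPolicy, expand_map
from .model import (
    Hyperparams,
    PropagationModel,
    evaluate_restrictions,
    model_from_graph,
    propagate_many,
)
from .screen import PhenotypeSignature
from .types import (
    DrugSignature,
    Eligibility,
    Interactome,
    Restriction,
    RestrictionTable,
    SeedEntry,
    SeedSet,
)
from .utils import derive_seed

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticScenario",
    "SynthesisError",
    "SyntheticDataset",
    "generate_interactome",
    "generate_condition_seeds",
    "generate_ground_truth_model",
    "generate_restrictions",
    "generate_drug_library",
    "generate_dataset",
]


class SynthesisError(RuntimeError):
    """Raised when a planted structure cannot be constructed."""


class SyntheticScenario(BaseModel):
    """All knobs of the synthetic benchmark (strict schema).

    Defaults define the standard desk-scale study conditions: a 45-node
    signed graph at mean degree 4 whose one-hop degeneration map has
    about 30 nodes (the shape of a hub-rich interactome, reduced ~100x
    from the thousands-of-nodes maps such screens use), a noiseless
    40-row truth table, and a 50-drug library (1,225 pairs) with one
    planted synergistic pair, three single actives, and one decoy pair
    failing exactly one eligibility flag.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    seed: int = 0
    # interactome
    n_nodes: int = 45
    mean_degree: float = 4.0
    inhibitory_fraction: float = Field(default=0.25, ge=0.0, le=1.0)
    weight_range: tuple[float, float] = (0.3, 1.0)
    # seeds
    n_motives: int = 3
    seeds_per_motive: int = 3
    seed_overlap: float = Field(default=0.4, ge=0.0, le=1.0)
    disagreement_prob: float = Field(default=0.5, ge=0.0, le=1.0)
    multi_motive_rate: float = Field(default=0.1, ge=0.0, le=1.0)
    # ground-truth model
    strength_range: tuple[float, float] = (0.6, 1.6)
    bias_scale: float = 0.0
    # restrictions
    n_restrictions: int = 40
    inputs_per_restriction: tuple[int, int] = (2, 3)
    restriction_noise: float = Field(default=0.0, ge=0.0, lt=1.0)
    restriction_tolerance: float = 0.5
    n_readouts: int = 6
    # drug library
    n_drugs: int = 50
    targets_per_drug: tuple[int, int] = (1, 2)
    n_planted_pairs: int = 1
    n_single_actives: int = 3
    n_pain_nodes: int = 4
    synergy_margin: float = 25.0
    single_cap: float = 50.0
    min_pair_efficacy: float = 55.0
    max_retries: int = 20

    @model_validator(mode="after")
    def _check(self) -> "SyntheticScenario":
        if self.mean_degree >= self.n_nodes:
            raise ValueError("mean degree must be below the node count")
        if self.targets_per_drug[0] < 0 or self.targets_per_drug[0] > self.targets_per_drug[1]:
            raise ValueError("infeasible targets_per_drug range")
        n_special = 2 * self.n_planted_pairs + 2 + self.n_single_actives
        if self.n_drugs < n_special:
            raise ValueError(
                f"n_drugs={self.n_drugs} cannot host {n_special} planted/decoy/active drugs"
            )
        return self

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(derive_seed(self.seed, stage))


# ---------------------------------------------------------------------------
# Interactome


def _node_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"P{i:0{width}d}" for i in range(n)]


def generate_interactome(scenario: SyntheticScenario) -> Interactome:
    """A directed signed random graph with heavy-tailed out-degree.

    The edge count is fixed to round(n * mean_degree / 2) so the realized
    average links per node equals the request up to the few bridging
    edges added to keep the graph connected-enough (largest weakly
    connected component >= 90% of nodes).  The inhibitory edge count is
    exact: round(inhibitory_fraction * |E|).
    """
    n = scenario.n_nodes
    if n < 10:
        raise ValueError("n_nodes must be >= 10")
    names = _node_names(n)
    n_edges = int(round(n * scenario.mean_degree / 2.0))

    for attempt in range(50):
        rng = np.random.default_rng(derive_seed(scenario.seed, f"interactome:{attempt}"))
        propensity = rng.pareto(2.0, size=n) + 0.5  # hubs-plus-leaves out-degree
        p_src = propensity / propensity.sum()
        pairs: set[tuple[int, int]] = set()
        guard = 0
        while len(pairs) < n_edges:
            batch = max(256, n_edges - len(pairs))
            src = rng.choice(n, size=batch, p=p_src)
            tgt = rng.integers(0, n, size=batch)
            for s, t in zip(src, tgt):
                if s != t:
                    pairs.add((int(s), int(t)))
                    if len(pairs) >= n_edges:
                        break
            guard += 1
            if guard > 10_000:
                raise SynthesisError("edge sampling failed to reach the requested density")
        edge_list = sorted(pairs)

        # bridge smaller weak components into the largest one
        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        g.add_edges_from(edge_list)
        comps = sorted(nx.weakly_connected_components(g), key=lambda c: (-len(c), sorted(c)))
        giant = sorted(comps[0])
        for comp in comps[1:]:
            s = giant[int(rng.integers(0, len(giant)))]
            t = sorted(comp)[int(rng.integers(0, len(comp)))]
            if (s, t) not in pairs and s != t:
                pairs.add((s, t))
        edge_list = sorted(pairs)

        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        g.add_edges_from(edge_list)
        lwcc = max(nx.weakly_connected_components(g), key=len)
        realized = 2.0 * len(edge_list) / n
        if len(lwcc) >= 0.9 * n and abs(realized - scenario.mean_degree) <= 0.15 * scenario.mean_degree:
            break
    else:
        raise SynthesisError("could not generate a connected-enough interactome")

    m = len(edge_list)
    signs = np.ones(m, dtype=int)
    n_inhib = int(round(scenario.inhibitory_fraction * m))
    signs[rng.permutation(m)[:n_inhib]] = -1
    lo, hi = scenario.weight_range
    weights = rng.uniform(lo, hi, size=m)
    return Interactome.from_edges(
        edges=[
            (names[s], names[t], int(signs[k]), float(weights[k]))
            for k, (s, t) in enumerate(edge_list)
        ],
        nodes=names,
    )


# ---------------------------------------------------------------------------
# Seed sets


def generate_condition_seeds(
    interactome: Interactome, scenario: SyntheticScenario
) -> tuple[SeedSet, SeedSet]:
    """Two motive-grouped seed sets with a controlled protein overlap.

    The degeneration-like and protection-like sets share
    round(seed_overlap * size) proteins; overlapping proteins disagree in
    expected state with probability ``disagreement_prob``.
    """
    rng = scenario.rng("seeds")
    size = scenario.n_motives * scenario.seeds_per_motive
    n_overlap = int(round(scenario.seed_overlap * size))
    nodes = interactome.nodes
    if size > len(nodes):
        raise ValueError(f"requested {size} seeds per condition but only {len(nodes)} nodes exist")
    if 2 * size - n_overlap > len(nodes):
        raise ValueError(
            f"overlap {scenario.seed_overlap} impossible: {2 * size - n_overlap} distinct "
            f"proteins needed, {len(nodes)} available"
        )

    order = [nodes[i] for i in rng.permutation(len(nodes))]
    deg_proteins = order[:size]
    prot_proteins = deg_proteins[:n_overlap] + order[size : 2 * size - n_overlap]

    deg_states = {p: int(rng.choice([1, -1])) for p in deg_proteins}
    prot_states: dict[str, int] = {}
    for p in prot_proteins:
        if p in deg_states:
            flip = rng.random() < scenario.disagreement_prob
            prot_states[p] = -deg_states[p] if flip else deg_states[p]
        else:
            prot_states[p] = int(rng.choice([1, -1]))

    def assemble(condition: str, proteins: list[str], states: dict[str, int]) -> SeedSet:
        motive_names = [f"{condition[:3]}_motive_{i + 1}" for i in range(scenario.n_motives)]
        entries = []
        for i, p in enumerate(proteins):
            motive = motive_names[i // scenario.seeds_per_motive]
            entries.append(SeedEntry(protein=p, motive=motive, expected_state=states[p]))
            if scenario.n_motives > 1 and rng.random() < scenario.multi_motive_rate:
                others = [m for m in motive_names if m != motive]
                extra = others[int(rng.integers(0, len(others)))]
                entries.append(SeedEntry(protein=p, motive=extra, expected_state=states[p]))
        return SeedSet(condition=condition, entries=tuple(entries))

    return (
        assemble("degeneration", deg_proteins, deg_states),
        assemble("protection", prot_proteins, prot_states),
    )


# ---------------------------------------------------------------------------
# Ground-truth model and restrictions


def generate_ground_truth_model(
    graph_like,
    scenario: SyntheticScenario,
    hyperparams: Hyperparams | None = None,
    attempt: int = 0,
) -> PropagationModel:
    """A hidden, fully parameterized model over an Interactome or ConditionMap.

    Edge strengths are drawn uniformly inside ``strength_range`` with the
    curated sign; biases are uniform in [-bias_scale, +bias_scale] (zero
    by default, so the unperturbed model rests at the neutral state).
    ``attempt`` selects an alternative draw; ``generate_dataset`` retries
    draws whose truth table fails the stability gate.
    """
    if graph_like.graph.number_of_nodes() == 0:
        raise ValueError("cannot build a ground-truth model on an empty graph")
    stage = "ground_truth" if attempt == 0 else f"ground_truth:{attempt}"
    rng = scenario.rng(stage)
    model = model_from_graph(graph_like, hyperparams or Hyperparams(), seed=0)
    lo, hi = scenario.strength_range
    model.strengths = model.edge_sign * rng.uniform(lo, hi, size=model.n_edges)
    model.bias = rng.uniform(-scenario.bias_scale, scenario.bias_scale, size=model.n_nodes)
    return model


def generate_restrictions(
    ground_truth_model: PropagationModel,
    scenario: SyntheticScenario,
    readout_nodes: Sequence[str],
) -> RestrictionTable:
    """Sample a truth table from the hidden model.

    Each row clamps a sparse random input signature (excluding read-outs)
    and records the ground-truth fixed-point states on the read-out set.
    A restriction is a record of an observed steady phenotype, so input
    signatures on which the dynamics do not converge (sustained
    oscillation instead of a fixed point) are resampled: recording the
    truncated trajectory would plant unlearnable artifacts.  With
    probability ``restriction_noise`` a row's output signs are flipped
    and the row is marked ``noisy`` (in-memory only).
    """
    if scenario.n_restrictions < 1:
        raise ValueError("n_restrictions must be >= 1")
    readouts = sorted(readout_nodes)
    if not readouts:
        raise ValueError("read-out node set is empty")
    missing = set(readouts) - set(ground_truth_model.index)
    if missing:
        raise ValueError(f"read-out node(s) not in the model: {', '.join(sorted(missing))}")

    rng = scenario.rng("restrictions")
    pool = [n for n in ground_truth_model.nodes if n not in set(readouts)]
    lo, hi = scenario.inputs_per_restriction

    def draw_signature() -> dict[str, float]:
        k = int(rng.integers(lo, hi + 1))
        picks = [pool[i] for i in rng.permutation(len(pool))[:k]]
        return {p: float(rng.choice([1.0, -1.0])) for p in picks}

    signatures = [draw_signature() for _ in range(scenario.n_restrictions)]
    X, conv = propagate_many(ground_truth_model, signatures)
    for _ in range(scenario.max_retries):
        if conv.all():
            break
        bad = np.flatnonzero(~conv)
        redraw = [draw_signature() for _ in bad]
        Xr, cr = propagate_many(ground_truth_model, redraw)
        for j, col in enumerate(bad):
            signatures[col] = redraw[j]
            X[:, col] = Xr[:, j]
            conv[col] = bool(cr[j])
    else:
        raise SynthesisError(
            f"could not sample {scenario.n_restrictions} convergent restriction inputs "
            f"after {scenario.max_retries} resampling rounds (oscillatory dynamics)"
        )
    rows = []
    for i, sig in enumerate(signatures):
        outputs = {r: float(X[ground_truth_model.index[r], i]) for r in readouts}
        noisy = rng.random() < scenario.restriction_noise
        if noisy:
            outputs = {r: -v for r, v in outputs.items()}
        rows.append(
            Restriction(
                row_id=f"r{i:04d}",
                inputs=sig,
                outputs=outputs,
                tolerance=scenario.restriction_tolerance,
                noisy=noisy,
            )
        )
    return RestrictionTable(rows=tuple(rows))


# ---------------------------------------------------------------------------
# Drug library with planted structure


def _readout_scores(X: np.ndarray, baseline: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Total absolute read-out displacement per column."""
    return np.abs(X[idx, :] - baseline[idx, None]).sum(axis=0)


def _signature_efficacy(x_readout: np.ndarray, desired: np.ndarray, mask: np.ndarray) -> float:
    """Efficacy (0-100) of read-out states against a desired-direction vector."""
    agree = np.clip(x_readout[mask] / desired[mask], -1.0, 1.0)
    return float(100.0 * max(0.0, agree.mean()))


def generate_drug_library(
    interactome: Interactome,
    ground_truth_model: PropagationModel,
    scenario: SyntheticScenario,
    readout_nodes: Sequence[str],
) -> tuple[list[DrugSignature], dict]:
    """A drug library with planted nulls, single actives, and synergistic pairs.

    Planted pairs are built from complementary upstream branches: each
    member alone moves only part of the read-out set, the joint clamp
    moves it strongly.  The construction is verified by direct simulation
    (pair efficacy must exceed both singles by ``synergy_margin``); if no
    such pair exists for the drawn candidate pool the search retries with
    a fresh sub-seed, and fails hard after ``max_retries``.

    Returns the library plus a labels dictionary: planted pair ids, the
    single-flag-ineligible decoy pair, null drugs, the protective and
    pain phenotype signatures the planted mechanism defines, and the
    bridge nodes expected to dominate the pair's mode of action.
    """
    model = ground_truth_model
    readouts = sorted(readout_nodes)
    if not readouts:
        raise ValueError("read-out node set is empty")
    ro_idx = np.array([model.index[r] for r in readouts])
    n_readouts = len(readouts)
    min_sig = max(2, n_readouts // 2)

    baseline = propagate_many(model, [{}])[0][:, 0]

    # single-clamp states for every (node, sign)
    nodes = model.nodes
    single_sigs = [{v: s} for v in nodes for s in (1.0, -1.0)]
    Xs, _ = propagate_many(model, single_sigs)

    # influence: total absolute downstream displacement, used for null drugs
    disp = np.abs(Xs - baseline[:, None])
    for j, sig in enumerate(single_sigs):
        disp[model.index[next(iter(sig))], j] = 0.0  # the clamped node itself is not "downstream"
    influence = {v: float(disp[:, 2 * i].sum() + disp[:, 2 * i + 1].sum()) for i, v in enumerate(nodes)}
    quartile = float(np.quantile(sorted(influence.values()), 0.25))
    low_influence = sorted(v for v in nodes if influence[v] <= quartile)

    planted: list[tuple[tuple[str, int], tuple[str, int]]] = []
    decoy_targets = None
    protection: dict[str, float] = {}
    pain: dict[str, float] = {}
    for attempt in range(scenario.max_retries):
        rng = scenario.rng(f"drugs:{attempt}")
        result = _plant_pairs(model, scenario, readouts, ro_idx, baseline, Xs, single_sigs, rng, min_sig)
        if result is not None:
            planted, decoy_targets, protection, pain_pool = result
            break
    else:
        raise SynthesisError(
            f"no synergistic pair with margin {scenario.synergy_margin} found on this graph "
            f"after {scenario.max_retries} candidate draws (read-outs: {', '.join(readouts)})"
        )

    rng = scenario.rng("drugs:assemble")
    prot_sig_vec = np.zeros(n_readouts)
    prot_mask = np.zeros(n_readouts, dtype=bool)
    for i, r in enumerate(readouts):
        if r in protection:
            prot_sig_vec[i] = protection[r]
            prot_mask[i] = True

    # single actives: strongest single movers of the protective signature
    single_effs = {}
    for j, sig in enumerate(single_sigs):
        v = next(iter(sig))
        s = int(sig[v])
        single_effs[(v, s)] = _signature_efficacy(Xs[ro_idx, j], prot_sig_vec, prot_mask)
    reserved = {t[0] for pair in planted for t in pair} | {t[0] for t in (decoy_targets or ())}
    active_candidates = sorted(
        ((eff, v, s) for (v, s), eff in single_effs.items() if v not in reserved and v not in protection),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    actives = [(v, s) for _, v, s in active_candidates[: scenario.n_single_actives]]

    # pain signature: nodes the anchor planted pair barely touches
    pair_sig = {t[0]: float(t[1]) for t in planted[0]}
    x_pair = propagate_many(model, [pair_sig])[0][:, 0]
    pain_nodes = sorted(pain_pool, key=lambda v: (abs(float(x_pair[model.index[v]])), v))[
        : scenario.n_pain_nodes
    ]
    for v in pain_nodes:
        x = float(x_pair[model.index[v]])
        pain[v] = -float(np.sign(x)) if abs(x) > 0.05 else float(rng.choice([1.0, -1.0]))

    # assemble drugs: planted pair members, decoy pair, actives, nulls
    all_true = Eligibility(True, True, True, True)
    entries: list[tuple[str, tuple[tuple[str, int], ...], Eligibility]] = []
    pair_roles: list[tuple[str, str]] = []
    for k, (ta, tb) in enumerate(planted):
        entries.append((f"pair{k}_a", (ta,), all_true))
        entries.append((f"pair{k}_b", (tb,), all_true))
        pair_roles.append((f"pair{k}_a", f"pair{k}_b"))
    # decoy: synergistic but ineligible on exactly one flag
    da, db = decoy_targets
    entries.append(("decoy_a", (da,), all_true))
    entries.append(("decoy_b", (db,), Eligibility(True, True, True, crosses_bbb=False)))
    for k, (v, s) in enumerate(actives):
        entries.append((f"active{k}", ((v, s),), all_true))

    n_null = scenario.n_drugs - len(entries)
    lo, hi = scenario.targets_per_drug
    for k in range(n_null):
        t = int(rng.integers(max(lo, 0), hi + 1))
        picks = [low_influence[i] for i in rng.permutation(len(low_influence))[:t]]
        targets = tuple((v, int(rng.choice([1, -1]))) for v in sorted(picks))
        flags = Eligibility(*(bool(rng.random() < 0.85) for _ in range(4)))
        entries.append((f"null{k}", targets, flags))

    # neutral ids in a shuffled order so roles are not readable from names
    perm = rng.permutation(len(entries))
    width = len(str(len(entries)))
    id_map = {entries[int(j)][0]: f"D{i:0{width}d}" for i, j in enumerate(perm)}
    library = sorted(
        (
            DrugSignature(drug_id=id_map[role], targets=targets, eligibility=flags)
            for role, targets, flags in entries
        ),
        key=lambda d: d.drug_id,
    )

    # mode-of-action bridge nodes: where the pair departs from both singles
    moa_nodes = _bridge_nodes(model, planted[0], pair_sig)

    labels = {
        "planted_pairs": [tuple(sorted((id_map[a], id_map[b]))) for a, b in pair_roles],
        "decoy_pair": tuple(sorted((id_map["decoy_a"], id_map["decoy_b"]))),
        "single_actives": sorted(id_map[f"active{k}"] for k in range(len(actives))),
        "null_drugs": sorted(id_map[f"null{k}"] for k in range(n_null)),
        "readouts": readouts,
        "protection_signature": dict(sorted(protection.items())),
        "pain_signature": dict(sorted(pain.items())),
        "moa_nodes": moa_nodes,
        "low_influence_nodes": low_influence,
    }
    return library, labels


def _plant_pairs(model, scenario, readouts, ro_idx, baseline, Xs, single_sigs, rng, min_sig):
    """Search for synergistic target pairs; returns None if the draw fails."""
    n_candidates = 16 + 4 * int(rng.integers(0, 4))  # pool size varies across retries
    strength = _readout_scores(Xs, baseline, ro_idx)
    # best sign per node, ranked by read-out displacement
    per_node: dict[str, tuple[float, int, int]] = {}
    for j, sig in enumerate(single_sigs):
        v = next(iter(sig))
        if v in readouts:
            continue
        s = int(sig[v])
        if v not in per_node or strength[j] > per_node[v][0]:
            per_node[v] = (float(strength[j]), s, j)
    ranked = sorted(per_node.items(), key=lambda kv: (-kv[1][0], kv[0]))
    pool = [kv for kv in ranked if kv[1][0] > 0.1][:n_candidates]
    if len(pool) < 2:
        return None

    cand = [(v, s, j) for v, (stren, s, j) in pool]
    pair_idx = [(a, b) for a in range(len(cand)) for b in range(a + 1, len(cand)) if cand[a][0] != cand[b][0]]
    if not pair_idx:
        return None
    pair_sigs = [{cand[a][0]: float(cand[a][1]), cand[b][0]: float(cand[b][1])} for a, b in pair_idx]
    Xp, _ = propagate_many(model, pair_sigs)

    # pick the anchor pair (largest feasible synergy under its own signature)
    best = None  # (synergy, mask, desired, a, b)
    for k, (a, b) in enumerate(pair_idx):
        x = Xp[ro_idx, k]
        mask = np.abs(x) >= 0.3
        if mask.sum() < min_sig:
            continue
        desired = np.sign(x)
        desired[~mask] = 1.0  # unused entries
        pair_eff = _signature_efficacy(x, desired, mask)
        eff_a = _signature_efficacy(Xs[ro_idx, cand[a][2]], desired, mask)
        eff_b = _signature_efficacy(Xs[ro_idx, cand[b][2]], desired, mask)
        synergy = pair_eff - max(eff_a, eff_b)
        if (
            pair_eff >= scenario.min_pair_efficacy
            and eff_a <= scenario.single_cap
            and eff_b <= scenario.single_cap
            and synergy >= scenario.synergy_margin
        ):
            if best is None or synergy > best[0]:
                best = (synergy, mask, desired, a, b)
    if best is None:
        return None

    _, mask, desired, a_best, b_best = best
    protection = {readouts[i]: float(desired[i]) for i in range(len(readouts)) if mask[i]}
    prot_vec = np.zeros(len(readouts))
    prot_vec[mask] = desired[mask]

    def as_targets(a: int, b: int):
        return ((cand[a][0], int(cand[a][1])), (cand[b][0], int(cand[b][1])))

    # every other pair, re-scored against the anchor's fixed signature
    others = []
    for k, (a, b) in enumerate(pair_idx):
        if (a, b) == (a_best, b_best):
            continue
        pair_eff = _signature_efficacy(Xp[ro_idx, k], prot_vec, mask)
        eff_a = _signature_efficacy(Xs[ro_idx, cand[a][2]], prot_vec, mask)
        eff_b = _signature_efficacy(Xs[ro_idx, cand[b][2]], prot_vec, mask)
        syn = pair_eff - max(eff_a, eff_b)
        if pair_eff >= scenario.min_pair_efficacy and syn >= scenario.synergy_margin:
            others.append((syn, a, b))
    others.sort(key=lambda t: (-t[0], t[1], t[2]))

    planted = [as_targets(a_best, b_best)]
    used = {cand[a_best][0], cand[b_best][0]}
    for syn, a, b in others:
        if len(planted) >= scenario.n_planted_pairs:
            break
        if {cand[a][0], cand[b][0]} & used:
            continue
        planted.append(as_targets(a, b))
        used |= {cand[a][0], cand[b][0]}
    if len(planted) < scenario.n_planted_pairs:
        return None

    # decoy: the next disjoint feasible pair, else a target copy of the anchor
    decoy = planted[0]  # copy fallback: same targets under new drug ids
    for syn, a, b in others:
        if {cand[a][0], cand[b][0]} & used:
            continue
        decoy = as_targets(a, b)
        break

    pain_pool = [
        v
        for v in model.nodes
        if v not in protection and v not in {t[0] for pair in planted for t in pair} and v not in {t[0] for t in decoy}
    ]
    if len(pain_pool) < scenario.n_pain_nodes:
        return None
    return planted, decoy, protection, pain_pool


def _bridge_nodes(model, pair_targets, pair_sig, threshold: float = 0.2) -> list[str]:
    """Nodes where the pair's ground-truth state departs from both singles."""
    ta, tb = pair_targets
    sig_a, sig_b = {ta[0]: float(ta[1])}, {tb[0]: float(tb[1])}
    X, _ = propagate_many(model, [pair_sig, sig_a, sig_b])
    out = []
    for i, node in enumerate(model.nodes):
        if node in pair_sig:
            continue
        xa, xb = float(X[i, 1]), float(X[i, 2])
        dominant = xa if abs(xa) >= abs(xb) else xb
        if abs(float(X[i, 0]) - dominant) >= threshold:
            out.append(node)
    return sorted(out)


# ---------------------------------------------------------------------------
# End-to-end dataset


@dataclass(frozen=True)
class SyntheticDataset:
    """Everything one scenario generates, wired consistently."""

    scenario: SyntheticScenario
    interactome: Interactome
    degeneration_seeds: SeedSet
    protection_seeds: SeedSet
    degeneration_map: ConditionMap
    protection_map: ConditionMap
    ground_truth: PropagationModel
    readouts: tuple[str, ...]
    restrictions: RestrictionTable
    library: tuple[DrugSignature, ...]
    labels: dict

    @property
    def signatures(self) -> dict[str, PhenotypeSignature]:
        return {
            "protection": PhenotypeSignature("protection", self.labels["protection_signature"]),
            "pain": PhenotypeSignature("pain", self.labels["pain_signature"]),
        }


def _pick_readouts(
    deg_map: ConditionMap, prot_seeds: SeedSet, scenario: SyntheticScenario, attempt: int
) -> list[str]:
    """Read-outs: protection seeds on the degeneration map when possible.

    Only nodes with incoming edges qualify (a node nothing feeds cannot
    respond to a perturbation).
    """
    rng = np.random.default_rng(derive_seed(scenario.seed, f"readouts:{attempt}"))
    g = deg_map.graph
    feedable = {n for n in g.nodes if g.in_degree(n) > 0}
    preferred = sorted(prot_seeds.proteins & feedable)
    rest = sorted(feedable - set(preferred))
    order = [preferred[i] for i in rng.permutation(len(preferred))] + [
        rest[i] for i in rng.permutation(len(rest))
    ]
    if len(order) < scenario.n_readouts:
        raise SynthesisError("not enough feedable nodes for the requested read-out set")
    return sorted(order[: scenario.n_readouts])


def _stable_truth_table(
    model: PropagationModel, table: RestrictionTable, scenario: SyntheticScenario
) -> bool:
    """True when the clean table survives tiny ground-truth perturbations.

    A well-posed truth table records stable fixed points: a model whose
    strengths are jittered by a hair (sigma 0.05, small against the
    0.6-1.6 strength range) must still satisfy essentially every row.
    Draws near a bifurcation fail this (their "outputs" are fragile
    trajectory artifacts, unlearnable by any fitting procedure).
    """
    rng = scenario.rng("gt_stability")
    bound = model.hyperparams.strength_bound
    for _ in range(2):
        probe = model.copy()
        probe.strengths = model.edge_sign * np.clip(
            np.abs(model.strengths) + rng.normal(0.0, 0.05, size=model.n_edges), 0.0, bound
        )
        sat, _, _ = evaluate_restrictions(probe, table)
        if sat < 0.95:
            return False
    return True


def generate_dataset(
    scenario: SyntheticScenario, policy: ExpansionPolicy = ExpansionPolicy(k=1)
) -> SyntheticDataset:
    """Run every generator in pipeline order on one scenario."""
    interactome = generate_interactome(scenario)
    deg_seeds, prot_seeds = generate_condition_seeds(interactome, scenario)
    deg_map = expand_map(interactome, deg_seeds, policy)
    prot_map = expand_map(interactome, prot_seeds, policy)

    clean_scenario = scenario.model_copy(update={"restriction_noise": 0.0})
    last_error: Exception | None = None
    done = False
    for gt_attempt in range(scenario.max_retries):
        ground_truth = generate_ground_truth_model(deg_map, scenario, attempt=gt_attempt)
        for attempt in range(5):
            readouts = _pick_readouts(deg_map, prot_seeds, scenario, attempt)
            try:
                clean = generate_restrictions(ground_truth, clean_scenario, readouts)
            except SynthesisError as exc:
                last_error = exc
                break  # too few convergent inputs: redraw the ground truth
            if not _stable_truth_table(ground_truth, clean, scenario):
                last_error = SynthesisError(
                    f"ground-truth draw {gt_attempt} yields an unstable truth table"
                )
                break  # a fresh read-out set will not stabilize the dynamics
            try:
                library, labels = generate_drug_library(interactome, ground_truth, scenario, readouts)
            except SynthesisError as exc:
                last_error = exc
                continue
            done = True
            break
        if done:
            break
    else:
        raise SynthesisError(
            f"no stable ground truth with a plantable pair after {scenario.max_retries} draws: {last_error}"
        )

    restrictions = generate_restrictions(ground_truth, scenario, readouts)
    return SyntheticDataset(
        scenario=scenario,
        interactome=interactome,
        degeneration_seeds=deg_seeds,
        protection_seeds=prot_seeds,
        degeneration_map=deg_map,
        protection_map=prot_map,
        ground_truth=ground_truth,
        readouts=tuple(readouts),
        restrictions=restrictions,
        library=tuple(library),
        labels=labels,
    )
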