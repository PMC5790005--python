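"""Pairwise in-silico drug screening on a trained propagation model.

Every drug and every unordered drug pair is applied to the degeneration
model as a clamp perturbation.  The resulting fixed-point state is scored
against two phenotype signatures: a protective signature (efficacy, the
predicted regenerative benefit) and an adverse signature (the predicted
relation to neuropathic pain).  Synergy follows the highest-single-agent
convention: the pair's efficacy minus the better of its two singles, in
percentage points.  Candidate selection applies two threshold tiers plus
the four eligibility criteria (safety profile, no pain liability, no
known regeneration effect, blood-brain-barrier passage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import PropagationModel, propagate, propagate_many
from .types import DrugSignature

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeSignature",
    "CombinationScore",
    "Thresholds",
    "ScreenConfig",
    "drug_input_signature",
    "efficacy_score",
    "adverse_score",
    "synergy_score",
    "score_singles",
    "screen_combinations",
    "filter_candidates",
    "extract_moa",
    "ranking_key",
]


@dataclass(frozen=True)
class PhenotypeSignature:
    """Desired node states (with weights) defining a phenotype read-out."""

    label: str
    desired: Mapping[str, float]
    weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.desired:
            raise ValueError(f"signature {self.label!r} is empty")
        weights = dict(self.weights) if self.weights else {p: 1.0 for p in self.desired}
        for p, d in self.desired.items():
            if not (-1.0 <= d <= 1.0) or d == 0.0:
                raise ValueError(f"signature {self.label!r}: desired state for {p!r} must be nonzero in [-1, +1]")
            if weights.get(p, 0.0) < 0.0:
                raise ValueError(f"signature {self.label!r}: negative weight for {p!r}")
        if sum(weights.get(p, 0.0) for p in self.desired) <= 0.0:
            raise ValueError(f"signature {self.label!r}: weights must sum to > 0")
        object.__setattr__(self, "desired", dict(sorted(self.desired.items())))
        object.__setattr__(self, "weights", {p: weights.get(p, 0.0) for p in self.desired})


@dataclass(frozen=True)
class Thresholds:
    """Candidate-selection thresholds, two tiers.

    Pass tier: efficacy >= 23 (inclusive), adverse <= 17 (inclusive),
    synergy > 20 (strict).  Top tier: efficacy > 75 (strict) and
    adverse < 2.5 (strict).  Inclusiveness of each boundary is
    overridable.
    """

    pass_efficacy: float = 23.0
    pass_adverse: float = 17.0
    pass_synergy: float = 20.0
    top_efficacy: float = 75.0
    top_adverse: float = 2.5
    pass_efficacy_inclusive: bool = True
    pass_adverse_inclusive: bool = True
    pass_synergy_inclusive: bool = False
    top_efficacy_inclusive: bool = False
    top_adverse_inclusive: bool = False

    def passes(self, efficacy: float, adverse: float, synergy: float) -> bool:
        ok_e = efficacy >= self.pass_efficacy if self.pass_efficacy_inclusive else efficacy > self.pass_efficacy
        ok_a = adverse <= self.pass_adverse if self.pass_adverse_inclusive else adverse < self.pass_adverse
        ok_s = synergy >= self.pass_synergy if self.pass_synergy_inclusive else synergy > self.pass_synergy
        return ok_e and ok_a and ok_s

    def tops(self, efficacy: float, adverse: float) -> bool:
        ok_e = efficacy >= self.top_efficacy if self.top_efficacy_inclusive else efficacy > self.top_efficacy
        ok_a = adverse <= self.top_adverse if self.top_adverse_inclusive else adverse < self.top_adverse
        return ok_e and ok_a


@dataclass(frozen=True)
class ScreenConfig:
    dose: float = 1.0
    chunk_size: int = 512

    def __post_init__(self) -> None:
        if not (0.0 < self.dose <= 1.0):
            raise ValueError("dose must be in (0, 1]")


@dataclass(frozen=True)
class CombinationScore:
    """Scores for one drug or one unordered drug pair.

    The pair is stored in canonical lexicographic order, so scoring
    (A, B) and (B, A) yields identical objects.  Synergy may be negative
    (a pair worse than its best single is kept, not clipped).
    """

    drugs: tuple[str, ...]
    efficacy: float
    adverse: float
    synergy: float
    eligible: bool = False
    pass_tier: bool = False
    top_tier: bool = False

    def __post_init__(self) -> None:
        if len(self.drugs) not in (1, 2):
            raise ValueError("a score covers one drug or one unordered pair")
        object.__setattr__(self, "drugs", tuple(sorted(self.drugs)))


def ranking_key(score: CombinationScore):
    """Total order: efficacy desc, adverse asc, synergy desc, canonical ids."""
    return (-score.efficacy, score.adverse, -score.synergy, score.drugs)


# ---------------------------------------------------------------------------
# Signatures and elementary scores


def drug_input_signature(
    drugs: Sequence[DrugSignature], model: PropagationModel, dose: float = 1.0
) -> tuple[dict[str, float], float]:
    """Clamp signature of one drug or a pair: union of target clamps.

    Each on-map target is clamped at action sign x dose; when both drugs
    hit the same target the contributions are summed and clipped to
    [-1, +1] (opposing actions cancel).  Off-map targets are skipped;
    the second return value is the on-map coverage of the target union.
    """
    if not (1 <= len(drugs) <= 2):
        raise ValueError("expected one or two drug signatures")
    raw: dict[str, float] = {}
    total = 0
    on_map = 0
    for drug in drugs:
        for protein, action in drug.targets:
            total += 1
            if protein not in model.index:
                continue
            on_map += 1
            raw[protein] = raw.get(protein, 0.0) + action * dose
    signature = {p: float(np.clip(v, -1.0, 1.0)) for p, v in sorted(raw.items())}
    coverage = on_map / total if total else 0.0
    if total and not signature:
        logger.warning(
            "drug(s) %s: no target is on the model's map (coverage 0)",
            "+".join(d.drug_id for d in drugs),
        )
    return signature, coverage


def _agreement(state: Mapping[str, float], signature: PhenotypeSignature) -> float:
    """Weighted directional agreement in [-1, +1].

    Per protein: state/desired, clipped to [-1, +1], so hitting the
    desired value exactly scores 1 and overshooting is not rewarded.
    """
    num = 0.0
    den = 0.0
    for protein, desired in signature.desired.items():
        if protein not in state:
            raise KeyError(f"state does not cover signature protein {protein!r}")
        w = signature.weights[protein]
        num += w * float(np.clip(state[protein] / desired, -1.0, 1.0))
        den += w
    return num / den


def _state_values(state) -> Mapping[str, float]:
    return state.values if hasattr(state, "values") and not isinstance(state, dict) else state


def efficacy_score(state, protection_signature: PhenotypeSignature) -> float:
    """Predicted benefit: 100 x max(0, weighted agreement with protection)."""
    return 100.0 * max(0.0, _agreement(_state_values(state), protection_signature))


def adverse_score(state, pain_signature: PhenotypeSignature) -> float:
    """Predicted adverse liability, same contract against the pain signature."""
    return 100.0 * max(0.0, _agreement(_state_values(state), pain_signature))


def synergy_score(pair_efficacy: float, efficacy_a: float, efficacy_b: float) -> float:
    """Highest-single-agent synergy: pair minus the best single, in points."""
    return pair_efficacy - max(efficacy_a, efficacy_b)


# ---------------------------------------------------------------------------
# Exhaustive screening


def _batched_scores(
    model: PropagationModel,
    signatures: Sequence[Mapping[str, float]],
    protection: PhenotypeSignature,
    pain: PhenotypeSignature,
) -> tuple[np.ndarray, np.ndarray]:
    """Efficacy/adverse arrays for a batch of input signatures."""
    X, _ = propagate_many(model, signatures)
    prot_idx = np.array([model.index[p] for p in protection.desired])
    prot_des = np.array([protection.desired[p] for p in protection.desired])
    prot_w = np.array([protection.weights[p] for p in protection.desired])
    pain_idx = np.array([model.index[p] for p in pain.desired])
    pain_des = np.array([pain.desired[p] for p in pain.desired])
    pain_w = np.array([pain.weights[p] for p in pain.desired])

    def score(idx, des, w):
        agree = np.clip(X[idx, :] / des[:, None], -1.0, 1.0)
        return 100.0 * np.maximum(0.0, (w[:, None] * agree).sum(axis=0) / w.sum())

    return score(prot_idx, prot_des, prot_w), score(pain_idx, pain_des, pain_w)


def score_singles(
    model: PropagationModel,
    library: Sequence[DrugSignature],
    protection: PhenotypeSignature,
    pain: PhenotypeSignature,
    config: ScreenConfig = ScreenConfig(),
) -> dict[str, tuple[float, float]]:
    """Efficacy and adverse score of every single drug."""
    sigs = [drug_input_signature([d], model, config.dose)[0] for d in library]
    eff, adv = _batched_scores(model, sigs, protection, pain)
    return {d.drug_id: (float(eff[i]), float(adv[i])) for i, d in enumerate(library)}


def screen_combinations(
    model: PropagationModel,
    library: Sequence[DrugSignature],
    signatures: Mapping[str, PhenotypeSignature],
    config: ScreenConfig = ScreenConfig(),
) -> list[CombinationScore]:
    """Score all n singles, then all n(n-1)/2 unordered pairs.

    ``signatures`` must carry "protection" and "pain".  Pair efficacy and
    adverse scores come from the pair's propagated state; synergy from the
    pair and single efficacies.  Eligibility (all four flags on both
    drugs) is recorded per pair; threshold tiers are applied by
    ``filter_candidates``.
    """
    if not library:
        raise ValueError("empty drug library")
    ids = [d.drug_id for d in library]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate drug ids in library")
    protection, pain = signatures["protection"], signatures["pain"]
    order = np.argsort(ids)
    library = [library[i] for i in order]  # canonical order => canonical pairs

    singles = score_singles(model, library, protection, pain, config)
    logger.info("screened %d single drugs", len(library))

    pairs = list(combinations(range(len(library)), 2))
    scores: list[CombinationScore] = []
    for start in range(0, len(pairs), config.chunk_size):
        chunk = pairs[start : start + config.chunk_size]
        sigs = [drug_input_signature([library[i], library[j]], model, config.dose)[0] for i, j in chunk]
        eff, adv = _batched_scores(model, sigs, protection, pain)
        for k, (i, j) in enumerate(chunk):
            a, b = library[i], library[j]
            scores.append(
                CombinationScore(
                    drugs=(a.drug_id, b.drug_id),
                    efficacy=float(eff[k]),
                    adverse=float(adv[k]),
                    synergy=synergy_score(float(eff[k]), singles[a.drug_id][0], singles[b.drug_id][0]),
                    eligible=a.eligibility.all_pass and b.eligibility.all_pass,
                )
            )
        logger.info("screened %d / %d pairs", min(start + config.chunk_size, len(pairs)), len(pairs))
    return scores


def filter_candidates(
    scores: Iterable[CombinationScore],
    library: Sequence[DrugSignature],
    thresholds: Thresholds = Thresholds(),
) -> tuple[list[CombinationScore], list[CombinationScore]]:
    """Apply eligibility plus the two threshold tiers and rank.

    Returns (pass list, top list): the pass list holds eligible scores
    meeting the pass tier; the top list is its subset also meeting the
    top tier.  Both are sorted by the ranking total order.
    """
    flags = {d.drug_id: d.eligibility.all_pass for d in library}
    passing: list[CombinationScore] = []
    top: list[CombinationScore] = []
    for s in scores:
        eligible = all(flags.get(d, False) for d in s.drugs)
        if not eligible:
            continue
        if not thresholds.passes(s.efficacy, s.adverse, s.synergy):
            continue
        is_top = thresholds.tops(s.efficacy, s.adverse)
        s = replace(s, eligible=True, pass_tier=True, top_tier=is_top)
        passing.append(s)
        if is_top:
            top.append(s)
    passing.sort(key=ranking_key)
    top.sort(key=ranking_key)
    return passing, top


# ---------------------------------------------------------------------------
# Mode-of-action extraction


@dataclass(frozen=True)
class MoaEntry:
    protein: str
    contribution: float
    pair_state: float
    state_a: float
    state_b: float


def extract_moa(
    model: PropagationModel,
    pair: Sequence[DrugSignature],
    protection_signature: PhenotypeSignature,
    top_k: int = 20,
    dose: float = 1.0,
) -> list[MoaEntry]:
    """Rank non-clamped nodes by their synergy contribution.

    For each node not clamped by the pair, the contribution is
    |state under the pair - dominant single state| where the dominant
    single state is whichever of the two single-drug states has the
    larger magnitude (the additive expectation under the
    highest-single-agent convention).  Nodes where the combination does
    something neither single does rank highest; the result is invariant
    to drug order.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if len(pair) != 2:
        raise ValueError("extract_moa expects exactly two drugs")
    a, b = sorted(pair, key=lambda d: d.drug_id)
    sig_pair, _ = drug_input_signature([a, b], model, dose)
    sig_a, _ = drug_input_signature([a], model, dose)
    sig_b, _ = drug_input_signature([b], model, dose)
    X, _ = propagate_many(model, [sig_pair, sig_a, sig_b])
    entries: list[MoaEntry] = []
    for i, node in enumerate(model.nodes):
        if node in sig_pair:
            continue
        xa, xb = float(X[i, 1]), float(X[i, 2])
        dominant = xa if abs(xa) >= abs(xb) else xb
        entries.append(
            MoaEntry(
                protein=node,
                contribution=abs(float(X[i, 0]) - dominant),
                pair_state=float(X[i, 0]),
                state_a=xa,
                state_b=xb,
            )
        )
    entries.sort(key=lambda e: (-e.contribution, e.protein))
    return entries[:top_k]
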