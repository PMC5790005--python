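"""Shared fixtures: tiny hand-built graphs and seeded synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from netscreen.maps import ConditionMap, ExpansionPolicy, expand_map
from netscreen.model import Hyperparams, PropagationModel, build_model
from netscreen.synth import SyntheticScenario, generate_dataset
from netscreen.types import Interactome, SeedEntry, SeedSet


@pytest.fixture
def chain_interactome() -> Interactome:
    """A -> B -> C -> D, all activating, weight 1."""
    return Interactome.from_edges(
        [("A", "B", 1, 1.0), ("B", "C", 1, 1.0), ("C", "D", 1, 1.0)]
    )


@pytest.fixture
def star_interactome() -> Interactome:
    """Hub H with leaves at weights 0.4, 0.6, 0.7."""
    return Interactome.from_edges(
        [("H", "L1", 1, 0.4), ("H", "L2", 1, 0.6), ("H", "L3", -1, 0.7)]
    )


def make_seed_set(condition: str, proteins: dict[str, int], motive: str = "m1") -> SeedSet:
    return SeedSet(
        condition=condition,
        entries=tuple(
            SeedEntry(protein=p, motive=motive, expected_state=s) for p, s in proteins.items()
        ),
    )


def chain_model(strengths: list[float], hyperparams: Hyperparams | None = None) -> PropagationModel:
    """n-node chain x0 -> x1 -> ... with given edge strengths (signs inferred)."""
    n = len(strengths) + 1
    return PropagationModel(
        nodes=[f"x{i}" for i in range(n)],
        edge_src=np.arange(n - 1),
        edge_tgt=np.arange(1, n),
        edge_sign=np.sign(strengths).astype(int),
        strengths=np.array(strengths, dtype=float),
        bias=np.zeros(n),
        hyperparams=hyperparams or Hyperparams(),
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded instance of the default synthetic scenario."""
    return generate_dataset(SyntheticScenario(seed=1))


@pytest.fixture(scope="session")
def small_map(default_dataset) -> ConditionMap:
    return default_dataset.degeneration_map
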