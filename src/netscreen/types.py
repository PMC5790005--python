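"""Core domain containers shared across the pipeline.

All containers validate their invariants at construction time and keep a
canonical internal ordering so that loading the same data in any row order
produces an identical in-memory object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "Interactome",
    "SeedEntry",
    "SeedSet",
    "Eligibility",
    "DrugSignature",
    "Restriction",
    "RestrictionTable",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a container's invariants are violated."""


@dataclass(frozen=True)
class Interactome:
    """A signed, weighted, directed protein functional-relationship graph.

    Edges carry a curated sign (+1 activating, -1 inhibiting) and a
    confidence weight in (0, 1].  The graph is the substrate over which
    condition-specific maps are built and signals are propagated.
    """

    graph: nx.DiGraph
    directed: bool = True

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop on {u!r}")
            sign = data.get("sign")
            weight = data.get("weight")
            if sign not in (1, -1):
                raise ValidationError(f"edge {u!r}->{v!r}: sign {sign!r} not in {{+1, -1}}")
            if not isinstance(weight, (int, float)) or not (0.0 < weight <= 1.0):
                raise ValidationError(f"edge {u!r}->{v!r}: weight {weight!r} not in (0, 1]")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int, float]],
        nodes: Iterable[str] = (),
        directed: bool = True,
    ) -> "Interactome":
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for src, tgt, sign, weight in edges:
            if g.has_edge(src, tgt):
                raise ValidationError(f"duplicate edge {src!r}->{tgt!r}")
            g.add_edge(src, tgt, sign=int(sign), weight=float(weight))
        return cls(graph=g, directed=directed)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, int, float]]:
        return sorted(
            (u, v, d["sign"], d["weight"]) for u, v, d in self.graph.edges(data=True)
        )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return (
            self.directed == other.directed
            and self.nodes == other.nodes
            and self.edges == other.edges
        )


@dataclass(frozen=True)
class SeedEntry:
    protein: str
    motive: str
    expected_state: int  # +1 or -1

    def __post_init__(self) -> None:
        if not self.protein:
            raise ValidationError("seed entry with empty protein id")
        if not self.motive:
            raise ValidationError(f"seed {self.protein!r} names a blank motive")
        if self.expected_state not in (1, -1):
            raise ValidationError(
                f"seed {self.protein!r}: expected_state {self.expected_state!r} not in {{+1, -1}}"
            )


@dataclass(frozen=True)
class SeedSet:
    """Curated seed proteins for one condition, grouped into motives.

    A protein may belong to several motives (each membership is one entry)
    but appears at most once per motive.
    """

    condition: str
    entries: tuple[SeedEntry, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            key = (e.protein, e.motive)
            if key in seen:
                raise ValidationError(
                    f"duplicate (protein, motive) pair {key!r} in condition {self.condition!r}"
                )
            seen.add(key)
        object.__setattr__(self, "entries", tuple(sorted(self.entries, key=lambda e: (e.protein, e.motive))))

    @property
    def proteins(self) -> set[str]:
        return {e.protein for e in self.entries}

    @property
    def motives(self) -> set[str]:
        return {e.motive for e in self.entries}

    def expected_state(self, protein: str) -> int:
        """The expected state of a protein (identical across its motives)."""
        states = {e.expected_state for e in self.entries if e.protein == protein}
        if not states:
            raise KeyError(protein)
        if len(states) > 1:
            raise ValidationError(f"conflicting expected states for {protein!r}")
        return states.pop()


@dataclass(frozen=True)
class Eligibility:
    """The four curation criteria a screened drug must satisfy."""

    safe_profile: bool
    no_pain_liability: bool
    no_known_regen_effect: bool
    crosses_bbb: bool

    @property
    def all_pass(self) -> bool:
        return (
            self.safe_profile
            and self.no_pain_liability
            and self.no_known_regen_effect
            and self.crosses_bbb
        )


@dataclass(frozen=True)
class DrugSignature:
    """A drug's target set (protein, action sign) plus eligibility metadata.

    An empty target list is legal (a null drug perturbs nothing).
    """

    drug_id: str
    targets: tuple[tuple[str, int], ...]
    eligibility: Eligibility

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for protein, action in self.targets:
            if action not in (1, -1):
                raise ValidationError(
                    f"drug {self.drug_id!r}: action {action!r} for {protein!r} not in {{+1, -1}}"
                )
            if protein in seen:
                raise ValidationError(f"drug {self.drug_id!r}: duplicate target {protein!r}")
            seen.add(protein)
        object.__setattr__(self, "targets", tuple(sorted(self.targets)))

    @property
    def target_proteins(self) -> set[str]:
        return {p for p, _ in self.targets}


def _check_unit_interval(values: Mapping[str, float], what: str, row_id: str) -> None:
    for protein, value in values.items():
        if not (-1.0 <= value <= 1.0):
            raise ValidationError(
                f"restriction {row_id!r}: {what} value {value!r} for {protein!r} outside [-1, +1]"
            )


@dataclass(frozen=True)
class Restriction:
    """One truth-table row: an input perturbation and the required output.

    ``noisy`` marks rows whose outputs were corrupted by the synthetic
    generator; it is in-memory metadata for test use and is not serialized.
    """

    row_id: str
    inputs: Mapping[str, float]
    outputs: Mapping[str, float]
    tolerance: float = 0.5
    noisy: bool = False

    def __post_init__(self) -> None:
        _check_unit_interval(self.inputs, "input", self.row_id)
        _check_unit_interval(self.outputs, "output", self.row_id)
        if not (0.0 < self.tolerance <= 2.0):
            raise ValidationError(f"restriction {self.row_id!r}: tolerance {self.tolerance!r} out of range")
        object.__setattr__(self, "inputs", dict(sorted(self.inputs.items())))
        object.__setattr__(self, "outputs", dict(sorted(self.outputs.items())))


@dataclass(frozen=True)
class RestrictionTable:
    """The truth table: every trained model must satisfy these rows."""

    rows: tuple[Restriction, ...]

    def __post_init__(self) -> None:
        ids = [r.row_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate restriction row ids")
        object.__setattr__(self, "rows", tuple(sorted(self.rows, key=lambda r: r.row_id)))

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def proteins(self) -> set[str]:
        out: set[str] = set()
        for r in self.rows:
            out.update(r.inputs)
            out.update(r.outputs)
        return out

    def subset(self, row_ids: Sequence[str]) -> "RestrictionTable":
        wanted = set(row_ids)
        return RestrictionTable(rows=tuple(r for r in self.rows if r.row_id in wanted))
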