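"""Readers and writers for every external table the pipeline touches.

All tables are UTF-8, tab-separated, with a mandatory header row; lines
starting with ``#`` are comments.  Parsing is strict: malformed rows fail
hard with the offending line number.  Writing is deterministic (canonical
row and column order, fixed float formatting) so that write-then-read is
an identity up to the printed precision.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .types import (
    DrugSignature,
    Eligibility,
    Interactome,
    Restriction,
    RestrictionTable,
    SeedEntry,
    SeedSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

_SIGN_TOKENS = {"+": 1, "-": -1, "+1": 1, "-1": -1, "1": 1}
_BOOL_TOKENS = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}

# weights and states are written at six decimals; percentages at four
WEIGHT_FMT = "{:.6f}"
PCT_FMT = "{:.4f}"


class FormatError(ValueError):
    """Raised on malformed input tables, naming the line number."""


def _rows(path: str | Path, n_fields: int, header: Sequence[str]) -> Iterable[tuple[int, list[str]]]:
    """Yield (line_number, fields) for each data row after validating the header."""
    path = Path(path)
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if [f.strip() for f in fields] != list(header):
                    raise FormatError(
                        f"{path}:{lineno}: expected header {list(header)!r}, got {fields!r}"
                    )
                header_seen = True
                continue
            if len(fields) != n_fields:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_fields} tab-separated fields, got {len(fields)}"
                )
            yield lineno, [f.strip() for f in fields]
    # a completely empty file is legal for some tables; callers decide


def _parse_sign(token: str, path: Path, lineno: int) -> int:
    if token not in _SIGN_TOKENS:
        raise FormatError(f"{path}:{lineno}: unknown sign token {token!r}")
    return _SIGN_TOKENS[token]


def _parse_float(token: str, path: Path, lineno: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: bad {what} {token!r}") from None


def _parse_bool(token: str, path: Path, lineno: int, what: str) -> bool:
    key = token.lower()
    if key not in _BOOL_TOKENS:
        raise FormatError(f"{path}:{lineno}: bad boolean {what} {token!r}")
    return _BOOL_TOKENS[key]


# ---------------------------------------------------------------------------
# Interactome


def read_interactome(
    path: str | Path,
    dialect: str = "edge",
    relation_signs: Mapping[str, int] | None = None,
) -> Interactome:
    """Load a signed interactome from an edge table.

    Dialects:
      * ``edge`` — ``source<TAB>target<TAB>sign<TAB>weight``
      * ``sif``  — ``source<TAB>relation<TAB>target``; ``relation_signs``
        maps relation names to +1/-1, and every edge gets weight 1.0.

    Duplicate (source, target) rows with equal sign merge by maximum
    weight; duplicates with opposite signs are a hard error.
    """
    path = Path(path)
    edges: dict[tuple[str, str], tuple[int, float]] = {}
    merged = 0
    if dialect == "edge":
        for lineno, (src, tgt, sign_tok, weight_tok) in _rows(
            path, 4, ("source", "target", "sign", "weight")
        ):
            sign = _parse_sign(sign_tok, path, lineno)
            weight = _parse_float(weight_tok, path, lineno, "weight")
            merged += _add_edge(edges, src, tgt, sign, weight, path, lineno)
    elif dialect == "sif":
        if relation_signs is None:
            raise ValueError("sif dialect requires a relation->sign lexicon")
        for lineno, (src, rel, tgt) in _rows(path, 3, ("source", "relation", "target")):
            if rel not in relation_signs:
                raise FormatError(f"{path}:{lineno}: unknown relation {rel!r}")
            merged += _add_edge(edges, src, tgt, int(relation_signs[rel]), 1.0, path, lineno)
    else:
        raise ValueError(f"unknown interactome dialect {dialect!r}")

    if merged:
        logger.info("read_interactome(%s): merged %d duplicate edge rows", path, merged)
    try:
        return Interactome.from_edges(
            (src, tgt, sign, weight) for (src, tgt), (sign, weight) in sorted(edges.items())
        )
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _add_edge(edges, src, tgt, sign, weight, path, lineno) -> int:
    """Insert or merge one edge row; returns 1 if the row merged a duplicate."""
    if src == tgt:
        raise FormatError(f"{path}:{lineno}: self-loop on {src!r}")
    key = (src, tgt)
    if key in edges:
        old_sign, old_weight = edges[key]
        if old_sign != sign:
            raise FormatError(
                f"{path}:{lineno}: duplicate edge {src!r}->{tgt!r} with conflicting signs"
            )
        edges[key] = (sign, max(old_weight, weight))
        return 1
    edges[key] = (sign, weight)
    return 0


def write_interactome(interactome: Interactome, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tsign\tweight\n")
        for src, tgt, sign, weight in interactome.edges:
            fh.write(f"{src}\t{tgt}\t{sign:+d}\t{WEIGHT_FMT.format(weight)}\n")


# ---------------------------------------------------------------------------
# Seed sets


def read_seed_sets(path: str | Path) -> list[SeedSet]:
    """Load motive-grouped seed proteins, one SeedSet per condition label."""
    path = Path(path)
    by_condition: dict[str, list[SeedEntry]] = {}
    for lineno, (condition, protein, motive, state_tok) in _rows(
        path, 4, ("condition", "protein", "motive", "expected_state")
    ):
        state = _parse_sign(state_tok, path, lineno)
        if not motive:
            raise FormatError(f"{path}:{lineno}: seed {protein!r} names a blank motive")
        try:
            entry = SeedEntry(protein=protein, motive=motive, expected_state=state)
        except ValidationError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        by_condition.setdefault(condition, []).append(entry)
    out = []
    for condition in sorted(by_condition):
        try:
            out.append(SeedSet(condition=condition, entries=tuple(by_condition[condition])))
        except ValidationError as exc:
            raise FormatError(f"{path}: condition {condition!r}: {exc}") from exc
    return out


def write_seed_sets(seed_sets: Iterable[SeedSet], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("condition\tprotein\tmotive\texpected_state\n")
        for ss in sorted(seed_sets, key=lambda s: s.condition):
            for e in ss.entries:
                fh.write(f"{ss.condition}\t{e.protein}\t{e.motive}\t{e.expected_state:+d}\n")


# ---------------------------------------------------------------------------
# Drug library (targets table + metadata table)

_META_HEADER = ("drug", "safe_profile", "no_pain_liability", "no_known_regen_effect", "crosses_bbb")


def read_drug_library(targets_path: str | Path, metadata_path: str | Path) -> list[DrugSignature]:
    """Load a drug library from a target table and an eligibility table.

    Every drug must have a metadata row; eligibility flags are never
    defaulted.  Drugs with a metadata row but no target rows are legal
    null drugs.
    """
    targets_path, metadata_path = Path(targets_path), Path(metadata_path)
    targets: dict[str, list[tuple[str, int]]] = {}
    for lineno, (drug, protein, action_tok) in _rows(targets_path, 3, ("drug", "target", "action")):
        action = _parse_sign(action_tok, targets_path, lineno)
        targets.setdefault(drug, []).append((protein, action))

    eligibility: dict[str, Eligibility] = {}
    for lineno, fields in _rows(metadata_path, 5, _META_HEADER):
        drug = fields[0]
        if drug in eligibility:
            raise FormatError(f"{metadata_path}:{lineno}: duplicate metadata row for {drug!r}")
        flags = [
            _parse_bool(tok, metadata_path, lineno, name)
            for tok, name in zip(fields[1:], _META_HEADER[1:])
        ]
        eligibility[drug] = Eligibility(*flags)

    missing = sorted(set(targets) - set(eligibility))
    if missing:
        raise FormatError(
            f"{metadata_path}: no eligibility row for drug(s) {', '.join(missing)} "
            "(flags are never assumed)"
        )
    out = []
    for drug in sorted(eligibility):
        try:
            out.append(
                DrugSignature(
                    drug_id=drug,
                    targets=tuple(targets.get(drug, ())),
                    eligibility=eligibility[drug],
                )
            )
        except ValidationError as exc:
            raise FormatError(f"{targets_path}: drug {drug!r}: {exc}") from exc
    return out


def write_drug_library(
    library: Iterable[DrugSignature], targets_path: str | Path, metadata_path: str | Path
) -> None:
    library = sorted(library, key=lambda d: d.drug_id)
    with Path(targets_path).open("w", encoding="utf-8") as fh:
        fh.write("drug\ttarget\taction\n")
        for drug in library:
            for protein, action in drug.targets:
                fh.write(f"{drug.drug_id}\t{protein}\t{action:+d}\n")
    with Path(metadata_path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_META_HEADER) + "\n")
        for drug in library:
            e = drug.eligibility
            flags = "\t".join(
                str(v).lower()
                for v in (e.safe_profile, e.no_pain_liability, e.no_known_regen_effect, e.crosses_bbb)
            )
            fh.write(f"{drug.drug_id}\t{flags}\n")


# ---------------------------------------------------------------------------
# Restrictions (long format)


def read_restrictions(path: str | Path) -> RestrictionTable:
    """Load a truth table from long format.

    ``row_id<TAB>side(in|out)<TAB>protein<TAB>value<TAB>tolerance``; the
    tolerance must be identical across the entries of one row.
    """
    path = Path(path)
    rows: dict[str, dict] = {}
    for lineno, (row_id, side, protein, value_tok, tol_tok) in _rows(
        path, 5, ("row_id", "side", "protein", "value", "tolerance")
    ):
        if side not in ("in", "out"):
            raise FormatError(f"{path}:{lineno}: side must be 'in' or 'out', got {side!r}")
        value = _parse_float(value_tok, path, lineno, "value")
        tol = _parse_float(tol_tok, path, lineno, "tolerance")
        rec = rows.setdefault(row_id, {"in": {}, "out": {}, "tol": tol})
        if rec["tol"] != tol:
            raise FormatError(f"{path}:{lineno}: row {row_id!r} has inconsistent tolerances")
        if protein in rec[side]:
            raise FormatError(f"{path}:{lineno}: duplicate {side} entry {protein!r} in row {row_id!r}")
        rec[side][protein] = value
    try:
        return RestrictionTable(
            rows=tuple(
                Restriction(row_id=rid, inputs=rec["in"], outputs=rec["out"], tolerance=rec["tol"])
                for rid, rec in sorted(rows.items())
            )
        )
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_restrictions(table: RestrictionTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("row_id\tside\tprotein\tvalue\ttolerance\n")
        for row in table.rows:
            for side, values in (("in", row.inputs), ("out", row.outputs)):
                for protein, value in values.items():
                    fh.write(
                        f"{row.row_id}\t{side}\t{protein}\t"
                        f"{WEIGHT_FMT.format(value)}\t{WEIGHT_FMT.format(row.tolerance)}\n"
                    )


# ---------------------------------------------------------------------------
# Phenotype signatures


def read_signatures(path: str | Path) -> dict[str, dict[str, tuple[float, float]]]:
    """Load phenotype signatures: label -> {protein: (desired, weight)}."""
    path = Path(path)
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for lineno, (label, protein, desired_tok, weight_tok) in _rows(
        path, 4, ("label", "protein", "desired", "weight")
    ):
        desired = _parse_float(desired_tok, path, lineno, "desired state")
        weight = _parse_float(weight_tok, path, lineno, "weight")
        sig = out.setdefault(label, {})
        if protein in sig:
            raise FormatError(f"{path}:{lineno}: duplicate protein {protein!r} in {label!r}")
        sig[protein] = (desired, weight)
    return out


def write_signatures(signatures: Mapping[str, Mapping[str, tuple[float, float]]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("label\tprotein\tdesired\tweight\n")
        for label in sorted(signatures):
            for protein in sorted(signatures[label]):
                desired, weight = signatures[label][protein]
                fh.write(
                    f"{label}\t{protein}\t{WEIGHT_FMT.format(desired)}\t{WEIGHT_FMT.format(weight)}\n"
                )


# ---------------------------------------------------------------------------
# Ranked combination scores

_RANKED_HEADER = (
    "drug_a",
    "drug_b",
    "efficacy_pct",
    "adverse_pct",
    "synergy_pts",
    "eligible",
    "pass_tier",
    "top_tier",
)


def write_ranked_combinations(scores, path: str | Path) -> None:
    """Write scored combinations in ranked order (header always present).

    Rows are sorted by (efficacy desc, adverse asc, synergy desc, ids) —
    the same total order the candidate filter uses.
    """
    from .screen import ranking_key  # local import to avoid a module cycle

    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_RANKED_HEADER) + "\n")
        for s in sorted(scores, key=ranking_key):
            drug_a = s.drugs[0]
            drug_b = s.drugs[1] if len(s.drugs) > 1 else "-"
            fh.write(
                f"{drug_a}\t{drug_b}\t{PCT_FMT.format(s.efficacy)}\t{PCT_FMT.format(s.adverse)}\t"
                f"{PCT_FMT.format(s.synergy)}\t{str(s.eligible).lower()}\t"
                f"{str(s.pass_tier).lower()}\t{str(s.top_tier).lower()}\n"
            )


def read_ranked_combinations(path: str | Path):
    """Read back a ranked-combination table written by this module."""
    from .screen import CombinationScore

    path = Path(path)
    out = []
    for lineno, fields in _rows(path, 8, _RANKED_HEADER):
        drug_a, drug_b = fields[0], fields[1]
        drugs = (drug_a,) if drug_b == "-" else (drug_a, drug_b)
        out.append(
            CombinationScore(
                drugs=drugs,
                efficacy=_parse_float(fields[2], path, lineno, "efficacy"),
                adverse=_parse_float(fields[3], path, lineno, "adverse"),
                synergy=_parse_float(fields[4], path, lineno, "synergy"),
                eligible=_parse_bool(fields[5], path, lineno, "eligible"),
                pass_tier=_parse_bool(fields[6], path, lineno, "pass_tier"),
                top_tier=_parse_bool(fields[7], path, lineno, "top_tier"),
            )
        )
    return out
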