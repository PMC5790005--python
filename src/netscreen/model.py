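"""Signal propagation over signed condition maps, and truth-table training.

A condition map is converted into a parameterized dynamical model: each
node carries a state in [-1, +1]; each curated edge carries a trainable
strength whose sign is locked to the edge's curated sign (activating
edges keep strength >= 0, inhibiting edges <= 0); each node carries a
trainable bias.  States evolve by a damped synchronous update

    x_next = (1 - alpha) * x + alpha * act(b + W x)

with a bounded, odd, monotone activation (tanh by default), while
perturbed nodes are clamped at their input values.  A fixed point of the
undamped update is a steady protein-activity profile; drugs perturb the
model by clamping their targets.

Training fits strengths and biases so that the model reproduces a
restriction table ("truth table"): for each row, clamping the row's
input signature must drive the designated read-out proteins to within a
tolerance of the required outputs.  The optimizer is seeded simulated
annealing with geometric cooling; sign constraints are enforced by
projection after every proposal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .types import RestrictionTable

__all__ = [
    "Hyperparams",
    "OptimizerParams",
    "PropagationModel",
    "StateVector",
    "FitReport",
    "CrossValidationResult",
    "build_model",
    "model_from_graph",
    "propagate",
    "propagate_many",
    "evaluate_restrictions",
    "train",
    "cross_validate",
    "save_model",
    "load_model",
]

ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "tanh": np.tanh,
    # piecewise-linear clipping: an alternative bounded odd monotone rule
    "hardtanh": lambda x: np.clip(x, -1.0, 1.0),
}


@dataclass(frozen=True)
class Hyperparams:
    """Dynamics hyperparameters.

    alpha (damping) 0.5 suppresses oscillation on cycles; tol/max_iter
    govern fixed-point convergence; init_scale sets the magnitude of the
    small random initial strengths.
    """

    activation: str = "tanh"
    damping: float = 0.5
    tol: float = 1e-10
    max_iter: int = 500
    init_scale: float = 0.1
    strength_bound: float = 5.0
    bias_bound: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.damping <= 1.0):
            raise ValueError("damping must be in (0, 1]")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


class PropagationModel:
    """A parameterized signal-propagation model over a fixed topology."""

    def __init__(
        self,
        nodes: Sequence[str],
        edge_src: np.ndarray,
        edge_tgt: np.ndarray,
        edge_sign: np.ndarray,
        strengths: np.ndarray,
        bias: np.ndarray,
        hyperparams: Hyperparams = Hyperparams(),
    ) -> None:
        self.nodes = list(nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.edge_src = np.asarray(edge_src, dtype=np.int64)
        self.edge_tgt = np.asarray(edge_tgt, dtype=np.int64)
        self.edge_sign = np.asarray(edge_sign, dtype=np.int64)
        self.strengths = np.asarray(strengths, dtype=np.float64)
        self.bias = np.asarray(bias, dtype=np.float64)
        self.hyperparams = hyperparams
        self._check_signs()

    # -- parameter handling -------------------------------------------------

    def _check_signs(self) -> None:
        bad = np.nonzero(self.edge_sign * self.strengths < 0)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"edge {self.nodes[self.edge_src[i]]}->{self.nodes[self.edge_tgt[i]]}: "
                f"strength {self.strengths[i]:g} violates curated sign {int(self.edge_sign[i]):+d}"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.edge_src.size

    def weight_matrix(self) -> np.ndarray:
        """Dense W with W[target, source] = strength (summed on multi-edges)."""
        W = np.zeros((self.n_nodes, self.n_nodes))
        np.add.at(W, (self.edge_tgt, self.edge_src), self.strengths)
        return W

    def params(self) -> np.ndarray:
        return np.concatenate([self.strengths, self.bias])

    def with_params(self, theta: np.ndarray) -> "PropagationModel":
        m = self.n_edges
        return PropagationModel(
            nodes=self.nodes,
            edge_src=self.edge_src,
            edge_tgt=self.edge_tgt,
            edge_sign=self.edge_sign,
            strengths=theta[:m].copy(),
            bias=theta[m:].copy(),
            hyperparams=self.hyperparams,
        )

    def project_params(self, theta: np.ndarray) -> np.ndarray:
        """Project a raw parameter vector onto the feasible set (signs, bounds)."""
        hp = self.hyperparams
        m = self.n_edges
        out = theta.copy()
        s = out[:m]
        s *= self.edge_sign  # now must be in [0, strength_bound]
        np.clip(s, 0.0, hp.strength_bound, out=s)
        out[:m] = s * self.edge_sign
        np.clip(out[m:], -hp.bias_bound, hp.bias_bound, out=out[m:])
        return out

    def copy(self) -> "PropagationModel":
        return self.with_params(self.params())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PropagationModel):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and np.array_equal(self.edge_src, other.edge_src)
            and np.array_equal(self.edge_tgt, other.edge_tgt)
            and np.array_equal(self.edge_sign, other.edge_sign)
            and np.array_equal(self.strengths, other.strengths)
            and np.array_equal(self.bias, other.bias)
            and self.hyperparams == other.hyperparams
        )


@dataclass(frozen=True)
class StateVector:
    """Fixed-point (or final-iterate) node states of one propagation run."""

    values: Mapping[str, float]
    converged: bool
    iterations: int

    def __getitem__(self, protein: str) -> float:
        return self.values[protein]


@dataclass(frozen=True)
class FitReport:
    satisfaction: float
    residuals: tuple[float, ...]  # per-row max |required - achieved| over read-outs
    iterations: int
    objective: float
    initial_objective: float
    seed: int


@dataclass(frozen=True)
class CrossValidationResult:
    mean_satisfaction: float
    per_fold: tuple[float, ...]
    fold_sizes: tuple[int, ...]


# ---------------------------------------------------------------------------
# Construction


def model_from_graph(graph_like, hyperparams: Hyperparams = Hyperparams(), seed: int = 0) -> PropagationModel:
    """Build a model skeleton from any object exposing a signed ``graph``.

    Accepts an Interactome or a ConditionMap.  Strengths are initialized
    small-random with the curated sign; biases are zero.
    """
    g = graph_like.graph
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = sorted((index[u], index[v], d["sign"], d["weight"]) for u, v, d in g.edges(data=True))
    src = np.array([e[0] for e in edges], dtype=np.int64)
    tgt = np.array([e[1] for e in edges], dtype=np.int64)
    sign = np.array([e[2] for e in edges], dtype=np.int64)
    rng = np.random.default_rng(seed)
    strengths = sign * rng.uniform(0.0, hyperparams.init_scale, size=sign.size)
    bias = np.zeros(len(nodes))
    return PropagationModel(nodes, src, tgt, sign, strengths, bias, hyperparams)


def build_model(condition_map, hyperparams: Hyperparams | None = None, seed: int = 0) -> PropagationModel:
    """Convert a condition map into a trainable propagation model."""
    if condition_map.graph.number_of_nodes() == 0:
        raise ValueError("cannot build a model on an empty map")
    return model_from_graph(condition_map, hyperparams or Hyperparams(), seed=seed)


# ---------------------------------------------------------------------------
# Propagation


def _batch_fixed_point(
    model: PropagationModel,
    clamp_mask: np.ndarray,
    clamp_values: np.ndarray,
    tol: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Damped synchronous iteration on a batch of input signatures.

    ``clamp_mask``/``clamp_values`` are (n_nodes, n_signatures); clamped
    entries are held fixed throughout.  Returns (states, converged,
    iterations) with one column per signature.
    """
    hp = model.hyperparams
    eps = hp.tol if tol is None else tol
    act = ACTIVATIONS[hp.activation]
    alpha = hp.damping
    W = model.weight_matrix()
    b = model.bias[:, None]

    X = np.where(clamp_mask, clamp_values, 0.0)
    m = X.shape[1]
    converged = np.zeros(m, dtype=bool)
    iterations = np.zeros(m, dtype=np.int64)
    for t in range(1, hp.max_iter + 1):
        Xn = act(b + W @ X)
        Xn = (1.0 - alpha) * X + alpha * Xn
        Xn[clamp_mask] = clamp_values[clamp_mask]
        delta = np.abs(Xn - X).max(axis=0) if X.size else np.zeros(m)
        # freeze converged columns so each result is independent of what
        # else shares the batch (chunking must not change any score)
        if converged.any():
            Xn[:, converged] = X[:, converged]
        X = Xn
        just = (~converged) & (delta < eps)
        iterations[just] = t
        converged |= just
        if converged.all():
            break
    iterations[~converged] = hp.max_iter
    np.clip(X, -1.0, 1.0, out=X)
    X[clamp_mask] = clamp_values[clamp_mask]
    return X, converged, iterations


def _signature_to_columns(
    model: PropagationModel, signatures: Sequence[Mapping[str, float]]
) -> tuple[np.ndarray, np.ndarray]:
    n, m = model.n_nodes, len(signatures)
    mask = np.zeros((n, m), dtype=bool)
    vals = np.zeros((n, m))
    for j, sig in enumerate(signatures):
        for protein, value in sig.items():
            i = model.index.get(protein)
            if i is None:
                raise KeyError(f"protein {protein!r} is not in the model's map")
            if not (-1.0 <= value <= 1.0):
                raise ValueError(f"input value {value!r} for {protein!r} outside [-1, +1]")
            mask[i, j] = True
            vals[i, j] = value
    return mask, vals


def propagate(model: PropagationModel, input_signature: Mapping[str, float]) -> StateVector:
    """Fixed-point node states under a clamped input signature.

    The perturbed proteins are held at their input values for every
    iteration; all other nodes relax under the damped update.  The
    converged flag is honest: if the iteration cap is hit first, the
    final iterate is returned with ``converged=False``.
    """
    mask, vals = _signature_to_columns(model, [input_signature])
    X, conv, iters = _batch_fixed_point(model, mask, vals)
    values = {node: float(X[i, 0]) for i, node in enumerate(model.nodes)}
    return StateVector(values=values, converged=bool(conv[0]), iterations=int(iters[0]))


def propagate_many(
    model: PropagationModel, signatures: Sequence[Mapping[str, float]], tol: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized propagation: returns (states[n_nodes, n_sigs], converged)."""
    mask, vals = _signature_to_columns(model, signatures)
    X, conv, _ = _batch_fixed_point(model, mask, vals, tol=tol)
    return X, conv


# ---------------------------------------------------------------------------
# Restriction evaluation and training


class _EncodedTable:
    """Restriction table pre-encoded as clamp/read-out matrices."""

    def __init__(self, model: PropagationModel, table: RestrictionTable) -> None:
        if len(table) == 0:
            raise ValueError("empty restriction table")
        missing = table.proteins - set(model.index)
        if missing:
            raise ValueError(
                f"restriction protein(s) not in the model's map: {', '.join(sorted(missing))}"
            )
        self.row_ids = [r.row_id for r in table.rows]
        self.clamp_mask, self.clamp_values = _signature_to_columns(
            model, [r.inputs for r in table.rows]
        )
        self.out_mask, self.out_values = _signature_to_columns(
            model, [r.outputs for r in table.rows]
        )
        self.tolerances = np.array([r.tolerance for r in table.rows])
        self.n_outputs = int(self.out_mask.sum())
        if self.n_outputs == 0:
            raise ValueError("restriction table has no required outputs")

    def score(self, model: PropagationModel, tol: float | None = None):
        X, _, _ = _batch_fixed_point(model, self.clamp_mask, self.clamp_values, tol=tol)
        return self._score_states(X)

    def _score_states(self, X: np.ndarray):
        resid = np.where(self.out_mask, X - self.out_values, 0.0)
        objective = float((resid**2).sum() / self.n_outputs)
        row_max = np.abs(resid).max(axis=0)
        satisfied = row_max <= self.tolerances
        return float(satisfied.mean()), row_max, objective


class _FastObjective:
    """Lean objective evaluator for annealing.

    Re-uses one weight-matrix buffer and always solves from the neutral
    zero state — the same initial condition the canonical ``propagate``
    uses — so the annealer optimizes exactly the objective the fit is
    judged on (the dynamics can be multistable, so the starting state is
    part of the model's definition).
    """

    def __init__(self, model: PropagationModel, enc: _EncodedTable, tol: float, max_iter: int = 200):
        self.model = model
        self.enc = enc
        self.tol = tol
        self.max_iter = max_iter
        self.n_edges = model.n_edges
        self.W = np.zeros((model.n_nodes, model.n_nodes))
        self.act = ACTIVATIONS[model.hyperparams.activation]
        self.alpha = model.hyperparams.damping
        self.X0 = np.where(enc.clamp_mask, enc.clamp_values, 0.0)

    def __call__(self, theta: np.ndarray):
        m = self.n_edges
        model = self.model
        # unique (src, tgt) pairs allow direct fancy assignment
        self.W[model.edge_tgt, model.edge_src] = theta[:m]
        b = theta[m:][:, None]
        mask, vals = self.enc.clamp_mask, self.enc.clamp_values
        X = self.X0.copy()
        alpha = self.alpha
        for _ in range(self.max_iter):
            Xn = self.act(b + self.W @ X)
            Xn = (1.0 - alpha) * X + alpha * Xn
            Xn[mask] = vals[mask]
            delta = np.abs(Xn - X).max()
            X = Xn
            if delta < self.tol:
                break
        np.clip(X, -1.0, 1.0, out=X)
        X[mask] = vals[mask]
        resid = np.where(self.enc.out_mask, X - self.enc.out_values, 0.0)
        obj = float((resid**2).sum() / self.enc.n_outputs)
        row_max = np.abs(resid).max(axis=0)
        sat = float((row_max <= self.enc.tolerances).mean())
        # a stricter band for the search: rows must land clearly inside
        # tolerance, so they stay satisfied under the tighter fixed-point
        # tolerance of the final full-precision re-score
        sat_strict = float((row_max <= 0.95 * self.enc.tolerances).mean())
        return sat, obj, sat_strict


def evaluate_restrictions(
    model: PropagationModel, table: RestrictionTable
) -> tuple[float, tuple[float, ...], float]:
    """(satisfaction fraction, per-row max residual, mean squared residual)."""
    enc = _EncodedTable(model, table)
    sat, row_max, obj = enc.score(model)
    return sat, tuple(float(r) for r in row_max), obj


@dataclass(frozen=True)
class OptimizerParams:
    """Simulated-annealing settings for truth-table training.

    The proposal scale anneals geometrically from ``sigma`` to
    ``sigma_final`` over the run (coarse moves early, refinement late).
    """

    steps: int = 1200  # annealing steps per restart
    restarts: int = 10  # independent re-initialized anneals; best result wins
    moves_per_step: int = 2
    sigma: float = 0.6
    sigma_final: float = 0.04
    t0: float = 0.01
    t_final: float = 1e-5
    restart_strength: tuple[float, float] = (0.2, 1.2)  # |strength| init range on restarts
    satisfaction_weight: float = 0.1  # annealing energy = MSE + weight * (1 - satisfaction)
    propagate_tol: float = 1e-6  # fixed-point tolerance during objective evaluation


def train(
    model: PropagationModel,
    restriction_table: RestrictionTable,
    optimizer_params: OptimizerParams | None = None,
    seed: int = 0,
) -> tuple[PropagationModel, FitReport]:
    """Fit strengths and biases to a restriction table by annealing.

    The objective is the mean squared residual over all required outputs;
    a row is satisfied when every read-out matches within the row's
    tolerance.  Sign constraints are projected after every proposal, so
    they hold at all times.  The search runs several independently
    initialized anneals (restarts) and keeps the best parameter vector
    seen anywhere, ranked by (satisfaction, -objective) — training never
    returns a model worse than its input, and restarts guard against a
    single anneal trapping in a poor basin of the multimodal landscape.

    Proposals are accepted by Metropolis on an annealing energy
    ``MSE + satisfaction_weight * (1 - satisfaction)``: the extra term
    pulls rows sitting just outside their tolerance band over the line,
    which plain MSE barely rewards.  The reported objective is the pure
    mean squared residual.
    """
    opt = optimizer_params or OptimizerParams()
    enc = _EncodedTable(model, restriction_table)
    rng = np.random.default_rng(seed)
    objective = _FastObjective(model, enc, tol=opt.propagate_tol)
    lam = opt.satisfaction_weight

    m = model.edge_sign.size
    theta0 = model.project_params(model.params())
    sat, obj, strict = objective(theta0)
    initial_objective = obj
    best_theta, best_sat, best_obj = theta0.copy(), sat, obj

    n_params = theta0.size
    steps = max(opt.steps, 1)
    lo, hi = opt.restart_strength
    total_steps = 0
    for restart in range(max(opt.restarts, 1)):
        if best_sat >= 1.0:
            break  # nothing left to improve
        if restart == 0:
            theta, cur_energy = theta0.copy(), obj + lam * (1.0 - strict)
        else:
            theta = np.zeros(n_params)
            theta[:m] = model.edge_sign * rng.uniform(lo, hi, size=m)
            theta = model.project_params(theta)
            _, r_obj, r_strict = objective(theta)
            cur_energy = r_obj + lam * (1.0 - r_strict)
        # jitter the schedule across restarts: identical schedules tend to
        # relax different inits into the same basin
        if restart == 0:
            t_start, s_start = opt.t0, opt.sigma
        else:
            t_start = opt.t0 * float(10.0 ** rng.uniform(-0.7, 0.7))
            s_start = opt.sigma * float(rng.uniform(0.6, 1.8))
        cool = (opt.t_final / t_start) ** (1.0 / steps)
        shrink = (opt.sigma_final / s_start) ** (1.0 / steps)
        temperature, sigma = t_start, s_start
        for _ in range(steps):
            total_steps += 1
            proposal = theta.copy()
            idx = rng.integers(0, n_params, size=min(opt.moves_per_step, n_params))
            proposal[idx] += rng.normal(0.0, sigma, size=idx.size)
            proposal = model.project_params(proposal)  # signs hold at all times
            cand_sat, cand_obj, cand_strict = objective(proposal)
            cand_energy = cand_obj + lam * (1.0 - cand_strict)
            accept = cand_energy <= cur_energy or rng.random() < math.exp(
                -(cand_energy - cur_energy) / max(temperature, 1e-12)
            )
            if accept:
                theta, cur_energy = proposal, cand_energy
                if (cand_sat, -cand_obj) > (best_sat, -best_obj):
                    best_theta, best_sat, best_obj = proposal.copy(), cand_sat, cand_obj
            temperature *= cool
            sigma *= shrink

    trained = model.with_params(best_theta)
    final_sat, row_max, final_obj = enc.score(trained)  # full-precision re-score
    # the best-seen vector is kept, so satisfaction never drops below the input model's
    report = FitReport(
        satisfaction=final_sat,
        residuals=tuple(float(r) for r in row_max),
        iterations=total_steps,
        objective=final_obj,
        initial_objective=initial_objective,
        seed=seed,
    )
    return trained, report


def cross_validate(
    model_builder: Callable[[int], PropagationModel],
    restriction_table: RestrictionTable,
    k_folds: int,
    seed: int = 0,
    optimizer_params: OptimizerParams | None = None,
) -> CrossValidationResult:
    """k-fold cross-validation of truth-table training.

    Rows are assigned to folds by a seeded permutation of the sorted row
    ids, so fold membership is invariant to the table's row order.  For
    each fold a fresh model from ``model_builder(fold_seed)`` is trained
    on the remaining rows and satisfaction is measured on the held-out
    fold.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    rows = sorted(r.row_id for r in restriction_table.rows)
    if len(rows) < k_folds:
        raise ValueError(f"{len(rows)} rows cannot be split into {k_folds} folds")
    rng = np.random.default_rng(seed)
    order = [rows[i] for i in rng.permutation(len(rows))]
    folds = [order[i::k_folds] for i in range(k_folds)]

    per_fold: list[float] = []
    for i, held_out in enumerate(folds):
        train_ids = [rid for rid in order if rid not in set(held_out)]
        fold_seed = int(rng.integers(0, 2**31 - 1))
        model = model_builder(fold_seed)
        trained, _ = train(
            model, restriction_table.subset(train_ids), optimizer_params, seed=fold_seed
        )
        sat, _, _ = evaluate_restrictions(trained, restriction_table.subset(held_out))
        per_fold.append(sat)
    return CrossValidationResult(
        mean_satisfaction=float(np.mean(per_fold)),
        per_fold=tuple(per_fold),
        fold_sizes=tuple(len(f) for f in folds),
    )


# ---------------------------------------------------------------------------
# Checkpointing (bit-exact: floats written with full repr precision)


def save_model(model: PropagationModel, path: str | Path) -> None:
    hp = model.hyperparams
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(
            f"# activation={hp.activation} damping={hp.damping!r} tol={hp.tol!r} "
            f"max_iter={hp.max_iter} init_scale={hp.init_scale!r} "
            f"strength_bound={hp.strength_bound!r} bias_bound={hp.bias_bound!r}\n"
        )
        fh.write("kind\tname\tvalue\n")
        for i, node in enumerate(model.nodes):
            fh.write(f"node\t{node}\t{float(model.bias[i])!r}\n")
        for j in range(model.n_edges):
            u, v = model.nodes[model.edge_src[j]], model.nodes[model.edge_tgt[j]]
            fh.write(f"edge\t{u}->{v}|{int(model.edge_sign[j]):+d}\t{float(model.strengths[j])!r}\n")


def load_model(path: str | Path) -> PropagationModel:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip()
    if not header.startswith("#"):
        raise ValueError(f"{path}: missing hyperparameter header")
    kv = dict(tok.split("=", 1) for tok in header[1:].split())
    hp = Hyperparams(
        activation=kv["activation"],
        damping=float(kv["damping"]),
        tol=float(kv["tol"]),
        max_iter=int(kv["max_iter"]),
        init_scale=float(kv["init_scale"]),
        strength_bound=float(kv["strength_bound"]),
        bias_bound=float(kv["bias_bound"]),
    )
    nodes: list[tuple[str, float]] = []
    edges: list[tuple[str, str, int, float]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line == "kind\tname\tvalue":
                continue
            kind, name, value = line.split("\t")
            if kind == "node":
                nodes.append((name, float(value)))
            elif kind == "edge":
                ends, sign = name.rsplit("|", 1)
                u, v = ends.split("->")
                edges.append((u, v, int(sign), float(value)))
            else:
                raise ValueError(f"{path}:{lineno}: unknown parameter kind {kind!r}")
    node_names = [n for n, _ in nodes]
    index = {n: i for i, n in enumerate(node_names)}
    return PropagationModel(
        nodes=node_names,
        edge_src=np.array([index[u] for u, _, _, _ in edges], dtype=np.int64),
        edge_tgt=np.array([index[v] for _, v, _, _ in edges], dtype=np.int64),
        edge_sign=np.array([s for _, _, s, _ in edges], dtype=np.int64),
        strengths=np.array([w for _, _, _, w in edges]),
        bias=np.array([b for _, b in nodes]),
        hyperparams=hp,
    )
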