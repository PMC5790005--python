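"""End-to-end pipeline orchestration: synth -> maps -> train -> screen -> moa.

A single strict-schema config drives every stage.  One global seed is
fanned out per stage (SHA-256 of the stage name, see utils.derive_seed)
so stages can be re-run in isolation reproducibly; identical config and
seed produce byte-identical output tables.  A manifest records input
hashes, stage seeds, and whether each stage was computed or reused.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__, io
from .maps import ExpansionPolicy, expand_map, map_overlap, map_stats
from .model import (
    Hyperparams,
    OptimizerParams,
    build_model,
    load_model,
    save_model,
    train,
)
from .screen import (
    PhenotypeSignature,
    ScreenConfig,
    Thresholds,
    extract_moa,
    filter_candidates,
    screen_combinations,
)
from .synth import SyntheticScenario, generate_dataset
from .utils import derive_seed

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "report_summary", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


class RunConfig(BaseModel):
    """Strict full-pipeline configuration (unknown keys are rejected)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    seed: int = 0
    scenario: SyntheticScenario = SyntheticScenario()
    expansion: ExpansionPolicy = ExpansionPolicy()
    hyperparams: Hyperparams = Hyperparams()
    optimizer: OptimizerParams = OptimizerParams()
    screen: ScreenConfig = ScreenConfig()
    thresholds: Thresholds = Thresholds()
    moa_top_k: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    """Bookkeeping for one pipeline invocation."""

    STAGES = ("synth", "build-maps", "train", "screen", "filter", "moa")

    def __init__(self, config: RunConfig, run_dir: Path, force: bool) -> None:
        self.config = config
        self.run_dir = Path(run_dir)
        self.force = force
        self.run_dir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "seed": config.seed,
            "version": __version__,
            "stage_seeds": {s: derive_seed(config.seed, s) for s in self.STAGES},
            "stages": {},
            "inputs": {},
        }

    def path(self, name: str) -> Path:
        return self.run_dir / name

    def should_run(self, stage: str, outputs: list[str]) -> bool:
        if self.force or not all(self.path(o).exists() for o in outputs):
            return True
        self.manifest["stages"][stage] = {"status": "reused", "outputs": outputs}
        logger.info("stage %s: outputs exist, reused (pass --force to recompute)", stage)
        return False

    def done(self, stage: str, outputs: list[str]) -> None:
        self.manifest["stages"][stage] = {
            "status": "computed",
            "outputs": outputs,
            "hashes": {o: _sha256(self.path(o)) for o in outputs},
        }

    def write_manifest(self) -> None:
        with self.path("manifest.json").open("w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: RunConfig, run_dir: str | Path, force: bool = False) -> Path:
    """Execute all stages in order; returns the run directory.

    Stages whose outputs already exist are skipped unless ``force``.
    Any stage error is re-raised as PipelineError naming the stage.
    """
    run = _Run(config, Path(run_dir), force)
    with run.path("config_used.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(json.loads(config.model_dump_json()), fh, sort_keys=True)

    stages = [
        ("synth", _stage_synth),
        ("build-maps", _stage_maps),
        ("train", _stage_train),
        ("screen", _stage_screen),
        ("filter", _stage_filter),
        ("moa", _stage_moa),
    ]
    for name, fn in stages:
        try:
            fn(run)
        except Exception as exc:
            run.write_manifest()
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    run.write_manifest()
    return run.run_dir


# -- stages ------------------------------------------------------------------

_SYNTH_OUT = [
    "interactome.tsv",
    "seeds.tsv",
    "restrictions.tsv",
    "drug_targets.tsv",
    "drug_metadata.tsv",
    "signatures.tsv",
    "ground_truth.yaml",
]


def _stage_synth(run: _Run) -> None:
    if not run.should_run("synth", _SYNTH_OUT):
        return
    scenario = run.config.scenario.model_copy(
        update={"seed": run.manifest["stage_seeds"]["synth"]}
    )
    ds = generate_dataset(scenario, policy=run.config.expansion)
    io.write_interactome(ds.interactome, run.path("interactome.tsv"))
    io.write_seed_sets([ds.degeneration_seeds, ds.protection_seeds], run.path("seeds.tsv"))
    io.write_restrictions(ds.restrictions, run.path("restrictions.tsv"))
    io.write_drug_library(ds.library, run.path("drug_targets.tsv"), run.path("drug_metadata.tsv"))
    io.write_signatures(
        {
            label: {p: (v, w) for p, v, w in _sig_rows(sig)}
            for label, sig in ds.signatures.items()
        },
        run.path("signatures.tsv"),
    )
    labels = {k: _plain(v) for k, v in ds.labels.items()}
    labels["readouts"] = list(ds.readouts)
    labels["noisy_rows"] = [r.row_id for r in ds.restrictions.rows if r.noisy]
    with run.path("ground_truth.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(labels, fh, sort_keys=True)
    run.done("synth", _SYNTH_OUT)


def _sig_rows(sig: PhenotypeSignature):
    for p in sig.desired:
        yield p, sig.desired[p], sig.weights[p]


def _plain(value):
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_plain(v) for v in value]
    return value


_MAPS_OUT = [
    "map_degeneration_edges.tsv",
    "map_protection_edges.tsv",
    "map_degeneration_nodes.tsv",
    "map_protection_nodes.tsv",
    "map_stats.tsv",
]


def _load_maps(run: _Run):
    interactome = io.read_interactome(run.path("interactome.tsv"))
    seed_sets = {s.condition: s for s in io.read_seed_sets(run.path("seeds.tsv"))}
    policy = run.config.expansion
    return (
        expand_map(interactome, seed_sets["degeneration"], policy),
        expand_map(interactome, seed_sets["protection"], policy),
    )


def _stage_maps(run: _Run) -> None:
    if not run.should_run("build-maps", _MAPS_OUT):
        return
    deg, prot = _load_maps(run)
    for cmap, label in ((deg, "degeneration"), (prot, "protection")):
        with run.path(f"map_{label}_nodes.tsv").open("w", encoding="utf-8") as fh:
            fh.write("node\tis_seed\tmotives\n")
            for node in cmap.nodes:
                motives = ";".join(cmap.motives.get(node, ())) or "-"
                fh.write(f"{node}\t{str(node in cmap.seed_nodes).lower()}\t{motives}\n")
        with run.path(f"map_{label}_edges.tsv").open("w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tsign\tweight\n")
            for u, v, d in sorted(cmap.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['sign']:+d}\t{io.WEIGHT_FMT.format(d['weight'])}\n")
    with run.path("map_stats.tsv").open("w", encoding="utf-8") as fh:
        fh.write("condition\tnodes\tedges\tavg_links_per_node\tseeds\tmotives\toverlap\n")
        ov = map_overlap(deg, prot)
        for cmap, label in ((deg, "degeneration"), (prot, "protection")):
            s = map_stats(cmap)
            fh.write(
                f"{label}\t{s.n_nodes}\t{s.n_edges}\t{s.avg_links_per_node:.1f}\t"
                f"{s.n_seeds}\t{s.n_motives}\t{ov}\n"
            )
    run.done("build-maps", _MAPS_OUT)


_TRAIN_OUT = ["model.tsv", "fit_report.json"]


def _stage_train(run: _Run) -> None:
    if not run.should_run("train", _TRAIN_OUT):
        return
    deg, _ = _load_maps(run)
    table = io.read_restrictions(run.path("restrictions.tsv"))
    seed = run.manifest["stage_seeds"]["train"]
    model = build_model(deg, run.config.hyperparams, seed=seed)
    trained, report = train(model, table, run.config.optimizer, seed=seed)
    save_model(trained, run.path("model.tsv"))
    with run.path("fit_report.json").open("w", encoding="utf-8") as fh:
        json.dump(
            {
                "satisfaction": report.satisfaction,
                "objective": report.objective,
                "initial_objective": report.initial_objective,
                "iterations": report.iterations,
                "seed": report.seed,
                "n_rows": len(table),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    run.done("train", _TRAIN_OUT)


_SCREEN_OUT = ["ranked.tsv", "singles.tsv"]


def _read_signatures(run: _Run) -> dict[str, PhenotypeSignature]:
    raw = io.read_signatures(run.path("signatures.tsv"))
    return {
        label: PhenotypeSignature(
            label,
            {p: dv[0] for p, dv in entries.items()},
            {p: dv[1] for p, dv in entries.items()},
        )
        for label, entries in raw.items()
    }


def _stage_screen(run: _Run) -> None:
    if not run.should_run("screen", _SCREEN_OUT):
        return
    model = load_model(run.path("model.tsv"))
    library = io.read_drug_library(run.path("drug_targets.tsv"), run.path("drug_metadata.tsv"))
    signatures = _read_signatures(run)
    scores = screen_combinations(model, library, signatures, run.config.screen)
    io.write_ranked_combinations(scores, run.path("ranked.tsv"))
    from .screen import score_singles

    singles = score_singles(model, library, signatures["protection"], signatures["pain"], run.config.screen)
    with run.path("singles.tsv").open("w", encoding="utf-8") as fh:
        fh.write("drug\tefficacy_pct\tadverse_pct\n")
        for drug in sorted(singles):
            eff, adv = singles[drug]
            fh.write(f"{drug}\t{io.PCT_FMT.format(eff)}\t{io.PCT_FMT.format(adv)}\n")
    run.done("screen", _SCREEN_OUT)


_FILTER_OUT = ["pass.tsv", "top.tsv"]


def _stage_filter(run: _Run) -> None:
    if not run.should_run("filter", _FILTER_OUT):
        return
    scores = io.read_ranked_combinations(run.path("ranked.tsv"))
    library = io.read_drug_library(run.path("drug_targets.tsv"), run.path("drug_metadata.tsv"))
    passing, top = filter_candidates(scores, library, run.config.thresholds)
    io.write_ranked_combinations(passing, run.path("pass.tsv"))
    io.write_ranked_combinations(top, run.path("top.tsv"))
    run.done("filter", _FILTER_OUT)


_MOA_OUT = ["moa.tsv"]


def _stage_moa(run: _Run) -> None:
    if not run.should_run("moa", _MOA_OUT):
        return
    passing = io.read_ranked_combinations(run.path("pass.tsv"))
    with run.path("moa.tsv").open("w", encoding="utf-8") as fh:
        fh.write("protein\tcontribution\tpair_state\tstate_a\tstate_b\n")
        pairs = [s for s in passing if len(s.drugs) == 2]
        if pairs:
            model = load_model(run.path("model.tsv"))
            library = {
                d.drug_id: d
                for d in io.read_drug_library(
                    run.path("drug_targets.tsv"), run.path("drug_metadata.tsv")
                )
            }
            signatures = _read_signatures(run)
            best = pairs[0]
            entries = extract_moa(
                model,
                [library[best.drugs[0]], library[best.drugs[1]]],
                signatures["protection"],
                top_k=run.config.moa_top_k,
                dose=run.config.screen.dose,
            )
            for e in entries:
                fh.write(
                    f"{e.protein}\t{io.PCT_FMT.format(e.contribution)}\t"
                    f"{io.PCT_FMT.format(e.pair_state)}\t{io.PCT_FMT.format(e.state_a)}\t"
                    f"{io.PCT_FMT.format(e.state_b)}\n"
                )
    run.done("moa", _MOA_OUT)


# -- reporting ---------------------------------------------------------------


def report_summary(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run (deterministic text)."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {run_dir}")
    with manifest_path.open("r", encoding="utf-8") as fh:
        manifest = json.load(fh)

    lines = [f"run {run_dir.name}: seed {manifest['seed']}, netscreen {manifest['version']}"]
    stats_path = run_dir / "map_stats.tsv"
    if stats_path.exists():
        for lineno, fields in io._rows(
            stats_path, 7, ("condition", "nodes", "edges", "avg_links_per_node", "seeds", "motives", "overlap")
        ):
            lines.append(
                f"map {fields[0]}: {fields[1]} nodes, avg links per node {fields[3]}, "
                f"{fields[4]} seeds; overlap {fields[6]} proteins"
            )
    fit_path = run_dir / "fit_report.json"
    if fit_path.exists():
        with fit_path.open("r", encoding="utf-8") as fh:
            fit = json.load(fh)
        lines.append(
            f"training: satisfaction {fit['satisfaction']:.3f} on {fit['n_rows']} restrictions "
            f"(objective {fit['objective']:.5f})"
        )
    ranked_path = run_dir / "ranked.tsv"
    if ranked_path.exists():
        scores = io.read_ranked_combinations(ranked_path)
        n_pairs = len(scores)
        # n(n-1)/2 = pairs  =>  n = (1 + sqrt(1+8p)) / 2
        n_drugs = int(round((1 + (1 + 8 * n_pairs) ** 0.5) / 2)) if n_pairs else 0
        lines.append(f"screen: {n_drugs} drugs, {n_pairs} binary combinations")
    for name, label in (("pass.tsv", "pass tier"), ("top.tsv", "top tier")):
        path = run_dir / name
        if path.exists():
            hits = io.read_ranked_combinations(path)
            lines.append(f"{label}: {len(hits)} combination(s)")
            for s in hits[:5]:
                lines.append(
                    f"  {' + '.join(s.drugs)}: efficacy {s.efficacy:.1f}%, "
                    f"adverse {s.adverse:.1f}%, synergy {s.synergy:.1f} pts"
                )
    return "\n".join(lines) + "\n"
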