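# netscreen

In-silico drug-combination screening on signed protein-interaction
networks.

Given a curated signed interactome, condition-defining seed proteins,
and a truth table of perturbation → phenotype observations, `netscreen`

1. expands the seeds into condition-specific network maps,
2. turns a map into a parameterized signal-propagation model
   (tanh dynamics, damped fixed-point iteration, drug targets held
   clamped),
3. trains the model's edge strengths and node biases against the truth
   table with sign-constrained simulated annealing,
4. exhaustively screens every unordered drug pair by clamping both
   drugs' targets and scoring the propagated steady state: efficacy
   against a protective phenotype signature, adverse effect against a
   pain signature, and synergy as pair efficacy minus the best single
   (highest-single-agent convention), and
5. filters candidates through eligibility flags and a two-tier threshold
   scheme, then extracts a mode-of-action node ranking for any pair.

Because real screens of this kind run on proprietary interactomes and
proteomics, the package ships a synthetic benchmark generator
(`netscreen.synth`) that plants verifiable ground truth — a hidden
generating model, a synergistic drug pair, single actives, null drugs,
and an almost-eligible decoy pair — so every stage is testable end to
end.

## Worked example: planted-pair recovery

Generate a benchmark and screen the generating model (the fast,
fully-determined case):

```python
from netscreen.synth import SyntheticScenario, generate_dataset
from netscreen.screen import screen_combinations, filter_candidates

ds = generate_dataset(SyntheticScenario(seed=2))
print("planted:", ds.labels["planted_pairs"], "decoy:", ds.labels["decoy_pair"])

scores = screen_combinations(ds.ground_truth, list(ds.library), ds.signatures)
for c in sorted(scores, key=lambda c: -c.synergy)[:5]:
    print(f"{c.drugs[0]}+{c.drugs[1]}: efficacy {c.efficacy:.1f}%, "
          f"adverse {c.adverse:.1f}%, synergy {c.synergy:.1f} pts, eligible={c.eligible}")

passing, top = filter_candidates(scores, list(ds.library))
print(f"pass tier: {len(passing)}, top tier: {len(top)}, best:", passing[0].drugs)
```

Output:

```
planted: [('D18', 'D22')] decoy: ('D03', 'D32')
D18+D22: efficacy 84.9%, adverse 0.0%, synergy 55.2 pts, eligible=True
D03+D18: efficacy 83.0%, adverse 0.0%, synergy 45.4 pts, eligible=False
D22+D32: efficacy 65.1%, adverse 0.0%, synergy 36.9 pts, eligible=True
D22+D34: efficacy 75.4%, adverse 0.0%, synergy 33.5 pts, eligible=True
D03+D32: efficacy 70.4%, adverse 0.0%, synergy 32.8 pts, eligible=False
pass tier: 10, top tier: 2, best: ('D18', 'D22')
```

The planted pair tops the screen and the filter; the decoy pair (D03,
D32) is synergistic but fails an eligibility flag and never surfaces.

## Worked example: full pipeline from the command line

```bash
printf 'seed: 2\n' > config.yaml
netscreen run --config config.yaml --outdir run/
netscreen report run/
```

Output (abridged):

```
run run: seed 2, netscreen 0.1.0
map degeneration: 25 nodes, avg links per node 3.9, 9 seeds; overlap 18 proteins
map protection: 30 nodes, avg links per node 3.5, 9 seeds; overlap 18 proteins
training: satisfaction 1.000 on 40 restrictions (objective 0.01650)
screen: 50 drugs, 1225 binary combinations
pass tier: 15 combination(s)
  D28 + D35: efficacy 83.2%, adverse 6.9%, synergy 41.2 pts
  ...
top tier: 2 combination(s)
  D16 + D28: efficacy 79.3%, adverse 0.0%, synergy 41.1 pts
  D16 + D41: efficacy 79.3%, adverse 0.0%, synergy 41.1 pts
```

The run directory contains every intermediate artifact as a plain TSV /
YAML / JSON file (`interactome.tsv`, `map_*.tsv`, `model.tsv`,
`ranked.tsv`, `pass.tsv`, `top.tsv`, `moa.tsv`, `manifest.json`, …).
Re-running the same config in the same directory reuses finished stages;
the same seed is byte-identical across machines.

Individual stages are also exposed as subcommands (`netscreen synth`,
`build-maps`, `train`, `screen`, `filter`, `moa`); see `netscreen --help`.

## Package layout

| module | role |
| --- | --- |
| `netscreen.io` | TSV/YAML readers and writers for every artifact (round-trip safe) |
| `netscreen.synth` | synthetic benchmark generator with planted, labeled ground truth |
| `netscreen.maps` | seed → condition-map expansion (k-hop policy, LWCC + seeds), map stats and overlap |
| `netscreen.model` | propagation model, fixed-point engine, annealing trainer, cross-validation |
| `netscreen.screen` | exhaustive pair screen, efficacy/adverse/synergy scores, two-tier filter, mode-of-action extraction |
| `netscreen.pipeline` / `netscreen.cli` | orchestrated runs with manifest + stage reuse; click CLI |

Method details, parameter rationale, and known limitations are in
[docs/methods.md](docs/methods.md).
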