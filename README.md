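# barrierscreen

Systematic in silico screening of enzyme mutants by activation-barrier
estimation along a single-distance reaction coordinate.

## The scientific problem

Improving an enzyme means lowering the activation barrier of its rate-limiting
chemical step. For a retaining glycoside hydrolase, that step (glycosylation)
is bracketed by two stationary points: the non-covalent enzyme–substrate
complex (**ES**) and the covalent glycosyl-enzyme intermediate (**GE**). The
progress of the reaction is well described by one distance, **x₁**, between
the nucleophile's carboxylate oxygen and the anomeric carbon C₁ of the
substrate.

Given those two endpoints, a reaction profile can be mapped by *adiabatic
mapping*: freeze x₁ at a ladder of values between its ES and GE endpoints,
relax everything else at each rung, and read the barrier off the resulting
energy profile. Doing this for **every single mutant of every active-site
position** (19 substitutions × each non-catalytic position within 4 Å of the
substrate) turns barrier estimation into a screening tool: mutants are ranked
by predicted barrier, the best single per position are recombined into double
mutants, and additivity of their effects is analysed.

`barrierscreen` implements that entire pipeline as a library:

- **structure model** — PDB I/O, covalent-link registry, distance queries,
  formal charges under standard protonation rules;
- **mutant factory** — geometric active-site detection, exhaustive single /
  double mutant enumeration, deterministic side-chain construction with a
  χ-angle clash search (sterically impossible mutants are *discarded with a
  reason*, never silently repaired);
- **pathway builder** — five endpoint-derivation pathways, Cartesian
  constraint sets (freeze residues beyond a layer radius), exact-x₁
  interpolation frames, close-contact filter;
- **engine adapters** — a uniform contract for the external semiempirical
  engine (MOPAC-dialect input decks, tolerant output parsing, Lewis-failure
  and charge-mismatch detection) plus an **analytic surrogate engine** with
  programmable ground-truth barriers so the whole pipeline is testable on a
  laptop in seconds;
- **screening orchestrator** — per-mutant pipeline, validity filters, barrier
  extraction, ranking, double-mutant additivity, reorthogonalization
  agreement, Eyring/TST rate conversion;
- **synthetic fixtures** — deterministic toy enzyme/substrate systems with
  controlled geometry and programmed energetics.

## Worked example

`examples/03_single_mutant_screen.py` screens all 38 single mutants of the
toy active site (3 positions inside 4 Å, nucleophile excluded) against a
surrogate surface with programmed barriers:

```text
3 active-site positions -> 38 single mutants
wild-type barrier: 18.50 kcal/mol
computed 38 / 38 (discarded: none)

lowest barriers (kcal/mol):
label   barrier  delta_vs_wt status
 A11E 11.097093    -7.402907     OK
 A10G 11.536000    -6.964000     OK
 A10V 11.617886    -6.882114     OK
 A10Y 12.044542    -6.455458     OK
 A10Q 12.961415    -5.538585     OK

max |recovered - programmed| barrier error: 0.00e+00 kcal/mol
```

The 12-frame ladder recovers every programmed barrier exactly, and the
ranking is the programmed ranking. Rate conversion works the other way too
(`examples/06_rates_and_reortho.py`):

```text
k_cat = 9.6 1/s at 313.15 K  ->  dG+ = 17.0 kcal/mol
inverse check: k(16.9543 kcal/mol) = 9.60 1/s
```

The remaining examples cover fixture generation (`01`), endpoint derivation
and frame ladders (`02`), double-mutant additivity (`04`), engine file I/O
(`05`), and reorthogonalization agreement (`06`). Each runs in seconds:

```bash
python examples/01_toy_fixture.py
```

A thin CLI wraps the same calls:

```bash
barrierscreen fixtures --out scratch/toy       # generate a toy fixture
barrierscreen enumerate scratch/toy/toy_ge.pdb --exclude 1
barrierscreen run --seed 7 --out scratch/records.csv
barrierscreen rank scratch/records.csv --top 10
```

## Reproduction

```bash
python -m pytest -q tests/                     # full suite, ~1 min
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script runs the pipeline's headline computations on seeded
synthetic systems (wild-type barrier recovery with and without a 10 Å
constraint layer, a 30-mutant screen with programmed failures, double-mutant
additivity, enumeration arithmetic, TST conversion) and writes each quantity
as `{"name": {"value": ..., "n": ...}}`. Every number is a deterministic
function of `--seed`.

See `docs/methods.md` for the model, its parameters, the design of the
surrogate surface, and known limitations.
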