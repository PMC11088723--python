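# branchsim

A scenario engine for **branching clinical case simulations** in
health-professions education, built around a severity-stratified point
system for medical errors and correct decisions.

Branching scenarios present a clinical case as a decision graph: at each
step the learner picks one of several options, each routing to a different
continuation. `branchsim` gives those choices a principled score. Errors
are graded on the NCCMERP nine-category seriousness index (A — potential
error that never reaches the patient, through I — patient death), correct
decisions on the specular nine-category positive scale (A′ — no state
change, through I′ — complete recovery). Every category carries an integer
point value and a *development action* (continue, continue with
monitoring/intervention, possible termination, stop, finish/follow-up);
only category I stops the scenario.

| category | A | B | C | D | E | F | G | H | I |
|---|---|---|---|---|---|---|---|---|---|
| error points | 0 | 0 | −1 | −2 | −3 | −4 | −5 | −6 | −10 |
| correct points (A′…I′) | 0 | 0 | +1 | +2 | +3 | +4 | +5 | +6 | +10 |

Each option also belongs to one of 11 **decision blocks** of clinical care
— communication (C), objective examination (OE), differential diagnosis 1
(DD1), lab tests (LT), diagnostic tests (DT), differential diagnosis 2
(DD2), making a diagnosis (MD), treatment (T), manual procedures (MP),
monitoring (M), follow-up (F) — and the total score of a playthrough is the
plain additive sum

Σ = ΣC<sub>n</sub> + ΣOE<sub>n</sub> + ΣDD1<sub>n</sub> + ΣLT<sub>n</sub> +
ΣDT<sub>n</sub> + ΣDD2<sub>n</sub> + ΣMD<sub>n</sub> + ΣT<sub>n</sub> +
ΣMP<sub>n</sub> + ΣM<sub>n</sub> + ΣF<sub>n</sub>,

where each term is the sum of step points within that block.

The package provides:

* **scenario format** — a versioned JSON script (decision nodes, categorized
  options, terminals) with parsing, canonical serialization, and validation
  (category-I options must stop, graphs must be acyclic and reachable,
  escalation-clause advisories for worsening steps after E–H harms);
* **scoring engine** — deterministic playthrough execution with per-block
  accumulation and stop semantics;
* **path analytics** — exhaustive root-to-terminal path enumeration, the
  score envelope, and the exact (rational-arithmetic) expected score under
  uniform choice;
* **learner simulation** — seeded Monte Carlo playthroughs under uniform,
  best, worst, and ε-greedy policies;
* **feedback statistics** — two-group Likert comparison tables from
  summary statistics (Welch or pooled t-tests), the averaged-score row, and
  a seeded synthetic Likert generator;
* **generators** — deterministic scenario fixtures, plus a hand-built
  reference case touching all 11 blocks.

## Worked example

Export the shipped reference case and replay a mixed-quality playthrough —
a rushed intake (D, −2), a sound differential (C′, +1), diagnostic
anchoring (E, −3), a botched procedure (G, −5), then diligent monitoring
(G′, +5):

```
$ python -c "from branchsim import reference_scenario, save_scenario; \
             save_scenario(reference_scenario(), 'reference.json')"
$ branchsim play reference.json --choices \
    intake_rushed,exam_syndrome,workup_anchor,manage_botched,salvage_monitor
  intake -> intake_rushed [D -2 C]
  exam -> exam_syndrome [C' +1 DD1]
  workup -> workup_anchor [E -3 DD2]
  manage -> manage_botched [G -5 MP]
  salvage -> salvage_monitor [G' +5 M]
     C: -2
   DD1: +1
   DD2: -3
    MP: -5
     M: +5
 total: -4
status: finished
```

(zero blocks elided here; the command prints all 11). The five step points
−2+1−3−5+5 re-sum to the −4 total — the additive formula in action.

Exact analytics over the same case:

```
$ branchsim analyze reference.json
paths: 50
envelope: [-15, 12]
expected score (uniform choice): -29/18 = -1.6111
```

A learner guessing uniformly at random averages −1.61 points over the 50
possible paths; a perfect run scores +12, the worst survivable-then-fatal
sequence −15. A mostly-competent simulated learner (best option with
probability 0.8):

```
$ branchsim simulate reference.json --policy epsilon_best --epsilon 0.2 \
    --n 1000 --seed 42
       n: 1000.000
    mean: 9.175
      sd: 5.719
     min: -12.000
  median: 12.000
     max: 12.000
```

Feedback statistics from per-criterion group summaries (CSV of
`criterion,group,n,mean,sd`) are available via `branchsim stats`, and
`branchsim tables` prints the full category reference tables.

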