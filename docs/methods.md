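# Methods

## The scoring model

`branchsim` implements an additive point system for branching clinical
case scenarios. Its backbone is the NCCMERP nine-category index for the
seriousness of medication errors, generalized to medical errors: each
category is defined by whether the error occurred, whether it reached the
patient, the associated harm, and the measures required. Categories map to
integer points — A/B: 0, C: −1, D: −2, E: −3, F: −4, G: −5, H: −6,
I: −10 — and correct decisions use the specular scale A′…I′ with exactly
negated values (0 … +10). Two modelling facts are preserved verbatim
rather than smoothed:

* the **gap** between H (−6) and I (−10) is intentional — patient death is
  qualitatively, not incrementally, worse — and is not interpolated;
* the mirror symmetry `correct_points(X′) = −error_points(X)` holds for all
  nine codes and is enforced by tests.

Each category carries a *development action*. Only category I is terminal
(STOP): after a fatal error no further step can be scored, and validation
requires every category-I option to route to a `stopped` terminal.
"Possible termination" (G/H) and "successful finish" (F′–I′) actions are
realized through graph structure — authors route those options to terminal
nodes where appropriate — rather than by engine-forced termination, because
the action semantics are advisory ("continue **or** finish") rather than
mandatory.

Categories E–H carry an **escalation floor** (E→F, F→F, G→G, H→H): if the
situation worsens after such an error, the follow-up step should be
classified at or below the floor. The floor is advisory authoring
metadata: validation emits a warning (rule V5) when a worsening error step
directly after an E–H option is more benign than the floor, but no point
arithmetic is rewritten — worsening is modelled as additional scored steps
carrying their own categories. The E row's floor is encoded as F exactly
as the classification states it, even though one might have expected E.

## Scenario graphs and the total score

A scenario is a directed **acyclic** graph of decision nodes (ordered,
categorized options) and terminals. Acyclicity is a hard rule: repetition
as a learning device is handled by replaying a scenario, not by in-graph
loops, which keeps path enumeration and expected-score computation exact
and finite. Every option carries exactly one category and one of the 11
decision blocks (C, OE, DD1, LT, DT, DD2, MD, T, MP, M, F); the total score
is the sum of the 11 per-block sums, identically equal to the sum of step
points (an invariant exercised on every generated playthrough). Scores
remain raw integers; no normalization or pass threshold is applied.

Scripts are JSON with an explicit `format_version` ("1.0"). Serialization
is canonical — nodes sorted by id, options kept in document (display)
order, two-space indentation — and the node tuple is canonicalized at model
construction, so structural equality and byte-identical serialization
coincide and `parse ∘ serialize` is the identity.

## Path analytics

All root-to-terminal paths are enumerated by depth-first replay through the
scoring engine, each with its uniform-choice probability (the product of
1/k over visited decision nodes with k options). Probabilities and
expectations use exact `fractions.Fraction` arithmetic so the oracle
identity — backward-recursion expectation equals the probability-weighted
path sum — can be asserted with `==`, never with a float tolerance.
Enumeration refuses scenarios above a configurable path cap (default 10⁶),
counted beforehand by a cheap recursion.

## Learner policies

Policies map a decision node to a distribution over its options: `uniform`,
`best`, `worst`, and `epsilon_best`. **Design choice:** `best`/`worst` are
defined by backward induction — the option maximizing/minimizing *option
points plus the value of the target subgraph* — rather than the greedy
per-step argmax of option points. Greedy maximization does not generally
attain the scenario's maximum total (a cheap option may guard a rich
subtree), and the contract these policies exist to satisfy is exactly
"best-policy totals equal the envelope maximum on every run", which the
induction definition meets by construction and tests verify against the
independent enumeration oracle. Ties break to the first option in document
order, for reproducibility.

Each simulate call uses one seed; run *i* draws from
`numpy.random.default_rng([seed, i])`, so totals are reproducible and
extending `n_runs` never reshuffles earlier runs.

## Feedback statistics

Two-group evaluation tables are recomputed from per-criterion summary
statistics (n, mean, SD per group) alone. The default test is **Welch's**
unequal-variance t with Satterthwaite degrees of freedom — chosen for
robustness since group variances need not match — with the pooled-variance
Student variant behind a flag; tests verify the significance conclusions at
the reference effect sizes hold under both. P-values are two-sided. The
averaged-score row is the equally weighted arithmetic mean of the criterion
means, rounded half-up to one decimal (the convention of published
feedback tables; 4.4625 → 4.5). No multiple-testing correction is applied,
matching the analysis the module reproduces.

The package bundles `REFERENCE_FEEDBACK`: per-criterion summaries from a
34-participant two-group evaluation (n = 16 without the score model,
n = 18 with it) of eight criteria rated 1–5. Where the narrative and the
table of that evaluation disagree (engagement SD 0.7 vs 0.5), the table
value is encoded.

### Synthetic Likert generator

`simulate_likert(n, mean, sd, seed)` draws i.i.d. ratings from a pmf on
{1…5} whose population moments equal the targets exactly. The pmf starts
as a discretized, clipped normal at the targets and is then projected onto
the two linear moment constraints by a minimal least-squares adjustment
(SLSQP, pmf kept non-negative); infeasible moment pairs — variance outside
[frac·(1−frac), (mean−1)(5−mean)] for the fractional part of the mean — are
rejected. The generator emulates only the *moments* of rating data: it is
i.i.d. across respondents and carries no rater effects, criterion
correlations, or ceiling clustering beyond what the support forces, so
passing tests certify the statistical pipeline, not the psychometrics of
real raters.

## Problem sizes and numerical choices

The test suite and acceptance script use generated scenario sweeps of
depth 1–4 and branching 2–3 (≤ 81 paths each; ≥ 100 scenarios per sweep),
1,000 random playthroughs for the additivity check, 2,000–4,000 Monte Carlo
runs for distributional checks (asserted at 3–5 standard errors), 10⁴
samples for Likert moment checks (tolerance 0.05), and 150–300 replicates
for the power property at the reference effect sizes. All stochastic tests
are seeded; hypothesis property tests run derandomized.

## Limitations

* Scenario *content* is out of scope: generated prompts are placeholders,
  and no authoring guidance, multimedia, timing, or adaptive difficulty is
  provided.
* Escalation clauses are advisory; the package does not attempt the
  "additional calculations" a worsening cascade might imply, because no
  arithmetic rule is defined for them.
* Custom per-option point weights are rejected: every score comes from the
  two category tables.
* The feedback module works from summary statistics; raw-rating analyses
  (ordinal regression, nonparametrics) are non-goals.
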