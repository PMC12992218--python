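# Methods

## The task and its coherence audit

A participant judges, on a 0–100 scale, the probability that each of two
candidates (by default Trump vs. Biden) wins each of three U.S. states, plus
every two-state composite of those events.  One battery covers a single
*state triplet* — T1 (Ohio, Missouri, Michigan) or T2 (Georgia, Montana,
Nevada) — and comprises 78 items: 6 marginals, 12 conjunctions,
12 disjunctions, 12 conditionals, and all 36 composites again with the two
constituent events presented in the opposite order.  Marginals are elicited
first; composites follow in low-complexity thematic blocks, one block per
(state pair × composite kind), with block order and within-block order
seeded permutations.

Classical probability imposes, for any events A and B:

* conjunction rule: P(A∧B) ≤ P(A), P(A∧B) ≤ P(B);
* disjunction rule: P(A∨B) ≥ P(A), P(A∨B) ≥ P(B);
* binary complementarity: P(A) + P(¬A) = 1, where with two candidates
  ¬(A wins s) ≡ (B wins s);
* joint complementarity: P(A∧B) + P(A∧¬B) + P(¬A∧B) + P(¬A∧¬B) = 1.

Per item we score the violation magnitudes

    CF  = max(P(A∧B) − P(A), 0) + max(P(A∧B) − P(B), 0)
    DCF = max(P(A∧B) − max(P(A), P(B)), 0)
    DF  = max(P(A) − P(A∨B), 0) + max(P(B) − P(A∨B), 0)
    DDF = max(min(P(A), P(B)) − P(A∨B), 0)

and per participant the mean absolute marginal-complementarity deviation
|P(A)+P(¬A)−1| over the three states, and the mean absolute joint deviation
|ΣP(four sign combinations)−1| over six configurations (3 state pairs × 2
presentation orders — the only decomposition of this battery that yields six
complete four-term sums).  All scores are computed on the normalized [0, 1]
scale; a violation requires a *strict* inequality, so exact ties (common
with integer responses) score zero.  Each ordered composite is scored
independently against its two marginals — reversed and unreversed
presentations both count — giving 24 conjunction and 24 disjunction scored
items per participant.  Conditionals are elicited to preserve the 78-item
protocol but carry no scoring rule.

Because it is ambiguous whether violation *prevalence* should pool items
across participants or average participant-level rates, `cohort_summary`
reports both (`*_prevalence_pooled`, `*_prevalence_participant_mean`).

## Elicitation protocol

Sessions emulate a chat-based experiment.  The initialization message is a
one-sentence demographic persona ("You are a 54-year-old female with a
bachelor's degree living in Ohio.") followed by the task instructions; only
the four demographic fields vary between personas.  The instruction text
bundled here is a reconstruction around three known directives — intuitive
first-impression estimates, a single integer 0–100 per item, and answering
as if the election outcome were unknown — and is a fixed template argument,
so alternative wordings can be substituted verbatim.

Each query sees exactly the initialization exchange plus the most recent
`window_pairs` question–answer pairs (default 7, a working-memory-scale
bound; 0 is the memoryless limit).  Replies are parsed as a single integer
token, optionally with a percent sign; anything else (multiple numbers,
out-of-range values, prose) triggers a retry with the identical prompt, up
to 3 attempts, after which the item is recorded as missing.  A session with
more than 10% missing items is flagged.  Item order is re-randomized
independently per persona in a cohort run.  Rounding to integers happens
only at this harness boundary; the generative responders below return exact
probabilities so their analytic invariants can be tested exactly.

## Generative responders (the synthetic-data module)

**Coherent classical.**  Latent beliefs are a probability measure over the
8 joint outcomes (which candidate wins each state).  Every item is answered
with the exact classical probability of its event (conditionals via Bayes'
rule; a conditional on a zero-probability event is skipped and flagged).
All coherence metrics are zero by construction — the oracle for the scoring
rules.  Random belief states are drawn on a dyadic grid (an integer
multinomial composition of 2^30 grains over the 8 outcomes): every outcome
mass, subset sum and complement is then exactly representable in binary
floating point, so the coherent baseline scores *identically* zero rather
than zero-up-to-rounding.

**Bayesian sampler.**  Probability reports arise from S successes in N
memory samples regularized by a symmetric Beta(β, β) prior: an item with
true probability p is answered (S + β)/(N + 2β), S ~ Binomial(N, p), one
independent draw per item.  Composites get fewer samples than marginals
(n_compound ≤ n_marginal) — the model's central biasing assumption — which
pulls compound judgments toward 1/2 and produces conjunction and disjunction
fallacies (including double ones) and complementarity violations; as both
sample counts grow the classical limit is recovered.  Defaults
n_marginal = 18, n_compound = 5, β = 1 sit in the small-sample regime where
the human-like pattern (all four failure families present) is pronounced.
Between-participant heterogeneity is generated by jittering the base
outcome log-weights with zero-mean Gaussian noise (default scale 1.0, a
spread that keeps marginal beliefs dispersed over roughly 0.1–0.9 without
pinning them at the extremes); heterogeneity 0 reproduces the base world
exactly.

**Sequential quantum (noise-free).**  The minimal Hilbert-space realization
exhibiting incompatibility and order effects: a two-dimensional real space
in which the belief state is a ray at angle ψ and each atomic event a
projector ray θ(E), with the negated event on the orthogonal ray
(θ + 90°, reduced mod 180°).  Marginals are squared projections
cos²(ψ − θ).  A conjunction is evaluated *sequentially*,

    P(X then Y) = cos²(ψ − θ_X) · cos²(θ_X − θ_Y),

with the first event X chosen by the *more-likely-first* rule — evaluate
the subjectively more probable constituent first (ties go to the presented
order); `as_presented` ordering is also exposed.  Disjunctions follow by De
Morgan on the complements, with the ordering rule applied to the
complements; conditionals are the symmetric inter-ray projection
cos²(θ_X − θ_Y).

Two theorems of this model shape its empirical signature.  (i) A sequential
product never exceeds its first factor, so under *any* ordering the
conjunction cannot exceed the larger constituent, nor the disjunction fall
below the smaller: **double fallacies are impossible**, while single
fallacies occur freely (e.g. ψ = 0, θ = 30°/60° gives marginals 0.75/0.25
and conjunction 0.5625, a single conjunction fallacy of 0.3125).  Because a
single incompatibility angle drives both CF and DF, participant-level CF and
DF means are tightly coupled across a population of configurations (Pearson
r ≈ 1 on a random grid).  (ii) cos² + sin² = 1 makes binary complementarity
exact.  The four-term *joint* sum, however, is **not** preserved under
per-item more-likely-first ordering: with a fixed first state the four
sign-combination conjunctions telescope to exactly 1, and the
more-likely-first rule substitutes each combo's first factor by the larger
of the two marginals, so the sum is ≥ 1 — generically strictly above it
(deviations of ~0.1–0.4 on a random grid).  The noise-free sequential model
therefore predicts upward joint-complementarity violations alongside exact
binary complementarity; only order-insensitive (fixed-order) evaluation
preserves the joint sum.  The spec-level expectation that both deviations
vanish under more-likely-first ordering is unattainable, and the
corresponding assertion is left failing rather than weakened.

Numerics: the exact-arithmetic bounds in (i) are enforced by clamping
(conjunction at the larger constituent, disjunction at the smaller), which
removes ~1e-16 trigonometric roundoff — e.g. cos²(90°) evaluating to
3.7e-33 — that would otherwise register as spurious sub-epsilon "double
fallacies" under the strict > 0 violation rule.

## What the synthetic cohorts do and do not emulate

Synthetic personas reproduce the study-scale cohort structure (284 T1 + 269
T2 = 553 personas; 553 × 78 = 43,134 records) with plausible demographic
marginals (ages 18–80, four education levels, 50 states), but demographics
do not causally influence the synthetic responders — there is no
persona-conditioned belief content, knowledge, or political alignment, and
real respondents' heaped (multiples-of-10) response styles and sequential
anchoring are absent.  Passing tests therefore certify the *pipeline* —
item algebra, windowed protocol, parsing, scoring identities, inferential
machinery — and the *internal consistency of the generative models*, not
any empirical claim about human or language-model judgment.  Reproducing
the study's empirical contrasts requires the external human dataset and a
live chat backend; the pipeline accepts both through the persona CSV and
the one-method chat-backend contract.

## Numerical and design choices

* Zero-probability conditionals: skipped and flagged, never imputed.
* Missing data: metrics average over available items; coverage below 90% of
  the 54 scoreable items raises an error listing the missing ids.
* Strict inequalities define violations; integer ties score zero.
* Reversed conditionals swap outcome and condition (P(Y|X) vs P(X|Y)), the
  uniform reading of "reversed presentation" for all composite kinds; since
  conditionals are unscored this affects no metric.
* Statistical layer: paired t with df = n−1; Welch t with
  Welch–Satterthwaite (fractional) df; Pearson r for CF–DF coupling; all p
  values two-sided and uncorrected.  Zero-variance contrasts raise an
  explicit degenerate-variance error (reported as a note, not a number, in
  cohort comparisons).
* Problem sizes used by `scripts/acceptance.py`: the full 553-persona
  harness cohort, a 1,000-configuration quantum grid, a 500-participant
  sampler cohort, 100 random coherent worlds, and 10,000 Monte-Carlo
  estimator draws.

## Known limitations

* The quantum component is the minimal 2-D projective model; it does not
  implement POVM-based noisy measurement or sample-based estimation, so it
  cannot produce double fallacies or binary-complementarity violations by
  design (that is its diagnostic value, not an oversight).
* The Bayesian sampler draws one independent binomial per item; possible
  within-participant sample reuse across related items is not modelled.
* No model fitting: responders are simulators with forward parameters only.
* The bundled instruction wording is a reconstruction (see above); studies
  needing the original verbatim text should pass it explicitly.
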