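# Methods

This note documents the models implemented in `songsyntax`, the numerical
and design choices behind them, and what the synthetic study conditions
do and do not establish.

## Models

All models generate a syllable sequence as a walk from a structural start
state to a structural end state; every emitting state carries exactly one
syllable.

**Markov.** One state per syllable. Transition probabilities are the
empirical pair frequencies, including start → first syllable and last
syllable → end. Transitions below a floor (default 0.01) are removed and
each state's remaining outgoing probabilities renormalized; renormalizing
is required to keep a valid generator and is applied uniformly, including
to the start state's transitions. Pruning that would disconnect the end
state raises an error rather than silently producing a defective model.

**Adaptation.** A state with initial self-transition probability
p ∈ [0, 1) and adaptation parameter α ∈ (0, 1] returns to itself with
probability p·α^(k−1) after its k-th consecutive emission; all other
outgoing probabilities are multiplied by (1 − p·α^(k−1))/(1 − p), so each
row stays normalized at every step, and probabilities recover when the
state is left. The convention that the k-th consecutive visit uses
exponent k−1 is what makes the closed-form repeat distributions below
come out exactly. α = 1 is the plain Markov case. During generation the
successor conditional on leaving the state is independent of k (the
rescaling is uniform over non-self targets), so sampling draws
stay-vs-leave first and then the successor from the base non-self
distribution — algebraically identical to materializing the rescaled row.

**Repeat-number families.** With A(n) = ∏_{k=1}^{n−1} p·α^(k−1):

* `single`: P(n) = A(n)·(1 − p·α^(n−1)); geometric when α = 1, peaked
  (interior mode) when p·α is large enough.
* `serial_one`: two serial states sharing the syllable, only the first
  with an (adaptive) self-loop; a hand-off with base probability p₁₂
  adds exactly one further emission. P(1) = 1 − p₁ − p₁₂;
  P(n) = A₁(n)(1 − p₁ − p₁₂)f₁(n) + A₁(n−1)·p₁₂·f₁(n−1), with
  f₁(m) = (1 − p₁α₁^(m−1))/(1 − p₁) the rescaling factor.
* `serial_two`: both serial states adaptive; the total count convolves
  the first state's count with the second's over the hand-off position.
* `pure_serial`: two serial states with no self-loops (P(1) = 1 − q,
  P(2) = q) for near-deterministic double repeats.

Every family is validated against a Monte-Carlo simulator that runs the
literal chain step by step (explicit adapted probabilities, one uniform
draw per step); the closed forms are never used inside the simulator.
The agreement check (`simulation_zscores`) follows standard
goodness-of-fit practice: bins with expected count below 10 are pooled
into a single tail bin, because an isolated far-tail bin with expected
count well under one turns a single chance observation into an enormous
z-score under the (there invalid) normal approximation. Because a check
at 10⁶ draws still spans several hundred pooled bins, "within 3 standard
errors" carries a multiplicity allowance: at most 1% of bins may exceed
3 s.e. (≈0.3% do so by chance) and no bin may exceed 6 s.e. (a genuinely
wrong formula produces z-scores in the tens at this sample size).

Fits are nonlinear least squares on raw pmf values (uniform weights) with
box constraints, the hand-off probability reparameterized as
p₁₂ = (1 − p₁)·w with w ∈ [0, 1] so the row constraint is a box bound.
Multi-start: p from the observed P(1), α from a {0.3, 0.6, 0.9, 1.0}
grid, plus random restarts. Fit adequacy is reported as the centered
cosine similarity between fitted and observed pmfs (identical to the
Pearson correlation).

**POMM derivation.** Run-length-encoded sequences are laid out as a
prefix tree in which every observed sequence maps to a unique
root-to-end path; each state accumulates its syllable's repeat counts
and the empirical distribution of the symbol sequences following it
(truncated at 15 symbols). Same-syllable states merge when their suffix
distributions are sufficiently similar; merging pools all counts
(transitions, repeats, suffixes — counts are conserved) and iterates to a
fixpoint, always taking the most similar pair first (ties broken by
lowest state ids, for determinism). Merging uses the plain (uncentered)
cosine of the suffix pmfs rather than the mean-centered one used
elsewhere: suffix supports can be as small as two strings, and a centered
cosine on a two-point support is identically ±1 with the sign set by
sampling noise, which makes equivalent states unmergeable. The uncentered
cosine of two probability vectors is well conditioned on any support
size. The merge threshold defaults to 0.95.

Pruning removes transitions below 0.01 and states reached fewer than
0.005 times per observed sequence. The reach statistic is each state's
pooled incoming count from the tree replay (exact, since merging
conserves counts) rather than a re-decode of the corpus, which can fail
for sequences whose path was transition-pruned. Dead-end states created
by the removals are dropped too.

Refinement greedily tests deletion of every state and merger of every
same-syllable pair, evaluating each candidate by generating 10 000
sequences (fixed per-candidate seed, so runs are reproducible) and
comparing the full d-value profile. A candidate is accepted iff every
d-value is at or below its benchmark *or* at or below the incumbent's
corresponding d-value; passes repeat to a fixpoint, and candidates
referencing states removed earlier in a pass are skipped. Emitting states
only are counted when model sizes are reported; the start and end states
are excluded.

**POMMA morph.** Each repeating state is replaced using a family
escalation ladder: near-deterministic double repeats (≥ 99% of the mass
on counts {1, 2} with 2 dominant) go directly to the `pure_serial` pair —
a single adaptive state with α → 0 can imitate that pmf numerically, but
two serial states are the structurally meaningful model of an almost
always doubled syllable. Otherwise families are tried in increasing
complexity (`single`, `serial_one`, `serial_two`, `pure_serial`) and the
first adequate one wins. Adequacy is cosine ≥ 0.95; when benchmarks of
the observed corpus are supplied, the fitted pmf must additionally match
the observed one with a d-value at or below half the syllable's repeat
benchmark. The margin of one half is a deliberate safety factor: the
final model is judged on generated sequences, whose sampling noise alone
is of benchmark scale, so the systematic model error has to sit well
below the floor, not at it. Wiring after a split: incoming transitions
attach to the first state; both states exit to the original successors
with the original exit distribution rescaled so every row (self + forward
+ exits) is normalized — the only scaling that preserves each replaced
state's marginal next-syllable distribution. For two serial states with
exits, both use the same (rescaled) exit distribution.

**POMM with repeats (non-adaptive alternative).** Each repeating state is
replaced by a single-syllable sub-model trained with the Baum-Welch
machinery (with one emission symbol the HMM *is* a POMM); the sub-state
count grows from 1 until the sub-model's analytic run-length pmf matches
the observed repeat pmf at cosine ≥ 0.95. Incoming transitions split over
the sub-model's start distribution; each sub-state's end mass exits to
the original successors. Peaked repeat pmfs need several sub-states, so
this model is always at least as large as the POMMA and strictly larger
on peaked fixtures — the compactness argument for adaptation.

**HMM baseline.** Baum-Welch with per-step scaling, a structural start
state and an absorbing end state (start → end and anything → start are
structural zeros; each row satisfies Σⱼ A[i,j] + a_end[i] = 1).
Convergence is the largest absolute change across all transition and
emission probabilities dropping below 10⁻³; 20 random restarts, best
log-likelihood wins, restart seeds derived deterministically from the
master seed. Duplicate sequences are aggregated with multiplicities, so
the E-step cost scales with the number of distinct sequences.

**Decoding.** Viterbi over tokens with the state space augmented by the
consecutive-visit count, so adaptation factors enter path probabilities
exactly; for models whose states carry empirical repeat pmfs, decoding is
over maximal runs (one state per run — same-syllable transitions cannot
occur at the non-repeat level, so a run never spans two states).

## Statistics

Repeat distributions count maximal runs per syllable. N-grams are
sliding windows within sequences (never across boundaries; start/end
tokens excluded), normalized per N; an N with no window is omitted with a
warning. Step probabilities are computed to a horizon T defaulting to the
99th percentile of observed sequence lengths; the end curve at step t is
the fraction of sequences of length < t, which is what makes each step's
probabilities (symbols + end) sum to one. d-values align pmfs on the
union of their supports with missing categories as zero; repeat d-values
are reported only for syllables that repeat in at least one of the two
corpora. Benchmarks assign each sequence to a half with probability 0.5
(empty halves redrawn), 500 splits, 0.95 quantile per statistic. The
permutation test for a difference of means uses (b + 1)/(n + 1)
smoothing so 500 shuffles cannot produce p = 0.

## Synthetic study conditions

The fixture generators define the conditions every test runs under:

* `example_s1` — the canonical two-symbol POMM: U("1") → V("2") with
  V ⇄ W("1") and equal probabilities on every state's outgoing
  transitions; sequences are 12, 121, 1212, … U and W share a symbol but
  differ in their suffix distributions (only W can end), so state merging
  has a well-defined three-state target at n = 5000.
* `random_pomm` — random layered DAGs (bounded sequence length, end
  always reachable). "Identifiable" candidates are rejection-sampled to
  have (a) same-symbol suffix similarity below a ceiling (default 0.9,
  under the merge measure), (b) every state visited at least 5% of
  sequences, and (c) prefix-unambiguous topology: each state's successors
  (and the start state's) carry distinct symbols. Condition (c) is not
  cosmetic — a prefix tree cannot separate two same-symbol states
  reachable through the same prefix, and merging can only merge, never
  split, so recovery is only a meaningful target for models with this
  property.
* `bengalese_like_pomma` — a fixed 7-syllable, 10-state POMMA with one
  peaked single-adaptive state (C: p = 0.9, α = 0.5), one adaptive serial
  pair (A), one near-deterministic double-repeat pair (B, q = 0.97), a
  geometric repeat state (G, α = 1) and a second B state with a different
  continuation. Corpus sizes follow the scale of a few nights of song
  recording: 2000 sequences for model derivation, 400/200 for the
  calibration experiment.

What these conditions do not emulate: segmentation and labeling noise
(every token is correct), within-syllable acoustic variation, long-range
drift over a recording session, and sequence lengths beyond what the
fixture topologies produce. Passing tests therefore establish the
correctness and internal consistency of the algorithms under the stated
generative assumptions, not robustness to annotation errors in real
corpora.

## Numerical details and degenerate inputs

* Closed-form pmfs truncate adaptively where the tail mass falls below
  10⁻¹⁰ (cap 10⁵ support points); all families are verified to sum to 1
  within 10⁻⁸.
* The adaptive-or-not decision after fitting leaves a state non-adaptive
  when the fitted α is within 0.05 of 1; the sampling spread of α̂ on
  truly geometric runs at a few thousand samples makes a tighter cut
  misclassify geometric states as adaptive.
* Suffix-similarity of two states concentrated on the same single suffix
  is 1 by convention; of disjoint single suffixes, 0.
* Generation truncates sequences at 1000 tokens with a warning (escalated
  to an error in strict mode if more than 1% truncate); model validation
  requires the end state reachable from every state, rows normalized to
  10⁻⁶, and no transitions into start or out of end.
* The calibration experiment's acceptance band was fixed in advance:
  every statistic's coverage ≥ 0.90 (the 3σ binomial lower bound at 200
  trials) and the mean across statistics within [0.92, 0.99].
* Model JSON round-trips probabilities exactly (IEEE doubles via their
  shortest repr); files are schema-tagged and validated on load.

## Known limitations

* Adaptation applies to self-transitions only; repeated short phrases
  (ABABAB…) whose pair transitions might also adapt are out of scope.
* Serial splits produce at most two states per syllable per site; repeat
  distributions needing three or more serial states raise an error
  rather than fit badly.
* The refine step is greedy and evaluated on stochastic generation; with
  very small corpora its accept/reject decisions sit inside benchmark
  noise. The per-candidate seeds make any given run reproducible.
* Benchmarks assume sequences are exchangeable; corpora with strong
  session-order effects would need block-wise splitting, which is not
  implemented.
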