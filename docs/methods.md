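# Methods

## The measurement problem

A semantic-fluency list is an ordered sequence of category members produced
under time pressure. Comparing two lists from the same person — typically
adjacent clinic visits a year apart — involves three kinds of change at
once: how many words, which words, and in what order. `fluencyrp`
represents a pair of lists as a binary recurrence (match) matrix and
reduces its order structure to one number, the distance from diagonal.

## Distance from diagonal (DfD)

Let `u` and `v` be the two lists after normalization and unique-reduction
(each token's first occurrence kept, later repeats dropped), and let
`m_ij = 1` iff `u_i = v_j`. Then

    DfD = Σ_ij m_ij · |i − j|

Because the inputs are duplicate-free, each row and column of `m` holds at
most one 1, so DfD is a sum over the shared items of how far each moved in
rank. It is a non-negative integer, symmetric in its arguments, zero for a
perfect order match, and each adjacent transposition of two shared items
changes it by at most 2.

Assumptions and degeneracies worth knowing:

- **DfD measures order similarity *of the overlap*, not overlap itself.**
  Fully disjoint lists also score 0 (no matching cells). In group data this
  confound is mild — adjacent-visit lists overlap heavily — but DfD should
  always be read next to the length metrics.
- **DfD is not length-normalized.** Longer lists mechanically support
  larger DfD. The `metrics` export offers an optional `dfd/(len_a·len_b)`
  convenience column, clearly marked as a non-standard variant; all
  analyses here use the raw integer.
- **Intrusions stay matchable by default.** Unique-reduction removes only
  repetitions; an out-of-category item produced at both visits is genuine
  order information. `compute_dfd(pair, exclude_intrusions=True)` removes
  them instead.

## Token matching

Tokens match by exact string equality after canonicalization: lowercase,
surrounding whitespace/punctuation stripped, internal whitespace collapsed
(multi-word animals stay one token). A vocabulary may add an alias map
(surface form → canonical member, e.g. plural → singular). There is no
stemming or fuzzy matching by default: transcripts in these datasets are
curated, and aggressive stemming would silently merge distinct animals.
Tokens empty after canonicalization are dropped with a logged warning.

## Per-pair metrics

- **Correct-word length**: unique AND in-category tokens per list;
  intrusions are not correct words. The pair average and the signed
  difference (second − first) are both exported.
- **Repetition proportion**: repeats divided by the *total* token count of
  the list (repeats included). The denominator is a documented switch
  (`total` | `unique`): with the unique denominator the degenerate list
  `[a, a]` would score 1.0 — "100 % repetition" — which overstates; the
  total-count reading keeps the proportion interpretable as "share of
  production that was perseveration".
- **Intrusions**: counted per occurrence (a repeated intrusion counts each
  time), summed over both lists of the pair. When the source table carries
  curated intrusion flags they take precedence over vocabulary lookup.

## Group heatmaps

Every chronologically adjacent within-participant pair contributes its
binary matrix (raw mode by default, so perseverations appear as the extra
points they are in the drawn plots). Matrices are zero-padded to the
group's maximum dimensions with the origin — first-recalled × first-recalled
— anchored at (0, 0): early-recall positions are the comparable ones across
lists of different lengths, and this anchoring is what concentrates mass
near the diagonal origin. The padded sum divided by the number of pairs
gives per-cell proportions in [0, 1]; two groups' grids, co-padded, subtract
to a difference map in [−1, 1].

A pair belongs to a diagnostic group only if **both** visits carry that
label (`pair_rule="both-visits"`); a participant transitioning between
diagnoses contributes no pair spanning the transition. The relaxed
`"first-visit"` rule assigns pairs by the earlier visit's label.

## Statistical analysis

**Analysis sample.** Participants with fewer than two lists are dropped
(no pair to score); participants ever labeled both HC and ProbAD are
dropped (group membership would be ambiguous); participants never labeled
either are dropped; each survivor contributes the metrics of their first
chronological pair only, because later pairs from the same person are not
independent observations. The filter reports stage-by-stage counts.

**Group comparisons** use the Welch unequal-variance t-test with the
Welch–Satterthwaite (fractional) degrees of freedom and two-sided p-values,
via `scipy.stats`. Two constant samples with different values return an
infinite statistic flagged `degenerate` rather than an exception.

**Model ladders.** Logistic regressions predict diagnosis (HC = 0,
ProbAD = 1) from z-scored metrics. z-scoring uses the sample SD (n − 1);
the design contains the intercept, the z-scored mains, and *all* products
of the mains (2-way up to n-way); interaction columns are not
re-standardized, and their names are canonicalized (sorted) so nesting
checks are order-insensitive. Each ladder is fit twice — with and without
the DfD score and all its interactions — and compared by the
likelihood-ratio χ² test, `LR = 2(LL_full − LL_reduced)` on the
parameter-count difference. The reported per-model `df` excludes the
intercept (the convention of regression tables in this literature);
`n_params` includes it; the LR df is identical either way. The five
standard ladders pair DfD against: average length + repetitions, average
length + intrusions, average length + length difference + repetitions,
length difference + repetitions, and length difference + intrusions.
(Repetitions and intrusions never co-occur in one model: with both rare
error types together these fits are known not to converge.)

**Convergence is reported, not papered over.** Fits that raise (perfect
separation, singular Hessian), fail the optimizer's convergence check, or
converge with |coefficient| > 50 on z-scored columns (quasi-separation: the
likelihood is flat and estimates diverge) are flagged `converged=False`;
LR comparisons refuse non-converged inputs, and the ladder output records
the gap.

## The synthetic cohort generator

The generator emulates the generative story behind the clinical contrast:
a person owns a personal *active vocabulary* — a frequency-weighted (Zipf,
weight ∝ 1/rank) subset of the category, shrunken in disease; each visit
they produce a roughly normal number of items with frequent items
surfacing early; between visits each item reappears with probability
`item_retention`, the retained order is perturbed by
`round((1 − order_stability) · n²/2)` random adjacent transpositions, the
list refills from the personal vocabulary, and perseverations/intrusions
are injected at per-token rates. Adjacent transpositions are the
perturbation kernel because DfD responds smoothly to them (±2 per swap).

Two participant-level random effects give realistic between-person spread:
a personal mean list length ~ N(group mean, group SD) with a within-person
visit-to-visit SD of 1.5 words, and a personal order stability ~ N(group
mean, group SD) truncated to [0, 1]. Without them, simulated groups are
nearly separable on length alone and logistic fits quasi-separate —
unlike any real cohort.

Default profiles (the study conditions the package simulates):

| parameter | HC | ProbAD | basis |
|---|---|---|---|
| active vocabulary size | 48 | 20 | shrunken semantic network in disease |
| mean list length (words) | 19.6 | 12.5 | reported clinical group means |
| between-person length SD | 3.35 | 3.67 | reported clinical group SDs |
| order stability (mean ± SD) | 0.62 ± 0.25 | 0.90 ± 0.08 | calibrated, see below |
| item retention | 0.88 | 0.95 | calibrated, see below |
| repetition rate / token | 0.020 | 0.100 | realized rep. proportions 0.020 / 0.090 |
| intrusion rate / token | 0.0036 | 0.016 | ≈ 0.14 / 0.40 intrusions per pair |

Order stability and item retention are not directly observable; they were
calibrated once, by grid search at n = 150/group, so that simulated group
mean DfD lands on the reported clinical values (≈ 43.5 for HC, ≈ 14.5 for
ProbAD), and then frozen. The calibrated generator also reproduces,
without further tuning, the relative strengths of the five ladder
comparisons seen in clinical data (median simulated LR ≈ 50 for the
length-difference + repetitions ladder, where the clinical value is ≈ 47;
weak and sometimes non-significant for ladders that already contain the
average length).

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: semantic clustering and subcategory switching
(items are exchangeable given frequency), practice/familiarity effects
across many visits, transcription noise, diagnosis transitions,
age/MMSE/sex covariates, and the full dispersion of healthy-control DfD
(simulated SD ≈ 19 vs ≈ 28 in clinic — real heterogeneity has sources this
mechanism lacks). Determinism: every participant draws from a substream
seeded by (seed, group index, participant index), so cohorts are
byte-identical across runs and generation order.

## Numerical and edge-case choices

- Matrix coordinates are 0-based internally, plots label 1-based;
  |i − j| is invariant to the base.
- Empty lists: DfD 0, repetition proportion 0, empty matrix dimensions.
- Visit order from dates: ascending label order, ties broken by file order
  with a warning.
- LR with zero df difference (identical designs): p = 1 at LR 0.
- Logistic fits: Newton iterations capped at 200; the quasi-separation
  threshold on z-scored columns is |β| > 50.
- χ² p-values reported to 4 significant digits; no multiple-testing
  correction is applied (five pre-specified ladder comparisons).

## Simulation sizes used in the test suite

The packaged checks run at desk scale, chosen as the smallest sizes at
which the estimated quantities are stable: oracle equivalence on 1,000
random list pairs of length ≤ 12 over a 20-word alphabet; direction and
power checks on cohorts of 120 participants (60/group, two visits); ladder
power over 100 simulated cohorts; the null rejection rate over 600
cohorts, because the finite-sample size of the LR test (≈ 7.5 % at nominal
5 % with these skewed predictors at n = 120; ≈ 6 % at n = 300) sits close
to the tolerance edge and needs the larger replicate count to estimate
precisely.

## Known limitations

- DfD conflates "identical order" with "nothing shared" at 0; report it
  with overlap/length metrics.
- The LR χ² test is anticonservative at n ≈ 120 with zero-inflated
  predictors (see above); exact or penalized alternatives are out of scope.
- Very short or highly disorganized lists carry little recurrence
  structure; the visualization is not informative there.
- The interactive HTML export is deliberately minimal (inline SVG with
  native tooltips); it has no zooming or linked views.
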