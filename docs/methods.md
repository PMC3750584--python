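# Methods

This note records the modeling assumptions, numerical choices and open
design decisions behind `timkit`, in the spirit of a statistical
software methods appendix.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Sensitivity scoring

The score maps IC50 to [0, 1] with anchors y(Cmax) = 1 and
y(MaxDose) = 0 and a log-linear middle branch.  Writing
r = 1 − log(Cmax)/log(MaxDose), the middle branch is
y = (1 − log(IC50)/log(MaxDose)) / r.  A widely-quoted variant uses the
un-inverted constant c = r instead of 1/r; that variant is *not*
continuous at Cmax (y jumps from 1 to r·(1 − log Cmax/log MaxDose) = r²
≠ 1 in general), so the continuous normalization is the default and the
other form is kept behind `BinarizationConfig(continuous_c=False)` for
comparison only.  Drugs whose IC50 was never reached within dosing
score 0: extrapolating beyond the screened range cannot be quantified.
When no Cmax is recorded, MaxDose/10 is substituted with a warning —
the scoring needs *some* toxicity anchor and a fixed fraction keeps the
substitution transparent and reversible.

All concentrations are nM and are floored at 1.01 nM before logs
(base 10) are taken.  The floor keeps every log strictly positive so
the binarization window α·log IC50 ≤ log EC50 ≤ β·log IC50 stays
well-ordered; sub-nanomolar potencies would otherwise flip the
inequality.  Defaults α = 0, β = 2: the window reaches down to 1 nM
(accommodating cooperative low-EC50 side targets) and up to IC50², a
deliberate compromise between capturing side targets and admitting
far-off interactions; β is exposed for sensitivity analysis and values
up to 3–4 remain reasonable.

Scores of a culture are additionally min–max rescaled to span [0, 1]
(`rescale_scores=True`, default), mirroring per-culture scaling of
experimental sensitivities; the flag exists because scoring-only
pipelines may prefer the raw anchored scores.

## Target-set scoring and search

Γ(T) adds the within-bin ℓ1 deviation and an inconsistency penalty.
The penalty compares every drug's scalar score against the mean of
every *other* bin whose pattern is a strict subset (penalized if the
bin out-scores the drug) or strict superset (penalized if it
under-scores it); strictness uses ε = 1e−9 so float noise never
triggers a penalty.  The all-bins pairing (rather than only the
nearest subset/superset bin) is the stricter reading and the default.
The empty-pattern bin is legitimate: it anchors the "no relevant
inhibition" side of the partition.

One consequence worth knowing: with many drugs and noisy scores the
penalty term scales like O(m²·σ) while the fit term scales like O(m),
so on large noisy screens Γ increasingly favors coarser target sets.
This is a property of the objective, not of the search.

SFFS starts from ∅; the forward step adds the candidate minimizing Γ
(ties to the lowest target index); the floating backward step
repeatedly removes the member whose removal most lowers Γ, as long as
that beats the best set recorded at the smaller cardinality (the
canonical conditional-exclusion rule).  The best set per cardinality is
tracked; the search stops when a full pass improves none of them or a
cardinality cap (default 20) is hit.  A plain greedy forward sweep is
folded into the records so the result can never fall behind pure
forward selection, the final answer breaks Γ ties toward smaller then
lexicographically smaller sets, and members whose removal leaves Γ
unchanged are pruned — the returned set is locally minimal.  Targets
hit by no usable drug are skipped as candidates (they cannot change the
partition).  One Γ evaluation is O(m²) in the number of drugs and one
sweep costs O(|K|) evaluations.

## TIM inference

Experimental entries are bin means (keeping the TIM consistent with
Γ's partition).  The all-zeros and all-ones combinations anchor at 0
and 1 unless measured.  For an unknown combination the bracket takes
the known subset of highest sensitivity (ties: largest cardinality,
then lowest bitmask — the "closest" subset) and the known superset of
lowest sensitivity (ties: smallest cardinality, then lowest bitmask),
then interpolates with the ratio (d/h)ⁿ, or Σα over added targets /
Σα over transition targets raised to n when per-target weights are
given.  The discount n defaults to 1 (linear); decreasing n is
optimistic.  The weighted ratio's numerator covers the d added targets
and its denominator all h transition targets, the only grouping
consistent with the unweighted form and the d = h endpoint.

Two repairs keep the map monotone, because raw bracket interpolation is
not jointly monotone even on consistent data (the anchors shift between
neighboring patterns and can invert a subset pair):

* **Clamp.**  If the data itself is non-monotone (best subset above
  worst superset), the upper bound is clamped up to the lower and a
  structured `InconsistentDataWarning` names the offending
  combinations once.  Measured entries are never edited, so the
  violation stays localized at the data.
* **Monotone closure.**  An inferred prediction is the maximum of its
  own interpolated value and the predictions of its immediate subsets.
  For consistent data the closure provably stays within the Rule-3
  bracket, and it restores p ⊆ q ⇒ ŷ(p) ≤ ŷ(q) everywhere except at
  measured entries that themselves violate the order.

Dense materialization is allowed up to 30 targets (2³⁰ entries);
beyond the default dense cap of 16 the map should be used lazily
(memoized per-pattern inference), which yields identical values.

Continuous dosing support: at concentration x a target with half
inhibition constant e is inhibited with ratio z = x/(x + e) (the
logistic in log-concentration, exactly 0.5 at x = e); combinations of
drugs compose independently as 1 − Π(1 − z), a stated convention (no
canonical formula exists), and thresholding z ≥ 0.5 is the documented
bridge back to binary profiles.

## Circuit extraction

The minimal-equation search walks combination sizes 1..M (default
M = 4, keeping the O(D·n^M) inference count desk-scale for ~20-target
maps), judging measured combinations against θ_e and inferred ones
against θ_i (both default 0.5, the natural binarization midpoint), and
never expands past an accepted term.  Measured combinations larger than
M are admitted as terms but not expanded.  An inferred term
contradicted by a measured superset below θ_e is dropped with a warning
(reachable only when θ_i < θ_e, since otherwise the clamp analysis
makes the contradiction impossible).  The final term set is an
antichain by construction and enforced by the `BooleanEquation` type.

Block grouping is display-only and heuristic (no canonical grouping
exists): greedily pick the target shared by the most uncovered terms,
try to factor those terms as a cartesian product of OR-lines, fall back
to one block per term.  An expansion check that the blocks reproduce
exactly the equation's terms is mandatory, so the heuristic can never
change semantics.  DOT output is deterministic: blocks in series
between junction points, each line a chain of target boxes.

## Cross-validation

Binarization is a fixed per-drug preprocessing (thresholds come from
config, the per-culture rescale from the full screen), so it is done
once; target selection and TIM construction are retrained inside every
fold — reusing a globally selected target set would leak the withheld
drugs' information.  Drugs excluded by binarization appear in reports
(prediction 0, flagged) but not in MAE or correlation denominators.
k-fold uses seeded fold assignment with fold sizes within one drug;
k = m reproduces leave-one-out exactly.  Pearson r pools all scored
(ŷ, y) pairs of a report.

The similarity Λ between two EC50 profiles sums min(E1, E2) over shared
targets against max(E1, E2) over the union.  Note that two drugs with
half their targets overlapping at equal EC50s do *not* generally score
0.5 — the union denominator includes the non-shared EC50s — and the
measure is implemented exactly as defined, with that caveat documented
rather than "fixed".  Two empty profiles score 0 with a warning.

## Synthetic benchmark generator

The generator emulates compact kinase survival circuits: for n_active
targets it draws L ≤ 3 serial blocks, each with ≤ 3 parallel lines
(uniform over the feasible counts, sizes by uniform random
composition), and embeds the active targets among 10 decoy kinases.  A
drug has Boolean sensitivity 1 iff its inhibited set contains at least
one target from every line of some block.  Library drugs inhibit
Poisson(λ = 3, min 1) targets drawn uniformly from the whole universe —
a screen in which most kinases are irrelevant and most drugs hit a
handful of targets.  Ground-truth 0/1 sensitivities feed the pipeline
directly as scores (no IC50 detour), matching the Boolean setup;
predictions are thresholded at 0.5 for accuracy scoring and a seeded
coin-flip baseline is reported alongside.  The benchmark's standard
scale is 40 replicates per n_active ∈ {6..10}, 60 training / 40 test
drugs per replicate from a 1000-drug library; everything is
reproducible from a single seed.

What the generator does *not* emulate: EC50 measurement error and the
IC50→score reduction (bypassed by design here), dose-dependent partial
inhibition, tumor-suppressor (NOT) or XOR relationships — the rule set
deliberately covers tumor promoters only — and correlated drug
families (library profiles are independent draws).  Passing benchmarks
therefore demonstrate recovery of monotone block structure from sparse
binary perturbations, not robustness to those real-data features.

For the parameter-recovery experiment the screens are exhaustive
perturbation panels over the pathway's own targets (every inhibition
combination measured once, Gaussian σ = 0.05 on the 0/1 sensitivities,
no decoys).  This is the identifiable setting for the question "does
the inference layer reconstruct a known circuit?": under sparse random
panels the Boolean function is generically *not* identifiable — targets
whose inhibition never flips any sampled drug's sensitivity are
invisible, and the Γ-minimal target set is then legitimately smaller
than the active set — so exact term recovery there would measure the
panel, not the method.  Circuit recovery is evaluated on the map built
over the true target set; predictive error (leave-one-out MAE, full
pipeline including selection) is evaluated on the same screens.

## Network dynamics

States carry one bit per target plus a phenotype bit (bit 0).
Transitions: an inhibited target is forced to 0; otherwise a mutated /
latently activated target rises to 1; otherwise the target follows its
upstream activators (OR by default, AND per node on request — OR is the
common case in curated pathways); a target with silent upstream decays
to 0; the phenotype bit copies the tumor driver's activation of the
previous step.  Activation graphs must be acyclic (feedback loops are
out of scope).  Attractors are found by iterating the deterministic map
(any trajectory cycles within 2^(n+1) steps, enforced as a hard stop);
a limit cycle counts as tumorous if *any* of its states is tumorous — a
conservative convention, chosen here, since oscillating phenotypes have
no canonical steady-state reading.  The dynamics-derived TIM runs the
inhibited network from the all-active state for each of the 2ⁿ
combinations (exhaustive mode capped at n = 16).

Counting: a block structure with L serial blocks and line sizes b
admits at most L!·ΠΠ b! distinct directional models.  The expected
number of steady-state experiments to order the L blocks is (2L − 1)/3
for L ≥ 2 and 0 for L = 1.  The worst-case bound for full
directionality adds, per block, max(max_j b_j − 2,
⌈(Σb_j − a)/(a − 1)⌉ − 1) to L − 1; the expected-case analog replaces
the inner counts by (2b_j − 4)/3 and ⌈(2Σb_j − a)/(3(a − 1))⌉ − 1 and
adds (2L − 1)/3.  (A stray symbol in the source derivation's final
"−1" terms is read as minus one, the only reading consistent with the
surrounding pattern.)  Per-block values are clamped at 0, and blocks
with a single line contribute only the line-length term (the cross-line
experiment is undefined at a = 1).  As printed, the worst-case bound
dominates the expected-case bound only when each block has at least two
lines averaging two or more targets; outside that regime the printed
expected-case expression can exceed the worst case, which is preserved
as-is rather than silently repaired.

## Problem sizes and determinism

Default test and benchmark scales (40 replicates × 5 pathway sizes,
1000-drug libraries, 12 recovery replicates at n = 6 and 8) were chosen
so the whole suite and the acceptance script each run in minutes on a
single core while keeping Monte-Carlo noise on reported accuracies
well inside a percentage point.  Every stochastic component takes a
seed or a `numpy.random.Generator`; equal seeds give byte-identical
artifacts (JSON serialization sorts keys, DOT emission is ordered).
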