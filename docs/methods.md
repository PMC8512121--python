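# Methods

## Scope and model

`hawkopt` implements box-constrained minimization with Harris Hawks
optimization (HHO) and an enhanced variant (eHHO), plus the apparatus used
to evaluate such optimizers: analytic benchmarks, a multi-run harness with
nonparametric comparison statistics, and a mixed-integer CNN hyperparameter
search space with a surrogate fitness. All budgets are in fitness-function
evaluations (FFEs); an iteration of a population of N hawks costs N FFEs
(plus up to one extra per rapid-dive candidate, and one replacement FFE for
eHHO), and comparing algorithms at equal FFEs rather than equal iterations
is the package's fairness convention throughout.

## The optimizer

Per hawk per update the algorithm draws scalar random numbers E0 ∈ [−1, 1],
J = 2(1 − r5), and branch selectors q, r ∈ [0, 1]; the escape energy is
E = 2·E0·(1 − FFEs/maxFFEs). `|E| ≥ 1` triggers exploration (random-member
or best-minus-mean move); otherwise one of four besiege modes fires on
(r, |E|). The dive modes propose Y and, if Y fails the greedy test,
Z = Y + S·LF(D) with S ~ U[0,1)^D and LF the Mantegna Lévy generator; Z is
only evaluated when needed (short-circuiting saves an FFE and cannot change
the greedy outcome). Choices the family of published HHO variants leaves
open, fixed here:

* **Lévy exponent** β = 1.5 (the standard Mantegna default), with
  σ(β) = [Γ(1+β)·sin(πβ/2) / (Γ((1+β)/2)·β·2^((β−1)/2))]^(1/β) ≈ 0.6966,
  u ~ N(0, σ²) and v ~ N(0, 1) drawn independently per dimension (u before
  v — draw order is part of the reproducibility contract).
* **Random multipliers are scalars** per hawk per update, the literal
  reading of the update equations; per-dimension variants exist in the
  literature but are not used.
* **Bound handling**: componentwise clamping after every position update.
* **Acceptance**: strict inequality; ties keep the incumbent.
* **Fitness caching**: a hawk's fitness is updated when it moves; the
  population is not re-evaluated wholesale at the top of each iteration.
  This keeps FFE accounting exact at the cost of a minor deviation from
  pseudocode that recomputes all fitnesses per iteration.
* **Accounting modes**: `all` (default) charges every objective call and
  permits a partially updated final iteration; `per_iteration` charges the
  idealized N (or N+1) per iteration, matching textbook complexity
  bookkeeping, and is provided because published budget figures are
  sometimes stated in that idealization.

## The enhancements

* **Chaotic initialization** uses the μ = 4 logistic map. Seeds are drawn
  from the run's single RNG stream and rejection-sampled away from
  {0.25, 0.5, 0.75, 1} (absolute tolerance 1e−12), where the map collapses
  onto fixed points or short cycles. Each individual is scaled by one
  scalar β_i (per-individual, not per-dimension — the literal reading of
  the mapping), then clamped, since scaling toward the origin can leave
  boxes with positive lower bounds. Selection of the best N from the 2N
  union is by stable sort on fitness.
* **QRL** draws per coordinate uniformly on the order-agnostic interval
  between the box midpoint and the incumbent best's coordinate.
* **CS** builds its spanning point from a *fresh per-dimension* logistic
  sequence each trigger (a scalar would collapse the spanning point onto a
  line through the box).
* **Controller**: the replacement step runs once per iteration after the
  hawk sweep. The branch order is: past the FFE threshold ψ, QRL challenges
  the worst hawk; before it, QRL challenges the best (stagnation counter k
  incremented on failure, reset on success); at k ≥ bt, CS challenges the
  best. The direction of the ψ comparison follows the controller equations
  as published together with the ψ-ablation that confirms them (ψ = 0 ⇒
  worst-replacement, i.e. exploration, throughout; ψ = maxFFEs ⇒
  best-refinement throughout); the accompanying prose suggests the opposite
  phase order and was not followed. k is also reset when CS improves the
  best — the source only states when k increments; resetting on any
  successful best-improvement is this package's choice.
* **Defaults**: ψ = maxFFEs/4; bt = round((maxFFEs − ψ)/(10N)) for
  benchmark-length budgets and round((maxFFEs − ψ)/N) for short
  design-search budgets, half-up rounding (so 37.5 → 38 deterministically,
  independent of banker's rounding), clamped to ≥ 1 with a warning.

## Benchmarks

Builtin functions are the classic, unshifted, unrotated textbook forms on
the boxes used by the CEC2019 "100-digit" suite (e.g. Rastrigin and Ackley
on [−100, 100]^10; Chebyshev fitting at D=9 on [−8192, 8192]; inverse
Hilbert at D=16; 6-atom Lennard-Jones at D=18 on [−4, 4]). The 12-6
Lennard-Jones minimum is the octahedron; the exact value −39204/3084 ≈
−12.7120622568 and the closed-form octahedron radius are recorded and
tested. Modified Schwefel uses the high-precision constants 418.9828872724338
and 420.9687462275036 so its recorded optimum holds to 1e−9. The official
shifted/rotated suite (functions 4–10) requires externally distributed
shift/rotation data; the adapter loads it from a user-supplied directory
and fails loudly when files are missing rather than substituting classic
forms, so classic-form results can never masquerade as suite results.

## Comparison statistics

The Friedman statistic is the classical tie-uncorrected form; on the
bundled reference table — which contains a fully tied row — it reproduces
the originally reported χ² = 51.4, so the original analysis evidently did
not tie-correct. A corrected variant is behind a flag. Holm p-values use
the one-sided upper-tail normal approximation with SE = √(k(k+1)/(6n)),
which reproduces the reported extremes (2.37×10⁻⁸ and 1.90×10⁻¹) to three
significant figures. In the step-down thresholds α/(K−i), K is the number
of comparisons (10 for eleven algorithms), matching the reported threshold
columns; the χ² critical value is taken at k−1 = 10 degrees of freedom.
The Iman–Davenport value reported alongside the source table (9.53) follows
from the rounded χ²; full precision gives 9.536, and the test tolerance
covers both.

Two bundled confusion-count tables carry the reported metric columns for
cross-checking the metric calculator. Their printed values mix rounding
conventions (0.9745 appears as 0.974 while 0.9775 appears as 0.978, and one
F1 was formed from already-rounded precision/recall), so recomputation is
checked to within one unit in the last printed decimal rather than half a
unit.

## CNN design space

The 11 genes and their ranges are listed in the package README. Decoding
clamps, then rounds: integers half-away-from-zero, enumerated sets (filter
count, hidden units) to the nearest member with ties to the smaller —
deterministic tie-breaking matters because optimizers revisit boundary
points. The text of the source protocol enumerates those two sets while its
summary table prints them as ranges; the enumerated sets are authoritative
here. The learning rate is searched on its literal linear scale [1e−4,
1e−2]; a log-scale option exists but is off by default, since nothing in
the protocol indicates log-scaling. Encoded activation 4 and optimizer 4
decode to LReLU and Adagrad (standard library spellings).

The **surrogate fitness** emulates what matters for testing a design loop:
a deterministic error in [0, 1] with a hidden ideal configuration, additive
per-gene penalties weighted most heavily on convolution depth and
hidden-unit width (the choices that move real validation accuracy most), a
smooth multimodal ripple that vanishes at the ideal, and exact plateaus
wherever two continuous vectors decode identically. It does *not* emulate
training noise, epoch-budget effects, or interactions between genes, so
passing tests show that the search loop handles a discrete, multimodal,
plateau-rich landscape under a small FFE budget — not that it reaches any
particular accuracy on MRI data. The real Keras backend (80/20 split, up to
100 epochs, early stop after 3 stale validation epochs, validation error as
fitness) is a documented adapter: tensorflow is optional, GPU-scale
training is out of scope for the automated suite, and designs whose feature
map would collapse below 1×1 (impossible at 128×128 input with at most six
2×2 poolings) score the worst error. Dropout layers sit after the first DL
dense layers; pooling is capped at min(PL, CL) blocks. A backend exception
scores 1.0 rather than aborting, keeping budget accounting exact.

## Problem sizes in tests and the acceptance script

The paired-dominance check runs 30 seeds per function on sphere/Rastrigin/
Ackley at 10-D and the reference budget of 25,000 FFEs; the acceptance
script reports 10-run means at the same budget and the full design protocol
(N=50, 800 FFEs, ψ=200, bt=12) over 10 paired surrogate instances. These
sizes keep a full desk run in the low minutes while leaving the budgets and
population sizes at their reference values.

## Known limitations

* The optional suite adapter's shifted/rotated composition follows the
  widely used shrink-rate convention but is validated only on its analytic
  members and error paths; exact parity with the official C implementation
  on functions 4–10 is not claimed.
* Basic HHO already solves most 10-D classics to machine precision at
  25,000 FFEs, so the enhancement's advantage there shows as non-strict
  dominance; tighter budgets (see the benchmark example) separate the two.
* The replacement controller's published prose and equations conflict on
  the ψ phase order; this package follows the equations (see above) and
  exposes branch counts so users can audit the phase behaviour.
* Only box constraints are supported; no discrete/combinatorial or
  multi-objective variants.
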