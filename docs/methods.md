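# Methods

## Model

The state space is a fixed atlas of N anatomical sites (N = 50 in the
bundled lung atlas). Disease progression is a discrete-time Markov chain:
a row vector *v<sub>k</sub>* of site probabilities evolves as
*v<sub>k+1</sub>* = *v<sub>k</sub>*·A, where A is row-stochastic and
A[i, j] is the probability that a circulating tumor cell leaving site *i*
next colonizes site *j*. The long-time metastatic distribution is the
stationary distribution π, a left eigenvector of A for eigenvalue 1. Row
vectors act on the left throughout, so "stationary" literally means
π·A = π.

Assumptions inherited from this framing:

* progression is memoryless site-to-site (no patient covariates, no
  explicit biology of extravasation/colonization);
* the autopsy-derived target distribution is interpreted as the chain's
  steady state, i.e. end-of-life is treated as the long-time limit;
* time is measured in steps of the chain; only *relative* timescales
  (ratios of mean first-passage times) are meaningful.

## Training (the inverse problem)

Given a target distribution t and a generic distribution g, the initial
matrix A₀ has the target on the primary site's row and the generic on all
other rows (rank 2). Training then iterates:

1. r ← stationary(A) − t (the residual), with stationary(A) computed by
   left power iteration warm-started from the previous iterate
   (absolute L1 tolerance 10⁻¹², cap 10⁵ sweeps);
2. c₊ ← argmax r (over-represented column), c₋ ← argmin r
   (under-represented column), ties to the lowest site id;
3. pick a row uniformly at random; if its entry in c₊ is zero, re-draw
   (`clip_mode="reject_row"`, the default; `"clamp"` keeps the row and
   caps the step instead);
4. move δ = `delta_scale`·‖r‖ of mass (capped so entries stay in [0, 1])
   from (row, c₊) to (row, c₋) — row sums are preserved exactly;
5. stop when ‖r‖ ≤ ε.

The sign convention in step 2–4 (decrease the over-represented column,
increase the under-represented one) is the only one under which the update
reduces the imbalance; convergence is verified empirically down to
ε = 10⁻⁵ on 50-site problems.

Parameters that matter:

| parameter | default | meaning |
|---|---|---|
| `epsilon` | 1e-3 | convergence threshold on the Euclidean residual norm |
| `delta_scale` | 0.1 | step size as a fraction of the residual norm |
| `max_iterations` | 2,000,000 | budget; exhaustion returns best-so-far, flagged |
| `seed` | 0 | row-selection stream; identical seeds give bit-identical matrices |

A 50-site, 27-support problem converges in ~7,000–8,000 iterations
(< 1 s on one CPU core). Because the adjustments are randomized, repeated
runs give an ensemble of distinct solutions; member seeds are derived from
one base seed via a seed sequence, so ensembles are reproducible.

## Effective rank: what training does and does not zero out

A trained matrix's singular-value spectrum has as many non-negligible
values as there are sites receiving incoming probability mass, which is
the size of the **union** of the target and generic supports — not the
target support alone. Reason: for the stationary distribution to equal
the target, all rows of sites *inside* the target support must lose their
mass into generic-only columns, and training does drive those entries to
zero. But rows of sites *outside* the target support carry no stationary
mass, so the residual is blind to them; their generic-distribution entries
in generic-only columns are only suppressed while those columns still hold
transient stationary mass, and freeze at a level set by the convergence
threshold (observed ~10⁻³–10⁻² of the leading singular value at ε = 10⁻³;
shrinking with ε but never below the 10⁻⁶ relative cutoff). Consequently:

* generic support = target support (27 of 50): effective rank 27 exactly;
* generic support 30 ⊇ target support 27 (the default study conditions):
  effective rank 30 — 27 structural values plus 3 residue values from the
  generic-only columns.

The historical claim that the rank equals the number of target entries
therefore holds only when the generic's mass is effectively confined to
the target's sites, or under a zero-tolerance coarse enough to discard
the residue values. We keep the scale-free relative tolerance
(10⁻⁶ × σ₁) and report what it measures.

The spectrum decays approximately as a power law in the index; the slope
is fit by least squares on log σ<sub>n</sub> vs log n over indices
2..(effective rank − 1), because σ₁ reflects row-stochasticity (σ₁ ≥ 1
always, since A maps the all-ones vector to itself) rather than the decay.

## Robustness to the initialization

A rank-2 perturbation (one uniform[−1, 1] vector for the primary row, a
second shared by all other rows, scaled so the mean absolute perturbation
is 5% of the mean entry of A₀, then clamped to [0, 1] and renormalized)
leaves the trained ensemble statistically unchanged: with ensembles of 20
members, the per-index mean singular values of the perturbed ensemble fall
within one standard deviation of the unperturbed ensemble across the
target-support part of the spectrum. The comparison is restricted to those
indices because the trailing residue values (previous section) are
threshold artifacts with near-zero spread: clamping noise re-populates
columns that training only suppresses to the ε scale, so no statistical
agreement can be expected there.

## Mean first-passage times

Two independent routes:

* **Monte Carlo** — walkers start at the source and step by sampling the
  current row; each walker runs until every target site has been visited
  (default targets: all sites; in study runs: the target support, since
  off-support sites receive vanishing mass and would stall termination).
  Arrivals count from step 1, so the source's own entry is the mean
  first-*return* time. Defaults: 10,000 walkers, 10⁶ step cap; truncated
  walkers are excluded from the statistics and a truncated fraction above
  1% raises a reliability warning.
* **Fundamental matrix** — the destination is made absorbing and
  (I − Q)m = 1 is solved over the transient states reachable from the
  source; if the walker can reach a set from which the destination is
  unreachable, the MFPT is ∞ and reported as such.

The two agree within three standard errors on random chains (tested for
sizes 5–8), which is the package's cross-validation of the walker code.

Normalized tables divide every mean (and std) by the reference site's
mean, so the reference row reads exactly 1. For a single-matrix Monte
Carlo table the reported std is per-walker dispersion; the published
table's ± (roughly 10% of the mean) is consistent with spread across
ensemble members of per-member means, not with per-walker dispersion of a
geometric-like variable, and the bundled fixture documents that reading.

## Classification rule

With one-step edge statistics (mean ± std across the ensemble) and best
two-step path probabilities (products of ensemble-mean edges, maximized
over the intermediate site, self-loops allowed), a site is labelled
second-order iff

    two_step ≥ one_step_mean − one_step_std.

This is the only simple operationalization of "taking standard deviations
into account" that reproduces the published 20/7 partition of the 27
lung-target sites exactly, including the position of the cut (Skeletal
Muscle last first-order, Skin first second-order); subtracting a std from
the two-step value as well, or using the bare means, breaks the printed
split. Two-step values use products of means (means of products are not
available from the published tables, and the published two-step column is
itself consistent with products of printed means).

Pathways are first-passage paths: the destination appears only as the
final site, intermediate revisits are allowed, matching the first-visit
semantics of the MFPT. Enumeration prunes below a probability floor
(default 10⁻⁸) and raises on a combinatorial budget (default 10⁵ edge
expansions) rather than hanging.

## Synthetic data

The real target/generic distributions exist only as histograms, so the
generator draws symmetric Dirichlet vectors on a chosen support:
concentration 0.5 by default, giving the observed shape — a few dominant
sites and a long tail — with one parameter; larger values flatten toward
uniform on the support. Default study conditions
(`generate_study`): 50 sites, primary at site 23, target support 27 drawn
to include the primary, generic support 30 ⊇ target support (sites seen
for one primary are a subset of sites seen across all primaries),
independent seeds for the two draws so A₀ has rank exactly 2.

What the generator does *not* emulate: correlations between site
prevalences, the identity of specific anatomical sites, or the sampling
noise of a finite autopsy series. Passing tests on synthetic data
therefore demonstrate correctness of the algorithms (recovery of a known
stationary target, rank structure, MC/analytic agreement), not fidelity
to any particular clinical distribution.

## Numerical choices

* Probability vectors must sum to 1 within 10⁻⁹; an explicit renormalize
  path forgives text-file rounding. Files store floats with 17 significant
  digits, so round-trips are bit-exact.
* Stationary distributions: eigen route takes the left eigenvector nearest
  eigenvalue 1, entrywise absolute value, renormalized; eigenvalue-1
  multiplicity > 1 (checked at 10⁻⁸) or a genuinely mixed-sign eigenvector
  raises a non-uniqueness warning and falls back to power iteration from
  the uniform start — one valid stationary distribution among many.
* Ties in argmax/argmin (training) and in rankings resolve to the lowest
  site id, for determinism under a fixed seed.
* Degenerate training inputs: a flat residual (argmax = argmin) stops the
  loop; a column with no donor row raises rather than looping.

## Test problem sizes

The suite runs ensembles of 8–200 members on supports of 5–27 sites and
single 50-site trainings; Monte-Carlo checks use 200–10,000 walkers on
chains of 2–8 states. These sizes were chosen so the full suite exercises
every code path in a few minutes on one core while keeping statistical
checks well-powered (ensemble spread, skewness, and SE-scaling tests all
operate at ≥ 3σ margins).

## Known limitations

* Edge values across an ensemble are only *approximately* normal: edges
  driven against the [0, 1] boundary during training are necessarily
  skewed (observed |skewness| up to ~10 for near-zero edges). The
  normality diagnostic is therefore population-level — median |skewness|
  below 1 and a clear majority of non-degenerate support-block edges below
  1 — rather than a per-edge guarantee.
* The trained matrix is one member of a large solution family conditioned
  on A₀; nothing identifies it as the biologically correct network.
* Off-support rows of a trained matrix are essentially untrained (they
  keep the generic distribution plus frozen random tweaks); quantities
  that depend on them — including the trailing singular values — are
  artifacts of the initialization, not inferences from the target.
* First-return ("self-seeding time") analysis is out of scope; only the
  instantaneous diagonal weights are ranked.
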