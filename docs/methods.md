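# Methods

## The knockout-depletion measurement

A knockout-depletion experiment deletes an essential gene and watches the
pre-existing protein pool dilute. The analysis rests on three
relationships:

1. **Dilution.** After synthesis stops, total protein amount over a
   progenitor's progeny is conserved, so the progeny-mean concentration is
   `C(t) = C0·V0/V(t)`. Segmented cell area stands in for volume
   throughout; the areal growth rate `k(t) = d ln A/dt` is robust to the
   aberrant morphologies that depleted mutants develop.
2. **Threshold arrest.** Growth rate is step-like in protein abundance:
   essentially wild-type above a critical concentration `C_A`, arrested
   below it. The overabundance is `o = C0/C_A`.
3. **Arrest-time conversion.** Because the population grows exponentially
   at `k0` until arrest, `o = V(T)/V0 = exp(k0·T)`; measuring when a
   mutant stops growing measures its overabundance.

## Single-cell branch (`lineage`)

Growth rates are centered sliding-window least-squares slopes of `ln A(t)`
(default window 5 samples per cell, 7 for the total-area series), with
truncated windows at track endpoints so short post-division tracks remain
usable. The aggregate rate is computed from the total live area, which is
insensitive to division events.

**Arrest detection rule.** The arrest time is the earliest time after
which the aggregate rate stays below `frac·k0` (default `frac = 0.5`) for
at least two consecutive samples, with the threshold crossing linearly
interpolated between samples. For a clean step the windowed slope ramps
linearly through the step, so the half-`k0` crossing is an unbiased
estimate of the step location. Cells lost before arrest contribute area up
to their last frame and are excluded from septation counts.

Two overabundance metrics are reported: `o_elongation = V(T)/V0` (total
live area at arrest over progenitor area) and `o_septation` (final
live-cell count over progenitor count). The elongation metric is the
quantitative one; septation saturates when cells filament without
dividing.

## Library branch (`tfnseq`)

Per-fraction counts are converted to anchored log relative abundances with
a pseudocount of 0.5 and delta-method (inverse-variance) weights
`Var(y_t) ≈ (1 − p̂_t)/(n_t + 0.5)`. Because every model carries a free
intercept, anchoring at the first fraction does not affect any residual
sum of squares. Insertion-level trajectories for one gene are aggregated
by summing counts before fitting.

**Models.** `y = c` (no-effect); `y = c − s·t` with `s ∈ [0, 2k0]`
(sufficient); `y = c` for `t ≤ T`, `c − k0(t − T)` after (overabundant).
The post-arrest slope is fixed at `−k0`: an arrested mutant holds constant
absolute abundance while the library grows at `k0`, and the fixed slope
makes the `o = exp(k0·T)` conversion self-consistent. The breakpoint is
located on a grid at one-tenth of the fraction interval and refined by
bounded scalar minimization; the grid includes `T = t_last`, where the
model degenerates to no-effect, so `rss(M2) ≤ rss(M0)` by construction.
Note that the sufficiency model is *not* nested in the overabundance
model (a gentle decline fits M1 exactly but M2 only approximately), so
`rss(M2) ≤ rss(M1)` is not guaranteed; the stage-2 statistic treats a
negative F as p = 1.

**Sequential tests.** Stage 1 rejects the no-effect null against the
better-fitting alternative with an F statistic on the weighted rss
reduction (2 extra parameters); testing against the best alternative
keeps the residual-variance estimate honest when the true decline is
gentle. Stage 2 rejects the sufficiency null against overabundance
(1 extra parameter). Breakpoint search makes these F references
approximate; simulation shows stage 1 is conservative (empirical
false-positive rate ≈ 0.01 at nominal 0.05 on a 1000-gene null library).
Benjamini–Hochberg correction is applied within each stage across the
library (defaults `alpha1 = alpha2 = 0.05`); the standard error of
`log10 o` comes from the local curvature of `rss(T)`.

**Detection-limit censoring.** Once a mutant's reads reach zero, the log
ratio saturates at the pseudocount floor and later fractions carry no
information about the continuing decline — fitting them as Gaussian data
would penalize the true model. All trailing zero-count fractions after the
first are therefore censored. Trajectories with fewer than four nonzero
fractions (or fewer than four usable points) are flagged unclassifiable
and excluded from downstream fractions and statistics.

**Composition drift.** Relative abundances are normalized by per-fraction
totals, so as perturbed mutants leave the pool every trajectory acquires a
shared rising offset. `classify_library` removes it by control-gene
normalization: either against a supplied reference set (e.g. annotated
neutral loci), or — the default — two passes in which genes classified
no-effect in pass 1 serve as the reference for pass 2. In a genome-like
library (~80% neutral) the drift is small; in balanced synthetic libraries
the correction is what keeps breakpoint estimates unbiased.

`k0` cannot be inferred from relative abundances alone; it is a config
input unless spike-in absolute library sizes are provided, in which case
it is fit from total library growth (`estimate_k0` records which path was
used).

## Expression branch (`expression`)

Message numbers are length-normalized count shares scaled by the total
number of transcripts produced per cell cycle. That absolute scale cannot
be determined from relative RNA-seq; it is a required parameter with a
bacterial order-of-magnitude default (30 000), and results that depend on
it say so. Length normalization can be disabled for 3′-counting
protocols. Genes with `µ_m < 1` are flagged as below the one-message-rule
threshold.

## Optimality model (`rlto`)

Expression noise is gamma with shape `µ_m` and mean `o` (in threshold
units), i.e. `CV² = 1/µ_m` — the burst-limited regime in which message
count dominates cell-to-cell variability. A lognormal with matched mean
and CV is provided as a robustness alternative. Fitness composes
multiplicatively: `F(o) = (1 − ε·o)·[(1 − P) + f_arrest·P]` with
`P = P(level < threshold)`, load `ε` (default 10⁻³, one gene's sufficient
expression as a ~0.1% proteome share) and arrest fitness `f_arrest`
(default 0). This objective is this package's reconstruction of the
published trade-off argument in spirit, not a re-derivation of the full
central-dogma optimization it descends from; it is isolated behind one
function so alternatives are drop-in. The optimizer is a deterministic
log-grid scan (200 points per decade over `o ∈ [10⁻², 10⁴]`, capped below
`1/ε`) plus bounded refinement, with a multimodality flag. `ε` enters the
optimum only logarithmically (`log10 o*` moves by < 2× as `ε` spans two
decades at `µ_m = 10`), which is what makes the predicted `o*(µ_m)` curve
effectively parameter-free. The model is compared to data by evaluation
at its defaults — never fitted — and it is known to sit below measured
overabundances for intermediate-expression genes; no attempt is made to
tune that away.

## Synthetic data: what it emulates and what it does not

`simulate_lineage` grows cells exponentially at per-cell rates
`k ~ k0·(1 + cv·N(0,1))` (floored at 5% of `k0`), divides them at a fixed
doubling area with a symmetric-Beta daughter fraction, partitions the
conserved protein pool in proportion to area, and arrests a cell from the
first sample at which its concentration falls below `C0/o_true`. An
optional Hill-type smooth arrest and an optional synthesis term (the
negative control for the dilution check) are included. Division at a fixed
area and instantaneous arrest are idealizations; real cells show adder-like
size control and a softer rate transition.

`simulate_tfnseq_library` draws per-fraction counts multinomially at fixed
depth (matching fraction sequencing; indistinguishable from independent
Poisson at depth ≫ gene count) around expected relative abundances
`∝ exp(g_i(t))` for the three growth classes, fractions every 2 h over
24 h at depth 10⁵ by default. `simulate_rnaseq` draws reads multinomially
with probabilities proportional to message numbers. `simulate_genome`
composes both: 150 essential and 350 non-essential genes (a deliberately
scaled-down genome), log-normal message numbers
(`log10 µ_m ~ N(0.9, 0.55)`), essential-gene overabundances scattered
(SD 0.15 in `log10 o`) around the RLTO optimum at `ε = 10⁻³` with a 31%
sufficient fraction, and 10% of non-essential genes carrying partial
growth defects. A drawn gene whose `log10 o` falls below 0.15 is labelled
sufficient, so truth classes derive from the drawn overabundance and the
truth table is the reference for recovery tests.

None of the generators emulate PCR/jackpot dispersion beyond multinomial
sampling, insertion-position effects, replicate fractions, or
transformation-efficiency differences between loci — so passing tests
demonstrate correctness of the estimators under the stated noise models,
not robustness to every artifact of real sequencing data. The magnitude of
single-cell growth-rate variability in ADP1 is not established; the 10%
default is a sensitivity-analysis placeholder, not an estimate.

## Numerical choices and degenerate inputs

- Randomness flows from a single integer seed per generator
  (`numpy.random.default_rng`); library seeds are spawned from the config
  seed, and runs are bit-reproducible.
- Strict inequality at the arrest threshold means an `o_true = 1` cell
  arrests at the first sample after `t = 0`, bounding its growth by one
  sampling step — the quantization also bounds arrest-time bias by one
  step.
- `detect_arrest` returns `None` when growth never durably drops below
  the threshold; `fitness_landscape` then reports no arrest abundance.
- Zero/negative areas, non-increasing times, counts exceeding totals,
  duplicate gene ids, empty tables and zero-scale normalizations all
  raise `ValueError` at the boundary rather than propagating NaNs.
- Trend windows are 0.25 wide in `log10 µ_m`, sliding by half a width,
  merged rightward until they hold ≥ 5 genes.
- The median/weighted-mean overabundance statistics include sufficient
  genes at their measured `o = 1` by default (switchable), and
  unclassifiable genes are excluded everywhere and counted in the
  reconciliation report.

## Problem sizes

The shipped tests and the acceptance script run the pipeline at reduced
but statistically meaningful sizes chosen as this package's own test
conditions: 300-gene balanced libraries and 1000-gene null libraries at
depth 10⁵, 20 seeds × 5 overabundance decades for single-cell recovery,
and a 500-gene genome for the end-to-end composition. These sizes keep
binomial error bars tight enough for the recovery claims being tested.
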