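# Methods

## Problem setting

`swarmbo` implements Bayesian optimization (BO) for mixed hyperparameter
spaces in which the acquisition surface is maximized by a swarm
metaheuristic rather than by random multi-start search.  The motivating
application is tuning a transfer-learning CNN for six-class classification
of visual-field (VF) defect images under a severe evaluation budget
(11 objective evaluations per run), where most configurations collapse to
an identical low validation accuracy and only narrow pockets of the space
train successfully.

One BO run is: evaluate a fixed shared starting configuration; then
repeatedly (a) fit a Gaussian-process surrogate to all observations on the
encoded unit cube, (b) score candidates with an acquisition function
(EI, PI, UCB or LCB), (c) maximize that surface with PSO, ABC, HHO, SFO or
a random multi-start baseline, (d) decode and evaluate the argmax.
Proposals duplicating an evaluated configuration are replaced by the best
unseen candidate from the maximizer's final population, so none of the 11
evaluations is wasted re-measuring a known point.

## Search-space encoding

Every parameter maps to a coordinate in [0, 1]: affinely for continuous
kinds, affinely in log10 for the learning rate, and by centre-of-bin for
integers ((i − lo + 0.5)/(hi − lo + 1)) and categoricals ((c + 0.5)/k).
Centre-of-bin encoding gives each discrete cell equal measure under uniform
sampling, and floor-binning with a top-edge rule makes decode∘encode the
identity.  Out-of-box swarm moves are clipped, never reflected.  The
built-in 11-dimensional VGG fine-tuning space uses the tightest round
bounds covering every configuration the reference tuning logs explored
(feature map 16–64, filter 1–3, ReLU/Sigmoid, pool 1–2, four optimizers,
learning rate 1e-4–1e-1 on the log scale, batch 1–32, epoch 10–200,
dropout 0.1–0.9, two fine-tuning booleans).  The epoch and batch lower
bounds are inferences from the smallest logged values, not stated ranges.

## Surrogate

A `sklearn` GP with kernel ConstantKernel × Matérn(ν = 5/2), one shared
length-scale, jitter α = 1e-6, targets standardized internally, and kernel
hyperparameters set by maximum marginal likelihood with 3 seeded restarts.
Observations are canonically sorted before fitting so predictions are
invariant to the order in which points were observed.

The length-scale is bounded to [0.1, 3.0] — sized to a unit cube whose
diameter is √D ≈ 3.3.  This bound matters: on plateau-like data the
unconstrained ML fit is degenerate, running either to a spike solution
(ℓ → 0: every observation is an island, σ constant elsewhere, acquisition
surfaces literally flat) or a mirror-flat solution (ℓ → ∞: σ constant
everywhere).  Both blind the acquisition functions; the bounded fit keeps
σ(x) monotone in distance-to-data at a resolvable scale.  The predictive σ
is floored at 1e-12 to protect downstream divisions.

## Acquisition functions

With μ, σ the posterior moments, f⁺ the incumbent, ξ ≥ 0, β > 0:

* EI = (μ − f⁺ − ξ)Φ(z) + σφ(z), z = (μ − f⁺ − ξ)/σ; max(0, μ − f⁺ − ξ)
  at σ = 0.
* PI = Φ(z).
* UCB = μ + βσ (the maximization convention).
* LCB = −(μ − βσ), maximized — the literal negated pessimistic bound.
  With β > 0 this rewards both uncertainty and *low* predicted mean, a
  deliberately exploration-heavy criterion.  The conventional μ − βσ
  reading is available as `lcb_minimize_mu=False`.

Defaults β = 1.96, ξ = 0.  EI and PI are validated against a stratified
Monte-Carlo oracle (inverse-CDF draws on a jittered uniform grid, 10⁶
points), which estimates E[max(0, y − f⁺)] and P[y > f⁺] to well below
1e-3 without referencing the closed forms.

## Swarm maximizers

All four optimizers share one contract — maximize a batch-callable f over
[0, 1]^D, seeded `numpy` Generator, non-finite values treated as −∞, ties
broken toward the lowest index, best-so-far tracked over every evaluation
so the history is monotone.  Update rules follow the algorithms' origin
formulations:

* **PSO** — inertia w = 0.729, c1 = c2 = 1.49445, velocities clamped to
  ±0.5 box widths and initialized uniformly at random (an explicitly
  supplied population starts at rest).
* **ABC** — SN = 15 sources, employed/onlooker/scout phases, one-coordinate
  moves v = x + φ(x − x_k), φ ~ U(−1, 1), greedy replacement, stagnation
  limit SN·D before a scout redraws a source.
* **HHO** — escape energy E = 2·E0·(1 − t/T) gating exploration against
  four besiege branches; rapid dives take Mantegna Levy steps (exponent
  1.5) and keep the better of dive and current position; the other
  branches move unconditionally.  (Applying greedy acceptance everywhere
  collapses the population onto the incumbent and stalls the
  shrinking-radius besiege refinement — measured as a ~3e-3 sphere gap
  versus ~1e-4 for the canonical form.)
* **SFO** — sailfish fraction 0.3 intensifies around the elite with
  λ = 2·rand·PD − PD; sardines diversify under attack power
  AP = A(1 − 2tε), A = 4, ε = 0.001 (all sardines/dimensions when
  AP ≥ 0.5, else AP-sized random subsets); sardines fitter than the worst
  sailfish are absorbed and respawned.

Default budget is population 30 × 50 iterations.  The random baseline
takes the best of 1000 uniform samples plus 50 single-coordinate polish
steps of shrinking width.

## The plateau benchmark

The synthetic stand-in for the fine-tuning landscape is

value = baseline + (peak − baseline) · max over basins of
[gate-match × exp(−‖u − centre‖² / 2ℓ²)] (+ optional seeded Gaussian noise),

with baseline 20.55 % (the modal accuracy of the reference logs), peak
98.6 % (their best observed accuracy), ℓ = 0.15.  Three basins each
require activation = ReLU plus one specific optimizer (ADAM, RMSprop,
SGD); centres sit over the four training-schedule coordinates
(learning rate, dropout, epoch, batch size) at mid-range, integer
coordinates snapped to encodable bin centres.  Under these defaults ~7 %
of uniformly sampled configurations clear baseline + 1, so the landscape
is "mostly plateau" while wide Gaussian tails give a surrogate something
to learn.  What the generator does *not* emulate: evaluation noise across
re-trainings (off by default), correlations between hyperparameters and
fine-tuning flags, and any structure favouring boundary values — so
passing results here say nothing about landscapes whose optima sit at
parameter-range extremes.

A known and deliberate consequence: on the pre-discovery plateau every
acquisition reduces to σ-seeking, and the *global* σ maximum of a box is
its corners.  Acquisition maximizers strong enough to find that corner
exactly (PSO, ABC, and the σ-amplified literal LCB) therefore propose
extreme configurations which, by construction of interior basins, never
score above baseline; weaker or population-clustered maximizers (random
multi-start, SFO's elite-centred populations) propose typical points and
discover basins far more often.  This is a faithful rendering of a real
BO failure mode under budget-constrained plateau landscapes, and it is
the package's explanation for why a sharper acquisition optimizer is not
automatically a better BO enhancer.

## Visual-field image generator

Humphrey-style sensitivity grids (default 32×32) in [0, 1]: background
0.8 + N(0, 0.05), defect region 0.15 + N(0, 0.05), clipped.  Regions:
central disk of radius U(0.12, 0.25)·width (central scotoma), its
complement (tunnel), a random half (hemianopia), quadrant
(quadrantanopia), top/bottom third (superior/inferior), or nothing
(normal).  Geometry draws precede pixel noise so identically seeded
central-scotoma and tunnel images are exact complements.  Default class
proportions follow the pooled reference dataset
(204/223/160/226/181/274 of 1268); per-class counts use largest-remainder
rounding and the 80:10:10 split is stratified per class with round(10 %)
validation and test.  The generator emulates class geometry only — not
real perimetry threshold values, SITA noise models, eccentricity effects
or instrument artefacts.

## Tiny-CNN demo objective

A pure-NumPy two-block conv-net realizes the configuration→architecture
mapping: block 1 fixed at 4 filters (3×3), block 2 takes feature-map
count, kernel size, activation and pooling from the configuration, then
dropout and a 6-way softmax.  Optimizer family, learning rate, batch size
and epochs come from the configuration, with epochs scaled by
`budget_scale` (default 0.1) and capped at 20.  The two booleans toggle
block trainability after a brief seeded pre-training pass on a synthetic
source task (bright-quadrant classification), imitating
freeze-or-fine-tune transfer.  Training that produces non-finite loss
returns the 6-class chance level (16.67 %) with a warning.  This objective
exists to make tuning runs measurable in seconds-to-minutes on a CPU;
it makes no claim of approaching the reference models' accuracy.

## Evaluation arithmetic

Run summaries use the plain mean μ = Σxᵢ/N over the N = 11 per-iteration
accuracies plus exact order-statistic extrema/median; quartiles use
linear interpolation between order statistics (the published quartiles of
the reference study are not reproducible from its own columns under any
standard convention, so quartiles are reported but not used as checks —
likewise a handful of published means and minima that disagree with their
own columns; the bundled reference columns carry notes on which summaries
are internally consistent).  Confusion matrices are tallied with rows as
actual classes; the per-class rate is the row-normalized diagonal and the
"overall" figure is the unweighted mean of defined per-class rates, which
exactly reproduces both published overall precision values (97.83 and
98.33) from the published per-class rates.

## Reproducibility and problem sizes

Every stochastic component draws from an explicit seed: BO repeat r of a
suite uses master + r, objective noise uses master + 90000 + r (identical
across variants, so comparisons are paired), per-iteration swarm seeds are
drawn from the run's own stream, and GP restarts use the run seed.  The
shipped comparison suites run the 11-evaluation budget over 50 paired
seeds with acquisition maximization at population 20 × 30 iterations;
the standalone-optimizer oracles run population 30 × 200 (sphere) and
30 × 50 (enumeration grid).  These sizes were chosen to make the full
suite run in minutes on one CPU while keeping Monte-Carlo margins far
from the asserted tolerances.

## Known limitations

* The GP uses a single shared length-scale; axis-anisotropic landscapes
  are modelled only on average.
* Categorical dimensions are embedded as ordered unit-interval bins; the
  surrogate sees an artificial ordering of categories.
* The literal LCB form is exploration-dominant by construction and is not
  expected to exploit; it is retained because it is the form the method
  defines, with the conventional reading behind a switch.
* The plateau benchmark's basins are interior by design; conclusions do
  not transfer to landscapes optimized at parameter bounds.
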