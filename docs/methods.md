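# Methods

## Problem and model

During walking, the three lumbosacral joint moments (extension–flexion,
lateral bending, axial rotation) computed by inverse dynamics must be
produced by the trunk musculature, but trunk EMG is rarely recorded.  The
estimator in this package reconstructs the 58 trunk musculotendon-unit
(MTU) activations — 29 per side, grouped into the six anatomical muscles
RA, ES, QL, MF, EO, IO — as non-negative combinations of the time-varying
synergy activations extracted from the ipsilateral leg muscles.  The
premise, supported by the synergy literature on locomotion, is that trunk
and leg muscles share a small set of temporal activation primitives; only
the weights with which trunk muscles recruit them are unknown.

### Musculotendon mechanics

MTUs are rigid-tendon Hill models: fiber length is `lMT − lTs`, normalized
by the optimal fiber length `lMo` and clamped to `[0.01, 1.8]` (clamps are
logged; they occur only for degenerate geometry).  The active force–length
multiplier is the Gaussian `exp(−(ℓ̃−1)²/γ)` with `γ = 0.45`, a standard
width for Hill-type models.  The force–velocity multiplier is fixed at 1
and the passive element is off by default: fiber lengths are tuned to stay
below optimal during gait (see *Personalization*), a region where the
standard passive curve is zero, and a force affine in activation keeps the
weight optimization convex.  Both choices are configurable (`passive=True`,
`gamma=`).

### The weight optimization

With row-max-normalized synergy activations `H` (so a weight is
interpretable as the activation contributed at the synergy's peak), trunk
activations `a = wH` are linear in the weights, and so are the joint
moments.  The objective

`J = J_M + J_a + J_a_dev + J_w_dev`

uses allowable-value scaling throughout: a term equals 1 when every
deviation equals its allowance (`AllowΔM = 5` Nm, `Allow_a` ∈ {1.00, 0.75,
0.50, 0.25} with default 0.50, `AllowΔa = AllowΔw = 0.05`).  `J_a_dev` and
`J_w_dev` tie the heads of one anatomical muscle together, encoding that
heads of the same muscle receive similar neural drive.  `J_w_dev` can be
switched off (`include_jw_dev=False`) to obtain a literal three-term
objective; with quadratic terms and the weight-deviation allowance defined,
including it is the natural default and its value at the optimum is
reported separately so the choice is auditable.

All time frames are solved simultaneously.  Because the objective is a
convex quadratic in `w` and the constraints (`w ≥ 0`, `a = wH ≤ 1` per
sample and muscle) are linear, the problem is a convex QP with an
essentially unique solution; multi-start is supported but unnecessary and
defaults to a single start.  The solver is bound-constrained L-BFGS with
analytic gradients plus lazy constraint generation for the upper activation
bounds: the activation-minimization term keeps activations far below 1, so
those constraints are almost never active, and any violated sample is added
as an explicit linear constraint and the problem re-solved (SLSQP) until
feasible to 1e-7.  Reported costs always decompose exactly into the listed
terms.

The reference moments are the inverse-dynamics lumbosacral moments with the
psoas contribution subtracted (`subtract_muscle_moments`), since psoas
activations are available from the calibrated leg model and psoas is not
part of the estimated trunk set.

### Static-optimization baseline

The comparator solves each frame independently: minimize `Σ a²` subject to
exact moment equality on the three DoFs and `0 ≤ a ≤ 1`.  Infeasible frames
raise an error naming the frame unless reserve actuators are enabled, in
which case per-DoF reserve torques enter the equality and are penalized
quadratically with weight 1000 — mirroring common practice.

### Personalization

Peak isometric force is ACSA × 100 N/cm² (maximum muscle stress), applied
to the personalized ACSA of each reduced-set trunk MTU; group totals are
distributed over member MTUs by generic ACSA fractions.  Fiber parameters
are tuned by rescaling `(lMo, lTs)` jointly — preserving the tendon-to-total
ratio — so the peak normalized fiber length over the gait trial equals a
target of 0.95, i.e. slightly less than optimal for near-maximal force
generation capacity throughout the cycle.  The optimization-based muscle-set
reduction solves non-negative least squares for reduced-set peak forces
that reproduce the original set's full-activation moments over random
poses; a rank-deficient pose system falls back to the minimum-norm solution
with a warning.

### Evaluation

Moment quality is per-DoF RMSE between estimated and reference moments.
Activation quality is the Pearson correlation between mean estimated
activation curves and measured excitations shifted by an electromechanical
delay (EMD) swept over 100–165 ms in 5 ms steps, per side; the delay with
the highest correlation is reported (ties break to the smallest delay), and
r > 0.7 is labelled a strong correlation.  Gait cycles are treated as
periodic, so the delay is a circular shift of the time-normalized cycle.
The shift is applied at *fractional-sample* resolution by linear
interpolation on the periodic extension: at 101 samples per ~1 s cycle the
sample period (~10 ms) is coarser than the 5 ms delay grid, and rounding to
whole samples would alias neighbouring delays onto identical shifts, making
the best delay ambiguous.  Amplitude scaling of measured excitations onto
estimates (`scale_to_match`) is least-squares and display-only; Pearson r
is scale-invariant.

## Synthetic data

The generator (`trunksyn.synthetic`) emulates a single-subject treadmill
study: 15 leg EMG channels and 29 trunk MTUs per side, 3 lumbosacral DoFs,
10 cycles of 101 time-normalized samples, 1.01 s cycles (1 m/s walking,
sampled at 100 Hz so the EMD grid lands on clean fractions of a sample).
Key constructions and the reasoning behind them:

* **Synergy activations** are wrapped-Gaussian bursts with peaks spread
  across the cycle and SDs of 4–7 % of the cycle.  Narrow, nearly disjoint
  bursts match the phasic character of locomotor synergies and make the
  non-negative factorization of the composed activations essentially
  unique, so extraction recovers the generating basis rather than an
  arbitrary rotation of it.  Left-side activations are the right-side ones
  advanced by half a cycle (steady-gait symmetry).
* **Leg weights** include one *anchor* muscle per synergy (a muscle loading
  that synergy alone), as seen in real gait EMG where e.g. soleus or
  tibialis anterior are dominated by a single synergy; anchors are what
  gives the factorization its uniqueness.
* **Trunk geometry** gives each muscle group one dominant moment direction
  (ES/MF extend, RA flexes, QL side-bends, EO/IO rotate contralaterally/
  ipsilaterally) with small off-axis arms, mirrored across sides, plus
  smooth within-cycle variation.  This is deliberately more orthogonal than
  real trunk anatomy, where bending leverage especially is shared across
  groups: it makes the moment-to-muscle-group inverse problem well posed,
  so recovery tests measure estimator correctness rather than anatomical
  redundancy.  Strength and fiber parameters come from the published
  reduced trunk set, with fiber lengths re-tuned to the synthetic length
  series (normalized fiber lengths stay in [0.7, 1.0]).
* **Ground-truth trunk weights** are drawn with group-structured recruitment
  (heads share weights; extensor and flexor groups draw from disjoint
  synergy pools at the modest activation fractions typical of trunk muscles
  in gait) and are then *projected onto the estimator's identifiable set*:
  net joint moments cannot determine antagonistic co-contraction or the
  division of load between mechanically equivalent muscles, so freely drawn
  weights are not recoverable from the moments they generate by any method.
  The drawn weights seed a forward simulation, and six passes of the weight
  optimization against the true synergy basis contract them to a
  direction-stable, moment-consistent truth.  Synergies the moments never
  demand contract below 0.01 of their own accord — reproducing the
  "minimally recruited synergy" phenomenon — and a muscle group whose
  moment direction is never demanded legitimately falls silent (such
  zero-variance groups are excluded from correlation metrics, where Pearson
  r is undefined).
* **Noise** is additive truncated Gaussian on activations (SD 0.02,
  clipped to [0, 1]) and plain Gaussian on moments (SD 1 Nm, well inside
  the 5 Nm allowance); the measured-excitation surrogate is a trunk (ES)
  group-mean activation circularly *advanced* by the injected EMD (120 ms
  by default) on a deliberately different amplitude scale.

What passing recovery tests therefore show: the estimator correctly inverts
the forward map wherever the inverse is well defined, at the study's full
problem size.  What they do not show: recovery of physiologically arbitrary
co-contraction (invisible to net moments), performance under real anatomical
redundancy, or real-data accuracy — on real data the method's validation
remains the EMD-swept correlation against measured erector spinae EMG.

## Problem sizes and numerics

The test suite and the acceptance script run the full study shape (406
design variables, 5,858 activation-bound constraints per fit); a single fit
takes well under a second, a full 10-cycle recovery under a minute, and the
5–8-synergy trend study (10 datasets × 4 synergy counts) about a minute.
NMF uses coordinate-descent with 10–20 random restarts (best Frobenius
error kept), tolerance 1e-6, at most 2000 iterations, and is bit-reproducible
for a fixed seed.  QP convergence uses gradient tolerance 1e-9-scale with
ftol 1e-13; constraint satisfaction is enforced to 1e-7 and reported
activations are clipped to [0, 1] (clip magnitude at most the constraint
tolerance).  Degenerate inputs (all-zero synergy rows, zero-variance
correlation inputs, empty muscle groups, NaN geometry) raise typed errors
rather than propagating silently.

## Known limitations

* Tendon compliance, force–velocity effects, pennation and activation
  dynamics are outside the muscle model; moments are therefore exactly
  affine in activation, which is what the convex formulation relies on.
* The synthetic world's orthogonalized moment arms overstate the
  identifiability of real trunk anatomy by design (see above).
* Whether synergies should be extracted from the 15 measured EMG channels
  or from all model-estimated leg activations is left to the caller; both
  are matrices to `extract_synergies`.
* EMD handling assumes cyclic signals; non-periodic trials would need a
  truncating shift instead of the circular one.
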