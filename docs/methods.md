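# Methods

## Congener model

A CP congener is described constitutionally by chain length *n* and a
chlorine multiplicity per carbon (1-based positions). Valence caps are 3 Cl
on a terminal carbon and 2 on an internal one, which covers every congener
in commercial analytical standards. Because the two numbering directions of
a linear chain name the same molecule, the stored form is canonical: of the
identity and the end-to-end flip `p -> n+1-p`, the direction whose sorted
locant list is lexicographically smaller wins (the lowest-locant convention
of systematic nomenclature); flip-symmetric patterns keep the identity.
Parsing, rendering and re-parsing is idempotent, and a congener built from
either numbering direction canonicalises to the same object — both are
property-tested.

## Stereoisomer counting

Stereogenic centers are internal carbons bearing exactly one chlorine whose
two chain-side substituents differ constitutionally (compared as the
outward-read sequences of per-carbon Cl counts). Terminal carbons are never
stereogenic (CH2Cl has two equivalent H; CCl3 three equivalent Cl), nor are
CCl2 carbons. The side comparison also excludes the pseudo-asymmetric
middle carbon of an odd, flip-symmetric chain; no commercial standard needs
it, and the exclusion keeps the flip a fixed-point-free involution on the
center set.

Configurations are abstract binary labels per center rather than CIP R/S
descriptors. This choice is deliberate: CIP priorities re-rank under chain
renumbering in a constitution-dependent way, while counting only needs a
consistent group action. The molecular mirror negates every label;
the chain flip — a proper rotation — permutes centers (`p -> n+1-p`)
without relabeling. The applicable group is {identity, mirror} generally
and {identity, flip, mirror, flip∘mirror} for flip-symmetric patterns.
"Diastereomers" are orbits of {0,1}^k under this group, i.e. enantiomer
pairs count once, matching how partition calculations treat enantiomers in
isotropic phases.

Counting is implemented twice, on purpose: exhaustive orbit enumeration
over all 2^k vectors (capped at k = 20 by default, with an explicit error
beyond) and the Burnside closed form

    (2^k + f_flip + f_mirror + f_flip∘mirror) / |G|,

with f_mirror = 0 for k ≥ 1, f_flip = 2^(cycles of the flip), and
f_flip∘mirror = 2^(2-cycles) when the flip is fixed-point free (else 0).
`count_diastereomers` cross-checks the two on every call, and the test
suite sweeps every valid congener with chain ≤ 9 and ≤ 5 chlorines (3,836
patterns) to confirm agreement. Orbit representatives for enumeration are
lexicographic minima, giving a deterministic ordering.

## Retention indices

LTPRI is linear interpolation of retention time between bracketing
n-alkanes with RI = 100·n at the alkanes. The implementation returns
100·n *bit-exactly* when the retention time equals a ladder knot (no
interpolation arithmetic is performed), and is strictly monotone piecewise
linear between knots. Ladders must be strictly increasing in both carbon
number and time; equal consecutive times are rejected at validation rather
than special-cased in the division. Extrapolation beyond the ladder extends
the terminal segment's slope and is off by default. A numerical tolerance
of 1e-9 (relative) is applied at the span boundaries only, so values
reconstructed through inverse transforms that land one ulp outside do not
spuriously error.

Multi-peak standards are summarised by the area-weighted mean RI and the
max − min range. Small peaks are retained; excluding suspected impurity
peaks is the caller's decision via peak ids. ΔRI subtracts the weighted
mean on the nonpolar reference column.

## ppLFER descriptor derivation

All fits are ordinary (unweighted) least squares via statsmodels, which
also supplies coefficient standard errors, R² and residual SD. The
temperature-programmed RI is used directly as the ppLFER response — an
approximation (RI is related, not proportional, to log K), adequate for
semi-quantitative congener comparison, which is the package's purpose. The
`bB` term is identically zero (no H-bond-donating phases), and CP `B`
values are never estimated. `E` values are inputs (an additive property
estimable from structure), not fit.

Stage 1 fits the nonpolar column with `RI = c + eE + lL` (s = a = 0 by
construction). Stage 2 inverts it per CP. Stage 3 fits each polar column
with the full equation, then solves the per-CP zero-intercept system
`RI_j − c_j − e_jE − l_jL = s_jS + a_jA` across polar columns; at least two
columns with non-proportional (s, a) are required, and any subset of polar
columns can be omitted to probe robustness (on noise-free data the result
is exactly invariant to such omission; on real data it is not, which is why
the machinery exists). A descriptor column that is identically zero in a
calibration set is dropped and its coefficient reported NaN ("not
estimable", and treated as zero in prediction); a nonzero constant column
is collinear with the intercept and raises a singular-design error.

## RI prediction from partition coefficients

The quantum-chemical computation of K_air-polymer is out of scope; the
module consumes tables of log10 K versus temperature (natural-log inputs
must be converted upstream). Per compound/stereoisomer, log K is regressed
on 1/T (exact through two points). The elution temperature is the crossing
of this line with a column-characteristic log K*, `T = slope/(logK* −
intercept)`; crossings outside the ramp span are clamped to T0 or Tmax with
a warning (the compound elutes during a hold — no finer treatment is
attempted). The characteristic log K* is a single scalar per column, fit by
bounded 1-D least squares (tolerance 1e-9 log-units) so that predicted
alkane elution temperatures match those implied by measured alkane
retention times through the ramp `T(rt) = T0 + rate·max(0, rt − hold0)`;
with one alkane it is solved exactly.

RI interpolation is done in the temperature domain, which is equivalent to
the time domain during the linear ramp; the alkane reference temperatures
default to the predicted-alkane pathway (the same van't Hoff machinery),
keeping the prediction self-consistent: an alkane predicted against its own
pathway returns exactly 100·n. Diastereomer predictions are aggregated by
unweighted mean and range — the stereoisomer composition of standards is
unknown, so no isomer is privileged. The empirical correction is an OLS
affine map from predicted to measured RI per column; since the identity is
in the model class, it can never increase RMSE.

## Synthetic data generator

The generator emulates the statistical structure of a six-column
retention study: one nonpolar reference column and five polar columns of
increasing polarity rank, each with the oven program typical for its phase
type (e.g. 70 °C, 1 min hold, 10 °C/min to 280 °C for the octyl phase).

Truth model. n-Alkanes define the RI scale on every column (RI = 100·n by
definition) and have E = S = A = 0, so consistency forces the truth systems
to share `c` and `l` across columns; alkane L values lie on
`L_n = (100n − c)/l`. With c = 71 and l = 198 this reproduces the canonical
alkane L pattern (L(C10) ≈ 4.69, increment ≈ 0.505 per CH2). Columns differ
in (e, s, a), chosen so the polar ranking is strict and no two (s, a) pairs
are proportional (S/A would otherwise be unidentifiable): from (20, 0, 0)
for the octyl phase to (150, 320, 450) for the polyethylene-glycol phase,
in RI units per descriptor unit.

Defaults are the study conditions: 40 reference compounds (10 of them
alkanes; the rest draw E, S, A, L uniformly from ranges spanning
alcohol/ester/PAH-like chemistry: E ∈ [0, 2.5], S ∈ [0, 1.3], A ∈ [0, 0.6],
L ∈ [3.5, 10.5]), calibration noise SD 20 RI units, ladder C7–C35. CP
descriptors draw from narrower CP-plausible ranges. Noise is Gaussian on
reference RIs only; CP per-isomer RIs are the congener's true ppLFER mean
plus a *deterministic* centered offset sequence scaled by
`diastereomer_spread × polarity_multiplier^rank` (default 40 RI units,
multiplier 1.3), so diastereomer separation grows with column polarity and
is exactly controllable; peak areas are lognormal. Retention times are
back-computed through the ladder so LTPRI recovers the intended RIs
exactly. Alkane ladder times place alkane elution temperatures affinely in
the ramp interior (a boiling-point-like map of carbon number), guaranteeing
strictly increasing knots inside every program.

logK tables are constructed in reverse: a van't Hoff slope is drawn from
[3000, 6000] K·log-units (typical of a 5-log-unit drop between 373 and
573 K) and the intercept solved so the characteristic-log K* crossing lands
at the elution temperature whose interpolated RI equals the target; values
are emitted at five grid temperatures in [373.15, 573.15] K. Fitting those
five points returns the constructed line exactly, and the full chain
reproduces target RIs well within 1 RI unit.

What passing tests show — and don't. The generator's RIs obey the ppLFER
exactly up to injected Gaussian noise, its diastereomer spreads are
symmetric and deterministic, and its logK tables are exactly linear in 1/T.
Real data violate all three (mixed retention mechanisms on polar columns,
unknown stereoisomer compositions, conformer-averaged partition behavior),
so recovery statistics here validate the pipeline's correctness and
conditioning, not instrument-level accuracy of descriptor values.

## Problem sizes and reproducibility

The statistical battery uses 100 seeded replicates of the full six-column,
40-reference calibration for parameter coverage (within 3 estimated SE of
truth ≥ 95% of the time) and CP descriptor recovery (L, S, A RMSE < 0.1
descriptor units at noise SD 20; exact at noise 0), and 50 replicates per
noise level for the monotone recovery curve over SD {40, 20, 10, 0}. The
exhaustive Burnside-versus-enumeration sweep covers all 3,836 valid
congeners with chain ≤ 9 and ≤ 5 Cl. All randomness flows through
`numpy.random.default_rng` seeded from `GeneratorConfig.seed` (plus a
per-table salt), making every synthetic dataset byte-identical across runs
with the same seed.

## Known limitations

* Descriptor labels are abstract; the package never assigns R/S names to
  enumerated stereoisomer representatives.
* Isothermal (Kovats, logarithmic) indices are not implemented; everything
  assumes a linear temperature program.
* Hold-time elution is handled only by clamping to the program limits.
* Reconciliation of RIs across different instruments/detectors is out of
  scope; one peak table per column is taken at face value.
* The RI-as-response ppLFER is an approximation; derived descriptors are
  for congener comparison, not for transfer to other partition systems.
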