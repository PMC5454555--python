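# Methods

## Measurement model

A triaxial accelerometer strapped to the body reads, per axis, the projection
of gravity plus body acceleration, distorted by a direction-dependent sensor
gain and corrupted by white noise. The package's processing chain assumes:

- **Static bias is multiplicative and direction-specific.** Each signed
  direction d gets one factor C_d = g/|m_d|, where m_d is the mean vertical
  reading of a 30 s static recording with d pointing up and g = 9.81 m/s².
  Both factors of an axis are kept positive and correction dispatches on the
  sign of the raw value, so correction never flips a sample's sign. Factors
  outside [0.5, 2.0] indicate a faulty sensor and raise a warning; a mean
  magnitude below 1 m/s² on the nominally vertical axis indicates a wrong
  orientation and also warns. The two non-vertical axes of a static
  recording are ignored: each direction's factor comes only from its own
  axis. No cross-axis (misalignment) or temperature model is attempted.

- **The balance index is the mean resultant magnitude.** Two variants:
  `literal` averages √(x²+y²+z²) of the corrected samples, so gravity
  dominates and quiet stance gives ≈ 9.81 m/s² — this is the variant used
  for calibration self-checks. `deviation` subtracts the per-trial mean
  acceleration vector before taking magnitudes, leaving the sway magnitude
  proper; it is the default for ranking and statistics, and its reciprocal
  lands on the 0.5–8 s²/m scale that separates easy from hard stances. No
  filtering, windowing, detrending or outlier rejection is applied at any
  point. A zero mean R (exactly constant signal) makes the reciprocal
  undefined; it is flagged as missing rather than infinite.

## Concordance

Rankings are strict permutations 1..K (1 = least difficult). The device
ranking assigns rank 1 to the condition with the largest mean reciprocal R.
Exact ties are refused unless a policy is chosen (`lexicographic` or
`mean-rank`; mean-rank output cannot feed kappa, which requires
permutations). Weighted kappa uses the K×K cross-tabulation of ranks with
expected counts from the product of marginals and disagreement weights
(i−j)² (quadratic, default) or |i−j| (linear). Quadratic is the default
because on permutations it coincides with the Spearman rank correlation
1 − 6Σd²/(K(K²−1)) — an identity the test suite asserts to 1e-12 against a
closed-form oracle — and because it reproduces the published concordance
endpoints of the bundled clinical table, which linear weights do not.
Device validity is summarised as "good agreement" when every device–rater
kappa exceeds 0.8. No kappa confidence intervals are computed.

## Repeated-measures ANOVA

The long table holds one transformed index value per (participant,
condition). The model is univariate: condition is the only within-subject
factor; participant sex may enter as a between-subject covariate. Sums of
squares are sequential (Type I) in the order sex → subjects within sex →
condition → residual; with a balanced design these are the classical
closed-form decompositions, and they are verified against a brute-force
nested least-squares fit. The covariate is fitted before the subject term —
sex is constant within participant, so the reverse order would
assign it zero SS by construction. The exercise F statistic tests condition
against the within-subject residual with df (K−1) and (n−1)(K−1); no
sex×condition interaction is modelled and no sphericity correction
(e.g. Greenhouse–Geisser) is applied. Post-hoc comparisons are two-sided
paired t tests over all C(K,2) condition pairs with Bonferroni adjustment
p_adj = min(1, p·C(K,2)). When the paired differences have zero variance the
t statistic is undefined; p is reported as 1 when the common difference is 0
and as 0 otherwise (a perfectly consistent non-zero effect).

## Sway simulator

The simulator is the package's test harness: it generates data with exactly
the structure the measurement chain assumes, plus known ground truth.

- **Sampling**: 30 s trials at 15 Hz (450 samples) by default; 14 Hz gives
  420. Timestamps are regular; duration and rate are configurable.
- **Geometry**: the device y axis is near-vertical, tilted `tilt_deg`
  (default 2°) toward x; gravity projects accordingly.
- **Sway**: a stationary AR(1) process (discrete Ornstein–Uhlenbeck) with
  lag-1 coefficient φ = 0.9 at 15 Hz, split evenly between the two
  horizontal axes so the configured σ is the total horizontal sway SD.
  AR(1) gives temporally correlated, band-limited sway with a one-parameter
  memory — adequate for exercising the pipeline, though real sway has
  richer (multi-scale, intermittent) dynamics.
- **Amplitudes**: knee σ is spaced geometrically from 0.1 m/s² (double-leg
  stance) to 2.0 m/s² (single-leg on foam, eyes closed) across the eight
  conditions in difficulty order; torso is ×0.7 and ankle ×1.1 of knee.
  Each participant draws a lognormal amplitude multiplier per location,
  with a wider spread at the ankle (CV 0.25 vs 0.10) so ankle residual
  variability exceeds the other sites. An optional multiplicative sex
  effect on σ (default 1.0, i.e. off) lets the covariate machinery be
  exercised.
- **Sensor imperfections**: per-direction true gains drawn N(1, 0.01) per
  device (or pinned explicitly), applied with the same sign-dispatch the
  correction undoes; white measurement noise with SD 0.03 m/s², an
  engineering choice for a consumer MEMS accelerometer — the target
  hardware's true noise floor is not documented.
- **Raters**: a simulated clinician perceives each condition's true
  difficulty score through independent Gaussian noise (SD τ) and ranks the
  perceived scores; exact ties are re-drawn.
- **Randomness**: one root seed; every stream (gains, calibrations, each
  trial, each participant's sex and amplitude multipliers) derives its own
  generator deterministically from the root plus structural indices, so
  regenerating any subset is reproducible and whole studies are
  byte-identical across runs.

What passing simulator-based tests shows: the chain recovers gains to
C·gain = 1 ± 0.002 under the default noise, recovers the configured
difficulty ordering from a single participant's session in ≥95% of seeded
replicates, and detects the exercise effect at p < 0.05 almost always. What
it does not show: robustness to non-stationary sway, movement artefacts,
sensor drift, sample dropouts or axis misalignment, none of which the
generator produces.

## File formats and conventions

Trial logs are UTF-8 CSV with header `t_s,ax_ms2,ay_ms2,az_ms2`, decimal
points (locale-independent), full float precision (write→read round-trips
below 1e-9 m/s²). Units are m/s² throughout; `units="g"` on read multiplies
by 9.81. Timestamps are seconds from trial start, strictly increasing,
irregular spacing tolerated. Axes are the raw device frame; no reorientation
is attempted. The session manifest is YAML (or JSON) linking trial files to
(participant, condition, leg, body location) and listing the six calibration
files per device; a complete session has 8 × 2 × 3 = 48 cells. Correction
factors serialise to a small JSON document. The rater table is CSV with
rows = assessors, columns = condition labels, cells = ranks.

## Problem sizes in the test suite

Replicate-based properties run the full pipeline in memory (no disk I/O):
the ranking-recovery rate uses 100 single-participant replicates, gain
recovery 10, and the ANOVA detection rate 20 two-participant replicates of
knee trials; unit-level property tests use Hypothesis with bounded example
counts. These sizes keep the whole suite under a minute while leaving the
Monte-Carlo margins wide (observed recovery rates are at or near 100%).

## Known limitations

- The `literal` and `deviation` variants answer different questions; which
  one a published knee reciprocal table used cannot be established from its
  scale alone, so ranking work defaults to `deviation` and the choice is
  recorded in the output.
- The interpretive reading of 1/mean R as "time to reach a given velocity"
  is dimensionally loose (s²/m, not s) and is not used computationally.
- Only the univariate per-location ANOVA is implemented; full multi-factor
  repeated-measures models with interactions are out of scope.
- Calibration is assumed stable over a study; no drift model.
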