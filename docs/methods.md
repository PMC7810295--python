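# Methods

## Curve model and landmark extraction

An ablation log is a strictly increasing time series of impedance samples,
either logged directly or derived from voltage and current by Ohm's law
(`Z = V / (I·10⁻³)` with current in milliamps, the equipment convention; a
`current_unit` switch handles ampere-logged files). Times are re-expressed as
seconds from log start, so every landmark time is a duration. Rows with
missing values, non-positive current or negative voltage are treated as
generator cut-out artifacts: dropped and counted, never interpolated.

The seven landmarks are computed as follows. `Z_initial` is the first
reading by default (`init_k` averages the first k readings instead).
`t_half = t_end / 2` by definition, and `Z_half` is obtained by linear
interpolation because sampling grids need not contain the midpoint. The
minimum is the earliest global minimum of the sampled trace restricted to
`[0, t_end]`; duplicating the minimum value later in the curve never moves
it (earliest-index tie-break).

Roll-off is the genuinely open definition. The two conventions implemented:

* **log_end** (default): the log's final sample is the roll-off event. The
  acquisition stops at the first roll-off, so the end of the log *is* the
  event. This convention reproduces the large ascent ratios (≈ 545 % for
  RF-only ablations) reported for real curves.
* **threshold**: the earliest time after the minimum at which impedance
  reaches `1.5 × Z_initial` (configurable factor), located by linear
  interpolation. This pins `Z_end = 1.5·Z_initial` and therefore pins
  `AR = 100·(1.5/(1 − DR/100) − 1)` ≲ 100 % — mathematically incompatible
  with the large published AR values, which is why both conventions exist
  and every output record carries its `rolloff_mode`. Crossings are searched
  only after the minimum so that an averaged `Z_initial` below an early
  spike cannot trigger a spurious roll-off. A curve that never reaches the
  level raises a no-roll-off error carrying the maximum impedance reached;
  the pipeline treats such samples as aborted ablations (excluded and
  listed), not as failures.

### Noise handling

The impedance minimum is a pointwise extreme, so sampling noise biases
`Z_minimum` low and hence DR high: with 2 Ω Gaussian noise on 1 Hz logs the
raw-trace bias is ≈ +4 percentage points of DR. Extraction therefore offers
an odd-window running-median filter (edges kept raw so `Z_initial` and the
log-end `Z_end` are untouched). A calibration sweep over the realistic index
range (300 curves, 2 Ω noise) gave DR biases of +4.3 / +1.6 / +0.85 / +0.30
points for windows 0 / 5 / 9 / 15; window 9 is the pipeline default for
sampled logs (the `extract_parameters` default remains 0, i.e. raw, for
clean or pre-filtered data). Window 15 would be marginally better on DR but
smears the roll-off ascent on fast curves.

## Performance indices

`delta = (t_minimum/t_half − 1)·100` is signed: positive when the minimum
falls after mid-procedure. The literal Drop Ratio formula
`(Z_minimum/Z_initial − 1)·100` is negative for any drop; reports and group
summaries use the positive drop magnitude `dr`, with the literal value kept
as `dr_signed`. `AR = (Z_end/Z_minimum − 1)·100` uses whichever `Z_end` the
roll-off convention produced. All three indices are invariant under
rescaling of all impedances or all times.

## Synthetic data

The generator is **index-faithful, not biophysical**: a curve is constructed
so its noise-free landmarks realize prescribed `delta`/`DR`/`AR` exactly
(minimum at `t_min = (1 + delta/100)·t_end/2`, `Z_min = Z_init(1 − DR/100)`,
`Z_end = Z_min(1 + AR/100)`), because every downstream computation consumes
only landmarks and indices. The decay is a saturating exponential (shape
1.5: early drop ≈ 4× faster than the approach to the minimum) and the rise a
power profile (exponent 2, accelerating into roll-off); both defaults were
chosen for qualitative resemblance to observed ex vivo curve morphology and
are exposed in `CurveSpec`. Gaussian noise (default 2 Ω) is added and floored
at 1 Ω to preserve positivity.

Cohort presets draw per-sample index targets from group-wise normals whose
means come from the bundled published tables and whose per-sample sd is
reconstructed as `(CI_upper − mean)/1.96·√10` — an approximation, since the
printed intervals pool variance across groups. DR targets are clipped to
[0, 99], AR to ≥ 0, delta to (−99, 99). Initial impedances are uniform on
the observed 66–117 Ω band; durations uniform on 180–600 s (constant-power
ex vivo ablations reach roll-off on the order of minutes; the published
tables do not print durations). Ablation volume is coupled to AR via a
Gaussian copula with Pearson parameter `2·sin(π·ρ_s/6)`, giving the target
Spearman correlation in expectation; published per-group coefficients are
used where available (0.72 / 0.73 / 0.78 for the control, ambient-deionized
and refrigerated-saline arms) and moderate positive defaults (0.40 / 0.30)
where only a direction was reported.

What the generator does **not** emulate: genuine biophysics (no Joule
heating, no temperature channel), multi-roll-off behaviour, equipment
artifacts other than i.i.d. Gaussian noise, or heavy-tailed index
distributions. Passing recovery tests therefore demonstrate that the
pipeline is a faithful inverse of this generative model over the realistic
index range — not that real tissue curves satisfy the model. One visible
consequence: arms whose AR distribution has substantial mass near the AR ≥ 0
truncation point (the low-ascent ambient-saline arm) recover slightly
inflated AR and delta means, because near-flat rises leave the minimum's
location noise-dominated.

## Statistics

* Shapiro–Wilk (on per-group-centred residuals in the pipeline report) and
  Levene with median centring (Brown–Forsythe), matching the R defaults of
  the routines named in the study protocol.
* One- and two-way ANOVA use the classical sum-of-squares decomposition
  (the 2×2 factorial is balanced by design, where all ANOVA types agree);
  both are cross-checked against independent implementations in the tests.
  The RF-only control has neither a solution nor a solution temperature, so
  it is excluded from the factorial and reported as a standalone reference
  level in every factor-wise marginal table; fitting it as a phantom level
  of both factors would make the design incomplete and the fit ill-posed.
* Tukey HSD uses the studentized-range distribution (via scipy) with
  simultaneous confidence intervals at `1 − alpha`.
* BCa bootstrap intervals (default B = 1000, level 0.95): bias term from
  the fraction of bootstrap replicates below the point estimate, acceleration
  from jackknife skewness. A degenerate bootstrap distribution (zero spread,
  or all replicates on one side) falls back to the percentile interval with
  a flag. Marginal-mean tables default to parametric t intervals —
  symmetric, like the published tables — with `bca_bootstrap` available.
* Spearman correlation uses midranks; the p-value is the t approximation
  except for n ≤ 9, where the full permutation distribution is enumerated.
* Outliers use Tukey fences (1.5·IQR beyond the quartiles, linear-
  interpolation quartiles); with IQR = 0 nothing is flagged.
* Alpha is 0.05 throughout; no multiplicity correction beyond Tukey HSD is
  applied, matching the study's protocol.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed; identical configurations
give byte-identical outputs (CSV floats written with 17 significant digits,
JSON with sorted keys, config hash covering the scientific settings only).
Recovery and calibration checks run at deliberately modest sizes — 500
replicate curves for noise bias, 20 replicate 50-sample cohorts for
cohort-level recovery, 1000 Monte-Carlo runs for BCa coverage — chosen as
the smallest ensembles whose Monte-Carlo error is well below the effect
being checked.

## Known limitations

* The deposited dataset workbook of the original study is consumed through
  a layout auto-detector (curve sheets vs precomputed index sheets); the
  detector is exercised against synthetic stand-ins, and its description of
  what it found is stamped into the run report.
* Threshold-mode analyses exclude ablations that never reach the level;
  group summaries in that mode are conditional on roll-off being reached.
* The sd reconstruction from pooled CIs overstates between-group variance
  differences; cohort-level checks use CI-containment rather than exact
  moment matching for this reason.
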