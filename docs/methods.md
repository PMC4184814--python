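# Methods

This note documents the models and procedures implemented in
`regimeshift`, the assumptions behind them, the defaults that matter,
and what the synthetic validation scenario does and does not show.

## Data model and preprocessing

A community record is a table of ages (years BP, present = AD 1950) and
percent abundances per species.  Records are stored oldest-first (ages
strictly decreasing); files may run in either direction and are
normalized on read.  Percentages are taken relative to the total count
per sample, so row sums at most 100 (tolerance 0.5 for rounding) but not
necessarily exactly 100.  Preprocessing removes barren steps — rows that
are entirely blank or entirely zero; a blank cell in an otherwise
populated row is treated as a format error, not as data — and collapses
*consecutive* runs of identical ages into column-wise means (equal ages
arise when an age–depth model assigns one age to several samples).
Non-consecutive duplicate ages are ambiguous and rejected.  The
operation is idempotent.

## Early-warning indicators

All indicators are computed per species over trailing windows of 10
steps (default; at least 8 is advisable), anchored at the window's last
time step so no indicator ever uses future data.  Definitions: sample
variance (ddof = 1 by default, switchable to the population form);
moment skewness `m3 / m2^1.5` and raw Pearson kurtosis `m4 / m2^2`, both
bias-uncorrected; lag-1 autocorrelation as the Pearson correlation of
the `w−1` within-window pairs `(x_t, x_{t+1})`.  Windows of zero
variance yield missing values for the shape and autocorrelation
indicators.  No detrending is applied.  These indicators are univariate
by construction; the package computes them for every species and leaves
the (often conflicting) interpretation to the user — motivating the two
multivariate methods below.

## Windowed Fisher Information

**State binning.**  The per-species state tolerance (*size of states*,
`sost_i`) is estimated from the record itself: a 10-step window slides
over the record and the window minimizing the *normalized* total
variability — the sum over species of within-window s.d. divided by
whole-record s.d., species with zero record-wide s.d. excluded — is
selected (earliest window on ties).  Normalization prevents
high-abundance taxa from dominating the choice.  `sost_i` is then a
configurable multiple (default 1.0; some applications use 2.0) of the
within-that-window sample s.d. of species `i`.

Within each analysis window, points are binned greedily in temporal
order: the first point founds state 1; each later point is compared
against the *founding* point of each existing state in creation order
and joins the first state within `sost` on every variable, else founds
a new state.  Comparing to founders (rather than centroids or all
members) makes the rule deterministic and order-stable; the rule used is
recorded in the output metadata.

**FI per window.**  With state probabilities `p(s)` (occupation counts
over `w`) and amplitudes `q(s) = sqrt(p(s))`, the numeric form

    FI = 4 * sum_{s=0}^{m} (q(s) - q(s+1))^2,   q(0) = q(m+1) = 0

uses amplitudes to avoid error amplification from small probabilities.
The zero boundary amplitudes give the literature's maximum FI = 8 for a
one-state window and `8/w` for `w` equiprobable singleton states; the
interior ordering is first-appearance (temporal) order, a convention
that matters because the sum is order-dependent.  Windows advance by one
step (maximally overlapping) and are anchored at their youngest age.
The *mean FI* track is a centered moving average over 5 windows by
default (span is configurable and reported in metadata: regime boundary
ages move by a few windows across spans).

**Segmentation.**  Mean-FI tracks of episodic systems fluctuate hard at
the window scale, so segmentation works at the segment scale: the track
is pre-smoothed with a centered moving average (width 61 windows by
default), then fitted with a piecewise-linear model whose breakpoints
are placed by dynamic programming (exact for a given number of pieces;
each piece at least `min_len` = 101 windows) with the number of pieces
chosen by BIC.  Pieces are classified by fitted slope against forward
time: |slope| ≤ 0.5 FI/kyr is stable, steeper negative slopes declining,
positive rising.  A local-slope labeling scheme was tried first and
rejected: with realistic window-scale FI noise its label runs alternate
unpredictably and short-run merging cascades, whereas the global fit is
stable across smoothing spans.  A declining segment followed by a
recovery — a labeled rising segment, or an abrupt jump that regains at
least a quarter of the decline's drop — marks a regime shift, dated at
the mean-FI minimum between the pre-decline stable span and the
recovery.

## PCNM-based redundancy analysis

**Temporal eigenfunctions.**  Euclidean distances between sampling times
are truncated at the largest gap between adjacent samples (the minimal
connectivity-preserving threshold); larger distances are set to four
times the truncation.  The truncated matrix is Gower-centered and
eigendecomposed; eigenvectors with eigenvalues above `1e-8 × λ_max`
are kept, unit-norm, signs fixed (first nonzero element positive) for
bitwise reproducibility.  The count of positive-eigenvalue PCNMs is
sensitive to this cutoff and is always reported with it.  The
construction is verified against R `vegan::pcnm` in the test suite
(eigenvalues agree to 1e-13 on shared fixtures).

**Forward selection.**  The community matrix is Hellinger-transformed
(square root of row-wise relative abundances, giving unit-norm rows) so
Euclidean-based ordination is appropriate.  Selection uses the double
stopping rule: a global permutation test of all PCNMs must pass at
`alpha` (else the selection is empty), and variables are added greedily
by R² gain while the candidate's permutation p-value (pseudo-F gain
against row permutations of the reduced-model residuals,
`p = (b+1)/(n_perm+1)`) stays ≤ `alpha` *and* the cumulative Ezekiel
adjusted R² stays at or below the global adjusted R².  Ties in gain go
to the lower PCNM index (longer period).  Defaults: `alpha` 0.05,
`n_perm` 999.  One algebraic caveat, exposed by the test suite: a PCNM
basis has `k/n ≈ 0.65`, so for a signal concentrated in very few PCNMs
with *white* residual noise the global adjusted R² (penalized by the
full `k`) can fall below the small model's adjusted R² and halt the
selection early — the ceiling is doing exactly what it was designed to
do, and full recovery should only be expected when the residual
variation is itself temporally structured.

**RDA.**  Both matrices are centered column-wise (implicit intercept);
the fitted values — the projection of the centered community matrix onto
the span of the selected PCNMs — are decomposed by SVD.  Canonical
eigenvalues are squared singular values over `n−1`; canonical plus
residual eigenvalues equal the total variance to 1e-8 (asserted, and the
eigenvalues are verified against `vegan::rda`).  Axis significance is
tested sequentially: each axis is tested marginally on the residual of
the community matrix after removing the preceding axes' fitted
components, by row permutation; the scan stops at the first
non-significant axis.  Per-axis "adjusted variance explained" is not
uniquely defined in the literature; the package reports both the raw
eigenvalue share and the share rescaled by the model's
adjusted-to-raw R² ratio.  The lc (linear-combination) site scores trace
each axis' modeled temporal pattern; the age of the largest single-step
change of axis 1 — after a 3-point median filter that removes one-step
flicker spikes while preserving sustained level changes — dates the
dominant compositional break.

## Synthetic validation scenario

The generator emulates the qualitative history of a long diatom record:
109 species, 800 steps at irregular 5–20 yr spacing rescaled to span
exactly 7 kyr; a first regime ending at 4.5 ka BP; a transition until
2.0 ka BP; then a calmer second regime numerically dominated by one
species (60%).

Its central design decision is that community variation is **low-rank
and exactly observed**: species covary through three latent drivers
(random unit loadings scaled to logit s.d. 0.5), the community switches
among six metastable configurations (logit offsets of the regime
profile, softmax-renormalized to percents) with near-regular dwell times
of 8–9 steps, and there is *no* independent per-species observation
noise.  The reason is structural: the FI state criterion requires *all*
~100 variables to match within `sost` simultaneously, and any i.i.d.
per-species noise component comparable to `sost` makes the matching
probability decay like `0.5^n_species` — every window becomes
all-distinct and FI degenerates to its floor.  Real percent-count data
escapes this through sparsity (most species absent from most samples)
and count quantization, which make recurring assemblages recur exactly;
the generator reproduces that property directly.  Consequently the
scenario validates the detection machinery, not robustness to
observation noise — a real record with heavy counting noise would
require a larger `sost` scale (the `--sost-scale` option) or fewer
effective variables.

The transition: the base profile steps through six short-lived
intermediate communities drifting 30% of the way toward the regime-2
profile (evenness declines), and the full dominance onset happens
abruptly at the shift age, as dominance onsets do in the motivating
record.  The switch rate ramps linearly (after a 10% onset delay) to 2.5
times the regime-1 rate at the shift; the excursion amplitude ramps at
half that factor; and flickering — one-step excursions to the other
regime's profile in a fresh driver configuration, each its own system
state — has per-step probability `0.6·u^12` in transition progress `u`,
i.e. it is concentrated immediately before the shift, where flickering
is expected.  The second regime is calmer (rate and amplitude × 0.85).
These schedules were chosen so that the mean-FI track shows the
qualitative structure the methods target: flat regimes, a visible
decline of roughly two millennia, a distinct minimum at the shift, and
a higher, steadier second regime.  Under the defaults the FI minimum and
the axis-1 lc break each recover the true shift age to ±250 yr in ≥80%
of replicate seeds (recomputed by `scripts/acceptance.py`).

A null configuration (identical regime profiles, no flickering, no
intensification, `regime2_noise=1`) is stationary and is used to check
that the indicators show no spurious trends.  All randomness flows from
one integer seed through independent substreams (ages, configuration
dynamics, flickering), so records are bitwise reproducible.

## Numerical and interface choices

- Problem sizes: the full scenario (800 × 109) runs each analysis in
  seconds except permutation-heavy selection/axis testing, which is
  O(`n_perm` × matrix product); recovery experiments use `n_perm` = 99
  for the per-replicate selection and the single-record axis analysis
  uses `n_perm` = 999.
- Permutation p-values are `(b+1)/(n_perm+1)`; permutation generators
  are seeded per call.
- The CLI (`regimeshift simulate|ews|fi|rda|run`) is a thin wrapper over
  the library; exit codes: 0 success, 2 validation error, 1 runtime
  error; logs go to standard error only.
- `summary.json` carries `schema_version: 1`.

## Known limitations

- The FI binning compares points to state founders; centroid or
  all-member rules would give different (also defensible) partitions.
  The rule is named in the output metadata.
- Eq.-level FI is order-dependent; first-appearance ordering is a
  convention.
- The segmentation's breakpoint ages inherit the pre-smoothing blur
  (roughly ±250 yr at the default widths for Foy-scale records).
- The generator's zero-observation-noise assumption (discussed above)
  means test results do not certify behavior on data whose noise is
  dominated by independent counting error.
- Axis counts and variance fractions from the RDA are properties of the
  analyzed record; on the synthetic scenario the dominance shift
  concentrates variance on axis 1 far more than a diverse empirical
  record would.
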