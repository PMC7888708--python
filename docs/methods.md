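# Methods

## Lineage simulation model

Cells are rods growing in one dimension. Each cell is born at length `BL`,
grows continuously — linearly, `L(t) = BL + v·t` (the default: fission yeast
extends by tip growth at roughly constant rate), or exponentially,
`L(t) = BL·e^{rt}` — and divides when its control rule fires:

| control | trigger | noise | BL/E slope |
|---|---|---|---|
| sizer | length reaches `L_T + ε` | `ε ~ N(0, σ_T)` µm | −1 |
| adder | length reaches `BL + Δ + ε` | `ε ~ N(0, σ_T)` µm | 0 |
| timer | age reaches `T_dur + ε` | `ε ~ N(0, σ_T)` min | 0 (linear growth), +1 (exponential, `rT = ln 2`) |

`ε` is drawn once per cell. Division is near symmetric: each daughter gets a
fraction `f ~ N(0.5, σ_f)` of the mother's division length, clipped to
[0.3, 0.7] to forbid degenerate daughters. Founders are drawn from
`N(µ0, σ0)` truncated at 0.1 µm; lineages are expanded breadth-first from one
seeded generator, so identical `(params, seed)` give bit-identical tables.

**Sampling model.** With `frame_interval Δt > 0` (default movies used 10-min
frames over 12 h) the recorded birth length is the true length at the first
frame at or after the actual birth, the recorded division length the true
length at the last frame at or before the actual division, each plus
independent `N(0, σ_m)` measurement noise; the recorded cycle time is the
frame-time difference (hence quantized to `Δt` and never more than `2Δt`
below the true cycle time). With `Δt = 0` the true event values are recorded.
Only generations 1–3 (`max_generations = 3`, mirroring the
first-three-generations measurement convention) dividing before `total_time`
are emitted.

**Degenerate inputs.** A cell whose trigger is already satisfied at birth
(e.g. born above the sizer target) divides after one frame interval — or
after a 1-min grace interval when frame sampling is off — and is flagged
rather than dropped; this keeps recorded extensions positive and cycle times
nonzero. Flag counts are reported by the pipeline log and manifest.

**Presets.** `sizer_preset`: `L_T = 14` µm, `σ_T = 1.12` µm (division CV
8%), `v = 0.0467` µm/min (≈150-min cycles, division at 13–14 µm — a
wild-type-like steady state). `adder_preset`: `Δ = 7` µm with `σ_T = 1.94`
µm; at the adder's fixed point `D = 2Δ = 14` µm the stationary variance is
`Var(D) ≈ (4/3)σ_T²`, giving CV ≈ 16% — an impaired-homeostasis strain.
`timer_preset`: exponential growth with `rT = ln 2`. Both lineage presets use
`σ_f = 0.02` (slightly asymmetric division). These presets are calibration
conveniences defining reproducible study conditions, not reproductions of any
measured dataset.

**Convergence note.** A noise-free sizer corrects any founder size within one
generation; a noise-free adder converges geometrically (`D_n − 2Δ =
(BL_0 − Δ)/2ⁿ` under symmetric division), never exactly in finite
generations. Tests assert the geometric sequence, not exact attainment.

**What the generator does not emulate.** No widths or septum geometry, no
growth-phase structure (constant single-phase growth), no lineage-correlated
noise beyond inheritance of birth size, no regrowth-before-separation
artefacts, no images. Passing tests therefore validate the statistical
machinery under idealized growth/division noise, not segmentation quality or
biological growth-law details.

## Dispersion statistics

CV uses the sample SD (n−1 denominator). CQV quartiles use linear
interpolation of order statistics (`h = (n−1)p + 1`, numpy's default), fixed
so results are bit-stable; the quartile rule is a documented convention.
Skewness is the plain moment ratio `g1 = m3/m2^{3/2}` (1/n central moments);
at the n ≥ 50 where the symmetry gate applies, the finite-sample adjustment
would not change any gate decision. P-values are reported as computed, never
truncated to zero.

## CV-equality inference

The asymptotic test is the Feltz–Miller chi-square statistic (see README for
the formula); the modified/SED variants are out of scope. The permutation
cross-check scales each group to unit mean — under the null of equal CVs the
scaled values are exchangeable across groups — permutes labels, and reports
`(b+1)/(B+1)`. Monte-Carlo checks in the acceptance suite: type-I error at
nominal 0.05 stays within [0.03, 0.07] (normal data, CV 8%, n=50/group, 2000
replicates); power for CV 16% vs 8% at α = 0.001 exceeds 0.8 (expected
noncentrality ≈ 21.6 against the 10.83 critical value); asymptotic and
permutation p-values are rank-concordant (Spearman > 0.9).

## SD-precision sample size

`sd_ci_factors(n, conf)` returns the multiplicative chi-square CI bounds for
σ; `min_sample_size(r, conf)` iterates n upward until both factors deviate
from 1 by at most `r`. Under this criterion `r = 0.5` needs n = 18 and
`r = 0.25` needs n = 49 — the latter essentially the common 50-cell minimum.
Because more than one reasonable precision criterion exists, both `r` and the
confidence level are explicit parameters rather than a hard-coded rule.

## BL/E regression and classification

Extension `E = D − BL` is computed exactly; records with `E ≤ 0` are flagged,
counted, and *retained* in the fit (excluding them would bias the slope).
The fit is plain OLS of E on BL on raw records (needs ≥ 10 distinct birth
lengths); cohorts are half-open bins `[k·w, (k+1)·w)` anchored at 0 with
`w = 0.5` µm, reported with per-bin n, mean BL, mean E and SD of E, for
display only. No errors-in-variables correction is applied: measurement noise
on BL enters E with opposite sign and biases the OLS slope toward −1 — an
adder measured with noisy birth lengths looks partly sizer-like. The test
suite asserts this bias is monotone in `σ_m`; interpret slopes from noisy
data accordingly.

Classification thresholds on the slope — ≤ −0.6 `sizer_like`, (−0.6, −0.2]
`impaired`, (−0.2, +0.2) `adder_like`, ≥ +0.2 `timer_like` — are conventions
calibrated to reported wild-type (≈ −0.72) and mutant (≈ −0.46, −0.066)
slopes, exposed in configuration.

## Screen decision rule

Four conjunctive gates (all must pass): `n ≥ min_n` (default 50); candidate
CV > control CV; two-sided Feltz–Miller p < α (default 0.001); candidate
skewness within [−1, +1]. The two-sided test is paired with an explicit
direction gate rather than halving the p-value. Candidates are tested
pairwise against the control with no multiplicity correction (the k-group
test remains available via `cv_equality_test` directly). An undersized
candidate fails the n gate, it does not raise.

## Multinucleate quantification

Counts are pooled across timepoints by default (per-timepoint summaries are a
matter of slicing the long-format table before calling). The asynchrony
denominator is cells with ≥ 2 nuclei — mononucleate cells carry no synchrony
information — and is fixed, not configurable; an empty denominator yields a
missing value, never 0%. Counts above 8 are pooled into an "8+" display bin
while kept exact internally. The independent-division reference distribution
is propagated exactly through the binomial branching recursion
(`c` nuclei → `c + k` with probability `C(c,k) q^k (1−q)^{c−k}`).

Per-cell intensity CVs use the sample SD over typically 4 nuclei — noted
because at n = 4 the SD is noticeably biased low (`c4(4) ≈ 0.921`); since
every cell is summarised the same way, group comparisons are unaffected.
Non-positive intensities (possible under heavy simulated noise) are truncated
at a small positive floor and flagged.

## Problem sizes and numerical choices

Default analysis runs use ~900 completed cycles per strain (130 founders ×
3 generations), 2000 replicates for error-rate calibration, 999 permutations
for the oracle, and 20 000 cells for multinucleate distribution checks —
sizes at which the statistical tolerances (3 SE bands, rate intervals) are
comfortably resolved while a full run finishes in seconds. Tolerances in
tests are derived from the quantity's own sampling SE, not tuned constants.

## Known limitations

* The simulator's growth laws are single-phase and deterministic between
  divisions; real cells show bilinear growth and rate fluctuations.
* OLS slope estimates are attenuated/biased under measurement noise (see
  above); no correction is offered.
* The screen's false-positive control assumes approximately normal length
  distributions; heavy tails inflate the CV test's type-I error.
* Per-timepoint vs pooled nuclei-count summaries are both supported, but the
  package defaults to pooling.
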