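# Methods

This note documents the models, conventions, defaults and numerical
choices behind `coordsam`, and what the simulation-based validation does
and does not establish.

## Motion extraction

Motion between consecutive grayscale frames is quantified per pixel as
`|I[t+1] − I[t]|` (method `framediff`, the default). The alternative
`denseflow` method reports the Euclidean norm of a dense iterative
Lucas–Kanade displacement field (scikit-image). Frame differencing is the
default because it is exactly reproducible, oracle-checkable, and — for
the static-camera interview setting this pipeline targets — a faithful
proxy for motion energy; dense flow is preferable only when large coherent
displacements (camera motion, whole-body translation) would otherwise
saturate the intensity-change signal. Color frames are collapsed to
luminance (Rec. 601 weights) before differencing.

ROIs are static axis-aligned rectangles in 0-based, half-open pixel
coordinates `[x0, x1) × [y0, y1)` with y indexing rows; head and body ROIs
must not overlap. Summing the magnitude grid over an ROI yields the motion
series in pixels/frame (length `n_frames − 1`). No per-frame intensity
normalization is applied by default; an optional mean-intensity detrend
guards against global lighting flicker.

For translations of a smooth blob the summed frame-difference response is
approximately linear in sub-pixel displacement but slightly *subadditive*
(doubling a displacement yields marginally less than double the response),
so amplitude-linearity checks assert proportionality within 2.5% rather
than exact doubling.

## Instantaneous correlation and IBC summaries

The coordination trace is the zero-lag moving-filter correlation of the
head and body motion series. Two filters:

* **boxcar** (default): Pearson correlation over a centered window of odd
  width `window_frames` (default 31 ≈ 1 s at 30 fps). Implemented with
  cumulative sums; edge frames without a full centered window are flagged
  invalid rather than computed from truncated windows.
* **exponential**: exponentially weighted running means, variances and
  covariance with weight `eta` (default 0.06, an effective memory of
  roughly one boxcar window); the first `ceil(1/eta)` frames are burn-in
  and flagged invalid. This is the causal filter used in published
  correlation-map implementations; the boxcar default keeps an exact
  brute-force oracle.

Windows whose variance in either signal falls below `min_variance`
(default 1e−12, an absolute threshold against genuinely static segments)
are invalid; summaries use valid frames only. Values are clamped to
[−1, 1] only against floating-point overshoot (an overshoot beyond 1e−12
raises instead of being silently clipped). Negative correlations are
retained as computed: rectifying or truncating the trace at zero would be
an undocumented transform of the summary distribution, so the signed trace
feeds all summaries.

**IBC level** is the mean of the valid trace; **IBC variability** is its
sample SD (ddof = 1, matching the cohort-descriptive convention). Cohort
descriptives report means, SDs and the level–variability Pearson
correlation, which is reported as undefined (NaN) — never 0 — when either
summary has no spread.

Lagged correlation maps (time-offset sweeps) and between-person synchrony
are out of scope; the pipeline computes the single zero-lag trace.

## Accuracy criteria

The validity criterion for target j on item k is the two-stage composite:
close-other reports (up to three) are averaged together first, then
averaged with the target's self-report; targets without close-other
reports use their self-report alone (recorded in a provenance flag).
Reports are never pooled as a flat mean across raters. The normative
profile N_k is the mean self-report of all panel targets on item k, and
the distinctive criterion is D_jk = C_jk − N_k. Missing report entries
raise; nothing is imputed.

Item observability ratings (1 = strongly agree the item is highly
observable … 7 = strongly disagree) are reverse-scored as `8 − raw`,
averaged per item, and grand-mean-centered across items. The SD of the
item profile (ddof = 1) is the step used for ±1 SD probes.

## The social accuracy model

One row per (perceiver, target, item). Fixed effects: intercept, D, N, O,
D·O, N·O, and for each target-level moderator M (and covariate, treated
identically): M, M·D, M·N, M·O, M·D·O, M·N·O. The M·O product is included
so the three-way terms are interpretable (omitting it measurably biases
them; verified against lme4's `M*D*O` expansion). Random structure:
intercept + D + N slopes for targets and, crossed, for perceivers, each
with an unstructured 3×3 covariance; observability interactions are fixed
effects only. Moderators are standardized across targets (mean 0, SD 1,
ddof = 1) before entry; observability enters centered but unstandardized.
These entry scalings are the package's convention — published reports of
this model family are often ambiguous about them, and the choice affects
only the unit, not the content, of the interaction coefficients.

### Estimation

`coordsam.lmm.CrossedLMM` minimizes the profiled (RE)ML deviance over the
relative Cholesky factors Λ_f of each factor's covariance
(σ²Λ_fΛ_f′), using the standard penalized-least-squares identities on
cross-products (Z′Z, Z′X, Z′y, X′X, X′y, y′y) accumulated once per
dataset; each deviance evaluation costs one dense Cholesky of the q×q
random-effects system (q ≈ 600 at study scale), independent of row count.
Optimization is L-BFGS-B with bounded diagonals, with a Nelder–Mead polish
if the quasi-Newton path reports failure, and an optional
diagonal-covariance fallback (tried automatically on non-convergence,
reported honestly via `converged`/`used_diagonal`). REML is the default;
ML is available for nested comparisons. The penalized residual sum of
squares is floored at 1e−300 so the zero-noise limit remains finite.

The fixed-effect design is checked for rank deficiency via the eigenvalue
spectrum of its correlation matrix; an informative error names the
collinear columns. p values use the normal reference for z = estimate/SE,
and no multiple-testing correction is applied anywhere.

Independent oracles in the test suite: statsmodels MixedLM for
single-factor models (agreement ~1e−6 on fixed effects) and lme4 via
Rscript for the full crossed design (agreement ~1e−4, and the achieved
REML criterion is required to be no worse than lme4's).

### Probing and effect sizes

A probed simple slope is the linear combination
γ_D + γ_DO·o + Σ_M (γ_MD·m + γ_MDO·m·o) at observability offset o (in
item-profile SD units) and moderator values m (already per-SD); its SE
comes from the fixed-effect covariance of the same contrast. The probing
identity — probed slope equals the base coefficient of a recentered
refit — is exact only at the shared optimum of the variance parameters,
which are algebraically invariant under recentering; the recentered refit
therefore carries the converged θ over and re-solves the fixed effects
(`fit_sam(..., reuse_theta=True)`), making the identity hold to ~1e−14.
Two independent optimizations agree only to ~1e−6 (stopping tolerance),
which is why the refit is defined this way.

The moderation effect size is d = 2·γ_mod / SD(target distinctive
slopes): the change in distinctive accuracy for a 2-SD increase in the
moderator, standardized by how much targets naturally differ in
expressive accuracy (the model's own scale for that heterogeneity). The
95% CI carries the Wald SE of γ_mod through the same linear scaling and
is therefore symmetric. With zero estimated slope variance d is reported
as undefined. This standardization is the package's documented choice;
alternatives (e.g. residual-SD scaling) would change the unit, not the
inference.

Empirical-Bayes accuracy scores split items at the centered observability
profile's zero (below/above the item mean), refit a moderator-free SAM on
the subset, and report each target's conditional-mode distinctive slope
(fixed effect + predicted random effect). These shrunken scores are for
visualization and rank-order analysis, not inference.

## Synthetic data

**Coupled signals.** The head series is a rectified AR(1) process
(smoothness 0.9, baseline 3, unit innovation scale — values qualitatively
matching the slow, positive, autocorrelated look of ROI motion traces);
the body series is ρ(t)·head + (1−|ρ(t)|)·noise with an independent
matched noise process, rectified at zero. ρ(t) is the experimenter's
handle: constant, block-alternating, or arbitrary profiles in [−1, 1].
The mixture's local Pearson correlation is monotone in ρ but not equal to
it; all validation properties are therefore comparative (higher/lower,
block vs constant), not point targets.

**Toy videos.** Two Gaussian blobs (σ = 4 px) in a 128×64 frame, one per
ROI, moving horizontally with per-frame displacements proportional to the
input signals (bouncing inside a fixed travel range, max step 1.2 px so
the frame-difference response stays near-linear). This validates the
motion→coordination path end to end; it deliberately does not emulate
articulated human motion, lighting change, or camera noise, so passing it
shows the *pipeline algebra* is right, not that frame differencing is
robust to real-world video artifacts.

**Rating studies.** True profiles are a normative backbone (item means ~
N(4.4, 0.8²) on the 1–7 scale) plus independent per-item distinctive
deviations (SD 1). Self-reports read the true profile exactly by default;
close-other reports add N(0, 0.5²) error, with 0–3 reports per target
(probabilities .27/.30/.25/.18, matching a cohort where ~3/4 of targets
have at least one report). Observability ratings are integer 1–7 responses
from 106 raters around a true item profile (mean 4, SD 0.9 on the reversed
scale). The IBC-variability moderator is log-normal with moments matched
to M = 0.19, SD = 0.06 — the only distributional facts available for it.
Perceivers view one of 8 subsets of targets (round-robin assignment),
giving 10–16 perceivers per target at the default 105/94 scale.

Ratings are generated from the model equation above using the *emitted*
tables: D, N and O entering the linear predictor are computed from the
generated self/other/observability data by the same criterion code the
analyst runs, so generator and fitter are algebraic inverses — with all
noise at zero, fitted coefficients equal generating ones to numerical
precision, and recovery is unbiased without errors-in-variables caveats.
Random effects are drawn with independent components (diagonal generating
covariance) while the fitter estimates the full covariance; residuals are
Gaussian and unclipped by default (clipping to [1, 7] is a flagged
sensitivity mode that deliberately breaks strict unbiasedness).

Default generating coefficients (intercept 4.0; D .12; N .64; O .05;
D·O .046; N·O −.233; M·D .025; M·D·O .05; others 0) form an internally
coherent set chosen to reproduce the published *pattern* of this model
family: distinctive accuracy ≈ .08 at −1 SD and ≈ .16 at +1 SD
observability, normative accuracy falling from ≈ .85 to ≈ .43 across the
same range, moderation by IBC variability appearing only on observable
items (slopes ≈ −.02 to ≈ .07), and a target distinctive-slope SD of .23
giving 2-SD effect sizes near d ≈ .6. Published interaction coefficients
for such models are sometimes printed on unstated predictor scalings;
where a printed coefficient conflicted with its own printed simple slopes,
the defaults follow the simple slopes.

## Validation studies: scales and what they show

All validation randomness derives from a single seed via
`numpy.random.SeedSequence` spawning. Problem sizes are the package's
stated study conditions: oracle comparison on 20 pairs of length 2000;
end-to-end video recovery on 10 rendered 900-frame videos;
volatility sensitivity on 50 paired replicates of 1200 frames; parameter
recovery on 50 replicates at full study scale (105 targets, 94 perceivers,
24 items, ~30k rows each); null calibration on 50 replicates at a reduced
scale (60 targets, 48 perceivers, 12 items), where type-I behavior is the
question and the smaller design answers it equally well.

Recovery is summarized as per-coefficient mean bias and the coverage of
95% Wald intervals pooled across coefficients and replicates. Pooling is
deliberate: at 50 replicates a per-coefficient coverage estimate has a
binomial SD of ~3 percentage points and takes the value 1.00 with
probability .08 even for perfectly calibrated intervals, so per-coefficient
bands would mostly measure Monte-Carlo noise; per-coefficient coverages
are still written to the recovery table for inspection.

## Known limitations

* Frame differencing conflates motion with any intensity change; no
  camera-motion compensation, tracking, or pose estimation is attempted,
  and ROIs are fixed for the whole recording.
* The exponential-kernel trace has no exact finite-window oracle; it is
  validated by invariants (perfect coupling, unit range, burn-in) rather
  than equality.
* Wald intervals and normal-reference p values are large-sample
  approximations; at small cluster counts (≲ 20 targets) they are
  anti-conservative, and the simulation scales were chosen to match the
  design the model is meant for rather than to probe that regime.
* The generator draws diagonal random-effect covariances; recovery of the
  random-effect *correlations* is therefore untested (the fitted
  covariances are validated against lme4 instead).
* Empirical-Bayes subset models omit the observability moderator by
  construction; with few items per subset, item-level misfit can leak into
  the shrunken slopes (visible as extra spread), which is why they are not
  used for inference.
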