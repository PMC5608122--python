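# Methods

`vesselrep` reimplements, as a tested library, the quantitative pipeline of a
gated-versus-ungated carotid vessel-wall MRI repeatability analysis: SNR/CNR
quantification against a noise-only scan with multi-channel coil correction,
scan-time-normalized effective CNR, contour/mask morphometry, Bland–Altman
repeatability summaries, and a permutation test on variance ratios of
repeat-difference vectors — exercised end to end on a synthetic multi-channel
vessel phantom that emulates gating-induced signal fluctuation.

## Signal model

Black-blood contrast is produced by a double-inversion-recovery (DIR)
preparation. Per tissue, the longitudinal recovery at readout is modeled as
the single-compartment expression

    S = M0 · (1 − 2·exp(−TI/T1) + exp(−TR/T1)),

signed: shots acquired while magnetization is still inverted contribute with
negative sign, and the modulus is taken only on the shot-averaged image
amplitude. Echo-train T2 decay is not modeled mechanistically; TE and readout
efficiency effects are folded into per-weighting effective M0 values.

Gating is the mechanism of interest: a gated sequence locks TR to
`rr_multiple` R-R intervals, so heart-rate variability makes TR — and through
it the T1 recovery, hence the image amplitude — fluctuate from shot to shot
and, after shot averaging, from repeat scan to repeat scan. Ungated sequences
keep TR fixed and acquire no such fluctuation. The R-R interval is drawn per
shot from a normal distribution truncated at a 300 ms floor; the default
shot-to-shot spread of 50 ms is a healthy-adult SDNN-scale stand-in, chosen
once (the emulated study did not record heart rates) and exposed as a
parameter. Effective per-shot TR is additionally floored at TI + 1 ms, since
no sequence can cycle faster than its preparation.

Tissue T1 values (3T): wall 1115 ms, muscle 1420 ms, lumen 1200 ms. The lumen
is modeled as an *effective residual compartment* — partial volume and slow
flow remaining after blood suppression — rather than perfectly nulled blood:
the DIR TI is chosen to null a ~1.6 s blood T1, so calibrating a lumen
amplitude through the near-zero blood recovery factor would require absurd M0
and produce unphysical TR sensitivity.

Because TI sits near the tissue null points at these TRs, absolute recovery
factors are small and sensitive; tissue M0 is therefore *calibrated per
protocol and per subject* so that, at the subject's nominal (mean-R-R) TR,
the noiseless amplitudes hit target ratios (wall : muscle : lumen =
1 : 1.72 : 0.29 for T1W, 1 : 1.28 : 0.37 for T2W, taken from observed
gated-acquisition SNR ratios). This mirrors practice — gated protocols are
tuned per subject — and leaves gating-induced fluctuation acting around a
controlled operating point. Ungated arms carry a net amplitude efficiency
factor (`signal_scale`: 0.80 for T1W, 0.65 for T2W) emulating the published
ungated/gated median SNR ratios (for T2W, the multi-slice cross-talk
penalty); cross-talk itself is deliberately not simulated.

## Geometry and rasterization

The scene is a concentric annulus (lumen radius 3.78 mm, outer radius
4.82 mm: lumen area ≈ 0.449 cm², wall ≈ 0.281 cm², the typical carotid
scale) plus a 12 mm square muscle block, on a 256×256 grid at 0.390625 mm
(10 cm FOV). Pixels are rendered by 4× supersampled area-weighted
rasterization with a pixel-center, 0-based convention used everywhere.

Cardiac pulsation (default peak amplitude 0.4 mm, the order of in-plane
carotid wall motion) is applied to gated repeats as a uniform zero-mean
radius draw; the outer boundary follows so that the wall cross-section is
conserved (`R' = sqrt(r'² + R² − r²)`). A lumen-only jitter would let a thin
wall invert (lumen radius exceeding the outer radius) and would impose a
wall-area variability that repeat measurements do not show; distension with
a conserved annulus is the physically sensible minimal model. Ungated
acquisitions use the cycle-averaged base radius.

## Noise model and the 0.695 correction

Independent complex Gaussian noise (`per_channel_sigma`, default 0.1 against
a unit wall amplitude, i.e. wall SNR ≈ 10) is added in each of 4 channels
*before* root-sum-of-squares combination. Pure-noise regions of the combined
magnitude then follow a central chi distribution with 2N = 8 degrees of
freedom whose SD is

    sigma_meas = sigma · sqrt(2N − 2·[Γ(N+½)/Γ(N)]²) ≈ 0.6953·sigma  (N = 4).

This is the physics behind the four-channel SNR correction: SNR is computed
as `SI/sigma_meas × 0.695`, which restores the per-channel noise scale. The
correction factor is exposed as a parameter; for other channel counts use
`central_chi_sd_factor(N)` (e.g. 0.655 for N=1 — the Rayleigh case — is
`sqrt(2 − π/2) ≈ 0.6551`).

One consequence worth knowing: the *mean* of a sum-of-squares magnitude over
a signal ROI is biased upward by the noise floor, by a factor
`sqrt(1 + (2N−1)/SNR²)` — about +3.4% at SNR 10 and larger at lumen-level
SNR ≈ 3. Real measurements carry the same bias, so it is left in place; the
test suite asserts recovery against the predicted bias rather than
pretending it does not exist.

Noise-only images reuse the same per-channel sigma with zero signal,
emulating a zero-RF-amplitude acquisition at fixed receiver gain; sigma is
estimated as the sample SD (n−1) of a spatially matched ROI on that image
(a 20 mm box centred on the muscle region by default — large enough that
sigma estimation noise, ~1/sqrt(2·n_pix), does not dominate ungated repeat
differences).

## Quantification

Per acquisition: ROI mean signal intensity (median available as a robust
option) for muscle, wall and lumen; `SNR = SI/sigma × 0.695`;
`CNR = SNR_wall − SNR_lumen` (negative values are kept, with a warning, to
avoid biasing repeatability statistics); per-slice scan time
`T_slice = (N_pe/ETL) · NEX · TR / slices_per_pass` with fractional shot
counts kept fractional (required to reproduce quoted multi-slice times such
as 40 s for 256 phase encodes at ETL 12); and
`CNR_eff = CNR / sqrt(T_slice in minutes)`. Gated TR in the scan-time
formula is `rr_multiple × 60/HR` at a 60 bpm reference.

Areas come from two independent paths: shoelace polygon integration of
closed contours in mm (shapely-backed, with loud validation of
self-intersection and lumen⊂outer nesting) and pixel counting of
half-coverage masks. The two agree within ~1.5 pixel-rings (one ring ≈
perimeter × spacing) at 0.39 mm; inscribed k-gon area converges to the
circle at O(k⁻²).

## Repeatability statistics

Distributions are summarized by median and Tukey-hinge IQR; Shapiro–Wilk
screens normality; gated-vs-ungated comparisons use the two-sided Wilcoxon
signed-rank test on repeat-1 values (Pratt zero handling; all-zero
differences reported as p = 1). No multiplicity correction is applied, by
design.

Bland–Altman repeatability per metric and arm: bias = mean(repeat1 −
repeat2) (sign convention fixed and tested), 95% LOA range = 2 × 1.96 × SD
of the differences (sample SD), and normalized LOA% = LOA range / median ×
100. The reference median defaults to the pooled repeat-1/repeat-2 values of
that arm; repeat-1-only and externally supplied medians (as when reproducing
published percentages) are selectable.

The arm comparison of repeatability is a one-sided permutation test of

    r_obs = var(d_gated) / var(d_ungated)

against the alternative that gated differences vary more. Default scheme
("pooled-resplit"): pool the 2n differences, re-split into two groups of n
without replacement, recompute the ratio. When C(2n, n) ≤ the permutation
budget the null is enumerated exhaustively and the exact p reported;
otherwise 50 000 *unique* random partitions are drawn (de-duplicated) and
the add-one estimator p = (1 + #{r ≥ r_obs})/(1 + B) is used, which cannot
return 0 and is validly conservative. A within-pair label-swap scheme (2ⁿ
swaps) is available as an alternative reading of the same null. Degenerate
inputs are handled explicitly: zero ungated variance gives an infinite
observed ratio compared against infinite permuted ratios; two zero variances
give a not-applicable result. The test is scale invariant and, at n = 13 per
arm (C(26,13) ≈ 1.04·10⁷), always takes the sampling path.

Calibration was verified by simulation: the enumeration path matches brute
force exactly and holds its size (empirical 0.049 at α = 0.05, n = 6 per
arm, 5000 replicates); the sampling path at B = 2000 shows the expected
size ≈ α + discreteness, with run-to-run binomial noise of ±1.4% at 1000
replicates. Power at variance ratio 4, n = 13 is ≈ 0.6–0.7, comfortably
above size.

## Study sizes used in tests and the acceptance script

Replicate-cohort experiments (type-I error, directional study, null-cohort
calibration) use a cropped 96×96 FOV at the unchanged 0.390625 mm spacing —
the vessel and muscle geometry is identical, only empty background is
dropped — with 13 subjects per cohort, 100 cohorts for the directional
study, and B = 2000 permutations per test. The full 256×256 default is
exercised in the end-to-end study runner. These sizes are the package's
choices for routine validation; all are parameters.

## Known limitations

* Single-compartment DIR with effective M0: no echo-train T2 modulation, no
  flow, no fat suppression, no k-space simulation; the near-null operating
  point makes absolute amplitudes sensitive to T1/TI choices, which is why
  amplitudes are calibrated rather than predicted.
* The phantom wall is concentric; eccentric (plaque-bearing) geometry is not
  modeled.
* Heart-rate variability defaults are unvalidated stand-ins; conclusions
  from synthetic cohorts are directional, not quantitative predictions of
  in-vivo LOA values.
* ROI placement uses simulation ground truth; observer segmentation
  variability — a real contributor to in-vivo repeatability — is absent, so
  synthetic LOA values are optimistic for area metrics in particular.
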