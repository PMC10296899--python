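# Methods

## Scope and model

`dialhrv` analyses beat-to-beat RR-interval recordings acquired over a
hemodialysis session alongside the session's blood-pressure course. The
scientific question it operationalizes: do patients who remain
hemodynamically stable exhibit a more complex (higher-entropy, more
1/f-like) heart-rate dynamics than patients who destabilize? The pipeline
is deliberately modular — stratification, preprocessing, spectral and
entropy features, two inference arms, and an unsupervised clustering
readout — with every stage usable on its own.

## Hemodynamic stratification

A session's SBP delta is `max(SBP) − min(SBP)` over its readings
(nominally eight: at the start and every 30 min of a 4-h session).
Stability is dichotomized at a fixed 30 mmHg: delta < 30 → HS,
delta ≥ 30 → HU; the boundary belongs to HU. A data-driven mode uses the
cohort median delta as the cutoff instead. The fixed 30 mmHg default is
what the published group definitions encode; the median mode reproduces
how such a cutoff is typically derived in the first place.

## Preprocessing

* **Artifact screening** (optional; default on for file inputs, off for
  synthetic cohorts, which are clean by construction): an interval
  deviating from the median of its 11-beat neighbourhood by more than 25 %
  is replaced by a cubic spline through the surrounding accepted beats.
  The screen is idempotent and reports its replacement count.
* **Detrending**: smoothness-priors regularization — the trend is
  `(I + λ²D₂ᵀD₂)⁻¹ z` with `D₂` the second-difference operator, solved as
  a sparse pentadiagonal system. λ = 500 gives a −3 dB point near
  0.035 Hz at 4 Hz sampling; the cutoff scales with the sampling rate, so
  on the beat-domain tachogram (~1.25 Hz) the same λ cuts near 0.011 Hz.
  A second-order zero-phase Butterworth high-pass at the equivalent cutoff
  is available as an alternative (`DetrendConfig.method`).
* **Resampling**: cubic-spline interpolation of the tachogram onto an even
  4 Hz grid spanning `[t_first, t_last]`, the prerequisite of FFT-based
  spectral analysis.

Order of operations: the spectral branch detrends the evenly resampled
series; the entropy branch runs on the beat-domain tachogram, detrended by
default (`entropy_on_detrended=False` switches to raw intervals). With
entropy measures invariant to level and tolerance tied to the SD,
detrending mainly removes slow ultrafiltration-driven drift that would
otherwise inflate coarse-scale variance.

## Spectral features

Welch periodogram of the detrended 4 Hz series: Hann taper, 256 s windows,
50 % overlap, per-segment mean removal, density scaling (PSD integral ≈
variance). Band powers are trapezoidal integrals over LF 0.04–0.15 Hz and
HF 0.15–0.4 Hz with interpolated band edges. Normalized units are
percentages of LF+HF — `LFnu = 100·LF/(LF+HF)` — so LFnu + HFnu = 100 by
construction; this matches the near-complementarity of published normalized
units and makes them invariant to PSD normalization conventions. VLF is
neither reported nor subtracted.

## Entropy features

Sample entropy uses the Richman–Moorman convention: `−ln(A/B)` where B
counts pairs of distinct m-point templates (start indices 0..N−m−1) within
Chebyshev distance r, and A the same pairs extended one point;
self-matches excluded. Multiscale entropy coarse-grains the series into
non-overlapping τ-point means (τ = 1..20) and evaluates SampEn at each
scale with r fixed at 0.2·SD of the *original* series (the canonical
choice; per-scale SD is available via `r_mode`). Defaults m = 2,
r = 0.2·SD, FuzzyEn exponent n = 2 are the universal short-term HRV
settings; the source analysis software does not expose its values, so
absolute entropy magnitudes are not comparable across implementations —
only arithmetic identities on published values and qualitative scale
signatures are validated (see below).

Summary indices are trapezoidal areas under the MSE curve on the unit
scale axis: MSE_1–20 (global), MSE_1–5 (short scales, vagally dominated
range) and MSE_6–20 (long scales, sympathetically dominated range). The
trapezoid is linear in the profile, so the AUC of a group-mean curve
equals the group mean of per-subject AUCs, and
`AUC(1,20) = AUC(1,5) + (S₅+S₆)/2 + AUC(6,20)` exactly.

Fuzzy entropy replaces the hard match count with the graded membership
`exp(−ln2·(d/r)^n)` of the Chebyshev distance between baseline-removed
(own-mean-subtracted) templates; the ln 2 constant places membership 0.5
at d = r. It is computed on the τ = 1 series only, matching how it is
reported. Undefined entropies (no template matches) propagate as flagged
NaN — never silently as zero — and poison the AUC indices of that subject,
whom the pipeline then quarantines.

The O(N²) template loops are numba-jitted with an early-abort m = 2
specialization; a 4-h tachogram (~18,000 beats) takes a few seconds per
profile on one core.

## Inference

**Frequentist arm.** Each feature is compared between HS and HU with
adjustment for session filtered volume and uremic status. The default
adjusts by OLS with standardized linear covariate terms and reports the
group coefficient (HS − HU), its 95 % CI, and two-sided p. An alternative
mode implements "covariates as random factors" literally as random
intercepts over joint covariate quartile bins (MixedLM, REML), falling
back to the fixed path when the bin design is singular or the fit does not
converge. The fixed path is the default because, in simulation at this
cohort size (n = 46, 16 small bins), it is the calibrated one: CI coverage
of an injected effect ≈ 95 % and type-I error ≈ 5 % under label
permutation, whereas the mixed fit's z-based CIs undercover (~80 %).
Both paths are reported in the output (`adjustment` column).

**Bayesian arm.** The two-sample Jeffreys–Zellner–Siow Bayes factor for
the pooled-variance t statistic:

    BF10 = ∫₀^∞ (1+N_e g r²)^(−1/2) (1 + t²/(ν(1+N_e g r²)))^(−(ν+1)/2) π(g) dg
           ─────────────────────────────────────────────────────────────────────
                                (1 + t²/ν)^(−(ν+1)/2)

with ν = n₁+n₂−2, N_e = n₁n₂/(n₁+n₂), and π(g) = (2π)^(−1/2) g^(−3/2)
e^(−1/(2g)), evaluated by adaptive quadrature (relative tolerance 1e−10;
cross-checked against a dense-grid oracle and an independent
implementation to ≤ 1e-3 relative). The Cauchy prior scale defaults to
1/√2, the standard default of the Bayesian t-test GUIs. Evidence is
labelled with the Lee–Wagenmakers bins (anecdotal 1–3, moderate 3–10,
strong 10–30, very strong 30–100, extreme > 100, mirrored reciprocals for
the null), and `100·BF10/(BF10+1)` is reported as the replication
probability. The Bayesian arm is unadjusted (no covariates) and
uncorrected for multiplicity across the 26 features, as in the analysis
it reproduces; Holm-adjusted p-values are available but off by default.

## Clustering and risk readout

Features with BF10 ≥ 3 are z-scored and clustered without using the
group labels: a random forest (500 trees) learns to separate the real
rows from a reference set built by independently permuting each column
(which preserves marginals and destroys the joint structure); proximity
of two subjects is the fraction of trees in which they share a terminal
leaf; PAM (deterministic BUILD + best-improvement SWAP, ties to the
lowest index) partitions the distance `√(1−proximity)`.

The number of clusters is scored by a spherical-Gaussian *classification*
BIC:

    BIC(k) = 2·Σ_c n_c·ln(n/n_c) + n·d·ln(2πσ̂²_k) + d·(n−k) + k·(d+1)·ln(n)

with σ̂²_k = SSE_k/(d(n−k)) the pooled within-cluster per-dimension
variance about centroids. The multinomial assignment term is essential: a
hard-assignment BIC without it (likelihood + centroid penalty only) is
monotonically decreasing in k on small samples — splitting any Gaussian
cluster refits σ̂² down by ~2/π along the split axis, which outweighs a
`d·ln n` penalty at these n — and would over-partition even two clean,
well-separated blobs. With the assignment cost, two 6-SD-separated blobs
select k = 2 and a single isotropic blob selects the smallest candidate k
(both covered by tests).

The default pipeline fixes `k_max = 2`: the downstream risk readout is a
2×2 cluster-by-group analysis, defined only for a complexity dichotomy
(which is also what the analysis being reproduced generated). With
`k_max ≥ 3` the BIC selection is active; on the synthetic cohort it then
typically prefers k = 4, because within-phenotype deviations are strongly
correlated across MSE scales (each subject contributes one noise
realization whose spectral idiosyncrasies shift all scales together),
producing elongated clusters that a spherical criterion splits. In that
case the contingency stage reports an explicit error rather than
collapsing clusters.

Clusters are relabelled so Cluster 1 is the high-complexity one (higher
mean feature z-score). The relative risk is oriented as: exposure = group
(HU vs HS), outcome = assignment to low-complexity Cluster 2 —
`rr = (a/(a+b))/(c/(c+d))` with a = HU∩C2, c = HS∩C2 — with the Katz
log-method CI `exp(ln rr ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))`; zero
cells get a flagged 0.5 continuity correction. The p-value is the
continuity-corrected chi-square test of the table (the corrected test,
not the raw one, reproduces the published p on the published counts).

## Synthetic cohort: what it emulates and what it does not

Each subject's tachogram is `mean_RR + w·pink + (1−w)·white + LF sine
(0.1 Hz) + HF sine (0.25 Hz)` evaluated at the running beat times, with
both noise components scaled to 50 ms SD before mixing and beats
accumulated to the session duration. Pink noise is synthesized by spectral
shaping (1/√f amplitude profile on white Gaussian noise, inverse FFT) —
exact, seedable, dependency-free. The mixing weight w is the complexity
phenotype: w = 0.9 (stable-like) yields the flat MSE curve of
long-range-correlated dynamics, w = 0.4 (unstable-like) the
scale-decaying curve of white-dominated dynamics. BP sessions draw the
SBP delta uniformly from [5, 29] mmHg (HS) or [30, 60] mmHg (HU) and
impose it exactly by placing the max and min readings in random slots, so
delta-based stratification recovers the construction truth by design.
Covariates are drawn from ranges typical of dialysis cohorts (filtered
volume ~N(2600, 950) mL truncated at 300; urea ~N(133, 33) mg/dL
truncated at 40), independent of group. Everything is a pure function of
(spec, seed); per-subject streams are seeded `(master_seed,
subject_index)` so individual subjects are reproducible in isolation.

Defaults mirror the target study design: 21 + 25 subjects, 4-h sessions
(~18,000 beats at mean RR 800 ms), 8 BP readings. The source reports no
recording SDs or heart-rate ranges, so the 50 ms noise SD and 15/10 ms
LF/HF amplitudes are plausibility choices, fixed once.

**Limitations.** All subjects of a phenotype share identical generator
parameters, so between-subject variance is pure estimation noise — far
smaller than physiological inter-subject variability. Consequences worth
being explicit about: (i) group contrasts on the synthetic cohort are
enormous (Bayes factors of order 10²⁰) rather than the moderate values
seen in patients, so recovery tests establish direction and machinery,
not effect sizes; (ii) both the spectral and the entropy arm separate the
phenotypes near-noiselessly, so the empirical finding that entropy
discriminates *better than* spectra — driven by physiological variance the
generator does not model — is not reproduced by construction and is not a
test target; (iii) cluster mixing (stable patients in the low-complexity
cluster and vice versa) is much rarer than in real cohorts, which pushes
the synthetic relative risk far above published magnitudes and often
yields a zero cell. Ectopy is not simulated beyond the artifact-screen
tests' injected spikes, and no baroreflex or ultrafiltration dynamics are
modelled.

## Validation strategy and problem sizes

The patient recordings behind the published tables are unavailable, so
the test suite validates (a) arithmetic identities on published summary
values — the replication-probability transform, AUC of per-scale means,
the Bayes factor recomputed from group summaries, the relative risk and
Katz CI from the 2×2 counts; (b) exact agreement (1e−12) of both
entropies with independent O(N²) brute-force oracles and of the Bayes
factor with a dense-grid integration oracle; (c) analytic limits (SampEn
of i.i.d. Gaussian noise at N = 50,000 vs −ln(2Φ(r/σ√2)−1)); and (d)
end-to-end properties on the synthetic cohort. Scale-signature tests use
10 seeds of 16,384-point noise series; the 25-replicate recovery test
runs the full pipeline on 46-subject cohorts with 30-minute sessions
(~2,250 beats) — the shortest length that cleanly supports 20-scale
entropy — keeping the phenotype contrast at its defaults; calibration
uses 200 label permutations of one cohort. `scripts/acceptance.py`
re-derives the headline quantities at run time with the same problem
sizes.

## Numerical notes

* Tolerance r is computed before coarse-graining and reused at all scales;
  per-scale r changes the white-noise signature qualitatively (it flattens
  it), which is why the fixed-r convention is the default.
* Undefined SampEn (A or B = 0) warns and returns NaN; the pipeline
  quarantines such subjects with the reason recorded in the report.
* The smoothness-priors solve uses a sparse LU of the pentadiagonal
  operator; λ = 0 short-circuits to the identity (zero residual).
* PAM and the BF quadrature are deterministic; forest and permutation
  randomness derive from the run seed, and reruns are byte-identical.
* Intervals are clipped to the physiological (200, 3000) ms window during
  generation; file readers reject out-of-range rows with line numbers
  (strict) or skip them with warnings.
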