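# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish about real annotation data.

## Annotation model

An annotation series is one rater's 1 Hz trace for one film × item on a
0–100 display scale. The generative model behind the synthetic module, and
implicitly behind the pipeline's statistics, is

    x(t) = clip( 50 + b + g · ( s(t) + ε(t) ), 0, 100 )

with a shared zero-mean unit-variance latent trajectory s(t) per film ×
item, rater-specific gain g > 0 and bias b, and iid Gaussian noise ε with
SD σ_n in latent units. Under this model two raters' series correlate at

    r = σ_s² / (σ_s² + σ_n²) = 1 / (1 + σ_n²)       (σ_s = 1),

which `choose_noise_for_agreement` inverts: σ_n = √(1/r − 1). Clipping at
the scale ends attenuates this slightly (about 0.005–0.01 at typical gains);
the attenuation is accepted and visible in the Monte-Carlo tests, which use
tolerances wide enough to cover it.

The latent is white noise convolved with a Gaussian kernel (default SD
5 s) and then standardised. This gives slow dynamics appropriate for
emotional responses at 1 Hz and a closed-form autocorrelation
ρ(k) = exp(−k²/(4·sd²)) — ρ(1) ≈ 0.990 at the default — which the tests
check directly. Wrap-around filtering keeps the marginal variance uniform.
An AR(1) latent would serve equally for the pipeline itself; the Gaussian
kernel was chosen for the closed form.

## Normalisation and screens

- **z-scoring** pools all of a rater's films for one item and divides by the
  population SD (N denominator). Pooling is per item, not across items,
  because items carry different pole meanings; a `pool_items` switch exposes
  the across-items reading. z-scoring first makes the later screens
  scale-free; imputation on z-scored values is equivalent to imputing raw
  values because the two-neighbour mean commutes with affine maps.
- **Imputation** replaces isolated missing samples by the mean of the two
  neighbours (edge samples copy the single neighbour). Runs of two or more
  missing samples are an error by default; an explicit `allow_gaps` flag
  fills them by linear interpolation and logs the count.
- **Constant screen**: zero variance, either of the pooled concatenation
  (the rater never moved for this item) or of a single film segment.
- **Outlier screen**: any sample strictly beyond |z| = 15. The boundary is
  read as strict; a sample at exactly 15.0 passes. Note an arithmetic
  constraint: m spikes among N pooled samples can reach at most
  |z| ≈ √(N/m) because the spikes inflate the normalising SD themselves.
  Screens on short single series therefore cannot flag multi-spike
  contamination; the simulator injects a single spike per contaminated
  rater accordingly.

## Exclusion cascade

Per film × item, after the screens:

1. **Deviance exclusion** (`delta = 0.20`, floor 3): greedily remove the
   series whose removal most increases the remaining mean pairwise r, while
   that increase exceeds 0.20 and at least three series would remain. The
   published rule names a criterion but not an iteration order; greedy
   re-evaluation is the determinate reading, and an exhaustive enumeration
   oracle in the test suite confirms the greedy result coincides with every
   admissible removal order on small instances.
2. **Worst of five**: combos still holding five series lose the one with
   the lowest mean correlation to the others. Ties remove the
   lexicographically last rater id; deviance ties take the smallest.

Reliability gating (item mean across films < 0.15 removed, < 0.20 flagged;
film mean across items < 0.25 removed) runs by default before the cascade
on the screened agreement matrix, with `gate_first=False` exposing the
reverse order; film means are recomputed without removed items so a few bad
items cannot sink a film. The exclusion ledger enforces the conservation
identity available = survivors + Σ removals on every run, and
`reconcile_ledger` derives the 3- vs 4-rater combo split from the design
constraint that every combo retains three or four series.

### Sensitivity limits of the 0.20 rule

Removing a single fully deviant rater from a four-rater combo at pairwise
agreement ρ raises the remaining mean r by ρ/2 in expectation — 0.25 at
ρ = 0.5, only 0.05 above the rule's threshold. The leave-one-out
improvement fluctuates with the spurious correlation between two smooth
latents, whose SD is ≈ √(√(2π)·sd/T) (≈ 0.13 for sd = 5 s, T ≈ 700 s), so
roughly a tenth of true deviants fall under the threshold at film-length
series; recall plateaus near 90% regardless of rater count and would need
hour-long films to exceed 95%. Two independent deviants in one four-rater
combo are essentially unremovable (each removal gains only ≈ ρ/6), which is
why the dataset simulator caps injection at one contaminated rater per item
group: the rule is identifiable only against a clean majority.

## Consensus

The consensus is the pointwise mean of the surviving z-scored series, not
re-standardised: its variance shrinks with noise and rater count, and that
agreement-dependent variance is informative (the consensus–latent
correlation 1/√(1 + σ_n²/(n·σ_s²)) is asserted to ±0.02 in the tests).
Combos failing the ≥3 floor are reported, never silently dropped.

## Clip validation

Sparse clip ratings are anchored at clip temporal midpoints — the least
phase-biased convention for a rating summarising the whole clip — and
linearly interpolated, with constant extension beyond the terminal anchors
to avoid unbounded edge excursions. Subject series are z-scored, averaged,
and correlated with the consensus; lengths may differ by one trailing
sample (truncated with a warning).

The default clip plan scales the clip count with film duration at ~21
clips per 11.5-minute film (uniform 4–10 s durations, uniform random
non-overlapping placement), covering ≈ 21% of each film; all subjects of a
film share one plan, as in a real post-scan session where everyone watches
the same excerpts. Two opposing effects govern the validation correlation:
averaging 3–4 subjects suppresses rating noise (pushing it above single-pair
agreement), while the shared sparse plan misses inter-anchor signal
(pushing it below). Under matched noise these nearly cancel; the residual
net bias in the benchmark is about −0.04 relative to mean inter-rater
agreement (it flips to ≈ +0.05 with independent per-subject plans). Exact
cancellation is not structural, so "validation r ≈ agreement r" should be
read as agreement to within a few hundredths, not as an identity. The
item-level meta-correlation — items with noisier raters validate worse — is
robustly positive under heterogeneous per-item noise.

## Physiological regressors

Raw traces (nominally 1000 Hz) are anti-alias downsampled to 40 Hz
(polyphase resampling with linear-trend padding) and low-pass filtered with
a 4th-order zero-phase Butterworth at 8 Hz (cardiac) or 2 Hz (respiration).
Peaks are prominent local maxima (default prominence: half the trace SD)
with a refractory period (default 0.5 s); a manual-edit hook applies
logged add/remove operations.

- **HBI**: per 1 Hz output sample, the median of inter-beat intervals whose
  midpoints fall in a centred 6 s window, convolved with the negated
  cardiac response function of Chang, Cunningham & Glover (2009).
- **RV**: population variance of the conditioned respiration trace in a
  centred 8 s window (truncated at run edges), convolved with the
  respiratory response function of Birn et al. (2008).

Both kernels are sampled on the output grid over a 60 s support and
normalised to **unit peak absolute amplitude**. The raw published forms are
biphasic with near-zero net area, so area normalisation is ill-conditioned;
peak normalisation fixes the regressor scale without touching its shape
(regression coefficients absorb the overall scale anyway). Windows with no
interval carry the nearest defined value, with a warning. The output rate
defaults to 1 Hz to align with annotations; resampling to a scanner TR is
left to the caller.

## Synthetic benchmark: scope and limits

Problem sizes in the tests and the acceptance script — 100–200 simulated
film × item combos over the 14 bundled credit-free film durations
(402–1028 s), four raters each, 30 screen-injection checks, 300 s
physiology runs — were chosen to hold Monte-Carlo standard errors near or
below the asserted tolerances while keeping a full run in seconds.

The generator reproduces the statistical skeleton the pipeline assumes:
shared smooth latents, affine raters with calibrated noise, archetypal
contaminants, sparse shared clip plans, quasi-periodic physiology with
ground-truth events. It deliberately omits film content structure, rater
fatigue and order effects, non-Gaussian rating noise, memory-based biases
in retrospective clip ratings, and individual differences in the latent
itself. Passing tests therefore establish that the pipeline's screens,
exclusions, averaging and validation behave as specified under the stated
noise model — not that real raters satisfy that model, nor that real-data
agreement values will match the simulated ones.
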