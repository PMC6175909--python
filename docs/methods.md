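# Methods

This note documents the models and procedures the package implements, the
defaults it ships, and the choices made where the underlying conventions
were open.

## Freezing classification

The classifier operates on per-frame changed-pixel counts. A pixel counts
as *changed* when its intensity differs from the previous frame by more
than a configurable delta (default 10 on the 0–255 scale; the criterion is
rarely published, so it is exposed in the API). The count trace is smoothed
with a discrete Gaussian (σ = 3 frames, kernel truncated at ±4σ and
renormalized to unit sum, boundaries by edge replication — constant traces
are preserved exactly). A frame is *freezing* iff it lies in a run of at
least `min_run` consecutive frames whose smoothed value is **strictly**
below threshold; ties at the threshold count as motion. Runs are reported
as half-open `[start, end)` frame intervals, 0-based.

Defaults: `min_run = ceil(1.5 s × 25 fps) = 38` frames; threshold 983 px in
whole-frame mode and 100 px in ROI mode. 983 px corresponds to 0.5% of a
512×384 frame (196,608 px); the package warns whenever a configured global
threshold deviates from 0.5% of the actual frame size by more than 10%.
ROI counting restricts to a dilated bounding region around the largest
moving blob (or a user-supplied mask) to discard patch-cord motion; an
empty ROI falls back to the global count with a logged warning.

Session summaries report the percentage of freezing frames per CS window
and per the 30 s preceding each CS, with an early/late split (first/last
half of the CS train; 20 CS of 30 s separated by 60 s is the default
protocol).

## Unit silencing and antidromic spiking

Spike times are trial-aligned with light onset at t = 0; all windows are
half-open, so a spike exactly at onset belongs to the light window.

*Suppression* (long pulses): per-trial spike counts in [−5, 0) vs [0, 5) s
are compared by a paired two-tailed t-test (10 trials per light power
density by default). A unit is *suppressed* when p < 0.05 **and** the mean
light count is below the mean pre count. The directional conjunction is a
deliberate choice: a pure two-tailed criterion would also flag activated
units. Its side effect is that the false-positive rate for the suppressed
label on null data is roughly half the nominal α (≈ 2.5–3% at α = 0.05),
which the calibration test verifies as staying under the 5–6% bound.
All-identical paired counts give p = 1 (no crash); zero-variance nonzero
differences give p = 0 flagged degenerate.

*Antidromic spiking* (short pulses): the same paired test on counts in
[−20, 0) vs [0, 20) ms around the onset of a 5 ms pulse (20 trials),
flagged when spiking is *elevated*. First-spike latency is averaged over
trials with ≥ 1 spike in the response window; units are ordered by
ascending mean latency with ties broken by unit id.

*Population summaries*: fractions of flagged units per LPD and construct
are compared with the 2×2 Pearson χ² when all cells are positive and with
Fisher's exact test when any cell is zero.

Relative firing rate is pooled over trials: FR(light)/FR(pre), undefined
(NaN, excluded from means) when the pre-light rate is zero. The population
PSTH divides each unit's binned rate (100 ms bins tiling [−pre,
pulse+post)) by that unit's mean pre-light rate before averaging across
units; zero-pre-rate units are excluded and counted in the log.

## Photocurrent and EPSC quantification

Sign convention: ACR photocurrents are outward (positive) at
V_hold = −35 mV; EPSC amplitudes are reported as magnitudes.

* *Stationary current*: mean over the final 10 ms of the light pulse
  (the pulse-end averaging window is not standardized; 10 ms is the
  package default) minus the pre-pulse baseline (50 ms). Invariant under
  additive baseline shifts.
* *Closing kinetics*: nonlinear least squares of
  I(t) = I₀·e^(−t/τ_off) + C on post-offset samples, initialized with
  I₀ = i(offset) − i(end), C = i(end) and τ from the 1/e crossing. Fits
  whose amplitude sign contradicts the data excursion, or whose τ exceeds
  the fitted data span (a ramp fits an exponential arbitrarily well in
  that limit), are returned with `converged=False` rather than raising.
* *Light sensitivity*: least-squares fit of
  I(LPD) = I_max·LPD/(EPD50 + LPD) to ≥ 3 stationary-current points; by
  construction the fitted curve passes through I_max/2 at LPD = EPD50.
* *EPSC amplitude*: the trace is smoothed by Savitzky–Golay with Welch
  (parabolic) weights — implemented as weighted local quadratic regression
  over an 11-sample window with weights w_k = 1 − (k/((m+1)/2))², since
  classic SG is unweighted; edges use truncated windows with the same
  weight law. The filter reproduces polynomials up to order 2 exactly.
  Amplitude = max |smoothed − pre-light baseline| within 20 ms of light
  delivery.

## Tissue optics

Fractional irradiance below the fiber tip factorizes into a geometric
cone-spread term, ρ = r·√((n/NA)² − 1), I_geom(z) = ρ²/(z + ρ)², and a
Kubelka–Munk-style tissue term e^(−μ_a z)/(S(λ)·z + 1). Defaults:
r = 0.1 mm, NA = 0.37, n = 1.36, and power-law S(λ) anchored at
≈ 11 mm⁻¹ near 470 nm — order-of-magnitude mouse-cortex values shipped as
an editable parameterization, **not** measured spectra; quantitative
depth estimates require user-supplied coefficients. Bundled action spectra
are synthetic Gaussian stand-ins (`ActionSpectrum.gaussian_standin`),
clearly labeled; the optimal-wavelength routine maximizes
spectrum × transmittance on the spectrum grid and red-shifts with depth
whenever attenuation decreases with wavelength.

## Histology metrics

Lateralization ratio = Σipsi/(Σipsi + Σcontra) over the regions of a class
(expressing / non-expressing), computed on **pooled counts**; the
per-region-mean alternative is available via a flag, since the pooling
convention is not fully determined by common usage. 0.5 indicates
hemispheric symmetry. The same normalization applied to DAPI counts serves
as a density control. The soma-restriction index is mean layer-1
fluorescence over mean injection-center fluorescence; fold changes divide
by a reference-group mean.

## Statistics

`TestResult` carries statistic, df, p, sidedness and notes for every test.
Standard procedures delegate to scipy/statsmodels behind this surface
(Pearson χ² *without* Yates correction — validated by exact reproduction of
five published statistics from reconstructed counts; Fisher two-sided by
summing hypergeometric probabilities ≤ the observed table's; Mann–Whitney
reporting U = min(U₁, U₂) with an exact-enumeration mode for small
untied samples and a continuity-corrected tie-robust normal mode;
tie-corrected Kruskal–Wallis; Holm step-down with monotonicity
enforcement). The Scheirer–Ray–Hare test and the one-way within-subject F
are implemented directly: SRH ranks all observations jointly (mean ranks on
ties), computes two-way ANOVA sums of squares on the ranks, and refers
H = SS_effect/MS_total, MS_total = SS_total/(N−1), to χ² with the effect's
df; main effects and the interaction are all returned. Default sidedness is
two-tailed everywhere; the one-sided Mann–Whitney normal path exists
because published U/p pairs in this literature are often only consistent
with that variant.

Note on Holm: enforcing monotonicity can raise a later adjusted p above
its raw step factor (m−k+1)×p_(k); published "corrected" values computed
without monotonicity enforcement may therefore differ slightly from this
package's adjusted p while remaining consistent with the step factors.

## Synthetic data

The generators define the conditions under which the package is validated:

* Spike trains are inhomogeneous-Poisson by thinning against the max-rate
  bound r₀(1 + g): rate r₀ before light, r₀(1 − s) during, and
  r₀(1 + g·e^(−(t−t_off)/τ_reb)) after offset. Refractoriness is ignored
  (no spiking model beyond Poisson is assumed), and rebound is opt-in
  (default gain 0). Antidromic spikes are extra events at
  onset + truncated-Gaussian latency, independent of the background.
  Baseline rates default to a fixed 5 Hz so analytic expectations stay
  closed-form; a gamma-distributed per-unit rate (via `rate_cv`) is
  available for heterogeneous populations. One integer seed drives
  everything; per-unit/trial sub-streams come from `SeedSequence.spawn`,
  so outputs are byte-identical under a fixed config.
* Behavior traces draw Gaussian changed-pixel counts around 3000 px/frame
  during motion and 20 px during bouts (clipped at 0), at 25 fps over a
  300 s default session with three scheduled bouts — chosen so the
  default-threshold classifier is strongly identifiable, which is what the
  round-trip tests require. Real traces have heavier tails, posture-
  dependent counts and grooming epochs; passing these tests demonstrates
  the algorithm, not robustness to such artifacts.
* Current traces: 20 kHz sampling; photocurrents rise mono-exponentially
  (τ_on = 3 ms) to the saturation-law stationary level (optional
  desensitizing transient), decay with τ_off after offset; EPSCs are
  difference-of-exponentials (rise 1 ms, decay 5 ms) at 8 ms latency,
  amplitude-normalized. Additive Gaussian noise only.
* Region counts: independent Poisson per (region, hemisphere); an
  ipsilateral suppression factor f in expressing regions gives the
  closed-form expected ratio f/(f+1).

## Problem sizes

The validation suite uses simulation sizes chosen to make Monte-Carlo
error small relative to the assertion bands while keeping the whole suite
fast: 1000 null units for classifier calibration (binomial SE ≈ 0.7 pp at
5%), 100 seeds for the τ_off and EPD50 recovery distributions, 200 units
for suppression-fraction recovery, 2000 replicates for the rank-test
calibration (SE ≈ 0.5 pp), and 1000 random traces for the freezing oracle
equivalence.

## Known limitations

* No spike sorting, waveform QC or drift handling — inputs are sorted
  event tables.
* The t-test on counts is an approximation for low-rate units (counts are
  small integers); its empirical calibration is verified only under the
  Poisson null.
* The optics model is analytical (no Monte-Carlo photon transport, no
  heating) and its default coefficients are stand-ins.
* EPSC quantification implements the excitatory 20 ms-window path only.
* The repeated-measures ANOVA covers a single within-subject factor
  without sphericity correction.
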