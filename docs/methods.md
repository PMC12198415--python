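# Methods

`dgsomi` re-implements, as a tested library, the analysis chain used for
head-fixed mice running a goal-oriented learning (GOL) task on a 4 m circular
virtual track while dentate-gyrus units — in particular optogenetically
identified somatostatin-expressing interneurons (SOMIs) — are recorded
extracellularly.  This note describes each model and procedure, the
parameters that matter, the synthetic data the package is validated on, and
the limits of what that validation shows.

## Session model and conventions

A session bundles sorted spike trains, mean waveforms, continuous position
(cm, wrapping at 400 cm) and speed (cm/s) traces, an event table (rewards,
licks, light pulses at two fiber sites, sensory stimuli) and a lap table.
All timestamps are float64 seconds on one clock; every time bin in the
package is half-open `[t, t + dt)`; alignment places event onset at `t = 0`.
One session seed feeds named child streams (`numpy` `SeedSequence`), so each
stochastic stage is reproducible on its own and the full pipeline is
bit-stable under a fixed `(config, session, seed)` triple.

Peri-reward windows: pre-zone `[-2, 0)` s, post-zone `[0, +2)` s, baseline
`[-6, -4)` s relative to reward onset.  The baseline window is a config key
(`baseline_window_s`) because published descriptions of the reference
baseline vary between "4–6 s before reward" and "3 s prior"; all analyses
here read the config value and compute baseline rates from raw spike times,
not from the aligned matrix.

## Behavioral analysis

Motion states: immobility below 0.5 cm/s, steady-state locomotion above
3 cm/s; the band between is labeled *intermediate* rather than forced into
either state.  A running onset requires at least 3 s of immobility followed
by reaching 3 cm/s within 3 s; the onset time is the first sample leaving
immobility, and offsets mirror this definition.  The implementation is
interval-based but is tested against an exhaustive per-sample scan oracle.

The expert criterion is two paired one-sided Wilcoxon signed-rank tests
across rewarded laps at alpha = 0.05: pre-zone lick rate above baseline, and
pre-zone speed below baseline.  Both must pass.  The test choice and alpha
are package defaults (the criterion is usually reported only as
"significant"); the signed-rank test was chosen because per-lap lick counts
are small and skewed.  The performance score is the fraction of laps whose
pre-zone lick rate exceeds the baseline rate, and the lick-rate-versus-lap
trend is an ordinary least-squares fit reported with Pearson r and its
two-sided p.

## Unit classification

The bursting index is the mean autocorrelogram count in the 3–5 ms bins
divided by the mean count in the 200–300 ms bins; the autocorrelogram uses
1 ms bins to 300 ms lag so both windows are exact bin unions, and it is
tested for exact equality with an O(n²) pair count.  Trough-to-peak duration
is measured on the recording site with the largest peak-to-peak amplitude,
from the global trough to the subsequent maximum.

Classes use strict thresholds: principal cells (PC) at bursting index > 3
and trough-to-peak > 0.45 ms; fast-spiking interneurons (FSI) below both;
wide-spike interneurons (WI) wide but non-bursty.  Values exactly on a
threshold and the bursty-narrow quadrant return "unclassified".

PC-class units are split into putative granule cells (GC) versus mossy
cells (MC) by k-means (k = 2, 50 restarts, fixed seed) on z-scored features:
the first two principal components of the second derivative of the waveform
(0–0.8 ms from the trough, PCA fit across all units of the session, central
differences on the raw grid), the resting dentate-spike amplitude — consumed
as an externally supplied per-unit scalar, never derived from LFP here — and
spatial information.  Spatial information is Skaggs' bits/spike,
`sum_i p_i (λ_i/λ̄) log2(λ_i/λ̄)`; this formula is a documented package
choice (the source literature cites it indirectly).  The cluster with higher
mean spatial information and lower mean rate is labeled GC.  Whether to
z-score before clustering is unstated in the source; z-scoring is the
package default so no single feature's units dominate.

## Optogenetic tagging

For each pulse set (one site, one duration; 50 ms and 250 ms sets are
analyzed separately), spike counts during pulses are compared with the
immediately preceding same-length epochs by a paired two-sided Wilcoxon
signed-rank test at alpha = 0.05 (the test and level are package defaults).
Tags: SOMI for a significant increase with median first-spike latency
<= 5 ms; disinhibited for a significant increase with later first spikes;
inhibited for a significant decrease.  The 5 ms rule is applied to the
*median* over pulses of the per-pulse first-spike latency — a per-pulse
reading would be fragile to spontaneous spikes near onset.  A unit with an
early increase but late suppression is flagged (`early_increase_late_
decrease`) rather than given a fifth class.  SOMIs whose firing also rises
during fimbria (axonal) stimulation are `proj`, otherwise `local`.
Protocols with fewer than 20 pulses are refused as underpowered.

## Monosynaptic connection detection

Cross-correlograms use 0.5 ms bins over ±50 ms: the 2-consecutive-bin rule
inside the 2.8 ms causal window needs sub-millisecond bins, and ±50 ms gives
the smoothing kernel full support.  The baseline is the CCG convolved with a
partially hollow Gaussian (SD 10 ms; center weight scaled by 1 − 0.6,
kernel renormalized to sum 1, edge mass redistributed by renormalizing over
in-window support — a flat CCG is its own baseline everywhere).

A pair is connected when (a) at least 2 consecutive bins with centers in
[+1.2, +4] ms exceed the 99.9th-percentile Poisson quantile of their
baseline mean, and (b) the causal peak count exceeds the same quantile
evaluated at the largest anti-causal peak (window mirrored to [−4, −1.2] ms;
the mirror window and the quantile form of comparison (b) are package
choices, as the source defines neither precisely).  Latency is the causal
peak's bin center.  The manual-curation step used on real data is replaced
by the automatic criteria plus a `borderline` flag for pairs passing exactly
one criterion.  Measured on simulated pairs: >= 90% detection power at
transmission probability 0.2 with 2000 presynaptic spikes on a 5 Hz
background, false positives <= 1% of independent pairs, latency recovered
within ±0.5 ms.

## Event-aligned responses

Alignment bins spikes at 100 ms over [−5, +5] s around each event; Gaussian
smoothing (sigma = 1 bin) acts along time only, and z-scoring uses the full
trial × bin matrix.  Reward modulation compares per-trial zone rates with
per-trial baseline rates (paired two-sided Wilcoxon, alpha = 0.05, per
zone); a cell is *anticipatory* iff its pre-zone is up-modulated.  The delay
to maximal change is the argmax over [−2, +2] s of the absolute difference
between the smoothed, z-scored trial-average and its baseline reference
(clipped into the aligned window); ties break to the earliest bin.  The
±2 s search window is a config default inferred from the magnitudes such
delays take in expert/non-expert comparisons.

ON/OFF classification compares mean rates in [−3, −1] s versus [+1, +3] s
around running transitions (windows chosen to avoid the speed ramp itself):
OFF cells drop at onset and rise at offset, ON cells the reverse, both by
paired one-sided Wilcoxon at alpha = 0.05; anything else, or fewer than 8
transitions per kind, is NON.  Speed regression is OLS of 100 ms-binned rate
on binned speed, optionally restricted to steady-state bins (> 3 cm/s).
Sensory responses compare during-versus-pre counts per modality with the
stimulus duration as the epoch.  The lap-activity correlation returns the
mean Pearson r of smoothed per-lap activity vectors over all pairs between
two lap groups, excluding constant vectors.

## GLM encoding model

Per trial, [−3, +3] s around reward is cut into 24 bins of 0.25 s (the bin
width follows from 24 bins over 6 s).  Response: binned rate.  Predictors:
binned lick rate, speed, acceleration (first difference of binned speed per
bin width), and a reward indicator that switches to 1 at the bin containing
delivery.  Fitting is OLS with intercept under 5-fold cross-validation
split by whole trials — row-level folds would leak within-trial
autocorrelation; the source does not say which it used, so trial-level is
the package choice.  Skill is explained variance on held-out rows pooled
over folds, EV = 1 − Var(y − ŷ)/Var(y).

Significance: 500 permutations that re-deal whole-trial predictor blocks
across trials (response fixed, temporal structure of each block intact);
a cell is significant when its EV exceeds the null distribution's 95th
percentile.  Per-variable importance permutes only that variable's blocks
and reports `ΔEV = EV_full − mean(EV_permuted)`.  The anticipatory variant
uses [−3, 0] s (12 bins) without the reward predictor.  Note that this
permutation scheme has power only against *trial-specific* covariance; a
response locked identically to every reward is preserved by the null.

## Maximum-likelihood decoder

Classes: *baseline* (the 2.75 s ending 1.5 s before reward — the source
bounds only its end, so the start is a package choice matching the longest
decoding window) and *expectation* (−1.5 to +1.5 s).  Per cell, class and
training fold, the rate is a Gaussian KDE (bandwidth 200 ms) of pooled
relative spike times, reflected at the window edges and normalized to Hz on
a 50 ms grid, floored at 0.1 Hz so log-likelihoods stay finite.  Cells
averaging less than 1 spike per 1.5 s are excluded.

For each decoding-window length L in {0.25, …, 2.75} s, each held-out trial
contributes one pattern per class, anchored at the class-period start
(window-per-trial rather than tiling the class period; the alternative
reading is noted as ambiguous in the source).  Patterns are classified by
the larger sum of time-resolved Poisson count log-likelihoods (0.25 s bins);
cross-validation is 2-fold over even/odd trials.  Significance compares
accuracy with the 99th percentile of 500 label shuffles; the shuffles
permute the class labels of the held-out patterns with the fitted rate
models kept fixed (re-estimating the KDE per shuffle is not implied by the
shuffled-label description and would change nothing about the null's
location at 0.5).  Population decoding sums log-likelihoods over cells
before the argmax, averaging over 50 random subsets per population size.

The residualized variant subtracts each cell's GLM-predicted speed-plus-
acceleration rate contribution from its 0.25 s-binned counts (floored at 0)
and re-estimates rate models by Gaussian smoothing (200 ms) of the binned
residual rates — residuals have no spike times, so spike-time KDE no longer
applies, and the Poisson likelihood uses `gammaln(n+1)` to admit non-integer
counts.

## Synthetic sessions and what they do (not) show

The generator composes inhomogeneous Poisson spike trains (thinning on a
5 ms rate grid) on top of a constructed behavioral session: piecewise-linear
speed segments between the two reward sites (cruise ~20 cm/s with lap
variability; experts decelerate linearly over the final 2 s to ~5 cm/s at
onset, matching reported reward-zone speeds; one >= 3.5 s immobility bout
per lap provides running transitions), licks as a zone-stepped Poisson
process (baseline 0.5 Hz; expert pre-zone 4 Hz; post-zone 6 Hz) with a
log-normal lap-to-lap intensity factor (sigma 0.4).

Unit structure: waveforms are parametric biphasic shapes with
class-specific trough-to-peak times; PC-class burstiness is injected as
4 ms doublets (probability 0.35 per spike); place fields are multiplicative
Gaussian bumps placed away from the peri-reward windows so unmodulated
units stay unmodulated; reward modulation is a multiplicative Gaussian bump
(predictive: peak −0.3 s, SD 0.5 s; consumption: peak +1.2 s, SD 0.4 s —
the SD is narrow enough that a consumption profile does not leak into the
pre-zone, keeping its label meaningful) or a boxcar for step designs.
Predictive SOMIs additionally track the instantaneous lick rate (0.8 Hz per
lick/s) and all SOMIs scale their per-trial modulation with the lap's
licking intensity: without such shared lap-to-lap variability every trial
is statistically identical and a trial-permutation test can never reject,
which is a property of over-homogeneous simulations, not of the method.
ChR2 responses are a ×10 rate step during pulses plus a deterministic first
spike at the unit's latency, so the 5 ms criterion is exercised on both
sides; inhibited units drop to 2% of baseline; disinhibited units step up
only 8 ms after onset.  Synapses add one postsynaptic spike per presynaptic
spike with the configured probability at latency + N(0, jitter).  A 0.1 ms
dead time enforces strictly increasing trains.

The default study sessions hold 12 SOMIs (expert: 8 predictive / 4
consumption; non-expert: all consumption), 20 PCs (10 GC-like, 10 MC-like,
4 SOM-inhibited, 2 disinhibited, 3 of them presynaptic to SOMIs at 0.3
efficacy / 2–3 ms latency) and 6 FSIs, over 30 laps (60 rewards) plus
dual-site light protocols (100 pulses × 250 ms at 5 s intervals per site).
Most units are reward-modulated, as is typical of recordings at learned
goal sites; the pure nulls bound how well any alpha = 0.05 classifier can
score against ground truth.

What passing tests show: the estimators compute what they claim (oracle
equality), the tests hold their false-positive rates under the generator's
Poisson null, and the full chain recovers planted structure at realistic
effect sizes.  What they do not show: robustness to non-Poisson firing
(bursting beyond doublets, refractoriness, rate drifts), spike-sorting
contamination, overlapping light artifacts, theta-locked dynamics, or any
LFP-derived quantity — dentate-spike amplitude enters only as a supplied
feature, and LFP analyses are out of scope.

## Numerical choices and degenerate inputs

Wilcoxon tests drop zero differences and fall back to p = 1 on degenerate
(all-tied or tiny) samples rather than raising.  OLS inside the GLM solves
the normal equations with an lstsq minimum-norm fallback for collinear
designs.  The KDE floor (0.1 Hz) and the Poisson quantile floor (mean
1e-12) keep likelihoods and thresholds finite at zero counts.  Constant
traces return flagged degenerate results (r = 0) in the regressions, an
error in delay-to-max-change, and flags in the lap correlation.  k-means on
constant features flags `constant_feature`/`single_cluster` instead of
failing.  Problem sizes in the test suite (session length, pair counts,
numbers of null replicates) are chosen so the whole suite validates the
statistical properties at Monte-Carlo error a few times smaller than the
tolerances being asserted.

## Known limitations

- The decoder's baseline period start, CCG bin width/span, ON/OFF windows,
  the delay search window, and all test/alpha choices marked above are
  package defaults where the source is silent; each is a config key.
- Inhibitory (trough-type) connections, jitter-corrected CCGs, LFP
  analyses, distance-binned activity maps and group-level repeated-measures
  statistics are out of scope.
- The GLM is identity-link linear regression without regularization, by
  design; Poisson links are not offered.
- Synthetic behavior is piecewise-deterministic with additive noise; it
  does not model hesitations, backward motion, or position-estimation
  error.
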