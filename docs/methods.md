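# Methods

## Signal model of the synthetic cohort

Each subject is a set of dipole sources on a toy head. Source 0 carries a
theta oscillation s_θ(t) = sin(2π f_θ t + φ), f_θ = 6 Hz by default
(inside the 4–7.5 Hz theta band). Source 1 carries

    g(t) = [1 − d + d·m(t)] · sin(2π f_γ t + ψ),

with f_γ = 40 Hz (inside 30.5–44 Hz), modulation depth d ∈ [0, 1] and
m(t) the theta carrier min–max normalized to [0, 1] over the realization
(min–max rather than z-scoring guarantees the envelope stays nonnegative
at d = 1). At d = 1 the gamma envelope is an affine image of the theta
waveform; at d = 0 it is constant. All remaining sources carry 1/f
(power-spectral slope −1) background noise at amplitude 0.3 relative to
the unit-amplitude rhythms — a minimal realistic EEG spectrum that keeps
closed-form control of the sensor SNR.

Every dipole points along the fixed +z orientation. This is deliberate:
the nesting statistic's theta component carries an arbitrary sign that
the principal-component convention (below) pins deterministically, so a
*random* dipole orientation would make the sign of the planted
theta–envelope correlation a coin flip. A fixed orientation plays the
role of consistent cortical dipole geometry across subjects.

Scalp data are gain × currents plus white Gaussian sensor noise with
variance (mean clean sensor power)/10^(SNR/10); defaults mirror a
resting-state acquisition (500 Hz, 5 min, 19-channel 10–20 montage,
SNR 10 dB). A recording with zero source currents receives unit-variance
noise, since the SNR ratio is undefined there.

Behavioral scores: per-subject modulation depth is uniform on the
configured range; the 0–10 loudness rating is 5 + 2·(r·z(d) +
√(1−r²)·ε) clipped to [0, 10], which targets corr(d, NRS) = r with only
a slight clipping attenuation. The matched loudness (dB SL) derives from
percept parameters drawn independently of d, so the two loudness measures
are dissociated by construction. The matching staircase responder is
deterministic (no lapses), which makes its convergence exactly testable:
pitch converges within half an octave, level within 2 dB, for every truth
inside the bounds.

### What the generator does not emulate

No anatomy (sensors on a schematic hemisphere, sources on a cubic grid,
infinite-homogeneous-conductor dipole gains), no non-stationarity, no
ocular/muscle artifacts beyond what the amplitude criterion can be tested
with, no multi-frequency tinnitus percepts, integer-free (continuous)
rating scores, and hearing loss reduced to a single threshold value.
Passing tests therefore demonstrate correctness of the *computations*
and recoverability of planted effects under idealized mixing — not
performance on clinical EEG.

## Sensor conditioning

Zero-phase (forward–backward) 4th-order Butterworth band-pass; the double
pass gives ≥ 40 dB attenuation one octave outside the 2–44 Hz edges.
Resampling is rational polyphase (500 → 128 Hz is exactly 32/125).
Common-average reference, then non-overlapping 2-s epochs; any epoch with
a sample exceeding the amplitude criterion (default 100 µV equivalent) is
dropped — an automated, reproducible stand-in for manual artifact
inspection. Cross-spectra use Hann-windowed DFTs averaged over epochs and
over the bins inside each band; 2-s epochs put at least two bins inside
the narrow delta band at 128 Hz. Band edges are closed intervals on bin
centers, first matching band wins. Scaling is chosen so the six band
powers sum approximately to the filtered signal's variance.

## Inverse solution

With H the average-reference centering matrix and K_c = H·K the centered
gain, the transform is T = K_cᵀ(K_c K_cᵀ + λH)⁺ and each source's
3-vector estimate is whitened by the inverse square root of its 3×3
diagonal block of the resolution matrix R = T·K_c, so the squared norm is
the standardized power. λ defaults to 10⁻² of the mean eigenvalue of
K_c K_cᵀ (no published value constrains this choice; the default is
configurable and λ = 0 falls back to the pseudoinverse). The standardized map has exactly zero localization error
for a noiseless point source — verified exhaustively on 16- and
64-source toy heads — and annihilates any common sensor offset.

"Power normalized to 1 and log transformed at each time point" is
ambiguous for signed currents; here the per-sample normalization scales
total squared current across sources to 1 (all-zero samples are flagged,
not divided), and logs are applied only to nonnegative power summaries.
ROI band log power is: per source, band-pass the 3-component current,
average squared magnitude over time, take the natural log, then average
over the region's (de-duplicated) sources.

The per-sample normalization is applied **only on the connectivity
path**. Measured on planted-zero-coupling subjects, normalizing before
the nesting computation inflates percent-time ~8 points above the
independent-signal null, because the normalization is a common
time-varying gain across sources that couples the theta component with
the gamma envelope; on raw standardized currents the gap vanishes. The
normalization belongs to the connectivity analysis, not to the nesting
procedure.

## Lagged phase synchronization

Per 2-s Hann epoch, Fourier coefficients in the band; variant `phase`
(the default, and the variant the headline loudness correlation is
reported with) normalizes every coefficient to unit modulus, variant
`linear` keeps amplitudes. Coherency c = ⟨X·Ȳ⟩/√(⟨|X|²⟩⟨|Y|²⟩) over epochs × bins, and

    lagged = Im(c)² / (1 − Re(c)²) ∈ [0, 1].

Identical signals (Re c = ±1) are a degenerate case defined as 0 with a
warning. The statistic is symmetric, amplitude-invariant in the phase
variant, ≈1 for quarter-period-lagged band-centered sinusoids, and
indistinguishable from the independence null for instantaneous mixtures.

## Theta–gamma nesting

Steps in the published order: band-pass the ROI's 3×T current in theta
and gamma; per band one principal component over the *whole* recording
(not per window); Hilbert envelope of the gamma component; Pearson r in
1-s windows advanced by one window length (non-overlapping, consistent
with the n = 180 significance rationale; per-sample sliding available via
`hop=1`); percent of defined windows with r ≥ 0.15, one-sided inclusive.
Windows with zero variance in either input are flagged undefined and
excluded from the denominator. The eigenvector sign is fixed by making
the largest-|loading| positive, which makes the statistic deterministic;
the gamma sign never matters because only its envelope is used.

Known property, preserved deliberately: the 0.15 cut-off is justified by
n = 180 *windows*, but each windowed correlation uses ~128 highly
autocorrelated samples, so the per-window null exceedance of r ≥ 0.15 is
far above 5% (~25–30% in this generator). Validation therefore compares
planted-zero-coupling subjects against a Monte-Carlo independent-signal
null (cross-subject theta/envelope pairings), not against the nominal 5%.

The planted-coupling recovery region spans both planted sources (theta
carrier + modulated gamma). In a region whose theta content arrives only
through inverse leakage, the sign of the leaked component depends on the
head geometry; containing the theta source pins it positive through the
positive-semidefinite resolution block.

## Group statistics

Critical correlation: r_c = t_c/√(t_c² + n − 2) with t_c the two-sided
Student-t quantile; r_c(180, 0.05) = 0.1463 ≈ 0.15. Behavior
correlations are Pearson r with listwise deletion. The multiple-testing
correction is the max-statistic permutation test on |r| across all
source × band features jointly: the observed statistic joins the null
set, so p ≥ 1/(B+1) and corrected p dominates the univariate permutation
p permutation-by-permutation. The multivariate ROI ANOVA of the original
analysis is routine off-the-shelf statistics and is not re-implemented;
the report emits per-band ROI correlations with both loudness measures
instead.

## Problem sizes used in validation

Chosen as the package's own validation conditions: localization sweep on
a 64-source head (3 orientations per node); volume-conduction null with
200 epochs × (200 null + 100 mixed) replicates; nesting recovery at
modulation depths {0, .25, .5, .75, 1} × 20 seeds, 120-s subjects at
128 Hz on the 16-source head at 60 dB sensor SNR; cohort recovery with
n = 136 subjects × 100 seeds (behavior tables only — the correlation is
defined on the planted depth and needs no EEG); family-wise error on
200 replicates of 20-subject, 20-feature global nulls at 1000
permutations. The full suite and the acceptance script each run in well
under a minute of compute per component on a single CPU.

## Known limitations

Toy head models only (no MNI/Talairach template, no boundary-element
leadfield, no atlas ROIs); no directed connectivity; no
modulation-index-style coupling estimators beyond the published
correlation statistic; EDF is read (via mne) but not written — synthetic
cohorts are delimited text; patient-cohort effect sizes are not numeric
targets because the original EEG is not deposited, so the report mirrors
the analysis *structure* instead.
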