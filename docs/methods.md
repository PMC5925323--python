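# Methods

## Signal model and separation

An interleaved dual-echo pCASL series at voxel x, volume v (time
t_v = v·TR), echo e is modeled as

    S_e(x, v) = M0_x · (1 + g_e · b_x(t_v)) · (1 − w_v · d_x(t_v)) + physio + noise

where w_v is 1 for label volumes and 0 for controls,
d_x(t) = ΔM_x/M0_x · (1 + a_f · f_x(t)) is the fractional label/control
difference with its perfusion fluctuation f, b is the BOLD fluctuation
and g_e = TE_e/TE2 the echo-dependent BOLD gain (linear-in-TE: the short
echo carries 10/28 of the long echo's fractional BOLD amplitude — small
but deliberately nonzero). ΔM is obtained by inverting the
quantification model (below) at the voxel's slice post-label delay, so
the synthetic forward model and the analysis share one perfusion scale.

Writing w_v = (1 − cos π(n−1))/2, the perfusion term splits into a
baseband part −M0·d(t)/2 and a part modulated onto the alternation
carrier +M0·d(t)·cos[π(n−1)]/2. The separation recipe:

* **CBF channel** (short echo): high-pass > 1/(4·TR), multiply by
  cos[π(n−1)], sum non-overlapping pairs. Output ≈ control − label
  (positive for positive perfusion with the default control-first
  interleave; a label-first interleave flips the carrier sign so the
  convention is preserved).
* **BOLD channel** (long echo): low-pass < 1/(4·TR), pair mean (sum/2,
  keeping signal units and the DC level; the CBF channel keeps the raw
  pair sum so it equals control − label — correlations are scale
  invariant either way).

Both outputs have n/2 frames at dt = 2·TR. 1-based frame indexing in
the demodulation carrier means frame 1 gets +1.

**Filter realization.** All temporal filters are zero-phase
frequency-domain masks (no group delay, exact cutoffs). The high/low
split at 1/(4·TR) is an *ideal* (brick-wall) mask, with weight 1/2
assigned to a bin falling exactly on the cutoff so that the two channels
partition the spectrum exactly. The reason is quantitative: the
fluctuation band extends to 0.071 Hz while the cutoff is 0.0714 Hz, so
any smooth transition spanning even one frequency bin overlaps the top
of the band and leaks band-edge BOLD into the demodulated CBF channel at
the ~2×10⁻³ variance level, an order of magnitude above the crosstalk
this package guarantees (< 10⁻³, and in practice ~10⁻²⁸ on synthetic
runs, i.e. machine precision). The output band-pass (0.01–0.071 Hz,
zero-mean) keeps a one-bin raised-cosine transition, which behaves
better on non-periodic real data. The first and last separated frames
sit on the filter edges; they are flagged "non-interior" and excluded
from quantitative assertions but retained in outputs.

**Irreducible echo cross-leak.** Two contaminations are physical, not
filtering artifacts, and no temporal filter can remove them: the BOLD
pair-mean retains the baseband perfusion term −ΔM(1+a_f·f)/2 (the mean
label attenuation is itself slowly modulated), and the demodulated CBF
channel carries the multiplicative term ΔM·g₁·b (the labeled signal is
BOLD-weighted too). With the default amplitudes these leaks bias the
zero-lag correlation estimate by about −0.05 and +0.04 respectively
(partially cancelling, net ≈ −0.02 at r ≈ 0.24). The crosstalk bounds
above therefore refer to what filtering can and does suppress: in-band
BOLD against the demodulated channel (tested on a full run with zero
perfusion fluctuation) and the label/control *modulation component*
against the BOLD channel.

**RETROICOR-style physiological regression.** Cardiac and respiratory
phases are assigned per volume at the slice-mean acquisition time
(t_v + TR/2; slice-timing correction is out of scope), computed from the
100 Hz traces by peak detection with linear phase interpolation between
peaks. Sine/cosine terms up to order 2 per process (8 regressors, a
common convention) are removed by least squares from label and control
volumes separately, mean preserved. Note the cost at this protocol's
length: fitting 8 regressors to 45 frames per tag class removes real
in-band fluctuation variance (the respiratory fundamental and harmonic
alias to 0.014/0.029 Hz, inside the analysis band at TR 3.5 s) and
attenuates recovered coupling by ≈ 0.04 on synthetic runs. This is a
property of the method at this run length, not of the implementation;
the recovery experiments therefore run on physio-free data and the
regression is validated separately.

Generic nuisance regression (caller-supplied confound matrix,
pseudo-inverse for rank-deficient designs, intercept preserved) stands
in for anatomical-mask-based confound construction, which requires a
structural segmentation and is out of scope. Spatial smoothing is
per-volume Gaussian, σ = FWHM/(2√(2 ln 2)) per axis in voxel units,
nearest-boundary mode so constant volumes are preserved.

## Lagged coupling

Both separated series (interior frames) are upsampled to 0.1 s by
Fourier (sinc) interpolation — `scipy.signal.resample`, integer factor,
original samples preserved exactly. The lag grid is ±7 s in 0.35 s
steps. 0.35 s is 3.5 upsampled samples, so each nominal τ is evaluated
at the nearest integer sample shift (worst-case rounding 0.05 s, half a
sample, far below the 0.35 s recovery tolerance). At each lag the
Pearson correlation is computed over the truncated overlap of the two
series — no zero padding and no circular wrap, avoiding spurious edge
correlation. r₀ is the τ = 0 entry of the scan, which makes
r_max ≥ r₀ an exact identity (τ = 0 is a grid member); it agrees with
the direct frame-level Pearson correlation to ~10⁻³. Ties in the argmax
resolve toward the smallest |τ|, then the negative one — the most
conservative shift correction. Sign convention everywhere: τ (and the
generator's lag) < 0 means BOLD is delayed with respect to CBF, matching
the reporting convention for delayed BOLD responses. The scan is
computed for all lags at once via an FFT cross-correlation plus prefix
sums for the per-overlap means/variances; it equals the per-lag direct
computation to machine precision (asserted in tests).

Undefined (zero-variance) voxels propagate as NaN and are excluded from
group tests and from the FDR family. Fisher z = atanh(r) clamps |r| at
1 − 10⁻⁷ so noise-free voxels stay finite. Group inference: one-sample
t (dof n−1) per group on z maps; pooled-variance unpaired two-sample t
(dof n_A+n_B−2; Welch variant behind a flag) between groups; BH-FDR
(statsmodels step-up) within the analysis mask, α = 0.05. ROI summaries
average a map over `mask ∧ (gm ≥ 0.3)`. The r_max − r₀ contrast is an
unpaired t on per-subject differences with Cohen's d (pooled SD).

## Baseline perfusion quantification

Single-compartment model, all times in seconds, the 6000 factor
converting ml/g/s to ml/100g/min:

    CBF = 6000 λ (SI_C − SI_L) e^{PLD/T1a} / [2 α α_inv T1a M0 (1 − e^{−τ/T1a})]

Defaults: λ = 0.9 ml/g, T1a = 1.65 s, α = 0.85, α_inv = 0.83 (background
suppression enters only through this efficiency factor), τ = 1.75 s.
SI_C and SI_L are temporal means of the control and label volumes. The
post-label delay ramps linearly from 1.9 s at the lowest slice to 2.8 s
at the top slice of the ascending 2D acquisition (50 ms/slice at 19
slices; the linear ramp is the natural reading of a printed range for a
constant-readout acquisition). Voxels with M0 ≤ 0 are masked invalid and
zeroed. No partial-volume or arterial-transit-time correction is
applied. The generator inverts exactly this formula, so noise-free
forward/inverse agreement is exact by construction (observed ~10⁻¹³
relative, asserted at 10⁻⁶).

## QC metrics

RSFA is the temporal SD of the band-passed (0.01–0.071 Hz) series,
unnormalized — the value carries the input's units; since group
comparisons are like-for-like the normalization choice is neutral, and
it is configurable. DVARS is, per consecutive frame pair, the RMS over
mask voxels of the frame difference, plus the run average. Motion RMS
pools all six realignment parameters over all frames, rotations
converted to arc displacement on a 50 mm sphere (a common convention;
configurable); exclusion is strict (> 1.5 mm, so exactly 1.5 mm is
kept).

## Synthetic generator

Fluctuation processes are synthesized in the frequency domain: unit
magnitude at every Fourier bin inside the band (default 0.01–0.071 Hz),
uniform random phases, exact sample-SD normalization — giving exact band
containment and making Fourier-domain time shifts exact (the processes
are periodic and band-limited, so circular shifts are true time shifts
and the end-to-end lag experiments are free of wrap artifacts; real data
edges are handled by the truncated-overlap correlation instead). The
coupled BOLD process is r·ŝ(t+lag) + √(1−r²)·ε̂ with ŝ the unit-SD
shifted perfusion process and ε̂ an independent phase-randomized
surrogate of it (exactly spectrum-matched), so the population
correlation with the lag-aligned perfusion process equals the target.
Between-subject coupling spread is applied on the Fisher-z scale, which
keeps |r| ≤ 1.

Default amplitudes (chosen once from typical 3T resting-state values and
the cross-leak analysis above): BOLD fluctuation SD 1% of M0 at TE2,
perfusion fluctuation SD 10% of the mean label/control difference,
thermal noise SD 2×10⁻⁴·M0, physiological sinusoids (cardiac 1 Hz,
respiratory 0.3 Hz, sampled at each volume's slice-mean time so they
alias realistically at TR 3.5 s) at gain 2×10⁻³·M0 when enabled. The
noise level is deliberately low: the generator's role is ground-truth
recovery, so the injected coupling is the observation-scale target and
estimation must be dominated by the injected structure, not by thermal
noise. Cohort presets: `young-like` (coupling 0.24, SD 0.03, BOLD
delayed 0.5 s) and `elderly-like` (0.18, SD 0.04, delayed 1.8 s),
between-subject lag SD 0.3 s.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: arterial transit delay dispersion, explicit
background-suppression pulse timing (folded into α_inv), head motion,
tissue segmentation/partial volume, spatially structured physiological
noise, scanner drifts, and non-periodic signal edges. "90 dynamics" is
read as 90 volumes = 45 control/label pairs, which matches the 45
separated frames used throughout.

## Validation experiment sizes

Experiments run on scaled-down grids chosen so the full suite stays fast
while every stage runs at the protocol's temporal design (90 volumes,
TR 3.5 s): unit tests mostly 6×6×4; recovery/power/direction studies
6×6×4 with 200 subject replicates (recovery), 40 cohort replicates of
15 + 16 subjects (power), and 100 replicates of 8 + 8 subject cohort
pairs (lag direction); the FDR null simulation uses m = 10,000 voxels ×
500 replicates. The measured recovery at these conditions: mean
estimated r₀ ≈ 0.217 / 0.154 for injected 0.24 / 0.18 (the ≈ −0.025
bias decomposes into the echo cross-leak ≈ −0.018 and thermal-noise
attenuation ≈ −0.01). The recovery study injects its couplings at zero
lag so r₀ estimates the injected coupling directly; lag effects on r₀
are what the lag-direction study measures (a cohort pair differing only
in lag, −1.8 s vs −0.5 s, shows the larger r_max − r₀ in the
larger-lag group). Under the complete null the per-replicate BH-FDR is
binary (any rejection), so the 500-replicate empirical FDR estimates
α = 0.05 with SE ≈ 0.01.

## Known limitations

* The zero-lag coupling estimate is biased low by the irreducible echo
  cross-leak (≈ −0.02 at the default amplitudes); real analyses share
  this property and between-group comparisons are affected equally.
* RETROICOR at 45 frames per tag class costs ≈ 0.04 of recovered
  coupling (overfit of in-band aliased regressors); longer runs shrink
  this as 1/n.
* Lag estimates are grid-quantized (0.35 s) and, at low coupling, biased
  toward extreme lags by the maximum over 41 noisy correlations (the
  well-known r_max selection bias); r_max inherits a positive bias for
  the same reason. The r_max − r₀ contrast partially cancels it between
  groups.
* Volume-level physiological phase assignment ignores per-slice timing.
* The pipeline assumes spatially aligned inputs; motion and label/control
  coregistration are upstream concerns.
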