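# Methods

## The problem this package models

Rapid invisible frequency tagging (RIFT) modulates stimulus properties at
rates above the perceptual threshold (~50 Hz) — here the luminance of a
to-be-named picture at f2 = 68 Hz and the amplitude of a spoken
distractor word at f1 = 54 Hz. Each drive evokes a steady-state response
at its own frequency; if the two neural representations *interact*, a
nonlinear system additionally produces power at the intermodulation
frequencies f2 − f1 = 14 Hz and f2 + f1 = 122 Hz. The package simulates
EEG with exactly this structure and implements the analysis chain that
detects it: windowed power spectra, percent power change, spatial
cluster-based permutation tests, and a per-participant electrode-selection
contrast at 14 Hz.

## Generative model

One epoch is 1 s of baseline followed by 1 s of tagging, sampled at
1000 Hz on 31 scalp channels in a 10–20 layout. During tagging, channel
c receives

    x_c(t) = w_a(c)·A_a·sin(2π f1 t) + w_v(c)·A_v·sin(2π f2 t)
           + w_im(c)·g·[A_a·sin(2π f1 t)]·[A_v·sin(2π f2 t)] + noise

The multiplicative term is the minimal nonlinearity that produces
intermodulation: by the product-to-sum identity it equals
(g·A_a·A_v/2)·[cos(2π·14·t) − cos(2π·122·t)], so the 14 and 122 Hz bins
each carry power (g·A_a·A_v/4)² at a unit-weight channel and nothing else
changes. The gain g depends on the trial condition: g_related ≤
g_unrelated, the direction the statistics are meant to recover (a
*stronger* interaction between unrelated picture–word pairs).

Topographies are Gaussian bumps on the schematic electrode grid, scaled
to a maximum weight of 1: broad and central for the auditory response,
occipital for the visual response, left-frontal for the interaction. They
are configuration, not hard-coded; the defaults match the qualitative
scalp patterns the analysis is designed around.

Background activity in both windows is 1/f Gaussian noise (spectral
exponent 1, per-trace SD `noise_sd`, synthesized in the frequency domain
with an analytic variance normalization) plus a 10 Hz alpha sinusoid with
random phase per trial and an occipital topography. Alpha sits on the
analysis grid, so it does not leak into the 12–16 Hz bins used by the
validation analyses; it makes the low-frequency neighborhood realistic
without confounding the 14 Hz contrast.

Per participant, both source amplitudes are multiplied by an independent
log-normal jitter (σ = 0.4 by default), so some simulated participants
show conspicuous tagging peaks and others do not — mimicking the
inter-individual variability of tagging responses. All randomness flows
from one integer seed through `numpy.random.SeedSequence`; equal configs
give bit-identical datasets.

Defaults: 30 participants, 55 trials per condition, A_a = A_v = 1 µV,
g_related = 0.3, g_unrelated = 0.6, noise_sd = 1 µV, alpha_amp = 2 µV.
With these values the single-trial 14 Hz signal-to-background ratio is
near 0.5 (related) to 2 (unrelated) at the best channel — a detectable
but far from trivial contrast. The interaction gains are calibration
knobs of the simulation, not estimates of any empirical effect size.

## Spectral analysis

Power is computed per trial from the full 1 s analysis window under a
rectangular (boxcar) taper — i.e., the raw windowed segment is Fourier
transformed — and read out on a 1–80 Hz grid in 1 Hz steps, the native
resolution of a 1 s window. Bin power is |X_k/N|², so a unit-amplitude
on-grid sinusoid yields 0.25 (amplitude²/4); no one-sided doubling is
applied. This convention is fixed and asserted by tests. Trial averaging
is done on power, not on the complex spectrum, so components that are not
phase-locked across trials survive averaging. The default grid ends at
80 Hz; the 122 Hz sum component is reachable by passing `f_hi=150`.

Percent power change is ((tagging − baseline)/baseline)·100 per
participant, condition, channel and frequency. Zero baseline power in any
cell raises an error naming the cell rather than producing ±inf.

## Cluster-based permutation test

Electrode-wise paired t values (df = n−1) are thresholded at a two-tailed
cluster-forming p < 0.05; significant electrodes of the same sign that
are neighbors on the montage adjacency graph form clusters (minimum size
2 — isolated electrodes never form clusters), each scored by the sum of
its t values. The null distribution of the maximum |mass| is built by
flipping each participant's condition labels independently with
probability ½ (paired exchangeability) and re-running the whole map →
threshold → cluster chain; 5,000 permutations by default. Per-cluster
Monte Carlo p is (1 + #{null ≥ |mass|})/(1 + n_perm), compared against
α = 0.05 from the single combined two-tailed null. With
`exhaustive=True` all 2ⁿ flips are enumerated and the plain proportion is
reported, which is the exact p (the identity flip makes it valid without
the +1 correction).

Numerical conventions: zero-variance electrodes get t = ±inf (always
supra-threshold) when the mean difference is nonzero, t = 0 when it is
zero; clusters are sorted by |mass| descending and their electrodes
listed in montage order; permutation t maps are computed vectorized from
the flipped-sign algebra (flipping negates d_i and leaves Σd_i²
unchanged).

## Electrode selection at the intermodulation frequency

Per participant: rank electrodes by percent change at the target
frequency with the two conditions averaged first (so selection cannot
favor either condition), take the top k = 6 (ties broken by montage
order), and reduce to the largest connected component of the induced
subgraph (size ties go to the component holding the largest value, then
montage order; singletons are allowed at this stage). The participant's
statistic is the mean percent change over that cluster per condition; the
group test is a two-tailed paired t (related − unrelated) with signed
Cohen's d = mean(diff)/sd(diff). Two validations re-run the identical
procedure (a) at 12/13/15/16 Hz — the group-mean selected percent change
should peak at 14 Hz — and (b) at 54/68 Hz, where the selected-electrode
histograms should concentrate on the corresponding tag topographies.

## Preprocessing

Simulated data contain no line noise or drifts, so filtering is off by
default in the pipeline and provided as an explicit stage: a zero-phase
4th-order Butterworth band-pass (0.1–100 Hz) plus 2nd-order Butterworth
band-stops of 3 Hz total width at 50/100/150 Hz, all applied
forward–backward with full-epoch padding (the 0.1 Hz edge has a settling
time comparable to the 2 s epoch, so default padding would leave large
transients). The chain attenuates a 50 Hz tone by ≥ 20 dB in RMS while
keeping a 54 Hz tone within ~7% and a 68 Hz tone within ~4% of its input
RMS. Re-referencing subtracts the mean of named reference channels.
Interpolation replaces a bad channel by the equal-weighted mean of its
graph neighbors — the simplest auditable weighting; spherical-spline
weights are out of scope.

## Pipeline and gating

`run_pipeline` computes spectra once and reuses them across all
frequencies (an in-run cache; a disk cache keyed by config hash was
considered and dropped as needless statefulness at these problem sizes).
Condition contrasts are gated: the related-vs-unrelated comparison at a
frequency is run only if the tagging-vs-baseline test at that frequency
is significant — at the base frequencies as a cluster test on percent
change, at 14 Hz through the selection procedure. Reports are
JSON/TSV with no timestamps, so a re-run with the same config and seed is
byte-identical.

## Validation studies and problem sizes

* **Type-I calibration**: 200 datasets with g_related = g_unrelated
  (nothing to detect), 10 participants × 20 trials per condition, 500
  permutations each; the fraction of datasets with any significant
  14 Hz condition cluster should lie in the 95% binomial band around the
  nominal 0.05 ([0.02, 0.09] for 200 draws). Trial count does not enter
  the validity of the participant-level permutation test, so a small
  count keeps the study fast without weakening the check.
* **Parameter recovery**: 100 runs at 12 participants × 20 trials per
  condition with the default gains; a detection requires p < 0.05 *and*
  the correct sign (related < unrelated). The detection rate must exceed
  ½, and a 30-run-per-point curve over gain gaps 0/0.15/0.3 (same seeds
  across gaps, so the comparison is paired) must be nondecreasing.
* **Qualitative pattern**: one default 30-participant run must show
  significant 54/68/14 Hz tagging-vs-baseline clusters, no significant
  base-frequency condition clusters, a significant negative 14 Hz
  selection contrast, and a 14 Hz peak exceeding its neighbors.

## What the simulation does and does not show

The generator reproduces the *statistical structure* the analysis
assumes: phase-locked narrowband drives, a quadratic interaction with
condition-dependent gain, 1/f-plus-alpha background, spatial smoothness
via topographies, and participant heterogeneity. It omits much of real
EEG: artifacts (blinks, muscle, electrode pops), non-stationary and
spatially correlated noise, latency/phase jitter of the driven responses,
volume-conduction mixing beyond the configured topographies, and any
model of lexical or semantic processing. Passing tests therefore
demonstrate that the analysis chain is correctly implemented and
statistically calibrated under its own assumptions — not that those
assumptions hold for any particular recording.

## Known limitations

* The adjacency graph comes from a schematic 2-D grid, not digitized
  electrode positions; it is a faithful neighborhood structure but not a
  measured one.
* The epoch container is a single documented HDF5 layout; no EDF+ export.
* The cluster test evaluates one frequency at a time (no spatio-spectral
  clustering), and only cluster *mass* is supported as the statistic.
* The two-tailed convention (single max-|mass| null, per-cluster p vs α)
  is one of several defensible choices; it is stated rather than
  configurable.
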