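# Methods

This note records the models behind `spadvi`, the defaults that matter,
and the numerical choices made where the design was genuinely open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Forward model

**Membrane dynamics.** Cells are passive single compartments: a current
step `I` relaxes the potential exponentially from its value at step onset
toward `V_rest + I·R` with the membrane time constant τ. Defaults
`R = 100 MΩ`, `τ = 15 ms`, `V_rest = −70 mV` are typical cortical/
hippocampal values. Voltage-clamp commands are followed with a fixed 1 ms
settling constant (clean command steps; electrode artifacts are not
modeled). The default step protocol is 100 ms baseline, −200…200 pA in
100 pA increments, 100 ms per step. Each step is followed by a 70 ms
recovery at rest: the standard measurement windows (120–180, 290–350,
460–520, 630–690, 800–860 ms) imply step onsets every 170 ms, so
back-to-back 100 ms steps cannot be what those windows measure;
`inter_step_s=0` restores gapless steps when wanted. The 460–520 ms
window belongs to the voltage-step scheme only — in current clamp it sits
on the 0 pA level, which contributes no (ΔV, ΔF/F) point.

**Action potentials** are stereotyped templates (1 ms linear rise,
1.5 ms exponential decay truncated at 5 constants, +80 mV peak), stamped
with their peak at each stimulus-pulse onset. This matches the
~millisecond AP duration the analysis must resolve without pretending to
conductance-based realism (a stated non-goal). Trains whose waveforms
would overlap at the requested frequency are rejected.

**Ensembles.** Common burst onsets are a Poisson process (default
0.5 Hz); within a burst all cells share template spike times (5 spikes,
12 ms apart) plus independent Gaussian jitter (default SD 1 ms), on top
of independent background spiking (1 Hz). Subthreshold activity is a
shared burst-locked envelope — one double-exponential bump per burst
(20 ms rise, 200 ms decay, 10 mV) — plus private Gaussian noise
(0.5 mV). These rates are package defaults, exposed as config: no
quantitative burst statistics were available to emulate, only the
qualitative structure (millisecond-scale synchrony, strongly correlated
subthreshold depolarizations). All randomness derives from one seed via
`SeedSequence.spawn` in a fixed order, so replay is bit-identical.

**Indicator and camera.** Fluorescence is linear in voltage,
`F_rel = 1 + c·(V − V_rest)`, filtered by first-order indicator kinetics
(default τ_ind = 0.5 ms, a fast Voltron-like value; identity when 0) and
floored at a small ε if a pathological coupling drives it non-positive.
The default coupling magnitude is 0.002 /mV. The per-pixel expected
photon count per exposure is

    λ(x,t) = η · B · w(x) · F_rel(t) · T_exp + DCR · T_exp

with detection efficiency η, baseline brightness B, footprint weight
w(x), exposure T_exp = 1/9938.4 s, and dark-count rate DCR (default
50 cps/pixel, typical for an 8 µm-pitch SPAD at room temperature). Each
pixel of each plane is then an independent Bernoulli draw with
`p = 1 − e^(−λ)`. A global shutter is assumed (rolling-shutter skew is
far below analysis timescales) and fluorescence is sample-and-held from
the voltage grid at each exposure start; the voltage grid must be at
least as fast as the sensor.

**Footprint and photon budget.** The default footprint is a soma of
radius 25 px with a 4 px membrane annulus (weight 1.0) and dim interior
(0.3), centered in a 64×64 crop — a ~10 µm soma imaged at 40× with 8 µm
pixels. Simulating a crop rather than the full 320×240 array changes
nothing downstream (ROI statistics involve only ROI pixels) and keeps
problem sizes small. Budgets are stated as expected ROI-summed photons
per plane: 300 for subthreshold step experiments and 1200 for spike
experiments. The step budget fixes per-annulus-pixel occupancy near 0.26,
low enough that binary-pixel saturation costs only ~10% of sensitivity;
the spike budget was chosen so single-AP SNR lands near the published
single-indicator range (~7–9 after the full chain), which is also what
reliable 10/10 detection at 100 Hz requires.

## Inverse chain

**Corrections.** For images, occupancy `p̂ = sum/n` is inverted through
the binary pixel's saturating response, `λ̂ = −ln(1 − p̂)`, then the
expected dark term is subtracted and the result clipped at 0; fully
saturated pixels are capped at `−ln(1/(2n))` to keep statistics finite.
For traces, only the logarithmic response is corrected, at the aggregate
ROI level: `counts′ = −M·ln(1 − counts/M)` for an M-pixel ROI. The
aggregate form is not the sum of per-pixel inversions when pixels differ
in brightness; it mildly under-corrects, which attenuates ΔF/F slightly
but leaves linearity essentially intact at the default occupancies.

**Filtering and binning.** All filters are zero-phase 4th-order
Butterworth (forward–backward `sosfiltfilt`): the filter family is a
free choice and spike timing matters, so phase preservation wins. Traces
are low-passed at 2 kHz at the native rate, then binned by non-overlapping
means (remainder samples dropped): ~100 Hz effective for subthreshold
analysis, ~1 kHz for spikes. The spike band is the 2 kHz-filtered trace
minus its own 10 Hz low-pass — a high-pass by subtraction that removes
subthreshold events and drift while preserving spike amplitude; a literal
10 Hz low-pass output is available as an option (`mode="lowpass"`), since
the conventional description of this step is ambiguous. Detrending
subtracts the OLS straight line. When the indicator coupling is negative,
a polarity flag inverts traces so depolarization is positive-going before
metrics and detection.

**Step metrics.** Baseline F is the mean over the first 100 ms; each
response window contributes `ΔF = mean(window) − F`, `ΔF/F = ΔF/F`,
`SNR = ΔF/SD(baseline)`, with SD taken on the binned analysis-rate trace
(the rate at which SNR is quoted matters and is fixed here as
"after binning"). Windows map to samples half-open `[start, end)` at the
effective rate, 0-based. The F–V relation is summarized by regression
through the origin, `slope = Σxy/Σx²`, with the uncentered
`R² = 1 − Σ(y−ŷ)²/Σy²` — the standard convention for forced-origin fits.

**τ fits.** `y(t) = A + B·e^(−t/τ)` is fit by least squares to the
100 ms after each step onset, initialized from the endpoints (A from the
last sample, B from first−last, τ from the time to 63% of range), with τ
bounded to (0.1 ms, 1 s); non-convergent or out-of-range fits return a
failure result rather than raising. Electrical fits use the native-rate
trace; optical fits use the 1 kHz binned trace, because a ~15 ms constant
is not identifiable from ten 100 Hz samples. At the 300 photons/plane
budget a single per-step optical fit is noisy (tens of percent), so the
modality comparison normalizes each post-onset deflection by its
ground-truth ΔV, averages all deflections of a batch (the simulated
cells share one membrane model), and fits once per modality.

**Spike detection.** On the positive-going spike band: baseline is a
rolling median over `window_samples` (default 51 at 1 kHz); the noise
scale is a robust SD estimated from the negative residual side only
(`median(−resid⁻)/0.6745`), which dense spiking cannot inflate — a
rolling or two-sided MAD collapses at the ~30% spike duty cycle a 100 Hz
train produces. Residual local maxima must exceed both
`sd_threshold × noise` (default 4) and an absolute floor; of any pair
closer than the refractory gap (default 5 ms — the zero-phase-filtered AP
waveform has a secondary peak at +3–4 ms) the larger survives, and peaks
within half a window of the trace edges are discarded (filter
transients). Detected/truth matching is greedy nearest-first one-to-one
within ±2 ms.

**Synchrony statistics.** PSTHs count target spikes in half-open bins
around each reference spike, summed over reference spikes (the "sum"
convention, taken literally). Bin edges sit at integer multiples of the
bin width with zero lag at an edge, so exact coincidences and
integer-bin shifts land in a single bin; for an odd bin count the window
is asymmetric by one bin. The shuffle null redraws both trains' spike
times uniformly (counts preserved; ISI permutation available), recomputes
the PSTH 100 times, and reports the per-bin mean and 5–95% envelope.
Subthreshold cross-correlation z-scores both traces and uses the biased
1/n normalization so autocorrelation at lag 0 equals 1; per-epoch curves
are averaged. Its null re-pairs traces from independent sources (default
100 pairs).

## What the simulations do and do not show

The generator reproduces the photon statistics (independent Bernoulli
pixels with `p = 1 − e^(−λ)`, dark counts), linear GEVI coupling with
first-order kinetics, and protocol/ensemble timing structure. It omits
motion, optical blur and crosstalk, afterpulsing, indicator bleaching and
nonlinearity, rolling-shutter skew, and biological variability in R, τ
and spike shape (cells in a batch are identical by construction). Passing
tests therefore validate the analysis chain against its own stated noise
model — shot-noise-limited binary imaging — not against every artifact of
real recordings.

Two consequences worth knowing. First, at the 300 photons/plane
subthreshold budget the 9-cell mean forced-origin R² has expectation
≈ 0.99 with a per-batch SE of ≈ 0.002, so individual batches scatter on
both sides of 0.990; this is the photon-budget-limited precision of the
statistic itself, not an implementation artifact (even a saturation-free,
dark-free sensor at the same budget behaves the same). Second, the
recovered F–V slope is the programmed coupling attenuated by ~10%
(measurement windows sample the response before full settling;
saturation; dark dilution) — the same attenuations a real recording
carries, and irrelevant to R².

## Problem sizes

Tests and the acceptance script simulate 64×64-pixel crops at 9938.4 Hz
for ≈1 s per cell (≈9,400 planes), batches of 9 cells, 10-second
ensembles, and 100-shuffle nulls; these sizes give each statistic enough
precision for its stated tolerance while keeping full runs in the
minutes range on one CPU.
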