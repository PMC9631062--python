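# spadvi — single-photon binary-frame voltage imaging

`spadvi` is a simulation and analysis toolkit for voltage imaging with
single-photon avalanche diode (SPAD) array sensors. A SPAD array running in
binary mode emits ~10,000 one-bit frames ("bit planes") per second: each
pixel reports 1 if at least one photon (or dark event) arrived during the
~100 µs exposure, and 0 otherwise. Genetically encoded voltage indicators
(GEVIs) such as Voltron couple membrane potential linearly into fluorescence
with millisecond kinetics, so a shot-noise-limited binary photon stream at
kilohertz rates can resolve both subthreshold membrane dynamics and single
action potentials — provided the bit planes are corrected, filtered and
binned correctly.

The package is written for people analyzing (or planning) such recordings:
it contains the complete inverse analysis chain, and a forward simulator
that generates bit planes with exactly the photon statistics the analysis
assumes, so every stage can be validated against ground truth without any
real recording.

## What is implemented

**Forward model** (`spadvi.neuron`, `spadvi.camera`)

- passive membrane responses to current/voltage step protocols
  (V relaxes toward `V_rest + I·R` with time constant τ), stereotyped
  ~1–2 ms action potentials evoked by pulse trains, and multi-cell bursting
  ensembles with millisecond-scale spike synchrony and a shared
  subthreshold depolarization envelope;
- linear GEVI coupling `F_rel = 1 + c·ΔV` with first-order indicator
  kinetics, a membrane-annulus cell footprint, and per-pixel Bernoulli
  sampling with `p = 1 − e^(−λ)` (Poisson photons plus dark counts).

**Inverse chain** (`spadvi.bitplane`, `spadvi.pipeline`, `spadvi.metrics`,
`spadvi.spikes`)

- a packed-bit `.spb` container (lossless, byte-exact) plus multipage TIFF
  interchange; image composition and the binary pixel's logarithmic-response
  correction `λ̂ = −ln(1 − p̂)` with dark-count subtraction;
- ROI trace extraction, trace-level log correction
  `−M·ln(1 − counts/M)`, zero-phase 4th-order Butterworth filtering,
  temporal binning (effective rate = native rate / N), linear detrending,
  and spike-band isolation (10 Hz high-pass by subtraction, 1 kHz binning);
- ΔF/F and SNR per step window (baseline = first 100 ms), forced-origin
  F–V regression with uncentered R², single-exponential τ fits, per-spike
  ΔF/F and SNR;
- a three-parameter spike detector (rolling-median baseline, robust noise
  scale, amplitude floor, refractory pruning), ground-truth scoring,
  PSTHs (50 ms/2 ms and 1 s/100 ms) with 100-shuffle spike-time nulls, and
  normalized subthreshold cross-correlations with cross-cell null bands.

`spadvi.workbench` wires whole experiments together from a serializable
config; the `spadvi` CLI and the numbered drivers under `analysis/` are thin
shells over it.

## Worked example

Simulate nine cells under the standard current-clamp protocol (100 ms
baseline, −200…200 pA in 100 pA steps, 100 ms per step), image them at
9938.4 Hz with a 300 photons/plane ROI budget, and regress ΔF/F on ΔV:

```sh
python analysis/01_subthreshold_linearity.py --seed 0
```

prints, per cell, the forced-origin slope and R², ending with

```
mean R^2 over 9 cells: 0.9895 +- 0.0025 (SEM)
mean slope: 0.00181 per mV (true coupling 0.00200, attenuated by
windowing, saturation and dark counts)
```

i.e. the optical readout is linear in membrane potential at this photon
budget (R² ≈ 0.99), and the recovered sensitivity is the programmed
coupling attenuated by the measurement-window timing, binary-pixel
saturation and dark counts — exactly the attenuations a real recording
suffers. The other drivers show the shot-noise side of the method:

```sh
python analysis/02_binning_tradeoffs.py   # SD ~ N^-0.5; dF/F stable, SNR grows
python analysis/03_spike_trains.py        # 10/10 spikes at 25 & 100 Hz, 0 FP
python analysis/04_ensemble_synchrony.py  # zero-lag PSTH & xcorr above nulls
```

For one-off runs there is also a CLI, e.g.

```sh
spadvi simulate --kind ensemble --seed 4 --out runs/ens
spadvi run --config my_experiment.yaml --seed 7 --out runs/exp
```

## Layout

```
src/spadvi/     library (simulation, I/O, pipeline, metrics, synchrony)
analysis/       numbered narrative drivers writing tables to results/
scripts/        acceptance script
tests/          pytest suite (unit, property and acceptance tests)
docs/methods.md model assumptions, defaults, and numerical choices
```
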