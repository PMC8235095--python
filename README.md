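# magtremor

Simulation and analysis toolkit for a coil-array magnetic positioning
system aimed at movement-disorder monitoring. The package models a
24-receiver magnetic tracker end to end — dipole-field forward model,
noisy voltage frames, Nelder–Mead pose inversion — and runs three
diagnostic analyses on the tracked signals: action-tremor spectroscopy,
stop-movement spectrogram change detection, and finger-tapping feature
extraction with k-NN classification.

## The system in one paragraph

A small transmitter coil (182 kHz, modeled as a magnetic dipole) is worn on
the limb; 24 fixed receiver coils around a 30 cm tracking volume measure
the RMS voltage the dipole induces in each of them. A frame of 24 voltage
magnitudes is inverted to the transmitter's pose — 3-D position plus
orientation unit vector (up to sign, since magnitudes discard phase) — by
least-squares minimization with Nelder–Mead at 62 poses/s. The tracked
coordinates then feed standard movement analyses: a high-pass + DFT chain
that reads off tremor frequency, a moving-window spectrogram that locates
the moment a movement regime changes, and a tapping pipeline (spectral band
integrals, an SVD periodicity measure, amplitude-rate scores) feeding a
k-nearest-neighbor classifier. Everything runs on synthetic data: ground
truth is generated, pushed through the physics, inverted, and analyzed.
See `docs/methods.md` for the model and all numerical choices.

## Worked example

Simulate a bradykinetic tapping take, extract features, and inspect them:

```bash
magtremor simulate tapping --out take.csv --condition disease --seed 7
magtremor ft-features --in take.csv --out feats.json
cat feats.json
```

```json
{
 "amxfr": 2.120598575903488,
 "ftts": 0.7006041446844972,
 "int1_4": 56.38131384154225,
 "int4_12": 24.637175920538038,
 "low_vel_frac": 0.49191685912240185,
 "n_periods": 12,
 "pm": 0.930380371205334
}
```

More than half of the spectral weight sits in the 1–4 Hz band (slowed,
irregular taps) and the periodicity measure is depressed. A healthy take
concentrates its weight in 4–12 Hz and scores PM ≈ 0.99. On the default
synthetic cohort (17 healthy + 20 disease takes, seed 1), 5-fold k-NN
separates the conditions perfectly:

```python
>>> from magtremor.experiments import run_tapping_experiment
>>> run_tapping_experiment(seed=1)
{'n_nodisease': 17, 'n_disease': 20,
 'acc_int14_int412': 100.0, 'acc_int14_ftts': 100.0,
 'acc_int412_ftts': 100.0, 'acc_all3': 100.0,
 'mean_pm_nodisease': 0.9933, 'mean_pm_disease': 0.9383}
```

The full tracking chain, library-side:

```python
from magtremor import (add_tremor, default_array, dft_spectrum,
                       dominant_frequency, highpass, square_trajectory,
                       trajectory_to_frames, track, TremorSpec, SampledSignal)

truth = add_tremor(square_trajectory(), TremorSpec(frequency=10.0))
array = default_array()
frames = trajectory_to_frames(truth, array, snr_db=20, seed=1)
est = track(frames, array, init=truth.poses[0])          # ~30 s for 930 frames
x = SampledSignal(values=est.coordinate("x"), rate=est.rate)
spec = dft_spectrum(highpass(x, 2.5))
print(dominant_frequency(spec, (2.5, 31.0)))             # -> 10.0
```

## Reproduction

`scripts/acceptance.py` recomputes the seven benchmark quantities from
scratch (tremor line, stop-movement phase frequencies and change time,
periodicity-measure analytic value, static pose accuracy):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Runtime is about 4 minutes on one CPU; with seed 1 it reports
t1 = 10.0 Hz, t2 = 2.0 Hz, t3 = 5.09 Hz (bin nearest 5), t4 = 3.19 s,
t5 = 1.0, t6 = 5.27 mm, t7 = 2.71°.

## Layout

| Path | Contents |
| --- | --- |
| `src/magtremor/coils.py` | dipole field, induced voltage, array geometry, noise |
| `src/magtremor/estimator.py` | cost function, Nelder–Mead inversion, multi-start, tracking |
| `src/magtremor/simulate.py` | trajectory and tapping generators |
| `src/magtremor/spectral.py` | high-pass, DFT, spectrogram, change detection |
| `src/magtremor/tapping.py` | band integrals, periodicity measure, tap scores |
| `src/magtremor/classify.py` | k-NN cross-validation |
| `src/magtremor/io.py`, `cli.py` | CSV/JSON formats and the `magtremor` CLI |
| `src/magtremor/experiments.py` | end-to-end experiment runners |
| `docs/methods.md` | model, parameters, design rationale |
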