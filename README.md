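# rifteeg

Synthetic rapid-invisible-frequency-tagging (RIFT) EEG and the statistics
that detect audiovisual interaction in it.

## What this is for

In a RIFT experiment, a visual stimulus flickers imperceptibly at f2
(here 68 Hz, via luminance modulation) while an auditory stimulus is
amplitude-modulated at f1 (54 Hz). Each drive evokes a steady-state
response at its own frequency, and — crucially — if the two neural
representations interact, the nonlinearity of that interaction creates
power at the intermodulation frequencies f2 ± f1 (14 and 122 Hz). The
scientific question is then carried by the 14 Hz line: does its strength
differ between experimental conditions (e.g., semantically related vs
unrelated picture–word pairs)?

`rifteeg` is for methodologists and students of this paradigm. It
provides a generative model of such recordings with a controllable,
condition-dependent interaction gain, plus a complete, tested
implementation of the analysis chain:

* boxcar-taper power spectra (1–80 Hz, 1 Hz steps) for the 1 s baseline
  and tagging windows, and the percent power change
  ((Pow_tagging − Pow_baseline)/Pow_baseline)·100;
* two-tailed nonparametric **cluster-based permutation tests** over
  electrodes: paired t per electrode, clusters of ≥ 2 neighboring
  same-sign significant electrodes scored by summed t (cluster mass),
  max-|mass| null from paired label flips, Monte Carlo
  p = (1 + #{null ≥ |mass|})/(1 + n_perm);
* the **per-participant electrode selection** at 14 Hz: each
  participant's top-6 electrodes by condition-averaged percent change,
  reduced to their largest neighboring cluster, then a group paired t
  with Cohen's d on the cluster-mean percent change, plus validations at
  neighboring (12/13/15/16 Hz) and base (54/68 Hz) frequencies;
* an end-to-end pipeline that enforces the gating rule (condition
  contrasts only where the tagging response beats baseline) and writes
  reproducible JSON/TSV reports.

Because the data are simulated, every claim the statistics make can be
checked against generative ground truth; the test suite does exactly
that, including a type-I-error calibration of the permutation test and a
power/monotonicity study of the selection contrast.

## Worked example

```bash
python examples/01_tags_and_spectrum.py
```

```
projector frame rate: 1440 Hz
intermodulation: {'difference': 14.0, 'sum': 122.0}
luminance tag: 1000 samples in [0.0, 1.0]
   54 Hz: 0.250000 uV^2 (peak channel Cz)
   68 Hz: 0.250000 uV^2 (peak channel Oz)
   14 Hz: 0.015625 uV^2 (peak channel FC5)
  122 Hz: 0.015625 uV^2 (peak channel FC5)
```

The two tags carry amplitude²/4 = 0.25 µV² at their own bins; the 14 and
122 Hz lines hold (g·A_a·A_v/4)² = 0.015625 µV² each — power that exists
*only* because the simulated cortex multiplied the two drives (gain
g = 0.5 here). Nothing else in the spectrum is nonzero in this noiseless
run.

```bash
python examples/03_electrode_selection.py
```

```
t(11) = -3.93, p = 0.0023, d = -1.14
sub-01 selected cluster: F7, F3, FC5, FC1, C3, Cz
```

The negative t recovers the generative ground truth: the unrelated
condition was simulated with the larger interaction gain, so its 14 Hz
percent power change is higher. The selected cluster sits on the
left-frontal channels where the interaction topography was placed.

The remaining examples run the cluster permutation test at 68 Hz
(`02_cluster_permutation_test.py`) and the full gated pipeline
(`04_full_pipeline.py`). The same pipeline is scriptable from the shell:

```bash
rift run-all --config examples/run_config.yaml --seed 42 --out out/
```

## Layout

```
src/rifteeg/
  montage.py     31-channel 10-20 montage + adjacency graph
  simulate.py    tag waveforms, generative model, datasets
  io.py          HDF5 epochs, YAML configs, JSON montages
  preprocess.py  zero-phase band-pass/notch, re-reference, interpolation
  spectral.py    boxcar power spectra, percent change, f2±f1
  cluster.py     cluster-based permutation test
  selection.py   electrode selection, group contrast, validations
  experiments.py calibration and detection-rate studies
  pipeline.py    gated end-to-end run with reports
  cli.py         `rift` command group
```

See `docs/methods.md` for the model, conventions and limitations.
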