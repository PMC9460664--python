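# eegscrub

Single-channel EEG artifact removal. One contaminated channel is decomposed
into narrow-band modes with **variational mode decomposition (VMD)**, the
mode matrix is blind-separated with **second-order blind identification
(SOBI)**, each separated component is scored with **fuzzy entropy**, the
components identified as EOG (ocular) and EMG (muscular) artifacts are
zeroed, and the retained components are back-projected and summed into a
cleaned signal. A mode-count selector picks the number of modes K
automatically from the stability of center frequencies between consecutive
decompositions (the *invalid-center-frequency* rule), and a seeded
semi-simulation generator builds contaminated test records at any target
SNR so the whole chain is testable offline.

## Library quick start

```python
import numpy as np
from eegscrub import (SimConfig, semi_simulate, run_pipeline, compute_metrics,
                      VmdConfig, fixed_centers_hz)

sim = semi_simulate(SimConfig(seed=7, snr_db=-1.0))        # 8 s at 250 Hz
cfg = VmdConfig(alpha=500, init_centers=fixed_centers_hz((5, 30, 150), 250))
result = run_pipeline(sim.mixture, vmd_cfg=cfg)            # or auto_k=True
print(result.labeling.labels)                              # e.g. EOG/EEG/EMG
print(compute_metrics(sim.eeg, result.cleaned))            # SNR, RRMSE, CC
```

Key entry points:

- `vmd_decompose(signal, VmdConfig)` / `reconstruct(modes)` — ADMM
  frequency-domain decomposition into K band-limited modes with
  center-frequency tracking (`K`, `alpha`, `gamma`, `epsilon`, init scheme
  `zeros | random | fixed`, iteration cap).
- `sobi_separate(data, SobiConfig)` — whitening, time-lagged covariances,
  joint approximate diagonalization by Givens sweeps; also exposed as
  `whiten`, `lagged_covariances`, `joint_diagonalize`.
- `fuzzy_entropy(x, FeConfig)` — similarity-based complexity score
  (embedding dimension `m`, membership gradient `n`, tolerance `r`).
- `select_k(signal, base_cfg, k_range)` — mode-count selection with a full
  trace (center-frequency table, judgment-accuracy table, invalid flags).
- `run_pipeline(...)` — the full chain; `label_components` supports an
  extremes policy (min entropy → EOG, max → EMG, with a spectral sanity
  veto) and a two-threshold policy for other component counts.
- `semi_simulate(SimConfig)` / `snr_sweep(...)` — reproducible fixtures
  `X = X_eeg + theta * X_artifact` with EOG (0–5 Hz), EEG (10–50 Hz) and
  EMG (80 Hz–Nyquist) surrogates, theta solved for the requested SNR.

## Command line

```bash
eegscrub simulate --seed 7 --snr -1 --duration 8 --out sim/
eegscrub clean --input sim/mixture.csv --fs 250 --k auto --alpha 500 \
    --reference sim/eeg.csv --out cleaned.csv --report report.json
eegscrub vmd --input sim/mixture.csv --fs 250 --k 3 --out modes.csv --sidecar modes.json
eegscrub sobi --input modes.csv --fs 250 --out sources.csv --matrices mat.json
eegscrub fe --input sources.csv   # single-column input: prints fuzzy entropy
eegscrub kselect --input sim/mixture.csv --fs 250 --init zeros --json-out trace.json
```

`clean --report` writes entropy scores, labels, center frequencies,
resolved configuration, and (when `--reference` is given) SNR/RRMSE/CC of
both the contaminated and cleaned signal. All flags can also be supplied
through `--config config.yaml`.

## Signal conventions

Center frequencies are normalized (cycles/sample, `[0, 0.5)`); multiply by
the sampling rate for Hz. Spectral updates run on the non-negative
half-spectrum with even mirror extension of half the signal length at each
end (cropped after inversion). Signals are single-column CSV files; modes
and sources are multi-column CSV (`imf1..imfK`, `ic1..icm`).
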