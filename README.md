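# nmrphaser

Automated zeroth- and first-order phase correction for 1D solution NMR
spectra.

After Fourier transformation, an NMR spectrum is only quantitatively usable
in pure absorption mode, which requires correcting the phase of every
complex point:

```
S_k  ->  S_k * exp(i * (PH0 + PH1 * k/(N-1)) * pi/180),     k = 0 .. N-1
```

where `PH0` (degrees) is the frequency-independent zeroth-order phase and
`PH1` is the total first-order phase change across the spectral width.
Classical automated phasers (integral criteria, entropy minimization,
baseline flatness) typically leave residual errors of several degrees,
which still distort peak shapes and volumes; experts fix these by eye.
`nmrphaser` automates that last step with a tandem pair of classifiers —
a 1D CNN front end feeding a vision transformer with relative positional
bias and global average pooling — trained to answer one deliberately simple
question each: *is the remaining PH0 (resp. PH1) error negative, zero, or
positive?*  An iterative loop then corrects the spectrum until both
networks answer "zero" and a finite-difference refinement of the two
"no-error" scores polishes the result below a 0.3° search step.

The package is aimed at NMR spectroscopists and metabolomics/proteomics
pipeline builders who need unattended, reproducible phasing of 1D spectra
(Bruker fid/acqus directories or JCAMP-DX files), and at anyone who wants a
self-contained, dependency-light reference implementation of this family of
methods: the entire neural stack (conv, attention, Adam, backprop) is plain
NumPy.

## What is in the box

| module | role |
| --- | --- |
| `nmrphaser.spectrum` | complex spectrum / FID model, phase application, FID processing |
| `nmrphaser.synth` | synthetic training spectra: Voigt lineshapes, peak-list augmentation, baseline, noise, labeled phase errors |
| `nmrphaser.entropy` | coarse autophasing: derivative-entropy objective + 2D grid search |
| `nmrphaser.nn` | the CNN + transformer classifier pair, training loop, checkpoints |
| `nmrphaser.phaser` | full workflow: coarse phase -> classifier loop -> gradient refinement |
| `nmrphaser.io` | Bruker 1D and JCAMP-DX readers/writers, dataset containers |
| `nmrphaser.cli` | `nmrphaser simulate / train / phase / eval / surface` |

## Worked example

Synthesize a dense 4096-point test spectrum, spoil its phase, and recover
it with the classical entropy stage:

```python
import numpy as np
from nmrphaser import (PhasePair, apply_phase, fixture_peaklists,
                       grid_search, synthesize_spectrum)

peaks = fixture_peaklists(1, np.random.default_rng(3), axis_len=4096)[0]
spec  = synthesize_spectrum(peaks, 4096)          # perfectly phased
wrong = apply_phase(spec, PhasePair(48.0, -95.0)) # inject a known error

result = grid_search(wrong)                       # -180..180, 10 deg steps
print(result.best_phase)
```

```
PhasePair(ph0=-50.0, ph1=100.0)
```

The grid search recommends `(-50, +100)` against the injected `(+48, -95)`
— a residual of (2.0, 5.0) degrees, i.e. within the coarse stage's 10°
design target but clearly visible in a zoomed-in plot.  The tandem
classifier stage removes that residual: train the two networks (minutes on
one CPU at the scaled-down size) and run the full workflow:

```bash
nmrphaser train --task ph0 --seed 7 --out ph0.npz
nmrphaser train --task ph1 --seed 7 --out ph1.npz
nmrphaser phase --input spec.dx --ph0-model ph0.npz --ph1-model ph1.npz \
                --out phased.dx --trace trace.json
```

```
applied correction PH0=-47.811 PH1=+94.630 deg
```

leaving a sub-degree residual; `trace.json` records every applied step with
both classifiers' probabilities.

## Acceptance script

`scripts/acceptance.py` regenerates the package's headline numbers from
scratch — the median residual of the entropy coarse stage on 50 dense
random-error spectra, and three generator-fidelity statistics (baseline
amplitude ratio, broad-peak inclusion rate, fine-task PH0 error extremes)
measured on fresh multi-thousand-sample draws:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Runtime is a few minutes on one CPU; all inputs are synthesized internally,
no data files are required.

## Scope and limits

Only PH0/PH1 errors are modeled (no higher-order phase correction, linear
prediction, or NUS reconstruction).  Phasing of 2D spectra via cross
sections and statistical baseline correction are out of scope; `--baseline
none` is a pass-through hook.  The shipped peak-list generator emulates
dense biofluid-like 1D proton spectra; real spectrometer data beyond the
Bruker/JCAMP readers is not bundled.  See `docs/methods.md` for the model
assumptions, parameter defaults and known limitations.
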