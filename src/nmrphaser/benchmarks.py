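"""Reproducible benchmark simulations for the headline behaviors.

Each function generates its own synthetic inputs from a seed, runs the
method under test, and measures the outcome — these are the computations
behind the package's quantitative claims (coarse-phasing residuals,
generator statistics).  They are shared between the test suite and
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .entropy import grid_search
from .spectrum import PhasePair, apply_phase, wrap_degrees
from .synth import (
    SynthConfig,
    augment_peaklist,
    build_dataset,
    fixture_peaklists,
    make_sample,
)

__all__ = [
    "entropy_coarse_residuals",
    "baseline_amplitude_ratio",
    "broad_peak_rate",
    "fine_task_phase_extremes",
]


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def entropy_coarse_residuals(
    seed: int,
    n_spectra: int = 50,
    lengths: tuple = (4096, 8192, 16384, 32768),
):
    """Residual |PH0| / |PH1| of the 10-degree entropy grid search.

    Simulates ``n_spectra`` dense fixture-list spectra (baseline and noise
    at generator defaults), injects PH0 and PH1 errors uniform in
    [-180, 180] degrees, runs the full -180..+180 grid search and measures
    the residual per component (PH0 wrapped to (-180, 180]).  Returns
    ``(median |PH0| residual, median |PH1| residual, residual array)``.
    """
    cfg = SynthConfig(n_points_choices=lengths)
    bases = fixture_peaklists(2, _stream(seed, 0))
    resid = np.empty((n_spectra, 2))
    for i in range(n_spectra):
        rng = _stream(seed, 1, i)
        base = bases[i % len(bases)]
        aug = augment_peaklist(base, cfg, rng)
        n_points = int(lengths[i % len(lengths)])
        sample = make_sample(aug, n_points, "ph0", "zero", cfg, rng)
        inj = PhasePair(rng.uniform(-180.0, 180.0), rng.uniform(-180.0, 180.0))
        wrong = apply_phase(sample.spectrum, inj)
        found = grid_search(wrong).best_phase
        resid[i, 0] = abs(wrap_degrees(inj.ph0 + found.ph0))
        resid[i, 1] = abs(inj.ph1 + found.ph1)
    return float(np.median(resid[:, 0])), float(np.median(resid[:, 1])), resid


def baseline_amplitude_ratio(seed: int, n_samples: int = 200) -> float:
    """Max over samples of max|baseline| / tallest peak, as a percentage.

    Samples are generated with ``make_sample`` at the full default
    configuration; the ratio is measured from the actually generated
    baseline of each sample.
    """
    cfg = SynthConfig()
    bases = fixture_peaklists(2, _stream(seed, 0))
    ratios = []
    for i in range(n_samples):
        rng = _stream(seed, 1, i)
        aug = augment_peaklist(bases[i % 2], cfg, rng)
        n_points = int(cfg.n_points_choices[i % len(cfg.n_points_choices)])
        category = ("negative", "zero", "positive")[i % 3]
        s = make_sample(aug, n_points, "ph0", category, cfg, rng)
        ratios.append(s.provenance["baseline_frac"])
    return float(100.0 * np.max(ratios))


def broad_peak_rate(seed: int, n_samples: int = 2000) -> float:
    """Percentage of default-config samples containing broad background peaks."""
    cfg = SynthConfig(n_augment_per_list=(n_samples // 18) + 1)
    bases = fixture_peaklists(2, _stream(seed, 0))
    manifest, _ = build_dataset(
        bases, cfg, "ph0", master_seed=seed, max_samples=n_samples, collect=False
    )
    flags = [e["has_broad"] for e in manifest.entries]
    return float(100.0 * np.mean(flags))


def fine_task_phase_extremes(seed: int, n_samples: int = 2000) -> float:
    """Max |PH0| over fine-task zeroth-order training samples, degrees."""
    cfg = SynthConfig()
    bases = fixture_peaklists(2, _stream(seed, 0))
    worst = 0.0
    for i in range(n_samples):
        rng = _stream(seed, 1, i)
        aug = augment_peaklist(bases[i % 2], cfg, rng)
        n_points = int(cfg.n_points_choices[i % len(cfg.n_points_choices)])
        category = ("positive", "negative")[i % 2]
        s = make_sample(aug, n_points, "ph0", category, cfg, rng)
        worst = max(worst, abs(s.true_phase.ph0))
    return float(worst)
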