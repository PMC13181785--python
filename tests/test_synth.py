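"""Synthetic-data engine: lineshapes, augmentation, baseline, sampling."""

import json

import numpy as np
import pytest

from nmrphaser import (
    PeakList,
    PhasePair,
    SynthConfig,
    VoigtPeak,
    add_noise,
    augment_peaklist,
    build_dataset,
    fixture_peaklists,
    hermite_baseline,
    make_sample,
    synthesize_spectrum,
)
from nmrphaser.synth import CATEGORIES, TrainingSample, scaled_config

from .test_spectrum import measure_fwhh


def count_interior_extrema(curve: np.ndarray) -> int:
    d = np.diff(curve)
    s = np.sign(d[np.abs(d) > 0])
    return int(np.sum(s[:-1] != s[1:]))


class TestSynthesize:
    def test_empty_list_gives_zero_spectrum(self):
        spec = synthesize_spectrum(PeakList(peaks=[], axis_len=1024), 1024)
        assert np.all(spec.points == 0)

    @pytest.mark.parametrize("gauss_fraction", [0.0, 0.5, 1.0])
    def test_height_and_width(self, gauss_fraction):
        pl = PeakList(
            peaks=[VoigtPeak(2048, 10.0, 1.0, gauss_fraction)], axis_len=4096
        )
        real = synthesize_spectrum(pl, 4096).real
        assert real.max() == pytest.approx(1.0, rel=0.02)
        assert int(np.argmax(real)) == 2048
        assert measure_fwhh(real) == pytest.approx(10.0, rel=0.05)

    def test_dispersion_integral_vanishes(self):
        """The dispersion component is antisymmetric: its integral ~ 0."""
        pl = PeakList(peaks=[VoigtPeak(2048, 10.0, 1.0, 0.0)], axis_len=4096)
        spec = synthesize_spectrum(pl, 4096)
        assert abs(spec.imag.sum()) < 0.01 * spec.real.sum()

    def test_out_of_axis_position_clipped_with_warning(self, caplog):
        pl = PeakList(peaks=[VoigtPeak(2000.0, 10.0, 1.0)], axis_len=1024)
        with caplog.at_level("WARNING", logger="nmrphaser.synth"):
            spec = synthesize_spectrum(pl, 1024)
        assert "clipping" in caplog.text
        assert len(spec) == 1024

    def test_position_scales_with_axis_length(self):
        pl = PeakList(peaks=[VoigtPeak(1000.0, 10.0, 1.0)], axis_len=4096)
        real = synthesize_spectrum(pl, 8192).real
        assert int(np.argmax(real)) == 2000


class TestHermiteBaseline:
    def test_zero_amplitude(self, rng):
        assert np.all(hermite_baseline(1024, 5, 0.0, rng) == 0)

    @pytest.mark.parametrize("seed", range(8))
    def test_exactly_five_interior_extrema(self, seed):
        b = hermite_baseline(4096, 5, 1.0, np.random.default_rng(seed))
        assert count_interior_extrema(b) == 5

    def test_exact_rescale_to_max_amp(self, rng):
        b = hermite_baseline(4096, 5, 0.0042, rng)
        assert np.abs(b).max() == pytest.approx(0.0042, rel=1e-12)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            hermite_baseline(16, 5, 1.0, rng)


class TestAddNoise:
    def test_sigma_zero_identity(self, rng, lorentzian_spec):
        out = add_noise(lorentzian_spec, 0.0, rng)
        np.testing.assert_array_equal(out.points, lorentzian_spec.points)

    def test_noise_statistics(self, rng):
        from nmrphaser import Spectrum1D

        clean = Spectrum1D(points=np.zeros(100000, complex) + 1.0)
        noisy = add_noise(clean, 1.0, rng)
        delta = noisy.points - clean.points
        assert np.std(delta.real) == pytest.approx(1.0, rel=0.02)
        assert np.std(delta.imag) == pytest.approx(1.0, rel=0.02)
        r = np.corrcoef(delta.real, delta.imag)[0, 1]
        assert abs(r) < 0.02


class TestAugment:
    def _noop_config(self):
        return SynthConfig(
            max_displacement=0.0,
            shuffle_segments=False,
            removal_max_frac=0.0,
            resample_geometry=False,
            invert_prob=0.0,
            shoulder_prob=0.0,
        )

    def test_noop_configuration_preserves_positions(self, dense_peaklist, rng):
        out = augment_peaklist(dense_peaklist, self._noop_config(), rng)
        np.testing.assert_array_equal(out.positions(), dense_peaklist.positions())

    def test_widths_within_stated_range(self, dense_peaklist):
        cfg = SynthConfig()
        for seed in range(5):
            out = augment_peaklist(dense_peaklist, cfg, np.random.default_rng(seed))
            widths = np.array([p.fwhh for p in out])
            assert np.all(widths >= 3.0) and np.all(widths <= 30.0)

    def test_forced_inversion_mirrors_positions(self, dense_peaklist):
        cfg = SynthConfig(
            max_displacement=0.0,
            shuffle_segments=False,
            removal_max_frac=0.0,
            resample_geometry=False,
            invert_prob=1.0,
            shoulder_prob=0.0,
        )
        out = augment_peaklist(dense_peaklist, cfg, np.random.default_rng(0))
        n = dense_peaklist.axis_len
        np.testing.assert_allclose(
            out.positions(), (n - 1) - dense_peaklist.positions(), atol=1e-6
        )

    def test_empty_base_rejected(self, rng):
        with pytest.raises(ValueError):
            augment_peaklist(PeakList(peaks=[], axis_len=4096), SynthConfig(), rng)


class TestFixturePeaklists:
    def test_contracts(self):
        lists = fixture_peaklists(2, np.random.default_rng(5), axis_len=32768)
        assert len(lists) == 2
        for pl in lists:
            assert len(pl) >= 100
            pos = pl.positions()
            dense = np.sum(
                (pos >= 0.425 * pl.axis_len) & (pos <= 0.575 * pl.axis_len)
            )
            assert dense / len(pl) >= 0.40
            h = pl.heights()
            assert h.max() / h.min() >= 100.0


class TestMakeSample:
    def test_zero_category(self, dense_peaklist, rng):
        s = make_sample(dense_peaklist, 4096, "ph0", "zero", scaled_config(), rng)
        assert s.true_phase == PhasePair(0.0, 0.0)
        assert s.label == "zero"

    def test_ph0_task_range_and_pure_ph0(self, dense_peaklist):
        cfg = scaled_config()
        for seed in range(10):
            s = make_sample(
                dense_peaklist, 4096, "ph0", "positive", cfg,
                np.random.default_rng(seed),
            )
            assert 0.5 <= s.true_phase.ph0 <= 5.0
            assert s.true_phase.ph1 == 0.0

    def test_ph1_task_constrained_magnitude(self, dense_peaklist):
        cfg = scaled_config()
        for seed in range(10):
            s = make_sample(
                dense_peaklist, 4096, "ph1", "negative", cfg,
                np.random.default_rng(seed),
            )
            assert s.true_phase.ph1 < 0
            assert abs(s.true_phase.ph0) == pytest.approx(abs(s.true_phase.ph1))
            assert 1.0 <= -s.true_phase.ph1 <= 10.0

    def test_pretrain_ranges(self, dense_peaklist):
        cfg = scaled_config()
        for seed in range(10):
            s0 = make_sample(
                dense_peaklist, 4096, "ph0", "negative", cfg,
                np.random.default_rng(seed), pretrain=True,
            )
            assert 5.0 <= -s0.true_phase.ph0 <= 10.0
            s1 = make_sample(
                dense_peaklist, 4096, "ph1", "positive", cfg,
                np.random.default_rng(seed), pretrain=True,
            )
            assert 5.0 <= s1.true_phase.ph1 <= 20.0

    def test_invalid_task_or_category(self, dense_peaklist, rng):
        with pytest.raises(ValueError):
            make_sample(dense_peaklist, 4096, "ph2", "zero", scaled_config(), rng)
        with pytest.raises(ValueError):
            make_sample(dense_peaklist, 4096, "ph0", "none", scaled_config(), rng)

    def test_zero_label_spectrum_has_symmetric_isolated_peak(self):
        """Without phase error an isolated absorption peak is symmetric."""
        pl = PeakList(peaks=[VoigtPeak(2048, 12.0, 1.0, 0.0)], axis_len=4096)
        cfg = SynthConfig(
            n_points_choices=(4096,),
            broad_peak_prob=0.0,
            baseline_max_frac=0.0,
            noise_sigma_range=(0.0, 0.0),
        )
        s = make_sample(pl, 4096, "ph0", "zero", cfg, np.random.default_rng(0))
        real = s.spectrum.real
        k = int(np.argmax(real))
        for w in (3, 6, 12):
            assert real[k - w] == pytest.approx(real[k + w], rel=1e-3)


class TestTrainingSampleInvariants:
    def test_label_sign_consistency_enforced(self, lorentzian_spec):
        with pytest.raises(ValueError):
            TrainingSample(
                spectrum=lorentzian_spec,
                label="positive",
                true_phase=PhasePair(-3.0, 0.0),
                task="ph0",
            )

    def test_ph0_task_requires_zero_ph1(self, lorentzian_spec):
        with pytest.raises(ValueError):
            TrainingSample(
                spectrum=lorentzian_spec,
                label="positive",
                true_phase=PhasePair(3.0, 2.0),
                task="ph0",
            )


class TestBuildDataset:
    def test_counting_small(self, dense_peaklist):
        cfg = SynthConfig(
            n_points_choices=(512,), n_augment_per_list=2, max_displacement=50
        )
        manifest, samples = build_dataset([dense_peaklist], cfg, "ph0", 3)
        assert len(samples) == 6
        assert manifest.class_counts() == {c: 2 for c in CATEGORIES}

    def test_counting_matches_stated_total(self, dense_peaklist):
        """2 lists x 1000 augmentations x 3 lengths x 3 categories = 18,000."""
        cfg = SynthConfig()  # defaults: n_augment=1000, 3 lengths
        expected = 2 * cfg.n_augment_per_list * len(cfg.n_points_choices) * 3
        assert expected == 18000
        # mechanism check at reduced scale with the same combinatorics
        small = SynthConfig(
            n_points_choices=(256, 128, 64),
            n_augment_per_list=5,
            max_displacement=10,
            baseline_max_frac=0.0,
        )
        manifest, _ = build_dataset(
            [dense_peaklist, dense_peaklist], small, "ph1", 4, collect=False
        )
        assert len(manifest.entries) == 2 * 5 * 3 * 3
        counts = manifest.class_counts()
        assert len(set(counts.values())) == 1  # exactly balanced

    def test_manifest_determinism(self, dense_peaklist):
        cfg = SynthConfig(
            n_points_choices=(512,), n_augment_per_list=3, max_displacement=50
        )
        m1, _ = build_dataset([dense_peaklist], cfg, "ph0", 11, collect=False)
        m2, _ = build_dataset([dense_peaklist], cfg, "ph0", 11, collect=False)
        assert m1.to_json() == m2.to_json()
        assert json.loads(m1.to_json())["master_seed"] == 11

    def test_default_length_menu_includes_131072(self):
        assert 131072 in SynthConfig().n_points_choices
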