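"""The five connectivity estimators and the region collapse.

Hand-computable and analytic cases per estimator, plus the shared invariances
(amplitude-scaling, symmetry) on random band-limited signals.
"""

import numpy as np
import pytest

from eegmark.atlas import RegionScheme
from eegmark.connectivity import (
    band_analytic,
    coherence_pair,
    collapse_regions,
    cross_spectra,
    pec_pair,
    plv_pair,
    region_connection_names,
    wpli_from_imag,
    wpli_pair,
)
from eegmark.prep import EpochedRecording
from eegmark.synth import bandlimited_noise

FS = 250.0


def _er(data, fs=FS):
    n_ep = data.shape[-1] // 1000
    ep = data[:, : n_ep * 1000].reshape(data.shape[0], n_ep, 1000).transpose(1, 0, 2)
    labels = [f"patch{i:03d}" for i in range(data.shape[0])]
    return EpochedRecording("s", ep, fs, 4.0, labels)


def _alpha_noise(n, seed):
    return bandlimited_noise(n, FS, np.random.default_rng(seed), f_lo=8.0, f_hi=13.0)


class TestCoherence:
    def test_real_scaling_gives_unit_coherence_zero_imcoh(self):
        x = _alpha_noise(60000, 0)
        cs = cross_spectra(_er(np.vstack([x, 0.5 * x])))
        for coh, imcoh in coherence_pair(cs, 0, 1).values():
            assert coh == pytest.approx(1.0, abs=1e-9)
            assert imcoh == pytest.approx(0.0, abs=1e-9)

    def test_quadrature_pair_has_unit_imaginary_coherence(self):
        from scipy.signal import hilbert

        x = _alpha_noise(60000, 1)
        y = np.imag(hilbert(x))  # 90 degree shifted copy
        cs = cross_spectra(_er(np.vstack([x, y])))
        coh, imcoh = coherence_pair(cs, 0, 1)["alpha"]
        assert coh > 0.98
        assert imcoh > 0.95

    def test_independent_noise_stays_near_chance_floor(self):
        rng = np.random.default_rng(2)
        cs = cross_spectra(_er(rng.standard_normal((2, 300000))))  # 75 epochs
        for coh, _ in coherence_pair(cs, 0, 1).values():
            assert coh < 0.2

    def test_delay_leaves_coherence_magnitude_intact(self):
        x = np.random.default_rng(3).standard_normal(60000)
        y = np.roll(x, 7)
        cs = cross_spectra(_er(np.vstack([x, y])))
        for coh, _ in coherence_pair(cs, 0, 1).values():
            assert coh > 0.95

    def test_single_epoch_rejected(self):
        with pytest.raises(ValueError):
            cross_spectra(_er(np.random.default_rng(0).standard_normal((2, 1000))))


class TestPlv:
    def test_identical_and_offset_phases_lock_fully(self):
        phi = np.random.default_rng(0).uniform(0, 2 * np.pi, 5000)
        a = np.exp(1j * np.cumsum(0.1 + 0.01 * phi[:5000]))
        assert plv_pair(a, a) == pytest.approx(1.0)
        assert plv_pair(a, a * np.exp(1j * 0.7)) == pytest.approx(1.0)

    def test_uniform_phase_differences_match_analytic_resultant(self):
        """E|mean of N unit phasors| = sqrt(pi / 4N) for iid uniform phases."""
        rng = np.random.default_rng(1)
        N = 1000
        plvs = [
            plv_pair(np.exp(1j * rng.uniform(0, 2 * np.pi, N)), np.ones(N))
            for _ in range(300)
        ]
        assert np.mean(plvs) == pytest.approx(np.sqrt(np.pi / (4 * N)), rel=0.1)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            plv_pair(np.array([]), np.array([]))


class TestWpli:
    def test_hand_computed_ensemble(self):
        im = np.array([[1.0], [1.0], [-1.0]])
        assert wpli_from_imag(im)[0] == pytest.approx(1.0 / 3.0)

    def test_consistent_lag_gives_unity(self):
        im = np.abs(np.random.default_rng(0).standard_normal((50, 4))) + 0.1
        assert np.allclose(wpli_from_imag(im), 1.0)

    def test_real_scaling_gives_zero_by_convention(self):
        x = _alpha_noise(60000, 4)
        cs = cross_spectra(_er(np.vstack([x, 2.0 * x])))
        for v in wpli_pair(cs, 0, 1).values():
            assert v == 0.0


class TestPec:
    def test_real_scaling_gives_zero_by_convention(self):
        from scipy.signal import hilbert

        x = _alpha_noise(30000, 5)
        a = hilbert(x)
        assert pec_pair(a, 0.5 * a) == pytest.approx(0.0, abs=1e-6)

    def test_common_amplitude_modulator_detected(self):
        t = np.arange(120000) / FS
        rng = np.random.default_rng(6)
        mod = 1.0 + 0.95 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 6))
        x = mod * _alpha_noise(120000, 7)
        y = mod * _alpha_noise(120000, 8)
        er = _er(np.vstack([x, y]))
        a = band_analytic(er, (8.0, 13.0))
        assert pec_pair(a[0], a[1]) > 0.5

    def test_independent_signals_near_zero(self):
        er = _er(np.vstack([_alpha_noise(60000, 9), _alpha_noise(60000, 10)]))
        a = band_analytic(er, (8.0, 13.0))
        assert abs(pec_pair(a[0], a[1])) < 0.1


class TestInvariances:
    def _pair_values(self, x, y):
        er = _er(np.vstack([x, y]))
        cs = cross_spectra(er)
        a = band_analytic(er, (8.0, 13.0))
        coh, imcoh = coherence_pair(cs, 0, 1)["alpha"]
        return np.array(
            [coh, imcoh, wpli_pair(cs, 0, 1)["alpha"], plv_pair(a[0], a[1]),
             pec_pair(a[0], a[1])]
        )

    def test_amplitude_scaling_and_symmetry(self):
        x = _alpha_noise(40000, 11) + 0.3 * _alpha_noise(40000, 12)
        y = _alpha_noise(40000, 12)
        base = self._pair_values(x, y)
        assert np.allclose(self._pair_values(5.0 * x, y), base, atol=1e-5)
        assert np.allclose(self._pair_values(y, x), base, atol=1e-5)


class TestRegionCollapse:
    scheme = RegionScheme()

    def test_full_atlas_has_76_named_connections(self):
        names = region_connection_names(self.scheme)
        assert len(names) == 76
        assert "insular-lh|insular-lh" not in names
        assert "insular-rh|insular-rh" not in names
        inter = [n for n in names if n.split("|")[0] != n.split("|")[1]]
        assert len(inter) == 66

    def test_constant_matrix_collapses_to_constant(self):
        cm = np.full((68, 68), 0.42)
        values, names = collapse_regions(cm, self.scheme)
        assert len(values) == 76
        assert np.allclose(values, 0.42)

    def test_two_patch_node_intra_value_is_the_single_pair(self):
        sub = RegionScheme(
            (
                "cuneus-lh", "lateraloccipital-lh",
                "cuneus-rh", "lateraloccipital-rh",
                "insula-lh", "insula-rh",
            )
        )
        cm = np.arange(36, dtype=float).reshape(6, 6)
        cm = 0.5 * (cm + cm.T)
        values, names = collapse_regions(cm, sub)
        assert values[names.index("occipital-lh|occipital-lh")] == pytest.approx(
            cm[0, 1]
        )
        # single-patch insular nodes contribute no intra value
        assert "insular-lh|insular-lh" not in names
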