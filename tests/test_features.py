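"""Beta-envelope feature extraction: filter, envelope, classification, spectra."""

import numpy as np
import pytest
from scipy import signal as sps

from tcdcm.containers import Epoch, EpochSet
from tcdcm.features import (
    bandpass_beta,
    envelope,
    estimate_condition_spectra,
    extract_condition_data,
    segment_and_classify,
    select_epochs,
)
from tcdcm.forward import default_freqs
from tcdcm.synthetic import BurstGeneratorConfig, generate_bursty_ecog

FS = 1000.0


def tone(freq, duration=10.0, fs=FS, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t), t


class TestBandpass:
    def test_passband_tone_preserved(self):
        x, _ = tone(25.0)
        y = bandpass_beta(x, FS)
        mid = slice(int(FS), int(9 * FS))
        assert np.max(np.abs(y[mid])) == pytest.approx(1.0, rel=0.05)

    def test_low_frequency_tone_rejected(self):
        x, _ = tone(2.0)
        y = bandpass_beta(x, FS)
        mid = slice(int(FS), int(9 * FS))
        assert np.max(np.abs(y[mid])) < 0.1

    def test_white_noise_energy_concentrates_in_band(self, rng):
        x = rng.standard_normal(int(60 * FS))
        y = bandpass_beta(x, FS)
        f, p = sps.welch(y, fs=FS, nperseg=4096)
        band = (f >= 15) & (f <= 35)
        assert p[band].sum() / p.sum() >= 0.8

    def test_sampling_rate_guard(self):
        with pytest.raises(ValueError, match="too low"):
            bandpass_beta(np.zeros(1000), 60.0)


class TestEnvelope:
    def test_constant_tone_amplitude_recovered(self):
        x, _ = tone(25.0, amp=2.5)
        env = envelope(bandpass_beta(x, FS))
        mid = slice(int(FS), int(9 * FS))
        assert np.all(np.abs(env[mid] - 2.5) < 0.05)

    def test_modulator_recovered(self):
        t = np.arange(int(20 * FS)) / FS
        mod = 1.0 + 0.5 * np.sin(2 * np.pi * 0.7 * t)
        x = mod * np.sin(2 * np.pi * 25.0 * t)
        env = envelope(x)
        mid = slice(int(FS), int(19 * FS))
        r = np.corrcoef(env[mid], mod[mid])[0, 1]
        assert r > 0.99

    def test_zeros_and_empty(self):
        assert np.all(envelope(np.zeros(100)) == 0)
        with pytest.raises(ValueError):
            envelope(np.array([]))


def brute_force_labels(areas, lo_pct=5.0, hi_pct=95.0):
    """Independent percentile oracle: sort-based interpolated quantiles."""
    srt = np.sort(areas)
    n = len(srt)

    def quantile(q):
        pos = q / 100 * (n - 1)
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        return srt[lo] + (pos - lo) * (srt[hi] - srt[lo])

    lo, hi = quantile(lo_pct), quantile(hi_pct)
    return (
        {i for i, a in enumerate(areas) if a < lo},
        {i for i, a in enumerate(areas) if a > hi},
    )


class TestSegmentAndClassify:
    def _env_from_areas(self, areas, fs=FS, epoch_ms=500.0):
        n_per = round(fs * epoch_ms / 1000)
        return np.repeat(np.asarray(areas, dtype=float) * fs / n_per, n_per)

    def test_hundred_increasing_areas_gives_five_per_tail(self):
        env = self._env_from_areas(np.arange(1.0, 101.0))
        eps = segment_and_classify(env, FS)
        assert eps.counts() == {"LB": 5, "HB": 5}
        assert sorted(e.index for e in eps.condition("LB")) == [0, 1, 2, 3, 4]
        assert sorted(e.index for e in eps.condition("HB")) == [95, 96, 97, 98, 99]

    def test_twenty_epochs_single_extreme(self):
        env = self._env_from_areas(np.arange(1.0, 21.0))
        eps = segment_and_classify(env, FS)
        assert eps.counts() == {"LB": 1, "HB": 1}
        assert eps.condition("LB")[0].index == 0

    def test_matches_brute_force_oracle_on_random_areas(self, rng):
        for _ in range(10):
            areas = rng.lognormal(0.0, 1.0, size=rng.integers(20, 200))
            env = self._env_from_areas(areas)
            eps = segment_and_classify(env, FS)
            lb, hb = brute_force_labels(areas)
            assert {e.index for e in eps.condition("LB")} == lb
            assert {e.index for e in eps.condition("HB")} == hb

    def test_tail_counts_bounded(self, rng):
        n = 137
        areas = rng.uniform(1, 2, n)
        eps = segment_and_classify(self._env_from_areas(areas), FS)
        assert len(eps.condition("LB")) <= int(np.ceil(0.05 * n))
        assert len(eps.condition("HB")) <= int(np.ceil(0.05 * n))

    def test_degenerate_envelope_rejected(self):
        env = np.ones(int(30 * FS))
        with pytest.raises(ValueError, match="zero spread"):
            segment_and_classify(env, FS)

    def test_trailing_partial_epoch_dropped(self):
        env = self._env_from_areas(np.arange(1.0, 31.0))
        eps_full = segment_and_classify(env, FS)
        eps_ragged = segment_and_classify(
            np.concatenate([env, np.full(123, 1e9)]), FS
        )
        assert {e.index for e in eps_full.epochs} == {
            e.index for e in eps_ragged.epochs
        }

    def test_too_few_epochs_rejected(self):
        with pytest.raises(ValueError, match="20 whole epochs"):
            segment_and_classify(np.random.default_rng(0).random(5000), FS)


class TestSelectEpochs:
    def _epoch_set(self, n_lb, n_hb, fs=FS):
        n_per = round(fs / 2)
        eps = []
        i = 0
        for label, count in (("LB", n_lb), ("HB", n_hb)):
            for _ in range(count):
                eps.append(Epoch(label, np.zeros(n_per), float(i), i))
                i += 1
        return EpochSet(fs=fs, epochs=eps)

    def test_five_per_condition(self):
        sel = select_epochs(self._epoch_set(10, 12), n=5, seed=3)
        assert sel.counts() == {"LB": 5, "HB": 5}

    def test_identity_when_n_equals_available(self):
        es = self._epoch_set(5, 5)
        sel = select_epochs(es, n=5, seed=0)
        assert {e.index for e in sel.epochs} == {e.index for e in es.epochs}

    def test_deterministic_under_seed(self):
        es = self._epoch_set(30, 30)
        a = select_epochs(es, n=5, seed=11)
        b = select_epochs(es, n=5, seed=11)
        assert [e.index for e in a.epochs] == [e.index for e in b.epochs]

    def test_insufficient_epochs_reports_counts(self):
        with pytest.raises(ValueError, match="LB=3"):
            select_epochs(self._epoch_set(3, 9), n=5)


class TestConditionSpectra:
    def _epochs_from_signal(self, x, labels, fs=FS):
        n_per = round(fs / 2)
        eps = [
            Epoch(lab, x[i * n_per : (i + 1) * n_per], 1.0 + i, i)
            for i, lab in enumerate(labels)
        ]
        return EpochSet(fs=fs, epochs=eps)

    def test_tone_peak_located(self):
        x, _ = tone(25.0, duration=5.0)
        x += 0.01 * np.random.default_rng(0).standard_normal(x.size)
        es = self._epochs_from_signal(x, ["LB", "HB"] * 5)
        csd = estimate_condition_spectra(es, default_freqs())
        for cond in ("LB", "HB"):
            g = csd.spectra[cond]
            assert abs(csd.freqs[np.argmax(g)] - 25.0) <= 1.0

    def test_white_noise_spectrum_flat(self, rng):
        x = rng.standard_normal(int(50 * FS / 2))
        es = self._epochs_from_signal(x, ["LB", "HB"] * 25)
        csd = estimate_condition_spectra(es, default_freqs(), ar_order=8)
        band = (csd.freqs >= 15) & (csd.freqs <= 35)
        for cond in ("LB", "HB"):
            g = csd.spectra[cond][band]
            assert g.max() / g.min() < 3.0

    def test_average_permutation_invariant(self, rng):
        x = rng.standard_normal(int(10 * FS / 2))
        labels = ["LB", "HB"] * 5
        es = self._epochs_from_signal(x, labels)
        fwd = estimate_condition_spectra(es, default_freqs())
        rev = EpochSet(fs=FS, epochs=list(reversed(es.epochs)))
        bwd = estimate_condition_spectra(rev, default_freqs())
        for cond in ("LB", "HB"):
            assert np.allclose(fwd.spectra[cond], bwd.spectra[cond])

    def test_frequency_below_epoch_resolution_rejected(self, rng):
        x = rng.standard_normal(int(10 * FS / 2))
        es = self._epochs_from_signal(x, ["LB", "HB"] * 5)
        with pytest.raises(ValueError, match="cannot support"):
            estimate_condition_spectra(es, np.arange(1.0, 48.0, 0.5))


class TestFullChain:
    def test_burst_epochs_classified_high_beta(self):
        """HB-labelled epochs overlap ground-truth bursts with precision >= 0.9."""
        cfg = BurstGeneratorConfig(seed=5)
        sig, bursts = generate_bursty_ecog(cfg)
        _, sel = extract_condition_data(sig, cfg.fs, default_freqs(), seed=5)
        hits = 0
        hb = sel.condition("HB")
        for ep in hb:
            t0, t1 = ep.index * 0.5, (ep.index + 1) * 0.5
            if any(not (b1 <= t0 or b0 >= t1) for b0, b1 in bursts):
                hits += 1
        assert hits / len(hb) >= 0.9
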