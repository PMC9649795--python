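"""Stimulus generators: noise bands, Weyl-mode impacts, rolling sounds."""

import numpy as np
import pytest

from soundshape import cochlear, forge, indices
from soundshape.audio_io import Waveform, normalize_rms
from soundshape.errors import ArgumentError, DegenerateInputError
from soundshape.forge import (
    DrumSpec,
    Envelope,
    NoiseBandSpec,
    RollSpec,
    envelope_db_range,
    extract_envelope,
    make_noise_band,
    shaped_noise,
    synth_impact,
    synth_roll,
    transplant_envelope,
    weyl_modes,
)
from soundshape.types import SpectralProfile

FS = 44_100


class TestNoiseBand:
    def test_no_dip_keeps_amplitude_flat(self):
        w = make_noise_band(NoiseBandSpec(fc=600, dip_amp=1.0, seed=3))
        s = w.samples
        seg = s[int(0.225 * FS) : int(0.275 * FS)]
        flank = s[int(0.05 * FS) : int(0.20 * FS)]
        ratio = np.sqrt(np.mean(seg**2)) / np.sqrt(np.mean(flank**2))
        assert 0.8 < ratio < 1.2

    def test_silent_dip_is_digital_silence(self):
        w = make_noise_band(NoiseBandSpec(fc=600, dip_amp=0.0, seed=3))
        core = w.samples[int(0.227 * FS) + 10 : int(0.273 * FS) - 10]
        assert np.all(core == 0.0)

    def test_spectral_peak_at_center_frequency(self):
        # Fourier peak-finding oracle; tolerance is one filter bandwidth
        w = make_noise_band(NoiseBandSpec(fc=600, dip_amp=1.0, seed=3))
        spec = np.abs(np.fft.rfft(w.samples)) ** 2
        freqs = np.fft.rfftfreq(w.samples.size, 1 / FS)
        assert abs(freqs[np.argmax(spec)] - 600.0) < 60.0

    def test_duration_and_rate(self):
        w = make_noise_band(NoiseBandSpec(fc=300, dip_amp=0.5, seed=0))
        assert w.fs == FS
        assert w.samples.size == int(0.5 * FS)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ArgumentError):
            NoiseBandSpec(fc=600, dip_amp=1.5)
        with pytest.raises(ArgumentError):
            NoiseBandSpec(fc=600, dip_amp=0.5, dip_window=(0.4, 0.6))


class TestNoiseBandCorpus:
    def test_factorial_structure(self, noise_band_set):
        waves, design, _ = noise_band_set
        assert len(waves) == 32
        assert design["fc"].nunique() == 8
        assert design["dip_amp"].nunique() == 4
        assert (design.groupby("dip_amp").size() == 8).all()

    def test_deterministic_under_master_seed(self):
        w1, d1 = forge.noise_band_corpus(9)
        w2, d2 = forge.noise_band_corpus(9)
        assert all(np.array_equal(a.samples, b.samples) for a, b in zip(w1, w2))
        assert d1.equals(d2)

    def test_balance_decreases_with_center_frequency(self, noise_band_set):
        _, design, results = noise_band_set
        df = design.copy()
        df["bal"] = [r.balance(25) for r in results]
        for _, grp in df.groupby("dip_amp"):
            bal = grp.sort_values("fc")["bal"].to_numpy()
            assert np.all(np.diff(bal) < 0)

    def test_continuity_increases_with_dip_amplitude(self, noise_band_set):
        _, design, results = noise_band_set
        df = design.copy()
        df["cont"] = [r.continuity for r in results]
        for _, grp in df.groupby("fc"):
            cont = grp.sort_values("dip_amp")["cont"].to_numpy()
            assert np.all(np.diff(cont) >= 0)
        means = df.groupby("dip_amp")["cont"].mean().to_numpy()
        assert np.all(np.diff(means) > 0)


class TestWeylModes:
    def test_larger_perimeter_raises_every_mode(self):
        area = 0.4
        p1 = 2 * np.sqrt(np.pi * area)
        f1 = weyl_modes(area, p1, 40)
        f2 = weyl_modes(area, 1.5 * p1, 40)
        assert np.all(f2 > f1)
        assert f2.mean() > f1.mean()

    def test_larger_area_lowers_fundamental(self):
        p = 2 * np.sqrt(np.pi * 0.8)  # legal for both areas
        assert weyl_modes(0.8, p, 10)[0] < weyl_modes(0.4, p, 10)[0]

    def test_disk_minimizes_mean_mode_frequency(self):
        area = 0.5
        disk = weyl_modes(area, 2 * np.sqrt(np.pi * area), 30)
        for factor in (1.01, 1.3, 1.8):
            poly = weyl_modes(area, factor * 2 * np.sqrt(np.pi * area), 30)
            assert poly.mean() > disk.mean()

    def test_modes_ascending_and_positive(self):
        f = weyl_modes(0.3, 1.6 * 2 * np.sqrt(np.pi * 0.3), 80)
        assert np.all(f > 0)
        assert np.all(np.diff(f) > 0)

    def test_isoperimetric_violation_rejected(self):
        with pytest.raises(ArgumentError, match="isoperimetric"):
            weyl_modes(1.0, 1.0, 10)

    def test_unit_area_disk_fundamental_calibration(self):
        f = weyl_modes(1.0, 2 * np.sqrt(np.pi), 1)
        assert f[0] == pytest.approx(forge.ROUND_DISK_F0, rel=1e-9)


class TestSynthImpact:
    def test_duration_within_printed_range(self):
        for seed in (0, 1):
            w = synth_impact(DrumSpec.round_drum(0.4, seed=seed))
            assert 0.200 <= w.duration <= 0.220 + 1e-9

    def test_stronger_damping_decays_faster(self):
        slow = synth_impact(DrumSpec.round_drum(0.4, damping=10.0, seed=2))
        fast = synth_impact(DrumSpec.round_drum(0.4, damping=40.0, seed=2))

        def frame_energy_at_100ms(w):
            seg = w.samples[int(0.095 * FS) : int(0.105 * FS)]
            return np.mean(seg**2)

        assert frame_energy_at_100ms(fast) < frame_energy_at_100ms(slow)

    def test_round_beats_spiky_on_balance(self):
        r = synth_impact(DrumSpec.round_drum(0.4, seed=3))
        s = synth_impact(DrumSpec.spiky_drum(0.4, perimeter_factor=1.6, seed=3))
        ir = indices.analyze_stimulus(r, continuity_eligible=False)
        js = indices.analyze_stimulus(s, continuity_eligible=False)
        assert ir.balance(25) > js.balance(25)


class TestBeatingCorpus:
    def test_cardinality_and_label_balance(self, beating_set):
        waves, design, _ = beating_set
        assert len(waves) == 30
        assert (design["category"] == "round").sum() == 15
        assert (design["category"] == "spiky").sum() == 15

    def test_band_energy_contrast(self, beating_set):
        """Round objects put more energy below 500 Hz; spiky objects more
        within 500-2000 Hz — for every one of the 30 sounds."""
        waves, design, _ = beating_set
        for w, (_, row) in zip(waves, design.iterrows()):
            S = cochlear.mean_spectrum(cochlear.cochleagram(normalize_rms(w)))
            low = S.S[S.center_freqs < 500].sum()
            mid = S.S[(S.center_freqs >= 500) & (S.center_freqs < 2000)].sum()
            if row["category"] == "round":
                assert low > mid
            else:
                assert mid > low

    def test_deterministic(self):
        w1, _ = forge.beating_corpus(5)
        w2, _ = forge.beating_corpus(5)
        assert all(np.array_equal(a.samples, b.samples) for a, b in zip(w1, w2))


class TestEnvelope:
    def test_constant_noise_has_small_envelope_variation(self):
        rng = np.random.default_rng(0)
        w = Waveform(0.3 * rng.standard_normal(FS // 2), FS)
        env = extract_envelope(w)
        v = env.values[50:-50]
        assert v.std() / v.mean() < 0.1

    def test_step_response_settles_within_31ms(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(FS // 2)
        amp = np.where(np.arange(FS // 2) < FS // 4, 0.1, 1.0)
        env = extract_envelope(Waveform(x * amp, FS))
        t = np.arange(env.values.size) / env.rate
        pre = env.values[(t > 0.25 - 0.080) & (t < 0.25 - 0.031)].mean()
        post = env.values[(t > 0.25 + 0.031) & (t < 0.25 + 0.080)].mean()
        assert post / pre > 8.0  # full 10x step, settled on both sides
        window = env.values[(t >= 0.25 - 0.0155) & (t <= 0.25 + 0.0155)]
        assert np.all(np.diff(window) >= -1e-6)  # monotone rise through the step

    def test_gain_equivariance(self):
        rng = np.random.default_rng(1)
        w = Waveform(0.2 * rng.standard_normal(FS // 4), FS)
        e1 = extract_envelope(w)
        e2 = extract_envelope(Waveform(2.0 * w.samples, FS))
        assert np.allclose(e2.values, 2.0 * e1.values, atol=1e-9)


class TestShapedNoise:
    def test_flat_profile_reproduced_within_3db(self):
        cfs = cochlear.erb_center_frequencies()
        target = SpectralProfile(S=np.ones(64), center_freqs=cfs)
        w = shaped_noise(target, duration=0.5, seed=2)
        S = cochlear.mean_spectrum(cochlear.cochleagram(normalize_rms(w))).S
        achieved = S / S.sum()
        err_db = 10 * np.abs(np.log10(achieved / (1.0 / 64)))
        assert err_db.max() < 3.0

    def test_balance_sign_preserved_from_source(self):
        src = synth_impact(DrumSpec.round_drum(0.4, seed=3))
        cfs = cochlear.erb_center_frequencies()
        S = cochlear.mean_spectrum(cochlear.cochleagram(normalize_rms(src)))
        w = shaped_noise(SpectralProfile(S=S.S, center_freqs=cfs), duration=0.5, seed=4)
        b_src = indices.analyze_stimulus(src, continuity_eligible=False).balance(25)
        b_out = indices.analyze_stimulus(w, continuity_eligible=False).balance(25)
        assert np.sign(b_out) == np.sign(b_src)

    def test_deterministic(self):
        cfs = cochlear.erb_center_frequencies()
        target = SpectralProfile(S=np.ones(64), center_freqs=cfs)
        w1 = shaped_noise(target, 0.3, seed=7)
        w2 = shaped_noise(target, 0.3, seed=7)
        assert np.array_equal(w1.samples, w2.samples)

    def test_zero_profile_rejected(self):
        cfs = cochlear.erb_center_frequencies()
        with pytest.raises(DegenerateInputError):
            shaped_noise(SpectralProfile(S=np.zeros(64), center_freqs=cfs), 0.3)


class TestTransplant:
    def test_unit_envelope_is_identity_up_to_gain(self):
        rng = np.random.default_rng(2)
        carrier = Waveform(0.2 * rng.standard_normal(FS // 4), FS)
        env = Envelope(values=np.ones(200), rate=1000.0)
        out = transplant_envelope(env, carrier)
        n = out.samples.size
        ref = normalize_rms(Waveform(carrier.samples[:n], FS), 0.1)
        assert np.allclose(out.samples, ref.samples, atol=1e-12)

    def test_sharp_envelope_lowers_continuity(self):
        rng = np.random.default_rng(3)
        carrier = Waveform(0.2 * rng.standard_normal(FS // 2), FS)
        smooth = extract_envelope(synth_roll(RollSpec("smooth", seed=1)))
        sharp = extract_envelope(synth_roll(RollSpec("sharp", seed=1)))
        c_smooth = indices.analyze_stimulus(transplant_envelope(smooth, carrier)).continuity
        c_sharp = indices.analyze_stimulus(transplant_envelope(sharp, carrier)).continuity
        assert c_smooth > c_sharp

    def test_zero_envelope_rejected(self):
        carrier = Waveform(np.ones(FS // 4) * 0.1, FS)
        env = Envelope(values=np.zeros(100), rate=1000.0)
        with pytest.raises(DegenerateInputError):
            transplant_envelope(env, carrier)

    def test_short_carrier_rejected(self):
        carrier = Waveform(np.ones(1000) * 0.1, FS)
        env = Envelope(values=np.ones(500), rate=1000.0)
        with pytest.raises(ArgumentError):
            transplant_envelope(env, carrier)


class TestRollingCorpus:
    def test_cardinality_and_split(self, rolling_set):
        _, design, _ = rolling_set
        assert len(design) == 36
        assert (design["kind"] == "original").sum() == 12
        assert (design["kind"] == "synthetic").sum() == 24

    def test_envelope_constraints_on_originals(self, rolling_set):
        """Smooth rolls stay under 6 dB over >40 ms windows; sharp rolls show
        an excursion above 8 dB within <40 ms."""
        waves, design, _ = rolling_set
        for w, (_, row) in zip(waves[:12], design[:12].iterrows()):
            env = extract_envelope(w)
            swing = envelope_db_range(env, 0.040)
            if row["envelope_shape"] == "smooth":
                assert swing < 6.0
            else:
                assert swing > 8.0

    def test_synthetic_design_crosses_envelope_and_carrier(self, rolling_set):
        _, design, _ = rolling_set
        synth = design[design["kind"] == "synthetic"]
        cells = synth.groupby(["envelope_shape", "carrier"]).size()
        assert len(cells) == 4
        assert (cells == 6).all()

    def test_continuity_ordering_pre_and_post_transplant(self, rolling_set):
        _, design, results = rolling_set
        df = design.copy()
        df["cont"] = [r.continuity for r in results]
        for kind in ("original", "synthetic"):
            sub = df[df["kind"] == kind]
            smooth = sub[sub["envelope_shape"] == "smooth"]["cont"]
            sharp = sub[sub["envelope_shape"] == "sharp"]["cont"]
            assert smooth.min() > sharp.max()
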