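"""ERP pipeline: re-referencing, filtering, epoching, rejection, inclusion,
averaging and ROI/window measurement."""

import numpy as np
import pandas as pd
import pytest

from syllastream import erp


def make_eeg(data, sfreq=512.0, ch_names=None):
    if ch_names is None:
        ch_names = [f"ch{i}" for i in range(len(data) - 2)] + ["M1", "M2"]
    return erp.ContinuousEEG(ch_names=ch_names, sfreq=sfreq,
                             data=np.asarray(data, dtype=float))


class TestRereference:
    def test_zero_mastoids_is_identity(self, rng):
        data = rng.normal(size=(4, 100))
        data[-2:] = 0.0
        eeg = make_eeg(data)
        out = erp.rereference_mastoids(eeg)
        np.testing.assert_allclose(out.data, data)

    def test_mastoid_average_vanishes(self, rng):
        eeg = make_eeg(rng.normal(size=(5, 200)))
        out = erp.rereference_mastoids(eeg)
        np.testing.assert_allclose(out.pick(["M1", "M2"]).mean(axis=0), 0.0,
                                   atol=1e-12)

    def test_common_mode_removed(self):
        eeg = make_eeg(np.full((4, 50), 3.0))
        out = erp.rereference_mastoids(eeg)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_missing_mastoid(self, rng):
        eeg = erp.ContinuousEEG(["a", "b"], 512.0, rng.normal(size=(2, 10)))
        with pytest.raises(KeyError, match="mastoid"):
            erp.rereference_mastoids(eeg)


class TestBandpass:
    def _tone_gain(self, freq, sfreq=512.0, seconds=60.0):
        # projection onto the input sine over the central third avoids the
        # multi-second transients of the 0.1 Hz high-pass corner
        t = np.arange(int(seconds * sfreq)) / sfreq
        x = np.sin(2 * np.pi * freq * t)
        y = erp.bandpass(make_eeg(np.stack([x, x, x]))).data[0]
        mid = slice(int(20 * sfreq), int(40 * sfreq))
        return 2 * np.mean(y[mid] * x[mid])

    def test_passband_tone_preserved(self):
        assert self._tone_gain(10.0) == pytest.approx(1.0, abs=0.01)

    def test_stopband_tone_attenuated(self):
        assert abs(self._tone_gain(50.0)) < 0.1

    def test_zero_phase_impulse_symmetry(self):
        n = 2 ** 17  # long record so the slow high-pass tail fits inside
        data = np.zeros((3, n))
        data[:, n // 2] = 1.0
        y = erp.bandpass(make_eeg(data)).data[0]
        window = y[n // 2 - 300:n // 2 + 301]
        np.testing.assert_allclose(window, window[::-1], atol=1e-9)

    def test_band_outside_nyquist(self):
        eeg = make_eeg(np.zeros((3, 100)), sfreq=50.0)
        with pytest.raises(ValueError, match="band"):
            erp.bandpass(eeg, 0.1, 30.0)


def make_epochs(rng, n_ep=24, n_ch=3, sfreq=64.0, tasks=("implicit",)):
    n_samp = round(1.5 * sfreq)
    times = (round(-0.3 * sfreq) + np.arange(n_samp)) / sfreq * 1000
    labels = pd.DataFrame([
        dict(task=task, tp_class=tp, half=half)
        for task in tasks
        for tp in ("high", "low")
        for half in (1, 2)
        for _ in range(n_ep // (len(tasks) * 4))])
    data = rng.normal(size=(len(labels), n_ch, n_samp))
    return erp.EpochSet(data=data, labels=labels, times_ms=times,
                        ch_names=[f"ch{i}" for i in range(n_ch)], sfreq=sfreq)


class TestEpoching:
    def test_epoch_length_at_512(self, rng):
        eeg = make_eeg(rng.normal(size=(3, 512 * 10)))
        events = pd.DataFrame({"onset_ms": [2000.0, 5000.0],
                               "tp_class": ["high", "low"]})
        eps = erp.epoch(eeg, events)
        assert eps.data.shape == (2, 3, 768)  # 1.5 s x 512 Hz

    def test_baseline_mean_zero(self, rng):
        eeg = make_eeg(rng.normal(size=(3, 512 * 10)) + 5.0)
        events = pd.DataFrame({"onset_ms": [2000.0, 5000.0]})
        eps = erp.epoch(eeg, events)
        mask = (eps.times_ms >= -300) & (eps.times_ms <= 0)
        np.testing.assert_allclose(eps.data[:, :, mask].mean(axis=2), 0.0,
                                   atol=1e-9)

    def test_edge_events_dropped(self, rng, caplog):
        eeg = make_eeg(rng.normal(size=(3, 512 * 4)))
        events = pd.DataFrame({"onset_ms": [100.0, 2000.0]})
        eps = erp.epoch(eeg, events)
        assert len(eps) == 1

    def test_full_stream_yields_one_epoch_per_word(self, short_timeline):
        from syllastream import synthdata as sd

        sfreq = 64.0
        n = int((short_timeline.total_duration_ms / 1000 + 4) * sfreq)
        eeg = erp.ContinuousEEG(["a", "b"], sfreq, np.zeros((2, n)))
        events = sd.simulated_event_table(short_timeline, "implicit")
        eps = erp.epoch(eeg, events)
        assert len(eps) == len(short_timeline.word_onsets())

    def test_order_robustness(self, rng):
        """Epoch-then-baseline equals baseline applied at construction."""
        eeg = make_eeg(rng.normal(size=(3, 512 * 10)))
        events = pd.DataFrame({"onset_ms": [2000.0, 4000.0, 6000.0]})
        combined = erp.epoch(eeg, events, baseline_ms=(-300, 0))
        deferred = erp.apply_baseline(
            erp.epoch(eeg, events, baseline_ms=None), (-300, 0))
        np.testing.assert_array_equal(combined.data, deferred.data)


class TestRejection:
    def test_boundary_cases(self, rng):
        eps = make_epochs(rng, n_ep=4)
        eps.data[:] = 0.0
        eps.data[0, 0, 10] = 99.9
        eps.data[1, 1, 20] = 100.1
        eps.data[2, 2, 30] = -100.1
        eps.data[3, 0, 0] = 100.0  # exactly at threshold: retained
        out = erp.reject_artifacts(eps, threshold_uv=100.0)
        assert out.retained.tolist() == [True, False, False, True]

    def test_mask_matches_brute_force(self, rng):
        eps = make_epochs(rng, n_ep=1000, n_ch=2, sfreq=16.0)
        eps.data *= 60.0  # make threshold crossings common
        out = erp.reject_artifacts(eps, threshold_uv=100.0)
        oracle = np.ones(len(eps), dtype=bool)
        for i in range(len(eps)):
            for c in range(eps.data.shape[1]):
                for s in range(eps.data.shape[2]):
                    if abs(eps.data[i, c, s]) > 100.0:
                        oracle[i] = False
        np.testing.assert_array_equal(out.retained, oracle)


class TestInclusion:
    def test_all_retained_included(self, rng):
        assert erp.include_participant(make_epochs(rng)) is True

    def test_half_retained_cell_excluded(self, rng):
        eps = make_epochs(rng, n_ep=24)
        cell = (eps.labels["tp_class"] == "high") & (eps.labels["half"] == 1)
        idx = np.flatnonzero(cell)
        eps.retained[idx[: len(idx) // 2]] = False  # 50% < 2/3
        assert erp.include_participant(eps) is False

    def test_exactly_two_thirds_included(self, rng):
        eps = make_epochs(rng, n_ep=24)  # 6 epochs per cell
        idx = np.flatnonzero((eps.labels["tp_class"] == "low")
                             & (eps.labels["half"] == 2))
        eps.retained[idx[:2]] = False  # 4/6 = 2/3 exactly
        assert erp.include_participant(eps) is True


class TestAveragingAndROIs:
    def test_identical_epochs_average_to_themselves(self, rng):
        eps = make_epochs(rng, n_ep=8)
        eps.data[:] = eps.data[0]
        erps = erp.condition_erps(eps)
        for wave in erps.values():
            np.testing.assert_allclose(wave, eps.data[0])

    def test_opposite_epochs_cancel(self, rng):
        eps = make_epochs(rng, n_ep=8)
        eps.data[::2] = 1.0
        eps.data[1::2] = -1.0
        for wave in erp.condition_erps(eps).values():
            np.testing.assert_allclose(wave, 0.0)

    def test_rejected_epochs_excluded_from_average(self, rng):
        eps = make_epochs(rng, n_ep=8)
        eps.data[:] = 1.0
        eps.data[0] = 100.0
        eps.retained[0] = False
        key = ("implicit", "high", 1)
        np.testing.assert_allclose(erp.condition_erps(eps)[key], 1.0)

    def test_grand_average_equals_mean_of_means(self, rng):
        waves = [erp.condition_erps(make_epochs(rng, n_ep=8))
                 for _ in range(3)]
        key = ("implicit", "high", 1)
        grand = np.mean([w[key] for w in waves], axis=0)
        np.testing.assert_allclose(
            grand, sum(w[key] for w in waves) / 3)

    def test_constant_waveform_roi_mean(self):
        ch = list(erp.CANONICAL_ROIS["central"])
        wave = np.full((9, 100), -5.0)
        times = np.linspace(-300, 1200, 100)
        roi = erp.RoiSpec("central", tuple(ch), (350, 450))
        assert erp.roi_window_mean(wave, times, ch, roi) == -5.0

    def test_canonical_central_roi(self):
        central = erp.CANONICAL_ROIS["central"]
        assert len(central) == 9 and "CPz" in central

    def test_roi_mean_matches_double_loop(self, rng):
        ch = [f"ch{i}" for i in range(5)]
        wave = rng.normal(size=(5, 200))
        times = np.linspace(-300, 1200, 200)
        roi = erp.RoiSpec("custom", ("ch1", "ch3"), (80, 120))
        total, count = 0.0, 0
        for c in ("ch1", "ch3"):
            for s in range(200):
                if 80 <= times[s] <= 120:
                    total += wave[ch.index(c), s]
                    count += 1
        assert erp.roi_window_mean(wave, times, ch, roi) == pytest.approx(
            total / count)

    def test_missing_electrode_reported(self, rng):
        roi = erp.RoiSpec("bad", ("ch0", "nope"), (80, 120))
        with pytest.raises(KeyError, match="nope"):
            erp.roi_window_mean(rng.normal(size=(2, 50)),
                                np.linspace(0, 500, 50), ["ch0", "ch1"], roi)


class TestPipelineProperties:
    def test_linearity(self, rng):
        """Scaling the input EEG by c scales every table amplitude by c
        (rejection disabled: filter, baseline and means are linear)."""
        from syllastream import synthdata as sd

        base = sd.simulate_subject_eeg(
            _tiny_timeline(), _tiny_effects(), task="implicit", seed=3,
            sfreq=64.0)
        events = sd.simulated_event_table(_tiny_timeline(), "implicit")
        tables = []
        for c in (1.0, 3.0):
            eeg = base.copy()
            eeg.data = eeg.data * c
            eeg = erp.bandpass(erp.rereference_mastoids(eeg))
            eps = erp.epoch(eeg, events)
            roi = erp.RoiSpec("central", erp.CANONICAL_ROIS["central"],
                              (350, 450))
            tables.append(erp.build_erp_table({"s": eps}, {"N400": roi}))
        np.testing.assert_allclose(tables[1]["amplitude"],
                                   3.0 * tables[0]["amplitude"], rtol=1e-9)

    def test_epoching_matches_mne(self, rng):
        """Independent oracle: MNE epoching + baseline on the same events."""
        import mne

        sfreq = 128.0
        data = rng.normal(size=(4, int(sfreq * 30)))
        ch = ["Fz", "Cz", "M1", "M2"]
        eeg = erp.ContinuousEEG(ch, sfreq, data)
        onsets = [5000.0, 10_000.0, 15_000.0]
        events = pd.DataFrame({"onset_ms": onsets})
        mine = erp.epoch(eeg, events, window_ms=(-300, 1200),
                         baseline_ms=(-300, 0))

        raw = eeg.to_mne()
        ev = np.array([[round(o / 1000 * sfreq), 0, 1] for o in onsets])
        epochs = mne.Epochs(raw, ev, tmin=-0.3, tmax=1.2,
                            baseline=(None, 0.0), preload=True, proj=False,
                            reject=None, flat=None, verbose="error")
        theirs = epochs.get_data(copy=True) * 1e6
        n = min(mine.data.shape[2], theirs.shape[2])
        np.testing.assert_allclose(mine.data[:, :, :n], theirs[:, :, :n],
                                   atol=1e-6)


def _tiny_timeline():
    from syllastream import lexicon as lx
    from syllastream import stream as sm

    lexicon = lx.load_canonical_syllabary("A")
    seq = sm.generate_word_sequence(lexicon, reps_per_block=1, n_blocks=2,
                                    seed=99)
    return sm.build_timeline(seq)


def _tiny_effects():
    from syllastream import synthdata as sd

    eff = sd.default_effect_spec("adults")
    eff.noise_sd = 5.0
    eff.artifact_rate = 0.0
    return eff
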