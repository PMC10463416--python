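"""Preprocessing: referencing, filters, epoching, ICA, rejection, inclusion."""

import numpy as np
import pytest

import nf1eeg as nf
from nf1eeg.preprocess import _fir_kernel
from nf1eeg.synthetic_eeg import ArtifactSpec, SynthConfig, inject_artifacts

from conftest import NO_ARTIFACTS


def _tone_recording(montage, freqs_amps, rate=512.0, dur_s=20.0):
    n = int(dur_s * rate)
    t = np.arange(n) / rate
    sig = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
    data = np.tile(sig, (montage.n_channels, 1))
    return nf.Recording(data=data, rate=rate, montage=montage, events=[(0, "rest_open")])


class TestRereference:
    def test_channel_equal_to_mastoids_zeroed(self, small_recording):
        rec = small_recording.copy()
        m = rec.montage
        ref = 0.5 * (rec.channel("M1") + rec.channel("M2"))
        rec.data[m.index("Cz")] = ref
        out = nf.rereference(rec, "averaged-mastoids")
        assert np.abs(out.channel("Cz")).max() < 1e-9

    def test_common_average_scalp_sum_zero(self, rest_epochs):
        scalp = rest_epochs.montage.scalp_indices
        sums = rest_epochs.data[:, scalp, :].sum(axis=1)
        assert np.abs(sums).max() < 1e-9

    def test_missing_mastoids_is_configuration_error(self):
        m = nf.Montage(("chx", "chy"), np.array([[0.0, 1.0, 0.0], [0.0, -1.0, 0.0]]),
                       np.array([True, True]))
        rec = nf.Recording(np.zeros((2, 100)), 512.0, m)
        with pytest.raises(ValueError, match="M1"):
            nf.rereference(rec, "averaged-mastoids")


class TestFilterChain:
    def test_output_rate_is_256(self, montage):
        rec = _tone_recording(montage, [(10.0, 5.0)])
        out = nf.filter_chain(rec, "rest")
        assert out.rate == 256.0
        assert out.n_samples == rec.n_samples // 2

    def test_dc_offset_removed(self, montage):
        rec = _tone_recording(montage, [(10.0, 5.0)])
        rec.data += 50.0
        out = nf.filter_chain(rec, "rest")
        steady = out.data[0, out.n_samples // 4 : -out.n_samples // 4]
        assert np.abs(steady.mean()) < 1.0

    def test_notch_attenuation_measured(self, montage):
        """>= 20 dB down at 50 Hz, <= 1 dB at 40 Hz (task profile)."""
        rec = _tone_recording(montage, [(50.0, 10.0), (40.0, 10.0)])
        out = nf.filter_chain(rec, "task")
        mid = slice(out.n_samples // 4, -out.n_samples // 4)
        t = np.arange(out.n_samples)[mid] / out.rate

        def tone_amp(freq):
            c = np.cos(2 * np.pi * freq * t)
            s = np.sin(2 * np.pi * freq * t)
            x = out.data[0, mid]
            return 2 * np.hypot((x * c).mean(), (x * s).mean())

        atten_50 = 20 * np.log10(tone_amp(50.0) / 10.0)
        atten_40 = 20 * np.log10(tone_amp(40.0) / 10.0)
        assert atten_50 <= -20.0
        assert atten_40 >= -1.0

    def test_highpass_edge_within_3db(self):
        h = _fir_kernel("highpass", 512.0, 0.1, None)
        w = np.exp(-2j * np.pi * 0.1 / 512.0 * np.arange(len(h)))
        resp = 20 * np.log10(abs(np.sum(h * w)))
        assert resp <= -3.0

    def test_event_indices_remapped(self, montage):
        rec = _tone_recording(montage, [(10.0, 1.0)])
        rec.events.append((5000, "response"))
        out = nf.filter_chain(rec, "rest")
        assert (2500, "response") in out.events

    def test_low_rate_rejected(self, montage):
        rec = nf.Recording(np.zeros((montage.n_channels, 100)), 128.0, montage)
        with pytest.raises(ValueError):
            nf.filter_chain(rec, "task")


class TestMakeEpochs:
    def test_rest_epochs_mean_centred(self, rest_epochs):
        assert np.abs(rest_epochs.data.mean(axis=2)).max() < 1e-9

    def test_150s_segment_yields_78_epochs(self, montage):
        rate = 256.0
        n = int(150 * rate)
        rec = nf.Recording(np.zeros((montage.n_channels, n)), rate, montage,
                           events=[(0, "rest_open")])
        ep = nf.make_epochs(rec, "rest-arbitrary")
        assert ep.n_epochs == 78

    def test_task_epoch_count_matches_stimuli(self, small_recording, task_epochs):
        n_stim = sum(1 for _, c in small_recording.events if c.startswith("stim_"))
        assert task_epochs.n_epochs == n_stim

    def test_response_classification(self, montage):
        """Hit, miss, false alarm and correct rejection map onto correctness."""
        rate = 256.0
        n = int(30 * rate)
        events = [
            (int(2 * rate), "stim_1back_target"), (int(2.5 * rate), "response"),      # hit
            (int(6 * rate), "stim_1back_target"),                                     # miss
            (int(10 * rate), "stim_1back_nontarget"), (int(10.6 * rate), "response"), # false alarm
            (int(14 * rate), "stim_1back_nontarget"),                                 # correct rejection
        ]
        rec = nf.Recording(np.zeros((montage.n_channels, n)), rate, montage, events=events)
        ep = nf.make_epochs(rec, "task")
        assert list(ep.target) == [True, True, False, False]
        assert list(ep.correct) == [True, False, False, True]

    def test_short_segment_yields_zero_epochs(self, montage, caplog):
        rate = 256.0
        rec = nf.Recording(np.zeros((montage.n_channels, int(3 * rate))), rate, montage,
                           events=[(0, "rest_open"), (int(1.0 * rate), "rest_closed")])
        ep = nf.make_epochs(rec, "rest-arbitrary")
        assert list(ep.conditions).count("eyes_open") == 0
        assert list(ep.conditions).count("eyes_closed") == 1


class TestRejectAndRepair:
    @staticmethod
    def _epochs(montage, n_ep=20, peak_uv=10.0, rate=256.0):
        n_samp = nf.window_n_samples(0.0, 1900.0, rate)
        rng = np.random.default_rng(0)
        data = rng.normal(0, peak_uv / 5, (n_ep, montage.n_channels, n_samp))
        data = np.clip(data, -peak_uv, peak_uv)
        return nf.Epochs(data=data, rate=rate, window_ms=(0.0, 1900.0),
                         conditions=np.array(["eyes_open"] * n_ep, dtype=object),
                         montage=montage)

    def test_amplitude_just_below_threshold_retained(self, montage):
        ep = self._epochs(montage, peak_uv=119.0)
        out = nf.reject_and_repair(ep, 120.0)
        assert out.rejected.sum() == 0

    def test_bad_channel_rule_and_rerun(self, montage):
        """A channel over threshold on 25% of epochs is interpolated and the
        affected epochs re-evaluated without it."""
        ep = self._epochs(montage, n_ep=20, peak_uv=50.0)
        cz = montage.index("Cz")
        ep.data[:5, cz, 100] = 500.0
        out = nf.reject_and_repair(ep, 120.0)
        assert out.bad_channels == {"Cz"}
        assert out.rejected.sum() == 0  # spikes confined to the bad channel
        assert np.abs(out.data[:, cz, :]).max() < 120.0

    def test_interpolation_recovers_smooth_field(self, montage):
        """A low-order harmonic topography is reconstructed within 5% RMS."""
        scalp = montage.scalp_indices
        field = montage.positions[:, 2]  # degree-1 spherical harmonic (z)
        n_samp = nf.window_n_samples(0.0, 1900.0, 256.0)
        data = np.zeros((3, montage.n_channels, n_samp))
        data[:, scalp, :] = 40.0 * field[scalp, None]
        cz = montage.index("Cz")
        truth = data[:, cz, :].copy()
        data[0, cz, 50] = 500.0  # corrupt Cz everywhere it matters
        data[1, cz, 50] = 500.0
        data[2, cz, 50] = 500.0
        ep = nf.Epochs(data=data, rate=256.0, window_ms=(0.0, 1900.0),
                       conditions=np.array(["eyes_open"] * 3, dtype=object), montage=montage)
        out = nf.reject_and_repair(ep, 120.0)
        assert "Cz" in out.bad_channels
        rms_err = np.sqrt(np.mean((out.data[:, cz, :] - truth) ** 2))
        rms_truth = np.sqrt(np.mean(truth**2))
        assert rms_err / rms_truth < 0.05

    def test_rejection_idempotent(self, montage):
        ep = self._epochs(montage, peak_uv=50.0)
        ep.data[3, montage.index("Pz"), 10] = 400.0
        once = nf.reject_and_repair(ep, 120.0)
        twice = nf.reject_and_repair(once, 120.0)
        assert np.array_equal(once.rejected, twice.rejected)
        assert once.bad_channels == twice.bad_channels
        assert np.allclose(once.data, twice.data)

    def test_all_channels_bad_is_fatal(self, montage):
        ep = self._epochs(montage, n_ep=10, peak_uv=10.0)
        ep.data[:, montage.scalp_indices, :] = 500.0
        with pytest.raises(nf.AllChannelsBadError):
            nf.reject_and_repair(ep, 120.0)


@pytest.fixture(scope="module")
def rest_pair():
    """(clean epochs, blink-contaminated epochs) from the same recording."""
    cfg = SynthConfig(seed=21, rest_open_s=30.0, rest_closed_s=0.0, blocks=(),
                      artifacts=NO_ARTIFACTS)
    clean = nf.generate_recording(cfg)
    dirty = inject_artifacts(
        clean, ArtifactSpec(blink_rate_hz=0.4, blink_amp_uv=300.0, saccade_rate_hz=0.0),
        seed=5,
    )

    def prep(rec):
        rr = nf.rereference(rec, "averaged-mastoids")
        return nf.make_epochs(nf.filter_chain(rr, "rest"), "rest-arbitrary")

    return prep(clean), prep(dirty)


class TestOcularIca:
    def test_component_count_is_32(self, rest_pair):
        model, _ = nf.ocular_ica(rest_pair[0], seed=3, max_iter=80)
        assert model.n_components == 32
        assert "TP7" in model.omitted_channels

    def test_artifact_free_input_unchanged(self, rest_pair):
        clean, _ = rest_pair
        model, out = nf.ocular_ica(clean, seed=3, max_iter=80)
        assert model.flagged == frozenset()
        rel = np.sqrt(np.mean((out.data - clean.data) ** 2) / np.mean(clean.data**2))
        assert rel < 0.05

    def test_single_blink_source_flagged_and_removed(self, rest_pair):
        clean, dirty = rest_pair
        model, out = nf.ocular_ica(dirty, seed=3, max_iter=80)
        assert len(model.flagged) == 1
        veog = dirty.data[:, dirty.montage.index("VEOG"), :].ravel()
        fp = dirty.montage.index("Fp1")

        def veog_cov(ep):
            return abs(np.cov(ep.data[:, fp, :].ravel(), veog)[0, 1])

        assert veog_cov(out) < 0.1 * veog_cov(dirty)

    def test_round_trip_on_retained_subspace(self, rest_pair):
        model, _ = nf.ocular_ica(rest_pair[1], seed=3, max_iter=80)
        keep = [k for k in range(32) if k not in model.flagged]
        rng = np.random.default_rng(1)
        x = rng.standard_normal((len(model.used_channels), 64))
        proj = model.mixing[:, keep] @ (model.unmixing[keep] @ x)
        again = model.mixing[:, keep] @ (model.unmixing[keep] @ proj)
        assert np.linalg.norm(again - proj) / np.linalg.norm(proj) < 1e-6


class TestInclusion:
    @staticmethod
    def _epochs(counts, rejected_counts, montage):
        conds, rej = [], []
        for cond, n, nr in counts:
            conds += [cond] * n
            rej += [True] * nr + [False] * (n - nr)
        n_ep = len(conds)
        n_samp = nf.window_n_samples(0.0, 1900.0, 256.0)
        return nf.Epochs(
            data=np.zeros((n_ep, montage.n_channels, n_samp)), rate=256.0,
            window_ms=(0.0, 1900.0), conditions=np.array(conds, dtype=object),
            montage=montage, rejected=np.array(rej),
        )

    def test_fourteen_open_epochs_excludes_rest(self, montage):
        ep = self._epochs([("eyes_open", 20, 6), ("eyes_closed", 20, 0)], None, montage)
        rep = nf.check_inclusion(ep, "rest")
        assert not rep.included
        assert rep.counts["eyes_open"] == 14

    def test_boundary_fifteen_is_inclusive(self, montage):
        ep = self._epochs([("eyes_open", 15, 0), ("eyes_closed", 15, 0)], None, montage)
        assert nf.check_inclusion(ep, "rest").included

    def test_task_exclusion_counts_correct_trials_only(self, montage):
        ep = self._epochs([("1back", 40, 0), ("2back", 20, 0)], None, montage)
        ep.correct = np.array([True] * 40 + [True] * 14 + [False] * 6)
        rep = nf.check_inclusion(ep, "task")
        assert not rep.included
        assert rep.counts == {"1back": 40, "2back": 14}


def test_cleaning_chain_preserves_band_power(rest_epochs, small_recording, montage):
    """End to end on artifact-free data: the cleaning steps (rejection,
    interpolation) move band powers < 0.05 log10 at a fixed reference."""
    rr = nf.rereference(small_recording, "averaged-mastoids")
    raw_ep = nf.make_epochs(nf.filter_chain(rr, "rest"), "rest-arbitrary")
    raw_ep = nf.rereference(raw_ep, "common-average")
    raw_bp = nf.band_power(nf.compute_log_spectrum(raw_ep, condition="eyes_open"),
                           "all_scalp", montage=montage)
    clean_bp = nf.band_power(nf.compute_log_spectrum(rest_epochs, condition="eyes_open"),
                             "all_scalp", montage=montage)
    for band in raw_bp.values:
        assert abs(clean_bp.values[band] - raw_bp.values[band]) < 0.05
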