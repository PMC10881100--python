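import numpy as np
import pytest
from scipy import signal

import hfonet
from hfonet.networks import (
    Network,
    NetworkParams,
    build_fcn,
    build_lan,
    derive_ulan_flan,
    envelope,
    pair_observations,
    preprocess_recording,
    rank_normalize_network,
    sample_background_windows,
    sample_event_windows,
    xcorr_peak,
    SampleWindow,
)

FS = 4096.0


def brute_force_xcorr(x, y, fs, p):
    """Pearson correlation at every admissible integer-sample lag."""
    T = len(x)
    kmax = min(T - 2, int(np.floor(p.max_lag * 1e-3 * fs)))
    best = (-np.inf, None)
    for k in range(-kmax, kmax + 1):
        lag_ms = k * 1000.0 / fs
        if abs(lag_ms) < p.lag_exclusion:
            continue
        if k >= 0:
            xi, yj = x[k:], y[:T - k]
        else:
            xi, yj = x[:T + k], y[-k:]
        if xi.std() == 0 or yj.std() == 0:
            c = 0.0
        else:
            c = float(np.corrcoef(xi, yj)[0, 1])
        if c > best[0]:
            best = (c, lag_ms)
    return best


class TestEnvelope:
    def test_zero_input_gives_zero_envelope(self):
        assert np.allclose(envelope(np.zeros(500), FS), 0.0)

    def test_steady_sinusoid_rms(self):
        t = np.arange(int(0.2 * FS)) / FS
        x = 3.0 * np.sin(2 * np.pi * 200.0 * t)
        env = envelope(x, FS)
        core = env[100:-100]
        assert np.allclose(core, 3.0 / np.sqrt(2), rtol=0.02)

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            envelope(np.zeros(10), FS)

    def test_low_frequency_attenuated_by_elliptic_design(self):
        """A 30 Hz tone is suppressed >= 20 dB relative to 200 Hz after the
        analysis band-pass."""
        p = NetworkParams()
        sos = signal.ellip(p.ellip_order, p.ellip_rp, p.ellip_rs, p.band,
                           btype="bandpass", fs=FS, output="sos")
        t = np.arange(int(1.0 * FS)) / FS
        out200 = signal.sosfiltfilt(sos, np.sin(2 * np.pi * 200 * t))
        out30 = signal.sosfiltfilt(sos, np.sin(2 * np.pi * 30 * t))
        e200 = envelope(out200, FS).mean()
        e30 = envelope(out30, FS).mean()
        assert 20 * np.log10(e200 / e30) >= 20.0


class TestXcorrPeak:
    def test_delayed_copy_negative_lag(self, rng):
        base = np.abs(np.convolve(rng.standard_normal(600), np.ones(30) / 30, "same"))
        d = 20  # samples -> ~4.88 ms
        x = base[50:450]
        y = np.roll(base, d)[50:450]
        c, lag = xcorr_peak(x, y, FS)
        assert c > 0.99
        assert lag == pytest.approx(-d * 1000 / FS)

    def test_identical_envelopes_skip_zero_lag(self, rng):
        x = np.abs(np.convolve(rng.standard_normal(500), np.ones(30) / 30, "same"))
        c, lag = xcorr_peak(x, x, FS)
        assert abs(lag) >= 1.0
        bc, blag = brute_force_xcorr(x, x, FS, NetworkParams())
        assert c == pytest.approx(bc)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_pearson_oracle(self, seed):
        r = np.random.default_rng(seed)
        x = np.abs(np.convolve(r.standard_normal(400), np.ones(20) / 20, "same"))
        y = np.abs(np.convolve(r.standard_normal(400), np.ones(20) / 20, "same"))
        p = NetworkParams()
        c, lag = xcorr_peak(x, y, FS, p)
        bc, blag = brute_force_xcorr(x, y, FS, p)
        assert c == pytest.approx(bc, abs=1e-10)
        assert lag == pytest.approx(blag)

    def test_constant_envelope_returns_zero(self):
        c, lag = xcorr_peak(np.ones(300), np.ones(300), FS)
        assert c == 0.0 and np.isnan(lag)


class TestSampleWindows:
    def test_caps_at_n_samples_per_channel(self, chain_recording, chain_detections):
        rec, _ = chain_recording
        p = NetworkParams(n_samples_per_channel=5)
        w = sample_event_windows(rec, chain_detections, p)
        per_chan = {}
        for win in w:
            per_chan[win.seed_channel] = per_chan.get(win.seed_channel, 0) + 1
        assert all(v <= 5 for v in per_chan.values())

    def test_uses_all_when_fewer_than_cap(self, chain_recording, chain_detections):
        rec, _ = chain_recording
        n_acc = {}
        for e in chain_detections:
            if e.accepted:
                n_acc[e.channel] = n_acc.get(e.channel, 0) + 1
        w = sample_event_windows(rec, chain_detections, NetworkParams())
        per_chan = {}
        for win in w:
            per_chan[win.seed_channel] = per_chan.get(win.seed_channel, 0) + 1
        assert per_chan == n_acc  # every accepted event used (< 500 available)

    def test_zero_recording_gives_zero_envelopes(self):
        rec = hfonet.Recording(np.zeros((2, int(2 * FS))), FS, ["a", "b"])
        ev = [hfonet.HFOEvent("a", 1.0, 1.02, 0.0)]
        w = sample_event_windows(rec, ev, NetworkParams())
        assert len(w) == 1
        assert np.allclose(w[0].envelopes, 0.0)

    def test_edge_event_skipped_with_warning(self):
        rec = hfonet.Recording(np.zeros((2, int(2 * FS))), FS, ["a", "b"])
        ev = [hfonet.HFOEvent("a", 0.01, 0.03, 0.0)]
        with pytest.warns(UserWarning, match="skipped 1"):
            w = sample_event_windows(rec, ev, NetworkParams())
        assert w == []


def _window_from_env(envs):
    return SampleWindow("a", 0.0, np.asarray(envs, float), FS)


class TestBuildFcn:
    def test_single_sample_background_equal_gives_edge_one(self, rng):
        env = np.abs(rng.standard_normal((2, 300)))
        w = [_window_from_env(env)]
        net = build_fcn(w, w, ["a", "b"])
        assert net.weights[0, 1] == pytest.approx(1.0)

    def test_independent_noise_edges_near_one(self, rng):
        p = NetworkParams()
        mk = lambda: [_window_from_env(np.abs(np.convolve(rng.standard_normal(400),
                     np.ones(20) / 20, "same")).reshape(1, -1).repeat(2, 0) * 0
                     + np.vstack([np.abs(np.convolve(rng.standard_normal(400), np.ones(20) / 20, "same")),
                                  np.abs(np.convolve(rng.standard_normal(400), np.ones(20) / 20, "same"))]))
                      for _ in range(60)]
        net = build_fcn(mk(), mk(), ["a", "b"], p)
        assert 0.8 < net.weights[0, 1] < 1.25

    def test_co_discharging_pair_dominates_background(self, chain_recording,
                                                      chain_detections):
        rec, _ = chain_recording
        p = NetworkParams(n_boot=100, background_n=40)
        filtered = preprocess_recording(rec, p)
        r = np.random.default_rng(0)
        w = sample_event_windows(rec, chain_detections, p, filtered=filtered, rng=r)
        bg = sample_background_windows(rec, chain_detections, p, filtered=filtered, rng=r)
        net = build_fcn(w, bg, rec.labels, p)
        assert net.weights[0, 1] > 1.2
        assert np.allclose(net.weights, net.weights.T)
        assert np.all(np.diag(net.weights) == 0)


class TestBuildLan:
    def test_all_negative_lags_give_one_zero(self, rng):
        # windows where channel 0 always leads channel 1 by ~5 ms
        base = np.abs(np.convolve(rng.standard_normal(600), np.ones(40) / 40, "same"))
        wins = []
        for s in range(40):
            b = np.roll(base, s * 7)
            wins.append(_window_from_env([b[:400], np.roll(b, 20)[:400]]))
        lan, dists = build_lan(wins, ["a", "b"], NetworkParams(n_boot=200))
        assert lan.weights[0, 1] > 0.8
        assert lan.weights[1, 0] < 0.1
        assert lan.weights[0, 1] + lan.weights[1, 0] <= 1.0 + 1e-9

    def test_symmetric_lags_give_symmetric_weights(self):
        p = NetworkParams(n_boot=300)
        rng_ = np.random.default_rng(5)
        # synthetic symmetric lag distribution injected via observations
        from hfonet.networks import PairObservation
        lags = np.concatenate([rng_.normal(-8, 1.5, 200), rng_.normal(8, 1.5, 200)])
        obs = [PairObservation(k, (0, 1), 0.9, l) for k, l in enumerate(lags)]
        lan, _ = build_lan([], ["a", "b"], p, observations=obs)
        assert lan.weights[0, 1] == pytest.approx(lan.weights[1, 0], abs=0.1)

    def test_pair_without_observations_gets_zero(self):
        lan, _ = build_lan([], ["a", "b"], NetworkParams())
        assert np.all(lan.weights == 0)

    def test_seeded_bootstrap_is_deterministic(self, rng):
        base = np.abs(np.convolve(rng.standard_normal(600), np.ones(40) / 40, "same"))
        wins = [_window_from_env([np.roll(base, s * 11)[:400],
                                  np.roll(base, s * 11 + 20)[:400]]) for s in range(20)]
        p = NetworkParams(n_boot=100, seed=9)
        lan1, _ = build_lan(wins, ["a", "b"], p)
        lan2, _ = build_lan(wins, ["a", "b"], p)
        assert np.array_equal(lan1.weights, lan2.weights)


class TestDeriveUlanFlan:
    def test_asymmetric_pair(self):
        W = np.array([[0.0, 0.8], [0.2, 0.0]])
        lan = Network("LAN", W, directed=True, labels=["a", "b"])
        ulan, flan = derive_ulan_flan(lan)
        assert ulan.weights[0, 1] == ulan.weights[1, 0] == 0.8
        assert flan.weights[0, 1] == 0.8 and flan.weights[1, 0] == 0.2

    def test_symmetric_lan_passes_through(self):
        W = np.array([[0.0, 0.4], [0.4, 0.0]])
        lan = Network("LAN", W, directed=True, labels=["a", "b"])
        ulan, flan = derive_ulan_flan(lan)
        assert np.allclose(ulan.weights, W)
        assert np.allclose(flan.weights, flan.weights.T)

    def test_zero_lan_gives_zero_derivatives(self):
        lan = Network("LAN", np.zeros((3, 3)), directed=True, labels=list("abc"))
        ulan, flan = derive_ulan_flan(lan)
        assert not np.any(ulan.weights) and not np.any(flan.weights)


class TestRankNormalize:
    def test_ranks_span_unit_interval(self, rng):
        W = rng.uniform(0.1, 5.0, (5, 5))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        net = rank_normalize_network(Network("FCN", W, directed=False,
                                             labels=[f"c{i}" for i in range(5)]))
        vals = W[np.triu_indices(5, 1)]
        got = net.weights[np.triu_indices(5, 1)]
        assert net.normalized == "rank"
        m = len(vals)
        assert got.min() == pytest.approx(1 / m) and got.max() == 1.0
        # rank order preserved; weakest present edge keeps positive weight
        assert np.array_equal(np.argsort(vals), np.argsort(got))

    def test_zero_edges_stay_zero(self):
        W = np.array([[0, 2.0, 0], [2.0, 0, 1.0], [0, 1.0, 0]])
        net = rank_normalize_network(Network("FCN", W, directed=False, labels=list("abc")))
        assert net.weights[0, 2] == 0.0


class TestDirectionalityRecovery:
    def test_embedded_lag_recovered_from_envelopes(self):
        """With near-zero noise, envelope cross-correlation recovers each
        edge's lag on the raw sampling grid."""
        cfg = hfonet.RecordingSimConfig(
            n_channels=2, duration=20.0, noise_sd=1e-3,
            propagation_graph=[(0, 1, 5.0, 1.0)], n_discharges=10,
            event_amplitude=100.0, seed=11)
        rec, gt = hfonet.make_recording(cfg)
        p = NetworkParams()
        from hfonet.detection import bandpass_filter
        bp = bandpass_filter(rec.samples, rec.fs, p.band)
        lags = []
        for ch, on, off, did in gt.events:
            if ch != 0:
                continue
            c = int((on + (off - on) / 2) * rec.fs)
            half = int(0.05 * rec.fs)
            env = envelope(bp[:, c - half:c + half], rec.fs, p)
            corr, lag = xcorr_peak(env[0], env[1], rec.fs, p)
            lags.append(lag)
        # one envelope sample = 1000/fs ms
        assert np.allclose(lags, -5.0, atol=1000 / rec.fs + 1e-9)

    def test_chain_source_has_top_flan_outcloseness(self, chain_recording,
                                                    chain_detections):
        rec, gt = chain_recording
        p = NetworkParams(n_boot=200, background_n=40)
        filtered = preprocess_recording(rec, p)
        w = sample_event_windows(rec, chain_detections, p,
                                 filtered=filtered, rng=np.random.default_rng(0))
        lan, _ = build_lan(w, rec.labels, p)
        _, flan = derive_ulan_flan(lan)
        oc = hfonet.outcloseness_centrality(flan.weights)
        assert int(np.argmax(oc)) == 0  # the planted source
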