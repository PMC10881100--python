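"""HFO functional and lag-asymmetry networks.

Each detected HFO seeds a 100 ms multichannel "sample" window. Windows are
common-average referenced per electrode group, comb-filtered at the mains
frequency, band-passed to 80-500 Hz with an elliptic filter and reduced to a
10 ms sliding-RMS envelope. Pairwise peak cross-correlations of these
envelopes, with lags within +/-1 ms excluded (zero-lag correlation is
attributed to volume conduction, not propagation), define three networks:

* **FCN** -- functional connectivity network: mean peak correlation per pair,
  normalized by the mean peak correlation of event-free background windows;
* **LAN** -- lag-asymmetry network: for each ordered pair (i, j), how likely
  channel i's HFO activity is to *lead* j's, measured as the
  bootstrap-supported kernel-density mass of the pair's peak-lag
  distribution on the i-leads side;
* **uLAN / fLAN** -- the undirected (peak connection per pair) and forward
  (lead-direction) derivatives of the LAN, feeding eigenvector and
  outcloseness centrality respectively.

Filtering is applied once to the full recording and windows are cut from the
filtered signal; away from window edges this is identical to per-window
filtering and avoids per-window filter transients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from hfonet.detection import HFOEvent
from hfonet.recording import Recording, common_average_reference


@dataclass
class NetworkParams:
    """Parameters of the network-construction stage.

    Defaults follow the analysis conventions: 500 event windows per channel,
    100 ms windows, 60 Hz comb filter, 80-500 Hz elliptic band-pass, 10 ms
    RMS envelopes advanced one raw sample at a time (so lag resolution stays
    on the raw sampling grid), +/-1 ms lag exclusion and a 45 ms maximum lag
    (just under half the window).
    """

    n_samples_per_channel: int = 500
    window: float = 100.0            # ms
    comb_base: float = 60.0          # Hz
    comb_q: float = 30.0
    band: tuple[float, float] = (80.0, 500.0)
    ellip_order: int = 4
    ellip_rp: float = 0.5            # dB passband ripple
    ellip_rs: float = 40.0           # dB stopband attenuation
    rms_window: float = 10.0         # ms
    lag_exclusion: float = 1.0       # ms
    max_lag: float = 45.0            # ms
    kde_bandwidth: float | None = None   # ms; None = Silverman's rule
    n_boot: int = 1000
    background_n: int = 100          # surrogate windows per channel
    background_clearance: float = 0.5  # s from any detection
    rank_normalize: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.lag_exclusion < self.max_lag < self.window / 2):
            raise ValueError("require 0 < lag_exclusion < max_lag < window/2")
        if self.n_samples_per_channel < 1:
            raise ValueError("n_samples_per_channel must be positive")


@dataclass
class SampleWindow:
    """One event-triggered (or background) multichannel envelope window."""

    seed_channel: str | None
    center_time: float
    envelopes: np.ndarray     # channels x envelope length, >= 0
    fs: float                 # envelope sampling grid (raw fs; hop = 1 sample)


@dataclass
class PairObservation:
    """Peak correlation and signed peak lag for one pair in one window."""

    sample_id: int
    pair: tuple[int, int]
    peak_corr: float
    peak_lag: float           # ms; negative = first channel leads


@dataclass
class Network:
    """An N x N weighted adjacency with its normalization state."""

    kind: str                 # FCN | LAN | uLAN | fLAN
    weights: np.ndarray
    directed: bool
    labels: list[str]
    normalized: str = "raw"   # raw | rank

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if len(self.labels) != n:
            raise ValueError("one label per node required")
        np.fill_diagonal(self.weights, 0.0)
        if not self.directed and not np.allclose(self.weights, self.weights.T):
            raise ValueError(f"{self.kind} must be symmetric")


def preprocess_recording(rec: Recording, p: NetworkParams) -> np.ndarray:
    """CAR per group, comb filter at the mains base, elliptic band-pass.

    Returns the filtered channels x time array used for window extraction.
    """
    car = common_average_reference(rec)
    x = car.samples
    # comb filter at the mains base: cascade of notches at every harmonic
    # inside the analysis band (iircomb proper needs fs divisible by the base)
    f0 = p.comb_base
    while f0 <= min(p.band[1] + p.comb_base, rec.fs / 2 * 0.95):
        b, a = signal.iirnotch(f0, p.comb_q, fs=rec.fs)
        x = signal.filtfilt(b, a, x, axis=-1)
        f0 += p.comb_base
    sos = signal.ellip(p.ellip_order, p.ellip_rp, p.ellip_rs, p.band,
                       btype="bandpass", fs=rec.fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def envelope(window: np.ndarray, fs: float, p: NetworkParams | None = None) -> np.ndarray:
    """Sliding-RMS envelope of a band-passed window, hop = 1 raw sample.

    The output has length ``T - n + 1`` for an ``n``-sample RMS window
    ('valid' windows only, so every value averages a full window).
    """
    p = p or NetworkParams()
    x = np.asarray(window, dtype=float)
    n = int(round(p.rms_window * 1e-3 * fs))
    if x.shape[-1] < n:
        raise ValueError("window shorter than the RMS window")
    sq = x ** 2
    c = np.cumsum(sq, axis=-1)
    zero = np.zeros(sq.shape[:-1] + (1,))
    c = np.concatenate([zero, c], axis=-1)
    ms = (c[..., n:] - c[..., :-n]) / n
    return np.sqrt(np.maximum(ms, 0.0))


def _window_bounds(center: float, fs: float, window_ms: float, n_total: int):
    half = int(round(window_ms * 1e-3 * fs / 2))
    c = int(round(center * fs))
    a, b = c - half, c + half
    if a < 0 or b > n_total:
        return None
    return a, b


def sample_event_windows(
    rec: Recording,
    events: list[HFOEvent],
    p: NetworkParams | None = None,
    filtered: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> list[SampleWindow]:
    """Event-triggered envelope windows, up to 500 per channel.

    Per channel, ``min(n_available, n_samples_per_channel)`` accepted events
    are sampled without replacement (seeded); each yields a full-band-filtered
    100 ms multichannel window centred on the detection, reduced to its RMS
    envelope. Events too close to a recording edge for a full window are
    skipped (the skip count is reported as a warning).
    """
    p = p or NetworkParams()
    p.validate()
    rng = rng or np.random.default_rng(p.seed)
    if filtered is None:
        filtered = preprocess_recording(rec, p)

    by_channel: dict[str, list[HFOEvent]] = {lab: [] for lab in rec.labels}
    for ev in events:
        if ev.accepted:
            by_channel[ev.channel].append(ev)

    windows: list[SampleWindow] = []
    n_skipped = 0
    for label in rec.labels:
        evs = by_channel[label]
        if len(evs) > p.n_samples_per_channel:
            idx = rng.choice(len(evs), size=p.n_samples_per_channel, replace=False)
            evs = [evs[i] for i in sorted(idx)]
        for ev in evs:
            bounds = _window_bounds(ev.center, rec.fs, p.window, rec.n_samples)
            if bounds is None:
                n_skipped += 1
                continue
            a, b = bounds
            env = envelope(filtered[:, a:b], rec.fs, p)
            windows.append(SampleWindow(label, ev.center, env, rec.fs))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} events too close to a recording edge")
    return windows


def sample_background_windows(
    rec: Recording,
    events: list[HFOEvent],
    p: NetworkParams | None = None,
    filtered: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> list[SampleWindow]:
    """Event-free surrogate windows for FCN background normalization.

    ``background_n`` window centers are drawn uniformly from times at least
    ``background_clearance`` seconds from every detection, then preprocessed
    identically to event windows.
    """
    p = p or NetworkParams()
    rng = rng or np.random.default_rng(p.seed + 1)
    if filtered is None:
        filtered = preprocess_recording(rec, p)
    half_s = p.window * 1e-3 / 2
    lo, hi = half_s, rec.duration - half_s
    if hi <= lo:
        raise ValueError("recording shorter than one analysis window")
    centers_ev = np.array([ev.center for ev in events]) if events else np.empty(0)

    windows: list[SampleWindow] = []
    attempts = 0
    while len(windows) < p.background_n and attempts < 50 * p.background_n:
        attempts += 1
        t = rng.uniform(lo, hi)
        if centers_ev.size and np.min(np.abs(centers_ev - t)) < p.background_clearance:
            continue
        bounds = _window_bounds(t, rec.fs, p.window, rec.n_samples)
        if bounds is None:
            continue
        a, b = bounds
        windows.append(SampleWindow(None, t, envelope(filtered[:, a:b], rec.fs, p), rec.fs))
    if len(windows) < p.background_n:
        warnings.warn(
            f"only {len(windows)} of {p.background_n} background windows found "
            "clear of detections"
        )
    return windows


def xcorr_peak(
    env_i: np.ndarray,
    env_j: np.ndarray,
    fs: float,
    p: NetworkParams | None = None,
) -> tuple[float, float]:
    """Peak normalized cross-correlation of two envelopes outside the lag
    exclusion zone.

    The correlation at integer-sample lag ``k`` is the Pearson correlation of
    ``env_i[t + k]`` with ``env_j[t]`` over their overlap, so a *negative*
    returned lag means channel i leads channel j. Only lags with
    ``lag_exclusion <= |lag| <= max_lag`` (ms) are admissible. Returns
    ``(peak_corr, peak_lag_ms)``; a constant envelope yields ``(0.0, nan)``.
    """
    p = p or NetworkParams()
    x = np.asarray(env_i, dtype=float)
    y = np.asarray(env_j, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("envelopes must be equal-length 1-D sequences")
    T = x.size
    if x.std() == 0 or y.std() == 0:
        return 0.0, float("nan")

    kmax = min(T - 2, int(np.floor(p.max_lag * 1e-3 * fs)))
    lags = np.arange(-kmax, kmax + 1)
    lag_ms = lags * 1000.0 / fs
    admissible = np.abs(lag_ms) >= p.lag_exclusion
    if not admissible.any():
        return 0.0, float("nan")

    # windowed sums via cumulative sums; cross products via np.correlate
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cx2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cy2 = np.concatenate([[0.0], np.cumsum(y * y)])
    full = np.correlate(x, y, mode="full")  # index (T-1)+k holds sum_t x[t+k] y[t]

    n = T - np.abs(lags)
    kpos = np.maximum(lags, 0)
    kneg = np.maximum(-lags, 0)
    sx = cx[T - kneg] - cx[kpos]
    sy = cy[T - kpos] - cy[kneg]
    sx2 = cx2[T - kneg] - cx2[kpos]
    sy2 = cy2[T - kpos] - cy2[kneg]
    sxy = full[(T - 1) + lags]

    cov = sxy - sx * sy / n
    vx = sx2 - sx * sx / n
    vy = sy2 - sy * sy / n
    denom = np.sqrt(np.maximum(vx, 0.0) * np.maximum(vy, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cov / denom, 0.0)
    corr = np.clip(corr, -1.0, 1.0)

    corr_adm = np.where(admissible, corr, -np.inf)
    best = int(np.argmax(corr_adm))
    return float(corr[best]), float(lag_ms[best])


def pair_observations(windows: list[SampleWindow],
                      p: NetworkParams | None = None) -> list[PairObservation]:
    """Peak correlation/lag for every unordered channel pair in every window."""
    p = p or NetworkParams()
    obs: list[PairObservation] = []
    for sid, w in enumerate(windows):
        C = w.envelopes.shape[0]
        for i in range(C):
            for j in range(i + 1, C):
                c, lag = xcorr_peak(w.envelopes[i], w.envelopes[j], w.fs, p)
                obs.append(PairObservation(sid, (i, j), c, lag))
    return obs


def build_fcn(
    samples: list[SampleWindow],
    background_samples: list[SampleWindow],
    labels: list[str],
    p: NetworkParams | None = None,
) -> Network:
    """Functional connectivity network: background-normalized mean peak
    correlation per pair.

    ``FCN[i, j]`` is the mean over event windows of the pair's peak envelope
    correlation, divided by the same mean over event-free background windows.
    Values near 1 therefore mean "no more correlated than background"; a pair
    with zero background mean gets weight 0 with a warning.
    """
    p = p or NetworkParams()
    n = len(labels)
    ev = _mean_peak_corr(samples, n, p)
    bg = _mean_peak_corr(background_samples, n, p)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if bg[i, j] > 0:
                W[i, j] = W[j, i] = max(0.0, ev[i, j] / bg[i, j])
            elif ev[i, j] != 0:
                warnings.warn(f"zero background correlation for pair ({i},{j}); edge set to 0")
    return Network("FCN", W, directed=False, labels=list(labels))


def _mean_peak_corr(windows: list[SampleWindow], n: int, p: NetworkParams) -> np.ndarray:
    acc = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for w in windows:
        for i in range(n):
            for j in range(i + 1, n):
                c, _ = xcorr_peak(w.envelopes[i], w.envelopes[j], w.fs, p)
                acc[i, j] += c
                cnt[i, j] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    return out


def _gaussian_kde_grid(lags: np.ndarray, grid: np.ndarray, bw: float) -> np.ndarray:
    """Gaussian KDE evaluated on a grid (density per ms)."""
    z = (grid[:, None] - lags[None, :]) / bw
    K = np.exp(-0.5 * z * z) / (bw * np.sqrt(2 * np.pi))
    return K.mean(axis=1)


def _silverman_bw(lags: np.ndarray) -> float:
    n = lags.size
    sd = lags.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(lags, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return 1.0  # ms; degenerate point mass
    return 0.9 * spread * n ** (-0.2)


def lead_probability(
    lags_ms: np.ndarray,
    p: NetworkParams,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Bootstrap-supported KDE mass of a lag distribution on each side.

    Returns ``(w_lead, w_lag)``: the kernel-density mass on the negative
    (first-channel-leads) and positive sides of the pair's peak-lag
    distribution, restricted to grid regions where the bootstrap 95%
    pointwise lower confidence band exceeds a uniform null density over
    ``[-max_lag, max_lag]``. With fewer than 5 observations the plain side
    fractions are returned (a KDE band is meaningless there).
    """
    lags = np.asarray(lags_ms, dtype=float)
    lags = lags[np.isfinite(lags)]
    if lags.size == 0:
        return 0.0, 0.0
    if lags.size < 5 or np.ptp(lags) == 0:
        return float(np.mean(lags < 0)), float(np.mean(lags > 0))

    bw = p.kde_bandwidth if p.kde_bandwidth else _silverman_bw(lags)
    grid = np.linspace(-p.max_lag, p.max_lag, 201)
    dens = _gaussian_kde_grid(lags, grid, bw)
    null = 1.0 / (2 * p.max_lag)

    # bootstrap via multinomial reweighting of the kernel matrix
    n = lags.size
    z = (grid[:, None] - lags[None, :]) / bw
    K = np.exp(-0.5 * z * z) / (bw * np.sqrt(2 * np.pi))  # grid x n
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=p.n_boot)  # boot x n
    boot = counts @ K.T / n                                          # boot x grid
    lower = np.percentile(boot, 2.5, axis=0)

    supported = lower > null
    dx = grid[1] - grid[0]
    lead = float(np.sum(dens[supported & (grid <= -p.lag_exclusion)]) * dx)
    lag = float(np.sum(dens[supported & (grid >= p.lag_exclusion)]) * dx)
    return min(lead, 1.0), min(lag, 1.0)


def build_lan(
    samples: list[SampleWindow],
    labels: list[str],
    p: NetworkParams | None = None,
    observations: list[PairObservation] | None = None,
) -> tuple[Network, dict[tuple[int, int], np.ndarray]]:
    """Lag-asymmetry network from per-pair peak-lag distributions.

    For each ordered pair (i, j), the weight is the bootstrap-supported KDE
    mass of the pair's peak-lag distribution on the i-leads (negative-lag)
    side -- an estimate of how likely channel i's HFO activity is to lead
    channel j's. Weights lie in [0, 1] and the two directions of a pair sum
    to at most 1 (the two sides are disjoint regions of one density).

    Returns the directed LAN and the per-unordered-pair lag samples (ms).
    """
    p = p or NetworkParams()
    rng = np.random.default_rng(p.seed + 2)
    n = len(labels)
    if observations is None:
        observations = pair_observations(samples, p)
    lag_lists: dict[tuple[int, int], list[float]] = {}
    for ob in observations:
        if np.isfinite(ob.peak_lag):
            lag_lists.setdefault(ob.pair, []).append(ob.peak_lag)

    W = np.zeros((n, n))
    lag_dists: dict[tuple[int, int], np.ndarray] = {}
    for (i, j), lst in sorted(lag_lists.items()):
        arr = np.asarray(lst)
        lag_dists[(i, j)] = arr
        w_lead, w_lag = lead_probability(arr, p, rng)
        W[i, j] = w_lead   # i leads j
        W[j, i] = w_lag    # j leads i
    return Network("LAN", W, directed=True, labels=list(labels)), lag_dists


def derive_ulan_flan(lan: Network) -> tuple[Network, Network]:
    """Undirected and forward derivatives of the LAN.

    ``uLAN[i, j] = max(LAN[i, j], LAN[j, i])`` keeps the peak connection per
    pair (symmetric, for eigenvector centrality); the fLAN keeps each ordered
    pair's forward-propagation (lead-direction) weight, i.e. the LAN weights
    themselves, for outcloseness centrality.
    """
    if not lan.directed:
        raise ValueError("LAN must be directed")
    W = lan.weights
    ulan = Network("uLAN", np.maximum(W, W.T), directed=False, labels=list(lan.labels),
                   normalized=lan.normalized)
    flan = Network("fLAN", W.copy(), directed=True, labels=list(lan.labels),
                   normalized=lan.normalized)
    return ulan, flan


def rank_normalize_network(net: Network) -> Network:
    """Ordinal-rank normalization of a network's nonzero edge weights.

    Nonzero edges are ranked by weight (ties by node-index order) and mapped
    to ``rank/m`` for ranks 1..m, so edges span ``(0, 1]``. The weakest
    *present* edge deliberately keeps a positive weight: a zero weight means
    an absent edge, and collapsing the weakest edge to zero would delete it
    from every shortest-path computation. Zero (absent) edges stay zero.
    Symmetric networks are ranked on the upper triangle and mirrored.

    This is the optional edge-level normalization path; by default
    (``NetworkParams.rank_normalize = False``) centralities run on raw
    weights and ordinal ranking is applied to the centralities themselves.
    """
    W = net.weights.copy()
    n = W.shape[0]
    if net.directed:
        pairs = [(i, j) for i in range(n) for j in range(n) if i != j and W[i, j] > 0]
    else:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if W[i, j] > 0]
    m = len(pairs)
    out = np.zeros_like(W)
    if m:
        vals = np.array([W[i, j] for i, j in pairs])
        order = np.lexsort((np.arange(m), vals))
        ranks = np.empty(m)
        ranks[order] = np.arange(1, m + 1, dtype=float)
        ranks /= m
        for (i, j), r in zip(pairs, ranks):
            out[i, j] = r
    if not net.directed:
        out = np.maximum(out, out.T)
    return Network(net.kind, out, net.directed, list(net.labels), normalized="rank")
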