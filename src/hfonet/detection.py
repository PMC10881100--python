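"""RMS-threshold HFO detection and artifact redaction.

The detector follows the classical root-mean-square thresholding scheme for
high-frequency oscillations: band-pass the common-average-referenced signal
to 80-500 Hz, compute a short (3 ms) sliding RMS, and accept maximal
supra-threshold intervals (mean + 5 SD of the epoch's RMS) that last at
least 6 ms and contain at least 6 rectified peaks above 3 SD. Detections are
then redacted when they coincide with widespread (likely non-neural) events,
sharp low-frequency transients, or muscle (EMG) activity.

All detector parameters are exposed in :class:`DetectorParams`; the defaults
are conventional values for this detector family, not immutable constants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from hfonet.centrality import ChannelRanking, ordinal_rank_normalize
from hfonet.recording import Recording


@dataclass
class DetectorParams:
    """Parameters of the RMS detector and the artifact-redaction rules.

    Attributes
    ----------
    band
        Detection pass-band in Hz (default 80-500, the ripple + fast-ripple
        range).
    rms_window
        Sliding RMS window, ms.
    rms_threshold
        Detection threshold in SD above the epoch-mean RMS.
    min_duration
        Minimum event duration, ms.
    min_peaks
        Minimum number of rectified peaks above ``peak_threshold`` SD.
    peak_threshold
        Rectified-peak threshold, SD above the rectified epoch mean.
    merge_gap
        Events separated by less than this gap (ms) are merged before the
        duration/peak tests.
    peak_pad
        Context (ms) added on each side of a supra-threshold interval when
        counting rectified peaks: the oscillation extends beyond the maximal
        RMS interval, so peaks are counted over the whole event
        neighbourhood.
    epoch_length
        Thresholds are computed per epoch of this many seconds, so long
        recordings with nonstationary background are handled; shorter
        recordings are treated as a single epoch.
    widespread_fraction, widespread_window
        Detections present on more than this fraction of channels within the
        window (ms) are redacted as widespread.
    sharp_band, sharp_threshold
        A low-frequency (< ``sharp_band`` Hz) excursion above this many SD
        co-timed with a detection redacts it as a sharp transient.
    emg_band, emg_ratio_threshold
        Detections whose ``emg_band`` / detection-band power ratio exceeds
        the threshold are redacted as EMG.
    seizure_buffer
        Minutes of data excluded around each seizure time (seizure times are
        an input; none are assumed here).
    """

    band: tuple[float, float] = (80.0, 500.0)
    rms_window: float = 3.0
    rms_threshold: float = 5.0
    min_duration: float = 6.0
    min_peaks: int = 6
    peak_threshold: float = 3.0
    merge_gap: float = 10.0
    peak_pad: float = 5.0
    epoch_length: float = 600.0
    widespread_fraction: float = 0.5
    widespread_window: float = 10.0
    sharp_band: float = 40.0
    sharp_threshold: float = 6.0
    emg_band: tuple[float, float] = (300.0, 500.0)
    emg_reference_band: tuple[float, float] = (80.0, 200.0)
    emg_ratio_threshold: float = 2.0
    seizure_buffer: float = 30.0

    def validate(self, fs: float) -> None:
        lo, hi = self.band
        if not (0 < lo < hi < fs / 2):
            raise ValueError(f"band {self.band} must lie inside (0, fs/2) = (0, {fs / 2})")
        for name in ("rms_window", "rms_threshold", "min_duration", "merge_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class HFOEvent:
    """One detected oscillation on one channel.

    ``start``/``stop`` are seconds from recording start, half-open
    ``[start, stop)``. ``accepted`` is cleared by redaction, with
    ``rejection_reason`` one of ``sharp_transient`` / ``widespread`` /
    ``emg``.
    """

    channel: str
    start: float
    stop: float
    peak_amplitude: float
    accepted: bool = True
    rejection_reason: str | None = None

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("event stop must exceed start")

    @property
    def duration(self) -> float:
        return self.stop - self.start

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.stop)


def bandpass_filter(x: np.ndarray, fs: float, band: tuple[float, float],
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def sliding_rms(x: np.ndarray, n: int) -> np.ndarray:
    """Centered sliding-window RMS with edge-shrunk windows (same length)."""
    if n < 1:
        raise ValueError("window must span at least one sample")
    sq = np.asarray(x, float) ** 2
    kernel = np.ones(n) / n
    ms = signal.convolve(sq, kernel, mode="same") if sq.ndim == 1 else np.apply_along_axis(
        lambda r: signal.convolve(r, kernel, mode="same"), -1, sq)
    return np.sqrt(np.maximum(ms, 0.0))


def _merge_intervals(intervals: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    if not intervals:
        return []
    merged = [list(intervals[0])]
    for a, b in intervals[1:]:
        if a - merged[-1][1] < gap:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def staba_detect(rec: Recording, p: DetectorParams | None = None) -> list[HFOEvent]:
    """Detect candidate HFOs on every channel of a CAR-referenced recording.

    Per channel and per epoch, events are maximal intervals where the
    band-passed sliding RMS exceeds ``mean + rms_threshold * SD`` of the
    epoch's RMS. Intervals closer than ``merge_gap`` are merged, then
    filtered by minimum duration and by the rectified-peak count
    (``min_peaks`` local maxima of the rectified band-passed signal above
    ``peak_threshold`` SD).

    Returns events sorted by (channel order, start time); all returned
    events are accepted (redaction is a separate pass).
    """
    p = p or DetectorParams()
    p.validate(rec.fs)
    fs = rec.fs
    nyq_guard = p.band[1] < fs / 2
    if not nyq_guard:
        raise ValueError("detection band exceeds the Nyquist frequency")

    filtered = bandpass_filter(rec.samples, fs, p.band)
    n_rms = max(1, int(round(p.rms_window * 1e-3 * fs)))
    n_min = int(round(p.min_duration * 1e-3 * fs))
    n_gap = int(round(p.merge_gap * 1e-3 * fs))
    n_epoch = max(1, int(round(p.epoch_length * fs)))

    events: list[HFOEvent] = []
    for ci, label in enumerate(rec.labels):
        bp = filtered[ci]
        rms = sliding_rms(bp, n_rms)
        rect = np.abs(bp)
        for e0 in range(0, rec.n_samples, n_epoch):
            e1 = min(e0 + n_epoch, rec.n_samples)
            seg_rms = rms[e0:e1]
            thr = seg_rms.mean() + p.rms_threshold * seg_rms.std()
            peak_thr = rect[e0:e1].mean() + p.peak_threshold * rect[e0:e1].std()
            above = seg_rms > thr
            if not above.any():
                continue
            edges = np.diff(above.astype(np.int8))
            starts = list(np.flatnonzero(edges == 1) + 1)
            stops = list(np.flatnonzero(edges == -1) + 1)
            if above[0]:
                starts.insert(0, 0)
            if above[-1]:
                stops.append(e1 - e0)
            intervals = _merge_intervals(list(zip(starts, stops)), n_gap)
            n_pad = int(round(p.peak_pad * 1e-3 * fs))
            for a, b in intervals:
                if b - a < n_min:
                    continue
                seg = rect[max(0, e0 + a - n_pad):min(rec.n_samples, e0 + b + n_pad)]
                if len(seg) >= 3:
                    pk, _ = signal.find_peaks(seg, height=peak_thr)
                    n_pk = len(pk)
                else:
                    n_pk = 0
                if n_pk < p.min_peaks:
                    continue
                events.append(HFOEvent(
                    channel=label,
                    start=(e0 + a) / fs,
                    stop=(e0 + b) / fs,
                    peak_amplitude=float(np.max(rect[e0 + a:e0 + b])),
                ))
    events.sort(key=lambda e: (rec.labels.index(e.channel), e.start))
    return events


def redact_artifacts(events: list[HFOEvent], rec: Recording,
                     p: DetectorParams | None = None) -> list[HFOEvent]:
    """Redact artifactual detections; accepted events pass through unchanged.

    Three rules, applied in order of precedence:

    * **widespread** -- detections co-occurring (centers within
      ``widespread_window``) on more than ``widespread_fraction`` of channels
      are most likely globally coherent noise;
    * **sharp_transient** -- a low-frequency (< ``sharp_band`` Hz) excursion
      beyond ``sharp_threshold`` SD overlapping the event marks an HFO riding
      on a sharp transient (filter ringing produces spurious band power);
    * **emg** -- a high ``emg_band`` / reference-band power ratio within the
      event window marks broadband muscle activity.

    Redaction never increases the accepted count and is idempotent.
    """
    p = p or DetectorParams()
    if not events:
        return []
    fs = rec.fs
    out = [replace(ev) for ev in events]
    accepted = [ev for ev in out if ev.accepted]

    # widespread: cluster accepted events by center time
    centers = np.array([ev.center for ev in accepted])
    chans = np.array([ev.channel for ev in accepted], dtype=object)
    win = p.widespread_window * 1e-3
    n_needed = p.widespread_fraction * rec.n_channels
    for k, ev in enumerate(accepted):
        near = np.abs(centers - centers[k]) <= win
        if len(set(chans[near])) > n_needed:
            ev.accepted = False
            ev.rejection_reason = "widespread"

    # sharp transients: low-frequency excursion co-timed with the event
    sos_lo = signal.butter(4, p.sharp_band, btype="lowpass", fs=fs, output="sos")
    low = signal.sosfiltfilt(sos_lo, rec.samples, axis=-1)
    lo_mean = low.mean(axis=-1, keepdims=True)
    lo_sd = low.std(axis=-1, keepdims=True)
    lo_sd[lo_sd == 0] = np.inf
    excursion = np.abs(low - lo_mean) > p.sharp_threshold * lo_sd
    for ev in accepted:
        if not ev.accepted:
            continue
        ci = rec.channel_index(ev.channel)
        a, b = int(ev.start * fs), max(int(ev.start * fs) + 1, int(ev.stop * fs))
        if excursion[ci, a:b].any():
            ev.accepted = False
            ev.rejection_reason = "sharp_transient"

    # EMG: band power ratio inside the event window
    for ev in accepted:
        if not ev.accepted:
            continue
        ci = rec.channel_index(ev.channel)
        pad = int(0.02 * fs)  # 20 ms context so Welch has support
        a = max(0, int(ev.start * fs) - pad)
        b = min(rec.n_samples, int(ev.stop * fs) + pad)
        seg = rec.samples[ci, a:b]
        if len(seg) < 16:
            continue
        f, pxx = signal.periodogram(seg, fs=fs)
        emg = pxx[(f >= p.emg_band[0]) & (f <= p.emg_band[1])].sum()
        ref = pxx[(f >= p.emg_reference_band[0]) & (f <= p.emg_reference_band[1])].sum()
        if ref > 0 and emg / ref > p.emg_ratio_threshold:
            ev.accepted = False
            ev.rejection_reason = "emg"
    return out


def rank_hfo_rate(events: list[HFOEvent], labels: list[str]) -> ChannelRanking:
    """Ranked HFO rate: ordinal rank of accepted-event counts per channel.

    The lowest-count channel is ranked 0, the highest N-1, normalized by the
    largest rank so scores span [0, 1]. Only accepted events are counted;
    ties are broken by channel-label order.
    """
    if len(labels) < 2:
        raise ValueError("rank normalization requires at least 2 channels")
    counts = np.zeros(len(labels))
    index = {lab: i for i, lab in enumerate(labels)}
    for ev in events:
        if ev.accepted:
            counts[index[ev.channel]] += 1
    return ChannelRanking("HFO-RATE", list(labels), counts,
                          ordinal_rank_normalize(counts, labels))
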