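"""Synthetic recordings and cohorts with known ground truth.

Two generators make every downstream stage testable without clinical data:

* :func:`make_recording` builds a multichannel signal of 1/f ("pink")
  background noise with embedded Gaussian-windowed oscillatory bursts that
  propagate across a hidden directed channel graph with per-edge millisecond
  lags and amplitude attenuation, plus solitary bursts and optional sharp
  / EMG / global artifacts. Ground truth lists every embedded event.
* :func:`make_feature_cohort` builds cohort-level patient feature sets
  (four channel rankings, SOZ and resection sets, outcome labels) whose
  class separation is controlled by a single enrichment parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from hfonet.centrality import MEASURES, ChannelRanking, ordinal_rank_normalize
from hfonet.exceptions import ConfigurationError
from hfonet.features import PatientAnnotation, classify_surgery, soz_resection_percentage
from hfonet.recording import Recording


# ---------------------------------------------------------------------------
# signal-level simulation
# ---------------------------------------------------------------------------

@dataclass
class RecordingSimConfig:
    """Configuration of a simulated intracranial recording.

    ``propagation_graph`` is a directed edge list ``(src, dst, lag_ms,
    attenuation)``: a network discharge starts on a root source channel and
    propagates along edges with the stated millisecond lags (>= 1 ms, so true
    propagation survives the analysis' +/-1 ms lag exclusion) and
    multiplicative amplitude attenuation. Discharges are emitted as a Poisson
    process per root source (or exactly ``n_discharges`` each if set);
    solitary HFOs are independent Poisson per channel.
    """

    n_channels: int = 8
    duration: float = 60.0                # s
    fs: float = 4096.0
    noise_sd: float = 10.0                # uV
    propagation_graph: list[tuple[int, int, float, float]] = field(default_factory=list)
    event_rate: float = 10.0              # discharges/min per source
    n_discharges: int | None = None       # exact count per source, overrides Poisson
    event_freq: float = 150.0             # Hz
    event_duration_ms: float = 50.0
    event_amplitude: float = 80.0         # uV
    solitary_rate: float = 0.0            # events/min per channel
    artifact_spec: dict[str, int] | None = None   # sharp_transient / emg / global counts
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1 or self.duration <= 0 or self.fs <= 0:
            raise ConfigurationError("n_channels, duration and fs must be positive")
        if not (80.0 <= self.event_freq <= 500.0):
            raise ConfigurationError("event_freq must lie in [80, 500] Hz")
        if self.fs <= 2 * 500.0:
            raise ConfigurationError("fs must exceed twice the upper event band (1000 Hz)")
        for src, dst, lag, att in self.propagation_graph:
            if not (0 <= src < self.n_channels and 0 <= dst < self.n_channels):
                raise ConfigurationError(
                    f"graph edge ({src}, {dst}) references a channel outside "
                    f"0..{self.n_channels - 1}")
            if lag < 1.0:
                raise ConfigurationError("edge lags must be >= 1 ms")
            if not (0 < att <= 1):
                raise ConfigurationError("attenuation must lie in (0, 1]")


@dataclass
class SignalGroundTruth:
    """Every embedded event, the per-pair modal lag, and the root sources."""

    events: list[tuple[int, float, float, int | None]]   # (channel, onset, offset, discharge_id)
    true_lag_matrix: np.ndarray                          # ms, nan where unconnected
    source_channels: set[int]

    def events_on(self, channel: int):
        return [e for e in self.events if e[0] == channel]


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int, sd: float) -> np.ndarray:
    """1/f noise by spectral shaping of white noise, per channel, std = sd."""
    if sd == 0:
        return np.zeros((n_channels, n))
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    x_sd = x.std(axis=-1, keepdims=True)
    x_sd[x_sd == 0] = 1.0
    return x / x_sd * sd


def _burst(fs: float, freq: float, dur_s: float, amp: float, phase: float) -> np.ndarray:
    """Gaussian-windowed sinusoid; the window peaks at the burst midpoint."""
    n = int(round(dur_s * fs))
    t = np.arange(n) / fs
    sigma = dur_s / 6.0
    window = np.exp(-0.5 * ((t - dur_s / 2) / sigma) ** 2)
    return amp * window * np.sin(2 * np.pi * freq * t + phase)


def make_recording(cfg: RecordingSimConfig) -> tuple[Recording, SignalGroundTruth]:
    """Simulate a recording with embedded propagating HFO discharges.

    Burst onsets are quantized to the sampling grid, so for every network
    discharge ``onset(dst) - onset(src)`` equals the edge's lag within one
    sample period. Identical configs and seeds give identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    x = _pink_noise(rng, cfg.n_channels, n, cfg.noise_sd)

    dur_s = cfg.event_duration_ms * 1e-3
    margin = dur_s + 0.1 + 0.05  # keep full bursts (incl. max 30 ms lag chains) inside
    events: list[tuple[int, float, float, int | None]] = []

    # adjacency for propagation
    out_edges: dict[int, list[tuple[int, float, float]]] = {}
    graph_nodes: set[int] = set()
    dsts: set[int] = set()
    for src, dst, lag, att in cfg.propagation_graph:
        out_edges.setdefault(src, []).append((dst, lag, att))
        graph_nodes.update((src, dst))
        dsts.add(dst)
    sources = {c for c in graph_nodes if c not in dsts}

    discharge_id = 0
    for root in sorted(sources):
        if cfg.n_discharges is not None:
            k = cfg.n_discharges
        else:
            k = rng.poisson(cfg.event_rate * cfg.duration / 60.0)
        for _ in range(k):
            t0 = rng.uniform(margin, cfg.duration - margin)
            phase = rng.uniform(0, 2 * np.pi)
            # breadth-first propagation; earliest arrival wins per channel
            onset: dict[int, float] = {root: t0}
            amp: dict[int, float] = {root: cfg.event_amplitude}
            frontier = [root]
            while frontier:
                nxt = []
                for c in frontier:
                    for dst, lag, att in out_edges.get(c, []):
                        t_dst = onset[c] + lag * 1e-3
                        if dst not in onset or t_dst < onset[dst]:
                            onset[dst] = t_dst
                            amp[dst] = amp[c] * att
                            nxt.append(dst)
                frontier = nxt
            for c, t in sorted(onset.items()):
                ts = round(t * cfg.fs) / cfg.fs   # quantize to the sample grid
                a = int(round(ts * cfg.fs))
                w = _burst(cfg.fs, cfg.event_freq, dur_s, amp[c], phase)
                b = min(n, a + len(w))
                if a < 0 or a >= n:
                    continue
                x[c, a:b] += w[: b - a]
                events.append((c, ts, ts + dur_s, discharge_id))
            discharge_id += 1

    # solitary HFOs, independent Poisson per channel
    if cfg.solitary_rate > 0:
        for c in range(cfg.n_channels):
            k = rng.poisson(cfg.solitary_rate * cfg.duration / 60.0)
            for _ in range(k):
                t0 = rng.uniform(margin, cfg.duration - margin)
                ts = round(t0 * cfg.fs) / cfg.fs
                a = int(round(ts * cfg.fs))
                w = _burst(cfg.fs, cfg.event_freq, dur_s, cfg.event_amplitude,
                           rng.uniform(0, 2 * np.pi))
                b = min(n, a + len(w))
                x[c, a:b] += w[: b - a]
                events.append((c, ts, ts + dur_s, None))

    _add_artifacts(x, cfg, rng)

    lag_mat = np.full((cfg.n_channels, cfg.n_channels), np.nan)
    for src, dst, lag, _ in cfg.propagation_graph:
        lag_mat[src, dst] = lag

    labels = [f"ch{c:02d}" for c in range(cfg.n_channels)]
    rec = Recording(x, cfg.fs, labels, ["depth"] * cfg.n_channels)
    gt = SignalGroundTruth(sorted(events, key=lambda e: (e[0], e[1])), lag_mat, sources)
    return rec, gt


def _add_artifacts(x: np.ndarray, cfg: RecordingSimConfig, rng: np.random.Generator) -> None:
    spec = cfg.artifact_spec or {}
    n_ch, n = x.shape
    fs = cfg.fs
    amp = 10.0 * cfg.event_amplitude
    for _ in range(spec.get("sharp_transient", 0)):
        c = rng.integers(n_ch)
        t = rng.uniform(0.2, n / fs - 0.2)
        a = int(t * fs)
        m = int(0.08 * fs)  # 80 ms raised-cosine monophasic transient
        bump = amp * 0.5 * (1 - np.cos(2 * np.pi * np.arange(m) / m))
        x[c, a:a + m] += bump[: max(0, min(m, n - a))]
    for _ in range(spec.get("emg", 0)):
        c = rng.integers(n_ch)
        t = rng.uniform(0.2, n / fs - 0.4)
        a = int(t * fs)
        m = int(0.2 * fs)   # 200 ms of high-band noise
        from scipy import signal as _sig
        sos = _sig.butter(4, (300, 500), btype="bandpass", fs=fs, output="sos")
        burst = _sig.sosfilt(sos, rng.standard_normal(m)) * amp / 3
        x[c, a:a + m] += burst[: max(0, min(m, n - a))]
    for _ in range(spec.get("global", 0)):
        t = rng.uniform(0.2, n / fs - 0.2)
        a = int(t * fs)
        m = int(0.03 * fs)  # 30 ms synchronous high-frequency burst everywhere
        t_ = np.arange(m) / fs
        w = np.sin(2 * np.pi * 200 * t_) * np.hanning(m) * amp / 2
        x[:, a:a + m] += w[: max(0, min(m, n - a))]


# ---------------------------------------------------------------------------
# cohort-level simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSimConfig:
    """Configuration of a simulated patient cohort.

    ``enrichment`` controls how strongly the epileptogenic (SOZ) channels
    dominate the four channel rankings: each measure's raw value is standard
    normal noise plus ``enrichment`` on epileptogenic channels, so
    ``enrichment = 0`` makes rankings exchangeable with respect to the SOZ.
    ``resection_quality`` in [0, 1] sets what fraction of each patient's
    resection targets the truly top-ranked channels (drawn uniformly per
    patient from the given range); the outcome is Bernoulli with
    ``P(Class 1) = expit(slope * (mean CReP30 - center))``.
    """

    n_patients: int = 40
    channels_per_patient: tuple[int, int] = (20, 60)
    soz_size: tuple[int, int] = (3, 8)
    rv_size: tuple[int, int] = (5, 15)
    enrichment: float = 2.0
    resection_quality: tuple[float, float] = (0.0, 1.0)
    outcome_link: dict[str, float] = field(default_factory=lambda: {"slope": 8.0, "center": 0.5})
    class2_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("cohort must contain at least one patient")
        if self.soz_size[1] > self.channels_per_patient[0]:
            raise ConfigurationError("soz_size must not exceed channels_per_patient")
        if self.enrichment < 0:
            raise ConfigurationError("enrichment must be >= 0")


@dataclass
class SimulatedPatient:
    """One simulated patient: annotation plus the four channel rankings."""

    patient_id: str
    annotation: PatientAnnotation
    rankings: dict[str, ChannelRanking]
    true_crep30: float          # mean over measures of the true CReP30 overlap
    p_class1: float


@dataclass
class CohortDataset:
    patients: list[SimulatedPatient]
    config: CohortSimConfig

    def __len__(self) -> int:
        return len(self.patients)


def make_feature_cohort(cfg: CohortSimConfig) -> CohortDataset:
    """Simulate a cohort of patients with rankings, SOZ/RV sets and outcomes.

    Per patient: channel count, SOZ and RV sizes are drawn uniformly from
    their ranges; four rankings (one per measure) are built from
    enrichment-boosted noise; the resection mixes top-ranked channels (per
    ``resection_quality``) with random ones; the Engel outcome is drawn from
    the logistic link on the patient's mean true CReP30 overlap.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    from hfonet.features import crep  # local import to avoid cycle at module load

    patients: list[SimulatedPatient] = []
    for pi in range(cfg.n_patients):
        n = int(rng.integers(cfg.channels_per_patient[0], cfg.channels_per_patient[1] + 1))
        labels = [f"ch{c:02d}" for c in range(n)]
        n_soz = int(rng.integers(cfg.soz_size[0], min(cfg.soz_size[1], n) + 1))
        soz_idx = rng.choice(n, size=n_soz, replace=False)
        epi = np.zeros(n, bool)
        epi[soz_idx] = True

        # latent "true epileptogenic importance"; observable rankings are
        # noisy views of the same enrichment signal, so at enrichment 0 the
        # measured rankings carry no information about the latent importance
        latent = rng.standard_normal(n) * 0.1 + cfg.enrichment * epi
        rankings: dict[str, ChannelRanking] = {}
        for m in MEASURES:
            raw = rng.standard_normal(n) + cfg.enrichment * epi
            rankings[m] = ChannelRanking(m, labels, raw, ordinal_rank_normalize(raw, labels))

        # resection: mix of truly-top channels and random ones
        n_rv = int(rng.integers(cfg.rv_size[0], min(cfg.rv_size[1], n) + 1))
        q = rng.uniform(*cfg.resection_quality)
        top_order = np.argsort(-latent, kind="stable")
        n_top = int(round(q * n_rv))
        rv_idx = list(top_order[:n_top])
        rest = [c for c in range(n) if c not in rv_idx]
        rv_idx += list(rng.choice(rest, size=n_rv - n_top, replace=False))
        rv = {labels[c] for c in rv_idx}

        ann = PatientAnnotation(
            channels=labels,
            soz={labels[c] for c in soz_idx},
            rv=rv,
            outcome=1,  # placeholder, set below
        )
        # the outcome link sees the TRUE overlap (resection vs latent
        # importance), never the measured rankings
        true_ranking = ChannelRanking("latent", labels, latent,
                                      ordinal_rank_normalize(latent, labels))
        true_crep30 = crep(true_ranking, ann, 30.0)
        p1 = float(expit(cfg.outcome_link["slope"] * (true_crep30 - cfg.outcome_link["center"])))
        if rng.uniform() < cfg.class2_fraction:
            outcome = 2
        else:
            outcome = 1 if rng.uniform() < p1 else 3
        ann.outcome = outcome
        patients.append(SimulatedPatient(f"sim-{pi:03d}", ann, rankings, true_crep30, p1))
    return CohortDataset(patients, cfg)


def annotation_summary(ann: PatientAnnotation) -> dict:
    """SOZ-resection percentage and DS/PS flag for one annotation."""
    pct = soz_resection_percentage(ann)
    return {"soz_resection_pct": pct, "surgery_type": classify_surgery(pct)}
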