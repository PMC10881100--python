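"""File I/O: EDF recordings, channel tables, event lists, networks, rankings.

Recordings interchange as EDF (16-bit, physical range set from the signal
extrema). Reading goes through :func:`mne.io.read_raw_edf`; writing uses a
minimal EDF writer implemented here (one 1-second data record per second of
signal, microvolt physical units). Tables are CSV, configuration and reports
JSON.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from hfonet.centrality import ChannelRanking
from hfonet.detection import HFOEvent
from hfonet.features import PatientAnnotation
from hfonet.networks import Network
from hfonet.recording import Recording


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _ascii(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF.

    Uses one-second data records (the sampling rate must therefore be a
    whole number of samples per second) and a symmetric physical range taken
    from the signal extrema of each channel. Signals are quantized to the
    16-bit digital range; the round-trip error is bounded by half a physical
    quantization step.
    """
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF export requires an integer number of samples per second")
    n_ch = rec.n_channels
    n_rec = math.ceil(rec.n_samples / spr)
    n_total = n_rec * spr

    x = np.zeros((n_ch, n_total))
    x[:, : rec.n_samples] = rec.samples
    phys_max = np.maximum(np.abs(x).max(axis=1), 1e-6)
    dig_min, dig_max = -32768, 32767

    header = b""
    header += _ascii("0", 8)                                  # version
    header += _ascii("X X X X", 80)                           # patient id (anonymous)
    header += _ascii("Startdate X X X X", 80)                 # recording id
    header += _ascii("01.01.00", 8) + _ascii("00.00.00", 8)   # date, time
    header += _ascii(str(256 * (n_ch + 1)), 8)                # header bytes
    header += _ascii("", 44)                                  # reserved
    header += _ascii(str(n_rec), 8)
    header += _ascii("1", 8)                                  # record duration, s
    header += _ascii(str(n_ch), 4)
    header += b"".join(_ascii(lab, 16) for lab in rec.labels)
    header += b"".join(_ascii(f"{g} EEG", 80) for g in rec.groups)   # transducer
    header += b"".join(_ascii("uV", 8) for _ in range(n_ch))
    header += b"".join(_ascii(f"{-m:.6g}"[:8], 8) for m in phys_max)  # phys min
    header += b"".join(_ascii(f"{m:.6g}"[:8], 8) for m in phys_max)   # phys max
    header += b"".join(_ascii(str(dig_min), 8) for _ in range(n_ch))
    header += b"".join(_ascii(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(_ascii("", 80) for _ in range(n_ch))           # prefiltering
    header += b"".join(_ascii(str(spr), 8) for _ in range(n_ch))
    header += b"".join(_ascii("", 32) for _ in range(n_ch))           # reserved

    scale = (dig_max - dig_min) / (2 * phys_max)
    digital = np.clip(np.round((x + phys_max[:, None]) * scale[:, None] + dig_min),
                      dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())


def read_edf(path: str | Path, channel_table: str | Path | None = None) -> Recording:
    """Read an EDF/EDF+ recording via mne.

    Signals are returned in microvolts. Electrode-group tags are taken from
    a sidecar channel table (CSV with a ``group`` column) when given,
    otherwise every channel defaults to ``depth``.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    labels = list(raw.ch_names)
    data = raw.get_data() * 1e6  # mne stores EEG in volts
    groups = ["depth"] * len(labels)
    if channel_table is not None:
        frag = read_channel_table(channel_table)
        group_map = frag["groups"]
        missing = [lab for lab in group_map if lab not in labels]
        if missing:
            raise ValueError(f"channel table labels not in recording: {missing}")
        groups = [group_map.get(lab, "depth") for lab in labels]
    return Recording(data, fs, labels, groups)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n", ""}


def _parse_bool(value: str, column: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"cannot parse boolean {value!r} in column {column!r}")


def read_channel_table(path: str | Path) -> dict:
    """Read a channel table CSV: ``label,group,soz,resected``.

    Returns a dict with ``labels`` (ordered), ``groups`` (label -> group),
    ``soz`` and ``rv`` (label sets). Booleans accept 0/1/true/false.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = ["label", "group", "soz", "resected"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"channel table is missing column {col!r}")
    labels = list(df["label"])
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate label in channel table")
    soz = {lab for lab, v in zip(labels, df["soz"]) if _parse_bool(v, "soz")}
    rv = {lab for lab, v in zip(labels, df["resected"]) if _parse_bool(v, "resected")}
    groups = dict(zip(labels, df["group"]))
    return {"labels": labels, "groups": groups, "soz": soz, "rv": rv}


def write_channel_table(ann: PatientAnnotation, groups: dict[str, str],
                        path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "group", "soz", "resected"])
        for lab in ann.channels:
            w.writerow([lab, groups.get(lab, "depth"),
                        int(lab in ann.soz), int(lab in ann.rv)])


def write_events_csv(events: list[HFOEvent], path: str | Path) -> None:
    """Event list CSV: channel,start_s,stop_s,peak_amplitude_uV,accepted,rejection_reason."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["channel", "start_s", "stop_s", "peak_amplitude_uV",
                    "accepted", "rejection_reason"])
        for ev in events:
            w.writerow([ev.channel, f"{ev.start:.6f}", f"{ev.stop:.6f}",
                        f"{ev.peak_amplitude:.6g}", int(ev.accepted),
                        ev.rejection_reason or ""])


def read_events_csv(path: str | Path) -> list[HFOEvent]:
    df = pd.read_csv(path)
    events = []
    for _, row in df.iterrows():
        events.append(HFOEvent(
            channel=str(row["channel"]),
            start=float(row["start_s"]),
            stop=float(row["stop_s"]),
            peak_amplitude=float(row["peak_amplitude_uV"]),
            accepted=bool(int(row["accepted"])),
            rejection_reason=(None if pd.isna(row.get("rejection_reason"))
                              or str(row.get("rejection_reason")) == ""
                              else str(row["rejection_reason"])),
        ))
    return events


def write_ground_truth_csv(gt, path: str | Path) -> None:
    """Ground-truth event CSV: channel,onset_s,offset_s,discharge_id."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["channel", "onset_s", "offset_s", "discharge_id"])
        for ch, on, off, did in gt.events:
            w.writerow([ch, f"{on:.6f}", f"{off:.6f}", "" if did is None else did])


def write_network(net: Network, path_csv: str | Path) -> None:
    """Adjacency matrix CSV plus a JSON sidecar with kind/metadata."""
    path_csv = Path(path_csv)
    pd.DataFrame(net.weights, index=net.labels, columns=net.labels).to_csv(path_csv)
    sidecar = path_csv.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "kind": net.kind, "directed": net.directed, "normalized": net.normalized,
        "labels": net.labels,
    }, indent=2, sort_keys=True))


def read_network(path_csv: str | Path) -> Network:
    path_csv = Path(path_csv)
    df = pd.read_csv(path_csv, index_col=0)
    meta = json.loads(path_csv.with_suffix(".json").read_text())
    return Network(meta["kind"], df.to_numpy(), meta["directed"],
                   list(df.columns), normalized=meta["normalized"])


def write_rankings_csv(rankings: dict[str, ChannelRanking], path: str | Path) -> None:
    """Ranking CSV: channel,measure,raw,rank01."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["channel", "measure", "raw", "rank01"])
        for measure, rk in rankings.items():
            for lab, raw, r01 in zip(rk.labels, rk.raw, rk.rank01):
                w.writerow([lab, measure, f"{raw:.8g}", f"{r01:.8g}"])


def write_lag_distributions_csv(lag_dists, labels: list[str], path: str | Path) -> None:
    """Pair lag CSV: i,j,lag_ms (one row per observation)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["i", "j", "lag_ms"])
        for (i, j), lags in sorted(lag_dists.items()):
            for lag in lags:
                w.writerow([labels[i], labels[j], f"{lag:.6f}"])
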