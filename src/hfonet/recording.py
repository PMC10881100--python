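"""Multichannel intracranial recordings and re-referencing.

A :class:`Recording` is the package's in-memory container for an intracranial
EEG segment: a channels x time matrix in microvolts plus sampling rate,
channel labels and per-channel electrode-group tags (``"grid"`` or
``"depth"``). All times are seconds from recording start; intervals are
half-open ``[start, stop)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Recording:
    """An intracranial EEG segment.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``, microvolts.
    fs
        Sampling rate in Hz.
    labels
        Unique channel labels, one per row of ``samples``.
    groups
        Electrode-group tag per channel (``"grid"`` or ``"depth"``). Channels
        in the same group share a common average reference.
    """

    samples: np.ndarray
    fs: float
    labels: list[str]
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not self.groups:
            self.groups = ["depth"] * self.n_channels
        if len(self.groups) != self.n_channels:
            raise ValueError("one group tag per channel required")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        return self.labels.index(label)


def common_average_reference(rec: Recording) -> Recording:
    """Re-reference each electrode group to its common average.

    At every time point, the mean over all channels of a group is subtracted
    from each channel in that group, removing globally coherent activity
    (movement, reference artifacts) within grids and within depth electrodes
    separately. After referencing, each group's per-sample mean is zero.

    Raises
    ------
    ValueError
        If any group contains a single channel (its reference would erase
        the channel entirely).
    """
    groups = np.asarray(rec.groups)
    out = rec.samples.copy()
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if idx.size < 2:
            raise ValueError(
                f"group {g!r} has a single channel; common average reference "
                "requires at least 2 channels per group"
            )
        out[idx] -= out[idx].mean(axis=0, keepdims=True)
    return replace(rec, samples=out)
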