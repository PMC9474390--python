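"""Electrical footprints (EFs).

An EF is the spike-triggered average extracellular waveform of one unit across
all electrodes that sense it: a (channels x samples) array in uV together with
the channel coordinates. The peak channel -- the electrode with the largest
absolute trough amplitude -- is the reference point for latency maps, waveform
clustering and unit tracking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ElectricalFootprint", "peak_channel_of"]


def peak_channel_of(waveform: np.ndarray) -> int:
    """Channel index attaining the maximum absolute trough amplitude.

    The trough is the negative-going deflection; a channel with no negative
    excursion has trough amplitude 0.
    """
    waveform = np.asarray(waveform, dtype=float)
    return int(np.argmax(np.maximum(-waveform.min(axis=1), 0.0)))


@dataclass
class ElectricalFootprint:
    """Per-unit average extracellular waveform.

    Attributes
    ----------
    unit_id : int
    waveform : (n_channels, n_samples) float array, uV
    channel_positions : (n_channels, 2) float array, um
    fs : sampling rate in Hz
    channel_ids : electrode ids of the rows of ``waveform``
    peak_channel : row index of the channel with the largest |trough|
    n_spikes_averaged : number of spikes that went into the average
    """

    unit_id: int
    waveform: np.ndarray
    channel_positions: np.ndarray
    fs: float
    channel_ids: np.ndarray = None
    peak_channel: int = field(default=None)
    n_spikes_averaged: int = 0

    def __post_init__(self):
        self.waveform = np.atleast_2d(np.asarray(self.waveform, dtype=np.float32))
        self.channel_positions = np.asarray(self.channel_positions, dtype=float).reshape(-1, 2)
        if self.channel_positions.shape[0] != self.waveform.shape[0]:
            raise ValueError("channel_positions rows must match waveform channels")
        if self.channel_ids is None:
            self.channel_ids = np.arange(self.waveform.shape[0])
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        if self.peak_channel is None:
            self.peak_channel = peak_channel_of(self.waveform)

    @property
    def n_channels(self) -> int:
        return self.waveform.shape[0]

    @property
    def n_samples(self) -> int:
        return self.waveform.shape[1]

    def peak_waveform(self) -> np.ndarray:
        """Waveform (uV) on the peak channel."""
        return np.asarray(self.waveform[self.peak_channel], dtype=float)

    def peak_position(self) -> np.ndarray:
        """(x, y) position in um of the peak channel."""
        return self.channel_positions[self.peak_channel]

    def trough_amplitudes(self) -> np.ndarray:
        """Absolute trough amplitude (uV) per channel (negative-going only)."""
        return np.maximum(-self.waveform.min(axis=1), 0.0)
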