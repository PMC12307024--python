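"""Minimal signal conditioning for simulated epochs.

Mirrors a conventional steady-state EEG preprocessing chain: a zero-phase
band-pass (0.1-100 Hz by default) with narrow notch filters at the line
frequency and its harmonics (50/100/150 Hz), re-referencing to the mean of
named reference channels, and replacement of a bad channel by the
equal-weighted mean of its montage neighbors.

All filters are applied forward-backward (``sosfiltfilt``) so the phase
of the tagged responses is preserved; the band-pass is a 4th-order
Butterworth in second-order sections and each notch a 2nd-order
Butterworth band-stop of total width ``notch_width`` (default 3 Hz,
giving >= 20 dB rejection of a tone at the notch frequency while leaving
a 54 Hz tag within 3% of its input amplitude). Padding uses the full
epoch length, which matters for the long settling time of the 0.1 Hz
high-pass edge on 2 s epochs.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import signal

from .montage import Montage
from .simulate import EpochSet

__all__ = ["bandpass_notch", "rereference", "interpolate_channel"]


def bandpass_notch(epochs: EpochSet, low: float = 0.1, high: float = 100.0,
                   notches: Sequence[float] = (50.0, 100.0, 150.0),
                   order: int = 4, notch_width: float = 3.0) -> EpochSet:
    """Zero-phase band-pass plus notch filtering of every trial and channel."""
    nyq = epochs.sample_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"require 0 < low < high < Nyquist ({nyq} Hz)")
    for f0 in notches:
        if not (notch_width / 2 < f0 < nyq - notch_width / 2):
            raise ValueError(f"notch frequency {f0} Hz outside (0, {nyq}) Hz")
    padlen = epochs.data.shape[-1] - 1
    sos = signal.butter(order, [low, high], btype="bandpass",
                        fs=epochs.sample_rate, output="sos")
    out = signal.sosfiltfilt(sos, epochs.data, axis=-1, padlen=padlen)
    for f0 in notches:
        stop = signal.butter(2, [f0 - notch_width / 2, f0 + notch_width / 2],
                             btype="bandstop", fs=epochs.sample_rate,
                             output="sos")
        out = signal.sosfiltfilt(stop, out, axis=-1, padlen=padlen)
    return epochs.copy_with(out)


def rereference(epochs: EpochSet, reference_channels: Sequence[str]) -> EpochSet:
    """Subtract the mean of the reference channels from every channel."""
    if not reference_channels:
        raise ValueError("need at least one reference channel")
    idx = [epochs.montage.index(c) for c in reference_channels]
    ref = epochs.data[:, idx, :].mean(axis=1, keepdims=True)
    return epochs.copy_with(epochs.data - ref)


def interpolate_channel(epochs: EpochSet, bad: str,
                        montage: Montage | None = None) -> EpochSet:
    """Replace ``bad`` by the equal-weighted mean of its adjacency neighbors.

    All other channels are untouched. Raises if the channel is isolated.
    """
    montage = montage or epochs.montage
    neighbors = montage.neighbors(bad)
    if not neighbors:
        raise ValueError(f"channel {bad!r} has no neighbors; cannot interpolate")
    nb_idx = [epochs.montage.index(c) for c in neighbors]
    out = epochs.data.copy()
    out[:, epochs.montage.index(bad), :] = epochs.data[:, nb_idx, :].mean(axis=1)
    return epochs.copy_with(out)
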