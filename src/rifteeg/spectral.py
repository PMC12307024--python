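"""Windowed power spectra and the percentage-power-change statistic.

Power convention
----------------
Each 1 s analysis window (baseline or tagging) is multiplied by a
rectangular (boxcar) taper spanning the full window and Fourier
transformed; the native frequency resolution of a 1 s window is 1 Hz, so
the requested 1-80 Hz grid falls exactly on DFT bins. Bin power is
``|X_k / N|**2``, so a unit-amplitude on-grid sinusoid carries bin power
0.25 (= amplitude**2 / 4); no one-sided doubling is applied. Power is
computed per trial and averaged over trials within condition — averaging
power rather than the complex spectrum, so components that are not
phase-locked across trials survive.

The percentage power change is
``((power during tagging - power during baseline) / power during baseline) * 100``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import CONDITIONS, EpochSet

__all__ = ["SpectrumSet", "PercentChangeMap", "windowed_power",
           "percent_change", "intermodulation_freqs"]


@dataclass
class SpectrumSet:
    """Trial-averaged power, (participant, condition, channel, frequency) in µV²."""

    power: np.ndarray
    freqs: np.ndarray
    window: str
    participants: tuple[str, ...]
    conditions: tuple[str, ...]
    channel_names: tuple[str, ...]
    n_trials: np.ndarray  # (participant, condition) trials averaged per cell

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        df = np.diff(self.freqs)
        if self.freqs.size > 1 and not (np.all(df > 0)
                                        and np.allclose(df, df[0])):
            raise ValueError("frequency grid must be strictly increasing and uniform")

    def freq_index(self, f: float) -> int:
        i = np.argmin(np.abs(self.freqs - f))
        if not np.isclose(self.freqs[i], f):
            raise ValueError(f"frequency {f} Hz is not on the analysis grid")
        return int(i)

    def to_frame(self) -> pd.DataFrame:
        """Long format: participant, condition, window, channel, frequency_hz, value."""
        p, c, ch, fr = np.meshgrid(
            np.arange(len(self.participants)), np.arange(len(self.conditions)),
            np.arange(len(self.channel_names)), np.arange(self.freqs.size),
            indexing="ij")
        return pd.DataFrame({
            "participant": np.asarray(self.participants)[p.ravel()],
            "condition": np.asarray(self.conditions)[c.ravel()],
            "window": self.window,
            "channel": np.asarray(self.channel_names)[ch.ravel()],
            "frequency_hz": self.freqs[fr.ravel()],
            "value": self.power.ravel(),
        })


@dataclass
class PercentChangeMap:
    """Percent power change, same axes as the SpectrumSets it came from."""

    pc: np.ndarray
    freqs: np.ndarray
    participants: tuple[str, ...]
    conditions: tuple[str, ...]
    channel_names: tuple[str, ...]

    freq_index = SpectrumSet.freq_index

    def to_frame(self) -> pd.DataFrame:
        p, c, ch, fr = np.meshgrid(
            np.arange(len(self.participants)), np.arange(len(self.conditions)),
            np.arange(len(self.channel_names)), np.arange(self.freqs.size),
            indexing="ij")
        return pd.DataFrame({
            "participant": np.asarray(self.participants)[p.ravel()],
            "condition": np.asarray(self.conditions)[c.ravel()],
            "window": "percent_change",
            "channel": np.asarray(self.channel_names)[ch.ravel()],
            "frequency_hz": self.freqs[fr.ravel()],
            "value": self.pc.ravel(),
        })


def _single_participant_power(epochs: EpochSet, window: str,
                              freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sl = epochs.window_indices(window)
    n = sl.stop - sl.start
    grid = np.fft.rfftfreq(n, 1.0 / epochs.sample_rate)
    bins = []
    for f in freqs:
        k = f * n / epochs.sample_rate
        if abs(k - round(k)) > 1e-9 or round(k) >= grid.size:
            raise ValueError(
                f"requested frequency {f} Hz does not fall on the "
                f"{epochs.sample_rate / n:g} Hz DFT grid of a {n}-sample window")
        bins.append(int(round(k)))
    seg = epochs.data[:, :, sl]  # boxcar taper: the raw full-window segment
    spec = np.fft.rfft(seg, axis=-1) / n
    power = np.abs(spec[:, :, bins]) ** 2  # (trial, channel, freq)
    out = np.empty((len(CONDITIONS), epochs.montage.n_channels, len(bins)))
    counts = np.empty(len(CONDITIONS), dtype=int)
    for j, cond in enumerate(CONDITIONS):
        mask = epochs.condition == cond
        counts[j] = mask.sum()
        out[j] = power[mask].mean(axis=0) if counts[j] else 0.0
    return out, counts


def windowed_power(dataset: EpochSet | Sequence[EpochSet], window: str,
                   f_lo: float = 1.0, f_hi: float = 80.0,
                   step: float = 1.0) -> SpectrumSet:
    """Boxcar-tapered Fourier power on a uniform grid, per participant/condition.

    ``window`` is "baseline" or "tagging". The default grid is 1-80 Hz in
    1 Hz steps; pass ``f_hi=150`` to reach the sum intermodulation
    frequency, which lies above the default grid.
    """
    n_steps = (f_hi - f_lo) / step if step > 0 else -1.0
    if step <= 0 or n_steps < 0 or abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("step must be positive and divide the requested range")
    epochs_list = [dataset] if isinstance(dataset, EpochSet) else list(dataset)
    if not epochs_list:
        raise ValueError("empty dataset")
    freqs = f_lo + step * np.arange(int(round((f_hi - f_lo) / step)) + 1)
    powers, counts = zip(*(_single_participant_power(e, window, freqs)
                           for e in epochs_list))
    first = epochs_list[0]
    return SpectrumSet(power=np.stack(powers), freqs=freqs, window=window,
                       participants=tuple(e.participant_id for e in epochs_list),
                       conditions=CONDITIONS,
                       channel_names=first.montage.channel_names,
                       n_trials=np.stack(counts))


def percent_change(tagging: SpectrumSet, baseline: SpectrumSet) -> PercentChangeMap:
    """((tagging - baseline) / baseline) * 100, element-wise."""
    if tagging.window != "tagging" or baseline.window != "baseline":
        raise ValueError("pass the tagging-window spectrum first, baseline second")
    same = (np.array_equal(tagging.freqs, baseline.freqs)
            and tagging.participants == baseline.participants
            and tagging.conditions == baseline.conditions
            and tagging.channel_names == baseline.channel_names)
    if not same:
        raise ValueError("tagging and baseline spectra have mismatched axes")
    zero = np.argwhere(baseline.power == 0)
    if zero.size:
        p, c, ch, fr = zero[0]
        raise ZeroDivisionError(
            "baseline power is zero (percent change undefined) at participant "
            f"{baseline.participants[p]}, condition {baseline.conditions[c]}, "
            f"channel {baseline.channel_names[ch]}, {baseline.freqs[fr]:g} Hz")
    pc = (tagging.power - baseline.power) / baseline.power * 100.0
    return PercentChangeMap(pc=pc, freqs=tagging.freqs.copy(),
                            participants=tagging.participants,
                            conditions=tagging.conditions,
                            channel_names=tagging.channel_names)


def intermodulation_freqs(f1: float, f2: float) -> dict[str, float]:
    """Difference and sum intermodulation frequencies of two tags (f2 > f1)."""
    if not (f2 > f1 > 0):
        raise ValueError("require f2 > f1 > 0")
    return {"difference": f2 - f1, "sum": f2 + f1}
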