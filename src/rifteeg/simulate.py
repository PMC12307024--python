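"""Synthetic rapid-frequency-tagging EEG.

Generates multi-channel epochs that mimic a picture-word-interference
experiment with rapid invisible frequency tagging: an auditory distractor
whose amplitude is modulated at ``f_audio`` (54 Hz) and a visual target
whose luminance is modulated at ``f_visual`` (68 Hz). During the 1 s
tagging window the simulated cortex produces

* a steady-state response at 54 Hz with a broad topography,
* a steady-state response at 68 Hz with an occipital/central topography,
* a multiplicative (quadratic) interaction of the two drives whose
  product-to-sum expansion lands exactly at the intermodulation
  frequencies ``f_visual - f_audio`` (14 Hz) and ``f_visual + f_audio``
  (122 Hz), with a left-frontal topography.

The interaction gain depends on the trial condition (``related`` vs
``unrelated``); a larger gain in the unrelated condition is the effect the
downstream statistics are meant to detect. The 1 s baseline preceding the
tagging window contains only background activity: 1/f Gaussian noise plus
a 10 Hz alpha oscillation with random phase per trial.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``, so datasets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .montage import Montage, default_montage

__all__ = [
    "TagConfig",
    "SimConfig",
    "EpochSet",
    "CONDITIONS",
    "make_luminance_tag",
    "make_amplitude_tag",
    "frame_schedule_rate",
    "simulate_epoch",
    "simulate_dataset",
    "gaussian_topography",
]

CONDITIONS = ("related", "unrelated")


@dataclass(frozen=True)
class TagConfig:
    """Frequencies and depth of the two stimulus tags.

    ``phase_at_onset`` applies to both tags at tagging onset; the default 0
    makes the drives phase-locked across trials.
    """

    f_audio: float = 54.0
    f_visual: float = 68.0
    modulation_depth: float = 1.0
    phase_at_onset: float = 0.0
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        nyq = self.sample_rate / 2.0
        if self.f_audio == self.f_visual:
            raise ValueError("tag frequencies must differ")
        if not (0 < self.f_audio < nyq and 0 < self.f_visual < nyq):
            raise ValueError(
                f"tag frequencies must lie strictly below the Nyquist "
                f"frequency {nyq} Hz (aliasing)"
            )
        if abs(self.f_visual - self.f_audio) < 1.0:
            raise ValueError("tag frequencies must differ by at least 1 Hz")
        if not (0 <= self.modulation_depth <= 1):
            raise ValueError("modulation_depth must lie in [0, 1]")


def _time_grid(duration: float, sample_rate: float) -> np.ndarray:
    n = duration * sample_rate
    if abs(n - round(n)) > 1e-9 or n <= 0:
        raise ValueError(
            f"duration {duration} s at {sample_rate} Hz does not give an "
            "integer, positive sample count"
        )
    return np.arange(int(round(n))) / sample_rate


def make_luminance_tag(duration: float, tag: TagConfig) -> np.ndarray:
    """Unit-range luminance modulation waveform for the visual tag.

    Returns ``0.5 * (1 + depth * sin(2*pi*f_visual*t + phase))`` sampled at
    ``tag.sample_rate``; values lie in [0, 1]. Deterministic in its
    arguments (phase-locked across trials).
    """
    t = _time_grid(duration, tag.sample_rate)
    return 0.5 * (1.0 + tag.modulation_depth
                  * np.sin(2 * np.pi * tag.f_visual * t + tag.phase_at_onset))


def make_amplitude_tag(audio_envelope: np.ndarray, tag: TagConfig) -> np.ndarray:
    """Apply the auditory amplitude tag to a sound envelope.

    The envelope (sampled at ``tag.sample_rate``) is multiplied by
    ``0.5 * (1 + depth * sin(2*pi*f_audio*t + phase))``; length preserved.
    """
    env = np.asarray(audio_envelope, dtype=float)
    if env.size == 0:
        raise ValueError("audio envelope is empty")
    t = np.arange(env.shape[-1]) / tag.sample_rate
    mod = 0.5 * (1.0 + tag.modulation_depth
                 * np.sin(2 * np.pi * tag.f_audio * t + tag.phase_at_onset))
    return env * mod


def frame_schedule_rate(refresh: int, n_quadrants: int, n_color_channels: int) -> int:
    """Achievable stimulus presentation rate of a quadrant/color-packed projector.

    A DLP projector that interprets the four quadrants and three color
    channels of each GPU frame as successive frames presents at
    ``refresh * n_quadrants * n_color_channels`` Hz (e.g. 120 * 4 * 3 = 1440).
    """
    vals = (refresh, n_quadrants, n_color_channels)
    if any(int(v) != v or v <= 0 for v in vals):
        raise ValueError("refresh, n_quadrants and n_color_channels must be positive integers")
    return int(refresh) * int(n_quadrants) * int(n_color_channels)


def gaussian_topography(montage: Montage, center: tuple[float, float],
                        sigma: float, floor: float = 0.0) -> np.ndarray:
    """Per-channel weights from a Gaussian bump on the montage's 2-D layout.

    Weights are in [0, 1] with the maximum normalized to exactly 1.
    ``floor`` lifts all weights (broad topographies) before renormalizing.
    """
    if montage.positions is None:
        raise ValueError("montage has no channel positions")
    xy = np.array([montage.positions[c] for c in montage.channel_names])
    d2 = ((xy - np.asarray(center)) ** 2).sum(axis=1)
    w = np.exp(-d2 / (2 * sigma ** 2)) + floor
    return w / w.max()


def _default_topographies(montage: Montage) -> dict[str, np.ndarray]:
    return {
        # broad, slightly central: the auditory steady-state response
        "audio": gaussian_topography(montage, (0.0, 0.5), sigma=3.0, floor=0.5),
        # occipital/central: the visual steady-state response
        "visual": gaussian_topography(montage, (0.0, -3.0), sigma=1.6),
        # left frontal/central: the intermodulation component
        "im": gaussian_topography(montage, (-1.0, 1.8), sigma=1.1),
    }


@dataclass(frozen=True)
class SimConfig:
    """All generative parameters of the synthetic experiment.

    Amplitudes are in microvolts. ``g_related``/``g_unrelated`` are the
    dimensionless interaction gains per condition; the defining constraint
    is ``g_unrelated >= g_related >= 0`` (stronger audiovisual interaction
    when the distractor is unrelated). ``participant_sigma`` is the sigma
    of a log-normal amplitude jitter applied per participant, so only a
    subset of simulated participants shows conspicuous tagging peaks.
    """

    n_participants: int = 30
    n_trials_per_condition: int = 55
    tag: TagConfig = field(default_factory=TagConfig)
    amp_audio: float = 1.0
    amp_visual: float = 1.0
    topo_audio: np.ndarray | None = None
    topo_visual: np.ndarray | None = None
    topo_im: np.ndarray | None = None
    g_related: float = 0.3
    g_unrelated: float = 0.6
    noise_exponent: float = 1.0
    alpha_amp: float = 2.0
    noise_sd: float = 1.0
    participant_sigma: float = 0.4
    seed: int = 0
    baseline_duration: float = 1.0
    tagging_duration: float = 1.0
    sample_rate: float = 1000.0
    montage: Montage = field(default_factory=default_montage)

    def __post_init__(self) -> None:
        if not (self.g_unrelated >= self.g_related >= 0):
            raise ValueError("require g_unrelated >= g_related >= 0")
        if self.amp_audio <= 0 or self.amp_visual <= 0:
            raise ValueError("source amplitudes must be positive")
        if self.noise_sd < 0 or self.alpha_amp < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.sample_rate != self.tag.sample_rate:
            raise ValueError("tag.sample_rate must match sample_rate")
        _time_grid(self.baseline_duration, self.sample_rate)
        _time_grid(self.tagging_duration, self.sample_rate)
        defaults = _default_topographies(self.montage)
        for name in ("audio", "visual", "im"):
            topo = getattr(self, f"topo_{name}")
            if topo is None:
                topo = defaults[name]
            topo = np.asarray(topo, dtype=float)
            if topo.shape != (self.montage.n_channels,):
                raise ValueError(f"topo_{name} must have one weight per channel")
            if topo.min() < 0 or not np.isclose(topo.max(), 1.0):
                raise ValueError(f"topo_{name} weights must be >= 0 with max 1")
            object.__setattr__(self, f"topo_{name}", topo)

    @property
    def n_samples(self) -> int:
        return int(round((self.baseline_duration + self.tagging_duration)
                         * self.sample_rate))


@dataclass
class EpochSet:
    """Simulated trials for one participant: (trials, channels, samples) in µV.

    Time axis runs from ``-baseline_duration`` to ``+tagging_duration``
    with 0 s at tagging onset (picture onset).
    """

    data: np.ndarray
    condition: np.ndarray  # label per trial, "related" | "unrelated"
    participant_id: str
    sample_rate: float
    t_start: float
    montage: Montage

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[0] != self.condition.shape[0]:
            raise ValueError("one condition label per trial required")
        if self.data.shape[1] != self.montage.n_channels:
            raise ValueError("channel count does not match montage")
        bad = set(self.condition) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels {bad}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.data.shape[2]) / self.sample_rate

    def window_indices(self, window: str) -> slice:
        """Sample slice of the named 'baseline' or 'tagging' analysis window."""
        t = self.times
        if window == "baseline":
            lo, hi = self.t_start, 0.0
        elif window == "tagging":
            lo, hi = 0.0, t[-1] + 1.0 / self.sample_rate
        else:
            raise ValueError(f"unknown window {window!r}")
        i0 = int(round((lo - self.t_start) * self.sample_rate))
        i1 = int(round((hi - self.t_start) * self.sample_rate))
        if i0 < 0 or i1 > self.data.shape[2] or i1 <= i0:
            raise ValueError(f"window {window!r} exceeds epoch bounds")
        return slice(i0, i1)

    def select(self, condition: str) -> np.ndarray:
        return self.data[self.condition == condition]

    def copy_with(self, data: np.ndarray) -> "EpochSet":
        return EpochSet(data=data, condition=self.condition.copy(),
                        participant_id=self.participant_id,
                        sample_rate=self.sample_rate, t_start=self.t_start,
                        montage=self.montage)


def _one_over_f_noise(rng: np.random.Generator, shape: tuple[int, ...],
                      n_samples: int, exponent: float, sd: float,
                      sample_rate: float) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent.

    Synthesized in the frequency domain with independent complex-Gaussian
    coefficients; scaled analytically so each trace has variance sd**2.
    """
    if sd == 0:
        return np.zeros(shape + (n_samples,))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sample_rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    if n_samples % 2 == 0:
        amp[-1] = 0.0  # drop Nyquist for a clean analytic variance
    z = rng.standard_normal((2,) + shape + (freqs.size,))
    coeff = np.empty(shape + (freqs.size,), dtype=complex)
    np.multiply(z[0], amp, out=coeff.real)
    np.multiply(z[1], amp, out=coeff.imag)
    x = np.fft.irfft(coeff, n=n_samples, axis=-1)
    # Var(x) = (4 / N^2) * sum(amp^2) for Hermitian-symmetric synthesis
    scale = sd * n_samples / (2.0 * np.sqrt((amp ** 2).sum()))
    return x * scale


def _background(cfg: SimConfig, rng: np.random.Generator,
                n_trials: int) -> np.ndarray:
    """1/f noise plus a 10 Hz alpha oscillation with random phase per trial."""
    n = cfg.n_samples
    noise = _one_over_f_noise(rng, (n_trials, cfg.montage.n_channels), n,
                              cfg.noise_exponent, cfg.noise_sd, cfg.sample_rate)
    if cfg.alpha_amp > 0:
        t = np.arange(n) / cfg.sample_rate
        phase = rng.uniform(0, 2 * np.pi, size=n_trials)
        alpha_topo = gaussian_topography(cfg.montage, (0.0, -2.5), sigma=2.0)
        wave = np.sin(2 * np.pi * 10.0 * t[None, :] + phase[:, None])
        noise += cfg.alpha_amp * alpha_topo[None, :, None] * wave[:, None, :]
    return noise


def _tagging_signal(cfg: SimConfig, condition: str,
                    amp_scale_audio: float = 1.0,
                    amp_scale_visual: float = 1.0) -> np.ndarray:
    """Deterministic (channels, n_tagging_samples) source mixture."""
    t = _time_grid(cfg.tagging_duration, cfg.sample_rate)
    ph = cfg.tag.phase_at_onset
    drive_a = (cfg.amp_audio * amp_scale_audio
               * np.sin(2 * np.pi * cfg.tag.f_audio * t + ph))
    drive_v = (cfg.amp_visual * amp_scale_visual
               * np.sin(2 * np.pi * cfg.tag.f_visual * t + ph))
    g = cfg.g_related if condition == "related" else cfg.g_unrelated
    sig = (cfg.topo_audio[:, None] * drive_a[None, :]
           + cfg.topo_visual[:, None] * drive_v[None, :]
           + cfg.topo_im[:, None] * g * (drive_a * drive_v)[None, :])
    return sig


def simulate_epoch(cfg: SimConfig, condition: str,
                   rng: np.random.Generator | int,
                   amp_scale_audio: float = 1.0,
                   amp_scale_visual: float = 1.0) -> np.ndarray:
    """One trial as a (channels, samples) array in µV.

    The baseline segment contains background activity only; the tagging
    segment adds the two steady-state drives and their multiplicative
    interaction, whose product-to-sum expansion places power at exactly
    ``f_visual - f_audio`` and ``f_visual + f_audio``.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    trial = _background(cfg, rng, 1)[0]
    n_base = int(round(cfg.baseline_duration * cfg.sample_rate))
    trial[:, n_base:] += _tagging_signal(cfg, condition,
                                         amp_scale_audio, amp_scale_visual)
    return trial


def simulate_participant(cfg: SimConfig, participant_id: str,
                         rng: np.random.Generator) -> EpochSet:
    """All trials of one participant, with log-normal amplitude jitter."""
    scale_a = float(rng.lognormal(0.0, cfg.participant_sigma))
    scale_v = float(rng.lognormal(0.0, cfg.participant_sigma))
    k = cfg.n_trials_per_condition
    labels = np.array([c for c in CONDITIONS for _ in range(k)], dtype=object)
    n_base = int(round(cfg.baseline_duration * cfg.sample_rate))
    data = _background(cfg, rng, 2 * k)
    for cond in CONDITIONS:
        sig = _tagging_signal(cfg, cond, scale_a, scale_v)
        data[labels == cond, :, n_base:] += sig[None, :, :]
    return EpochSet(data=data, condition=labels, participant_id=participant_id,
                    sample_rate=cfg.sample_rate, t_start=-cfg.baseline_duration,
                    montage=cfg.montage)


def simulate_dataset(cfg: SimConfig) -> list[EpochSet]:
    """One EpochSet per participant, fully determined by ``cfg.seed``."""
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_participants)
    out = []
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        out.append(simulate_participant(cfg, f"sub-{i + 1:02d}", rng))
    return out


def null_config(cfg: SimConfig, g: float | None = None) -> SimConfig:
    """A copy of ``cfg`` with equal interaction gains in both conditions."""
    if g is None:
        g = cfg.g_related
    return replace(cfg, g_related=g, g_unrelated=g)
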