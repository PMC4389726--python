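"""Seeded synthetic streams: generated video, spiking signals, event schedules.

Everything the operator packs consume can be generated here with a known
ground truth, so the whole pipeline — tracking, spike extraction, task
control — is testable end to end without any recorded data.  All generators
are pure functions of their config (same config, same bytes).

What these fixtures emulate, and what they do not: the video generator
renders a single bright disc (an LED / bright animal on dark background) or
a rotating bar (a pendulum / elongated body) over Gaussian pixel noise —
there is no occlusion, background clutter, or illumination drift.  The
spike generator injects a fixed biphasic template into Gaussian noise — real
extracellular recordings add drift, overlapping units and correlated noise.
Event schedules are homogeneous Poisson or explicit lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Notification, Observable, Subject, VirtualScheduler, hot
from .ephys import SampleBuffer
from .vision import Frame


# ---------------------------------------------------------------------------
# Video: moving dot / rotating bar with per-frame ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DotVideoConfig:
    """A bright shape moving over a noisy dark background.

    ``kind="dot"``: a disc of ``radius`` px following a Lissajous path.
    ``kind="bar"``: a centered bar oscillating in angle (pendulum analogue);
    ``angle_amplitude`` degrees of swing, angle measured from +x toward +y.
    ``noise_sigma`` is the Gaussian pixel-noise scale (8-bit intensity).
    """

    seed: int = 0
    n_frames: int = 300
    width: int = 120
    height: int = 90
    kind: str = "dot"  # "dot" | "bar"
    radius: float = 6.0
    noise_sigma: float = 5.0
    amplitude: int = 255
    bar_length: float = 40.0
    bar_width: float = 7.0
    angle_amplitude: float = 55.0
    angle_period: int = 120
    ticks_per_frame: int = 1


def _dot_path(cfg: DotVideoConfig) -> tuple[np.ndarray, np.ndarray]:
    margin = cfg.radius + 4.0
    t = np.arange(cfg.n_frames)
    cx = margin + (cfg.width - 1 - 2 * margin) * \
        (0.5 + 0.5 * np.sin(2 * np.pi * t / 97.0))
    cy = margin + (cfg.height - 1 - 2 * margin) * \
        (0.5 + 0.5 * np.sin(2 * np.pi * t / 61.0 + 1.0))
    return cx, cy


def gen_dot_video(cfg: DotVideoConfig) -> tuple[list[Frame], "np.ndarray"]:
    """Render the fixture video; returns (frames, ground_truth).

    ``ground_truth`` is a structured array with per-frame true ``cx, cy``
    (dot) plus ``angle`` degrees (bar; constant NaN for dots).  Shapes are
    rendered with a one-pixel soft edge so sub-pixel position survives
    discretization.
    """
    rng = np.random.default_rng(cfg.seed)
    ys, xs = np.mgrid[0:cfg.height, 0:cfg.width]
    frames: list[Frame] = []
    truth = np.zeros(cfg.n_frames,
                     dtype=[("cx", "f8"), ("cy", "f8"), ("angle", "f8")])
    if cfg.kind == "dot":
        cxs, cys = _dot_path(cfg)
        angles = np.full(cfg.n_frames, np.nan)
    elif cfg.kind == "bar":
        cxs = np.full(cfg.n_frames, (cfg.width - 1) / 2.0)
        cys = np.full(cfg.n_frames, (cfg.height - 1) / 2.0)
        t = np.arange(cfg.n_frames)
        angles = cfg.angle_amplitude * np.sin(2 * np.pi * t / cfg.angle_period)
    else:
        raise ValueError(f"unknown fixture kind {cfg.kind!r}")

    for i in range(cfg.n_frames):
        if cfg.kind == "dot":
            dist = np.hypot(xs - cxs[i], ys - cys[i])
            shape = np.clip(cfg.radius + 0.5 - dist, 0.0, 1.0)
        else:
            theta = np.radians(angles[i])
            dx, dy = xs - cxs[i], ys - cys[i]
            u = dx * np.cos(theta) + dy * np.sin(theta)
            v = -dx * np.sin(theta) + dy * np.cos(theta)
            shape = (np.clip(cfg.bar_length / 2 + 0.5 - np.abs(u), 0, 1) *
                     np.clip(cfg.bar_width / 2 + 0.5 - np.abs(v), 0, 1))
        pixels = cfg.amplitude * shape
        if cfg.noise_sigma > 0:
            pixels = pixels + rng.normal(0.0, cfg.noise_sigma, pixels.shape)
        pixels = np.clip(np.round(pixels), 0, 255).astype(np.uint8)
        frames.append(Frame(pixels, time=i * cfg.ticks_per_frame, index=i))
        truth[i] = (cxs[i], cys[i], angles[i])
    return frames, truth


def frames_to_stream(scheduler: VirtualScheduler,
                     frames: Sequence[Frame]) -> Subject:
    """Hot stream pushing each frame at its own tick, completing at the last."""
    script = [Notification.next_(f.time, f) for f in frames]
    if script:
        script.append(Notification.completed(script[-1].time))
    return hot(scheduler, script)


# ---------------------------------------------------------------------------
# Electrophysiology: noise + injected biphasic spikes, known times
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeSignalConfig:
    """Multichannel Gaussian noise with a biphasic template injected on one
    channel (attenuated copies on the others).

    ``snr`` is trough depth over noise sigma.  ``spike_times`` (absolute
    sample indices of the troughs) may be scripted; otherwise ``n_spikes``
    are placed uniformly at random with spacing >= ``min_gap`` samples.
    """

    seed: int = 0
    channels: int = 4
    rate: float = 30000.0
    n_samples: int = 90000
    noise_sigma: float = 1.0
    snr: float = 8.0
    spike_channel: int = 0
    cross_channel_gain: float = 0.3
    n_spikes: int = 100
    min_gap: int = 90
    spike_times: Optional[Sequence[int]] = None
    buffer_samples: int = 3000


def biphasic_template(depth: float, rate: float = 30000.0
                      ) -> tuple[np.ndarray, int]:
    """A spike-like waveform: sharp negative trough then a slower positive
    overshoot, ~1.5 ms total.  Returns (template, trough offset)."""
    n = max(int(round(1.5e-3 * rate)), 9)
    t = np.arange(n)
    center = n // 3
    wave = (-np.exp(-0.5 * ((t - center) / (0.04e-3 * rate + 0.2)) ** 2)
            + 0.35 *
            np.exp(-0.5 * ((t - center - 0.35e-3 * rate) /
                           (0.25e-3 * rate + 1)) ** 2))
    wave *= depth / -wave.min()  # overlapping lobes: renormalize the trough
    trough = int(np.argmin(wave))
    return wave, trough


def gen_spike_signal(cfg: SpikeSignalConfig
                     ) -> tuple[list[SampleBuffer], np.ndarray, np.ndarray]:
    """Build the signal; returns (buffers, trough sample indices, template)."""
    rng = np.random.default_rng(cfg.seed)
    template, trough = biphasic_template(cfg.snr * cfg.noise_sigma, cfg.rate)
    data = rng.normal(0.0, cfg.noise_sigma,
                      (cfg.channels, cfg.n_samples)) if cfg.noise_sigma > 0 \
        else np.zeros((cfg.channels, cfg.n_samples))

    if cfg.spike_times is not None:
        times = np.asarray(sorted(cfg.spike_times), dtype=int)
    else:
        # uniform spike positions with a minimum gap: draw from the
        # gap-compressed interval, sort, then re-insert the gaps
        lo = trough + 1
        hi = cfg.n_samples - (len(template) - trough) - 1
        usable = (hi - lo) - (cfg.n_spikes - 1) * cfg.min_gap
        if usable <= 0:
            raise ValueError(
                f"cannot place {cfg.n_spikes} spikes with gap "
                f">= {cfg.min_gap} in {cfg.n_samples} samples")
        picks = np.sort(rng.integers(0, usable, cfg.n_spikes))
        times = picks + lo + np.arange(cfg.n_spikes) * cfg.min_gap

    for t in times:
        start = t - trough
        seg = slice(start, start + len(template))
        for ch in range(cfg.channels):
            gain = 1.0 if ch == cfg.spike_channel else cfg.cross_channel_gain
            data[ch, seg] += gain * template
    buffers = [SampleBuffer(data[:, s:s + cfg.buffer_samples].copy(), s,
                            cfg.rate)
               for s in range(0, cfg.n_samples, cfg.buffer_samples)]
    return buffers, times, template


def buffers_to_stream(scheduler: VirtualScheduler,
                      buffers: Sequence[SampleBuffer],
                      ticks_per_buffer: int = 1) -> Subject:
    """Hot stream delivering one buffer per ``ticks_per_buffer`` ticks."""
    script = [Notification.next_(i * ticks_per_buffer, buf)
              for i, buf in enumerate(buffers)]
    if script:
        script.append(Notification.completed(script[-1].time))
    return hot(scheduler, script)


# ---------------------------------------------------------------------------
# Event schedules: explicit lists or Poisson processes on the virtual clock
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventScheduleConfig:
    """Scripted or Poisson event times (integer ticks in [0, duration))."""

    seed: int = 0
    duration: int = 10000
    rate: float = 0.0  # expected events per tick (Poisson mode)
    times: Optional[Sequence[int]] = None  # explicit mode wins if given


def gen_event_schedule(cfg: EventScheduleConfig) -> np.ndarray:
    """Event times as a sorted integer array."""
    if cfg.times is not None:
        times = np.asarray(sorted(cfg.times), dtype=int)
        return times[(times >= 0) & (times < cfg.duration)]
    if cfg.rate <= 0:
        return np.array([], dtype=int)
    rng = np.random.default_rng(cfg.seed)
    # exponential gaps; ties collapse to distinct integer ticks by ceil >= 1
    times = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / cfg.rate)
        tick = int(np.floor(t))
        if tick >= cfg.duration:
            break
        times.append(tick)
    return np.unique(np.array(times, dtype=int))


def events_to_stream(scheduler: VirtualScheduler, times: Sequence[int],
                     payload=1, complete_at: Optional[int] = None) -> Subject:
    """Hot stream with one NEXT per scheduled tick.

    ``complete_at`` adds a COMPLETED at that tick (e.g. the fixture
    duration); omit it for an open-ended stream.
    """
    script = [Notification.next_(int(t), payload) for t in times]
    if complete_at is not None:
        script.append(Notification.completed(int(complete_at)))
    return hot(scheduler, script)
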