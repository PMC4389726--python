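"""Buffered time-series operators: band-pass filtering, threshold spike
detection, spike-triggered multichannel window extraction, and raw int16 I/O.

Acquisition hardware delivers multichannel signals as a stream of
:class:`SampleBuffer` chunks (channels x samples).  All operators here are
*streaming*: filter state, detector state and lookback history are carried
across buffer boundaries, so results are identical however the signal is
chunked (buffer-split invariance) — the property that makes an online
pipeline trustworthy against its offline equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from scipy import signal as sps

from .core import ContractError, Observable


@dataclass(frozen=True)
class SampleBuffer:
    """One chunk of a multichannel signal.

    ``data`` is channels x samples; ``start_index`` is the absolute sample
    index of column 0, so contiguous buffers satisfy
    ``next.start_index == prev.start_index + prev.data.shape[1]``.
    """

    data: np.ndarray
    start_index: int
    rate: float

    @property
    def channels(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SpikeEvent:
    """A detected spike: trough (or peak) position on one channel."""

    channel: int
    sample_index: int
    threshold: float


@dataclass(frozen=True)
class TriggeredWindow:
    """All-channel slice aligned on a spike: column ``pre`` is the event sample."""

    data: np.ndarray  # channels x (pre + post + 1)
    event: SpikeEvent


class BandpassState:
    """Causal 2nd-order (biquad) band-pass with state carried across buffers.

    A first-order Butterworth band-pass designed by bilinear transform; the
    geometric-mean frequency sqrt(low*high) sits at 0 dB and DC is fully
    rejected.  Zero-phase filtering is deliberately not offered: it needs
    the future and cannot run online.
    """

    def __init__(self, low_hz: float, high_hz: float, rate: float,
                 channels: int) -> None:
        nyquist = rate / 2.0
        if not (0.0 < low_hz < high_hz < nyquist):
            raise ContractError(
                f"need 0 < low ({low_hz}) < high ({high_hz}) < rate/2 ({nyquist})")
        self.sos = sps.butter(1, [low_hz, high_hz], btype="bandpass",
                              fs=rate, output="sos")
        self._zi = np.zeros((channels, self.sos.shape[0], 2))

    def process(self, data: np.ndarray) -> np.ndarray:
        out = np.empty_like(data, dtype=np.float64)
        for ch in range(data.shape[0]):
            out[ch], self._zi[ch] = sps.sosfilt(self.sos, data[ch],
                                                zi=self._zi[ch])
        return out


def bandpass(src: Observable, low_hz: float, high_hz: float, rate: float,
             channels: int) -> Observable:
    """Per-channel streaming band-pass; output buffers align 1:1 with input."""
    state = BandpassState(low_hz, high_hz, rate, channels)
    from .combinators import map_
    return map_(src, lambda buf: SampleBuffer(state.process(buf.data),
                                              buf.start_index, buf.rate))


class SpikeDetectorState:
    """Streaming threshold-crossing detector with trough alignment.

    For a negative threshold: a crossing opens a search span of
    ``refractory`` samples; the event lands on the minimum within that span,
    and further crossings inside the span are suppressed.  A positive
    threshold is the mirror image (peak alignment).  Because the trough
    search needs ``refractory`` samples of lookahead, events are emitted as
    soon as their span is fully seen; a span cut short by end-of-stream is
    flushed with the samples available.
    """

    def __init__(self, channel: int, threshold: float, refractory: int) -> None:
        if refractory < 1:
            raise ContractError(f"refractory must be >= 1, got {refractory}")
        self.channel = channel
        self.threshold = threshold
        self.refractory = refractory
        self._sign = -1.0 if threshold < 0 else 1.0
        self._prev: Optional[float] = None
        # open search span: (crossing_index, best_index, best_value)
        self._pending: Optional[tuple[int, int, float]] = None

    def _crossed(self, prev: float, x: float) -> bool:
        if self._sign < 0:
            return prev >= self.threshold > x
        return prev <= self.threshold < x

    def process(self, buf: SampleBuffer) -> list[SpikeEvent]:
        events: list[SpikeEvent] = []
        trace = np.asarray(buf.data[self.channel], dtype=np.float64)
        for offset, x in enumerate(trace):
            i = buf.start_index + offset
            if self._pending is not None:
                crossing, best_i, best_v = self._pending
                if self._sign * x > self._sign * best_v:
                    best_i, best_v = i, x
                if i >= crossing + self.refractory:
                    events.append(SpikeEvent(self.channel, best_i,
                                             self.threshold))
                    self._pending = None
                else:
                    self._pending = (crossing, best_i, best_v)
            elif self._prev is not None and self._crossed(self._prev, x):
                self._pending = (i, i, x)
            self._prev = x
        return events

    def flush(self) -> list[SpikeEvent]:
        if self._pending is None:
            return []
        crossing, best_i, _ = self._pending
        self._pending = None
        return [SpikeEvent(self.channel, best_i, self.threshold)]


def detect_spikes(src: Observable, channel: int, threshold: float,
                  refractory: int) -> Observable:
    """Stream of :class:`SpikeEvent` from threshold crossings on one channel."""
    state = SpikeDetectorState(channel, threshold, refractory)

    def on_subscribe(guard):
        def on_buffer(buf):
            for event in state.process(buf):
                guard.on_next(event)

        def done():
            for event in state.flush():
                guard.on_next(event)
            guard.on_completed()

        return src.subscribe(on_next=on_buffer, on_completed=done,
                             on_error=guard.on_error).dispose

    return Observable(src.scheduler, on_subscribe)


class TriggeredExtractorState:
    """Aligns all-channel waveform slices on spike events.

    Retains just enough signal history (``pre + post`` samples beyond the
    current buffer) for lookback; events whose context reaches before the
    start of the stream — or before the retained history — are dropped and
    counted.  Events are emitted once their ``post`` samples have arrived.
    """

    def __init__(self, pre: int, post: int) -> None:
        if pre < 0 or post < 0:
            raise ContractError("pre and post must be non-negative")
        self.pre = pre
        self.post = post
        self.dropped = 0
        self._history: Optional[np.ndarray] = None
        self._history_start = 0
        self._queue: list[SpikeEvent] = []

    def add_event(self, event: SpikeEvent) -> None:
        self._queue.append(event)

    def add_buffer(self, buf: SampleBuffer) -> list[TriggeredWindow]:
        if self._history is None:
            self._history = np.asarray(buf.data, dtype=np.float64)
            self._history_start = buf.start_index
        else:
            self._history = np.concatenate([self._history, buf.data], axis=1)
        out = self.drain()
        keep = self.pre + self.post
        extra = self._history.shape[1] - keep
        if extra > 0:
            self._history = self._history[:, extra:]
            self._history_start += extra
        return out

    def drain(self) -> list[TriggeredWindow]:
        """Emit every queued event whose full context is in the history."""
        if self._history is None:
            return []
        end = self._history_start + self._history.shape[1]
        out: list[TriggeredWindow] = []
        still_waiting: list[SpikeEvent] = []
        for event in self._queue:
            lo = event.sample_index - self.pre
            hi = event.sample_index + self.post + 1
            if lo < 0 or lo < self._history_start:
                self.dropped += 1  # not enough past context (stream edge)
                continue
            if hi > end:
                still_waiting.append(event)  # future samples not here yet
                continue
            sl = self._history[:, lo - self._history_start:hi - self._history_start]
            out.append(TriggeredWindow(sl.copy(), event))
        self._queue = still_waiting
        return out

    def flush(self) -> None:
        self.dropped += len(self._queue)  # stream ended before their post span
        self._queue.clear()


def extract_triggered(src: Observable, events: Observable, pre: int,
                      post: int) -> Observable:
    """All-channel slices [index-pre, index+post] around each spike event.

    Edge events (insufficient past or future context) are dropped; the drop
    count is available on the returned observable as ``.extractor.dropped``.
    Completes when the data stream completes.
    """
    state = TriggeredExtractorState(pre, post)

    def on_subscribe(guard):
        def on_event(event):
            state.add_event(event)
            for window in state.drain():
                guard.on_next(window)

        def on_buffer(buf):
            for window in state.add_buffer(buf):
                guard.on_next(window)

        def done():
            for window in state.drain():
                guard.on_next(window)
            state.flush()
            guard.on_completed()

        # events first: when both derive from one upstream subject, spikes
        # for a chunk are queued before the chunk itself is added, so the
        # pre+post history bound suffices (recommend post >= refractory).
        sub_ev = events.subscribe(on_next=on_event, on_error=guard.on_error)
        sub_src = src.subscribe(on_next=on_buffer, on_completed=done,
                                on_error=guard.on_error)

        def teardown():
            sub_src.dispose()
            sub_ev.dispose()

        return teardown

    out = Observable(src.scheduler, on_subscribe)
    out.extractor = state  # expose drop counter
    return out


# ---------------------------------------------------------------------------
# Raw int16 binary format: little-endian, sample-major interleaved
# (c0s0, c1s0, ..., cNs0, c0s1, ...) — the common flat ephys layout.
# ---------------------------------------------------------------------------

def write_raw_binary(path: str | Path,
                     buffers: Iterable[SampleBuffer]) -> int:
    """Write buffers as interleaved little-endian int16; returns samples written.

    Values outside the int16 range are clipped on write.
    """
    total = 0
    with open(path, "wb") as fh:
        for buf in buffers:
            clipped = np.clip(np.round(buf.data), -32768, 32767).astype("<i2")
            fh.write(np.ascontiguousarray(clipped.T).tobytes())
            total += buf.samples
    return total


def read_raw_binary(path: str | Path, channels: int, rate: float,
                    buffer_samples: Optional[int] = None
                    ) -> Iterator[SampleBuffer]:
    """Invert :func:`write_raw_binary`; yields buffers of ``buffer_samples``.

    With ``buffer_samples=None`` the whole file comes back as one buffer.
    A file length not divisible by 2*channels is a format error.
    """
    raw = Path(path).read_bytes()
    frame_bytes = 2 * channels
    if len(raw) % frame_bytes:
        raise ValueError(f"file length {len(raw)} is not a whole number of "
                         f"{channels}-channel int16 samples")
    flat = np.frombuffer(raw, dtype="<i2")
    data = flat.reshape(-1, channels).T.astype(np.float64)
    n = data.shape[1]
    step = n if buffer_samples is None else buffer_samples
    for start in range(0, n, max(step, 1)):
        chunk = data[:, start:start + step]
        if chunk.shape[1]:
            yield SampleBuffer(chunk, start, rate)
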