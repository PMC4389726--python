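"""Stream slicing into sub-sequences (windows) and per-window processing.

A window is itself an observable (a hot subject tagged with its ordinal):
the outer stream emits each window as it opens, and the window then relays
exactly the source elements belonging to it, at their original ticks, with
no buffering delay.  Windows may overlap (count mode with skip < count), in
which case an element is relayed into every open window that covers it.

:func:`select_many` instantiates a fresh, state-isolated inner dataflow per
window and merges all inner outputs by time, which is how per-trial
processing, triggered file splitting and moving averages are expressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Optional

from .core import ContractError, Observable, Subject, VirtualScheduler


class Window(Subject):
    """A sub-sequence of a source stream, tagged with its opening ordinal."""

    def __init__(self, scheduler: VirtualScheduler, window_id: int) -> None:
        super().__init__(scheduler)
        self.window_id = window_id


@dataclass(frozen=True)
class WindowedElement:
    """An element annotated with the window it belongs to."""

    window_id: int
    payload: Any
    time: int


def window_count(src: Observable, count: int, skip: int) -> Observable:
    """Slice by element count: a window opens at source elements 0, skip,
    2*skip, ...; each closes after ``count`` elements or at source
    completion (trailing partial windows are emitted).  skip < count gives
    overlapping windows."""
    if count < 1 or skip < 1:
        raise ContractError(f"window_count requires count >= 1 and skip >= 1, "
                            f"got count={count}, skip={skip}")

    def on_subscribe(guard):
        state = {"index": 0, "next_id": 0}
        open_windows: list[list] = []  # [window, elements_remaining]

        def on_next(value):
            if state["index"] % skip == 0:
                win = Window(src.scheduler, state["next_id"])
                state["next_id"] += 1
                open_windows.append([win, count])
                guard.on_next(win)
            state["index"] += 1
            for entry in list(open_windows):
                win, remaining = entry
                win.on_next(value)
                entry[1] -= 1
                if entry[1] == 0:
                    win.on_completed()
                    open_windows.remove(entry)

        def on_completed():
            for win, _ in open_windows:
                win.on_completed()
            open_windows.clear()
            guard.on_completed()

        def on_error(info):
            for win, _ in open_windows:
                win.on_error(info)
            open_windows.clear()
            guard.on_error(info)

        return src.subscribe(on_next=on_next, on_completed=on_completed,
                             on_error=on_error).dispose

    return Observable(src.scheduler, on_subscribe)


def window_time(src: Observable, duration: int) -> Observable:
    """Slice by fixed time intervals [k*d, (k+1)*d) from the subscription tick.

    An element is assigned to the interval active at its arrival; a boundary
    element belongs to the *later* window (half-open convention).  Intervals
    without elements still yield (empty) windows, materialized when the
    stream next advances, so interval indexing matches elapsed time.
    """
    if duration <= 0:
        raise ContractError(f"window_time requires duration > 0, got {duration}")

    def on_subscribe(guard):
        t0 = src.scheduler.clock
        state: dict = {"interval": 0, "window": None}

        def open_window(k):
            win = Window(src.scheduler, k)
            state["interval"], state["window"] = k, win
            guard.on_next(win)
            return win

        open_window(0)

        def catch_up(k):
            while state["interval"] < k:
                state["window"].on_completed()
                open_window(state["interval"] + 1)

        def on_next(value):
            catch_up((src.scheduler.clock - t0) // duration)
            state["window"].on_next(value)

        def on_completed():
            # intervals that began strictly before completion still emit;
            # a completion exactly on a boundary does not open a new one
            catch_up(max(0, src.scheduler.clock - t0 - 1) // duration)
            state["window"].on_completed()
            guard.on_completed()

        def on_error(info):
            state["window"].on_error(info)
            guard.on_error(info)

        return src.subscribe(on_next=on_next, on_completed=on_completed,
                             on_error=on_error).dispose

    return Observable(src.scheduler, on_subscribe)


def window_trigger(src: Observable, boundary: Observable) -> Observable:
    """Slice at external trigger events.

    The first window opens at subscription; each boundary element closes the
    current window (possibly empty) and opens the next; source completion
    closes the last window.
    """

    def on_subscribe(guard):
        state: dict = {"window": None, "next_id": 0, "done": False}

        def open_window():
            win = Window(src.scheduler, state["next_id"])
            state["next_id"] += 1
            state["window"] = win
            guard.on_next(win)

        open_window()

        def on_next(value):
            state["window"].on_next(value)

        def on_boundary(_):
            if state["done"]:
                return
            state["window"].on_completed()
            open_window()

        def finish():
            state["done"] = True
            state["window"].on_completed()
            guard.on_completed()

        def fail(info):
            state["done"] = True
            state["window"].on_error(info)
            guard.on_error(info)

        sub_src = src.subscribe(on_next=on_next, on_completed=finish, on_error=fail)
        sub_bnd = boundary.subscribe(on_next=on_boundary, on_error=fail)

        def teardown():
            sub_src.dispose()
            sub_bnd.dispose()

        return teardown

    return Observable(src.scheduler, on_subscribe)


def select_many(windows: Observable,
                inner: Callable[[Observable], Observable]) -> Observable:
    """Process each window with a fresh inner dataflow and merge all outputs.

    ``inner`` is a blueprint: called once per window with that window's
    stream, it returns the observable whose elements feed the merged result.
    Instances share the scheduler but no state.  Output ties at one tick
    resolve to the lower window_id (instantiation order).  The result
    completes when the outer stream and every inner instance have completed.
    """

    def on_subscribe(guard):
        state = {"active": 0, "outer_done": False}
        subs = []

        def check_done():
            if state["outer_done"] and state["active"] == 0:
                guard.on_completed()

        def on_window(win):
            try:
                out = inner(win)
            except Exception as exc:
                guard.on_error(f"inner dataflow instantiation failed: {exc!r}")
                return
            state["active"] += 1

            def inner_done():
                state["active"] -= 1
                check_done()

            subs.append(out.subscribe(on_next=guard.on_next,
                                      on_completed=inner_done,
                                      on_error=guard.on_error))

        def outer_done():
            state["outer_done"] = True
            check_done()

        sub_outer = windows.subscribe(on_next=on_window, on_completed=outer_done,
                                      on_error=guard.on_error)
        subs.append(sub_outer)

        def teardown():
            for sub in subs:
                sub.dispose()

        return teardown

    return Observable(windows.scheduler, on_subscribe)


def _window_mean(k: int) -> Callable[[Observable], Observable]:
    def blueprint(win: Observable) -> Observable:
        def on_subscribe(guard):
            acc: list[float] = []

            def done():
                if len(acc) == k:  # trailing partial windows contribute nothing
                    guard.on_next(sum(acc) / k)
                guard.on_completed()

            return win.subscribe(on_next=acc.append, on_completed=done,
                                 on_error=guard.on_error).dispose

        return Observable(win.scheduler, on_subscribe)

    return blueprint


def moving_average(src: Observable, k: int) -> Observable:
    """Sliding mean over the last/next k elements via overlapping windows.

    Composition of ``window_count(k, 1)`` with a per-window mean emitted at
    window completion; only complete windows contribute, so the output is
    time-shifted by the k-1 future samples each mean waits for.
    """
    if k < 1:
        raise ContractError(f"moving_average requires k >= 1, got {k}")
    return select_many(window_count(src, k, 1), _window_mean(k))


def collect_windows(windows: Observable) -> tuple[list[list], list]:
    """Test/demo helper: subscribe every window as it opens and gather payloads.

    Returns (per-window payload lists, outer-stream terminal log).  Time must
    be advanced by the caller.
    """
    gathered: list[list] = []
    terminals: list = []

    def on_window(win):
        bucket: list = []
        gathered.append(bucket)
        win.subscribe(on_next=bucket.append)

    windows.subscribe(on_next=on_window,
                      on_completed=lambda: terminals.append("completed"),
                      on_error=lambda info: terminals.append(("error", info)))
    return gathered, terminals
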