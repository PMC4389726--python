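"""Marble-diagram DSL: timeline strings compiled to notification scripts.

Grammar, per character position (each character consumes one index; time =
index * tick):

* ``-`` one tick of silence
* ``|`` COMPLETED
* ``#`` ERROR
* ``( ... )`` group of simultaneous notifications, all stamped at the
  opening parenthesis' index
* any other character: NEXT whose payload is looked up in the value map
  (the character itself if unmapped)

``"a-b|"`` with tick=1 is NEXT('a')@0, NEXT('b')@2, COMPLETED@3.  The DSL is
the executable form of the timeline diagrams conventionally drawn for
reactive operators, and drives both example-based and randomized tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Optional, Sequence

from .core import (Kind, Notification, Observable, Recorder, Subject,
                   VirtualScheduler, hot)


class MarbleError(ValueError):
    """Malformed marble string."""


@dataclass(frozen=True)
class MarbleScript:
    """A marble string plus its tick size and symbol-to-payload mapping."""

    text: str
    tick: int = 1
    values: Mapping[str, Any] = field(default_factory=dict)


def parse_marble(script: MarbleScript | str, tick: int = 1,
                 values: Optional[Mapping[str, Any]] = None) -> list[Notification]:
    """Compile a marble string into a time-ordered notification list."""
    if isinstance(script, str):
        script = MarbleScript(script, tick, values or {})
    out: list[Notification] = []
    terminated = False
    in_group = False
    group_time = 0
    for index, char in enumerate(script.text):
        time = index * script.tick
        if char == "-":
            if in_group:
                raise MarbleError(f"'-' inside group at index {index}")
            continue
        if char == "(":
            if in_group:
                raise MarbleError(f"nested '(' at index {index}")
            in_group, group_time = True, time
            continue
        if char == ")":
            if not in_group:
                raise MarbleError(f"unmatched ')' at index {index}")
            in_group = False
            continue
        if terminated:
            raise MarbleError(f"symbol {char!r} after terminal at index {index}")
        stamp = group_time if in_group else time
        if char == "|":
            out.append(Notification.completed(stamp))
            terminated = True
        elif char == "#":
            out.append(Notification.error(stamp, "scripted error"))
            terminated = True
        else:
            out.append(Notification.next_(stamp, script.values.get(char, char)))
    if in_group:
        raise MarbleError("unbalanced '(': group never closed")
    return out


@dataclass
class MarbleReport:
    """Outcome of one marble test: expected vs recorded notifications."""

    passed: bool
    expected: list[Notification]
    actual: list[Notification]
    mismatches: list[str]

    def __bool__(self) -> bool:
        return self.passed


def _compare(expected: Sequence[Notification],
             actual: Sequence[Notification]) -> list[str]:
    problems = []
    for i, (e, a) in enumerate(zip(expected, actual)):
        if (e.time, e.kind) != (a.time, a.kind) or \
                (e.kind is Kind.NEXT and e.payload != a.payload):
            problems.append(f"notification {i}: expected {e!r}, got {a!r}")
    if len(expected) != len(actual):
        problems.append(f"length: expected {len(expected)}, got {len(actual)}")
    return problems


def run_marble_test(inputs: Sequence[MarbleScript | str],
                    pipeline: Callable[..., Observable],
                    expected: MarbleScript | str,
                    tick: int = 1,
                    values: Optional[Mapping[str, Any]] = None) -> MarbleReport:
    """Execute ``pipeline`` on hot scripted inputs and diff against ``expected``.

    All scripts share one scheduler and one tick size.  Sources are created
    (hence ordered for tie-breaking) left to right.  Time is advanced past
    every scripted event before comparing.
    """
    scheduler = VirtualScheduler()
    sources = [hot(scheduler, parse_marble(s, tick, values)) for s in inputs]
    result = pipeline(*sources)
    recorder = Recorder(scheduler)
    result.subscribe(recorder)
    scheduler.run()
    want = parse_marble(expected, tick, values)
    problems = _compare(want, recorder.log)
    return MarbleReport(not problems, want, recorder.log, problems)
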