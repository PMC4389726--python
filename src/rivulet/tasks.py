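"""Reactive task control: state machines from stream combinators, a
reaction-time task, and the probabilistic-foraging coincidence detector.

A finite-state machine is expressed without any loop in the dataflow: each
state is a nested stream truncated by take(1) on its exit trigger, states
are chained so one state's exit activates the next, and the whole chain is
restarted by repeat() at the end of every trial.  The foraging model is the
canonical case where this formulation beats an explicit product-state
machine: independent sites are independent dataflow replicas, while the
equivalent flat FSM needs every combination of per-site states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Sequence

import pandas as pd

from .core import ContractError, Observable, VirtualScheduler
from .combinators import filter_, map_, merge, repeat, take


@dataclass(frozen=True)
class StateSpec:
    """One state: a name, entry side effects, and the stream whose first
    element exits the state.  ``exit_trigger`` is a blueprint (called fresh
    at each activation) so cold timers re-arm per visit while hot input
    streams are simply listened to for the duration of the state."""

    name: str
    exit_trigger: Callable[[], Observable]
    entry_actions: Sequence[Callable[[int], None]] = ()


@dataclass(frozen=True)
class Transition:
    """A state activation in the machine's log."""

    state: str
    time: int


@dataclass(frozen=True)
class TrialRecord:
    """One reaction-time trial: stimulus onset, response, and their difference."""

    trial: int
    stimulus_time: int
    response_time: int

    @property
    def rt(self) -> int:
        return self.response_time - self.stimulus_time


@dataclass(frozen=True)
class RewardEvent:
    """A collected reward: the sample that coincided with an armed availability."""

    site_id: int
    time: int
    availability_time: int


def chain_states(scheduler: VirtualScheduler,
                 states: Sequence[StateSpec]) -> Callable[[], Observable]:
    """Compile an ordered state list into a restartable machine blueprint.

    The returned factory builds a stream of :class:`Transition` records: a
    record at each state's activation tick (entry actions fire then), and
    COMPLETED when the last state exits.  Each state subscribes take(1) of
    its exit trigger, so exactly one trigger element advances the machine;
    wrap the blueprint in :func:`rivulet.combinators.repeat` to loop trials.
    """
    states = list(states)
    if not states:
        raise ContractError("chain_states requires at least one state")

    def factory() -> Observable:
        def on_subscribe(guard):
            ctx: dict = {"sub": None, "disposed": False}

            def activate(k: int) -> None:
                if ctx["disposed"]:
                    return
                spec = states[k]
                guard.on_next(Transition(spec.name, scheduler.clock))
                for action in spec.entry_actions:
                    action(scheduler.clock)
                exited = {"done": False}

                def on_exit(_value):
                    if exited["done"]:
                        return
                    exited["done"] = True
                    if k + 1 < len(states):
                        activate(k + 1)
                    else:
                        guard.on_completed()

                ctx["sub"] = take(spec.exit_trigger(), 1).subscribe(
                    on_next=on_exit, on_error=guard.on_error)

            activate(0)

            def teardown():
                ctx["disposed"] = True
                if ctx["sub"] is not None:
                    ctx["sub"].dispose()

            return teardown

        return Observable(scheduler, on_subscribe)

    return factory


def reaction_time_task(scheduler: VirtualScheduler, timer_delay: int,
                       key_stream: Observable,
                       stimulus_on: Optional[Callable[[int], None]] = None,
                       stimulus_off: Optional[Callable[[int], None]] = None
                       ) -> Observable:
    """Ready/Go trial loop measuring response times.

    Ready arms a timer (stimulus off); after ``timer_delay`` ticks the
    machine enters Go (stimulus on) and waits for the first key press, which
    closes the trial with rt = key tick - stimulus tick; the machine then
    loops back to Ready.  Key presses during Ready are ignored — the Go
    state only starts listening at stimulus onset.  Emits one
    :class:`TrialRecord` per completed trial, at the response tick.
    """
    from .core import timer as timer_source

    ready = StateSpec("Ready",
                      exit_trigger=lambda: timer_source(scheduler, timer_delay),
                      entry_actions=[stimulus_off] if stimulus_off else ())
    go = StateSpec("Go",
                   exit_trigger=lambda: key_stream,
                   entry_actions=[stimulus_on] if stimulus_on else ())
    machine = repeat(scheduler, chain_states(scheduler, [ready, go]))

    state = {"stimulus": None, "trial": 0}

    def to_record(transition: Transition):
        if transition.state == "Go":
            state["stimulus"] = transition.time
            return None
        if transition.state == "Ready" and state["stimulus"] is not None:
            state["trial"] += 1
            rec = TrialRecord(state["trial"], state["stimulus"],
                              transition.time)
            state["stimulus"] = None
            return rec
        return None

    return filter_(map_(machine, to_record), lambda r: r is not None)


def foraging_site(avail: Observable, sample_stream: Observable, w: int,
                  site_id: int = 0) -> Observable:
    """Coincidence detector of one foraging site.

    Each availability event (A) arms the site for ``w`` ticks; the first
    sample event (S) while armed collects the reward (R) and disarms; a
    sample at an unarmed site does nothing; a new A while armed replaces the
    pending availability (single-item site: the old item is gone).  Rewards
    are emitted at the sample tick.  The output completes when both inputs
    have completed.
    """
    if w <= 0:
        raise ContractError(f"availability window w must be > 0, got {w}")

    def on_subscribe(guard):
        state: dict = {"avail": None, "open": 2}

        def on_avail(_):
            state["avail"] = avail.scheduler.clock

        def on_sample(_):
            t = sample_stream.scheduler.clock
            armed_at = state["avail"]
            if armed_at is not None and t <= armed_at + w:
                state["avail"] = None
                guard.on_next(RewardEvent(site_id, t, armed_at))

        def one_done():
            state["open"] -= 1
            if state["open"] == 0:
                guard.on_completed()

        sub_a = avail.subscribe(on_next=on_avail, on_completed=one_done,
                                on_error=guard.on_error)
        sub_s = sample_stream.subscribe(on_next=on_sample,
                                        on_completed=one_done,
                                        on_error=guard.on_error)

        def teardown():
            sub_a.dispose()
            sub_s.dispose()

        return teardown

    return Observable(avail.scheduler, on_subscribe)


def foraging_multisite(sites: Sequence[tuple[Observable, Observable, int]]
                       ) -> Observable:
    """Independent foraging sites merged into one tagged reward stream.

    ``sites[i]`` is (availability stream, sample stream, window) for site i;
    rewards carry ``site_id = i``.  Sites share nothing, so each site's
    reward list is identical to running that site alone; simultaneous
    rewards appear in site order.
    """
    if not sites:
        raise ContractError("foraging_multisite requires at least one site")
    scheduler = sites[0][0].scheduler
    streams = [foraging_site(a, s, w, site_id=i)
               for i, (a, s, w) in enumerate(sites)]
    return merge(scheduler, streams)


def fsm_explosion_count(n_sites: int, states_per_site: int,
                        nodes_per_site: int = 4) -> tuple[int, int]:
    """Size of the flat product machine vs the replicated dataflow.

    A flat FSM over n independent sites needs every combination of per-site
    states: ``states_per_site ** n_sites``.  The dataflow just replicates
    one site's nodes (availability source, sample source, coincidence
    detector, reward — 4 by default): ``n_sites * nodes_per_site``, linear.
    """
    if n_sites < 1 or states_per_site < 1:
        raise ContractError("n_sites and states_per_site must be >= 1")
    return states_per_site ** n_sites, n_sites * nodes_per_site


def rewards_to_frame(rewards: Sequence[RewardEvent]) -> pd.DataFrame:
    """Reward events as a tidy table (CSV-ready)."""
    return pd.DataFrame([{"site_id": r.site_id, "time": r.time,
                          "availability_time": r.availability_time}
                         for r in rewards],
                        columns=["site_id", "time", "availability_time"])


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Trial records as a tidy table (CSV-ready)."""
    return pd.DataFrame([{"trial": t.trial, "stimulus_time": t.stimulus_time,
                          "response_time": t.response_time, "rt": t.rt}
                         for t in trials],
                        columns=["trial", "stimulus_time", "response_time",
                                 "rt"])
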