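"""Task control: state chaining vs an explicit FSM interpreter, reaction
times, and the foraging coincidence rule vs an event-sweep oracle."""

import numpy as np
import pytest

import rivulet as rv
from rivulet.core import ContractError, Kind
from rivulet.fixtures import EventScheduleConfig, events_to_stream, \
    gen_event_schedule
from rivulet.tasks import (RewardEvent, StateSpec, Transition, chain_states,
                           foraging_multisite, foraging_site,
                           fsm_explosion_count, reaction_time_task,
                           rewards_to_frame, trials_to_frame)


def fsm_interpreter(delay, keys, until):
    """Explicit hand-coded Ready/Go machine: the oracle for the reactive one.

    Keys at or before the stimulus tick are ignored (the Go state only
    listens from stimulus onset).
    """
    transitions = [("Ready", 0)]
    trials = []
    t, trial = 0, 0
    while True:
        stimulus = t + delay
        if stimulus > until:
            break
        transitions.append(("Go", stimulus))
        key = next((k for k in keys if k > stimulus), None)
        if key is None or key > until:
            break
        trial += 1
        trials.append((trial, stimulus, key))
        transitions.append(("Ready", key))
        t = key
    return transitions, trials


def foraging_sweep(avail_times, sample_times, w):
    """Stateful sweep over the merged event list: the coincidence oracle."""
    events = sorted([(int(t), 0) for t in avail_times] +
                    [(int(t), 1) for t in sample_times])
    armed = None
    rewards = []
    for t, kind in events:
        if kind == 0:
            armed = t  # re-arming replaces the pending availability
        elif armed is not None and t <= armed + w:
            rewards.append((t, armed))
            armed = None
    return rewards


class TestChainStates:
    def test_two_state_machine_transition_log(self, scheduler):
        keys = events_to_stream(scheduler, [8, 30, 55])
        ready = StateSpec("Ready", lambda: rv.timer(scheduler, 5))
        go = StateSpec("Go", lambda: keys)
        machine = rv.repeat(scheduler, chain_states(scheduler, [ready, go]))
        log = []
        machine.subscribe(on_next=log.append)
        scheduler.advance_to(60)
        assert [(t.state, t.time) for t in log] == [
            ("Ready", 0), ("Go", 5), ("Ready", 8), ("Go", 13),
            ("Ready", 30), ("Go", 35), ("Ready", 55), ("Go", 60)]

    def test_entry_actions_fire_at_activation_tick(self, scheduler):
        fired = []
        spec = StateSpec("S", lambda: rv.timer(scheduler, 3),
                         entry_actions=[fired.append])
        chain_states(scheduler, [spec])().subscribe()
        scheduler.run()
        assert fired == [0]

    def test_immediate_exit_loop_trips_zero_time_guard(self, scheduler):
        instant = StateSpec("S", lambda: rv.cold(
            scheduler, rv.parse_marble("(x|)")))
        machine = rv.repeat(scheduler, chain_states(scheduler, [instant]))
        log = rv.record(machine)
        assert log[-1].kind is Kind.ERROR
        assert "zero-time loop" in log[-1].error_info

    def test_n_states_cycle_twice_under_take(self, scheduler):
        names = ["a", "b", "c"]
        specs = [StateSpec(n, lambda: rv.timer(scheduler, 1)) for n in names]
        machine = rv.take(
            rv.repeat(scheduler, chain_states(scheduler, specs)), 6)
        log = rv.record(machine)
        assert [t.payload.state for t in log if t.kind is Kind.NEXT] == \
            names * 2

    def test_empty_state_list_rejected(self, scheduler):
        with pytest.raises(ContractError):
            chain_states(scheduler, [])


class TestReactionTimeTask:
    def run_task(self, delay, keys, until=10000):
        scheduler = rv.VirtualScheduler()
        key_stream = events_to_stream(scheduler, keys)
        trials = []
        reaction_time_task(scheduler, delay, key_stream).subscribe(
            on_next=trials.append)
        scheduler.advance_to(until)
        return trials

    def test_constant_latency_gives_constant_rt(self):
        delay, latency = 5, 3
        keys, t = [], 0
        for _ in range(4):
            t += delay + latency
            keys.append(t)
        trials = self.run_task(delay, keys, until=100)
        assert [tr.rt for tr in trials] == [3, 3, 3, 3]

    def test_no_key_press_no_trial(self):
        assert self.run_task(5, [], until=100) == []

    def test_keys_during_ready_are_ignored(self):
        # key at tick 2 lands in Ready (stimulus at 5); only the key at 9
        # closes the trial
        trials = self.run_task(5, [2, 9], until=50)
        assert [(tr.stimulus_time, tr.response_time) for tr in trials][:1] == \
            [(5, 9)]

    def test_random_latencies_recovered_exactly(self, rng):
        delay = 50
        latencies = [int(x) for x in rng.integers(1, 200, 60)]
        keys, t = [], 0
        for latency in latencies:
            t += delay + latency
            keys.append(t)
        trials = self.run_task(delay, keys, until=t + 1)
        assert [tr.rt for tr in trials] == latencies

    def test_matches_fsm_interpreter_on_random_scripts(self, rng):
        for _ in range(20):
            delay = int(rng.integers(1, 30))
            keys = sorted(int(x) for x in rng.integers(1, 2000, 40))
            until = 2000
            scheduler = rv.VirtualScheduler()
            key_stream = events_to_stream(scheduler, keys)
            ready = StateSpec("Ready", lambda: rv.timer(scheduler, delay))
            go = StateSpec("Go", lambda: key_stream)
            log = []
            rv.repeat(scheduler, chain_states(scheduler, [ready, go])
                      ).subscribe(on_next=log.append)
            scheduler.advance_to(until)
            got = [(t.state, t.time) for t in log]
            want, _ = fsm_interpreter(delay, keys, until)
            # the interpreter stops at `until`; compare the common prefix
            assert got[:len(want)] == want
            assert len(got) - len(want) <= 1


class TestForagingSite:
    def run_site(self, avail, samples, w, until=1000):
        scheduler = rv.VirtualScheduler()
        a = events_to_stream(scheduler, avail, complete_at=until)
        s = events_to_stream(scheduler, samples, complete_at=until)
        rewards = []
        foraging_site(a, s, w).subscribe(on_next=rewards.append)
        scheduler.run()
        return rewards

    def test_sample_within_window_collects(self):
        rewards = self.run_site([10], [12], w=5)
        assert [(r.time, r.availability_time) for r in rewards] == [(10 + 2, 10)]

    def test_sample_after_window_rots(self):
        assert self.run_site([10], [16], w=5) == []

    def test_rearming_replaces_pending_availability(self):
        rewards = self.run_site([10, 12], [13], w=10)
        assert [(r.time, r.availability_time) for r in rewards] == [(13, 12)]

    def test_one_reward_per_availability(self):
        rewards = self.run_site([10], [11, 12, 13], w=10)
        assert len(rewards) == 1

    def test_window_is_inclusive_at_both_ends(self):
        assert len(self.run_site([10], [10], w=5)) == 1
        assert len(self.run_site([10], [15], w=5)) == 1

    def test_nonpositive_window_rejected(self, scheduler):
        with pytest.raises(ContractError):
            foraging_site(rv.never(scheduler), rv.never(scheduler), 0)

    def test_matches_event_sweep_oracle_on_poisson_schedules(self):
        duration, w = 50000, 60
        avail = gen_event_schedule(EventScheduleConfig(
            seed=21, duration=duration, rate=1 / 200))
        samples = gen_event_schedule(EventScheduleConfig(
            seed=22, duration=duration, rate=1 / 50))
        got = self.run_site(avail, samples, w, until=duration)
        want = foraging_sweep(avail, samples, w)
        assert [(r.time, r.availability_time) for r in got] == want

    def test_reward_validity_invariant(self):
        duration, w = 30000, 40
        avail = gen_event_schedule(EventScheduleConfig(
            seed=23, duration=duration, rate=1 / 150))
        samples = gen_event_schedule(EventScheduleConfig(
            seed=24, duration=duration, rate=1 / 30))
        rewards = self.run_site(avail, samples, w, until=duration)
        for r in rewards:
            assert r.availability_time <= r.time <= r.availability_time + w
        # at most one reward per availability event
        assert len({r.availability_time for r in rewards}) == len(rewards)


class TestForagingMultisite:
    def make_sites(self, scheduler, schedules, w, until):
        return [(events_to_stream(scheduler, a, complete_at=until),
                 events_to_stream(scheduler, s, complete_at=until), w)
                for a, s in schedules]

    def test_events_only_at_site_zero(self, scheduler):
        sites = self.make_sites(scheduler, [([10], [12]), ([], [])], 5, 100)
        rewards = []
        foraging_multisite(sites).subscribe(on_next=rewards.append)
        scheduler.run()
        assert [r.site_id for r in rewards] == [0]

    def test_simultaneous_rewards_ordered_by_site(self, scheduler):
        sites = self.make_sites(scheduler, [([10], [12]), ([11], [12])], 5, 100)
        rewards = []
        foraging_multisite(sites).subscribe(on_next=rewards.append)
        scheduler.run()
        assert [(r.site_id, r.time) for r in rewards] == [(0, 12), (1, 12)]

    def test_site_independence(self):
        until, w = 20000, 50
        schedules = []
        for i in range(3):
            avail = gen_event_schedule(EventScheduleConfig(
                seed=31 + 2 * i, duration=until, rate=1 / 180))
            samp = gen_event_schedule(EventScheduleConfig(
                seed=32 + 2 * i, duration=until, rate=1 / 60))
            schedules.append((avail, samp))
        scheduler = rv.VirtualScheduler()
        rewards = []
        foraging_multisite(self.make_sites(scheduler, schedules, w, until)
                           ).subscribe(on_next=rewards.append)
        scheduler.run()
        for i, (avail, samp) in enumerate(schedules):
            solo_sched = rv.VirtualScheduler()
            solo = []
            foraging_site(
                events_to_stream(solo_sched, avail, complete_at=until),
                events_to_stream(solo_sched, samp, complete_at=until),
                w, site_id=i).subscribe(on_next=solo.append)
            solo_sched.run()
            mine = [(r.time, r.availability_time) for r in rewards
                    if r.site_id == i]
            assert mine == [(r.time, r.availability_time) for r in solo]

    def test_reward_probability_matches_arming_rule_closed_form(self):
        # P(reward | availability i) = 1 - exp(-lam_s * k_i) with k_i the
        # armed tick count min(w+1, gap to next A, remaining duration)
        duration, w = 400000, 60
        lam_s = 1 / 50
        avail = gen_event_schedule(EventScheduleConfig(
            seed=41, duration=duration, rate=1 / 200))
        samples = gen_event_schedule(EventScheduleConfig(
            seed=42, duration=duration, rate=lam_s))
        rewards = foraging_sweep(avail, samples, w)
        gaps = np.diff(np.append(avail, duration))
        k = np.minimum(w + 1, gaps)
        p = 1.0 - np.exp(-lam_s * k)
        expected = p.sum()
        se = np.sqrt((p * (1 - p)).sum())
        assert abs(len(rewards) - expected) < 3 * se
        # and the engine agrees with the sweep (spot check at this size)
        scheduler = rv.VirtualScheduler()
        got = []
        foraging_site(
            events_to_stream(scheduler, avail, complete_at=duration),
            events_to_stream(scheduler, samples, complete_at=duration),
            w).subscribe(on_next=got.append)
        scheduler.run()
        assert len(got) == len(rewards)


class TestFsmExplosion:
    @pytest.mark.parametrize("sites,states,product", [
        (1, 2, 2), (2, 2, 4), (5, 3, 243)])
    def test_product_machine_grows_exponentially(self, sites, states, product):
        flat, dataflow = fsm_explosion_count(sites, states)
        assert flat == product
        assert dataflow == 4 * sites

    def test_bad_arguments_rejected(self):
        with pytest.raises(ContractError):
            fsm_explosion_count(0, 2)


class TestExports:
    def test_reward_frame_columns(self):
        frame = rewards_to_frame([RewardEvent(1, 12, 10)])
        assert list(frame.columns) == ["site_id", "time", "availability_time"]
        assert frame.iloc[0]["time"] == 12

    def test_trials_frame_has_rt(self):
        from rivulet.tasks import TrialRecord
        frame = trials_to_frame([TrialRecord(1, 5, 9)])
        assert frame.iloc[0]["rt"] == 4
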