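"""Workflow model: validation diagnostics, builder semantics, YAML round
trips, property externalization, and CLI exit codes."""

import numpy as np
import pytest
from click.testing import CliRunner

import rivulet as rv
from rivulet.cli import main as cli_main
from rivulet.core import Kind
from rivulet.fixtures import (DotVideoConfig, events_to_stream,
                              frames_to_stream, gen_dot_video)
from rivulet.graph import (BuildError, Category, DataflowGraph, StreamNode,
                           WorkflowError, build, default_registry,
                           load_workflow, save_workflow, validate)
from rivulet.vision import read_frames


def node(nid, category, operator, params=None, props=None):
    return StreamNode(nid, category, operator, params or {}, props or [])


@pytest.fixture()
def registry():
    return default_registry()


class TestValidate:
    def test_minimal_source_sink_graph_is_clean(self, registry):
        g = DataflowGraph(
            nodes=[node("src", Category.SOURCE, "marble", {"text": "ab|"}),
                   node("out", Category.SINK, "log")],
            edges=[("src", "out", 0)])
        assert validate(g, registry) == []

    def test_two_cycle_is_diagnosed(self, registry):
        g = DataflowGraph(
            nodes=[node("a", Category.TRANSFORM, "map", {"function": "identity"}),
                   node("b", Category.TRANSFORM, "map", {"function": "identity"})],
            edges=[("a", "b", 0), ("b", "a", 0)])
        assert any("cycle" in d for d in validate(g, registry))

    def test_transform_with_two_inputs_is_an_arity_error(self, registry):
        g = DataflowGraph(
            nodes=[node("s1", Category.SOURCE, "marble", {"text": "a|"}),
                   node("s2", Category.SOURCE, "marble", {"text": "b|"}),
                   node("t", Category.TRANSFORM, "map",
                        {"function": "identity"})],
            edges=[("s1", "t", 0), ("s2", "t", 1)])
        assert any("arity" in d and "'t'" in d for d in validate(g, registry))

    def test_unknown_operator_is_diagnosed(self, registry):
        g = DataflowGraph(nodes=[node("s", Category.SOURCE, "warp_drive")])
        assert any("unknown operator" in d for d in validate(g, registry))

    def test_unknown_edge_endpoint(self, registry):
        g = DataflowGraph(nodes=[node("s", Category.SOURCE, "timer")],
                          edges=[("s", "ghost", 0)])
        assert any("unknown node 'ghost'" in d for d in validate(g, registry))


class TestBuild:
    def test_single_source_pipeline(self, scheduler):
        g = DataflowGraph(nodes=[node("s", Category.SOURCE, "marble",
                                      {"text": "ab|"})])
        pipeline = build(g, scheduler).run()
        assert [n.payload for n in pipeline.taps["s"].log
                if n.kind is Kind.NEXT] == ["a", "b"]

    def test_snapshot_graph_saves_one_frame_per_key(self, scheduler,
                                                    tmp_path):
        g = DataflowGraph(
            nodes=[node("cam", Category.SOURCE, "fixture", {"name": "video"}),
                   node("keys", Category.SOURCE, "fixture", {"name": "keys"}),
                   node("snap", Category.COMBINATOR, "sample"),
                   node("save", Category.SINK, "frame_file",
                        {"path": "snaps.frames"})],
            edges=[("cam", "snap", 0), ("keys", "snap", 1),
                   ("snap", "save", 0)])
        frames, _ = gen_dot_video(DotVideoConfig(seed=0, n_frames=30))
        fixtures = {"video": frames_to_stream(scheduler, frames),
                    "keys": events_to_stream(scheduler, [4, 11, 17],
                                             complete_at=30)}
        build(g, scheduler, fixtures=fixtures, out_dir=tmp_path).run()
        assert len(read_frames(tmp_path / "snaps.frames")) == 3

    def test_user_function_transform_equals_direct_map(self, scheduler):
        g = DataflowGraph(
            nodes=[node("s", Category.SOURCE, "marble",
                        {"text": "123|", "values": {"1": 1, "2": 2, "3": 3}}),
                   node("t", Category.TRANSFORM, "map",
                        {"function": "double"})],
            edges=[("s", "t", 0)])
        pipeline = build(g, scheduler).run()
        got = [(n.payload, n.time) for n in pipeline.taps["t"].log
               if n.kind is Kind.NEXT]
        sched2 = rv.VirtualScheduler()
        direct = rv.record(rv.map_(
            rv.hot(sched2, rv.parse_marble("123|",
                                           values={"1": 1, "2": 2, "3": 3})),
            lambda v: v * 2))
        assert got == [(n.payload, n.time) for n in direct
                       if n.kind is Kind.NEXT]

    def test_property_binding_drives_threshold(self, scheduler):
        # threshold defaults to 10; a property stream lowers it to 5 at
        # tick 2; values 8@1 and 8@3 -> only the later one passes
        g = DataflowGraph(
            nodes=[node("data", Category.SOURCE, "marble",
                        {"text": "-v-v|", "values": {"v": 8}}),
                   node("thr", Category.SOURCE, "marble",
                        {"text": "--5|", "values": {"5": 5}}),
                   node("test", Category.CONDITION, "filter",
                        {"function": "ge_threshold", "threshold": 10},
                        props=["threshold"]),
                   node("set_thr", Category.PROPERTY, "property",
                        {"target": "test", "name": "threshold"})],
            edges=[("data", "test", 0), ("thr", "set_thr", 0)])
        pipeline = build(g, scheduler).run()
        got = [(n.payload, n.time) for n in pipeline.taps["test"].log
               if n.kind is Kind.NEXT]
        assert got == [(8, 3)]

    def test_unexposed_property_is_a_build_error(self, scheduler):
        g = DataflowGraph(
            nodes=[node("data", Category.SOURCE, "marble", {"text": "a|"}),
                   node("thr", Category.SOURCE, "marble", {"text": "b|"}),
                   node("test", Category.CONDITION, "filter",
                        {"function": "ge_threshold"}),
                   node("p", Category.PROPERTY, "property",
                        {"target": "test", "name": "threshold"})],
            edges=[("data", "test", 0), ("thr", "p", 0)])
        with pytest.raises(BuildError):
            build(g, scheduler)

    def test_nested_group_compiles_and_runs(self, scheduler):
        inner = DataflowGraph(
            nodes=[node("in0", Category.SOURCE, "group_input", {"slot": 0}),
                   node("dbl", Category.TRANSFORM, "map",
                        {"function": "double"}),
                   node("out", Category.SINK, "group_output")],
            edges=[("in0", "dbl", 0), ("dbl", "out", 0)])
        g = DataflowGraph(
            nodes=[node("s", Category.SOURCE, "marble",
                        {"text": "12|", "values": {"1": 1, "2": 2}}),
                   node("grp", Category.NESTED, "group")],
            edges=[("s", "grp", 0)], groups={"grp": inner})
        pipeline = build(g, scheduler).run()
        assert [n.payload for n in pipeline.taps["grp"].log
                if n.kind is Kind.NEXT] == [2, 4]

    def test_group_reused_twice_is_state_isolated(self, scheduler):
        # 'add' reads its params per element; two instances must not share
        # NodeParams even when compiled from one group description
        inner = DataflowGraph(
            nodes=[node("in0", Category.SOURCE, "group_input", {"slot": 0}),
                   node("t", Category.COMBINATOR, "take", {"n": 1}),
                   node("out", Category.SINK, "group_output")],
            edges=[("in0", "t", 0), ("t", "out", 0)])
        g = DataflowGraph(
            nodes=[node("s1", Category.SOURCE, "marble", {"text": "ab|"}),
                   node("s2", Category.SOURCE, "marble", {"text": "-xy|"}),
                   node("g1", Category.NESTED, "group"),
                   node("g2", Category.NESTED, "group")],
            edges=[("s1", "g1", 0), ("s2", "g2", 0)],
            groups={"g1": inner, "g2": inner})
        pipeline = build(g, scheduler).run()
        assert [n.payload for n in pipeline.taps["g1"].log
                if n.kind is Kind.NEXT] == ["a"]
        assert [n.payload for n in pipeline.taps["g2"].log
                if n.kind is Kind.NEXT] == ["x"]

    def test_select_many_group_runs_per_window(self, scheduler):
        inner = DataflowGraph(
            nodes=[node("in0", Category.SOURCE, "group_input", {"slot": 0}),
                   node("first", Category.COMBINATOR, "take", {"n": 1}),
                   node("out", Category.SINK, "group_output")],
            edges=[("in0", "first", 0), ("first", "out", 0)])
        g = DataflowGraph(
            nodes=[node("s", Category.SOURCE, "marble", {"text": "abcd|"}),
                   node("w", Category.COMBINATOR, "window_count",
                        {"count": 2, "skip": 2}),
                   node("sm", Category.NESTED, "select_many")],
            edges=[("s", "w", 0), ("w", "sm", 0)], groups={"sm": inner})
        pipeline = build(g, scheduler).run()
        # first element of each pair-window
        assert [n.payload for n in pipeline.taps["sm"].log
                if n.kind is Kind.NEXT] == ["a", "c"]


class TestWorkflowFiles:
    def test_minimal_yaml_loads(self, tmp_path):
        path = tmp_path / "wf.yaml"
        path.write_text("nodes:\n- id: s\n  category: source\n"
                        "  operator: timer\n")
        graph = load_workflow(path)
        assert len(graph.nodes) == 1
        assert graph.nodes[0].category is Category.SOURCE

    def test_unknown_category_rejected(self, tmp_path):
        path = tmp_path / "wf.yaml"
        path.write_text("nodes:\n- id: s\n  category: wormhole\n"
                        "  operator: timer\n")
        with pytest.raises(WorkflowError):
            load_workflow(path)

    def _random_graph(self, rng):
        n_sources = int(rng.integers(1, 4))
        nodes = [node(f"s{i}", Category.SOURCE, "marble",
                      {"text": "ab|", "tick": int(rng.integers(1, 5))})
                 for i in range(n_sources)]
        edges = []
        for i in range(n_sources):
            nodes.append(node(f"t{i}", Category.TRANSFORM, "map",
                              {"function": "identity"}))
            edges.append((f"s{i}", f"t{i}", 0))
        if rng.random() < 0.5:
            nodes.append(node("m", Category.COMBINATOR, "merge"))
            edges.extend((f"t{i}", "m", i) for i in range(n_sources))
        return DataflowGraph(nodes, edges)

    def test_randomized_round_trips_are_structural_identities(self, tmp_path,
                                                              rng):
        for i in range(15):
            graph = self._random_graph(rng)
            path = tmp_path / f"wf{i}.yaml"
            save_workflow(graph, path)
            assert load_workflow(path) == graph

    def test_build_after_round_trip_gives_identical_logs(self, tmp_path):
        g = DataflowGraph(
            nodes=[node("s", Category.SOURCE, "marble", {"text": "a-b-c|"}),
                   node("t", Category.TRANSFORM, "map",
                        {"function": "identity"})],
            edges=[("s", "t", 0)])
        path = tmp_path / "wf.yaml"
        save_workflow(g, path)
        first = build(g, rv.VirtualScheduler()).run()
        second = build(load_workflow(path), rv.VirtualScheduler()).run()
        to_rows = lambda p: [(n.time, n.kind, n.payload)
                             for n in p.taps["t"].log]
        assert to_rows(first) == to_rows(second)


class TestCli:
    def write(self, tmp_path, text):
        path = tmp_path / "wf.yaml"
        path.write_text(text)
        return str(path)

    def test_validate_clean_workflow_exits_zero(self, tmp_path):
        wf = self.write(tmp_path, "nodes:\n- id: s\n  category: source\n"
                                  "  operator: timer\n")
        result = CliRunner().invoke(cli_main, ["validate", wf])
        assert result.exit_code == 0

    def test_validate_cyclic_workflow_exits_one(self, tmp_path):
        wf = self.write(
            tmp_path,
            "nodes:\n"
            "- {id: a, category: transform, operator: map,"
            " params: {function: identity}}\n"
            "- {id: b, category: transform, operator: map,"
            " params: {function: identity}}\n"
            "edges:\n- [a, b, 0]\n- [b, a, 0]\n")
        result = CliRunner().invoke(cli_main, ["validate", wf])
        assert result.exit_code == 1 and "cycle" in result.output

    def test_run_twice_with_same_seed_is_deterministic(self, tmp_path):
        wf = self.write(
            tmp_path,
            "nodes:\n"
            "- {id: keys, category: source, operator: fixture,"
            " params: {name: keys}}\n"
            "- {id: stamped, category: combinator, operator: timestamp}\n"
            "edges:\n- [keys, stamped, 0]\n")
        runner = CliRunner()
        outputs = []
        for run in ("one", "two"):
            out = tmp_path / run
            result = runner.invoke(cli_main, [
                "run", wf, "--seed", "7", "--out", str(out)])
            assert result.exit_code == 0, result.output
            outputs.append((out / "notifications.csv").read_text())
        assert outputs[0] == outputs[1]

    def test_demo_foraging_writes_reward_csv(self, tmp_path):
        result = CliRunner().invoke(cli_main, [
            "demo", "foraging", "--until", "10000", "--out", str(tmp_path),
            "--seed", "3"])
        assert result.exit_code == 0, result.output
        text = (tmp_path / "rewards.csv").read_text()
        assert text.startswith("site_id,time,availability_time")
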