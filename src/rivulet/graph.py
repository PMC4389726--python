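"""Declarative dataflow graphs: typed nodes, validation, YAML workflows,
and a builder that compiles a graph into a live subscription.

A workflow is a directed acyclic graph of typed nodes (source, transform,
condition, sink, combinator, property, nested).  Edges are positional: the
k-th inbound edge of a multi-input combinator feeds its input slot k (e.g.
``sample``'s data vs trigger input).  Nested nodes encapsulate a sub-graph
whose ``group_input`` placeholder sources stand for the node's inbound
connections and whose single ``group_output`` sink is the node's output;
the same sub-graph powers ``select_many``, instantiated afresh per window.

The workflow file format is YAML (JSON-compatible) with ``nodes``,
``edges`` and ``groups`` keys; see docs/workflow.schema.json.  This format
is an original design for this engine, not a reproduction of any existing
tool's file dialect.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Optional, Sequence

import networkx as nx
import yaml

from . import combinators as cb
from . import windows as wd
from .core import (ContractError, Notification, Observable, Recorder,
                   VirtualScheduler, hot, timer)
from .marble import parse_marble
from .vision import Frame, frame_writer, grayscale, track_largest


class Category(enum.Enum):
    SOURCE = "source"
    COMBINATOR = "combinator"
    TRANSFORM = "transform"
    CONDITION = "condition"
    SINK = "sink"
    PROPERTY = "property"
    NESTED = "nested"


#: inbound-edge arity per category: (min, max); None = unbounded
_ARITY: dict[Category, tuple[int, Optional[int]]] = {
    Category.SOURCE: (0, 0),
    Category.TRANSFORM: (1, 1),
    Category.CONDITION: (1, 1),
    Category.SINK: (1, 1),
    Category.PROPERTY: (1, 1),
    Category.COMBINATOR: (0, None),
    Category.NESTED: (0, None),
}


@dataclass
class StreamNode:
    """One dataflow node: a category, a registered operator, and parameters."""

    id: str
    category: Category
    operator: str
    params: dict = field(default_factory=dict)
    exposed_properties: list[str] = field(default_factory=list)


@dataclass
class DataflowGraph:
    """Nodes plus ordered positional edges; nested graphs per NESTED node."""

    nodes: list[StreamNode] = field(default_factory=list)
    edges: list[tuple[str, str, int]] = field(default_factory=list)
    groups: dict[str, "DataflowGraph"] = field(default_factory=dict)

    def node(self, node_id: str) -> StreamNode:
        for node in self.nodes:
            if node.id == node_id:
                return node
        raise KeyError(node_id)

    def inbound(self, node_id: str) -> list[tuple[str, int]]:
        """(from_id, slot) pairs feeding node_id, in edge order."""
        return [(f, slot) for f, t, slot in self.edges if t == node_id]


# ---------------------------------------------------------------------------
# Operator registry
# ---------------------------------------------------------------------------

class NodeParams:
    """A node's parameter view: static values, overridable by live bindings.

    Operators read parameters *per element* through this object, so an
    externalized property bound at runtime takes effect for every element
    after the update, with no operator-side plumbing.
    """

    def __init__(self, static: dict) -> None:
        self._static = dict(static)
        self._bindings: dict[str, cb.PropertyBinding] = {}

    def bind(self, name: str, binding: cb.PropertyBinding) -> None:
        self._bindings[name] = binding

    def get(self, name: str, default: Any = None) -> Any:
        if name in self._bindings:
            return self._bindings[name].current_value
        return self._static.get(name, default)

    def __contains__(self, name: str) -> bool:
        return name in self._bindings or name in self._static


@dataclass
class BuildContext:
    """Everything a node factory may need at instantiation time."""

    scheduler: VirtualScheduler
    fixtures: dict[str, Observable] = field(default_factory=dict)
    out_dir: Optional[Path] = None
    registry: "OperatorRegistry" = None  # set by build()


Factory = Callable[[StreamNode, NodeParams, list[Observable], BuildContext],
                   Observable]


class BuildError(RuntimeError):
    """Graph could not be compiled (unknown operator, missing fixture, ...)."""


class OperatorRegistry:
    """name -> factory table; operator packs register their nodes at import."""

    def __init__(self) -> None:
        self._factories: dict[str, Factory] = {}
        self.functions: dict[str, Callable] = {}

    def register(self, name: str, factory: Factory) -> None:
        self._factories[name] = factory

    def register_function(self, name: str, fn: Callable) -> None:
        """Pure named functions usable from map/filter nodes in workflows."""
        self.functions[name] = fn

    def __contains__(self, name: str) -> bool:
        return name in self._factories

    def factory(self, name: str) -> Factory:
        if name not in self._factories:
            raise BuildError(f"unknown operator {name!r}")
        return self._factories[name]


def _resolve_function(registry: OperatorRegistry, params: NodeParams,
                      node: StreamNode) -> Callable:
    name = params.get("function")
    if name not in registry.functions:
        raise BuildError(f"node {node.id!r}: unknown function {name!r}")
    fn = registry.functions[name]

    def call(value):
        return fn(value, params)

    return call


def default_registry() -> OperatorRegistry:
    """The built-in operator and function tables."""
    reg = OperatorRegistry()

    # --- sources -----------------------------------------------------------
    def src_fixture(node, params, inputs, ctx):
        name = params.get("name")
        if name not in ctx.fixtures:
            raise BuildError(f"node {node.id!r}: no fixture named {name!r}")
        return ctx.fixtures[name]

    def src_marble(node, params, inputs, ctx):
        notifs = parse_marble(params.get("text", "|"),
                              tick=params.get("tick", 1),
                              values=params.get("values", {}))
        return hot(ctx.scheduler, notifs)

    def src_timer(node, params, inputs, ctx):
        return timer(ctx.scheduler, params.get("delay", 1),
                     params.get("payload", 0))

    reg.register("fixture", src_fixture)
    reg.register("marble", src_marble)
    reg.register("timer", src_timer)

    # --- transforms / conditions / sinks ----------------------------------
    def op_map(node, params, inputs, ctx):
        fn = _resolve_function(ctx.registry, params, node)
        return cb.map_(inputs[0], fn)

    def op_filter(node, params, inputs, ctx):
        fn = _resolve_function(ctx.registry, params, node)
        return cb.filter_(inputs[0], fn)

    def op_log(node, params, inputs, ctx):
        return inputs[0]  # taps record every node output; log is identity

    def op_frame_file(node, params, inputs, ctx):
        path = (ctx.out_dir or Path(".")) / params.get("path", f"{node.id}.frames")
        return frame_writer(inputs[0], path)

    reg.register("map", op_map)
    reg.register("filter", op_filter)
    reg.register("log", op_log)
    reg.register("frame_file", op_frame_file)

    # --- combinators -------------------------------------------------------
    reg.register("sample", lambda n, p, i, c: cb.sample(i[0], i[1]))
    reg.register("merge", lambda n, p, i, c: cb.merge(c.scheduler, i))
    reg.register("take", lambda n, p, i, c: cb.take(i[0], p.get("n", 1)))
    reg.register("timestamp", lambda n, p, i, c: cb.timestamp(i[0]))
    reg.register("window_count",
                 lambda n, p, i, c: wd.window_count(i[0], p.get("count", 1),
                                                    p.get("skip", 1)))
    reg.register("window_time",
                 lambda n, p, i, c: wd.window_time(i[0], p.get("duration", 1)))
    reg.register("window_trigger",
                 lambda n, p, i, c: wd.window_trigger(i[0], i[1]))
    reg.register("moving_average",
                 lambda n, p, i, c: wd.moving_average(i[0], p.get("k", 1)))

    # --- named pure functions for map/filter nodes -------------------------
    reg.register_function("identity", lambda v, p: v)
    reg.register_function("double", lambda v, p: v * 2)
    reg.register_function("add", lambda v, p: v + p.get("addend", 0))
    reg.register_function(
        "rescale", lambda v, p: cb.rescale(v, p.get("lo", 0.0),
                                           p.get("hi", 1.0),
                                           p.get("range_lo", 0.0),
                                           p.get("range_hi", 1.0)))
    reg.register_function("even", lambda v, p: v % 2 == 0)
    reg.register_function("ge_threshold",
                          lambda v, p: v >= p.get("threshold", 0))
    reg.register_function(
        "grayscale", lambda f, p: Frame(grayscale(f.pixels), f.time, f.index))
    reg.register_function(
        "track_largest",
        lambda f, p: track_largest(f, p.get("lo", 128), p.get("hi", 255),
                                   p.get("invert", False)))
    return reg


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate(graph: DataflowGraph,
             registry: Optional[OperatorRegistry] = None) -> list[str]:
    """Structural diagnostics; an empty list means the graph is buildable.

    Checks: edge endpoints exist, per-category input arity, acyclicity,
    nested-group placeholder structure, and (when a registry is supplied)
    operator existence.
    """
    diagnostics: list[str] = []
    ids = [n.id for n in graph.nodes]
    if len(set(ids)) != len(ids):
        diagnostics.append("duplicate node ids")
    known = set(ids)

    for f, t, slot in graph.edges:
        for endpoint in (f, t):
            if endpoint not in known:
                diagnostics.append(f"edge references unknown node {endpoint!r}")

    digraph = nx.MultiDiGraph()
    digraph.add_nodes_from(known)
    digraph.add_edges_from((f, t) for f, t, _ in graph.edges
                           if f in known and t in known)
    if not nx.is_directed_acyclic_graph(digraph):
        cycle = nx.find_cycle(digraph)
        members = sorted({a for a, b, *_ in cycle})
        diagnostics.append(f"cycle through nodes {members}")

    for node in graph.nodes:
        fan_in = [(f, s) for f, t, s in graph.edges if t == node.id]
        lo, hi = _ARITY[node.category]
        if len(fan_in) < lo or (hi is not None and len(fan_in) > hi):
            bound = f"exactly {lo}" if lo == hi else f"between {lo} and {hi}"
            diagnostics.append(
                f"arity: node {node.id!r} ({node.category.value}) has "
                f"{len(fan_in)} inputs, expects {bound}")
        slots = sorted(s for _, s in fan_in)
        if slots != list(range(len(slots))):
            diagnostics.append(
                f"arity: node {node.id!r} input slots {slots} are not 0..n-1")
        builtin = ("group", "select_many", "group_input", "group_output",
                   "property")
        if registry is not None and node.category is not Category.NESTED \
                and node.category is not Category.PROPERTY \
                and node.operator not in builtin \
                and node.operator not in registry:
            diagnostics.append(
                f"operator: node {node.id!r} uses unknown operator "
                f"{node.operator!r}")
        if node.category is Category.PROPERTY:
            target = node.params.get("target")
            if target not in known:
                diagnostics.append(
                    f"property: node {node.id!r} targets unknown node "
                    f"{target!r}")
        if node.category is Category.NESTED:
            diagnostics.extend(_validate_group(graph, node, registry))
    return diagnostics


def _validate_group(graph: DataflowGraph, node: StreamNode,
                    registry: Optional[OperatorRegistry]) -> list[str]:
    problems = []
    group = graph.groups.get(node.id)
    if group is None:
        return [f"nested: node {node.id!r} has no group definition"]
    n_inputs = len(graph.inbound(node.id))
    placeholders = [n for n in group.nodes if n.operator == "group_input"]
    outputs = [n for n in group.nodes if n.operator == "group_output"]
    expected_inputs = 1 if node.operator == "select_many" else n_inputs
    got_slots = sorted(n.params.get("slot", 0) for n in placeholders)
    if got_slots != list(range(expected_inputs)):
        problems.append(
            f"nested: group of {node.id!r} needs one input placeholder per "
            f"external input (slots 0..{expected_inputs - 1}), got {got_slots}")
    if len(outputs) != 1:
        problems.append(
            f"nested: group of {node.id!r} needs exactly one group_output, "
            f"got {len(outputs)}")
    problems.extend(validate(group, registry))
    return problems


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------

@dataclass
class Pipeline:
    """A compiled workflow: per-node output streams and recorders."""

    scheduler: VirtualScheduler
    outputs: dict[str, Observable]
    taps: dict[str, Recorder]
    subscriptions: list = field(default_factory=list)

    def run(self, until: Optional[int] = None) -> "Pipeline":
        if until is None:
            self.scheduler.run()
        else:
            self.scheduler.advance_to(until)
        return self

    def log_rows(self) -> list[tuple[str, int, str, str]]:
        """(tap, tick, kind, payload-repr) rows for all taps, time-ordered."""
        rows = []
        for name, recorder in self.taps.items():
            for notif in recorder.log:
                rows.append((name, notif.time, notif.kind.name,
                             repr(notif.payload)))
        rows.sort(key=lambda r: (r[1], r[0]))
        return rows


def _topo_order(graph: DataflowGraph) -> list[StreamNode]:
    digraph = nx.DiGraph()
    digraph.add_nodes_from(n.id for n in graph.nodes)
    digraph.add_edges_from((f, t) for f, t, _ in graph.edges)
    order = list(nx.lexicographical_topological_sort(digraph))
    return [graph.node(nid) for nid in order]


def _instantiate(graph: DataflowGraph, ctx: BuildContext,
                 bound_inputs: Optional[dict[int, Observable]] = None,
                 tap: bool = True) -> Pipeline:
    registry = ctx.registry
    params_of = {n.id: NodeParams(n.params) for n in graph.nodes}
    outputs: dict[str, Observable] = {}
    pipeline = Pipeline(ctx.scheduler, outputs, {})
    property_nodes: list[StreamNode] = []

    for node in _topo_order(graph):
        inputs = [outputs[f] for f, _ in
                  sorted(graph.inbound(node.id), key=lambda e: e[1])]
        params = params_of[node.id]
        if node.operator == "group_input":
            slot = node.params.get("slot", 0)
            if bound_inputs is None or slot not in bound_inputs:
                raise BuildError(f"node {node.id!r}: unbound group input "
                                 f"slot {slot}")
            outputs[node.id] = bound_inputs[slot]
            continue
        if node.operator == "group_output":
            outputs[node.id] = inputs[0]
            continue
        if node.category is Category.PROPERTY:
            property_nodes.append(node)
            outputs[node.id] = inputs[0]
            continue
        if node.category is Category.NESTED:
            group = graph.groups[node.id]
            if node.operator == "select_many":
                blueprint = (lambda grp: lambda win: _instantiate(
                    grp, ctx, bound_inputs={0: win}, tap=False
                ).outputs[_group_output_id(grp)])(group)
                outputs[node.id] = wd.select_many(inputs[0], blueprint)
            else:  # plain group: one shared instance
                inner = _instantiate(group, ctx,
                                     bound_inputs=dict(enumerate(inputs)),
                                     tap=False)
                outputs[node.id] = inner.outputs[_group_output_id(group)]
            continue
        try:
            outputs[node.id] = registry.factory(node.operator)(
                node, params, inputs, ctx)
        except BuildError:
            raise
        except Exception as exc:
            raise BuildError(f"node {node.id!r}: {exc}") from exc

    for node in property_nodes:
        target = node.params.get("target")
        prop_name = node.params.get("name")
        target_node = graph.node(target)
        if prop_name not in target_node.exposed_properties:
            raise BuildError(
                f"node {node.id!r}: {target!r} does not expose property "
                f"{prop_name!r}")
        binding = cb.PropertyBinding(target, prop_name,
                                     default=target_node.params.get(prop_name))
        params_of[target].bind(prop_name, binding)
        pipeline.subscriptions.append(
            cb.bind_property(outputs[node.id], binding))

    if tap:
        for node in graph.nodes:
            if node.params.get("tap", False) or _is_terminal(graph, node):
                recorder = Recorder(ctx.scheduler)
                pipeline.subscriptions.append(
                    outputs[node.id].subscribe(recorder))
                pipeline.taps[node.id] = recorder
    return pipeline


def _group_output_id(group: DataflowGraph) -> str:
    for node in group.nodes:
        if node.operator == "group_output":
            return node.id
    raise BuildError("group has no group_output node")


def _is_terminal(graph: DataflowGraph, node: StreamNode) -> bool:
    if node.category is Category.PROPERTY:
        return False
    return not any(f == node.id for f, _, _ in graph.edges)


def build(graph: DataflowGraph, scheduler: VirtualScheduler,
          registry: Optional[OperatorRegistry] = None,
          fixtures: Optional[dict[str, Observable]] = None,
          out_dir: Optional[Path] = None) -> Pipeline:
    """Compile a validated graph into live streams with recorders on taps.

    Nodes are instantiated in topological order; terminal nodes and nodes
    with ``tap: true`` get a :class:`Recorder`.  Raises :class:`BuildError`
    on an unbuildable graph (validate first for diagnostics).
    """
    registry = registry or default_registry()
    problems = validate(graph, registry)
    if problems:
        raise BuildError("; ".join(problems))
    ctx = BuildContext(scheduler, fixtures or {}, out_dir, registry)
    return _instantiate(graph, ctx)


# ---------------------------------------------------------------------------
# Workflow files (YAML)
# ---------------------------------------------------------------------------

class WorkflowError(ValueError):
    """Malformed workflow file."""


def _graph_to_dict(graph: DataflowGraph) -> dict:
    return {
        "nodes": [{"id": n.id, "category": n.category.value,
                   "operator": n.operator,
                   **({"params": n.params} if n.params else {}),
                   **({"exposed_properties": n.exposed_properties}
                      if n.exposed_properties else {})}
                  for n in graph.nodes],
        "edges": [[f, t, slot] for f, t, slot in graph.edges],
        **({"groups": {k: _graph_to_dict(v)
                       for k, v in graph.groups.items()}}
           if graph.groups else {}),
    }


def _graph_from_dict(data: dict, where: str = "workflow") -> DataflowGraph:
    if not isinstance(data, dict):
        raise WorkflowError(f"{where}: expected a mapping")
    nodes = []
    for i, raw in enumerate(data.get("nodes", [])):
        where_n = f"{where}.nodes[{i}]"
        try:
            category = Category(raw["category"])
        except (KeyError, ValueError):
            raise WorkflowError(
                f"{where_n}: unknown category {raw.get('category')!r}")
        if "id" not in raw or "operator" not in raw:
            raise WorkflowError(f"{where_n}: 'id' and 'operator' are required")
        nodes.append(StreamNode(str(raw["id"]), category,
                                str(raw["operator"]),
                                dict(raw.get("params", {})),
                                list(raw.get("exposed_properties", []))))
    edges = []
    for i, raw in enumerate(data.get("edges", [])):
        if not (isinstance(raw, (list, tuple)) and len(raw) in (2, 3)):
            raise WorkflowError(
                f"{where}.edges[{i}]: expected [from, to, slot?]")
        f, t = str(raw[0]), str(raw[1])
        slot = int(raw[2]) if len(raw) == 3 else 0
        edges.append((f, t, slot))
    groups = {str(k): _graph_from_dict(v, f"{where}.groups[{k}]")
              for k, v in (data.get("groups") or {}).items()}
    return DataflowGraph(nodes, edges, groups)


def save_workflow(graph: DataflowGraph, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_graph_to_dict(graph),
                                         sort_keys=False))


def load_workflow(path: str | Path) -> DataflowGraph:
    """Parse a workflow file; schema violations raise WorkflowError with the
    offending location, YAML syntax errors propagate with line marks."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise WorkflowError(f"{path}: {exc}") from exc
    return _graph_from_dict(data or {})
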