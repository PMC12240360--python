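"""Signed interaction digraphs and feedback-loop enumeration.

The qualitative stability mechanism of the MEST community is read off a
signed digraph: an edge ``u -> v`` with sign +1 means u promotes v's
growth, -1 means u inhibits it.  Predation contributes a positive edge
from prey to predator and a negative edge back; resource competition
contributes negative edges both ways between the mutualist and each
exploiter and among exploiters.  A feedback loop is a simple directed
cycle; its sign is the product of its edge signs.  Negative loops damp
perturbations, positive loops amplify them, and the *maximal* (longest)
loops carry the dominant indirect effects.

Adaptive foraging enters as a qualitative ``AF`` node: the predator's
abundance drives its foraging trait (``P -> AF`` always +), and the trait
redirects predation pressure onto the specialist predator C and the
exploiter F1 according to a named strategy, e.g. intensified predation on
C with relaxed predation on F1 is ``AF -o C`` (-) together with
``AF -> F1`` (+).  Switching strategy flips the loop signs — the
trait-mediated route by which foraging adaptation retunes community
stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

__all__ = [
    "AF_STRATEGIES",
    "FeedbackLoop",
    "build_signed_digraph",
    "enumerate_loops",
    "maximal_loops",
    "loop_sign_summary",
    "to_dot",
]

#: AF-node edge signs (to C, to F1) per foraging strategy.  ``inhibit``
#: means intensified predation on that prey.
AF_STRATEGIES = {
    "inhibitC_promoteF1": (-1, +1),
    "promoteC_inhibitF1": (+1, -1),
    "both_promote": (+1, +1),
    "both_inhibit": (-1, -1),
    "none": None,
}

#: Hard cap on enumerated cycle length; keeps the search desk-scale.
MAX_LOOP_LENGTH = 12


@dataclass(frozen=True)
class FeedbackLoop:
    """A simple directed cycle with its edge signs.

    ``nodes`` is rotated so the lexicographically smallest node comes
    first; ``sign`` is the product of the edge signs.
    """

    nodes: tuple[str, ...]
    edge_signs: tuple[int, ...]
    sign: int

    def __post_init__(self):
        prod = 1
        for s in self.edge_signs:
            prod *= s
        if prod != self.sign:
            raise ValueError("loop sign must equal the edge-sign product")

    @property
    def length(self) -> int:
        return len(self.nodes)

    def __str__(self) -> str:
        parts = []
        for i, u in enumerate(self.nodes):
            s = "+" if self.edge_signs[i] > 0 else "-"
            parts.append(f"{u}→{s}")
        return "".join(parts) + self.nodes[0]


def build_signed_digraph(n: int = 1, *, include_AF: bool = False,
                         AF_strategy: str = "none",
                         predator_prey: tuple[bool, ...] | None = None
                         ) -> nx.DiGraph:
    """Signed interaction digraph of a MEST community with n exploiters.

    ``predator_prey`` selects which of P's links ``(F0, F1..Fn, C)`` are
    present (default: all).  With ``include_AF`` a qualitative AF node is
    added: ``P -> AF`` (+) and AF edges to C and F1 signed per
    ``AF_strategy`` (see :data:`AF_STRATEGIES`).

    The mutualist-exploiter edge pair carries the competition sign (-)
    both ways: the exploiters free-ride on the mutualism while competing
    with the mutualist for its resource flow, and the net qualitative
    effect used in the loop analysis is inhibitory.
    """
    if AF_strategy not in AF_STRATEGIES:
        raise ValueError(
            f"unknown AF strategy {AF_strategy!r}; "
            f"choose from {sorted(AF_STRATEGIES)}")
    if include_AF and AF_STRATEGIES[AF_strategy] is None:
        raise ValueError("include_AF=True needs a concrete AF_strategy")

    exploiters = [f"F{i}" for i in range(1, n + 1)]
    prey = ["F0"] + exploiters + ["C"]
    if predator_prey is None:
        predator_prey = tuple(True for _ in prey)
    if len(predator_prey) != len(prey):
        raise ValueError("predator_prey must cover (F0, F1..Fn, C)")

    G = nx.DiGraph()
    G.add_nodes_from(["F0", *exploiters, "C", "P"])

    def pred(preyname, predname):
        G.add_edge(preyname, predname, sign=+1)
        G.add_edge(predname, preyname, sign=-1)

    pred("F0", "C")                                   # C is F0's specialist
    for name, linked in zip(prey, predator_prey):
        if linked:
            pred(name, "P")
    for e in exploiters:                              # resource competition
        G.add_edge("F0", e, sign=-1)
        G.add_edge(e, "F0", sign=-1)
    for i, a in enumerate(exploiters):
        for b in exploiters[i + 1:]:
            G.add_edge(a, b, sign=-1)
            G.add_edge(b, a, sign=-1)

    if include_AF:
        sC, sF1 = AF_STRATEGIES[AF_strategy]
        G.add_node("AF")
        G.add_edge("P", "AF", sign=+1)
        G.add_edge("AF", "C", sign=sC)
        G.add_edge("AF", "F1", sign=sF1)
    return G


def _canonical(cycle: list[str]) -> tuple[str, ...]:
    """Rotate a cycle so its smallest node leads (deterministic identity)."""
    i = min(range(len(cycle)), key=lambda k: cycle[k])
    return tuple(cycle[i:] + cycle[:i])


def enumerate_loops(graph: nx.DiGraph,
                    max_length: int = MAX_LOOP_LENGTH) -> list[FeedbackLoop]:
    """All simple directed cycles of length <= ``max_length``, signed.

    Deterministic output: loops are sorted by (length, node tuple).
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    loops = []
    for cyc in nx.simple_cycles(graph, length_bound=max_length):
        nodes = _canonical(cyc)
        signs = tuple(
            graph.edges[nodes[i], nodes[(i + 1) % len(nodes)]]["sign"]
            for i in range(len(nodes))
        )
        prod = 1
        for s in signs:
            prod *= s
        loops.append(FeedbackLoop(nodes=nodes, edge_signs=signs, sign=prod))
    loops.sort(key=lambda l: (l.length, l.nodes))
    return loops


def maximal_loops(loops: list[FeedbackLoop]) -> list[FeedbackLoop]:
    """Loops of maximal length (the dominant indirect-effect routes)."""
    if not loops:
        raise ValueError("no loops to filter")
    m = max(l.length for l in loops)
    return [l for l in loops if l.length == m]


def loop_sign_summary(loops: list[FeedbackLoop]) -> dict[str, int]:
    """Counts of positive and negative loops."""
    return {"positive": sum(1 for l in loops if l.sign > 0),
            "negative": sum(1 for l in loops if l.sign < 0)}


def to_dot(graph: nx.DiGraph) -> str:
    """GraphViz DOT export with signs as edge labels."""
    lines = ["digraph MEST {"]
    for node in graph.nodes:
        lines.append(f'  "{node}";')
    for u, v, data in graph.edges(data=True):
        label = "+" if data["sign"] > 0 else "-"
        lines.append(f'  "{u}" -> "{v}" [label="{label}"];')
    lines.append("}")
    return "\n".join(lines)
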