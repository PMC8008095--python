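"""Iterative expansion of the ganglioside biosynthetic network.

Starting from a seed glycolipid (by default bare ceramide, ``T``), every
active enzyme activity is applied to every structure discovered in the
previous pass; novel products become the substrates of the next pass.
Expansion stops at a fixed point — a pass producing no new structure —
or at a user-set pass limit.  With the default rule set the expansion
from ceramide closes after 11 productive passes on 41 product structures
joined by 49 reactions.

The module also provides single-enzyme knockout scans, network diffs,
reachability queries, backward inference of the enzymes required to make
a target glycan, and an independent closed-form enumeration of the
expected wild-type network used as a test oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import GangliosimError, InvalidKnockoutError, UnreachableTargetError
from .rules import (AcceptorPattern, EnzymeRule, ReactionEvent, apply_rule,
                    default_ruleset)
from .structures import Structure

logger = logging.getLogger(__name__)


def _as_structure(value: Structure | str) -> Structure:
    return value if isinstance(value, Structure) else Structure.parse(value)


@dataclass
class SimulationConfig:
    """Run configuration for :func:`expand_network`."""

    seed: Structure = field(default_factory=lambda: Structure.parse("T"))
    ruleset: tuple[EnzymeRule, ...] = field(default_factory=default_ruleset)
    knockouts: frozenset[int] = frozenset()
    max_iterations: int = 20

    def __post_init__(self) -> None:
        self.seed = _as_structure(self.seed)
        self.knockouts = frozenset(self.knockouts)
        if self.max_iterations < 1:
            raise GangliosimError("max_iterations must be at least 1")
        numbers = {r.number for r in self.ruleset}
        bad = self.knockouts - numbers
        if bad:
            raise InvalidKnockoutError(
                f"knockout of unknown enzyme number(s) {sorted(bad)}")


class Network:
    """Accumulated structures and reactions of one expansion.

    Nodes are canonical abbreviated identifiers, each tagged with the
    pass (generation) at which it first appeared (seed = 0); edges are
    (substrate, enzyme, product) reaction events.  ``iterations_run``
    counts the passes that produced at least one novel structure; the
    pass that merely confirms the fixed point is not counted.
    """

    def __init__(self, seed: Structure, config: SimulationConfig | None = None):
        self.graph = nx.MultiDiGraph()
        self.seed = seed
        self.config = config
        self.iterations_run = 0
        self.truncated = False
        self._add_node(seed, 0)

    # -- construction (used by the expander and the oracle) -----------------

    def _add_node(self, structure: Structure, generation: int) -> None:
        self.graph.add_node(structure.abbreviated, structure=structure,
                            generation=generation)

    def _add_event(self, event: ReactionEvent) -> None:
        self.graph.add_edge(event.substrate.abbreviated,
                            event.product.abbreviated,
                            key=event.enzyme_number, event=event)

    # -- interrogation ------------------------------------------------------

    @property
    def seed_id(self) -> str:
        return self.seed.abbreviated

    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def products(self) -> list[str]:
        """Canonical identifiers of all non-seed structures, sorted."""
        return sorted(n for n in self.graph.nodes if n != self.seed_id)

    @property
    def n_products(self) -> int:
        return len(self.graph.nodes) - 1

    @property
    def n_reactions(self) -> int:
        return self.graph.number_of_edges()

    def events(self) -> list[ReactionEvent]:
        """All reaction events, deterministically ordered."""
        evs = [data["event"] for _, _, data in self.graph.edges(data=True)]
        return sorted(evs, key=lambda e: e.triple)

    def edge_triples(self) -> set[tuple[str, int, str]]:
        return {(u, k, v) for u, v, k in self.graph.edges(keys=True)}

    def generation(self, identifier: str) -> int:
        return self.graph.nodes[identifier]["generation"]

    def structure(self, identifier: str) -> Structure:
        return self.graph.nodes[identifier]["structure"]

    def __contains__(self, identifier: object) -> bool:
        if isinstance(identifier, Structure):
            identifier = identifier.abbreviated
        return identifier in self.graph.nodes

    def __repr__(self) -> str:
        return (f"<Network seed={self.seed_id!r} products={self.n_products} "
                f"reactions={self.n_reactions} iterations={self.iterations_run}>")


def expand_network(config: SimulationConfig | None = None) -> Network:
    """Breadth-first expansion of a seed under an enzyme rule set.

    Every pass applies every active enzyme to every structure novel in
    the previous pass, recording all discovered reactions — including
    edges into already-known products.  The result is independent of the
    order in which rules are applied.  If the pass limit is reached while
    products are still appearing the network is flagged ``truncated``.
    """
    cfg = config or SimulationConfig()
    active = [r for r in cfg.ruleset if r.number not in cfg.knockouts]
    net = Network(cfg.seed, cfg)
    frontier: list[Structure] = [cfg.seed]
    for iteration in range(1, cfg.max_iterations + 1):
        events: set[ReactionEvent] = set()
        for acceptor in sorted(frontier, key=lambda s: s.abbreviated):
            for rule in active:
                events |= apply_rule(rule, acceptor)
        novel: list[Structure] = []
        for event in sorted(events, key=lambda e: e.triple):
            pid = event.product.abbreviated
            if pid not in net.graph.nodes:
                net._add_node(event.product, iteration)
                novel.append(event.product)
            net._add_event(event)
            logger.debug("pass %d: enzyme %d: %s -> %s", iteration,
                         event.enzyme_number, event.substrate.abbreviated, pid)
        if not novel:
            break
        net.iterations_run = iteration
        frontier = novel
    else:
        # the pass budget ran out while the frontier was still productive
        net.truncated = True
    return net


def knockout_scan(config: SimulationConfig | None = None) -> dict[int, Network]:
    """Regenerate the network once per single-enzyme knockout.

    Returns a mapping from enzyme number to the network expanded with
    that enzyme disabled (on top of any baseline knockouts in the
    config); key 0 holds the unmodified reference network.
    """
    cfg = config or SimulationConfig()
    result = {0: expand_network(cfg)}
    for rule in cfg.ruleset:
        ko_cfg = replace(cfg, knockouts=cfg.knockouts | {rule.number})
        result[rule.number] = expand_network(ko_cfg)
    return result


@dataclass(frozen=True)
class NetworkDiff:
    """Set differences between two networks (a relative to b)."""

    nodes_lost: frozenset[str]
    nodes_gained: frozenset[str]
    edges_lost: frozenset[tuple[str, int, str]]
    edges_gained: frozenset[tuple[str, int, str]]

    @property
    def empty(self) -> bool:
        return not (self.nodes_lost or self.nodes_gained
                    or self.edges_lost or self.edges_gained)


def network_diff(a: Network, b: Network) -> NetworkDiff:
    """Nodes and edges present in ``a`` but not ``b``, and vice versa."""
    na, nb = set(a.graph.nodes), set(b.graph.nodes)
    ea, eb = a.edge_triples(), b.edge_triples()
    return NetworkDiff(frozenset(na - nb), frozenset(nb - na),
                       frozenset(ea - eb), frozenset(eb - ea))


def downstream_products(net: Network, node: Structure | str) -> set[str]:
    """All structures reachable from ``node`` by directed reactions."""
    nid = node.abbreviated if isinstance(node, Structure) else node
    if nid not in net.graph.nodes:
        raise GangliosimError(f"{nid!r} is not a node of this network")
    return set(nx.descendants(net.graph, nid))


# ---------------------------------------------------------------------------
# backward inference of required enzymes

@dataclass(frozen=True)
class InferenceResult:
    """Enzymes required for a target plus one witness biosynthetic path."""

    target: Structure
    enzymes: frozenset[int]
    path: tuple[ReactionEvent, ...]


def _inverse(pattern: AcceptorPattern) -> AcceptorPattern:
    return AcceptorPattern(pattern.replacement, pattern.pattern, pattern.anchor)


def _predecessors(sid: str, rules: Sequence[EnzymeRule]
                  ) -> list[tuple[str, EnzymeRule]]:
    """Admissible (precursor, rule) pairs: inverting a rewrite must be
    confirmed by the forward rule regenerating ``sid``."""
    found: dict[tuple[str, int], EnzymeRule] = {}
    for rule in rules:
        for pattern in rule.patterns:
            for text in _inverse(pattern).rewrite(sid):
                try:
                    pred = Structure.parse(text)
                except GangliosimError:
                    continue
                pid = pred.abbreviated
                if (pid, rule.number) in found:
                    continue
                if any(e.product.abbreviated == sid
                       for e in apply_rule(rule, pred)):
                    found[(pid, rule.number)] = rule
    return sorted(((pid, rule) for (pid, _), rule in found.items()),
                  key=lambda t: (t[0], t[1].number))


def infer_required_enzymes(target: Structure | str,
                           ruleset: Sequence[EnzymeRule] | None = None
                           ) -> InferenceResult:
    """Which enzymes does the biosynthesis of ``target`` require?

    Works backward from the target, stripping the last-added residue by
    inverting rule rewrites until bare ceramide is reached; ties between
    alternative precursors are broken by exploring them in lexicographic
    (precursor identifier, enzyme number) order, so the witness path is
    deterministic.  Raises :class:`UnreachableTargetError`, naming the
    first underivable intermediate, when no rule chain can produce the
    target.
    """
    rules = tuple(ruleset) if ruleset is not None else default_ruleset()
    target = _as_structure(target)
    dead: set[str] = set()

    def derive(sid: str) -> list[ReactionEvent] | None:
        if sid == "T":
            return []
        if sid in dead:
            return None
        for pid, rule in _predecessors(sid, rules):
            upstream = derive(pid)
            if upstream is not None:
                event = ReactionEvent(Structure.parse(pid),
                                      Structure.parse(sid), rule.number,
                                      rule.donor, rule.byproduct)
                return upstream + [event]
        dead.add(sid)
        return None

    path = derive(target.abbreviated)
    if path is None:
        # report the first structure (in DFS discovery order) with no way back
        blocked = target.abbreviated
        frontier = [target.abbreviated]
        seen = set()
        while frontier:
            sid = frontier.pop(0)
            if sid in seen:
                continue
            seen.add(sid)
            preds = _predecessors(sid, rules)
            if not preds:
                blocked = sid
                break
            frontier.extend(pid for pid, _ in preds)
        raise UnreachableTargetError(
            f"{target.abbreviated!r} is not derivable under this rule set: "
            f"no enzyme produces {blocked!r}", blocked)
    return InferenceResult(target, frozenset(e.enzyme_number for e in path),
                           tuple(path))


# ---------------------------------------------------------------------------
# closed-form oracle

_CHAIN_BRANCH = {0: "", 1: "[S3]", 2: "[S8S3]", 3: "[S8S8S3]"}
_CHAIN_TERMINAL = {0: "", 1: "S3", 2: "S8S3", 3: "S8S8S3"}


def _full_core(ii: int, iv: int, alpha: int) -> str:
    return (_CHAIN_TERMINAL[iv] + "L3" + ("[S6]" if alpha else "")
            + "Vb4" + _CHAIN_BRANCH[ii] + "L4GT")


def reference_enumeration() -> Network:
    """The expected wild-type network, built without the rewrite engine.

    Constructed from the closed-form parameterization of the product
    families: the Gala arm (GalCer and its sialyl chain of up to three),
    the Glc-arm intermediates (GlcCer, LacCer, its 0–3-sialyl decorations
    and their GalNAc extensions), and the fully extended core grid —
    position II branch 0–3 × position IV terminal chain 0–3 × optional
    α2,6 Neu5Ac on position III (only with a sialylated position IV) —
    with edges written down per-rule.  Serves as the independent oracle
    for :func:`expand_network`.
    """
    seed = Structure.parse("T")
    net = Network(seed, None)
    rules = {r.number: r for r in default_ruleset()}

    nodes = ["GT", "LT", "L4GT"]
    nodes += [_CHAIN_BRANCH[k] + "LT" for k in (1, 2, 3)]
    nodes += [_CHAIN_BRANCH[k] + "L4GT" for k in (1, 2, 3)]
    nodes += ["Vb4" + _CHAIN_BRANCH[k] + "L4GT" for k in (0, 1, 2, 3)]
    nodes += [_full_core(ii, iv, alpha)
              for ii in (0, 1, 2, 3) for iv in (0, 1, 2, 3)
              for alpha in ((0, 1) if iv else (0,))]

    edges: list[tuple[str, int, str]] = [
        ("T", 1, "GT"), ("T", 2, "LT"), ("GT", 3, "L4GT"),
        ("L4GT", 4, "[S3]L4GT"), ("LT", 4, "[S3]LT"),
        ("[S3]L4GT", 5, "[S8S3]L4GT"), ("[S3]LT", 5, "[S8S3]LT"),
    ]
    # activity 6, terminal-chain growth on position IV
    for iv in (1, 2):
        for ii in (0, 1, 2, 3):
            for alpha in (0, 1):
                edges.append((_full_core(ii, iv, alpha), 6,
                              _full_core(ii, iv + 1, alpha)))
    # activity 6, branch growth [S8S3] -> [S8S8S3] wherever the branch sits
    edges += [("[S8S3]LT", 6, "[S8S8S3]LT"),
              ("[S8S3]L4GT", 6, "[S8S8S3]L4GT"),
              ("Vb4[S8S3]L4GT", 6, "Vb4[S8S8S3]L4GT")]
    for iv in (0, 1, 2, 3):
        for alpha in ((0, 1) if iv else (0,)):
            edges.append((_full_core(2, iv, alpha), 6, _full_core(3, iv, alpha)))
    # activities 7–10 along the core
    for ii in (0, 1, 2, 3):
        lac = _CHAIN_BRANCH[ii] + "L4GT"
        edges.append((lac, 7, "Vb4" + lac))
        edges.append(("Vb4" + lac, 8, _full_core(ii, 0, 0)))
        edges.append((_full_core(ii, 0, 0), 9, _full_core(ii, 1, 0)))
        edges.append((_full_core(ii, 1, 0), 10, _full_core(ii, 1, 1)))

    plain = nx.DiGraph((u, v) for u, _, v in edges)
    generations = nx.single_source_shortest_path_length(plain, "T")
    for nid in nodes:
        net._add_node(Structure.parse(nid), generations[nid])
    for u, enzyme, v in edges:
        rule = rules[enzyme]
        net._add_event(ReactionEvent(net.structure(u), net.structure(v),
                                     enzyme, rule.donor, rule.byproduct))
    net.iterations_run = max(generations.values())
    return net
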