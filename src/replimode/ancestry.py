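"""Parsimony reconstruction of replication-mode evolution on a species tree.

Sankoff dynamic programming computes the minimum number of state changes
(unit cost by default) needed to explain the tip distribution of a
character — here the chromid replication mode, uni- vs bidirectional —
optionally with the root constrained to a given ancestral state. Comparing
root-constrained minima is the classic argument for inferring the ancestral
mode: if a unidirectional ancestor explains the extant distribution with
one change while a bidirectional ancestor needs two, parsimony favors the
former.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

INF = float("inf")


@dataclass
class TraitTree:
    """A rooted tree with a (possibly partial) discrete character at tips.

    Tips missing from ``tip_states`` are treated as missing data (zero cost
    for every assignment). ``cost`` maps (from_state, to_state) -> cost;
    default is the unit (Fitch) cost.
    """

    tree: dendropy.Tree
    tip_states: dict[str, str]
    alphabet: tuple[str, ...] = ("uni", "bi")
    cost: dict[tuple[str, str], float] | None = None
    allow_missing: bool = False

    def __post_init__(self) -> None:
        known = set(self.alphabet)
        for tip, state in self.tip_states.items():
            if state not in known:
                raise ValueError(
                    f"tip {tip!r} has unknown state {state!r}; "
                    f"alphabet is {self.alphabet}"
                )

    def cost_of(self, a: str, b: str) -> float:
        if self.cost is not None:
            return self.cost[(a, b)]
        return 0.0 if a == b else 1.0


@dataclass
class ParsimonyResult:
    min_changes: float
    root_constraint: str | None
    ancestral_sets: dict[int, frozenset[str]]
    change_edges: list[tuple[int, int]] = field(default_factory=list)


def _leaf_label(node: dendropy.Node) -> str:
    label = node.taxon.label if node.taxon is not None else (node.label or "")
    # newick treats unquoted underscores as spaces; trait tables use underscores
    return label.replace(" ", "_")


def min_changes(
    trait_tree: TraitTree, root_constraint: str | None = None
) -> ParsimonyResult:
    """Sankoff minimum-change count with optional fixed root state.

    Returns the minimal total cost, the per-internal-node sets of states
    attainable in at least one optimal labeling, and the edges on which a
    change occurs in at least one optimal labeling. Multifurcations are
    handled natively (cost vectors sum over children); missing tip states
    cost zero for every assignment.
    """
    tree = trait_tree.tree
    states = trait_tree.alphabet
    if root_constraint is not None and root_constraint not in states:
        raise ValueError(f"unknown root state {root_constraint!r}")
    k = len(states)

    nodes = list(tree.postorder_node_iter())
    node_id = {id(n): i for i, n in enumerate(nodes)}
    up = {}  # node index -> cost vector S(v, s)

    for n in nodes:
        i = node_id[id(n)]
        if n.is_leaf():
            label = _leaf_label(n)
            if label not in trait_tree.tip_states:
                if not trait_tree.allow_missing:
                    raise ValueError(f"tip {label!r} has no state assigned")
                up[i] = np.zeros(k)  # missing data: any state, zero cost
                continue
            state = trait_tree.tip_states[label]
            vec = np.full(k, INF)
            vec[states.index(state)] = 0.0
            up[i] = vec
        else:
            vec = np.zeros(k)
            for child in n.child_nodes():
                cvec = up[node_id[id(child)]]
                trans = np.array([
                    min(trait_tree.cost_of(s, t) + cvec[j]
                        for j, t in enumerate(states))
                    for s in states
                ])
                vec = vec + trans
            up[i] = vec

    root = tree.seed_node
    ri = node_id[id(root)]
    root_vec = up[ri].copy()
    if root_constraint is not None:
        keep = states.index(root_constraint)
        restricted = np.full(k, INF)
        restricted[keep] = root_vec[keep]
        root_vec = restricted
    total = float(root_vec.min())

    # Top-down pass: optimal state sets per node and obligatory-change edges.
    optimal: dict[int, set[str]] = {}
    optimal[ri] = {
        states[j] for j in range(k) if root_vec[j] == total
    }
    change_edges: list[tuple[int, int]] = []
    # out[i][s]: minimal cost of the whole tree given node i takes state s
    out_cost: dict[int, np.ndarray] = {ri: root_vec}
    for n in reversed(nodes):  # preorder
        i = node_id[id(n)]
        if n.is_leaf():
            continue
        children = n.child_nodes()
        cvecs = [up[node_id[id(c)]] for c in children]
        # contribution of each child to parent state s
        contrib = []
        for cvec in cvecs:
            contrib.append(np.array([
                min(trait_tree.cost_of(s, t) + cvec[j]
                    for j, t in enumerate(states))
                for s in states
            ]))
        parent_total = out_cost[i]
        for ci, child in enumerate(children):
            cidx = node_id[id(child)]
            cvec = cvecs[ci]
            child_cost = np.full(k, INF)
            edge_changes = False
            for si, s in enumerate(states):
                if parent_total[si] == INF:
                    continue
                base = parent_total[si] - contrib[ci][si]
                for ti, t in enumerate(states):
                    c = base + trait_tree.cost_of(s, t) + cvec[ti]
                    if c < child_cost[ti]:
                        child_cost[ti] = c
                    if c == total and s != t:
                        edge_changes = True
            out_cost[cidx] = child_cost
            if not child.is_leaf():
                optimal[cidx] = {
                    states[j] for j in range(k) if child_cost[j] == total
                }
            if edge_changes:
                change_edges.append((i, cidx))

    ancestral = {
        i: frozenset(s) for i, s in optimal.items()
    }
    return ParsimonyResult(
        min_changes=total,
        root_constraint=root_constraint,
        ancestral_sets=ancestral,
        change_edges=change_edges,
    )


def read_tree(path_or_string: str, schema: str = "newick") -> dendropy.Tree:
    """Read a rooted tree from a Newick file path or literal string."""
    if "(" in path_or_string:
        return dendropy.Tree.get(data=path_or_string, schema=schema)
    return dendropy.Tree.get(path=path_or_string, schema=schema)


def map_modes_to_tree(
    tree: dendropy.Tree,
    calls: dict[str, object],
    drop_unpredictable: bool = True,
    normalize=lambda s: s.strip().replace(" ", "_"),
) -> TraitTree:
    """Join replication-mode calls onto tree tips.

    ``calls`` maps tip names to either mode strings or objects with a
    ``mode`` attribute (e.g. ReplicationCall). Mode names are mapped to the
    parsimony alphabet (bidirectional -> bi, unidirectional -> uni).
    Unpredictable calls become missing data (dropped from tip_states).
    Errors if fewer than half the tips can be matched.
    """
    mode_map = {"bidirectional": "bi", "unidirectional": "uni",
                "bi": "bi", "uni": "uni"}
    norm_calls = {}
    for name, call in calls.items():
        mode = getattr(call, "mode", call)
        norm_calls[normalize(name)] = mode
    tip_states: dict[str, str] = {}
    matched = 0
    tips = [_leaf_label(t) for t in tree.leaf_node_iter()]
    for label in tips:
        key = normalize(label)
        if key not in norm_calls:
            continue
        matched += 1
        mode = norm_calls[key]
        if mode == "unpredictable":
            if not drop_unpredictable:
                tip_states[label] = mode  # will fail alphabet validation
            continue
        tip_states[label] = mode_map[mode]
    if matched < 0.5 * len(tips):
        raise ValueError(
            f"only {matched}/{len(tips)} tips matched a replication call"
        )
    return TraitTree(tree=tree, tip_states=tip_states, allow_missing=True)
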