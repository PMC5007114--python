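"""Outer-membrane presence/absence mapped on a tree: Dollo and Fitch
parsimony.

The envelope state is a single binary character (diderm = outer membrane
present, monoderm = absent).  Under Dollo parsimony the outer membrane is
gained exactly once - here it is assumed present at the root, which is the
reading appropriate when the outgroup and deep lineages are diderm - and
the reconstruction may only lose it.  The minimal labelling is then
forced: an internal node is 'present' precisely when its subtree still
contains a present tip (every such node lies on a path between a present
tip and the root), and each maximal all-absent subtree contributes exactly
one loss on its stem edge.  ``fitch_changes`` gives the unconstrained
minimum number of state changes for comparison (gains allowed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .phylo_core import Tree
from .synthetic_data import DIDERM, MONODERM, CharacterMap

__all__ = ["LossScenario", "dollo_losses", "fitch_changes"]

PRESENT, ABSENT = True, False

_STATE = {DIDERM: PRESENT, MONODERM: ABSENT, "present": PRESENT, "absent": ABSENT}


def _tip_states(tree: Tree, chars: CharacterMap) -> dict[int, bool]:
    states = {}
    for tip in tree.tips():
        if tip.label not in chars:
            raise KeyError(f"tip {tip.label!r} has no character state")
        raw = chars[tip.label]
        if isinstance(raw, str):
            if raw not in _STATE:
                raise ValueError(f"unknown state {raw!r} for tip {tip.label!r}")
            states[id(tip)] = _STATE[raw]
        else:
            states[id(tip)] = bool(raw)
    return states


@dataclass
class LossScenario:
    """A minimum-loss Dollo reconstruction.

    ``loss_edges`` names each present->absent transition edge by the tip
    set below it; ``node_states`` maps every node (keyed by the tip set
    below it) to its reconstructed state.  The loss count equals the
    number of maximal all-absent subtrees.
    """

    losses: int
    loss_edges: frozenset[frozenset[str]]
    node_states: dict[frozenset[str], bool] = field(repr=False, default_factory=dict)

    def annotated(self, tree: Tree) -> Tree:
        """A copy of ``tree`` with '*loss*' appended to the internal label
        of every loss edge's child node (tips get a suffixed label)."""
        out = tree.copy()
        for node in out.postorder():
            if node.parent is None:
                continue
            if node.tip_set() in self.loss_edges:
                node.label = (node.label or "") + "*loss*"
        return out


def dollo_losses(tree: Tree, chars: CharacterMap) -> LossScenario:
    """Minimum number of independent losses of a root-present binary
    character, with the edges on which they occur.

    The tree's current rooting is used (root the tree on the outgroup
    first when mapping envelope states).  The root is forced 'present';
    no absent->present transition appears anywhere in the labelling.
    """
    states = _tip_states(tree, chars)
    node_state: dict[int, bool] = {}
    for node in tree.postorder():
        if node.is_tip:
            node_state[id(node)] = states[id(node)]
        else:
            node_state[id(node)] = any(
                node_state[id(c)] for c in node.children
            )
    node_state[id(tree.root)] = PRESENT
    loss_edges = []
    node_states = {}
    for node in tree.postorder():
        node_states[node.tip_set()] = node_state[id(node)]
        if node.parent is None:
            continue
        parent_state = (
            PRESENT if node.parent is tree.root else node_state[id(node.parent)]
        )
        if parent_state == PRESENT and node_state[id(node)] == ABSENT:
            loss_edges.append(node.tip_set())
        assert not (parent_state == ABSENT and node_state[id(node)] == PRESENT), (
            "Dollo labelling produced a regain"
        )
    return LossScenario(
        losses=len(loss_edges),
        loss_edges=frozenset(loss_edges),
        node_states=node_states,
    )


def fitch_changes(tree: Tree, chars: CharacterMap) -> int:
    """Unconstrained minimum number of state changes (gains or losses) of
    the binary character, by the Fitch two-state union/intersection pass.
    The count is rooting-invariant on binary trees."""
    states = _tip_states(tree, chars)
    changes = 0
    sets: dict[int, frozenset[bool]] = {}
    for node in tree.postorder():
        if node.is_tip:
            sets[id(node)] = frozenset([states[id(node)]])
        else:
            inter = None
            for c in node.children:
                s = sets[id(c)]
                inter = s if inter is None else (inter & s)
            if inter:
                sets[id(node)] = inter
            else:
                union = frozenset()
                for c in node.children:
                    union = union | sets[id(c)]
                sets[id(node)] = union
                changes += 1
    return changes


def dollo_summary_table(scenario: LossScenario):
    import pandas as pd

    return pd.DataFrame(
        [
            {"loss_edge": ",".join(sorted(edge)), "n_tips": len(edge)}
            for edge in sorted(scenario.loss_edges, key=lambda e: sorted(e))
        ]
    )
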