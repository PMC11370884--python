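"""Dollo parsimony reconstruction of gene-family gains and losses.

Under Dollo's law a binary character (family presence) arises exactly once
and can only be lost.  On a rooted tree the minimum-loss reconstruction is
unique: the gain sits at the most recent common ancestor of the present
leaves, and the losses are the root edges of the maximal all-absent subtrees
inside that clade.

Uniqueness sketch: moving the gain above the MRCA adds at least one absent
subtree whose root edge must become a loss, and cannot remove any; placing
the gain below the MRCA leaves some present leaf unexplained.  Given the
gain node, each maximal absent subtree requires at least one loss on its
root path and a single loss on its root edge suffices, while any loss edge
with a present descendant is contradictory.  Hence the stated solution is
the unique minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .profiles import ProfileMatrix
from .tree import SpeciesTree

__all__ = ["DolloEvents", "dollo_reconstruct", "family_events", "branch_event_table"]


@dataclass
class DolloEvents:
    """Per-family gains/losses plus per-branch aggregates for one family class."""

    tree: SpeciesTree
    gain_node: dict[str, str]
    loss_branches: dict[str, frozenset[str]]
    #: per-node aggregate gain count, indexed by node label
    gains: pd.Series = field(default=None)
    #: per-branch aggregate loss count, indexed by child-node label
    losses: pd.Series = field(default=None)
    #: per-leaf presence count
    presence: pd.Series = field(default=None)

    def table(self) -> pd.DataFrame:
        """Branch table: internal branches before terminal branches, in preorder."""
        order = [i for i in range(self.tree.n_nodes) if not self.tree.is_leaf[i]] + [
            i for i in range(self.tree.n_nodes) if self.tree.is_leaf[i]
        ]
        labels = [self.tree.labels[i] for i in order]
        df = pd.DataFrame(
            {
                "gains": self.gains.reindex(labels).fillna(0).astype(int),
                "losses": self.losses.reindex(labels).fillna(0).astype(int),
                "presence_at_leaf": self.presence.reindex(labels),
            },
            index=pd.Index(labels, name="branch"),
        )
        return df


def dollo_reconstruct(
    presence: np.ndarray | dict[str, bool], tree: SpeciesTree
) -> tuple[str, frozenset[str]]:
    """Reconstruct (gain node, loss branches) for one binary profile.

    ``presence`` is either a boolean vector aligned with ``tree.leaf_labels``
    or a mapping from leaf label to presence.  Loss branches are named by
    their child node.  Raises ``ValueError`` for an all-absent profile.
    """
    if isinstance(presence, dict):
        presence = np.array([bool(presence.get(l, False)) for l in tree.leaf_labels])
    else:
        presence = np.asarray(presence, dtype=bool)
    gain, losses = _reconstruct_many(presence[None, :], tree)
    return tree.labels[gain[0]], frozenset(
        tree.labels[c] for c in np.flatnonzero(losses[0])
    )


def _reconstruct_many(P: np.ndarray, tree: SpeciesTree) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Dollo over a (families x leaves) presence matrix.

    Returns (gain node index per family, families x nodes loss-branch mask).
    """
    if P.shape[1] != tree.n_leaves:
        raise ValueError("presence matrix width != number of leaves")
    if not P.any(axis=1).all():
        bad = int(np.flatnonzero(~P.any(axis=1))[0])
        raise ValueError(f"all-absent profile (row {bad}) is not reconstructible")
    lm = tree.leaf_matrix  # (nodes, leaves)
    below = P @ lm.T.astype(np.int64)  # present-leaf count under each node
    total = P.sum(axis=1)
    covers = below == total[:, None]  # nodes covering all present leaves: a root path
    # gain = deepest covering node
    depth_key = np.where(covers, tree.depth[None, :], -1)
    gain = np.argmax(depth_key, axis=1)
    # loss at branch to c iff subtree(c) all-absent, parent subtree has presence,
    # and parent lies inside the gain clade
    parent = tree.parent
    nodes = np.arange(tree.n_nodes)
    absent = below == 0
    parent_has = np.zeros_like(absent)
    parent_has[:, 1:] = below[:, parent[1:]] > 0
    in_gain_clade = tree.descendant_or_self[gain]  # (families, nodes), via fancy rows
    parent_in = np.zeros_like(absent)
    parent_in[:, 1:] = in_gain_clade[:, parent[1:]]
    losses = absent & parent_has & parent_in
    losses[:, 0] = False
    return gain, losses


def family_events(profiles: ProfileMatrix, tree: SpeciesTree) -> DolloEvents:
    """Dollo events for every family in ``profiles`` (presence = count > 0)."""
    P = profiles.presence(tree)
    gain, losses = _reconstruct_many(P, tree)
    fams = profiles.family_ids
    gain_node = {f: tree.labels[g] for f, g in zip(fams, gain)}
    loss_branches = {
        f: frozenset(tree.labels[c] for c in np.flatnonzero(row))
        for f, row in zip(fams, losses)
    }
    ev = DolloEvents(tree, gain_node, loss_branches)
    gains = np.bincount(gain, minlength=tree.n_nodes)
    ev.gains = pd.Series(gains, index=tree.labels)
    ev.losses = pd.Series(losses.sum(axis=0), index=tree.labels)
    leaf_presence = pd.Series(P.sum(axis=0), index=tree.leaf_labels)
    ev.presence = leaf_presence.reindex(tree.labels)
    return ev


def branch_event_table(
    profiles: ProfileMatrix, tree: SpeciesTree, family_class: str | None = None
) -> pd.DataFrame:
    """Aggregate gain/loss/presence branch table for one family class.

    ``family_class=None`` aggregates all families.  The sum of gains over
    nodes equals the number of families aggregated.
    """
    if family_class is not None:
        sub = profiles.counts.index[profiles.classes == family_class]
        if len(sub) == 0:
            warnings.warn(f"no families of class {family_class!r}; empty table")
            empty = pd.DataFrame(
                {"gains": 0, "losses": 0, "presence_at_leaf": np.nan},
                index=pd.Index(tree.labels, name="branch"),
            )
            return empty
        profiles = profiles.subset(sub)
    return family_events(profiles, tree).table()
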