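"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package's algorithms: Dollo
reconstruction is checked against exhaustive enumeration of internal state
assignments, the pure-loss likelihood against per-element survival-pattern
enumeration with explicit root-size marginalization, and the enrichment
score against a literal step-by-step running sum.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from toxdescent.tree import SpeciesTree


# ----------------------------------------------------------------------
# Dollo: minimum-loss single-gain reconstruction by state enumeration


def dollo_oracle(tree: SpeciesTree, presence: np.ndarray):
    """All minimum-loss Dollo solutions for one binary leaf profile.

    Enumerates every 0/1 assignment to internal nodes (leaves fixed at the
    observed states), keeps assignments with exactly one gain (root state 1,
    or a single 0->1 edge) and no other 0->1 edge, and returns the set of
    (gain_node_label, frozenset(loss_branch_labels)) attaining the minimum
    loss count, together with that minimum.
    """
    n = tree.n_nodes
    internal = [v for v in range(n) if not tree.is_leaf[v]]
    leaf_idx = {v: j for j, v in enumerate(np.flatnonzero(tree.is_leaf))}
    best = None
    solutions = set()
    for assign in itertools.product([0, 1], repeat=len(internal)):
        state = np.zeros(n, dtype=int)
        for v, s in zip(internal, assign):
            state[v] = s
        for v, j in leaf_idx.items():
            state[v] = int(presence[j])
        gains = []
        losses = []
        if state[0] == 1:
            gains.append(0)
        for v in range(1, n):
            p = tree.parent[v]
            if state[p] == 0 and state[v] == 1:
                gains.append(v)
            elif state[p] == 1 and state[v] == 0:
                losses.append(v)
        if len(gains) != 1:
            continue
        k = len(losses)
        if best is None or k < best:
            best = k
            solutions = set()
        if k == best:
            solutions.add(
                (tree.labels[gains[0]], frozenset(tree.labels[v] for v in losses))
            )
    return solutions, best


def all_rooted_binary_trees(leaves: list[str]):
    """All rooted binary labeled topologies on the given leaves, as newick."""

    def grow(trees, remaining):
        if not remaining:
            return trees
        leaf = remaining[0]
        out = []
        for t in trees:
            for pos in range(count_edges(t) + 1):
                out.append(insert(t, leaf, pos))
        return grow(out, remaining[1:])

    def count_edges(t):
        # edges = 2 * n_leaves - 2 for a rooted binary tree, counted structurally
        if isinstance(t, str):
            return 0
        return 2 + count_edges(t[0]) + count_edges(t[1])

    def insert(t, leaf, pos):
        # pos 0 inserts above the current root; pos >= 1 walks edges in order
        if pos == 0:
            return (t, leaf)
        return _insert_edge(t, leaf, pos - 1)[0]

    def _insert_edge(t, leaf, pos):
        if isinstance(t, str):
            return t, pos
        left, right = t
        if pos == 0:
            return ((left, leaf), right), -1
        new_left, pos = _insert_edge(left, leaf, pos - 1)
        if pos == -1:
            return (new_left, right), -1
        if pos == 0:
            return (left, (right, leaf)), -1
        new_right, pos = _insert_edge(right, leaf, pos - 1)
        if pos == -1:
            return (left, new_right), -1
        return t, pos

    def to_newick(t):
        if isinstance(t, str):
            return t
        return f"({to_newick(t[0])},{to_newick(t[1])})"

    if len(leaves) == 1:
        return [leaves[0] + ";"]
    trees = [(leaves[0], leaves[1])] if len(leaves) >= 2 else []
    trees = grow(trees, leaves[2:])
    return [to_newick(t) + ";" for t in trees]


# ----------------------------------------------------------------------
# Pure loss: enumeration over root sizes and per-element survival patterns


class PureLossEnumerationOracle:
    """Exact pure-loss quantities for tiny trees by explicit enumeration.

    Conditional on the root holding n elements, each element independently
    realizes a survival pattern over all nodes (survives to node v iff it
    survives every branch from the root to v).  The joint distribution of
    counts at any set of tracked nodes is the n-fold convolution of the
    single-element pattern distribution; the root size is marginalized over
    a Poisson prior truncated at ``n_root_max``.
    """

    def __init__(self, tree: SpeciesTree, survival: np.ndarray, lam: float,
                 n_root_max: int = 25):
        self.tree = tree
        self.survival = np.asarray(survival, dtype=float)
        self.lam = lam
        self.n_root_max = n_root_max
        n = tree.n_nodes
        # pattern = tuple of 0/1 survival at every node (root always 1)
        branch_sets = []
        for v in range(n):
            path = []
            u = v
            while u != 0:
                path.append(u)
                u = tree.parent[u]
            branch_sets.append(path)
        self.patterns = []
        self.pattern_probs = []
        branches = list(range(1, n))
        for outcome in itertools.product([0, 1], repeat=len(branches)):
            surv = dict(zip(branches, outcome))
            prob = 1.0
            for b, o in surv.items():
                s = self.survival[b]
                prob *= s if o else (1 - s)
            at_node = tuple(
                1 if all(surv[b] for b in branch_sets[v]) else 1 if v == 0 else 0
                for v in range(n)
            )
            self.patterns.append(at_node)
            self.pattern_probs.append(prob)

    def joint_counts(self, track: list[int]) -> dict[int, np.ndarray]:
        """P(counts at tracked nodes | root = n) for each root size n.

        Returns {n: array of shape (n+1,)*len(track)}.
        """
        dims = len(track)
        single = np.zeros((2,) * dims)
        for pat, pr in zip(self.patterns, self.pattern_probs):
            idx = tuple(pat[v] for v in track)
            single[idx] += pr
        out = {0: np.zeros((1,) * dims)}
        out[0][(0,) * dims] = 1.0
        cur = out[0]
        for n in range(1, self.n_root_max + 1):
            new = np.zeros((n + 1,) * dims)
            for idx in itertools.product([0, 1], repeat=dims):
                p = single[idx]
                if p == 0:
                    continue
                slc_dst = tuple(slice(i, i + n) for i in idx)
                slc_src = tuple(slice(0, n) for _ in idx)
                new[slc_dst] += p * cur[slc_src]
            out[n] = new
            cur = new
        return out

    def likelihood(self, leaf_counts: dict[str, int]) -> float:
        track = [self.tree.index(l) for l in self.tree.leaf_labels]
        obs = tuple(leaf_counts[l] for l in self.tree.leaf_labels)
        joints = self.joint_counts(track)
        lik = 0.0
        for n, arr in joints.items():
            if max(obs, default=0) <= n:
                lik += stats.poisson.pmf(n, self.lam) * arr[obs]
        return lik

    def node_posterior(self, node_label: str, leaf_counts: dict[str, int],
                       n_max: int) -> np.ndarray:
        v = self.tree.index(node_label)
        leaf_nodes = [self.tree.index(l) for l in self.tree.leaf_labels]
        track = ([v] if v not in leaf_nodes else []) + leaf_nodes
        obs = {self.tree.index(l): leaf_counts[l] for l in self.tree.leaf_labels}
        joints = self.joint_counts(track)
        post = np.zeros(n_max + 1)
        vpos = track.index(v)
        for n, arr in joints.items():
            if max(obs.values(), default=0) > n:
                continue
            pn = stats.poisson.pmf(n, self.lam)
            it = [range(n + 1) if u not in obs else [obs[u]] for u in track]
            for idx in itertools.product(*it):
                k = idx[vpos]
                if k <= n_max:
                    post[k] += pn * arr[idx]
        return post / post.sum()

    def branch_event_prob(self, child_label: str, leaf_counts: dict[str, int],
                          parent_min: int, child_exact: int) -> float:
        """P(parent count >= parent_min, child count == child_exact | data)."""
        c = self.tree.index(child_label)
        p = self.tree.parent[c]
        leaf_nodes = [self.tree.index(l) for l in self.tree.leaf_labels]
        track = []
        for v in (p, c):
            if v not in track:
                track.append(v)
        for v in leaf_nodes:
            if v not in track:
                track.append(v)
        obs = {self.tree.index(l): leaf_counts[l] for l in self.tree.leaf_labels}
        joints = self.joint_counts(track)
        num = 0.0
        den = 0.0
        for n, arr in joints.items():
            if max(obs.values(), default=0) > n:
                continue
            pn = stats.poisson.pmf(n, self.lam)
            it = [range(n + 1) if v not in obs else [obs[v]] for v in track]
            for idx in itertools.product(*it):
                val = pn * arr[idx]
                if val == 0:
                    continue
                den += val
                kp = idx[track.index(p)]
                kc = idx[track.index(c)]
                if kp >= parent_min and kc == child_exact:
                    num += val
        return num / den


# ----------------------------------------------------------------------
# Enrichment: literal running-sum extremum


def es_bruteforce(scores: np.ndarray, in_set: np.ndarray, p: float = 1.0) -> float:
    """Step-by-step weighted KS running sum over the whole ranked list.

    An exact tie between the positive and negative extreme deviations
    resolves to the positive one (the package's documented convention).
    """
    scores = np.asarray(scores, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    w = np.abs(scores) ** p
    W = w[in_set].sum()
    n_miss = (~in_set).sum()
    run = 0.0
    best = 0.0
    for i in range(len(scores)):
        if in_set[i]:
            run += (w[i] / W) if W > 0 else 0.0
        else:
            run -= 1.0 / n_miss
        if abs(run) > abs(best) or (abs(run) == abs(best) and run > best):
            best = run
    return best
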