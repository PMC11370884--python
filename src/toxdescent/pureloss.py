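"""Pure-loss phylogenetic model of pathway content evolution.

Model: a pathway enters the root of the tree with N elements (gene families
or reactions), N ~ Poisson(lambda).  Each element survives each branch b
independently with probability ``s_b`` in (0, 1]; an element lost on a
branch is never regained.  The observed data are the per-species element
counts (survivors at the leaves).

Conditional on a node holding k elements, the count at a child across a
branch with survival s is Binomial(k, s), which yields a postorder dynamic
program for the likelihood and an inside-outside (upward-downward) pass for
exact ancestral count posteriors.  The Poisson root prior is truncated at
``n_max`` with tail mass below 1e-12.

There is a single shared survival probability per branch across all
pathways of a class (rates are properties of lineages, not of individual
pathways), and no time calibration: branches are parameterized directly by
s_b, and the reported "loss length" of a branch is -ln(s_b).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .tree import SpeciesTree

__all__ = [
    "PureLossModel",
    "FitReport",
    "profile_loglik",
    "fit",
    "ancestral_posterior",
    "branch_loss_tally",
    "rate_tree",
]

_TAIL = 1e-12


@dataclass
class PureLossModel:
    """Fitted or specified pure-loss model on a rooted tree.

    ``survival[v]`` is the survival probability of the branch above node v
    (index aligned with ``tree.labels``; entry 0, the root, is unused and
    held at 1).
    """

    tree: SpeciesTree
    survival: np.ndarray
    lam: float
    n_max: int

    def __post_init__(self):
        self.survival = np.asarray(self.survival, dtype=float)
        if self.survival.shape != (self.tree.n_nodes,):
            raise ValueError("survival must have one entry per tree node")
        s = self.survival[1:]
        if np.any(s <= 0) or np.any(s > 1):
            raise ValueError("branch survival probabilities must lie in (0, 1]")
        if self.lam <= 0:
            raise ValueError("lambda (root Poisson mean) must be positive")

    def branch_survival(self) -> pd.Series:
        """Per-branch survival probabilities indexed by child-node label."""
        return pd.Series(self.survival[1:], index=self.tree.labels[1:], name="survival")

    def to_frame(self) -> pd.DataFrame:
        df = self.branch_survival().to_frame()
        df["loss_length"] = -np.log(df["survival"])
        df.attrs["lambda"] = self.lam
        df.attrs["n_max"] = self.n_max
        return df


@dataclass
class FitReport:
    loglik: float
    n_profiles: int
    converged: bool
    restarts: int
    start_seeds: list[int] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)


class FitError(RuntimeError):
    """Optimization failed to converge; carries the best model found so far."""

    def __init__(self, msg: str, model: PureLossModel, report: FitReport):
        super().__init__(msg)
        self.model = model
        self.report = report


# ----------------------------------------------------------------------
# Likelihood machinery


def _counts_matrix(leaf_counts, tree: SpeciesTree) -> np.ndarray:
    """Coerce input counts to an (n_profiles, n_leaves) int array in leaf order."""
    if isinstance(leaf_counts, pd.DataFrame):
        C = leaf_counts[tree.leaf_labels].to_numpy()
    elif isinstance(leaf_counts, dict):
        C = np.array([[leaf_counts[l] for l in tree.leaf_labels]])
    else:
        C = np.asarray(leaf_counts)
        if C.ndim == 1:
            C = C[None, :]
    if C.shape[1] != tree.n_leaves:
        raise ValueError("leaf count width != number of leaves")
    if np.any(C < 0) or not np.issubdtype(np.asarray(C).dtype, np.integer):
        C = np.asarray(C)
        if np.any(C != np.floor(C)) or np.any(C < 0):
            raise ValueError("leaf counts must be non-negative integers")
        C = C.astype(np.int64)
    return C.astype(np.int64)


def _binom_matrix(n_max: int, s: float) -> np.ndarray:
    """B[k, j] = P(Binomial(k, s) = j) for 0 <= j, k <= n_max."""
    k = np.arange(n_max + 1)[:, None]
    j = np.arange(n_max + 1)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        logb = (
            gammaln(k + 1)
            - gammaln(j + 1)
            - gammaln(k - j + 1)
            + j * np.log(s)
            + np.where(k - j >= 0, (k - j) * np.log1p(-s) if s < 1 else 0.0, 0.0)
        )
    B = np.where(j <= k, np.exp(logb), 0.0)
    if s == 1.0:
        B = np.eye(n_max + 1)
    return B


def _upward(model: PureLossModel, C: np.ndarray):
    """Postorder conditional likelihoods.

    Returns (L, M, logscale): L[v] is (n_profiles, n_max+1) with
    L[v][p, k] = P(leaf data under v | v holds k) (rescaled), M[v] the
    branch-transition message above v, and logscale the per-profile log of
    the accumulated rescaling factors (applies to the root L).
    """
    tree, n_max = model.tree, model.n_max
    n_prof = C.shape[0]
    leaf_col = {v: j for j, v in enumerate(np.flatnonzero(tree.is_leaf))}
    L: list[np.ndarray | None] = [None] * tree.n_nodes
    M: list[np.ndarray | None] = [None] * tree.n_nodes
    logscale = np.zeros(n_prof)
    ks = np.arange(n_max + 1)
    for v in tree.postorder():
        if tree.is_leaf[v]:
            obs = C[:, leaf_col[v]]
            Lv = np.zeros((n_prof, n_max + 1))
            Lv[np.arange(n_prof), obs] = 1.0
        else:
            Lv = np.ones((n_prof, n_max + 1))
            for c in tree.children[v]:
                Lv = Lv * M[c]
            # rescale to guard against underflow on deep trees
            mx = Lv.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            Lv = Lv / mx[:, None]
            logscale += np.log(mx)
        L[v] = Lv
        if v != 0:
            s = model.survival[v]
            if tree.is_leaf[v]:
                obs = C[:, leaf_col[v]]
                # M[v][p, k] = Binom(obs_p; k, s): gather one pmf column per profile
                B = _binom_matrix(n_max, s)
                M[v] = B[:, obs].T.copy()
            else:
                B = _binom_matrix(n_max, s)
                M[v] = Lv @ B.T
    return L, M, logscale


def _root_prior(model: PureLossModel) -> np.ndarray:
    prior = stats.poisson.pmf(np.arange(model.n_max + 1), model.lam)
    tail = stats.poisson.sf(model.n_max, model.lam)
    if tail > _TAIL:
        raise ValueError(
            f"Poisson tail beyond n_max={model.n_max} is {tail:.2e} > {_TAIL}; raise n_max"
        )
    return prior


def profile_loglik(model: PureLossModel, leaf_counts) -> np.ndarray | float:
    """Log-likelihood of leaf count profiles under the model.

    ``leaf_counts`` may be a dict (one profile), a 1-D array in
    ``tree.leaf_labels`` order, a 2-D array (profiles x leaves), or a
    DataFrame with species columns.  Returns a scalar for a single profile,
    else a vector.
    """
    C = _counts_matrix(leaf_counts, model.tree)
    single = C.shape[0] == 1 and (
        isinstance(leaf_counts, dict) or np.asarray(leaf_counts).ndim == 1
    )
    if C.max(initial=0) > model.n_max:
        raise ValueError(
            f"observed count {C.max()} exceeds n_max={model.n_max}; raise n_max"
        )
    L, _, logscale = _upward(model, C)
    prior = _root_prior(model)
    lik = L[0] @ prior
    with np.errstate(divide="ignore"):
        ll = np.log(lik) + logscale
    return float(ll[0]) if single else ll


def default_n_max(max_count: int, lam: float) -> int:
    """Truncation point: beyond the data and the root prior's 1e-12 tail."""
    n = int(max(max_count, np.ceil(lam + 6 * np.sqrt(lam) + 10)))
    while stats.poisson.sf(n, lam) > _TAIL:
        n += max(5, int(np.sqrt(lam)))
    return n


# ----------------------------------------------------------------------
# Fitting


def _moment_init(C: np.ndarray, tree: SpeciesTree) -> tuple[np.ndarray, float]:
    """Moment-based starting point: survival from leaf-mean ratios along paths."""
    leaf_mean = C.mean(axis=0)
    lam0 = float(max(leaf_mean.max() * 1.2, 1.0))
    # mean count "below" each node = average of its leaves' means
    below = (tree.leaf_matrix * leaf_mean).sum(axis=1) / np.maximum(
        tree.leaf_matrix.sum(axis=1), 1
    )
    t = np.clip(below / lam0, 1e-3, 1.0)  # survival from root to node
    s = np.ones(tree.n_nodes)
    for v in range(1, tree.n_nodes):
        s[v] = np.clip(t[v] / max(t[tree.parent[v]], 1e-3), 0.05, 0.98)
    return s, lam0


def fit(
    pathways,
    tree: SpeciesTree,
    restarts: int = 5,
    seed: int = 0,
    n_max: int | None = None,
    maxiter: int = 300,
) -> tuple[PureLossModel, FitReport]:
    """Maximum-likelihood branch survivals and root Poisson mean.

    ``pathways``: per-pathway leaf counts (DataFrame with species columns or
    (n_pathways x n_leaves) array in ``tree.leaf_labels`` order).  Optimizes
    logit(s_b) and log(lambda) jointly by L-BFGS-B with ``restarts``
    jittered multi-starts.  Returns (model, report); raises
    :class:`FitError` carrying the best model if no start converges.
    """
    C = _counts_matrix(pathways, tree)
    n_prof = C.shape[0]
    if n_prof < 10:
        warnings.warn(f"only {n_prof} pathway profiles; estimates will be unstable")
    s0, lam0 = _moment_init(C, tree)
    if n_max is None:
        n_max = default_n_max(int(C.max()), lam0 * 1.5)
    elif C.max() > n_max:
        raise ValueError(f"observed count {C.max()} exceeds n_max={n_max}; raise n_max")

    nb = tree.n_nodes - 1  # branches (one per non-root node)

    def unpack(x):
        s = np.empty(tree.n_nodes)
        s[0] = 1.0
        s[1:] = 1.0 / (1.0 + np.exp(-x[:nb]))
        lam = np.exp(x[nb])
        return s, lam

    def objective(x):
        s, lam = unpack(x)
        model = PureLossModel(tree, np.clip(s, 1e-9, 1.0), lam, n_max)
        try:
            ll = profile_loglik(model, C)
        except ValueError:
            return 1e12
        val = -np.sum(ll)
        return val if np.isfinite(val) else 1e12

    rng = np.random.default_rng(seed)
    # largest lambda whose Poisson tail beyond n_max stays below the truncation error
    lo, hi = 0.1, float(n_max)
    if stats.poisson.sf(n_max, hi) > _TAIL:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if stats.poisson.sf(n_max, mid) > _TAIL:
                hi = mid
            else:
                lo = mid
        hi = lo
    lam_hi = np.log(hi)
    bounds = [(-8.0, 8.0)] * nb + [(np.log(max(C.mean(), 0.5)) - 1.0, lam_hi)]
    x0_base = np.concatenate(
        [np.log(s0[1:] / (1 - s0[1:] + 1e-9)), [np.log(lam0)]]
    )
    x0_base = np.clip(x0_base, [b[0] for b in bounds], [b[1] for b in bounds])

    best = None
    report = FitReport(loglik=-np.inf, n_profiles=n_prof, converged=False, restarts=restarts)
    for r in range(restarts):
        start_seed = int(rng.integers(0, 2**31 - 1))
        report.start_seeds.append(start_seed)
        jrng = np.random.default_rng(start_seed)
        x0 = x0_base if r == 0 else x0_base + jrng.normal(0, 0.5, size=len(x0_base))
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": maxiter}
        )
        report.messages.append(str(res.message))
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            report.converged = True
    s, lam = unpack(best.x)
    model = PureLossModel(tree, s, lam, n_max)
    report.loglik = -best.fun
    if not report.converged:
        raise FitError("no optimizer start converged", model, report)
    return model, report


# ----------------------------------------------------------------------
# Posteriors and branch tallies


def _downward(model: PureLossModel, C: np.ndarray):
    """Inside-outside pass.

    Returns (L, M, O): upward arrays plus outside weights O[v] with
    O[v][p, k] proportional to P(data outside subtree(v), v holds k).
    """
    tree, n_max = model.tree, model.n_max
    L, M, _ = _upward(model, C)
    prior = _root_prior(model)
    O: list[np.ndarray | None] = [None] * tree.n_nodes
    O[0] = np.broadcast_to(prior, L[0].shape).copy()
    for v in range(tree.n_nodes):
        kids = tree.children[v]
        if not kids:
            continue
        # prefix/suffix products of sibling messages (avoids dividing by zero)
        pref = [None] * len(kids)
        suf = [None] * len(kids)
        acc = np.ones_like(L[v])
        for i, c in enumerate(kids):
            pref[i] = acc
            acc = acc * M[c]
        acc = np.ones_like(L[v])
        for i in range(len(kids) - 1, -1, -1):
            suf[i] = acc
            acc = acc * M[kids[i]]
        for i, c in enumerate(kids):
            W = O[v] * pref[i] * suf[i]  # outside weight at parent, excluding c
            B = _binom_matrix(n_max, model.survival[c])
            O[c] = W @ B
            # rescale per profile for stability
            mx = O[c].max(axis=1)
            O[c] = O[c] / np.where(mx > 0, mx, 1.0)[:, None]
    return L, M, O


def ancestral_posterior(model: PureLossModel, leaf_counts) -> dict[str, np.ndarray]:
    """Exact posterior count distributions at every node given leaf data.

    Returns a mapping node label -> (n_profiles, n_max+1) probability array;
    rows sum to 1, and leaf rows are point masses at the observed counts.
    """
    C = _counts_matrix(leaf_counts, model.tree)
    if C.max(initial=0) > model.n_max:
        raise ValueError(f"observed count {C.max()} exceeds n_max={model.n_max}")
    L, _, O = _downward(model, C)
    out = {}
    for v, lab in enumerate(model.tree.labels):
        post = O[v] * L[v]
        Z = post.sum(axis=1, keepdims=True)
        if np.any(Z <= 0):
            raise FloatingPointError("zero posterior normalizer (data impossible?)")
        out[lab] = post / Z
    return out


def branch_joint_loss(model: PureLossModel, leaf_counts) -> pd.DataFrame:
    """Per-branch, per-profile P(parent >= 1, child = 0) and P(parent >= 2, child = 1).

    Returns a DataFrame indexed by (branch, profile) with columns
    ``p_lost`` and ``p_contracted``.
    """
    tree = model.tree
    C = _counts_matrix(leaf_counts, tree)
    L, M, O = _downward(model, C)
    n_prof = C.shape[0]
    recs = {}
    for v in range(tree.n_nodes):
        kids = tree.children[v]
        if not kids:
            continue
        pref, suf = [None] * len(kids), [None] * len(kids)
        acc = np.ones_like(L[v])
        for i, c in enumerate(kids):
            pref[i] = acc
            acc = acc * M[c]
        acc = np.ones_like(L[v])
        for i in range(len(kids) - 1, -1, -1):
            suf[i] = acc
            acc = acc * M[kids[i]]
        for i, c in enumerate(kids):
            W = O[v] * pref[i] * suf[i]  # (profiles, k): outside-of-c weight at parent
            B = _binom_matrix(model.n_max, model.survival[c])
            # joint[p, k, j] ∝ W[p, k] B[k, j] L_c[p, j]; we need two slices of j
            Z = ((W @ B) * L[c]).sum(axis=1)  # total likelihood (unnormalized)
            p_lost = ((W[:, 1:] @ B[1:, 0]) * L[c][:, 0]) / Z
            p_con = ((W[:, 2:] @ B[2:, 1]) * L[c][:, 1]) / Z
            recs[tree.labels[c]] = (p_lost, p_con)
    rows = []
    for lab, (pl, pc) in recs.items():
        for p in range(n_prof):
            rows.append((lab, p, pl[p], pc[p]))
    return pd.DataFrame(rows, columns=["branch", "profile", "p_lost", "p_contracted"]).set_index(
        ["branch", "profile"]
    )


def branch_loss_tally(model: PureLossModel, leaf_counts) -> pd.DataFrame:
    """Expected pathway losses and contractions per branch.

    A pathway is *lost* on a branch when the parent holds >= 1 element and
    the child none; *contracted* when the parent holds >= 2 and the child
    exactly 1.  Expectations are sums of exact posterior joint
    probabilities over pathways.  ``cum_lost`` accumulates expected losses
    along the root-to-node path; ``pct`` columns are percentages of the
    pathway set.
    """
    joint = branch_joint_loss(model, leaf_counts)
    n_prof = joint.index.get_level_values("profile").nunique()
    agg = joint.groupby(level="branch").sum()
    tree = model.tree
    order = [l for l in tree.labels if l in agg.index]
    agg = agg.loc[order].rename(columns={"p_lost": "expected_lost", "p_contracted": "expected_contracted"})
    cum = np.zeros(tree.n_nodes)
    for v in range(1, tree.n_nodes):
        lab = tree.labels[v]
        cum[v] = cum[tree.parent[v]] + (
            agg.loc[lab, "expected_lost"] if lab in agg.index else 0.0
        )
    agg["cum_lost"] = [cum[tree.index(l)] for l in agg.index]
    agg["pct_lost"] = 100 * agg["expected_lost"] / n_prof
    agg["pct_contracted"] = 100 * agg["expected_contracted"] / n_prof
    agg["pct_cum_lost"] = 100 * agg["cum_lost"] / n_prof
    agg.index.name = "branch"
    return agg


def rate_tree(model: PureLossModel) -> str:
    """Newick of the tree with branch lengths -ln(s_b) (per-element loss intensity)."""
    s = model.survival
    if np.any(s[1:] <= 0):
        raise ValueError("survival of 0 implies infinite branch length")
    lengths = np.full(model.tree.n_nodes, np.nan)
    lengths[1:] = -np.log(s[1:])
    return model.tree.to_newick(branch_lengths=lengths)
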