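"""Subsampling null distributions and z-scores for branch statistics.

The observed class (disease families) is compared branch-by-branch against
repeated random subsamples of the reference class (non-disease families):
each replicate draws the observed class's size from the reference pool
without replacement, reruns the Dollo branch-event tally, and records every
branch gain/loss count and per-leaf presence count.  Replicates are
independent of each other (the pool is restored between draws).

Summary statistics per branch statistic: mean, sd (n-1 denominator),
se = sd / sqrt(n_reps), the one-sided normal 99% upper limit of the mean
(mean + 2.326 * se), and z = (observed - mean) / sd.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .dollo import _reconstruct_many, branch_event_table
from .profiles import ProfileMatrix
from .tree import SpeciesTree

__all__ = [
    "draw_null_replicates",
    "null_summary",
    "summary_from_moments",
    "subsampling_null_table",
    "Z_ONE_SIDED_99",
]

#: one-sided standard-normal 99% quantile used for the upper limit column
Z_ONE_SIDED_99 = 2.326


def _statistic_frame(tree: SpeciesTree) -> tuple[list[str], list[str]]:
    """Statistic names in output order: leaf presence, node gains, branch losses."""
    leaves = [l for l in tree.labels if l in set(tree.leaf_labels)]
    internal = [l for l in tree.labels if l not in set(tree.leaf_labels)]
    presence = [f"presence:{l}" for l in tree.leaf_labels]
    gains = [f"gains:{l}" for l in internal + leaves]
    losses = [f"losses:{l}" for l in internal[1:] + leaves]  # no branch above root
    return presence + gains + losses, leaves


def _stats_vector(table: pd.DataFrame, tree: SpeciesTree) -> pd.Series:
    names, _ = _statistic_frame(tree)
    vals = {}
    for n in names:
        kind, label = n.split(":", 1)
        col = {"presence": "presence_at_leaf", "gains": "gains", "losses": "losses"}[kind]
        vals[n] = table.loc[label, col]
    return pd.Series(vals, name="observed")


def draw_null_replicates(
    profiles: ProfileMatrix,
    tree: SpeciesTree,
    target_class: str = "disease",
    null_class: str = "non_disease",
    n_reps: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Branch statistics for ``n_reps`` random subsamples of the null class.

    Each replicate samples ``|target_class|`` families from ``null_class``
    without replacement and tallies Dollo branch events.  Returns a
    (n_reps x statistics) DataFrame.

    Per-family gains and losses are precomputed once; a replicate's branch
    tally is then the column sum over its sampled families, which is
    identical to rerunning the event table on the subsample.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible subsampling")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (variance undefined otherwise)")
    n_target = int((profiles.classes == target_class).sum())
    pool = profiles.subset(profiles.counts.index[profiles.classes == null_class])
    if len(pool) < n_target:
        raise ValueError(
            f"null pool ({len(pool)}) smaller than target class size ({n_target})"
        )
    P = pool.presence(tree)
    gain, losses = _reconstruct_many(P, tree)
    gain_onehot = np.zeros((len(pool), tree.n_nodes), dtype=np.int64)
    gain_onehot[np.arange(len(pool)), gain] = 1
    losses = losses.astype(np.int64)
    leaf_cols = [tree.labels.index(l) for l in tree.leaf_labels]

    rng = np.random.default_rng(seed)
    names, _ = _statistic_frame(tree)
    out = np.empty((n_reps, len(names)), dtype=np.int64)
    for r in range(n_reps):
        idx = rng.choice(len(pool), size=n_target, replace=False)
        g = gain_onehot[idx].sum(axis=0)
        l = losses[idx].sum(axis=0)
        pres = P[idx].sum(axis=0)
        row = {}
        for j, lab in enumerate(tree.leaf_labels):
            row[f"presence:{lab}"] = pres[j]
        for v, lab in enumerate(tree.labels):
            row[f"gains:{lab}"] = g[v]
            row[f"losses:{lab}"] = l[v]
        out[r] = [row[n] for n in names]
    return pd.DataFrame(out, columns=names)


def summary_from_moments(
    observed: float, mean: float, sd: float, n_reps: int
) -> dict[str, float]:
    """se / upper99 / z from a statistic's null mean and sd.

    ``z`` is ``inf``-signed when sd == 0 and the observation departs from the
    mean (degenerate null); 0 when it coincides.
    """
    se = sd / np.sqrt(n_reps)
    upper99 = mean + Z_ONE_SIDED_99 * se
    if sd > 0:
        z = (observed - mean) / sd
    elif observed == mean:
        z = 0.0
    else:
        warnings.warn("degenerate null (sd = 0) with observed != mean; z set to +/-inf")
        z = np.inf if observed > mean else -np.inf
    return {"se": se, "upper99": upper99, "z": z}


def null_summary(
    replicates: pd.DataFrame, observed: pd.Series, seed: int | None = None
) -> pd.DataFrame:
    """Per-statistic null summary table.

    Columns: observed, mean, sd, se, upper99, z.  ``replicates`` must have
    >= 2 rows; ``observed`` is aligned by statistic name.
    """
    if len(replicates) < 2:
        raise ValueError("need >= 2 replicates to summarize a null distribution")
    n = len(replicates)
    rows = []
    for name in replicates.columns:
        x = replicates[name].to_numpy(dtype=float)
        mean = x.mean()
        sd = x.std(ddof=1)
        obs = float(observed[name]) if name in observed.index else np.nan
        s = summary_from_moments(obs, mean, sd, n)
        rows.append(
            {
                "statistic": name,
                "observed": obs,
                "mean": mean,
                "sd": sd,
                "se": s["se"],
                "upper99": s["upper99"],
                "z": s["z"],
            }
        )
    out = pd.DataFrame(rows).set_index("statistic")
    out.attrs["n_reps"] = n
    if seed is not None:
        out.attrs["seed"] = seed
    return out


def subsampling_null_table(
    profiles: ProfileMatrix,
    tree: SpeciesTree,
    target_class: str = "disease",
    null_class: str = "non_disease",
    n_reps: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """End-to-end observed-vs-null branch table (observed class vs subsampled null)."""
    obs_table = branch_event_table(profiles, tree, target_class)
    observed = _stats_vector(obs_table, tree)
    reps = draw_null_replicates(
        profiles, tree, target_class, null_class, n_reps=n_reps, seed=seed
    )
    return null_summary(reps, observed, seed=seed)
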