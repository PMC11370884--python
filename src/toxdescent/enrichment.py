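"""Shannon-index ranking of gene families and preranked ortholog-set GSEA.

The Shannon index H' of a family's per-species copy counts measures how
evenly the family is distributed across genomes (natural log; maximum
ln(S) for a uniform single-copy family over S species, 0 for a family
private to one species).  Gene sets are converted to *ortholog sets* by
mapping gene IDs to family IDs and deduplicating, then scored against the
H'-ranked family list with the standard weighted Kolmogorov-Smirnov running
sum; significance comes from random same-size set permutations (the only
null available for a preranked analysis).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .profiles import ProfileMatrix

__all__ = [
    "shannon_index",
    "rank_families",
    "read_gmt",
    "write_gmt",
    "to_ortholog_sets",
    "preranked_es",
    "permutation_stats",
    "random_panel_experiment",
]


def shannon_index(counts) -> float:
    """H' = -sum p_i ln p_i over species with non-zero copy counts."""
    c = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("copy counts must be non-negative")
    tot = c.sum()
    if tot == 0:
        raise ValueError("all-zero profile has no Shannon index")
    p = c[c > 0] / tot
    return float(-(p * np.log(p)).sum())


def rank_families(
    profiles: ProfileMatrix, tie_shuffle_seed: int | None = None
) -> pd.Series:
    """Families sorted by descending H' (copy counts, not presence).

    Ties are broken by ascending family_id, which is stable and
    deterministic; within-tie order is arbitrary biologically and can shift
    ES slightly for small sets, so ``tie_shuffle_seed`` permutes tied
    blocks to quantify that sensitivity.
    """
    C = profiles.counts.to_numpy(dtype=float)
    tot = C.sum(axis=1)
    if np.any(tot == 0):
        raise ValueError("profiles with all-zero counts cannot be ranked")
    P = C / tot[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        H = -np.where(P > 0, P * np.log(P), 0.0).sum(axis=1)
    s = pd.Series(H, index=profiles.counts.index, name="shannon_h")
    # ascending-id pass first, then a stable descending-score pass -> ties by id
    s = s.sort_index(kind="stable").sort_values(ascending=False, kind="stable")
    if tie_shuffle_seed is not None:
        rng = np.random.default_rng(tie_shuffle_seed)
        idx = np.array(s.index)
        vals = s.to_numpy()
        start = 0
        for end in range(1, len(s) + 1):
            if end == len(s) or vals[end] != vals[start]:
                rng.shuffle(idx[start:end])
                start = end
        s = pd.Series(vals, index=idx, name=s.name)
    return s


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (set name, description, members per line)."""
    from gseapy.parser import read_gmt as _read_gmt  # heavy import, deferred

    sets = _read_gmt(str(path))
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def to_ortholog_sets(
    genesets: Mapping[str, Iterable[str]],
    gene_to_family: Mapping[str, str],
    min_size: int = 3,
    max_size: int = 500,
) -> dict[str, list[str]]:
    """Swap gene IDs for family IDs, deduplicate, and apply size bounds.

    Sets with no mappable gene are dropped with a warning; sets whose
    unique-family count falls outside ``[min_size, max_size]`` are excluded.
    """
    if not genesets:
        raise ValueError("empty gene-set collection")
    out: dict[str, list[str]] = {}
    unmapped = []
    for name, genes in genesets.items():
        fams: list[str] = []
        seen = set()
        for g in genes:
            f = gene_to_family.get(g)
            if f is not None and f not in seen:
                seen.add(f)
                fams.append(f)
        if not fams:
            unmapped.append(name)
            continue
        if min_size <= len(fams) <= max_size:
            out[name] = fams
    if unmapped:
        warnings.warn(f"{len(unmapped)} gene sets had no mappable genes and were dropped")
    return out


# ----------------------------------------------------------------------
# Weighted Kolmogorov-Smirnov running-sum enrichment


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, n_total: int) -> np.ndarray:
    """Signed enrichment score(s) from sorted hit positions.

    ``pos``: (m, k) 0-based positions of set members in the ranked list,
    sorted ascending along axis 1.  ``weights``: the |score|^p weight of
    every ranked item.  The running sum increments by the normalized hit
    weight at hits and decrements by 1/(N-k) at misses; its extrema occur
    immediately after a hit (maxima) or just before one (minima), so only
    those 2k candidate values need evaluating.
    """
    pos = np.atleast_2d(pos)
    m, k = pos.shape
    if k == 0:
        return np.zeros(m)
    hitw = weights[pos]
    W = hitw.sum(axis=1, keepdims=True)
    H = np.cumsum(hitw, axis=1)
    H = np.divide(H, W, out=np.zeros_like(H), where=W > 0)
    miss_rate = 1.0 / max(n_total - k, 1)
    dec = (pos - np.arange(k)) * miss_rate  # misses seen before each hit
    after = H - dec
    before = np.concatenate([np.zeros((m, 1)), H[:, :-1]], axis=1) - dec
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), 0.0)
    # exact ties between the extremes resolve to the positive deviation
    return np.clip(np.where(hi >= -lo, hi, lo), -1.0, 1.0)


def preranked_es(ranked: pd.Series, members: Iterable[str], weight_p: float = 1.0) -> float:
    """Weighted KS enrichment score of one ortholog set against a ranking.

    ``ranked``: family scores in descending order (see
    :func:`rank_families`).  Raises ``KeyError`` naming members missing from
    the ranked universe.
    """
    members = list(dict.fromkeys(members))
    index = pd.Index(ranked.index)
    locs = index.get_indexer(members)
    if (locs < 0).any():
        missing = [m for m, l in zip(members, locs) if l < 0]
        raise KeyError(f"set members missing from ranked universe: {missing}")
    weights = np.abs(ranked.to_numpy(dtype=float)) ** weight_p
    pos = np.sort(locs)
    return float(_es_from_positions(pos[None, :], weights, len(ranked))[0])


def _null_es(
    rng: np.random.Generator, n_total: int, k: int, n_perm: int, weights: np.ndarray
) -> np.ndarray:
    keys = rng.random((n_perm, n_total))
    pos = np.sort(np.argpartition(keys, k, axis=1)[:, :k], axis=1)
    return _es_from_positions(pos, weights, n_total)


def permutation_stats(
    ranked: pd.Series,
    sets: Mapping[str, Iterable[str]],
    n_perm: int = 1000,
    seed: int | None = None,
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """ES / NES / nominal p / FDR q for each set by gene-set permutation.

    Null ES are drawn from random same-size subsets of the ranked universe.
    NES divides ES by the mean magnitude of same-sign null ES; nominal p is
    the same-sign null exceedance fraction; FDR q uses the standard
    NES-based empirical ratio, monotonized.  Deterministic under a fixed
    seed.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible permutations")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    N = len(ranked)
    weights = np.abs(ranked.to_numpy(dtype=float)) ** weight_p
    rng = np.random.default_rng(seed)
    rows = []
    null_nes_all: list[np.ndarray] = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in sets.items():
        es = preranked_es(ranked, members, weight_p)
        k = len(set(members))
        if k > N / 2:
            warnings.warn(f"set {name!r} covers more than half the universe; null poorly defined")
        if k not in null_cache:
            null_cache[k] = _null_es(rng, N, k, n_perm, weights)
        null = null_cache[k]
        pos_mean = null[null > 0].mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        if es > 0:
            nes = es / pos_mean if np.isfinite(pos_mean) else np.nan
            same = null[null > 0]
            p = (same >= es).sum() / len(same) if len(same) else 1.0
        elif es < 0:
            nes = -abs(es) / neg_mean if np.isfinite(neg_mean) else np.nan
            same = null[null < 0]
            p = (same <= es).sum() / len(same) if len(same) else 1.0
        else:
            nes, p = 0.0, 1.0
        null_nes = np.where(
            null > 0,
            null / (pos_mean if np.isfinite(pos_mean) else 1.0),
            null / (neg_mean if np.isfinite(neg_mean) else 1.0),
        )
        null_nes_all.append(null_nes)
        rows.append({"set": name, "size": k, "es": es, "nes": nes, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    pooled = np.concatenate(null_nes_all) if null_nes_all else np.array([])
    obs = out["nes"].to_numpy()
    q = np.ones(len(out))
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            q[i] = np.nan
        elif nes > 0:
            num = (pooled >= nes).mean() / max((pooled > 0).mean(), 1e-12)
            den = (obs >= nes).sum() / max((obs > 0).sum(), 1)
            q[i] = min(1.0, num / den) if den > 0 else 1.0
        elif nes < 0:
            num = (pooled <= nes).mean() / max((pooled < 0).mean(), 1e-12)
            den = (obs <= nes).sum() / max((obs < 0).sum(), 1)
            q[i] = min(1.0, num / den) if den > 0 else 1.0
    out["fdr_q"] = q
    out.attrs["n_perm"] = n_perm
    out.attrs["seed"] = seed
    return out


def random_panel_experiment(
    panel: Iterable[str],
    universe: Iterable[str],
    gene_to_family: Mapping[str, str],
    ranked: pd.Series,
    n_sets: int = 100,
    set_size: int = 100,
    n_perm: int = 1000,
    seed: int | None = None,
    weight_p: float = 1.0,
) -> dict:
    """Enrichment p-values for random panel subsets vs random genome subsets.

    Draws ``n_sets`` gene subsets of ``set_size`` from the biomarker panel
    and from the whole gene universe, maps each to an ortholog set, and
    tests each against ``ranked``.  Returns both p-value vectors and the
    fraction below 0.05 for each sampling frame.
    """
    if seed is None:
        raise ValueError("a seed is required")
    panel = sorted(set(panel))
    universe = sorted(set(universe))
    if not set(panel) <= set(universe):
        raise ValueError("panel must be a subset of the gene universe")
    if set_size > len(panel):
        raise ValueError(f"set_size {set_size} exceeds panel size {len(panel)}")
    rng = np.random.default_rng(seed)
    fam_universe = set(ranked.index)

    def draw_pvals(pool: list[str], sub_seed: int) -> np.ndarray:
        srng = np.random.default_rng(sub_seed)
        sets = {}
        for i in range(n_sets):
            genes = srng.choice(len(pool), size=set_size, replace=False)
            fams = {gene_to_family.get(pool[g]) for g in genes}
            fams = sorted(f for f in fams if f is not None and f in fam_universe)
            if fams:
                sets[f"rand_{i}"] = fams
        if not sets:
            return np.array([])
        stats = permutation_stats(ranked, sets, n_perm=n_perm, seed=sub_seed + 1, weight_p=weight_p)
        return stats["p"].to_numpy()

    if n_sets == 0:
        return {
            "p_panel": np.array([]),
            "p_universe": np.array([]),
            "frac_panel": np.nan,
            "frac_universe": np.nan,
        }
    s1, s2 = (int(x) for x in rng.integers(0, 2**31 - 2, size=2))
    p_panel = draw_pvals(panel, s1)
    p_universe = draw_pvals(universe, s2)
    return {
        "p_panel": p_panel,
        "p_universe": p_universe,
        "frac_panel": float((p_panel < 0.05).mean()) if len(p_panel) else np.nan,
        "frac_universe": float((p_universe < 0.05).mean()) if len(p_universe) else np.nan,
    }
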