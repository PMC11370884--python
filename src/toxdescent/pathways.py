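"""Pathway gene/reaction conservation summaries and the conservation GLM.

A pathway record holds, for one terminal human pathway, the number of human
genes and reactions and the per-species counts of those that are conserved
(shared with humans).  The table layout is
``pathway_id, name, disease_flag, is_terminal, n_human_genes,
n_human_reactions`` followed by ``<species>:genes`` and
``<species>:reactions`` columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "read_pathways",
    "write_pathways",
    "filter_pathways",
    "conservation_percent",
    "group_average",
    "disease_gene_fraction",
    "conserved_fraction_summary",
    "ConservationGLM",
    "fit_conservation_glm",
    "predict_surface",
]

META_COLS = [
    "name",
    "disease_flag",
    "is_terminal",
    "n_human_genes",
    "n_human_reactions",
]


def _species_of(records: pd.DataFrame) -> list[str]:
    return sorted({c.split(":", 1)[0] for c in records.columns if ":" in c})


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    for col in META_COLS:
        if col not in records.columns:
            raise ValueError(f"pathway table missing column {col!r}")
    for sp in _species_of(records):
        for el, tot in (("genes", "n_human_genes"), ("reactions", "n_human_reactions")):
            col = f"{sp}:{el}"
            if col not in records.columns:
                raise ValueError(f"pathway table missing column {col!r}")
            if (records[col] > records[tot]).any():
                bad = records.index[records[col] > records[tot]][0]
                raise ValueError(f"conserved {el} exceed human {el} for pathway {bad!r}")
            if (records[col] < 0).any():
                raise ValueError(f"negative conserved count in {col!r}")
    return records


def read_pathways(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="pathway_id")
    df["disease_flag"] = df["disease_flag"].astype(bool)
    df["is_terminal"] = df["is_terminal"].astype(bool)
    return _validate(df)


def write_pathways(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index_label="pathway_id")


def filter_pathways(
    records: pd.DataFrame,
    min_elements: int = 3,
    max_elements: int = 1227,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep terminal pathways whose human gene count lies in the size window.

    Elements are counted as human genes (reactions are never used for size
    filtering).  Returns (filtered records, filter log); the log's removal
    counts and the retained count sum to the input size.
    """
    _validate(records)
    non_terminal = ~records["is_terminal"]
    small = records["is_terminal"] & (records["n_human_genes"] < min_elements)
    large = (
        records["is_terminal"]
        & (records["n_human_genes"] > max_elements)
        & ~small
    )
    keep = ~(non_terminal | small | large)
    log = {
        "input": int(len(records)),
        "retained": int(keep.sum()),
        "removed_small": int(small.sum()),
        "removed_large": int(large.sum()),
        "removed_non_terminal": int(non_terminal.sum()),
    }
    return records[keep].copy(), log


def conservation_percent(
    records: pd.DataFrame, species: str, element: str = "genes"
) -> pd.Series:
    """Per-pathway percent of human ``genes`` or ``reactions`` conserved in a species."""
    if element not in ("genes", "reactions"):
        raise ValueError("element must be 'genes' or 'reactions'")
    col = f"{species}:{element}"
    if col not in records.columns:
        raise KeyError(f"species {species!r} absent from pathway table")
    tot = records["n_human_genes" if element == "genes" else "n_human_reactions"]
    if (tot == 0).any():
        bad = records.index[tot == 0][0]
        raise ZeroDivisionError(f"pathway {bad!r} has zero human {element}")
    return 100.0 * records[col] / tot


def group_average(
    records: pd.DataFrame, species_group: list[str], element: str = "genes"
) -> pd.Series:
    """Per-pathway unweighted mean conservation percent over a species group."""
    if not species_group:
        raise ValueError("species group must be non-empty")
    cols = [conservation_percent(records, sp, element) for sp in species_group]
    return pd.concat(cols, axis=1).mean(axis=1)


def disease_gene_fraction(flags) -> float | None:
    """Percent of a pathway's conserved genes that are disease-linked.

    ``flags`` are the disease indicators of the genes conserved in one
    species; an empty input (no conserved genes) is undefined and returns
    ``None``.
    """
    flags = list(flags)
    if not flags:
        return None
    return 100.0 * sum(bool(f) for f in flags) / len(flags)


def conserved_fraction_summary(
    records: pd.DataFrame,
    vert_group: list[str],
    invert_group: list[str],
    element: str = "genes",
    threshold: float = 75.0,
) -> dict[str, float]:
    """How many vertebrate-conserved pathways remain conserved in invertebrates.

    A pathway counts as conserved in a group when the group-average
    conservation percent exceeds ``threshold``.
    """
    v = group_average(records, vert_group, element)
    i = group_average(records, invert_group, element)
    vert_conserved = v > threshold
    both = vert_conserved & (i > threshold)
    n_vert = int(vert_conserved.sum())
    return {
        "n_vert_conserved": n_vert,
        "n_also_invert": int(both.sum()),
        "pct_also_invert": (100.0 * both.sum() / n_vert) if n_vert else np.nan,
    }


# ----------------------------------------------------------------------


@dataclass
class ConservationGLM:
    """Fitted invertebrate-conservation model.

    Model: invertebrate mean conservation ~ vertebrate mean conservation +
    human pathway gene count + interaction, with a binomial family / logit
    link weighted by pathway size (default) or a gaussian identity
    sensitivity mode.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    family: str
    link: str
    n_obs: int
    result: object  # statsmodels results, for prediction

    #: observed predictor ranges, used to flag extrapolation in predictions
    vert_range: tuple[float, float] = (0.0, 1.0)
    ngenes_range: tuple[float, float] = (0.0, np.inf)


def _design(vert_prop: np.ndarray, n_genes: np.ndarray) -> pd.DataFrame:
    X = pd.DataFrame(
        {
            "vertebrate_conservation": vert_prop,
            "n_genes": n_genes,
            "interaction": vert_prop * n_genes,
        }
    )
    return sm.add_constant(X, has_constant="add")


def fit_conservation_glm(
    records: pd.DataFrame,
    vert_group: list[str],
    invert_group: list[str],
    element: str = "genes",
    family: str = "binomial",
) -> ConservationGLM:
    """Fit the pathway-conservation GLM.

    Response: per-pathway invertebrate mean conserved proportion.
    Predictors: vertebrate mean conserved proportion, human gene count, and
    their interaction.  ``family='binomial'`` uses a logit link with
    pathway gene counts as variance weights; ``family='gaussian'`` is an
    identity-link sensitivity mode.
    """
    if len(records) == 0:
        raise ValueError("no pathway records to fit")
    if len(records) < 30:
        warnings.warn(f"only {len(records)} pathways; GLM estimates will be unstable")
    y = group_average(records, invert_group, element).to_numpy() / 100.0
    v = group_average(records, vert_group, element).to_numpy() / 100.0
    ng = records["n_human_genes"].to_numpy(dtype=float)
    X = _design(v, ng)
    if family == "binomial":
        model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=ng)
    elif family == "gaussian":
        model = sm.GLM(y, X, family=sm.families.Gaussian())
    else:
        raise ValueError("family must be 'binomial' or 'gaussian'")
    try:
        res = model.fit()
    except Exception as exc:
        raise RuntimeError(f"GLM fit failed (separation or singular design?): {exc}")
    if not np.all(np.isfinite(res.bse)):
        raise RuntimeError("GLM fit produced non-finite standard errors (separation?)")
    return ConservationGLM(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        family=family,
        link="logit" if family == "binomial" else "identity",
        n_obs=len(records),
        result=res,
        vert_range=(float(v.min()), float(v.max())),
        ngenes_range=(float(ng.min()), float(ng.max())),
    )


def predict_surface(
    model: ConservationGLM,
    vert_grid: np.ndarray,
    ngenes_grid: np.ndarray,
) -> pd.DataFrame:
    """Predicted invertebrate conserved proportion on a lattice.

    Rows indexed by vertebrate conservation proportion, columns by human
    gene count.  Grid points outside the fitted range trigger an
    extrapolation warning but are still predicted.
    """
    vert_grid = np.asarray(vert_grid, dtype=float)
    ngenes_grid = np.asarray(ngenes_grid, dtype=float)
    lo_v, hi_v = model.vert_range
    lo_n, hi_n = model.ngenes_range
    if vert_grid.min() < lo_v or vert_grid.max() > hi_v or (
        ngenes_grid.min() < lo_n or ngenes_grid.max() > hi_n
    ):
        warnings.warn("prediction grid extends beyond the observed range (extrapolation)")
    V, N = np.meshgrid(vert_grid, ngenes_grid, indexing="ij")
    X = _design(V.ravel(), N.ravel())
    pred = model.result.predict(X).to_numpy().reshape(V.shape)
    return pd.DataFrame(
        pred,
        index=pd.Index(vert_grid, name="vertebrate_conservation"),
        columns=pd.Index(ngenes_grid, name="n_genes"),
    )
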