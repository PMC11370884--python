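"""Gene-family phylogenetic profiles: copy-number matrices, class labels, I/O.

A *profile* is the vector of per-species gene copy counts for one ortholog
family.  Families are classified ``disease`` (every human paralog linked to a
genetic disease), ``non_disease`` (none linked), or ``mixed`` (some linked);
analyses anchored on humans require every family to contain a human gene.
"""

from __future__ import annotations

import io
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .tree import SpeciesTree, TreeError

__all__ = [
    "ProfileMatrix",
    "ProfileFormatError",
    "CLASSES",
    "DEFAULT_ALIASES",
    "read_profile_matrix",
    "write_profile_matrix",
    "classify_families",
    "binarize",
    "conservation_summary",
    "percentage",
]

CLASSES = ("disease", "non_disease", "mixed", "unlabeled")

ANCHOR_SPECIES = "Homo_sapiens"

# Exact-string species matching, with a small alias table for common
# shorthand; extend via the `aliases` argument of read_profile_matrix.
DEFAULT_ALIASES: dict[str, str] = {
    "Homo sapiens": "Homo_sapiens",
    "Mus musculus": "Mus_musculus",
    "Rattus norvegicus": "Rattus_norvegicus",
    "Xenopus tropicalis": "Xenopus_tropicalis",
    "Fundulus heteroclitus": "Fundulus_heteroclitus",
    "Gallus gallus": "Gallus_gallus",
    "Danio rerio": "Danio_rerio",
    "Drosophila melanogaster": "Drosophila_melanogaster",
    "Anopheles gambiae": "Anopheles_gambiae",
    "Nasonia vitripennis": "Nasonia_vitripennis",
    "Daphnia magna": "Daphnia_magna",
    "Daphnia pulex": "Daphnia_pulex",
    "Hyalella azteca": "Hyalella_azteca",
    "Caenorhabditis elegans": "Caenorhabditis_elegans",
    "Hsap": "Homo_sapiens",
    "Mmus": "Mus_musculus",
    "Dmel": "Drosophila_melanogaster",
    "Cele": "Caenorhabditis_elegans",
    "Dmag": "Daphnia_magna",
    "Dpul": "Daphnia_pulex",
}


class ProfileFormatError(ValueError):
    """Malformed profile TSV or inconsistent matrix contents."""


class ProfileMatrix:
    """Family-by-species copy-count matrix with per-family class labels.

    Parameters
    ----------
    counts
        DataFrame indexed by family_id with one integer column per species;
        row order is preserved throughout.
    classes
        Series of class labels aligned with ``counts`` (default
        ``unlabeled``); values must be in :data:`CLASSES`.
    anchor
        Species that every family must contain (>= 1 copy); ``None``
        disables the check.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        classes: pd.Series | None = None,
        anchor: str | None = ANCHOR_SPECIES,
    ):
        counts = counts.copy()
        if counts.shape[0] == 0:
            raise ProfileFormatError("profile matrix has no families")
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ProfileFormatError(f"duplicate family_id: {dups}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ProfileFormatError("copy counts must be integers")
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ProfileFormatError("copy counts must be non-negative")
        self.counts = counts
        if classes is None:
            classes = pd.Series("unlabeled", index=counts.index)
        classes = classes.reindex(counts.index)
        bad = set(classes.dropna().unique()) - set(CLASSES)
        if bad or classes.isna().any():
            raise ProfileFormatError(f"invalid class labels: {sorted(map(str, bad))}")
        self.classes = classes
        self.anchor = anchor
        if anchor is not None:
            if anchor not in counts.columns:
                raise ProfileFormatError(f"anchor species {anchor!r} not in matrix")
            missing = counts.index[counts[anchor] < 1]
            if len(missing):
                raise ProfileFormatError(
                    f"{len(missing)} families absent from anchor species {anchor!r}: "
                    f"{missing[:5].tolist()}..."
                )

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def family_ids(self) -> list[str]:
        return list(self.counts.index)

    def subset(self, family_ids: Iterable[str]) -> "ProfileMatrix":
        ids = list(family_ids)
        return ProfileMatrix(self.counts.loc[ids], self.classes.loc[ids], anchor=self.anchor)

    def of_class(self, label: str) -> "ProfileMatrix":
        if label not in CLASSES:
            raise ProfileFormatError(f"unknown class {label!r}")
        return self.subset(self.counts.index[self.classes == label])

    def presence(self, tree: SpeciesTree | None = None) -> np.ndarray:
        """Boolean presence matrix, columns ordered to ``tree.leaf_labels`` if given."""
        cols = self.species if tree is None else tree.leaf_labels
        missing = set(cols) - set(self.species)
        if missing:
            raise ProfileFormatError(f"species missing from matrix: {sorted(missing)}")
        return self.counts[cols].to_numpy() > 0

    def __len__(self) -> int:
        return self.counts.shape[0]

    def __repr__(self) -> str:  # pragma: no cover
        cc = self.classes.value_counts().to_dict()
        return f"ProfileMatrix({len(self)} families x {len(self.species)} species, classes={cc})"


# ----------------------------------------------------------------------
# I/O: family_id <TAB> class <TAB> species1 ... speciesN, integer cells.


def read_profile_matrix(
    path,
    anchor: str | None = ANCHOR_SPECIES,
    aliases: Mapping[str, str] | None = None,
) -> ProfileMatrix:
    """Read a profile TSV; validates counts and reports offending rows."""
    alias = dict(DEFAULT_ALIASES)
    if aliases:
        alias.update(aliases)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ProfileFormatError(f"empty profile file: {path}") from None
    if df.shape[1] < 3 or list(df.columns[:2]) != ["family_id", "class"]:
        raise ProfileFormatError(
            "profile TSV must start with columns 'family_id', 'class' then species"
        )
    if df.shape[0] == 0:
        raise ProfileFormatError(f"profile file has no rows: {path}")
    species = [alias.get(c, c) for c in df.columns[2:]]
    counts = {}
    for col_in, col_out in zip(df.columns[2:], species):
        raw = df[col_in]
        try:
            vals = pd.to_numeric(raw)
        except (ValueError, TypeError):
            bad = raw.index[pd.to_numeric(raw, errors="coerce").isna()][0]
            raise ProfileFormatError(
                f"non-numeric count in column {col_out!r}, row {bad + 2}"
            ) from None
        if (vals != np.floor(vals)).any() or (vals < 0).any():
            bad = vals.index[(vals != np.floor(vals)) | (vals < 0)][0]
            raise ProfileFormatError(
                f"negative or non-integer count in column {col_out!r}, row {bad + 2}"
            )
        counts[col_out] = vals.astype(np.int64)
    mat = pd.DataFrame(counts)
    mat.index = pd.Index(df["family_id"], name="family_id")
    classes = pd.Series(df["class"].to_numpy(), index=mat.index)
    return ProfileMatrix(mat, classes, anchor=anchor)


def write_profile_matrix(profiles: ProfileMatrix, path) -> None:
    out = profiles.counts.copy()
    out.insert(0, "class", profiles.classes)
    out.to_csv(path, sep="\t", index=True, index_label="family_id")


# ----------------------------------------------------------------------


def classify_families(
    family_genes: Mapping[str, Iterable[str]],
    morbid_genes: Iterable[str],
) -> dict[str, str]:
    """Classify each family by its human genes' disease links.

    ``disease`` iff *all* human genes of the family are in the morbid list,
    ``non_disease`` iff none are, ``mixed`` otherwise.
    """
    morbid = set(morbid_genes)
    out: dict[str, str] = {}
    for fam, genes in family_genes.items():
        genes = list(genes)
        if not genes:
            raise ProfileFormatError(f"family {fam!r} has an empty gene list")
        hits = sum(g in morbid for g in genes)
        if hits == len(genes):
            out[fam] = "disease"
        elif hits == 0:
            out[fam] = "non_disease"
        else:
            out[fam] = "mixed"
    return out


def binarize(profiles: ProfileMatrix) -> ProfileMatrix:
    """Presence/absence transform: count > 0 -> 1.  Classes preserved."""
    return ProfileMatrix(
        (profiles.counts > 0).astype(np.int64), profiles.classes, anchor=profiles.anchor
    )


def percentage(numerator: int, denominator: int, decimals: int = 0) -> float:
    """``100 * numerator / denominator`` rounded half-up to ``decimals``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    q = Decimal(1).scaleb(-decimals)
    val = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(val)


# ----------------------------------------------------------------------

#: Conservation categories, in output row order.
SUMMARY_CATEGORIES = (
    "total",
    "single_copy",
    "in_all_species",
    "in_all_species_single_copy",
    "in_vert_and_invert",
    "in_vertebrate",
    "in_all_vertebrates",
    "only_in_vertebrate",
    "only_in_all_vertebrates",
)


def conservation_summary(
    profiles: ProfileMatrix,
    tree: SpeciesTree,
    vert_clade: str = "Vertebrata",
    invert_clade: str = "Ecdysozoa",
) -> pd.DataFrame:
    """Per-class cross-species conservation category counts.

    Categories (a family may fall in several):

    - ``single_copy``: no species carries more than one copy;
    - ``in_all_species`` / ``in_all_species_single_copy``: present in every
      leaf (and single copy everywhere);
    - ``in_vert_and_invert``: present in >= 1 leaf of each of the two clades;
    - ``in_vertebrate`` / ``in_all_vertebrates``: present in >= 1 / in all
      leaves under ``vert_clade``;
    - ``only_in_vertebrate`` / ``only_in_all_vertebrates``: as above but
      absent from every leaf outside ``vert_clade``.

    Returns a DataFrame with category rows and one column per class plus a
    ``total`` column.
    """
    vert_leaves = set(tree.leaves_under(vert_clade))
    invert_leaves = set(tree.leaves_under(invert_clade))
    if not set(profiles.species) == set(tree.leaf_labels):
        raise ProfileFormatError("profile species do not match tree leaves")
    pres = profiles.presence(tree)
    cnts = profiles.counts[tree.leaf_labels].to_numpy()
    vmask = np.array([l in vert_leaves for l in tree.leaf_labels])
    imask = np.array([l in invert_leaves for l in tree.leaf_labels])
    nonv = ~vmask

    single = (cnts <= 1).all(axis=1)
    in_all = pres.all(axis=1)
    in_vert = pres[:, vmask].any(axis=1)
    in_invert = pres[:, imask].any(axis=1)
    in_all_vert = pres[:, vmask].all(axis=1)
    outside_vert = pres[:, nonv].any(axis=1)

    flags = {
        "total": np.ones(len(profiles), dtype=bool),
        "single_copy": single,
        "in_all_species": in_all,
        "in_all_species_single_copy": in_all & single,
        "in_vert_and_invert": in_vert & in_invert,
        "in_vertebrate": in_vert,
        "in_all_vertebrates": in_all_vert,
        "only_in_vertebrate": in_vert & ~outside_vert,
        "only_in_all_vertebrates": in_all_vert & ~outside_vert,
    }
    cls = profiles.classes.to_numpy()
    cols = [c for c in CLASSES if (cls == c).any()]
    data = {
        c: [int(flags[cat][cls == c].sum()) for cat in SUMMARY_CATEGORIES] for c in cols
    }
    data["total"] = [int(flags[cat].sum()) for cat in SUMMARY_CATEGORIES]
    return pd.DataFrame(data, index=pd.Index(SUMMARY_CATEGORIES, name="category"))
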