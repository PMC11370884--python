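"""Synthetic study inputs with the statistical structure the pipeline assumes.

Everything downstream is testable without database downloads: gene-family
profiles follow a single-origin (Dollo-compatible) gain process with
branch-specific loss and duplication; disease-class families originate
disproportionately at the root; pathway reactions survive whenever at least
one member gene survives (making reactions more conserved than genes); and
gene sets can be biased toward deeply conserved or recently gained
families.  Every generator returns a truth log alongside the data so
inference can be checked against the generating events.

Scale defaults are desk-scale: roughly one tenth of the magnitudes of the
curated ortholog-database inputs the pipeline is designed for (about 10,400
families across 12 species; about 1,500 pathways averaging 29 genes and 11
reactions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .profiles import ProfileMatrix
from .pureloss import PureLossModel
from .tree import SpeciesTree, suite1_tree, suite2_tree

__all__ = [
    "GeneratorConfig",
    "suite1_like",
    "suite2_like",
    "simulate_profiles",
    "simulate_pathways",
    "simulate_gene_sets",
    "simulate_pureloss_counts",
]

ANCHOR = "Homo_sapiens"


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic input generator.

    ``origin_probs`` maps each family class to a probability distribution
    over gain nodes (ancestors of the anchor species, root first).
    ``loss_prob`` is the per-branch probability that a family present at
    the parent is absent at the child; ``default_loss_prob`` fills branches
    not listed.  Duplication adds geometric extra copies with probability
    ``dup_prob`` per surviving branch.
    """

    tree: SpeciesTree
    seed: int
    n_families: int = 1044
    class_counts: dict[str, int] = field(
        default_factory=lambda: {"disease": 160, "non_disease": 745, "mixed": 139}
    )
    origin_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    loss_prob: dict[str, float] = field(default_factory=dict)
    default_loss_prob: float = 0.08
    dup_prob: float = 0.05
    dup_mean_extra: float = 1.0
    genes_per_family_mean: float = 1.8
    # pathway generation
    n_pathways: int = 300
    pathway_size_lognorm: tuple[float, float] = (np.log(29.0) - 0.32, 0.8)
    disease_pathway_size_lognorm: tuple[float, float] = (np.log(18.0) - 0.32, 0.8)
    reactions_per_pathway_mean: float = 11.0
    genes_per_reaction_mean: float = 2.5
    disease_pathway_fraction: float = 0.23
    non_terminal_fraction: float = 0.1
    # gene sets
    n_gene_sets: int = 50
    gene_set_size_range: tuple[int, int] = (19, 132)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for d in (self.loss_prob,):
            for k, v in d.items():
                if not 0 <= v <= 1:
                    raise ValueError(f"loss probability out of [0,1] for branch {k!r}")
        for cls, dist in self.origin_probs.items():
            tot = sum(dist.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"origin distribution for {cls!r} sums to {tot}")

    def branch_loss(self) -> np.ndarray:
        """Per-node loss probability array (entry 0 unused)."""
        p = np.full(self.tree.n_nodes, self.default_loss_prob)
        for lab, v in self.loss_prob.items():
            p[self.tree.index(lab)] = v
        p[0] = 0.0
        return p


def _anchor_path(tree: SpeciesTree) -> list[int]:
    v = tree.index(ANCHOR)
    path = []
    while v != -1:
        path.append(v)
        v = tree.parent[v]
    return path[::-1]  # root .. anchor


def suite1_like(seed: int, scale: float = 1.0) -> GeneratorConfig:
    """12-species gene-family preset.

    Origin distributions put ~71% of disease families and ~59% of
    non-disease families at the root; mammal-specific families are mostly
    non-disease.  Invertebrate branches (the nematode especially) lose
    ancestral families at higher rates than vertebrate branches.
    """
    tree = suite1_tree()
    origin = {
        "disease": {
            "Bilateria": 0.71,
            "Vertebrata": 0.18,
            "Tetrapoda": 0.04,
            "Mammalia": 0.04,
            "Homo_sapiens": 0.03,
        },
        "non_disease": {
            "Bilateria": 0.59,
            "Vertebrata": 0.25,
            "Tetrapoda": 0.06,
            "Mammalia": 0.07,
            "Homo_sapiens": 0.03,
        },
        "mixed": {
            "Bilateria": 0.65,
            "Vertebrata": 0.22,
            "Tetrapoda": 0.06,
            "Mammalia": 0.05,
            "Homo_sapiens": 0.02,
        },
    }
    loss = {
        "Caenorhabditis_elegans": 0.40,
        "Anopheles_gambiae": 0.15,
        "Drosophila_melanogaster": 0.12,
        "Nasonia_vitripennis": 0.12,
        "Hexapoda": 0.15,
        "Diptera": 0.08,
        "Crustacea": 0.04,
        "Cladocera": 0.08,
        "Daphnia_magna": 0.12,
        "Daphnia_pulex": 0.08,
        "Hyalella_azteca": 0.14,
        "Arthropoda": 0.03,
        "Ecdysozoa": 0.0,
        "Vertebrata": 0.0,
        "Xenopus_tropicalis": 0.10,
        "Fundulus_heteroclitus": 0.05,
        "Danio_rerio": 0.04,
        "Fish": 0.02,
        "Mus_musculus": 0.02,
        "Tetrapoda": 0.02,
        "Mammalia": 0.01,
        "Homo_sapiens": 0.0,
    }
    cc = {k: max(1, round(v * scale)) for k, v in
          {"disease": 160, "non_disease": 745, "mixed": 139}.items()}
    return GeneratorConfig(
        tree=tree,
        seed=seed,
        n_families=sum(cc.values()),
        class_counts=cc,
        origin_probs=origin,
        loss_prob=loss,
    )


def suite2_like(seed: int) -> GeneratorConfig:
    """8-species pathway-suite preset (pathway records, pure-loss inputs)."""
    tree = suite2_tree()
    origin = {
        "disease": {"Bilateria": 0.8, "Vertebrata": 0.12, "Tetrapoda": 0.04,
                    "Amniota": 0.02, "Euarchontoglires": 0.01, "Homo_sapiens": 0.01},
        "non_disease": {"Bilateria": 0.68, "Vertebrata": 0.18, "Tetrapoda": 0.06,
                        "Amniota": 0.04, "Euarchontoglires": 0.02, "Homo_sapiens": 0.02},
        "mixed": {"Bilateria": 0.75, "Vertebrata": 0.15, "Tetrapoda": 0.05,
                  "Amniota": 0.03, "Euarchontoglires": 0.01, "Homo_sapiens": 0.01},
    }
    loss = {
        "Caenorhabditis_elegans": 0.45,
        "Drosophila_melanogaster": 0.30,
        "Ecdysozoa": 0.05,
        "Danio_rerio": 0.12,
        "Xenopus_tropicalis": 0.12,
        "Gallus_gallus": 0.10,
        "Rattus_norvegicus": 0.04,
        "Mus_musculus": 0.04,
        "Rodentia": 0.02,
        "Euarchontoglires": 0.02,
        "Amniota": 0.03,
        "Tetrapoda": 0.03,
        "Vertebrata": 0.0,
        "Homo_sapiens": 0.0,
    }
    return GeneratorConfig(
        tree=tree,
        seed=seed,
        n_families=1044,
        class_counts={"disease": 160, "non_disease": 745, "mixed": 139},
        origin_probs=origin,
        loss_prob=loss,
    )


# ----------------------------------------------------------------------


def simulate_profiles(config: GeneratorConfig) -> tuple[ProfileMatrix, pd.DataFrame]:
    """Simulate a family-by-species copy matrix plus its true event log.

    Each family gains once at a node drawn from its class's origin
    distribution, is inherited down the tree, lost on each branch with that
    branch's loss probability, and duplicated (geometric extra copies) with
    probability ``dup_prob`` per surviving branch.  Families absent from
    the anchor species are redrawn, conditioning the process on anchoring.

    Returns (matrix, truth) where truth has columns ``class``,
    ``gain_node`` and ``loss_branches`` (comma-joined child labels of
    branches where a present family was lost).
    """
    tree = config.tree
    rng = np.random.default_rng(config.seed)
    loss = config.branch_loss()
    path = set(_anchor_path(tree))
    if any(loss[v] >= 1.0 for v in path if v != 0):
        raise ValueError("loss probability of 1 on the anchor path makes anchoring infeasible")

    fams, classes, gains, loss_logs = [], [], [], []
    counts_rows = []
    fam_no = 0
    for cls, n_cls in config.class_counts.items():
        dist = config.origin_probs.get(cls)
        if dist is None:
            anchor_nodes = _anchor_path(tree)
            dist = {tree.labels[v]: 1.0 / len(anchor_nodes) for v in anchor_nodes}
        labels = list(dist)
        probs = np.array([dist[l] for l in labels])
        origin_idx = np.array([tree.index(l) for l in labels])
        pending = n_cls
        while pending > 0:
            g_nodes = origin_idx[rng.choice(len(labels), size=pending, p=probs)]
            counts = np.zeros((pending, tree.n_nodes), dtype=np.int64)
            lost_on = np.zeros((pending, tree.n_nodes), dtype=bool)
            counts[np.arange(pending), g_nodes] = 1
            under = tree.descendant_or_self[g_nodes]  # (pending, nodes)
            for v in range(1, tree.n_nodes):
                par = tree.parent[v]
                alive = (counts[:, par] > 0) & under[:, v]
                if not alive.any():
                    continue
                survive = alive & (rng.random(pending) >= loss[v])
                lost_on[:, v] = alive & ~survive
                c = counts[:, par].copy()
                dup = survive & (rng.random(pending) < config.dup_prob)
                extra = rng.geometric(1.0 / (1.0 + config.dup_mean_extra), size=pending)
                c = c + np.where(dup, extra, 0)
                counts[:, v] = np.where(survive, c, 0)
                # a gain at v itself keeps its single founding copy
                counts[:, v] = np.where(g_nodes == v, 1, counts[:, v])
            anchor_ok = counts[:, tree.index(ANCHOR)] > 0
            for i in np.flatnonzero(anchor_ok):
                fams.append(f"fam{fam_no:05d}")
                fam_no += 1
                classes.append(cls)
                gains.append(tree.labels[g_nodes[i]])
                loss_logs.append(
                    ",".join(tree.labels[v] for v in np.flatnonzero(lost_on[i]))
                )
                counts_rows.append(counts[i][tree._leaf_nodes])
            pending = int((~anchor_ok).sum())

    mat = pd.DataFrame(
        np.array(counts_rows), columns=tree.leaf_labels,
        index=pd.Index(fams, name="family_id"),
    )
    profiles = ProfileMatrix(mat, pd.Series(classes, index=mat.index))
    truth = pd.DataFrame(
        {"class": classes, "gain_node": gains, "loss_branches": loss_logs},
        index=mat.index,
    )
    return profiles, truth


def simulate_genes(
    profiles: ProfileMatrix, config: GeneratorConfig
) -> tuple[dict[str, list[str]], set[str]]:
    """Human gene IDs per family plus a morbid-gene list consistent with classes.

    Disease families have every gene in the morbid list, non-disease none,
    mixed families a proper subset, so re-classification recovers the
    generated labels exactly.
    """
    rng = np.random.default_rng(config.seed + 1)
    family_genes: dict[str, list[str]] = {}
    morbid: set[str] = set()
    for fam in profiles.family_ids:
        cls = profiles.classes[fam]
        n = 1 + rng.poisson(config.genes_per_family_mean - 1)
        if cls == "mixed" and n < 2:
            n = 2
        genes = [f"{fam}_g{i}" for i in range(n)]
        family_genes[fam] = genes
        if cls == "disease":
            morbid.update(genes)
        elif cls == "mixed":
            k = int(rng.integers(1, n))
            morbid.update(genes[:k])
    return family_genes, morbid


def simulate_pathways(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, dict]:
    """Simulate pathway records over the config's tree.

    Pathway genes are families simulated with the profile generator; a gene
    is conserved in a species iff its family is present there, and a
    reaction is conserved iff at least one member gene is conserved — the
    mechanism that makes reactions systematically more conserved than
    genes.  Returns (records, truth) where truth carries the underlying
    family presence matrix and per-pathway gene/reaction membership.
    """
    rng = np.random.default_rng(config.seed + 2)
    profiles, truth_fams = simulate_profiles(config)
    presence = pd.DataFrame(
        profiles.presence(config.tree), index=profiles.counts.index,
        columns=config.tree.leaf_labels,
    )
    fam_ids = np.array(profiles.family_ids)
    n_univ = len(fam_ids)
    species = config.tree.leaf_labels

    rows = []
    membership = {}
    for i in range(config.n_pathways):
        pid = f"PW{i:04d}"
        disease = bool(rng.random() < config.disease_pathway_fraction)
        mu, sg = (
            config.disease_pathway_size_lognorm if disease else config.pathway_size_lognorm
        )
        size = int(np.clip(np.round(rng.lognormal(mu, sg)), 1, n_univ))
        gene_fams = fam_ids[rng.choice(n_univ, size=size, replace=False)]
        n_re = max(1, rng.poisson(config.reactions_per_pathway_mean))
        reactions = []
        for _ in range(n_re):
            k = int(np.clip(1 + rng.poisson(config.genes_per_reaction_mean - 1), 1, size))
            reactions.append(list(gene_fams[rng.choice(size, size=k, replace=False)]))
        pres = presence.loc[gene_fams]
        row = {
            "name": f"synthetic pathway {i}",
            "disease_flag": disease,
            "is_terminal": bool(rng.random() >= config.non_terminal_fraction),
            "n_human_genes": size,
            "n_human_reactions": n_re,
        }
        for sp in species:
            row[f"{sp}:genes"] = int(pres[sp].sum())
            row[f"{sp}:reactions"] = int(
                sum(presence.loc[r, sp].any() for r in reactions)
            )
        rows.append(pd.Series(row, name=pid))
        membership[pid] = {"genes": list(gene_fams), "reactions": reactions}
    records = pd.DataFrame(rows)
    records.index.name = "pathway_id"
    truth = {"presence": presence, "membership": membership, "families": truth_fams}
    return records, truth


def simulate_gene_sets(
    config: GeneratorConfig,
    profiles: ProfileMatrix,
    family_genes: dict[str, list[str]] | None = None,
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Gene sets biased toward conserved, recent, or random families.

    One third of the sets sample genes from top-quartile Shannon-index
    families ("conserved"), one third from the bottom quartile ("recent"),
    one third uniformly ("neutral").  Returns (sets of gene IDs, truth
    labels per set).
    """
    from .enrichment import rank_families

    rng = np.random.default_rng(config.seed + 3)
    if family_genes is None:
        family_genes, _ = simulate_genes(profiles, config)
    ranked = rank_families(profiles)
    q = len(ranked) // 4
    if q == 0:
        raise ValueError("too few families to form quartiles")
    top = list(ranked.index[:q])
    bottom = list(ranked.index[-q:])
    allf = list(ranked.index)
    lo, hi = config.gene_set_size_range
    if lo < 1:
        raise ValueError("gene set sizes must be >= 1")
    sets: dict[str, list[str]] = {}
    labels: dict[str, str] = {}
    kinds = ["conserved", "recent", "neutral"]
    for i in range(config.n_gene_sets):
        kind = kinds[i % 3]
        pool = {"conserved": top, "recent": bottom, "neutral": allf}[kind]
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(pool))
        fams = [pool[j] for j in rng.choice(len(pool), size=size, replace=False)]
        genes = [rng.choice(family_genes[f]) for f in fams]
        name = f"{kind.upper()}_SET_{i:03d}"
        sets[name] = [str(g) for g in genes]
        labels[name] = kind
    return sets, labels


def simulate_pureloss_counts(
    model: PureLossModel, n_pathways: int, seed: int
) -> pd.DataFrame:
    """Exact draws from the pure-loss model: Poisson root, binomial thinning."""
    rng = np.random.default_rng(seed)
    tree = model.tree
    counts = np.zeros((n_pathways, tree.n_nodes), dtype=np.int64)
    counts[:, 0] = rng.poisson(model.lam, size=n_pathways)
    for v in range(1, tree.n_nodes):
        counts[:, v] = rng.binomial(counts[:, tree.parent[v]], model.survival[v])
    leaf_cols = [tree.labels.index(l) for l in tree.leaf_labels]
    return pd.DataFrame(
        counts[:, leaf_cols], columns=tree.leaf_labels,
        index=pd.Index([f"PW{i:04d}" for i in range(n_pathways)], name="pathway_id"),
    )
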