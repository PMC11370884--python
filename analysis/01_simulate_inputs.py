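#!/usr/bin/env python
"""Generate the synthetic study inputs every later stage consumes.

Writes, under results/inputs/:
  profiles.tsv      family-by-species copy counts with class labels (12 species)
  gene2family.tsv   human gene -> family map
  morbid.txt        disease-linked human gene list
  genesets.gmt      biased + neutral gene sets with truth labels in genesets_truth.tsv
  pathways.tsv      per-pathway conserved gene/reaction counts (8 species)
  suite1.nwk / suite2.nwk   the two species trees
  profiles_truth.tsv        true gain node and loss branches per family
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

import toxdescent as td

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    cfg1 = td.suite1_like(seed=SEED)
    profiles, truth = td.simulate_profiles(cfg1)
    td.write_profile_matrix(profiles, OUT / "profiles.tsv")
    truth.to_csv(OUT / "profiles_truth.tsv", sep="\t")

    family_genes, morbid = td.simulate_genes(profiles, cfg1)
    pd.DataFrame(
        [(g, f) for f, gs in family_genes.items() for g in gs],
        columns=["gene", "family_id"],
    ).to_csv(OUT / "gene2family.tsv", sep="\t", index=False)
    (OUT / "morbid.txt").write_text("\n".join(sorted(morbid)) + "\n")

    sets, labels = td.simulate_gene_sets(cfg1, profiles, family_genes)
    td.write_gmt(sets, OUT / "genesets.gmt")
    pd.Series(labels, name="bias").rename_axis("set").to_csv(
        OUT / "genesets_truth.tsv", sep="\t"
    )

    cfg2 = td.suite2_like(seed=SEED)
    records, _ = td.simulate_pathways(cfg2)
    td.write_pathways(records, OUT / "pathways.tsv")

    (OUT / "suite1.nwk").write_text(cfg1.tree.to_newick() + "\n")
    (OUT / "suite2.nwk").write_text(cfg2.tree.to_newick() + "\n")

    print(f"wrote {len(profiles)} family profiles, {len(records)} pathways,")
    print(f"{len(sets)} gene sets and {len(morbid)} morbid genes to {OUT}")


if __name__ == "__main__":
    main()
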