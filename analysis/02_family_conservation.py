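#!/usr/bin/env python
"""Family-level conservation: class summary, Dollo events, branch z-scores.

Reads results/inputs/, writes:
  family_conservation_summary.tsv   per-class conservation category counts
  dollo_events_disease.tsv / dollo_events_non_disease.tsv
  branch_null_z.tsv                 disease vs subsampled non-disease statistics
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import toxdescent as td

SEED = 42
BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    tree = td.SpeciesTree.from_newick((BASE / "inputs" / "suite1.nwk").read_text())
    profiles = td.read_profile_matrix(BASE / "inputs" / "profiles.tsv")

    summary = td.conservation_summary(profiles, tree, "Vertebrata", "Ecdysozoa")
    summary.to_csv(BASE / "family_conservation_summary.tsv", sep="\t")

    binary = td.binarize(profiles)
    for cls in ("disease", "non_disease"):
        tab = td.branch_event_table(binary, tree, cls)
        tab.to_csv(BASE / f"dollo_events_{cls}.tsv", sep="\t")

    nullz = td.subsampling_null_table(
        profiles, tree, target_class="disease", null_class="non_disease",
        n_reps=1000, seed=SEED,
    )
    nullz.to_csv(BASE / "branch_null_z.tsv", sep="\t")

    dis = td.branch_event_table(binary, tree, "disease")
    n_dis = int((profiles.classes == "disease").sum())
    n_non = int((profiles.classes == "non_disease").sum())
    root = tree.labels[0]
    pct_root_dis = td.percentage(int(dis.loc[root, "gains"]), n_dis, 0)
    mean_root_non = nullz.loc[f"gains:{root}", "mean"]
    print(f"{n_dis} disease vs {n_non} non-disease families")
    print(f"disease families gaining at the root: {pct_root_dis:.0f}%")
    print(f"subsampled non-disease root gains:    {100 * mean_root_non / n_dis:.0f}%")
    zr = nullz.loc[f"gains:{root}", "z"]
    print(f"root-gain z-score (disease vs null):  {zr:.2f}")


if __name__ == "__main__":
    main()
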