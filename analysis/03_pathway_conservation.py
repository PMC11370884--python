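#!/usr/bin/env python
"""Pathway gene vs reaction conservation and the invertebrate-conservation GLM.

Reads results/inputs/pathways.tsv, writes:
  pathway_conservation.tsv   per-pathway vertebrate/invertebrate average percents
  glm_coefficients.tsv       fitted binomial-logit model
  glm_surface.tsv            predicted invertebrate conservation lattice
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

import toxdescent as td

BASE = Path(__file__).resolve().parents[1] / "results"
VERT = ["Mus_musculus", "Rattus_norvegicus", "Danio_rerio",
        "Xenopus_tropicalis", "Gallus_gallus"]
INVERT = ["Drosophila_melanogaster", "Caenorhabditis_elegans"]


def main() -> None:
    records = td.read_pathways(BASE / "inputs" / "pathways.tsv")
    kept, log = td.filter_pathways(records)
    print(f"pathway filter: {log}")

    out = pd.DataFrame(index=kept.index)
    for el in ("genes", "reactions"):
        out[f"vert_{el}_pct"] = td.group_average(kept, VERT, el)
        out[f"invert_{el}_pct"] = td.group_average(kept, INVERT, el)
    out["disease_flag"] = kept["disease_flag"]
    out.to_csv(BASE / "pathway_conservation.tsv", sep="\t")
    for el in ("genes", "reactions"):
        v, i = out[f"vert_{el}_pct"].mean(), out[f"invert_{el}_pct"].mean()
        print(f"mean {el:9s} conservation: vertebrates {v:.0f}%, invertebrates {i:.0f}%")
    frac = td.conserved_fraction_summary(kept, VERT, INVERT, "genes")
    print(
        f"{frac['n_vert_conserved']} pathways >75% conserved in vertebrates; "
        f"{frac['n_also_invert']} ({frac['pct_also_invert']:.0f}%) also in invertebrates"
    )

    model = td.fit_conservation_glm(kept, VERT, INVERT, family="binomial")
    coef = pd.DataFrame(
        {"coef": model.params, "se": model.bse, "p": model.pvalues}
    )
    coef.to_csv(BASE / "glm_coefficients.tsv", sep="\t")
    print(coef.round(4))

    grid_v = np.linspace(*model.vert_range, 21)
    grid_n = np.unique(np.geomspace(max(model.ngenes_range[0], 3),
                                    model.ngenes_range[1], 15).round())
    surf = td.predict_surface(model, grid_v, grid_n)
    surf.to_csv(BASE / "glm_surface.tsv", sep="\t")


if __name__ == "__main__":
    main()
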