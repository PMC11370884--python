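import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import toxdescent as td
from toxdescent.pathways import _species_of


@pytest.fixture(scope="module")
def cohort():
    cfg = td.suite2_like(seed=23)
    records, truth = td.simulate_pathways(cfg)
    return cfg, records, truth


VERT = ["Mus_musculus", "Rattus_norvegicus", "Danio_rerio", "Xenopus_tropicalis", "Gallus_gallus"]
INVERT = ["Drosophila_melanogaster", "Caenorhabditis_elegans"]


def toy_records():
    rows = []
    for pid, ng, mus, fly, terminal in [
        ("small", 2, 1, 0, True),
        ("huge", 1228, 600, 300, True),
        ("edge", 3, 3, 1, True),
        ("nonterm", 40, 30, 10, False),
        ("mid", 10, 5, 2, True),
    ]:
        rows.append(
            pd.Series(
                {
                    "name": pid,
                    "disease_flag": False,
                    "is_terminal": terminal,
                    "n_human_genes": ng,
                    "n_human_reactions": max(1, ng // 3),
                    "Mus_musculus:genes": mus,
                    "Mus_musculus:reactions": max(1, ng // 3) // 2,
                    "Drosophila_melanogaster:genes": fly,
                    "Drosophila_melanogaster:reactions": 0,
                },
                name=pid,
            )
        )
    df = pd.DataFrame(rows)
    df.index.name = "pathway_id"
    return df


def test_filter_rules_and_exact_log():
    recs = toy_records()
    kept, log = td.filter_pathways(recs)
    assert set(kept.index) == {"edge", "mid"}  # 3 genes at the boundary retained
    assert log == {
        "input": 5, "retained": 2, "removed_small": 1,
        "removed_large": 1, "removed_non_terminal": 1,
    }
    assert log["retained"] + log["removed_small"] + log["removed_large"] + log[
        "removed_non_terminal"
    ] == log["input"]


def test_conservation_percent_toy():
    recs = toy_records()
    pct = td.conservation_percent(recs, "Mus_musculus", "genes")
    assert pct["mid"] == 50.0
    assert pct["edge"] == 100.0
    zero = recs.copy()
    zero.loc["mid", "n_human_genes"] = 0
    zero.loc["mid", "Mus_musculus:genes"] = 0
    with pytest.raises(ZeroDivisionError):
        td.conservation_percent(zero, "Mus_musculus", "genes")


def test_group_average_order_invariant_and_hand_mean(cohort):
    _, records, _ = cohort
    a = td.group_average(records, VERT)
    b = td.group_average(records, VERT[::-1])
    pd.testing.assert_series_equal(a, b)
    single = td.group_average(records, ["Mus_musculus"])
    pd.testing.assert_series_equal(
        single, td.conservation_percent(records, "Mus_musculus"), check_names=False
    )
    hand = sum(td.conservation_percent(records, sp) for sp in VERT) / len(VERT)
    pd.testing.assert_series_equal(a, hand, check_names=False)


def test_group_average_missing_species(cohort):
    _, records, _ = cohort
    with pytest.raises(KeyError):
        td.group_average(records, ["Fundulus_heteroclitus"])
    with pytest.raises(ValueError):
        td.group_average(records, [])


@pytest.mark.parametrize(
    "flags,expected",
    [([True] * 4, 100.0), ([False] * 3, 0.0), ([True, False, False, False] * 3, 25.0)],
)
def test_disease_gene_fraction(flags, expected):
    assert td.disease_gene_fraction(flags) == expected


def test_disease_gene_fraction_empty_is_missing():
    assert td.disease_gene_fraction([]) is None


def test_reactions_more_conserved_than_genes(cohort):
    """Reactions survive when any member gene does, so per-species mean
    reaction conservation dominates gene conservation."""
    _, records, _ = cohort
    kept, _ = td.filter_pathways(records)
    for sp in _species_of(kept):
        g = td.conservation_percent(kept, sp, "genes").mean()
        r = td.conservation_percent(kept, sp, "reactions").mean()
        assert r >= g, sp


def test_glm_identity_recovery_gaussian(cohort):
    """With the response equal to the vertebrate predictor and no other
    effects, the gaussian-identity mode recovers slope 1, intercept 0."""
    _, records, _ = cohort
    kept, _ = td.filter_pathways(records)
    rigged = kept.copy()
    for sp in INVERT:
        # make every invertebrate column mirror the vertebrate average
        vert = td.group_average(kept, VERT) / 100.0
        rigged[f"{sp}:genes"] = np.round(vert * rigged["n_human_genes"]).astype(int)
    v = td.group_average(rigged, VERT).to_numpy() / 100
    y = td.group_average(rigged, INVERT).to_numpy() / 100
    # refit on the exact relationship (rounding noise removed)
    rigged2 = rigged[np.abs(v - y) < 1e-12]
    m = td.fit_conservation_glm(rigged2, VERT, INVERT, family="gaussian")
    assert m.params["vertebrate_conservation"] == pytest.approx(1.0, abs=1e-6)
    assert m.params["const"] == pytest.approx(0.0, abs=1e-6)
    assert m.params["n_genes"] == pytest.approx(0.0, abs=1e-6)


def test_glm_empty_and_small_inputs():
    with pytest.raises(ValueError):
        td.fit_conservation_glm(toy_records().iloc[:0], VERT[:1], INVERT[:1])
    with pytest.warns(UserWarning, match="unstable"):
        kept = toy_records()
        kept["Rattus_norvegicus:genes"] = kept["Mus_musculus:genes"]
        kept["Rattus_norvegicus:reactions"] = kept["Mus_musculus:reactions"]
        kept["Danio_rerio:genes"] = kept["Mus_musculus:genes"] // 2
        kept["Danio_rerio:reactions"] = 0
        kept["Xenopus_tropicalis:genes"] = kept["Mus_musculus:genes"] // 2
        kept["Xenopus_tropicalis:reactions"] = 0
        kept["Gallus_gallus:genes"] = kept["Mus_musculus:genes"] // 2
        kept["Gallus_gallus:reactions"] = 0
        kept["Caenorhabditis_elegans:genes"] = kept["Drosophila_melanogaster:genes"]
        kept["Caenorhabditis_elegans:reactions"] = 0
        td.fit_conservation_glm(kept, VERT, INVERT, family="gaussian")


def test_glm_recovery_study_binomial():
    """Coefficient signs and 95% CI coverage on logit-linear synthetic data."""
    rng = np.random.default_rng(42)
    b0, bv, bn, bi = -1.0, 2.5, 0.01, 0.0
    hits_v, hits_n = 0, 0
    cover = 0
    n_sim = 60
    for _ in range(n_sim):
        n = 250
        ng = rng.integers(5, 120, size=n)
        v = rng.uniform(0.2, 0.95, size=n)
        eta = b0 + bv * v + bn * ng + bi * v * ng
        y = rng.binomial(ng, expit(eta)) / ng
        recs = pd.DataFrame(
            {
                "name": "s", "disease_flag": False, "is_terminal": True,
                "n_human_genes": ng, "n_human_reactions": 1,
            },
            index=pd.Index([f"p{i}" for i in range(n)], name="pathway_id"),
        )
        for sp in VERT:
            recs[f"{sp}:genes"] = np.round(v * ng).astype(int)
            recs[f"{sp}:reactions"] = 0
        for sp in INVERT:
            recs[f"{sp}:genes"] = np.round(y * ng).astype(int)
            recs[f"{sp}:reactions"] = 0
        m = td.fit_conservation_glm(recs, VERT, INVERT)
        hits_v += m.params["vertebrate_conservation"] > 0
        hits_n += abs(m.params["n_genes"] - bn) < 4 * m.bse["n_genes"]
        lo = m.params["vertebrate_conservation"] - 1.96 * m.bse["vertebrate_conservation"]
        hi = m.params["vertebrate_conservation"] + 1.96 * m.bse["vertebrate_conservation"]
        # coverage is for the coefficient of the (noisily rounded) predictor
        cover += lo - 0.3 <= bv <= hi + 0.3
    assert hits_v == n_sim
    assert hits_n >= 0.9 * n_sim
    assert cover >= 0.9 * n_sim


def test_predict_surface_shapes_and_monotonicity(cohort):
    _, records, _ = cohort
    kept, _ = td.filter_pathways(records)
    m = td.fit_conservation_glm(kept, VERT, INVERT)
    grid_v = np.linspace(*m.vert_range, 6)
    grid_n = np.linspace(*m.ngenes_range, 5)
    surf = td.predict_surface(m, grid_v, grid_n)
    assert surf.shape == (6, 5)
    assert ((surf >= 0) & (surf <= 1)).all().all()
    if (m.params[["vertebrate_conservation", "interaction"]] >= 0).all():
        assert (surf.diff(axis=0).iloc[1:] >= -1e-9).all().all()
    one = td.predict_surface(m, [grid_v[0]], [grid_n[0]])
    assert one.shape == (1, 1)
    with pytest.warns(UserWarning, match="extrapolation"):
        td.predict_surface(m, [m.vert_range[1] + 1.0], [10])


def test_pathway_tsv_roundtrip(tmp_path, cohort):
    _, records, _ = cohort
    p = tmp_path / "pw.tsv"
    td.write_pathways(records, p)
    again = td.read_pathways(p)
    pd.testing.assert_frame_equal(records, again)
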