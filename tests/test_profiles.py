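import numpy as np
import pandas as pd
import pytest

import toxdescent as td
from toxdescent.profiles import ProfileFormatError

from conftest import make_profiles


TOY_TSV = (
    "family_id\tclass\tHomo_sapiens\tMus_musculus\n"
    "f1\tdisease\t1\t0\n"
    "f2\tnon_disease\t2\t3\n"
    "f3\tmixed\t1\t1\n"
)


def test_read_toy_tsv(tmp_path):
    p = tmp_path / "toy.tsv"
    p.write_text(TOY_TSV)
    m = td.read_profile_matrix(p)
    assert len(m) == 3
    assert m.species == ["Homo_sapiens", "Mus_musculus"]
    assert m.counts.loc["f2", "Mus_musculus"] == 3
    assert m.classes["f3"] == "mixed"


def test_roundtrip_write_read(tmp_path, sim):
    _, profiles, _ = sim
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    td.write_profile_matrix(profiles, p1)
    again = td.read_profile_matrix(p1)
    td.write_profile_matrix(again, p2)
    assert p1.read_text().rstrip() == p2.read_text().rstrip()
    pd.testing.assert_frame_equal(profiles.counts, again.counts)


@pytest.mark.parametrize(
    "content,match",
    [
        ("", "empty"),
        ("family_id\tclass\tHomo_sapiens\n", "no rows"),
        (TOY_TSV.replace("2\t3", "-2\t3"), "row 3"),
        (TOY_TSV.replace("2\t3", "2.5\t3"), "row 3"),
        (TOY_TSV.replace("f3", "f1"), "duplicate"),
        ("id\tHomo_sapiens\nf1\t1\n", "family_id"),
    ],
)
def test_malformed_tsv_raises(tmp_path, content, match):
    p = tmp_path / "bad.tsv"
    p.write_text(content)
    with pytest.raises(ProfileFormatError, match=match):
        td.read_profile_matrix(p)


def test_species_aliases_mapped(tmp_path):
    p = tmp_path / "alias.tsv"
    p.write_text("family_id\tclass\tHomo sapiens\tDmel\nf1\tdisease\t1\t2\n")
    m = td.read_profile_matrix(p)
    assert m.species == ["Homo_sapiens", "Drosophila_melanogaster"]


def test_anchor_enforced(suite1):
    with pytest.raises(ProfileFormatError, match="anchor"):
        make_profiles(suite1, {"f1": {"Mus_musculus": 1}})
    # disabled anchor accepts the same matrix
    mat = pd.DataFrame({"Mus_musculus": [1]}, index=["f1"])
    td.ProfileMatrix(mat, anchor=None)


@pytest.mark.parametrize(
    "genes,morbid,expected",
    [
        (["g1", "g2"], {"g1", "g2"}, "disease"),
        (["g1", "g2"], {"g1"}, "mixed"),
        (["g1"], set(), "non_disease"),
    ],
)
def test_classify_families(genes, morbid, expected):
    assert td.classify_families({"fam": genes}, morbid)["fam"] == expected


def test_classify_partitions_and_rejects_empty(sim):
    cfg, profiles, _ = sim
    fg, morbid = td.simulate_genes(profiles, cfg)
    cls = td.classify_families(fg, morbid)
    assert set(cls.values()) <= {"disease", "non_disease", "mixed"}
    assert len(cls) == len(profiles)
    with pytest.raises(ProfileFormatError, match="empty"):
        td.classify_families({"fam": []}, set())


def test_binarize(toy):
    b = td.binarize(toy)
    assert set(np.unique(b.counts.to_numpy())) <= {0, 1}
    assert (b.counts.to_numpy() == (toy.counts.to_numpy() > 0)).all()
    again = td.binarize(b)
    pd.testing.assert_frame_equal(again.counts, b.counts)
    assert (b.classes == toy.classes).all()


@pytest.mark.parametrize(
    "num,den,dec,expected",
    [
        (414, 1597, 0, 26),
        (1133, 1597, 1, 70.9),
        (0, 5, 0, 0),
        (25, 1000, 0, 3),     # half-up, not banker's
        (125, 1000, 1, 12.5),
    ],
)
def test_percentage_half_up(num, den, dec, expected):
    assert td.percentage(num, den, dec) == expected


def test_percentage_zero_denominator():
    with pytest.raises(ZeroDivisionError):
        td.percentage(1, 0)


def test_summary_single_family_everywhere(suite1):
    m = make_profiles(suite1, {"f1": {l: 1 for l in suite1.leaf_labels}})
    s = td.conservation_summary(m, suite1)
    assert s.loc["total", "total"] == 1
    for cat in ("single_copy", "in_all_species", "in_all_species_single_copy",
                "in_vert_and_invert", "in_vertebrate", "in_all_vertebrates"):
        assert s.loc[cat, "total"] == 1
    assert s.loc["only_in_vertebrate", "total"] == 0
    assert s.loc["only_in_all_vertebrates", "total"] == 0


def test_summary_vertebrate_only_family(suite1):
    m = make_profiles(suite1, {"f1": {"Homo_sapiens": 1, "Mus_musculus": 1}})
    s = td.conservation_summary(m, suite1)
    assert s.loc["in_vertebrate", "total"] == 1
    assert s.loc["only_in_vertebrate", "total"] == 1
    assert s.loc["in_vert_and_invert", "total"] == 0
    assert s.loc["in_all_vertebrates", "total"] == 0


def test_summary_matches_bruteforce_recount(sim, suite1):
    """Category counts equal an independent per-family set evaluation."""
    _, profiles, _ = sim
    sub = profiles.subset(profiles.family_ids[:50])
    s = td.conservation_summary(sub, suite1)
    vert = set(suite1.leaves_under("Vertebrata"))
    inv = set(suite1.leaves_under("Ecdysozoa"))
    expect = {cat: 0 for cat in s.index}
    for fam in sub.family_ids:
        row = sub.counts.loc[fam]
        present = {sp for sp in sub.species if row[sp] > 0}
        expect["total"] += 1
        expect["single_copy"] += all(row[sp] <= 1 for sp in sub.species)
        expect["in_all_species"] += present == set(sub.species)
        expect["in_all_species_single_copy"] += (
            present == set(sub.species) and all(row[sp] <= 1 for sp in sub.species)
        )
        expect["in_vert_and_invert"] += bool(present & vert) and bool(present & inv)
        expect["in_vertebrate"] += bool(present & vert)
        expect["in_all_vertebrates"] += vert <= present
        expect["only_in_vertebrate"] += bool(present & vert) and not (present - vert)
        expect["only_in_all_vertebrates"] += vert <= present and not (present - vert)
    for cat, n in expect.items():
        assert s.loc[cat, "total"] == n, cat


def test_summary_invariants(sim, suite1):
    _, profiles, _ = sim
    s = td.conservation_summary(profiles, suite1)
    assert (
        s.loc["total", ["disease", "non_disease", "mixed"]].sum()
        == s.loc["total", "total"]
        == len(profiles)
    )
    assert s.loc["in_all_species", "total"] <= s.loc["in_all_vertebrates", "total"]
    assert s.loc["in_all_vertebrates", "total"] <= s.loc["in_vertebrate", "total"]


def test_summary_unknown_clade(toy, suite1):
    with pytest.raises(td.TreeError):
        td.conservation_summary(toy, suite1, vert_clade="NotAClade")


def test_fullscale_presence_column_sums_roundtrip(tmp_path, suite1):
    """A full-scale generated matrix with prescribed per-species family
    counts survives TSV round-trip with exact presence column sums."""
    per_species = {
        "Homo_sapiens": 10441, "Mus_musculus": 10282, "Xenopus_tropicalis": 9018,
        "Fundulus_heteroclitus": 8694, "Danio_rerio": 8839,
        "Drosophila_melanogaster": 4683, "Anopheles_gambiae": 4589,
        "Nasonia_vitripennis": 5204, "Daphnia_magna": 5248,
        "Daphnia_pulex": 5560, "Hyalella_azteca": 5611,
        "Caenorhabditis_elegans": 4052,
    }
    n = per_species["Homo_sapiens"]
    rng = np.random.default_rng(1)
    cols = {}
    for sp, k in per_species.items():
        v = np.zeros(n, dtype=np.int64)
        v[:k] = 1
        if sp != "Homo_sapiens":
            rng.shuffle(v)
        cols[sp] = v
    mat = pd.DataFrame(cols, index=pd.Index([f"og{i}" for i in range(n)], name="family_id"))
    m = td.ProfileMatrix(mat[suite1.leaf_labels])
    p = tmp_path / "full.tsv"
    td.write_profile_matrix(m, p)
    again = td.read_profile_matrix(p)
    sums = (again.counts > 0).sum()
    for sp, k in per_species.items():
        assert sums[sp] == k
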