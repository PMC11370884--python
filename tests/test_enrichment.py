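import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

import toxdescent as td

from oracles import es_bruteforce


def test_shannon_examples():
    assert td.shannon_index([1] * 12) == pytest.approx(np.log(12))
    assert td.shannon_index([0, 7, 0]) == 0.0
    assert td.shannon_index([2, 1, 1]) == pytest.approx(
        -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))
    )


def test_shannon_all_zero_rejected():
    with pytest.raises(ValueError):
        td.shannon_index([0, 0, 0])


@given(st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=12))
@settings(max_examples=200, deadline=None)
def test_shannon_bounds_and_zero_invariance(counts):
    if sum(counts) == 0:
        return
    h = td.shannon_index(counts)
    assert 0.0 <= h <= np.log(len(counts)) + 1e-12
    # dropping all-zero species never changes H'
    assert td.shannon_index([c for c in counts if c > 0]) == pytest.approx(h)
    if h == pytest.approx(np.log(len(counts))):
        nz = [c for c in counts if c > 0]
        assert len(set(nz)) == 1 and len(nz) == len(counts)


def test_rank_families_orders_and_breaks_ties_by_id(suite1):
    from conftest import make_profiles

    m = make_profiles(
        suite1,
        {
            "zed": {l: 1 for l in suite1.leaf_labels},       # H' = ln 12
            "abc": {l: 1 for l in suite1.leaf_labels},       # tie with zed
            "solo": {"Homo_sapiens": 5},                     # H' = 0
        },
    )
    r = td.rank_families(m)
    assert list(r.index) == ["abc", "zed", "solo"]
    assert (r.to_numpy()[:-1] >= r.to_numpy()[1:]).all()


def test_shannon_tracks_species_breadth(sim):
    """H' correlates strongly with the number of species carrying the family."""
    _, profiles, _ = sim
    r = td.rank_families(profiles)
    breadth = (profiles.counts > 0).sum(axis=1).reindex(r.index)
    rho = spearmanr(r.to_numpy(), breadth.to_numpy()).statistic
    assert rho > 0.9


def test_to_ortholog_sets_dedup_sizes_and_warnings():
    g2f = {"g1": "F1", "g2": "F1", "g3": "F2", "g4": "F3", "g5": "F4"}
    sets = {
        "tiny": ["g1", "g2"],              # one unique family -> below min size
        "ok": ["g1", "g3", "g4", "g5"],    # 4 unique families
        "unmapped": ["x1", "x2"],
    }
    with pytest.warns(UserWarning, match="no mappable"):
        out = td.to_ortholog_sets(sets, g2f, min_size=3, max_size=500)
    assert set(out) == {"ok"}
    assert out["ok"] == ["F1", "F2", "F3", "F4"]
    big = {"big": [f"g{i}" for i in range(600)]}
    out = td.to_ortholog_sets(big, {f"g{i}": f"F{i}" for i in range(600)})
    assert out == {}  # above max size
    with pytest.raises(ValueError):
        td.to_ortholog_sets({}, g2f)


def test_gmt_roundtrip(tmp_path):
    sets = {"S1": ["a", "b", "c"], "S2": ["d", "e"]}
    p = tmp_path / "sets.gmt"
    td.write_gmt(sets, p, descriptions={"S1": "first"})
    again = td.read_gmt(p)
    assert {k: sorted(v) for k, v in again.items()} == {
        k: sorted(v) for k, v in sets.items()
    }


def test_es_whole_universe_and_top_hit():
    ranked = pd.Series([5.0, 4, 3, 2, 1, 0.5], index=list("abcdef"))
    assert td.preranked_es(ranked, list("abcdef")) == pytest.approx(1.0)
    assert td.preranked_es(ranked, ["a"]) == pytest.approx(1.0)


def test_es_hand_computed_six_element_example():
    scores = np.array([5.0, 4, 3, 2, 1, 0.5])
    ranked = pd.Series(scores, index=list("abcdef"))
    es = td.preranked_es(ranked, ["a", "b"], weight_p=1.0)
    # hits at positions 0,1 with weights 5,4: running peak after second hit = 1
    assert es == pytest.approx(es_bruteforce(scores, np.array([1, 1, 0, 0, 0, 0], bool)))
    assert es == pytest.approx(1.0)
    es2 = td.preranked_es(ranked, ["e", "f"])
    assert es2 == pytest.approx(es_bruteforce(scores, np.array([0, 0, 0, 0, 1, 1], bool)))
    assert es2 < 0


def test_es_missing_members_listed():
    ranked = pd.Series([2.0, 1.0], index=["a", "b"])
    with pytest.raises(KeyError, match="ghost"):
        td.preranked_es(ranked, ["a", "ghost"])


def test_es_equals_bruteforce_exhaustively_short_lists():
    """Every subset of ranked lists up to length 12 matches the literal
    running-sum recomputation."""
    rng = np.random.default_rng(3)
    for n in (5, 8, 12):
        scores = np.round(np.sort(rng.gamma(2.0, 1.0, size=n))[::-1], 3)
        ranked = pd.Series(scores, index=[f"f{i}" for i in range(n)])
        for r in range(1, n + 1):
            for comb in itertools.combinations(range(n), r):
                mask = np.zeros(n, bool)
                mask[list(comb)] = True
                es = td.preranked_es(ranked, [f"f{i}" for i in comb])
                ref = es_bruteforce(scores, mask)
                if abs(es - ref) > 1e-9:
                    # positive and negative extremes tied to within rounding:
                    # either sign is a valid extremum of the running sum
                    assert abs(abs(es) - abs(ref)) < 1e-9


def test_permutation_stats_deterministic_and_bounded(sim):
    _, profiles, _ = sim
    ranked = td.rank_families(profiles)
    sets = {"top": list(ranked.index[:25]), "rand": list(ranked.index[::40])}
    a = td.permutation_stats(ranked, sets, n_perm=200, seed=5)
    b = td.permutation_stats(ranked, sets, n_perm=200, seed=5)
    pd.testing.assert_frame_equal(a, b)
    assert ((a["es"].abs() <= 1) & (a["p"].between(0, 1)) & (a["fdr_q"].between(0, 1))).all()
    # a set made of the top-ranked families is maximally enriched
    assert a.loc["top", "p"] <= 1 / 201
    assert a.loc["top", "es"] > 0.9


def test_permutation_stats_validates_inputs(sim):
    _, profiles, _ = sim
    ranked = td.rank_families(profiles)
    with pytest.raises(ValueError, match="n_perm"):
        td.permutation_stats(ranked, {"s": list(ranked.index[:5])}, n_perm=10, seed=1)
    with pytest.raises(ValueError, match="seed"):
        td.permutation_stats(ranked, {"s": list(ranked.index[:5])}, n_perm=200)
    with pytest.warns(UserWarning, match="half the universe"):
        td.permutation_stats(
            ranked, {"s": list(ranked.index[: len(ranked) // 2 + 5])},
            n_perm=100, seed=1,
        )


def test_panel_experiment_positive_control_and_edge_cases(sim):
    cfg, profiles, _ = sim
    fg, _ = td.simulate_genes(profiles, cfg)
    g2f = {g: f for f, gs in fg.items() for g in gs}
    ranked = td.rank_families(profiles)
    universe = sorted(g2f)
    # positive control: panel drawn only from families present in all species
    breadth = (profiles.counts > 0).sum(axis=1)
    deep = set(breadth.index[breadth == len(profiles.species)])
    panel = [g for g in universe if g2f[g] in deep]
    res = td.random_panel_experiment(
        panel, universe, g2f, ranked, n_sets=12, set_size=40, n_perm=150, seed=8
    )
    assert res["frac_panel"] > res["frac_universe"]
    assert res["frac_panel"] >= 0.75
    # no sets requested -> empty outputs
    empty = td.random_panel_experiment(
        panel, universe, g2f, ranked, n_sets=0, set_size=10, n_perm=150, seed=8
    )
    assert len(empty["p_panel"]) == 0 and np.isnan(empty["frac_panel"])
    with pytest.raises(ValueError, match="set_size"):
        td.random_panel_experiment(
            panel[:5], universe, g2f, ranked, n_sets=2, set_size=10, n_perm=150, seed=8
        )
    with pytest.raises(ValueError, match="subset"):
        td.random_panel_experiment(
            ["alien"], universe, g2f, ranked, n_sets=2, set_size=1, n_perm=150, seed=8
        )


def test_panel_identical_frames_agree(sim):
    cfg, profiles, _ = sim
    fg, _ = td.simulate_genes(profiles, cfg)
    g2f = {g: f for f, gs in fg.items() for g in gs}
    ranked = td.rank_families(profiles)
    universe = sorted(g2f)
    res = td.random_panel_experiment(
        universe, universe, g2f, ranked, n_sets=20, set_size=60, n_perm=150, seed=2
    )
    assert abs(res["frac_panel"] - res["frac_universe"]) <= 0.35  # binomial noise, n=20


def test_tie_shuffle_permutes_only_within_tied_blocks(sim):
    _, profiles, _ = sim
    base = td.rank_families(profiles)
    shuf = td.rank_families(profiles, tie_shuffle_seed=9)
    # identical multiset of (family, score) pairs and identical score order
    np.testing.assert_array_equal(base.to_numpy(), shuf.to_numpy())
    assert sorted(base.index) == sorted(shuf.index)
    assert base.sort_index().equals(shuf.sort_index())
    # some tied block actually moved (ln 12 families are massively tied)
    assert list(base.index) != list(shuf.index)
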