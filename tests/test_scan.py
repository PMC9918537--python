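import numpy as np
import pandas as pd
import pytest

from migtime import scan as sc
from migtime.simulate import GenotypeMatrix


def make_G(g):
    return GenotypeMatrix([f"s{i}" for i in range(g.shape[0])], np.asarray(g, float))


def var_table(n, scaffold="scaf_1", spacing=100):
    return pd.DataFrame({"scaffold": scaffold, "pos": np.arange(1, n + 1) * spacing})


def test_make_windows_tiles_scaffolds():
    w = sc.make_windows({"a": 250, "b": 100}, size=100)
    assert w[w["scaffold"] == "a"][["start", "end"]].to_numpy().tolist() == [
        [0, 100], [100, 200], [200, 250],
    ]
    assert w[w["scaffold"] == "b"][["start", "end"]].to_numpy().tolist() == [[0, 100]]


def test_select_extremes_disjoint_and_ordered():
    ph = pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(10)],
         "arrival_date_ordinal": np.arange(10, dtype=float)}
    )
    grp = sc.select_extremes(ph, 3)
    assert grp.early == ("s0", "s1", "s2")
    assert grp.late == ("s9", "s8", "s7")
    with pytest.raises(ValueError):
        sc.select_extremes(ph, 6)  # groups would overlap


def test_fst_fixed_difference_is_one():
    g1 = np.zeros((8, 20))
    g2 = np.full((8, 20), 2.0)
    G = make_G(np.vstack([g1, g2]))
    var = var_table(20)
    w = sc.make_windows({"scaf_1": 2000}, 2000)
    fst = sc.wc_fst_window(G, G.samples[:8], G.samples[8:], w, var)
    assert fst["value"].iloc[0] == pytest.approx(1.0, abs=1e-12)


def test_window_with_no_usable_sites_is_invalid():
    g = np.zeros((6, 5))  # monomorphic everywhere
    G = make_G(g)
    var = var_table(5)
    w = sc.make_windows({"scaf_1": 1000}, 1000)
    fst = sc.wc_fst_window(G, G.samples[:3], G.samples[3:], w, var)
    assert not bool(fst["valid"].iloc[0])
    td = sc.tajimas_d_window(G, G.samples, w, var)
    assert not bool(td["valid"].iloc[0])  # no segregating sites
    piw = sc.pi_window(G, G.samples, w, var)
    assert piw["value"].iloc[0] == 0.0  # pi is defined (zero diversity)


def test_net_fst_subtracts_and_clips_validity():
    w = pd.DataFrame({"scaffold": ["a", "a"], "start": [0, 10], "end": [10, 20]})
    a = w.assign(value=[0.5, 0.2], valid=[True, True], n_variant_sites=[3, 3])
    b = w.assign(value=[0.1, np.nan], valid=[True, False], n_variant_sites=[3, 0])
    d = sc.net_fst(a, b)
    assert d["value"].iloc[0] == pytest.approx(0.4)
    assert not bool(d["valid"].iloc[1])


def test_detect_region_needs_multiwindow_outlier_runs():
    n = 200
    base = pd.DataFrame(
        {"scaffold": "scaf_1", "start": np.arange(n) * 100,
         "end": (np.arange(n) + 1) * 100}
    )
    rng = np.random.default_rng(0)
    vals = rng.normal(0.0, 0.01, n)
    single = base.assign(value=vals.copy(), valid=True, n_variant_sites=5)
    single.loc[50, "value"] = 1.0  # isolated spike
    assert len(sc.detect_region(single)) == 0

    run = base.assign(value=vals.copy(), valid=True, n_variant_sites=5)
    run.loc[100:103, "value"] = 1.0
    regions = sc.detect_region(run)
    assert len(regions) == 1
    assert regions["start"].iloc[0] == 100 * 100
    assert regions["end"].iloc[0] == 104 * 100


def test_genes_in_region_overlap():
    regions = pd.DataFrame(
        {"scaffold": ["scaf_1"], "start": [1000], "end": [2000]}
    )
    genes = pd.DataFrame(
        {"scaffold": ["scaf_1", "scaf_1", "scaf_2"],
         "start": [900, 2100, 1500], "end": [1100, 2200, 1600],
         "name": ["in", "out", "wrong_scaffold"], "score": 0, "strand": "+"}
    )
    hits = sc.genes_in_region(regions, genes)
    assert len(hits) == 1
    assert hits[0]["name"].tolist() == ["in"]
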