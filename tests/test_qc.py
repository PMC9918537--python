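import numpy as np
import pytest

from migtime.qc import (
    FilterConfig,
    apply_filters,
    hwe_exact_test,
    impute_missing_mean,
)
from migtime.simulate import GenotypeMatrix, simulate_cohort, SimulationConfig
import pandas as pd


def test_hwe_basic_properties():
    # allele-label symmetry and range
    assert hwe_exact_test(3, 4, 13) == hwe_exact_test(13, 4, 3)
    assert 0 < hwe_exact_test(5, 10, 5) <= 1.0
    assert 0 < hwe_exact_test(0, 25, 0) < 1e-6
    assert hwe_exact_test(10, 0, 0) == 1.0
    # monomorphic-in-alleles table is the only outcome given its allele counts
    assert hwe_exact_test(0, 0, 7) == 1.0
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


def test_impute_preserves_column_means():
    d = np.array([[0, 1, np.nan], [2, np.nan, 1], [np.nan, 1, 1], [2, 0, 0]], float)
    G = GenotypeMatrix(["a", "b", "c", "d"], d)
    Gi = impute_missing_mean(G)
    assert not np.isnan(Gi.dosages).any()
    np.testing.assert_allclose(
        Gi.dosages.mean(axis=0), np.nanmean(d, axis=0), atol=1e-12
    )
    with pytest.raises(ValueError, match="all calls missing"):
        impute_missing_mean(
            GenotypeMatrix(["a", "b"], np.array([[np.nan, 1], [np.nan, 0]]))
        )


def test_disabled_filters_pass_everything():
    cfg = SimulationConfig(
        n_pops=2, samples_per_pop=(10, 10), n_loci=100, n_causal=5,
        missing_rate=0.1, seed=3,
    )
    G, var, _, _ = simulate_cohort(cfg)
    off = FilterConfig(
        qual_min=None, mq_min=None, max_missing_fraction=None,
        maf_min=None, hwe_alpha=None, biallelic_only=False,
    )
    _, vf, report = apply_filters(G, var, off)
    assert report == {"n_input": 100, "n_pass": 100}
    assert len(vf) == 100


def test_filter_order_changes_attribution_not_survivors():
    cfg = SimulationConfig(
        n_pops=2, samples_per_pop=(20, 20), n_loci=300, n_causal=5,
        missing_rate=0.25, qual_range=(10.0, 60.0), seed=9,
    )
    G, var, _, _ = simulate_cohort(cfg)
    var = var.assign(biallelic=True)
    _, v1, r1 = apply_filters(G, var)
    order = ("hwe", "maf", "missingness", "mq", "qual", "biallelic")
    _, v2, r2 = apply_filters(G, var, order=order)
    assert v1["pos"].tolist() == v2["pos"].tolist()
    assert r1["n_pass"] == r2["n_pass"]
    with pytest.raises(ValueError, match="permutation"):
        apply_filters(G, var, order=("qual",))
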