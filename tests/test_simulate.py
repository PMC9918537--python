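import numpy as np
import pandas as pd
import pytest

from migtime.qc import read_vcf
from migtime.simulate import (
    SimulationConfig,
    balding_nichols_freqs,
    simulate_cohort,
    write_cohort,
)


def small_cfg(**kw):
    base = dict(
        n_pops=2, samples_per_pop=(15, 15), n_loci=400, n_causal=10,
        missing_rate=0.1, seed=5,
    )
    base.update(kw)
    return SimulationConfig(**base)


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError, match="samples_per_pop"):
        SimulationConfig(n_pops=3, samples_per_pop=(10, 10)).validate()
    with pytest.raises(ValueError, match="background_fst"):
        SimulationConfig(background_fst=1.5).validate()
    with pytest.raises(ValueError, match="sweep_region"):
        SimulationConfig(sweep_region=("scaf_1", 5, 2)).validate()
    with pytest.raises(ValueError, match="sweep scaffold"):
        SimulationConfig(sweep_region=("nope", 0, 10)).validate()
    with pytest.raises(ValueError, match="n_causal"):
        SimulationConfig(n_loci=10, n_causal=20).validate()


def test_reproducible_from_seed():
    a = simulate_cohort(small_cfg())
    b = simulate_cohort(small_cfg())
    np.testing.assert_array_equal(a[0].dosages, b[0].dosages)
    pd.testing.assert_frame_equal(a[2], b[2])
    c = simulate_cohort(small_cfg(seed=6))
    assert not np.array_equal(
        np.nan_to_num(a[0].dosages), np.nan_to_num(c[0].dosages)
    )


def test_realized_pve_is_exact():
    G, var, pheno, effects = simulate_cohort(small_cfg(target_pve=0.6))
    assert effects.attrs["realized_pve"] == pytest.approx(0.6, abs=1e-12)


def test_missing_rate_and_shapes():
    cfg = small_cfg(missing_rate=0.2)
    G, var, pheno, _ = simulate_cohort(cfg)
    assert G.dosages.shape == (30, len(var))
    assert np.isnan(G.dosages).mean() == pytest.approx(0.2, abs=0.02)
    assert list(pheno["sample_id"]) == G.samples
    # pre-masking dosages are complete and agree where observed
    full = G.full_dosages
    obs = ~np.isnan(G.dosages)
    assert not np.isnan(full).any()
    np.testing.assert_array_equal(full[obs], G.dosages[obs])


def test_balding_nichols_moments():
    rng = np.random.default_rng(1)
    draws = np.array(
        [balding_nichols_freqs(0.3, 0.1, 1, rng)[0] for _ in range(20000)]
    )
    assert draws.mean() == pytest.approx(0.3, abs=0.01)
    assert draws.var() == pytest.approx(0.1 * 0.3 * 0.7, abs=0.002)
    np.testing.assert_array_equal(
        balding_nichols_freqs(0.3, 0.0, 4, rng), np.full(4, 0.3)
    )


def test_write_cohort_roundtrip(tmp_path):
    cfg = small_cfg()
    G, var, pheno, _ = simulate_cohort(cfg)
    paths = write_cohort(G, var, pheno, cfg, tmp_path / "cohort")
    G2, var2 = read_vcf(paths["vcf"])
    assert G2.samples == G.samples
    np.testing.assert_array_equal(
        np.nan_to_num(G2.dosages, nan=-1), np.nan_to_num(G.dosages, nan=-1)
    )
    assert var2["pos"].tolist() == var["pos"].tolist()
    ph2 = pd.read_csv(paths["phenotypes"], sep="\t")
    assert list(ph2["sample_id"]) == G.samples
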