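"""Coalescent simulator: contracts, oracles and msprime cross-validation."""

import numpy as np
import pytest
from scipy import stats as sps

from ghostflow import (MISSING, SampleConfig, ScenarioParams,
                       build_reference_table, default_priors, simulate_snps)
from ghostflow.simulate import simulate_branch_stats
from ghostflow.sumstats import STAT_NAMES, sumstats_from_dosages


def _panmictic(n=10000):
    # CI with the split at time ~0 collapses to one ancestral population
    return ScenarioParams(scenario="CI", N_A=n, N_B=n, N_anc=0.5,
                          T_div=1e-6)


def test_simulate_snps_contract(ghgea_median_params):
    sc = SampleConfig(n_snps=150)
    gm = simulate_snps(ghgea_median_params, sc, seed=4)
    assert gm.n_sites == 150
    assert gm.n_individuals == 30
    assert list(gm.individuals["group"]).count("TaiA") == 20
    # ghost never sampled
    assert set(gm.individuals["group"]) == {"TaiA", "TaiB"}
    alt = gm.genotypes.sum(axis=0)
    maf = np.minimum(alt, 60 - alt) / 60
    assert maf.min() >= 0.05
    for chrom, sub in gm.sites.groupby("chrom"):
        assert (np.diff(sub["pos"]) > 0).all()


def test_simulate_snps_deterministic_under_seed(ghgea_median_params):
    sc = SampleConfig(n_snps=60)
    a = simulate_snps(ghgea_median_params, sc, seed=11)
    b = simulate_snps(ghgea_median_params, sc, seed=11)
    np.testing.assert_array_equal(a.genotypes, b.genotypes)
    c = simulate_snps(ghgea_median_params, sc, seed=12)
    assert not np.array_equal(a.genotypes, c.genotypes)


def test_missing_rate_masks_genotypes(ghgea_median_params):
    sc = SampleConfig(n_snps=150, missing_rate=0.2)
    gm = simulate_snps(ghgea_median_params, sc, seed=4)
    frac = (gm.genotypes == MISSING).mean()
    assert 0.15 < frac < 0.25


def test_watterson_segregating_sites_oracle():
    """Mean segregating sites matches Watterson's theta * a_{n-1}."""
    n_loci = 2000
    N, mu = 10000, 1e-5
    total_len, _ = simulate_branch_stats(_panmictic(N),
                                         SampleConfig(n_snps=1),
                                         n_loci, seed=5)
    S = np.random.default_rng(0).poisson(total_len * mu)
    nh = 60
    a1 = (1.0 / np.arange(1, nh)).sum()
    expected = 4 * N * mu * a1
    se = S.std(ddof=1) / np.sqrt(n_loci)
    assert abs(S.mean() - expected) < 3 * se


def test_no_divergence_limit_gives_zero_fst():
    """T_div -> 0 means panmixia: multilocus W-C F_ST ~ 0."""
    p = ScenarioParams(scenario="CI", N_A=10000, N_B=10000, N_anc=0.5,
                       T_div=1.0)
    gm = simulate_snps(p, SampleConfig(n_snps=2000), seed=9)
    stats = sumstats_from_dosages(gm.genotypes[:20], gm.genotypes[20:])
    fst = stats[list(STAT_NAMES).index("fst")]
    assert abs(fst) < 0.02


def test_tmrca_increases_with_divergence_time():
    """Mean between-group coalescence grows with T_div (weak monotonicity)."""
    grid = [2e4, 6e4, 1.2e5, 2.5e5, 5e5]
    means = []
    for i, t in enumerate(grid):
        p = ScenarioParams(scenario="CI", N_A=3000, N_B=3000, N_anc=1.0,
                           T_div=t)
        gm = simulate_snps(p, SampleConfig(n_snps=200), seed=100 + i)
        stats = sumstats_from_dosages(gm.genotypes[:20], gm.genotypes[20:])
        means.append(stats[list(STAT_NAMES).index("fst")])
    assert all(b > a - 0.02 for a, b in zip(means, means[1:]))
    assert means[-1] > means[0]


def test_ascertainment_failure_is_reported():
    # deep split between tiny demes: variants are near-fixed differences
    # (minor count 20 of 60), so a 0.49 MAF cutoff is almost never met
    p = ScenarioParams(scenario="CI", N_A=10, N_B=10, N_anc=1e-3, T_div=1e6)
    sc = SampleConfig(n_snps=10, maf_asc=0.49)
    with pytest.raises(RuntimeError, match="ascertainment"):
        simulate_snps(p, sc, seed=3)


@pytest.mark.parametrize("scenario", ["PC", "GhGeA", "GhHyB"])
def test_native_engine_matches_msprime(scenario, ghgea_median_params):
    """KS cross-validation of the two backends on every summary statistic."""
    kw = dict(N_A=2228, N_B=2505, N_aA=10318, N_aB=11436, N_anc=2.62,
              N_ghost=10318, m_A=1.03e-3, m_B=1.12e-3, T_m=4252,
              T_div=301759)
    if scenario != "PC":
        kw.update(T_divG=411780)
    if scenario == "GhGeA":
        kw.update(m_G=4.6e-4, m_AG=2.4e-4, T_G=8249)
    if scenario == "GhHyB":
        kw.update(h_frac=0.4)
    p = ScenarioParams(scenario=scenario, **kw)
    sc = SampleConfig(n_snps=250)
    native = np.array([
        sumstats_from_dosages(g.genotypes[:20], g.genotypes[20:])
        for g in (simulate_snps(p, sc, seed=s) for s in range(20))])
    msp = np.array([
        sumstats_from_dosages(g.genotypes[:20], g.genotypes[20:])
        for g in (simulate_snps(p, sc, seed=500 + s, backend="msprime")
                  for s in range(20))])
    pvals = [sps.ks_2samp(native[:, i], msp[:, i]).pvalue for i in range(22)]
    # Bonferroni-style guard: no statistic may differ strongly
    assert min(pvals) > 0.01 / 22


def test_ghgea_without_ghost_flow_equals_ghpc(ghgea_median_params):
    """GhGeA with m_G = m_AG = 0 is distributionally GhPC."""
    base = dict(N_A=2228, N_B=2505, N_aA=10318, N_aB=11436, N_anc=2.62,
                N_ghost=10318, m_A=1.03e-3, m_B=1.12e-3, T_m=4252,
                T_div=301759, T_divG=411780)
    pa = ScenarioParams(scenario="GhGeA", m_G=0.0, m_AG=0.0, T_G=8249,
                        **base)
    pb = ScenarioParams(scenario="GhPC", **base)
    sc = SampleConfig(n_snps=250)
    A = np.array([sumstats_from_dosages(g.genotypes[:20], g.genotypes[20:])
                  for g in (simulate_snps(pa, sc, seed=s)
                            for s in range(25))])
    B = np.array([sumstats_from_dosages(g.genotypes[:20], g.genotypes[20:])
                  for g in (simulate_snps(pb, sc, seed=300 + s)
                            for s in range(25))])
    pvals = [sps.ks_2samp(A[:, i], B[:, i]).pvalue for i in range(22)]
    assert min(pvals) > 0.01 / 22


class TestReferenceTable:
    def test_shape_and_finiteness(self, small_config):
        rt = build_reference_table(["CI", "PC"], default_priors(), 25,
                                   small_config, seed=3)
        assert len(rt.data) == 50
        assert np.isfinite(rt.stats_matrix()).all()
        hexp = rt.data[["hexp_A", "hexp_B"]].to_numpy()
        assert ((hexp > 0) & (hexp <= 0.5)).all()

    def test_same_seed_identical_table(self, small_config):
        a = build_reference_table(["CI"], default_priors(), 10,
                                  small_config, seed=4)
        b = build_reference_table(["CI"], default_priors(), 10,
                                  small_config, seed=4)
        assert a.data.equals(b.data)

    def test_chunked_equals_single_pass(self, small_config):
        whole = build_reference_table(["CI"], default_priors(), 12,
                                      small_config, seed=6)
        lo = build_reference_table(["CI"], default_priors(), 12,
                                   small_config, seed=6, row_range=(0, 7))
        hi = build_reference_table(["CI"], default_priors(), 12,
                                   small_config, seed=6, row_range=(7, 12))
        import pandas as pd
        merged = pd.concat([lo.data, hi.data], ignore_index=True)
        assert whole.data.equals(merged)

    def test_round_trip_csv(self, small_config, tmp_path):
        rt = build_reference_table(["CI"], default_priors(), 8,
                                   small_config, seed=8)
        path = tmp_path / "ref.csv"
        rt.save(path)
        from ghostflow import ReferenceTable
        back = ReferenceTable.load(path)
        assert back.data.shape == rt.data.shape
        np.testing.assert_allclose(back.stats_matrix(), rt.stats_matrix())
        assert back.meta["scenarios"] == "CI"


class TestDdradDesign:
    def test_yield_scales_with_population_scale(self, ghgea_median_params):
        """The SNP yield of the fixed-mutation-rate design increases when
        all sizes and times are scaled up together — the absolute-scale
        anchor that pure frequency panels lack."""
        import dataclasses

        sc = SampleConfig(n_loci=800)
        yields = []
        for c in (0.5, 1.0, 2.0):
            p = dataclasses.replace(
                ghgea_median_params,
                **{f: getattr(ghgea_median_params, f) * c
                   for f in ("N_A", "N_B", "N_aA", "N_aB", "N_ghost",
                             "T_m", "T_div", "T_divG", "T_G")},
                **{f: getattr(ghgea_median_params, f) / c
                   for f in ("m_A", "m_B", "m_G", "m_AG")})
            n = np.mean([simulate_snps(p, sc, seed=70 + s,
                                       design="ddrad").n_sites
                         for s in range(4)])
            yields.append(n)
        assert yields[0] < yields[1] < yields[2]

    def test_expected_yield_at_fitted_parameters(self, ghgea_median_params):
        sc = SampleConfig()
        counts = [simulate_snps(ghgea_median_params, sc, seed=200 + s,
                                design="ddrad").n_sites for s in range(6)]
        assert 700 < np.mean(counts) < 900

    def test_deterministic_and_ascertained(self, ghgea_median_params):
        sc = SampleConfig(n_loci=400)
        a = simulate_snps(ghgea_median_params, sc, seed=3, design="ddrad")
        b = simulate_snps(ghgea_median_params, sc, seed=3, design="ddrad")
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        alt = a.genotypes.sum(axis=0)
        maf = np.minimum(alt, 60 - alt) / 60
        assert maf.min() >= 0.05
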