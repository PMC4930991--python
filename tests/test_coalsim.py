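"""Coalescent simulator: structure, determinism and calibration."""

import numpy as np
import pytest

from coalabc.coalsim import (
    BottleneckParams,
    IMParams,
    SampleConfig,
    drop_mutations,
    simulate_bottleneck_locus,
    simulate_dataset,
    simulate_im_locus,
    simulate_species_sites,
    study_template,
)
from coalabc.sumstats import summarize_im


def test_param_validation():
    with pytest.raises(ValueError):
        IMParams(N=0, N_asp=1, N_cra=1, T=1, M_cra_to_asp=0, M_asp_to_cra=0)
    with pytest.raises(ValueError):
        BottleneckParams(N=1e4, Nb=1e3, N0=1e4, Tb=10, Te=20)  # Te > Tb
    with pytest.raises(ValueError):
        SampleConfig(locus_lengths=(), n_per_deme=(4,))


def test_forced_tmrca_after_split():
    """With one lineage per deme and no migration, coalescence is older
    than the split time in every replicate."""
    p = IMParams(N=5e3, N_asp=5e3, N_cra=5e3, T=2000.0,
                 M_cra_to_asp=0.0, M_asp_to_cra=0.0)
    for seed in range(1, 30):
        ts = simulate_im_locus(p, 100, (1, 1), seed)
        tree = ts.first()
        assert tree.time(tree.root) >= 2000.0


def test_im_degenerate_split_matches_single_population():
    """T ~ 0 with equal sizes: mean pairwise TMRCA ~ 2N (n=2)."""
    N = 10_000
    p = IMParams(N=N, N_asp=N, N_cra=N, T=0.0, M_cra_to_asp=0.0, M_asp_to_cra=0.0)
    times = []
    for seed in range(1, 1501):
        ts = simulate_im_locus(p, 50, (1, 1), seed)
        tree = ts.first()
        times.append(tree.time(tree.root))
    se = np.std(times) / np.sqrt(len(times))
    assert abs(np.mean(times) - 2 * N) < 3 * se


def test_bottleneck_degenerate_constant_size():
    N = 8_000
    p = BottleneckParams(N=N, Nb=N, N0=N, Tb=100.0, Te=0.0)
    times = []
    for seed in range(1, 1501):
        ts = simulate_bottleneck_locus(p, 50, 2, seed)
        tree = ts.first()
        times.append(tree.time(tree.root))
    se = np.std(times) / np.sqrt(len(times))
    assert abs(np.mean(times) - 2 * N) < 3 * se


def test_zero_mutation_rate_monomorphic(rng):
    p = BottleneckParams(N=1e4, Nb=1e4, N0=1e4, Tb=10.0, Te=0.0)
    ts = simulate_bottleneck_locus(p, 200, 6, 11)
    aln = drop_mutations(ts, 0.0, 200, rng)
    assert np.all(aln.haplotypes == aln.haplotypes[0])


def test_drop_mutations_perfect_outgroup(rng):
    p = BottleneckParams(N=5e4, Nb=5e4, N0=5e4, Tb=10.0, Te=0.0)
    ts = simulate_bottleneck_locus(p, 500, 8, 13)
    aln = drop_mutations(ts, 1e-7, 500, rng)
    assert aln.outgroup is not None
    from coalabc.seq_data import build_site_table

    st = build_site_table(aln)
    assert np.all(st.ancestral >= 0)  # every site polarized


def test_watterson_calibration():
    """E[S] ~ theta * a1 for the constant-size coalescent."""
    N, L, mu, n = 50_000, 1000, 1e-8, 10
    theta = 4 * N * mu * L  # = 2
    p = BottleneckParams(N=N, Nb=N, N0=N, Tb=1.0, Te=0.0, mu=mu)
    cfg = SampleConfig((L,), (n,))
    S = [
        sl[0].sites.n_sites
        for sl in (simulate_species_sites(p, cfg, seed=s) for s in range(2000))
    ]
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    se = np.sqrt((theta * a1 + theta**2 * a2) / len(S))
    assert abs(np.mean(S) - theta * a1) < 3 * se


def test_fst_monotone_in_migration():
    """Mean F_ST decreases from the no-migration to the high-migration
    regime at fixed split time."""
    base = dict(N=2e4, N_asp=2e4, N_cra=2e4, T=2e5)  # T = 5 x 2N: deep split
    cfg = SampleConfig((800,) * 4, (10, 10))
    means = []
    for M in (0.0, 20.0):
        vals = []
        for s in range(40):
            p = IMParams(**base, M_cra_to_asp=M, M_asp_to_cra=M)
            v = summarize_im(simulate_species_sites(p, cfg, seed=500 + s))
            vals.append(v.values[list(v.names).index("Fst")])
        means.append(np.nanmean(vals))
    assert means[0] > 0.6 > 0.3 > means[1]


def test_bottleneck_positive_tajimas_d():
    """A severe recent contraction leaves an excess of intermediate
    frequencies: mean Tajima's D over replicates > 0."""
    p = BottleneckParams(N=2e5, Nb=2e3, N0=2e4, Tb=4000.0, Te=500.0)
    cfg = SampleConfig((800,) * 4, (20,))
    from coalabc.sumstats import summarize_bottleneck

    Ds = []
    for s in range(60):
        v = summarize_bottleneck(simulate_species_sites(p, cfg, 300 + s), scope="pop")
        Ds.append(v.values[1])
    assert np.nanmean(Ds) > 0


def test_simulate_dataset_deterministic():
    params = IMParams(N=1e4, N_asp=1e4, N_cra=1e4, T=1e3,
                      M_cra_to_asp=1.0, M_asp_to_cra=1.0)
    cfg = SampleConfig((400,) * 3, (6, 6))
    a = simulate_dataset(params, cfg, seed=77)
    b = simulate_dataset(params, cfg, seed=77)
    for x, y in zip(a.alignments, b.alignments):
        assert np.array_equal(x.haplotypes, y.haplotypes)
    c = simulate_dataset(params, cfg, seed=78)
    assert any(
        not np.array_equal(x.haplotypes, y.haplotypes)
        for x, y in zip(a.alignments, c.alignments)
    )


def test_simulated_dataset_feeds_summaries():
    params = IMParams(N=5e4, N_asp=5e4, N_cra=5e4, T=5e3,
                      M_cra_to_asp=5.0, M_asp_to_cra=5.0)
    ds = simulate_dataset(params, study_template(True), seed=3)
    v = summarize_im(ds)
    assert v.values.size == 13 and v.valid


def test_fast_path_matches_full_rendering_statistically():
    """Site tables from the fast path and from rendered alignments carry
    the same segregating-site counts for the same seeds."""
    params = IMParams(N=3e4, N_asp=3e4, N_cra=3e4, T=1e3,
                      M_cra_to_asp=2.0, M_asp_to_cra=2.0)
    cfg = SampleConfig((600,) * 5, (8, 8))
    fast = simulate_species_sites(params, cfg, seed=21)
    S_fast = sorted(sl.sites.n_sites for sl in fast)
    from coalabc.seq_data import build_site_table

    ds = simulate_dataset(params, cfg, seed=21)
    S_full = sorted(build_site_table(a).n_sites for a in ds.alignments)
    assert S_fast == S_full
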