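"""Diversity, neutrality tests, Phi_ST and the ABC summary vectors."""

import itertools
import math

import numpy as np
import pytest

from coalabc.seq_data import build_site_table
from coalabc.sumstats import (
    BOTTLENECK_STAT_NAMES,
    IM_STAT_NAMES,
    SpeciesSites,
    between_species_diff,
    diversity,
    ewens_log_pmf,
    fay_wu_h,
    fu_fs,
    fu_li_star,
    haplotype_and_private,
    neutrality_panel,
    phi_st,
    summarize_bottleneck,
    summarize_im,
    tajimas_d,
)

from conftest import random_alignment_dataset


def brute_force_pi(H):
    """Average Hamming distance over all sequence pairs (byte matrix)."""
    n = H.shape[0]
    diffs = [
        int((H[i] != H[j]).sum())
        for i, j in itertools.combinations(range(n), 2)
    ]
    return sum(diffs) / len(diffs)


def test_diversity_two_sequences_three_diffs():
    mat = np.array(
        [list("A" * 100), list("TTT" + "A" * 97)], dtype="S1"
    )
    from coalabc.seq_data import LocusAlignment, LocusSpec

    aln = LocusAlignment(LocusSpec("x", 100), mat, [("a", 1), ("a", 2)])
    d = diversity(aln)
    assert d.S == 3 and d.pi_site == pytest.approx(0.03)
    assert d.theta_w_site == pytest.approx(0.03)  # a1 = 1 for n = 2


def test_diversity_monomorphic(edge_fixtures):
    aln = edge_fixtures["monomorphic"].alignments[0]
    d = diversity(aln)
    assert d.S == 0 and d.pi_abs == 0 and d.theta_w_abs == 0


def test_diversity_requires_two_sequences():
    from coalabc.seq_data import LocusAlignment, LocusSpec

    aln = LocusAlignment(
        LocusSpec("x", 4), np.array([list("ACGT")], dtype="S1"), [("a", 1)]
    )
    with pytest.raises(ValueError):
        diversity(aln)


def test_pi_matches_brute_force_random(rng):
    for _ in range(10):
        ds = random_alignment_dataset(rng, n_seq=8, length=50)
        aln = ds.alignments[0]
        d = diversity(aln)
        assert d.pi_abs == pytest.approx(brute_force_pi(aln.haplotypes), abs=1e-12)


def test_tri_allelic_eta_exceeds_s(edge_fixtures):
    aln = edge_fixtures["tri_allelic"].alignments[0]
    d = diversity(aln)
    assert d.S == 1 and d.eta == 2  # eta = S + 1 at the tri-allelic site


def test_tajimas_d_na_and_zero():
    assert math.isnan(tajimas_d(0, 0.0, 20))
    assert math.isnan(tajimas_d(5, 1.0, 3))  # n < 4
    a1 = sum(1.0 / i for i in range(1, 10))
    assert tajimas_d(5, 5 / a1, 10) == pytest.approx(0.0)


def test_fu_li_na_and_star_sign():
    assert all(math.isnan(v) for v in fu_li_star(0, 0, 0.0, 10))
    # star-like sample: every mutation a singleton -> D* < 0
    n, eta = 10, 8
    pi = eta * 2 * (n - 1) / (n * (n - 1))
    d_star, f_star = fu_li_star(eta, eta, pi, n)
    assert d_star < 0


def test_fay_wu_hand_example():
    # n=4, one site with derived allele at count 3:
    # theta_pi = 0.5, theta_H = 1.5 -> H = -1
    from coalabc.seq_data import LocusAlignment, LocusSpec

    mat = np.array([list("T"), list("T"), list("T"), list("A")], dtype="S1")
    aln = LocusAlignment(
        LocusSpec("x", 1, outgroup_id="og"),
        mat,
        [("a", 1), ("a", 2), ("b", 1), ("b", 2)],
        outgroup=np.array([b"A"]),
    )
    assert fay_wu_h(aln) == pytest.approx(-1.0)


def test_fay_wu_needs_outgroup(edge_fixtures):
    aln = edge_fixtures["fixed_difference"].alignments[0]
    with pytest.raises(ValueError, match="outgroup"):
        fay_wu_h(aln)


def test_fay_wu_na_without_variation(edge_fixtures):
    st = build_site_table(edge_fixtures["tiny"].alignments[0])
    # drop all sites -> no usable site
    st.genotypes = st.genotypes[:, :0]
    st.ancestral = st.ancestral[:0]
    assert math.isnan(fay_wu_h(st))


def test_ewens_distribution_sums_to_one():
    for n in (2, 6, 12, 20):
        for theta in (0.3, 1.0, 5.0):
            total = np.exp(ewens_log_pmf(n, theta)).sum()
            assert total == pytest.approx(1.0, abs=1e-12)


def test_fu_fs_closed_form_n2():
    # n=2, K=2, theta=1: P(K=2) = theta/(1+theta) = 0.5 -> Fs = ln(1) = 0
    assert fu_fs(2, 1.0, 2) == pytest.approx(0.0, abs=1e-12)
    assert math.isnan(fu_fs(1, 0.0, 2))


def test_haplotype_and_private_hand_cases():
    G_mono = np.zeros((4, 0), dtype=np.int8)
    assert haplotype_and_private(G_mono, G_mono) == (1, 1, 0, 0, 0, 0, 0)
    # one site: sp1 polymorphic A/T, sp2 fixed A -> private to sp1
    G1 = np.array([[0], [1], [0], [0]], dtype=np.int8)
    G2 = np.zeros((4, 1), dtype=np.int8)
    K1, K2, S1, S2, P1, P2, St = haplotype_and_private(G1, G2)
    assert (S1, S2, P1, P2, St) == (1, 0, 1, 0, 1)
    # sp2 fixed for an allele absent from sp1 -> not a private site of sp1
    G2b = np.full((4, 1), 2, dtype=np.int8)
    assert haplotype_and_private(G1, G2b)[4] == 0


def test_s_total_bounded_below_by_species_s(rng):
    for _ in range(5):
        ds = random_alignment_dataset(rng)
        sl = SpeciesSites.from_alignment(ds.alignments[0], ds)
        G = sl.sites.genotypes
        _, _, S1, S2, _, _, St = haplotype_and_private(
            G[sl.rows["asp"]], G[sl.rows["cra"]]
        )
        assert St >= max(S1, S2)


def test_between_species_diff_oracle(rng):
    # 1 vs 1 sequence with 5 differences
    G1 = np.zeros((1, 5), dtype=np.int8)
    G2 = np.ones((1, 5), dtype=np.int8)
    assert between_species_diff(G1, G2) == pytest.approx(5.0)
    for _ in range(5):
        ds = random_alignment_dataset(rng)
        aln = ds.alignments[0]
        sl = SpeciesSites.from_alignment(aln, ds)
        H = aln.haplotypes
        r1, r2 = sl.rows["asp"], sl.rows["cra"]
        brute = np.mean(
            [int((H[i] != H[j]).sum()) for i in r1 for j in r2]
        )
        got = between_species_diff(
            sl.sites.genotypes[r1], sl.sites.genotypes[r2]
        )
        assert got == pytest.approx(brute, abs=1e-12)


def test_phi_st_fixed_difference_is_one(edge_fixtures):
    phi, _ = phi_st(edge_fixtures["fixed_difference"], n_permutations=50, seed=1)
    assert phi == pytest.approx(1.0)


def test_phi_st_null_near_zero(rng):
    # random labels on a panmictic sample: Phi ~ 0, p not extreme
    ds = random_alignment_dataset(rng, n_seq=16, length=120, n_loci=3)
    phi, p = phi_st(ds, n_permutations=200, seed=3)
    assert abs(phi) < 0.15
    assert p > 0.05


def test_phi_st_requires_two_per_species(edge_fixtures):
    from coalabc.seq_data import MultiLocusDataset

    base = edge_fixtures["fixed_difference"]
    ds = MultiLocusDataset(base.samples, base.alignments)
    ds.samples = [s for s in ds.samples if s.sample_id != "c2"]
    # c2's rows are still in the alignment -> unknown sample; rebuild instead
    aln = base.alignments[0]
    keep = [i for i, (sid, _) in enumerate(aln.sequence_ids) if sid != "c2"]
    from coalabc.seq_data import LocusAlignment

    small = LocusAlignment(
        aln.locus,
        aln.haplotypes[keep][:5],  # only one 'cra' sequence left
        [aln.sequence_ids[i] for i in keep][:5],
    )
    ds2 = MultiLocusDataset(
        [s for s in base.samples if s.sample_id in {"a1", "a2", "c1"}], [small]
    )
    with pytest.raises(ValueError):
        phi_st(ds2, n_permutations=10, seed=0)


def test_summary_vector_shapes_and_validity(edge_fixtures, rng):
    ds = random_alignment_dataset(rng)
    v = summarize_im(ds)
    assert v.names == IM_STAT_NAMES and v.values.size == 13
    b = summarize_bottleneck(ds, scope="pooled")
    assert b.names == BOTTLENECK_STAT_NAMES and b.values.size == 4
    mono = summarize_im(edge_fixtures["monomorphic"])
    assert not mono.valid  # D/Fs undefined everywhere -> excluded row


def test_summarize_im_compositional(rng):
    """Each slot equals the stand-alone operation averaged across loci."""
    ds = random_alignment_dataset(rng, n_seq=8, length=60, n_loci=3)
    v = dict(zip(IM_STAT_NAMES, summarize_im(ds).values))
    per = [SpeciesSites.from_alignment(a, ds) for a in ds.alignments]
    K1 = K2 = 0
    S1s, pis, Ds = [], [], []
    for sl in per:
        G = sl.sites.genotypes
        G1, G2 = G[sl.rows["asp"]], G[sl.rows["cra"]]
        k1, k2, s1, *_ = haplotype_and_private(G1, G2)
        K1 += k1
        K2 += k2
        S1s.append(s1)
        from coalabc.sumstats import _allele_count_stats

        Sp, _, _, pip = _allele_count_stats(G)
        Ds.append(tajimas_d(Sp, pip, G.shape[0]))
        _, _, _, pi1 = _allele_count_stats(G1)
        pis.append(pi1)
    assert v["K_sp1"] == K1 and v["K_sp2"] == K2
    assert v["S_sp1"] == pytest.approx(np.mean(S1s))
    assert v["pi_sp1"] == pytest.approx(np.mean(pis))
    assert v["D_pooled"] == pytest.approx(np.nanmean(Ds))


def test_bottleneck_pooled_equals_species_when_identical(edge_fixtures):
    ds = edge_fixtures["tri_allelic"]
    pooled = summarize_bottleneck(ds, scope="pooled")
    assert pooled.values.size == 4


def test_statistics_invariant_to_row_order(rng):
    ds = random_alignment_dataset(rng, n_seq=8, length=60)
    aln = ds.alignments[0]
    p1 = neutrality_panel(aln)
    perm = rng.permutation(aln.n_sequences)
    from coalabc.seq_data import LocusAlignment

    shuffled = LocusAlignment(
        aln.locus, aln.haplotypes[perm], [aln.sequence_ids[i] for i in perm]
    )
    p2 = neutrality_panel(shuffled)
    for f in ("S", "eta", "eta_s", "pi_abs", "D", "D_star", "F_star", "Fs", "K"):
        a, b = getattr(p1, f), getattr(p2, f)
        assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)


def test_panel_monomorphic_all_na(edge_fixtures):
    p = neutrality_panel(edge_fixtures["monomorphic"].alignments[0])
    assert p.S == 0
    for f in ("D", "D_star", "F_star", "Fs"):
        assert math.isnan(getattr(p, f))


# ---------------------------------------------------------------------------
# property-based invariants


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n_seq=st.integers(min_value=4, max_value=8),
    length=st.integers(min_value=8, max_value=25),
    data=st.data(),
)
def test_pi_brute_force_property(n_seq, length, data):
    """pi by counts equals the brute-force pairwise average for arbitrary
    alignments, and is invariant to row order."""
    from coalabc.seq_data import LocusAlignment, LocusSpec

    rows = [
        data.draw(
            st.text(alphabet="ACGT", min_size=length, max_size=length)
        )
        for _ in range(n_seq)
    ]
    mat = np.array([list(r) for r in rows], dtype="S1")
    ids = [(f"s{i}", 1) for i in range(n_seq)]
    aln = LocusAlignment(LocusSpec("h", length), mat, ids)
    d = diversity(aln)
    assert d.pi_abs == pytest.approx(brute_force_pi(mat), abs=1e-12)
    rev = LocusAlignment(LocusSpec("h", length), mat[::-1], ids)
    assert diversity(rev).pi_abs == pytest.approx(d.pi_abs, abs=1e-12)
    assert diversity(rev).S == d.S
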