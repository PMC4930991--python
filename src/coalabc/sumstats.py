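"""Per-locus and multilocus population-genetic summary statistics.

Implements diversity estimators (S, eta, eta_s, pi, Watterson's theta),
the frequency-spectrum neutrality tests (Tajima's D, Fu & Li's D* and F*
with the corrected variance constants, Fay & Wu's H with the optional
normalization of Zeng et al.), Fu's Fs via the exact Ewens sampling
distribution, AMOVA-based Phi_ST with a permutation test, and the two
summary-statistic vectors used by the ABC stages (13 statistics for the
two-species isolation-with-migration model, 4 for the single-population
bottleneck model).

Conventions: S counts segregating sites; eta counts inferred mutations
(a tri-allelic site contributes 2); Tajima's D is computed from S while
D*/F* use eta and the singleton count eta_s; singletons are counted on
allele multiplicity (an allele carried by exactly one sequence), so
D*/F* need no outgroup.  pi is reported both as the mean number of
pairwise differences per locus (``pi_abs``) and per included site.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seq_data import LocusAlignment, MultiLocusDataset, SiteTable, build_site_table

__all__ = [
    "DiversityResult",
    "NeutralityPanel",
    "AbcSummaryVector",
    "SpeciesSites",
    "diversity",
    "tajimas_d",
    "fu_li_star",
    "fay_wu_h",
    "fu_fs",
    "ewens_log_pmf",
    "haplotype_and_private",
    "between_species_diff",
    "phi_st",
    "summarize_im",
    "summarize_bottleneck",
    "neutrality_panel",
    "IM_STAT_NAMES",
    "BOTTLENECK_STAT_NAMES",
]

IM_STAT_NAMES = (
    "K_sp1", "K_sp2", "S_sp1", "S_sp2", "Spriv_sp1", "Spriv_sp2",
    "pi_sp1", "pi_sp2", "D_pooled", "Fs_pooled", "Fst", "pi_between", "S_total",
)
BOTTLENECK_STAT_NAMES = ("S", "D", "pi_site", "Fs")


# ---------------------------------------------------------------------------
# harmonic-number constants


def _a1(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def _a2(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n) ** 2))


# ---------------------------------------------------------------------------
# site-frequency helpers on SiteTable genotype matrices


def _as_sites(data: LocusAlignment | SiteTable) -> SiteTable:
    if isinstance(data, SiteTable):
        return data
    return build_site_table(data)


def _site_count_matrix(
    G: np.ndarray, n_alleles: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site allele counts over non-missing rows.

    Returns ``(counts, nn)`` with ``counts`` of shape (sites, alleles) and
    ``nn`` the per-site non-missing sample size.
    """
    n, m = G.shape
    if m == 0:
        return np.zeros((0, 1), dtype=np.int64), np.zeros(0, dtype=np.int64)
    A = n_alleles if n_alleles is not None else max(int(G.max()) + 1, 1)
    valid = G >= 0
    flat = (G.astype(np.int64) + np.arange(m, dtype=np.int64)[None, :] * A)[valid]
    counts = np.bincount(flat, minlength=m * A).reshape(m, A)
    return counts, valid.sum(axis=0).astype(np.int64)


def _allele_count_stats(G: np.ndarray) -> tuple[int, int, int, float]:
    """(S, eta, eta_s, pi_abs) from an (n, sites) allele-code matrix.

    Missing codes (<0) are excluded per site; pi uses the per-site
    non-missing sample size (pairwise deletion is a no-op under the default
    complete-deletion site table, which never contains missing codes).
    """
    counts, nn = _site_count_matrix(G)
    k = (counts > 0).sum(axis=1)
    use = (k >= 2) & (nn >= 2)
    if not use.any():
        return 0, 0, 0, 0.0
    S = int(use.sum())
    eta = int((k[use] - 1).sum())
    ones = (counts == 1).sum(axis=1)
    eta_s = int(np.minimum(ones[use], k[use] - 1).sum())
    same = (counts * (counts - 1)).sum(axis=1)
    pi = float(np.sum(1.0 - same[use] / (nn[use] * (nn[use] - 1.0))))
    return S, eta, eta_s, pi


@dataclass
class DiversityResult:
    S: int
    eta: int
    eta_s: int
    pi_abs: float
    pi_site: float
    theta_w_abs: float
    theta_w_site: float
    length: int


def diversity(
    data: LocusAlignment | SiteTable, site_class: str = "all"
) -> DiversityResult:
    """Diversity summary for one locus over all or only silent sites."""
    st = _as_sites(data)
    if st.n_seq < 2:
        raise ValueError("diversity needs at least 2 sequences")
    if site_class == "all":
        G, length = st.genotypes, st.length_included
    elif site_class == "silent":
        G, length = st.genotypes[:, st.silent], st.length_silent
    else:
        raise ValueError("site_class must be 'all' or 'silent'")
    S, eta, eta_s, pi_abs = _allele_count_stats(G)
    a1 = _a1(st.n_seq)
    theta_w = S / a1
    denom = max(length, 1)
    return DiversityResult(
        S, eta, eta_s, pi_abs, pi_abs / denom, theta_w, theta_w / denom, length
    )


# ---------------------------------------------------------------------------
# neutrality tests


def tajimas_d(S: int, pi_abs: float, n: int) -> float:
    """Tajima's D from the segregating-site count and mean pairwise diffs.

    Returns NaN when undefined: no variation (S=0) or n < 4 (the variance
    constants are unstable below that).
    """
    if S == 0 or n < 4:
        return math.nan
    a1, a2 = _a1(n), _a2(n)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi_abs - S / a1) / math.sqrt(var)


def _fu_li_constants(n: int) -> tuple[float, float, float, float]:
    """(uD*, vD*, uF*, vF*) with the corrected variance constants."""
    a = _a1(n)
    b = _a2(n)
    an1 = a + 1.0 / n  # a_{n+1}
    c = 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    d = (
        c
        + (n - 2) / (n - 1) ** 2
        + (2 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n)
    )
    nn = n / (n - 1.0)
    v_dstar = (nn**2 * b + a**2 * d - 2 * (n * a * (a + 1)) / (n - 1) ** 2) / (
        a**2 + b
    )
    u_dstar = nn * (a - nn) - v_dstar
    v_fstar = (
        d + 2 * (n * n + n + 3) / (9 * n * (n - 1)) - (2 / (n - 1)) * (4 * b - 6 + 8.0 / n)
    ) / (a**2 + b)
    u_fstar = (
        nn
        + (n + 1) / (3.0 * (n - 1))
        - 4.0 / (n * (n - 1))
        + 2 * (n + 1) / (n - 1) ** 2 * (an1 - 2.0 * n / (n + 1))
    ) / a - v_fstar
    return u_dstar, v_dstar, u_fstar, v_fstar


def fu_li_star(eta: int, eta_s: int, pi_abs: float, n: int) -> tuple[float, float]:
    """Fu & Li's D* and F* (outgroup-free, singletons by multiplicity)."""
    if eta == 0 or n < 4:
        return math.nan, math.nan
    a = _a1(n)
    u_d, v_d, u_f, v_f = _fu_li_constants(n)
    num_d = (n / (n - 1.0)) * eta - a * eta_s
    var_d = u_d * eta + v_d * eta * eta
    num_f = pi_abs - ((n - 1.0) / n) * eta_s
    var_f = u_f * eta + v_f * eta * eta
    d_star = num_d / math.sqrt(var_d) if var_d > 0 else math.nan
    f_star = num_f / math.sqrt(var_f) if var_f > 0 else math.nan
    return d_star, f_star


def fay_wu_h(
    data: LocusAlignment | SiteTable, normalized: bool = False
) -> float:
    """Fay & Wu's H from outgroup-polarized derived-allele frequencies.

    Unnormalized (default): ``H = theta_pi - theta_H`` with
    ``theta_H = sum_i 2 S_i i^2 / (n(n-1))`` over derived-allele counts i.
    With ``normalized=True`` the statistic is ``(theta_pi - theta_L)``
    divided by its null standard deviation (Zeng et al.'s normalization),
    with theta and theta^2 estimated from S.  Sites with unresolved
    ancestral state are skipped; returns NaN when no usable site remains.
    """
    st = _as_sites(data)
    if st.ancestral.size and not np.any(st.ancestral >= 0):
        raise ValueError("Fay & Wu's H needs an outgroup to polarize sites")
    n = st.n_seq
    if n < 2:
        raise ValueError("need at least 2 sequences")
    theta_pi = theta_h = theta_l = 0.0
    S_used = 0
    for j in range(st.n_sites):
        anc = st.ancestral[j]
        if anc < 0:
            continue
        col = st.genotypes[:, j]
        col = col[col >= 0]
        if col.size != n:
            continue  # polarized spectrum needs complete data at the site
        counts = np.bincount(col)
        for a, c in enumerate(counts):
            if a == anc or c == 0:
                continue
            i = int(c)
            if i == n:
                continue  # fixed difference, not polymorphic
            theta_pi += 2.0 * i * (n - i) / (n * (n - 1))
            theta_h += 2.0 * i * i / (n * (n - 1))
            theta_l += i / (n - 1.0)
            S_used += 1
    if S_used == 0:
        return math.nan
    if not normalized:
        return theta_pi - theta_h
    a_n = _a1(n)
    b_n = _a2(n)
    b_n1 = b_n + 1.0 / n**2
    theta = S_used / a_n
    theta2 = S_used * (S_used - 1) / (a_n**2 + b_n)
    var = (n - 2) / (6.0 * (n - 1)) * theta + (
        18 * n**2 * (3 * n + 2) * b_n1 - (88 * n**3 + 9 * n**2 - 13 * n + 6)
    ) / (9.0 * n * (n - 1) ** 2) * theta2
    if var <= 0:
        return math.nan
    return (theta_pi - theta_l) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Fu's Fs via the Ewens sampling distribution

_LOG_STIRLING_ROWS: dict[int, np.ndarray] = {1: np.array([-np.inf, 0.0])}


def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind)."""
    top = max(_LOG_STIRLING_ROWS)
    row = _LOG_STIRLING_ROWS[top]
    for m in range(top, n):
        # |s(m+1, k)| = m * |s(m, k)| + |s(m, k-1)|
        grown = np.concatenate([row, [-np.inf]])
        shifted = np.concatenate([[-np.inf], row])
        new = np.logaddexp(math.log(m) + grown, shifted)
        new[0] = -np.inf
        _LOG_STIRLING_ROWS[m + 1] = new
        row = new
    return _LOG_STIRLING_ROWS[n]


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k) for k = 1..n under the Ewens sampling distribution."""
    if n < 1 or theta <= 0:
        raise ValueError("need n >= 1 and theta > 0")
    ls = _log_stirling_row(n)[1:]
    k = np.arange(1, n + 1)
    log_norm = float(np.sum(np.log(theta + np.arange(n))))
    return ls + k * math.log(theta) - log_norm


def fu_fs(K: int, pi_abs: float, n: int) -> float:
    """Fu's Fs: log-odds of observing >= K haplotypes under neutrality.

    ``S' = P(K_Ewens >= K | theta = pi_abs, n)`` computed exactly;
    ``Fs = ln(S' / (1 - S'))``.  NaN when pi_abs = 0 or S' degenerates.
    """
    if pi_abs <= 0 or n < 2:
        return math.nan
    logp = ewens_log_pmf(n, pi_abs)
    p = np.exp(logp)
    s_prime = float(p[K - 1 :].sum())
    if not (0.0 < s_prime < 1.0):
        return math.nan
    return math.log(s_prime / (1.0 - s_prime))


# ---------------------------------------------------------------------------
# two-species statistics


@dataclass
class SpeciesSites:
    """Pooled site table for one locus plus per-species row indices."""

    sites: SiteTable
    rows: dict[str, np.ndarray]

    @classmethod
    def from_alignment(
        cls, aln: LocusAlignment, ds: MultiLocusDataset
    ) -> "SpeciesSites":
        st = build_site_table(aln)
        rows = {
            sp: aln.rows_for_samples(ds.sample_ids_for_species(sp))
            for sp in ds.species_labels
        }
        return cls(st, rows)


def _n_haplotypes(G: np.ndarray) -> int:
    if G.shape[1] == 0:
        return 1
    u = np.ascontiguousarray(G).view(
        np.dtype((np.void, G.dtype.itemsize * G.shape[1]))
    )
    return int(np.unique(u).size)


def _variable_mask(G: np.ndarray) -> np.ndarray:
    """Per-site: >= 2 alleles among non-missing rows of G."""
    counts, nn = _site_count_matrix(G)
    return ((counts > 0).sum(axis=1) >= 2) & (nn >= 2)


def haplotype_and_private(
    G1: np.ndarray, G2: np.ndarray
) -> tuple[int, int, int, int, int, int, int]:
    """(K1, K2, S1, S2, Spriv1, Spriv2, S_total) from two allele-code
    matrices over the same (pooled) site list.

    A private site of species 1 is polymorphic within species 1 while
    species 2 is monomorphic for an allele that is present in species 1.
    """
    K1, K2 = _n_haplotypes(G1), _n_haplotypes(G2)
    m = G1.shape[1]
    if m == 0:
        return K1, K2, 0, 0, 0, 0, 0
    A = max(int(max(G1.max(initial=0), G2.max(initial=0))) + 1, 1)
    c1, n1 = _site_count_matrix(G1, A)
    c2, n2 = _site_count_matrix(G2, A)
    v1 = ((c1 > 0).sum(axis=1) >= 2) & (n1 >= 2)
    v2 = ((c2 > 0).sum(axis=1) >= 2) & (n2 >= 2)
    shared_allele = ((c1 > 0) & (c2 > 0)).any(axis=1)
    Spriv1 = int((v1 & ~v2 & ((n2 == 0) | shared_allele)).sum())
    Spriv2 = int((v2 & ~v1 & ((n1 == 0) | shared_allele)).sum())
    cp = c1 + c2
    vp = ((cp > 0).sum(axis=1) >= 2) & ((n1 + n2) >= 2)
    return K1, K2, int(v1.sum()), int(v2.sum()), Spriv1, Spriv2, int(vp.sum())


def between_species_diff(G1: np.ndarray, G2: np.ndarray) -> float:
    """Mean pairwise differences across species over pooled sites."""
    if G1.shape[0] < 1 or G2.shape[0] < 1:
        raise ValueError("need at least one sequence per species")
    if G1.shape[1] == 0:
        return 0.0
    A = max(int(max(G1.max(initial=0), G2.max(initial=0))) + 1, 1)
    c1, n1 = _site_count_matrix(G1, A)
    c2, n2 = _site_count_matrix(G2, A)
    ok = (n1 > 0) & (n2 > 0)
    same = (c1 * c2).sum(axis=1)
    return float(np.sum(1.0 - same[ok] / (n1[ok] * n2[ok])))


# ---------------------------------------------------------------------------
# AMOVA Phi_ST


def _pairwise_diff_matrix(G: np.ndarray) -> np.ndarray:
    n = G.shape[0]
    if G.shape[1] == 0:
        return np.zeros((n, n))
    neq = G[:, None, :] != G[None, :, :]
    both = (G[:, None, :] >= 0) & (G[None, :, :] >= 0)
    return (neq & both).sum(axis=2).astype(float)


def _amova_components(D: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(sigma2_among, sigma2_within) for one locus, two or more groups.

    Standard AMOVA on squared distances; with distances equal to pairwise
    difference counts this reproduces the sequence-based Phi_ST.
    """
    N = D.shape[0]
    groups = np.unique(labels)
    G = groups.size
    ssd_total = D[np.triu_indices(N, 1)].sum() / N
    ssd_within = 0.0
    sum_n2 = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ng = idx.size
        sum_n2 += ng * ng
        if ng > 1:
            sub = D[np.ix_(idx, idx)]
            ssd_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ssd_among = ssd_total - ssd_within
    df_among = G - 1
    df_within = N - G
    if df_within <= 0 or df_among <= 0:
        return 0.0, 0.0
    msd_within = ssd_within / df_within
    msd_among = ssd_among / df_among
    n_prime = (N - sum_n2 / N) / df_among
    sigma_within = msd_within
    sigma_among = (msd_among - msd_within) / n_prime
    return sigma_among, sigma_within


def _multilocus_phi(
    dists: list[np.ndarray], label_arrays: list[np.ndarray]
) -> float:
    among = within = 0.0
    for D, lab in zip(dists, label_arrays):
        a, w = _amova_components(D, lab)
        among += a
        within += w
    tot = among + within
    return among / tot if tot > 0 else 0.0


def phi_st(
    ds: MultiLocusDataset,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Multilocus AMOVA Phi_ST between the two species, with permutation p.

    Variance components are summed over loci (sum of among-species
    components over sum of total components).  The permutation scheme
    reassigns whole individuals (both alleles together) between species and
    reports the fraction of permutations with Phi >= observed.
    """
    species = ds.species_labels
    if len(species) != 2:
        raise ValueError("phi_st needs exactly two species labels")
    sp_of = {s.sample_id: s.species_label for s in ds.samples}
    dists: list[np.ndarray] = []
    row_sample_idx: list[np.ndarray] = []
    sample_ids = [s.sample_id for s in ds.samples]
    sample_pos = {sid: i for i, sid in enumerate(sample_ids)}
    for aln in ds.alignments:
        st = build_site_table(aln)
        dists.append(_pairwise_diff_matrix(st.genotypes))
        row_sample_idx.append(
            np.array([sample_pos[sid] for sid, _ in aln.sequence_ids], dtype=int)
        )
    base_labels = np.array(
        [0 if sp_of[sid] == species[0] else 1 for sid in sample_ids], dtype=int
    )
    for lab, aln in zip(
        (base_labels[idx] for idx in row_sample_idx), ds.alignments
    ):
        for v in np.bincount(lab, minlength=2):
            if v < 2:
                raise ValueError(
                    f"locus {aln.locus.locus_name}: each species needs >= 2 sequences"
                )
    observed = _multilocus_phi(dists, [base_labels[i] for i in row_sample_idx])
    if n_permutations <= 0:
        return observed, math.nan
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(base_labels)
        phi = _multilocus_phi(dists, [perm[i] for i in row_sample_idx])
        if phi >= observed:
            hits += 1
    return observed, hits / n_permutations


# ---------------------------------------------------------------------------
# ABC summary vectors


@dataclass
class AbcSummaryVector:
    model: str
    names: tuple[str, ...]
    values: np.ndarray
    valid: bool = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = bool(np.all(np.isfinite(self.values)))


def _per_locus_sites(
    data: MultiLocusDataset | list[SpeciesSites],
) -> list[SpeciesSites]:
    if isinstance(data, MultiLocusDataset):
        return [SpeciesSites.from_alignment(a, data) for a in data.alignments]
    return data


def summarize_im(
    data: MultiLocusDataset | list[SpeciesSites],
) -> AbcSummaryVector:
    """The 13-statistic two-species summary vector.

    Order: K_sp1, K_sp2, S_sp1, S_sp2, Spriv_sp1, Spriv_sp2, pi_sp1,
    pi_sp2, D_pooled, Fs_pooled, Fst, pi_between, S_total.  Haplotype
    counts are summed across loci; every other slot is the mean across
    loci of the per-locus value (loci where a test statistic is undefined
    are skipped; a slot is NaN only if undefined at every locus).
    """
    per_locus = _per_locus_sites(data)
    labels = list(per_locus[0].rows)
    if len(labels) != 2:
        raise ValueError("summarize_im needs exactly two species")
    sp1, sp2 = labels
    K1tot = K2tot = 0
    acc: dict[str, list[float]] = {k: [] for k in IM_STAT_NAMES}
    dists: list[np.ndarray] = []
    lab_arrays: list[np.ndarray] = []
    for sl in per_locus:
        G = sl.sites.genotypes
        r1, r2 = sl.rows[sp1], sl.rows[sp2]
        G1, G2 = G[r1], G[r2]
        K1, K2, S1, S2, P1, P2, Stot = haplotype_and_private(G1, G2)
        K1tot += K1
        K2tot += K2
        acc["S_sp1"].append(S1)
        acc["S_sp2"].append(S2)
        acc["Spriv_sp1"].append(P1)
        acc["Spriv_sp2"].append(P2)
        acc["S_total"].append(Stot)
        _, _, _, pi1 = _allele_count_stats(G1)
        _, _, _, pi2 = _allele_count_stats(G2)
        acc["pi_sp1"].append(pi1)
        acc["pi_sp2"].append(pi2)
        n = sl.sites.n_seq
        Sp, _, _, pip = _allele_count_stats(G)
        acc["D_pooled"].append(tajimas_d(Sp, pip, n))
        acc["Fs_pooled"].append(fu_fs(_n_haplotypes(G), pip, n))
        acc["pi_between"].append(between_species_diff(G1, G2))
        lab = np.empty(n, dtype=int)
        lab[r1] = 0
        lab[r2] = 1
        dists.append(_pairwise_diff_matrix(G))
        lab_arrays.append(lab)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.array(
            [
                K1tot,
                K2tot,
                np.mean(acc["S_sp1"]),
                np.mean(acc["S_sp2"]),
                np.mean(acc["Spriv_sp1"]),
                np.mean(acc["Spriv_sp2"]),
                np.mean(acc["pi_sp1"]),
                np.mean(acc["pi_sp2"]),
                np.nanmean(acc["D_pooled"]),
                np.nanmean(acc["Fs_pooled"]),
                _multilocus_phi(dists, lab_arrays),
                np.mean(acc["pi_between"]),
                np.mean(acc["S_total"]),
            ]
        )
    return AbcSummaryVector("IM", IM_STAT_NAMES, values)


def summarize_bottleneck(
    data: MultiLocusDataset | list[SpeciesSites], scope: str = "pooled"
) -> AbcSummaryVector:
    """The 4-statistic vector (mean S, Tajima's D, per-site pi, Fu's Fs).

    ``scope`` is a species label or ``"pooled"``; statistics are computed
    per locus over the scoped sequences and averaged across loci.
    """
    per_locus = _per_locus_sites(data)
    Ss: list[float] = []
    Ds: list[float] = []
    pis: list[float] = []
    Fss: list[float] = []
    for sl in per_locus:
        if scope == "pooled":
            rows = np.arange(sl.sites.n_seq)
        elif scope in sl.rows:
            rows = sl.rows[scope]
        else:
            raise ValueError(f"unknown scope {scope!r}")
        if rows.size < 2:
            raise ValueError("scope selects fewer than 2 sequences")
        G = sl.sites.genotypes[rows]
        S, _, _, pi_abs = _allele_count_stats(G)
        Ss.append(S)
        Ds.append(tajimas_d(S, pi_abs, rows.size))
        pis.append(pi_abs / max(sl.sites.length_included, 1))
        Fss.append(fu_fs(_n_haplotypes(G), pi_abs, rows.size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.array(
            [np.mean(Ss), np.nanmean(Ds), np.mean(pis), np.nanmean(Fss)]
        )
    return AbcSummaryVector("BOTTLENECK", BOTTLENECK_STAT_NAMES, values)


# ---------------------------------------------------------------------------
# per-locus neutrality panel


@dataclass
class NeutralityPanel:
    locus_name: str
    n: int
    S: int
    eta: int
    eta_s: int
    pi_abs: float
    pi_site: float
    pi_silent: float
    theta_w_abs: float
    theta_w_site: float
    D: float
    D_star: float
    F_star: float
    H: float
    Fs: float
    K: int


def neutrality_panel(
    aln: LocusAlignment, rows: np.ndarray | None = None, normalized_h: bool = False
) -> NeutralityPanel:
    """Full per-locus statistics panel for one (sub)sample of sequences."""
    st = build_site_table(aln)
    if rows is not None:
        st = SiteTable(
            n_seq=int(rows.size),
            length_included=st.length_included,
            length_silent=st.length_silent,
            positions=st.positions,
            genotypes=st.genotypes[rows],
            alleles=st.alleles,
            ancestral=st.ancestral,
            silent=st.silent,
            indel_positions=st.indel_positions,
            missing_mode=st.missing_mode,
        )
    div = diversity(st)
    div_silent = diversity(st, site_class="silent")
    D = tajimas_d(div.S, div.pi_abs, st.n_seq)
    d_star, f_star = fu_li_star(div.eta, div.eta_s, div.pi_abs, st.n_seq)
    try:
        H = fay_wu_h(st, normalized=normalized_h)
    except ValueError:
        H = math.nan
    K = _n_haplotypes(st.genotypes)
    Fs = fu_fs(K, div.pi_abs, st.n_seq)
    return NeutralityPanel(
        aln.locus.locus_name,
        st.n_seq,
        div.S,
        div.eta,
        div.eta_s,
        div.pi_abs,
        div.pi_site,
        div_silent.pi_site,
        div.theta_w_abs,
        div.theta_w_site,
        D,
        d_star,
        f_star,
        H,
        Fs,
        K,
    )


def panel_frame(panels: list[NeutralityPanel]) -> pd.DataFrame:
    """Stack per-locus panels into a table (NaN rendered as NA on write)."""
    return pd.DataFrame([vars(p) for p in panels])
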