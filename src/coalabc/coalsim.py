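"""Coalescent simulation of multilocus sequence data under the two
demographies of the analysis: an isolation-with-migration (IM) model and
a three-epoch bottleneck model.

Genealogies are simulated with msprime (continuous-time coalescent with
exponential competing risks) and mutations are dropped under an
infinite-sites model at rate ``mu`` per site per generation.  Population
sizes are DIPLOID individual counts throughout (coalescent rates use 2N
gene copies); times are in generations before present.

The migration parameters of the IM model are expected migrant gene
copies per generation into the destination deme, so the backward
per-lineage migration rate out of the destination is ``M / (2 N_dest)``.
An alternative per-copy-rate interpretation is available via
``migration_is_rate=True`` on :func:`im_demography`.

Loci are independent (free recombination between loci, none within).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import tskit

from .seq_data import (
    LocusAlignment,
    LocusSpec,
    MultiLocusDataset,
    SampleRecord,
    SiteTable,
)
from .sumstats import SpeciesSites

__all__ = [
    "IMParams",
    "BottleneckParams",
    "SampleConfig",
    "im_demography",
    "bottleneck_demography",
    "simulate_im_locus",
    "simulate_bottleneck_locus",
    "drop_mutations",
    "simulate_dataset",
    "simulate_species_sites",
    "study_template",
]

MU_DEFAULT = 1e-8  # per site per generation

SP1 = "asp"  # species 1 label used for simulated datasets
SP2 = "cra"  # species 2 label


@dataclass(frozen=True)
class IMParams:
    """Isolation-with-migration parameters (diploid sizes, generations)."""

    N: float  # ancestral size
    N_asp: float  # current size, species 1
    N_cra: float  # current size, species 2
    T: float  # split time, generations ago
    M_cra_to_asp: float  # migrant gene copies/generation into species 1
    M_asp_to_cra: float  # migrant gene copies/generation into species 2
    mu: float = MU_DEFAULT

    def __post_init__(self) -> None:
        if min(self.N, self.N_asp, self.N_cra) <= 0:
            raise ValueError("population sizes must be > 0")
        if self.T < 0 or min(self.M_cra_to_asp, self.M_asp_to_cra) < 0:
            raise ValueError("T and migration must be >= 0")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")


@dataclass(frozen=True)
class BottleneckParams:
    """Three-epoch single-population history.

    Forward in time: size ``N`` until ``Tb`` generations ago, ``Nb``
    during the bottleneck (``Tb`` to ``Te``), then ``N0`` from ``Te`` to
    the present.  The post-expansion size ``N0`` is a free parameter.
    """

    N: float
    Nb: float
    N0: float
    Tb: float
    Te: float
    mu: float = MU_DEFAULT

    def __post_init__(self) -> None:
        if min(self.N, self.Nb, self.N0) <= 0:
            raise ValueError("population sizes must be > 0")
        if not (self.Tb > self.Te >= 0):
            raise ValueError("need Tb > Te >= 0")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")


@dataclass(frozen=True)
class SampleConfig:
    """Per-locus lengths and sampled gene copies per deme."""

    locus_lengths: tuple[int, ...]
    n_per_deme: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.locus_lengths) == 0:
            raise ValueError("need at least one locus")
        if any(l <= 0 for l in self.locus_lengths):
            raise ValueError("locus lengths must be > 0")
        if sum(self.n_per_deme) < 2:
            raise ValueError("need at least 2 sampled sequences per locus")

    @property
    def n_loci(self) -> int:
        return len(self.locus_lengths)


def study_template(reduced: bool = True) -> SampleConfig:
    """13 loci of 800 bp; 20+20 sequences (reduced) or the full 176+256."""
    n = (20, 20) if reduced else (176, 256)
    return SampleConfig(locus_lengths=(800,) * 13, n_per_deme=n)


def im_demography(
    p: IMParams, migration_is_rate: bool = False
) -> msprime.Demography:
    d = msprime.Demography()
    d.add_population(name=SP1, initial_size=p.N_asp)
    d.add_population(name=SP2, initial_size=p.N_cra)
    d.add_population(name="anc", initial_size=p.N)
    if migration_is_rate:
        m1, m2 = p.M_cra_to_asp, p.M_asp_to_cra
    else:
        m1 = p.M_cra_to_asp / (2.0 * p.N_asp)
        m2 = p.M_asp_to_cra / (2.0 * p.N_cra)
    # backward in time, lineages sampled in the destination deme trace
    # back to the source deme of the forward migration
    if m1 > 0:
        d.set_migration_rate(source=SP1, dest=SP2, rate=m1)
    if m2 > 0:
        d.set_migration_rate(source=SP2, dest=SP1, rate=m2)
    d.add_population_split(time=max(p.T, 1e-9), derived=[SP1, SP2], ancestral="anc")
    return d


def bottleneck_demography(p: BottleneckParams) -> msprime.Demography:
    d = msprime.Demography()
    d.add_population(name="pop", initial_size=p.N0)
    if p.Te > 0:
        d.add_population_parameters_change(time=p.Te, initial_size=p.Nb)
    else:
        d["pop"].initial_size = p.Nb
    d.add_population_parameters_change(time=p.Tb, initial_size=p.N)
    return d


def _ancestry(
    demography: msprime.Demography,
    samples: list[msprime.SampleSet],
    length_bp: int,
    seed: int,
    num_replicates: int | None = None,
):
    return msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        sequence_length=length_bp,
        recombination_rate=0.0,
        ploidy=2,
        random_seed=seed,
        num_replicates=num_replicates,
        record_provenance=False,
    )


def _seed_stream(seed: int | None, n: int) -> np.ndarray:
    """n independent msprime-safe seeds derived from one integer."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n, dtype=np.uint32).astype(np.int64) % (2**31 - 2) + 1


def simulate_im_locus(
    params: IMParams, length_bp: int, n_per_deme: tuple[int, int], seed: int
) -> tskit.TreeSequence:
    """One genealogy under the IM model; samples are haploid gene copies."""
    samples = [
        msprime.SampleSet(n_per_deme[0], population=SP1, ploidy=1),
        msprime.SampleSet(n_per_deme[1], population=SP2, ploidy=1),
    ]
    return _ancestry(im_demography(params), samples, length_bp, seed)


def simulate_bottleneck_locus(
    params: BottleneckParams, length_bp: int, n: int, seed: int
) -> tskit.TreeSequence:
    """One genealogy under the bottleneck model."""
    samples = [msprime.SampleSet(n, population="pop", ploidy=1)]
    return _ancestry(bottleneck_demography(params), samples, length_bp, seed)


def _mutate(ts: tskit.TreeSequence, mu: float, seed: int) -> tskit.TreeSequence:
    return msprime.sim_mutations(
        ts,
        rate=mu,
        random_seed=seed,
        model=msprime.JC69(),
        discrete_genome=False,  # infinite sites
        record_provenance=False,
    )


def _integer_columns(positions: np.ndarray, length_bp: int) -> np.ndarray:
    """Map continuous infinite-sites positions to distinct integer columns."""
    if positions.size > length_bp:
        raise ValueError(
            f"{positions.size} mutations exceed locus length {length_bp}; "
            "use a longer locus"
        )
    cols = np.floor(positions).astype(int)
    used: set[int] = set()
    out = np.empty_like(cols)
    for i, c in enumerate(cols):
        while c in used:
            c += 1
        if c >= length_bp:
            c = 0
            while c in used:
                c += 1
        used.add(c)
        out[i] = c
    return out


def sites_from_ts(
    mts: tskit.TreeSequence, length_bp: int, with_positions: bool = True
) -> SiteTable:
    """Compact site table straight from a mutated tree sequence.

    Allele code 0 is the ancestral state at every site, so the table
    carries perfectly polarized ancestral information (the simulator
    plays the role of an ideal outgroup).  ``with_positions=False`` skips
    the mapping of continuous mutation positions to integer columns
    (sites are numbered consecutively); no statistic depends on it.
    """
    G = mts.genotype_matrix().T.astype(np.int8)  # (n, sites)
    n = mts.num_samples
    m = mts.num_sites
    if with_positions:
        pos = mts.tables.sites.position
        cols = _integer_columns(pos, length_bp) if m else np.zeros(0, int)
        order = np.argsort(cols, kind="stable")
        cols, G = cols[order] + 1, (G[:, order] if m else G)
    else:
        if m > length_bp:
            raise ValueError(
                f"{m} mutations exceed locus length {length_bp}; "
                "use a longer locus"
            )
        cols = np.arange(1, m + 1)
    return SiteTable(
        n_seq=n,
        length_included=length_bp,
        length_silent=length_bp,
        positions=cols,
        genotypes=G,
        alleles=[b"" for _ in range(m)],  # filled only when rendered to bases
        ancestral=np.zeros(m, dtype=int),
        silent=np.ones(m, dtype=bool),
        indel_positions=np.zeros(0, dtype=int),
    )


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def drop_mutations(
    g: tskit.TreeSequence,
    mu: float,
    length_bp: int,
    rng: np.random.Generator,
    locus: LocusSpec | None = None,
    sequence_ids: list[tuple[str, int]] | None = None,
    mut_seed: int | None = None,
) -> LocusAlignment:
    """Drop infinite-sites mutations on a genealogy and render a full
    nucleotide alignment.

    The invariant background is drawn uniformly from ACGT; variable
    columns use the simulated ancestral/derived states.  The returned
    alignment carries the true ancestral sequence as a perfect outgroup.
    """
    seed = int(rng.integers(1, 2**31 - 2)) if mut_seed is None else mut_seed
    mts = _mutate(g, mu, seed)
    st = sites_from_ts(mts, length_bp)
    n = st.n_seq
    background = _BASES[rng.integers(0, 4, size=length_bp)]
    matrix = np.tile(background, (n, 1))
    outgroup = background.copy()
    for j in range(st.n_sites):
        c = st.positions[j] - 1
        col = st.genotypes[:, j]
        k = int(col.max()) + 1
        states = rng.permutation(_BASES)[:k]
        matrix[:, c] = states[col]
        outgroup[c] = states[0]
    if locus is None:
        locus = LocusSpec("locus", length_bp, outgroup_id="ancestral")
    if sequence_ids is None:
        sequence_ids = [(f"seq{i:04d}", 1) for i in range(n)]
    aln = LocusAlignment(locus, matrix, sequence_ids, outgroup=outgroup)
    return aln


@dataclass
class _SimLabels:
    samples: list[SampleRecord]
    sequence_ids: list[tuple[str, int]]
    rows: dict[str, np.ndarray]


def _labels_for(cfg: SampleConfig, model: str) -> _SimLabels:
    names = (SP1, SP2) if model == "IM" else ("pop",)
    samples: list[SampleRecord] = []
    sequence_ids: list[tuple[str, int]] = []
    rows: dict[str, np.ndarray] = {}
    row = 0
    for deme, n in zip(names, cfg.n_per_deme):
        idx = []
        for i in range(0, n, 2):
            sid = f"{deme}{i // 2 + 1:03d}"
            take = min(2, n - i)  # a trailing odd copy becomes a haploid sample
            samples.append(SampleRecord(sid, deme.upper(), deme, ploidy=take))
            for k in range(1, take + 1):
                sequence_ids.append((sid, k))
                idx.append(row)
                row += 1
        rows[deme] = np.asarray(idx, dtype=int)
    return _SimLabels(samples, sequence_ids, rows)


def _locus_ancestries(
    params: IMParams | BottleneckParams, cfg: SampleConfig, seed: int
):
    """Generator of per-locus tree sequences (one demography, many loci)."""
    if isinstance(params, IMParams):
        demography = im_demography(params)
        samples = [
            msprime.SampleSet(cfg.n_per_deme[0], population=SP1, ploidy=1),
            msprime.SampleSet(cfg.n_per_deme[1], population=SP2, ploidy=1),
        ]
    else:
        demography = bottleneck_demography(params)
        samples = [
            msprime.SampleSet(cfg.n_per_deme[0], population="pop", ploidy=1)
        ]
    lengths = set(cfg.locus_lengths)
    if len(lengths) == 1:
        yield from _ancestry(
            demography,
            samples,
            cfg.locus_lengths[0],
            seed,
            num_replicates=cfg.n_loci,
        )
    else:
        for i, L in enumerate(cfg.locus_lengths):
            yield _ancestry(demography, samples, L, int(seed) + i)


def simulate_species_sites(
    params: IMParams | BottleneckParams, cfg: SampleConfig, seed: int
) -> list[SpeciesSites]:
    """Fast path: per-locus site tables with species row maps, no FASTA
    rendering.  Statistically identical to building alignments via
    :func:`simulate_dataset` and re-tabulating them.
    """
    model = "IM" if isinstance(params, IMParams) else "BOTTLENECK"
    seeds = _seed_stream(seed, 2 * cfg.n_loci)
    out: list[SpeciesSites] = []
    if model == "IM":
        rows = {
            SP1: np.arange(cfg.n_per_deme[0]),
            SP2: np.arange(cfg.n_per_deme[0], sum(cfg.n_per_deme[:2])),
        }
    else:
        rows = {"pop": np.arange(cfg.n_per_deme[0])}
    for i, ts in enumerate(_locus_ancestries(params, cfg, int(seeds[0]))):
        mts = _mutate(ts, params.mu, int(seeds[2 * i + 1]))
        out.append(
            SpeciesSites(
                sites_from_ts(mts, cfg.locus_lengths[i], with_positions=False),
                rows,
            )
        )
    return out


def simulate_dataset(
    params: IMParams | BottleneckParams,
    cfg: SampleConfig,
    seed: int,
) -> MultiLocusDataset:
    """Simulate a full multilocus dataset with rendered alignments.

    Loci are independent; species labels follow the sampling
    configuration; the run is reproducible bit-for-bit under a fixed seed.
    """
    model = "IM" if isinstance(params, IMParams) else "BOTTLENECK"
    labels = _labels_for(cfg, model)
    seeds = _seed_stream(seed, 2 * cfg.n_loci)  # same stream as the fast path
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    alignments: list[LocusAlignment] = []
    for i, ts in enumerate(_locus_ancestries(params, cfg, int(seeds[0]))):
        spec = LocusSpec(
            f"locus{i + 1:02d}", cfg.locus_lengths[i], outgroup_id="ancestral"
        )
        aln = drop_mutations(
            ts,
            params.mu,
            cfg.locus_lengths[i],
            rng,
            locus=spec,
            sequence_ids=labels.sequence_ids,
            mut_seed=int(seeds[2 * i + 1]),
        )
        alignments.append(aln)
    return MultiLocusDataset(labels.samples, alignments)
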