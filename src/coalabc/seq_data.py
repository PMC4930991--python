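"""Data model and I/O for multi-locus phased alignment datasets.

A dataset is a set of per-locus multiple sequence alignments of phased
haplotypes (two rows per diploid individual) together with a sample map
assigning each individual to a population and one of two species.  All
coordinates are 1-based and intervals are closed.  Alignment matrices use
the alphabet ``{A, C, G, T, -, N}``; any other character is mapped to
``N`` on input.

FASTA header grammar
--------------------
Each record header must be ``<sample_id>_<allele_index>`` with
``allele_index`` in ``1..ploidy`` (e.g. ``P018-03_1``, ``P018-03_2``), so
that the sample-to-haplotype pairing is deterministic without sidecar
files.  A header equal to the locus' configured outgroup id is routed to
the alignment's ``outgroup`` slot instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = b"ACGT-N"
GAP = ord("-")
MISSING = ord("N")

__all__ = [
    "SampleRecord",
    "LocusSpec",
    "LocusAlignment",
    "MultiLocusDataset",
    "SiteTable",
    "ValidationReport",
    "read_sample_map",
    "read_locus_config",
    "read_fasta_locus",
    "write_fasta_locus",
    "read_dataset",
    "write_dataset",
    "build_site_table",
    "validate_dataset",
]


@dataclass(frozen=True)
class SampleRecord:
    """One sampled individual with its population and species assignment."""

    sample_id: str
    population_code: str
    species_label: str
    ploidy: int = 2


@dataclass
class LocusSpec:
    """Static description of one locus: length, coding annotation, outgroup.

    ``coding_intervals`` is a list of 1-based closed ``(start, end, frame)``
    triples; ``frame`` in ``{0, 1, 2}`` is the offset of the first complete
    codon position relative to ``start``.
    """

    locus_name: str
    length_bp: int
    coding_intervals: list[tuple[int, int, int]] = field(default_factory=list)
    outgroup_id: str | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"locus {self.locus_name}: length_bp must be > 0")
        for start, end, frame in self.coding_intervals:
            if not (1 <= start <= end <= self.length_bp):
                raise ValueError(
                    f"locus {self.locus_name}: coding interval ({start},{end}) "
                    f"outside [1,{self.length_bp}]"
                )
            if frame not in (0, 1, 2):
                raise ValueError(f"locus {self.locus_name}: frame must be 0, 1 or 2")

    def silent_site_mask(self, reference: np.ndarray | None = None) -> np.ndarray:
        """Boolean vector (length ``length_bp``): True where a site is silent.

        All non-coding positions are silent.  Within coding intervals a
        position is silent iff it is fourfold degenerate for the reference
        codon (every nucleotide substitution at the position is synonymous).
        Without a reference sequence all coding positions are conservatively
        non-silent.
        """
        mask = np.ones(self.length_bp, dtype=bool)
        if not self.coding_intervals:
            return mask
        fwd = standard_dna_table.forward_table
        stops = set(standard_dna_table.stop_codons)

        def _aa(codon: str) -> str:
            return "*" if codon in stops else fwd.get(codon, "?")

        for start, end, frame in self.coding_intervals:
            mask[start - 1 : end] = False
            if reference is None:
                continue
            first = start - 1 + frame
            for cstart in range(first, end - 2, 3):
                codon = reference[cstart : cstart + 3].tobytes().decode("ascii")
                if any(ch not in "ACGT" for ch in codon):
                    continue
                for off in range(3):
                    variants = {
                        _aa(codon[:off] + nt + codon[off + 1 :]) for nt in "ACGT"
                    }
                    if len(variants) == 1:
                        mask[cstart + off] = True
        return mask


@dataclass
class LocusAlignment:
    """Phased haplotype alignment for one locus.

    ``haplotypes`` has shape ``(n_sequences, length_bp)`` with dtype ``S1``;
    ``sequence_ids[i]`` is the ``(sample_id, allele_index)`` of row ``i``.
    ``outgroup`` is an optional single haplotype used only for polarizing
    ancestral states.
    """

    locus: LocusSpec
    haplotypes: np.ndarray
    sequence_ids: list[tuple[str, int]]
    outgroup: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype="S1")
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        n, L = self.haplotypes.shape
        if L != self.locus.length_bp:
            raise ValueError(
                f"locus {self.locus.locus_name}: matrix width {L} != "
                f"spec length {self.locus.length_bp}"
            )
        if len(self.sequence_ids) != n:
            raise ValueError("sequence_ids length must match haplotype rows")
        if self.outgroup is not None:
            self.outgroup = np.asarray(self.outgroup, dtype="S1").ravel()
            if self.outgroup.size != L:
                raise ValueError("outgroup length mismatch")

    @property
    def n_sequences(self) -> int:
        return self.haplotypes.shape[0]

    def rows_for_samples(self, sample_ids: set[str]) -> np.ndarray:
        return np.array(
            [i for i, (sid, _) in enumerate(self.sequence_ids) if sid in sample_ids],
            dtype=int,
        )


@dataclass
class MultiLocusDataset:
    """Samples plus one alignment per locus (13 in the study template)."""

    samples: list[SampleRecord]
    alignments: list[LocusAlignment]

    @property
    def species_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.species_label not in seen:
                seen.append(s.species_label)
        return seen

    def sample_ids_for_species(self, label: str) -> set[str]:
        return {s.sample_id for s in self.samples if s.species_label == label}

    def sample_of(self, sample_id: str) -> SampleRecord:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


@dataclass
class SiteTable:
    """Variable sites of one alignment after indel (and missing) exclusion.

    ``genotypes`` is ``(n_seq, n_sites)`` int8 with per-site allele codes
    ``0..k-1`` (ordered by byte value of the allele) and ``-9`` for missing.
    ``ancestral[j]`` is the code of the ancestral allele at site ``j`` (from
    the outgroup) or ``-1`` when unknown.  ``length_included`` counts the
    alignment columns (monomorphic ones included) that survive exclusion and
    is the denominator of per-site statistics; ``length_silent`` is the
    included silent length.
    """

    n_seq: int
    length_included: int
    length_silent: int
    positions: np.ndarray
    genotypes: np.ndarray
    alleles: list[bytes]
    ancestral: np.ndarray
    silent: np.ndarray
    indel_positions: np.ndarray
    missing_mode: str = "complete"

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def allele_counts(self, j: int) -> dict[bytes, int]:
        col = self.genotypes[:, j]
        col = col[col >= 0]
        counts = np.bincount(col, minlength=len(self.alleles[j]))
        return {
            bytes([self.alleles[j][a]]): int(c) for a, c in enumerate(counts) if c > 0
        }

    def singleton_flags(self) -> np.ndarray:
        """True for sites carrying at least one allele of multiplicity 1."""
        flags = np.zeros(self.n_sites, dtype=bool)
        for j in range(self.n_sites):
            col = self.genotypes[:, j]
            counts = np.bincount(col[col >= 0])
            flags[j] = bool(np.any(counts == 1))
        return flags


def read_sample_map(path: str | Path) -> list[SampleRecord]:
    """Read a TSV ``sample_id  population  species`` (header optional)."""
    records: list[SampleRecord] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0].lower() in ("sample_id", "sample"):
            continue
        if len(parts) < 3:
            raise ValueError(f"sample map line needs 3 columns: {line!r}")
        records.append(SampleRecord(parts[0], parts[1], parts[2]))
    return records


def read_locus_config(path: str | Path) -> list[LocusSpec]:
    """Read a TSV ``locus  length  coding_intervals  outgroup_id``.

    ``coding_intervals`` is ``start-end:frame`` triples joined by ``;`` or
    ``.`` for none; ``outgroup_id`` may be ``.``.
    """
    specs: list[LocusSpec] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0].lower() in ("locus", "locus_name"):
            continue
        name, length = parts[0], int(parts[1])
        intervals: list[tuple[int, int, int]] = []
        if len(parts) > 2 and parts[2] not in (".", ""):
            for chunk in parts[2].split(";"):
                span, _, frame = chunk.partition(":")
                start, _, end = span.partition("-")
                intervals.append((int(start), int(end), int(frame or 0)))
        outgroup = parts[3] if len(parts) > 3 and parts[3] not in (".", "") else None
        specs.append(LocusSpec(name, length, intervals, outgroup))
    return specs


def _clean(seq: str, length: int, name: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype="u1").copy()
    if arr.size != length:
        raise ValueError(
            f"record {name!r}: sequence length {arr.size} != expected {length}"
        )
    known = np.isin(arr, np.frombuffer(ALPHABET, dtype="u1"))
    arr[~known] = MISSING
    return arr.view("S1")


def read_fasta_locus(
    path: str | Path,
    locus_spec: LocusSpec,
    sample_map: list[SampleRecord],
) -> LocusAlignment:
    """Read one locus FASTA into an alignment, grouping rows by sample."""
    by_id = {s.sample_id: s for s in sample_map}
    per_sample: dict[str, dict[int, np.ndarray]] = {}
    outgroup: np.ndarray | None = None
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        seq = _clean(str(rec.seq), locus_spec.length_bp, header)
        if locus_spec.outgroup_id is not None and header == locus_spec.outgroup_id:
            outgroup = seq
            continue
        sample_id, _, idx = header.rpartition("_")
        if not sample_id or not idx.isdigit():
            raise ValueError(
                f"header {header!r} does not match '<sample_id>_<allele_index>'"
            )
        if sample_id not in by_id:
            raise ValueError(
                f"sample {sample_id!r} in {path} is absent from the sample map"
            )
        per_sample.setdefault(sample_id, {})[int(idx)] = seq
    rows: list[np.ndarray] = []
    ids: list[tuple[str, int]] = []
    for s in sample_map:
        alleles = per_sample.pop(s.sample_id, None)
        if alleles is None:
            continue
        if sorted(alleles) != list(range(1, s.ploidy + 1)):
            raise ValueError(
                f"sample {s.sample_id!r}: expected allele indices "
                f"1..{s.ploidy}, got {sorted(alleles)}"
            )
        for k in range(1, s.ploidy + 1):
            rows.append(alleles[k])
            ids.append((s.sample_id, k))
    if not rows:
        raise ValueError(f"no ingroup sequences found in {path}")
    return LocusAlignment(locus_spec, np.vstack(rows), ids, outgroup)


def write_fasta_locus(aln: LocusAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(aln.haplotypes[i].tobytes().decode("ascii")),
            id=f"{sid}_{idx}",
            description="",
        )
        for i, (sid, idx) in enumerate(aln.sequence_ids)
    ]
    if aln.outgroup is not None:
        og_id = aln.locus.outgroup_id or "outgroup"
        records.append(
            SeqRecord(Seq(aln.outgroup.tobytes().decode("ascii")), id=og_id, description="")
        )
    SeqIO.write(records, str(path), "fasta")


def read_dataset(
    fasta_dir: str | Path,
    sample_map_path: str | Path,
    locus_config_path: str | Path,
) -> MultiLocusDataset:
    """Read ``<fasta_dir>/<locus>.fasta`` for every configured locus."""
    samples = read_sample_map(sample_map_path)
    specs = read_locus_config(locus_config_path)
    alignments = [
        read_fasta_locus(Path(fasta_dir) / f"{spec.locus_name}.fasta", spec, samples)
        for spec in specs
    ]
    return MultiLocusDataset(samples, alignments)


def write_dataset(ds: MultiLocusDataset, out_dir: str | Path) -> list[Path]:
    """Write one FASTA per locus plus sample map and locus config TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for aln in ds.alignments:
        p = out / f"{aln.locus.locus_name}.fasta"
        write_fasta_locus(aln, p)
        written.append(p)
    smap = out / "samples.tsv"
    smap.write_text(
        "sample_id\tpopulation\tspecies\n"
        + "".join(
            f"{s.sample_id}\t{s.population_code}\t{s.species_label}\n"
            for s in ds.samples
        )
    )
    written.append(smap)
    lconf = out / "loci.tsv"
    lines = ["locus\tlength\tcoding_intervals\toutgroup_id\n"]
    for aln in ds.alignments:
        spec = aln.locus
        ivals = (
            ";".join(f"{a}-{b}:{f}" for a, b, f in spec.coding_intervals)
            if spec.coding_intervals
            else "."
        )
        og = spec.outgroup_id or ("outgroup" if aln.outgroup is not None else ".")
        lines.append(f"{spec.locus_name}\t{spec.length_bp}\t{ivals}\t{og}\n")
    lconf.write_text("".join(lines))
    written.append(lconf)
    return written


def build_site_table(aln: LocusAlignment, missing: str = "complete") -> SiteTable:
    """Tabulate the variable non-indel columns of an alignment.

    Columns with a gap in any ingroup row are flagged as indel columns and
    excluded from every downstream statistic.  Under ``missing="complete"``
    (default) columns containing ``N`` in any ingroup row are excluded as
    well; under ``"pairwise"`` they are kept with per-sequence missing codes.
    The ancestral allele of a site is taken from the outgroup when present,
    non-gap, and segregating in the ingroup; otherwise it is unknown.
    """
    if missing not in ("complete", "pairwise"):
        raise ValueError("missing must be 'complete' or 'pairwise'")
    H = aln.haplotypes.view("u1")
    if H.shape[0] == 0:
        raise ValueError("empty alignment")
    n, L = H.shape
    indel_cols = (H == GAP).any(axis=0)
    miss_cols = (H == MISSING).any(axis=0)
    if missing == "complete":
        included = ~indel_cols & ~miss_cols
    else:
        included = ~indel_cols
    silent_full = aln.locus.silent_site_mask(
        reference=aln.haplotypes[0] if aln.locus.coding_intervals else None
    )
    # variable among included columns
    positions: list[int] = []
    genos: list[np.ndarray] = []
    alleles: list[bytes] = []
    ancestral: list[int] = []
    silent: list[bool] = []
    cand = np.flatnonzero(included & (H != H[0]).any(axis=0))
    og = aln.outgroup.view("u1") if aln.outgroup is not None else None
    for c in cand:
        col = H[:, c]
        obs = col[col != MISSING]
        uniq = np.unique(obs)
        if uniq.size < 2:
            continue
        code = np.full(n, -9, dtype=np.int8)
        for a, b in enumerate(uniq):
            code[col == b] = a
        anc = -1
        if og is not None and og[c] != GAP and og[c] != MISSING:
            hit = np.flatnonzero(uniq == og[c])
            if hit.size:
                anc = int(hit[0])
        positions.append(c + 1)
        genos.append(code)
        alleles.append(uniq.tobytes())
        ancestral.append(anc)
        silent.append(bool(silent_full[c]))
    G = (
        np.stack(genos, axis=1)
        if genos
        else np.zeros((n, 0), dtype=np.int8)
    )
    return SiteTable(
        n_seq=n,
        length_included=int(included.sum()),
        length_silent=int((included & silent_full).sum()),
        positions=np.asarray(positions, dtype=int),
        genotypes=G,
        alleles=alleles,
        ancestral=np.asarray(ancestral, dtype=int),
        silent=np.asarray(silent, dtype=bool),
        indel_positions=np.flatnonzero(indel_cols) + 1,
        missing_mode=missing,
    )


@dataclass
class ValidationReport:
    n_loci: int
    species_sequence_counts: dict[str, int]
    violations: list[str]
    hard: bool

    @property
    def ok(self) -> bool:
        return not self.hard

    def __str__(self) -> str:
        counts = " + ".join(
            f"{v}" for v in self.species_sequence_counts.values()
        )
        status = "OK" if self.ok else "; ".join(self.violations)
        return (
            f"{self.n_loci} loci, {len(self.species_sequence_counts)} species, "
            f"{counts} sequences, {status}"
        )


def validate_dataset(ds: MultiLocusDataset, two_population: bool = True) -> ValidationReport:
    """Structural validation; returns a report, never raises on content."""
    violations: list[str] = []
    hard = False
    ids = [s.sample_id for s in ds.samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        violations.append(f"duplicate sample_id(s): {dupes}")
        hard = True
    names = [a.locus.locus_name for a in ds.alignments]
    if len(set(names)) != len(names):
        violations.append("duplicate locus names")
        hard = True
    species = ds.species_labels
    if two_population and len(species) != 2:
        violations.append(
            f"two-population analyses need exactly 2 species labels, got {len(species)}"
        )
        hard = True
    counts: dict[str, int] = {sp: 0 for sp in species}
    ploidy = {s.sample_id: s.ploidy for s in ds.samples}
    for aln in ds.alignments:
        per: dict[str, int] = {}
        for sid, _ in aln.sequence_ids:
            per[sid] = per.get(sid, 0) + 1
        for sid, k in per.items():
            if sid not in ploidy:
                violations.append(
                    f"locus {aln.locus.locus_name}: sequence for unknown sample {sid!r}"
                )
                hard = True
            elif k != ploidy[sid]:
                violations.append(
                    f"locus {aln.locus.locus_name}: sample {sid!r} contributes "
                    f"{k} rows, expected {ploidy[sid]}"
                )
                hard = True
    if ds.alignments:
        first = ds.alignments[0]
        for sp in species:
            sids = ds.sample_ids_for_species(sp)
            counts[sp] = int(
                sum(1 for sid, _ in first.sequence_ids if sid in sids)
            )
    return ValidationReport(len(ds.alignments), counts, violations, hard)
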