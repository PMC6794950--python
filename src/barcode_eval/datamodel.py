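"""Core data structures and I/O for species-labelled barcode alignments.

The central objects are :class:`BarcodeRecord` (one aligned sequence with its
species, sample and locus identity), :class:`LocusAlignment` (a rectangular
collection of records for one locus or a concatenation), and
:class:`SpeciesMap` (the species -> samples partition with singleton flags).

FASTA headers follow the ``Genus_species|sample_id`` scheme by default; the
delimiter is configurable. Multi-locus datasets are assembled by per-sample
concatenation, dropping samples that lack any member locus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# IUPAC nucleotide codes plus alignment gap '-' and missing '?'.
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")
ALLOWED_CHARS = IUPAC_CODES | frozenset("-?")

DEFAULT_DELIMITER = "|"


class BarcodeError(Exception):
    """Base class for all errors raised by this package."""


class AlignmentError(BarcodeError):
    """Ragged or otherwise malformed alignment."""


class HeaderFormatError(BarcodeError):
    """FASTA header does not parse under the label scheme."""


class InputError(BarcodeError):
    """Empty or inconsistent input data."""


class UsageError(BarcodeError):
    """Invalid arguments (e.g. a locus combination of size < 2)."""


@dataclass(frozen=True)
class BarcodeRecord:
    """One aligned barcode sequence with its identity triple."""

    sample_id: str
    species: str
    locus: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"empty sequence for sample {self.sample_id!r}")
        if not self.species:
            raise HeaderFormatError(
                f"empty species label for sample {self.sample_id!r}"
            )
        seq = self.sequence.upper()
        bad = set(seq) - ALLOWED_CHARS
        if bad:
            raise InputError(
                f"sample {self.sample_id!r}: illegal characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def label(self) -> str:
        return f"{self.species}{DEFAULT_DELIMITER}{self.sample_id}"

    @property
    def ungapped_length(self) -> int:
        return sum(1 for c in self.sequence if c not in "-?")


class LocusAlignment:
    """A rectangular set of :class:`BarcodeRecord` for one locus.

    Records keep their input order. ``(sample_id, locus)`` must be unique.
    """

    def __init__(self, locus: str, records: Sequence[BarcodeRecord]):
        records = list(records)
        if not records:
            raise InputError(f"locus {locus!r}: no records")
        length = len(records[0].sequence)
        for rec in records:
            if len(rec.sequence) != length:
                raise AlignmentError(
                    f"locus {locus!r}: record {rec.sample_id!r} has length "
                    f"{len(rec.sequence)}, expected {length}"
                )
        seen: set[str] = set()
        for rec in records:
            if rec.sample_id in seen:
                raise InputError(
                    f"locus {locus!r}: duplicate sample_id {rec.sample_id!r}"
                )
            seen.add(rec.sample_id)
        self.locus = locus
        self.records = records
        self.aligned_length = length

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def species_of(self) -> dict[str, str]:
        return {r.sample_id: r.species for r in self.records}

    def record_for(self, sample_id: str) -> BarcodeRecord:
        for rec in self.records:
            if rec.sample_id == sample_id:
                return rec
        raise InputError(f"sample {sample_id!r} not in alignment {self.locus!r}")

    def subset(self, sample_ids: Iterable[str]) -> "LocusAlignment":
        """Restrict to the given samples, keeping record order."""
        keep = set(sample_ids)
        recs = [r for r in self.records if r.sample_id in keep]
        return LocusAlignment(self.locus, recs)


@dataclass(frozen=True)
class SpeciesMap:
    """Disjoint cover of the dataset's samples by species."""

    mapping: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        all_samples: set[str] = set()
        for sp, samples in self.mapping.items():
            if not samples:
                raise InputError(f"species {sp!r} has no samples")
            if all_samples & samples:
                raise InputError(f"species {sp!r} shares samples with another")
            all_samples |= samples

    @property
    def species(self) -> list[str]:
        return sorted(self.mapping)

    @property
    def samples(self) -> frozenset[str]:
        return frozenset().union(*self.mapping.values())

    @property
    def singletons(self) -> frozenset[str]:
        return frozenset(sp for sp, s in self.mapping.items() if len(s) == 1)

    def is_singleton(self, species: str) -> bool:
        return len(self.mapping[species]) == 1

    def species_for(self, sample_id: str) -> str:
        for sp, samples in self.mapping.items():
            if sample_id in samples:
                return sp
        raise InputError(f"sample {sample_id!r} not in species map")

    def eligible_samples(self) -> frozenset[str]:
        """Samples of species with >= 2 individuals (singletons excluded)."""
        out: set[str] = set()
        for sp, samples in self.mapping.items():
            if len(samples) >= 2:
                out |= samples
        return frozenset(out)


def parse_header(header: str, delimiter: str = DEFAULT_DELIMITER) -> tuple[str, str]:
    """Split ``Genus_species|sample_id`` into (species, sample_id)."""
    head = header.split()[0] if header.split() else ""
    if delimiter not in head:
        raise HeaderFormatError(
            f"header {header!r} lacks delimiter {delimiter!r}"
        )
    species, _, sample_id = head.rpartition(delimiter)
    if not species or not sample_id:
        raise HeaderFormatError(f"header {header!r} does not parse")
    return species, sample_id


def read_locus_fasta(
    path: str | Path,
    locus: str | None = None,
    delimiter: str = DEFAULT_DELIMITER,
) -> LocusAlignment:
    """Read one aligned FASTA file into a :class:`LocusAlignment`.

    Header order is preserved; lowercase bases are normalised to uppercase.
    The locus name defaults to the file stem.
    """
    path = Path(path)
    if locus is None:
        locus = path.stem
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        species, sample_id = parse_header(rec.description, delimiter)
        records.append(
            BarcodeRecord(
                sample_id=sample_id,
                species=species,
                locus=locus,
                sequence=str(rec.seq),
            )
        )
    if not records:
        raise InputError(f"{path}: no FASTA records")
    return LocusAlignment(locus, records)


def write_locus_fasta(
    alignment: LocusAlignment,
    path: str | Path,
    delimiter: str = DEFAULT_DELIMITER,
) -> None:
    """Write the alignment back to FASTA, one record per sample, in order."""
    seqs = [
        SeqRecord(
            Seq(rec.sequence),
            id=f"{rec.species}{delimiter}{rec.sample_id}",
            description="",
        )
        for rec in alignment.records
    ]
    SeqIO.write(seqs, str(Path(path)), "fasta-2line")


def build_species_map(
    alignment: LocusAlignment, outgroups: Iterable[str] = ()
) -> SpeciesMap:
    """Species -> sample-set partition of the alignment's ingroup samples.

    ``outgroups`` may list species names or sample ids to exclude.
    """
    out = set(outgroups)
    mapping: dict[str, set[str]] = {}
    for rec in alignment.records:
        if rec.species in out or rec.sample_id in out:
            continue
        mapping.setdefault(rec.species, set()).add(rec.sample_id)
    if not mapping:
        raise InputError("no ingroup samples in alignment")
    return SpeciesMap({sp: frozenset(s) for sp, s in mapping.items()})


def enumerate_combinations(locus_names: Iterable[str]) -> list[tuple[str, ...]]:
    """All locus subsets of size >= 2, ordered by size then lexicographically.

    Four loci yield the familiar eleven multi-locus barcodes
    (C(4,2) + C(4,3) + C(4,4) = 11).
    """
    names = sorted(set(locus_names))
    if not 2 <= len(names) <= 8:
        raise UsageError(f"need 2-8 loci, got {len(names)}")
    combos: list[tuple[str, ...]] = []
    for size in range(2, len(names) + 1):
        combos.extend(itertools.combinations(names, size))
    return combos


@dataclass
class ConcatenationResult:
    alignment: LocusAlignment
    partition: dict[str, tuple[int, int]]  # locus -> half-open column interval
    dropped: list[str] = field(default_factory=list)


def concatenate(
    loci: Mapping[str, LocusAlignment] | Sequence[LocusAlignment],
    combo: Iterable[str],
) -> ConcatenationResult:
    """Concatenate the named loci sample-wise, in the given locus order.

    Samples missing any member locus are dropped (and listed in the result);
    the partition record gives each locus's 0-based half-open column interval.
    """
    if not isinstance(loci, Mapping):
        loci = {aln.locus: aln for aln in loci}
    combo = list(combo)
    if len(combo) < 2:
        raise UsageError("a combination needs at least 2 loci")
    missing = [name for name in combo if name not in loci]
    if missing:
        raise UsageError(f"loci not in dataset: {missing}")
    members = [loci[name] for name in combo]
    shared = set(members[0].sample_ids)
    for aln in members[1:]:
        shared &= set(aln.sample_ids)
    all_samples = set().union(*(aln.sample_ids for aln in members))
    dropped = sorted(all_samples - shared)
    if not shared:
        raise InputError(f"no sample has all of {combo}")

    partition: dict[str, tuple[int, int]] = {}
    offset = 0
    for aln in members:
        partition[aln.locus] = (offset, offset + aln.aligned_length)
        offset += aln.aligned_length

    order = [s for s in members[0].sample_ids if s in shared]
    species_of = members[0].species_of
    records = []
    for sample in order:
        seq = "".join(aln.record_for(sample).sequence for aln in members)
        records.append(
            BarcodeRecord(
                sample_id=sample,
                species=species_of[sample],
                locus="+".join(combo),
                sequence=seq,
            )
        )
    return ConcatenationResult(
        alignment=LocusAlignment("+".join(combo), records),
        partition=partition,
        dropped=dropped,
    )


def write_partition_file(
    partition: Mapping[str, tuple[int, int]], path: str | Path
) -> None:
    """Tab-separated partition table: locus, start, end (0-based, half-open)."""
    with open(path, "w") as fh:
        fh.write("locus\tstart\tend\n")
        for locus, (start, end) in partition.items():
            fh.write(f"{locus}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Bundled voucher table (printed sampling design of the Pulsatilla study)
# ---------------------------------------------------------------------------

VOUCHER_LOCI = ("matK", "rbcL", "trnH_psbA", "ITS")


def load_voucher_table() -> pd.DataFrame:
    """The study's printed voucher table as a DataFrame.

    Columns: species, sample_id, group (ingroup/outgroup), and one GenBank
    accession column per locus ('-' where the locus was not obtained).
    """
    with resources.files("barcode_eval.data").joinpath(
        "pulsatilla_vouchers.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


@dataclass(frozen=True)
class SamplingStructure:
    n_species: int
    n_singletons: int
    n_samples_per_locus: dict[str, int]
    species_map: SpeciesMap


def voucher_sampling_structure(table: pd.DataFrame | None = None) -> SamplingStructure:
    """Recover the ingroup sampling design from the voucher table.

    Counts species, singleton species and per-locus sequenced individuals,
    ignoring outgroup rows.
    """
    if table is None:
        table = load_voucher_table()
    ingroup = table[table["group"] == "ingroup"]
    mapping: dict[str, set[str]] = {}
    for _, row in ingroup.iterrows():
        mapping.setdefault(row["species"], set()).add(row["sample_id"])
    smap = SpeciesMap({sp: frozenset(s) for sp, s in mapping.items()})
    per_locus = {
        locus: int((ingroup[locus] != "-").sum()) for locus in VOUCHER_LOCI
    }
    return SamplingStructure(
        n_species=len(mapping),
        n_singletons=len(smap.singletons),
        n_samples_per_locus=per_locus,
        species_map=smap,
    )
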