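"""Reference genomes, genomic intervals, target sets and bait pools.

Coordinates follow a half-open convention: an interval ``(start, end)``
covers bases ``start .. end-1`` and has length ``end - start``.  Locus
coordinates quoted in the hybrid-capture literature as ``nt. s - e`` are
stored with ``start = s`` and ``end = e``, which makes the quoted locus
length equal ``e - s`` (e.g. the 1317-bp phage Lambda target at
41053-42370).  BED files use the BED standard unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = set("ACGTN")

__all__ = [
    "Genome",
    "GenomicInterval",
    "TargetSet",
    "Bait",
    "BaitPool",
    "interval_from_coords",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "tile_baits",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a named reference sequence."""

    ref: str
    start: int
    end: int
    strand: str = "."  # '+', '-' or '.' (unstranded)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.ref}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval {self.ref}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of bases shared with *other* (0 if different references)."""
        if self.ref != other.ref:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:
        return f"{self.ref}:{self.start}-{self.end}"


def interval_from_coords(ref: str, s: int, e: int) -> GenomicInterval:
    """Build an interval from literature-style ``nt. s - e`` coordinates.

    The stored interval is ``(start=s, end=e)`` so that ``length() == e - s``,
    the convention under which every published locus length in the study
    system (rrn operons, tRNA genes, the Lambda target) is reproduced.
    """
    if s < 0 or e <= s:
        raise ValueError(f"require e > s >= 0, got s={s}, e={e}")
    return GenomicInterval(ref, s, e)


class Genome:
    """An ordered collection of named uppercase A/C/G/T/N sequences."""

    def __init__(self, records: Iterable[tuple[str, str]]):
        self._names: list[str] = []
        self._seqs: dict[str, str] = {}
        for name, seq in records:
            if not name:
                raise ValueError("empty record name")
            if name in self._seqs:
                raise ValueError(f"duplicate record name {name!r}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence for record {name!r}")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"record {name!r} contains invalid characters {sorted(bad)}"
                )
            self._names.append(name)
            self._seqs[name] = seq

    @property
    def names(self) -> list[str]:
        return list(self._names)

    @property
    def records(self) -> list[tuple[str, str]]:
        return [(n, self._seqs[n]) for n in self._names]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __len__(self) -> int:
        return len(self._names)

    def sequence(self, name: str) -> str:
        if name not in self._seqs:
            raise KeyError(f"unknown reference {name!r}")
        return self._seqs[name]

    def length(self, name: str) -> int:
        return len(self.sequence(name))

    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self._seqs.items()}

    def fetch(self, interval: GenomicInterval) -> str:
        """Subsequence covered by *interval*; bounds-checked."""
        seq = self.sequence(interval.ref)
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval} exceeds reference length {len(seq)}"
            )
        return seq[interval.start : interval.end]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self.records == other.records


@dataclass
class TargetSet:
    """Named target loci, with optional exclusion regions (e.g. the
    spiked-in sequencing control, which is removed from all comparative
    statistics)."""

    loci: list[tuple[str, GenomicInterval]]
    exclusions: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names")

    def names(self) -> list[str]:
        return [n for n, _ in self.loci]

    def intervals(self) -> list[GenomicInterval]:
        return [iv for _, iv in self.loci]

    def total_length(self) -> int:
        return sum(iv.length() for iv in self.intervals())


@dataclass(frozen=True)
class Bait:
    interval: GenomicInterval
    sequence: str
    pool_class: str = "custom"  # S / M / L / custom

    @property
    def has_ambiguous(self) -> bool:
        return "N" in self.sequence


@dataclass
class BaitPool:
    baits: list[Bait]
    overlap_bp: int = 0
    # relative capture efficiency of this pool; the study system quantifies
    # only qualitative differences between bait length classes, so this is
    # an optional multiplier with neutral default
    efficiency: float = 1.0

    def __len__(self) -> int:
        return len(self.baits)

    def intervals(self) -> list[GenomicInterval]:
        return [b.interval for b in self.baits]


# ---------------------------------------------------------------------------
# FASTA I/O (Bio.SeqIO backed)

def read_fasta(path: str | Path) -> Genome:
    """Load a (multi-)FASTA file into a :class:`Genome`.

    Lowercase is normalised to uppercase; duplicate headers and non-ACGTN
    characters are rejected.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(records)


def write_fasta(path: str | Path, genome: Genome, width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# BED I/O (BED3/BED6, 0-based half-open)

def read_bed(path: str | Path, genome: Genome | None = None) -> TargetSet:
    """Read a BED3/BED6 file as a :class:`TargetSet`.

    The name column (when present) becomes the locus name; unnamed
    intervals are named ``locus_<i>``.  When *genome* is given, intervals
    are bounds-checked against it.
    """
    loci: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, s_raw, e_raw = fields[0], fields[1], fields[2]
            try:
                start, end = int(s_raw), int(e_raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative chromStart {start}")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: chromEnd {end} <= chromStart {start}")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else f"locus_{len(loci) + 1}"
            iv = GenomicInterval(chrom, start, end, strand)
            if genome is not None:
                genome.fetch(iv)  # bounds/reference check
            loci.append((name, iv))
    return TargetSet(loci)


def write_bed(path: str | Path, targets: TargetSet) -> None:
    with open(path, "w") as fh:
        for name, iv in targets.loci:
            fh.write(f"{iv.ref}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Bait tiling

_CLASS_BY_LENGTH = {242: "S", 460: "M", 884: "L"}


def tile_baits(
    genome: Genome,
    target: GenomicInterval,
    bait_len: int,
    overlap_bp: int = 20,
) -> BaitPool:
    """Tile uniform-length baits across *target* with a fixed overlap.

    Baits are placed at step ``bait_len - overlap_bp`` starting at
    ``target.start``; the final bait is clipped to ``target.end`` so the
    union of baits covers the target with no gaps.  The bait count is
    ``ceil((target_length - bait_len)/step) + 1``; for the 1317-bp Lambda
    target this yields 6, 3 and 2 baits at nominal lengths 242, 460 and
    884 bp — the short/medium/long PCR-bait pools of the study system.
    """
    if bait_len < overlap_bp + 1:
        raise ValueError(f"bait_len {bait_len} must exceed overlap {overlap_bp}")
    tlen = target.length()
    if bait_len > tlen:
        raise ValueError(
            f"bait_len {bait_len} exceeds target length {tlen}; "
            "use a single full-length bait instead"
        )
    pool_class = _CLASS_BY_LENGTH.get(bait_len, "custom")
    step = bait_len - overlap_bp
    n = math.ceil((tlen - bait_len) / step) + 1
    baits = []
    for i in range(n):
        start = target.start + i * step
        end = min(start + bait_len, target.end)
        iv = GenomicInterval(target.ref, start, end)
        baits.append(Bait(iv, genome.fetch(iv), pool_class))
    return BaitPool(baits, overlap_bp=overlap_bp)
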