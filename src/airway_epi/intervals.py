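"""Genomic-interval data model and flat-file readers/writers.

All coordinates are 0-based half-open (BED convention). The types here are
the currency of the whole ATAC arm of the pipeline: peaks, fragments, TSS
annotations, chromosome sizes, and position-weight matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_EXCLUDED_CHROMS = frozenset({"chrY", "chrM"})


class BedParseError(ValueError):
    """Raised when a BED-like file cannot be parsed."""


class IntervalValidationError(ValueError):
    """Raised when interval coordinates violate the half-open invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise IntervalValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Fragment:
    """A sequenced fragment; coordinates as GenomicInterval, plus provenance."""

    chrom: str
    start: int
    end: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise IntervalValidationError(
                f"invalid fragment {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class TSSRecord:
    """Transcription start site of one gene (0-based position, strand-aware)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"negative TSS position for {self.gene_id}")


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp."""

    def __init__(self, sizes: Dict[str, int]):
        for name, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        super().__init__(sizes)

    def validate(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self:
            raise IntervalValidationError(f"unknown chromosome {interval.chrom}")
        if interval.end > self[interval.chrom]:
            raise IntervalValidationError(
                f"{interval.chrom}:{interval.start}-{interval.end} exceeds "
                f"chromosome length {self[interval.chrom]}"
            )


@dataclass
class PWM:
    """Position-weight matrix: per-position probabilities over A, C, G, T."""

    motif_id: str
    matrix: np.ndarray  # shape (L, 4)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.motif_id}: rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.motif_id}: background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


# ---------------------------------------------------------------------------
# Readers / writers


def read_bed(path) -> List[GenomicInterval]:
    """Parse a BED3/BED4(+score) file into intervals, preserving file order."""
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 0:
                raise BedParseError(f"{path}: line {lineno}: negative coordinate")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score))
            except IntervalValidationError as exc:
                raise IntervalValidationError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(repr(iv.score))
            fh.write("\t".join(fields) + "\n")


def read_fragments(path, sample_id: str = "") -> List[Fragment]:
    """Read a fragment file (BED-like chrom/start/end) for one sample."""
    return [
        Fragment(iv.chrom, iv.start, iv.end, sample_id) for iv in read_bed(path)
    ]


def write_fragments(fragments: Iterable[Fragment], path) -> None:
    with open(path, "w") as fh:
        for fr in fragments:
            fh.write(f"{fr.chrom}\t{fr.start}\t{fr.end}\n")


def read_chrom_sizes(path) -> ChromSizes:
    """Two-column text: chromosome name, length."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(f"{path}: line {lineno}: need name and length")
            name = fields[0]
            if name in sizes:
                raise ValueError(f"{path}: duplicate chromosome {name}")
            sizes[name] = int(fields[1])
    return ChromSizes(sizes)


def write_chrom_sizes(sizes: ChromSizes, path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_tss_table(path) -> List[TSSRecord]:
    """Four-column TSV: gene_id, chrom, strand, tss (0-based)."""
    records: List[TSSRecord] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}: line {lineno}: need 4 columns")
            gene_id = fields[0]
            if gene_id in seen:
                raise ValueError(f"{path}: duplicate gene_id {gene_id}")
            seen.add(gene_id)
            records.append(TSSRecord(gene_id, fields[1], fields[2], int(fields[3])))
    return records


def write_tss_table(records: Iterable[TSSRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.chrom}\t{r.strand}\t{r.tss}\n")


def read_fasta(path) -> Dict[str, str]:
    """Genome FASTA -> dict chrom -> sequence string (case preserved)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Dict[str, str], path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_pwms(path) -> List[PWM]:
    """PWM library as JSON: [{motif_id, matrix (Lx4), background (4)}]."""
    with open(path) as fh:
        data = json.load(fh)
    return [
        PWM(
            motif_id=entry["motif_id"],
            matrix=np.asarray(entry["matrix"], dtype=float),
            background=np.asarray(entry.get("background", [0.25] * 4), dtype=float),
        )
        for entry in data
    ]


def write_pwms(pwms: Sequence[PWM], path) -> None:
    data = [
        {
            "motif_id": p.motif_id,
            "matrix": p.matrix.tolist(),
            "background": p.background.tolist(),
        }
        for p in pwms
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


# ---------------------------------------------------------------------------
# Interval operations


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff a and b share >= 1 bp (same chromosome, half-open)."""
    return a.overlaps(b)


def filter_chromosomes(items, excluded=DEFAULT_EXCLUDED_CHROMS):
    """Drop intervals/fragments on excluded chromosomes (default chrY, chrM).

    Mirrors the manual removal of Y-chromosome and mitochondrial reads before
    any downstream ATAC step. Order is preserved; matching is exact-string.
    """
    excluded = set(excluded)
    return [item for item in items if item.chrom not in excluded]
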