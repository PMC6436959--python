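"""Coordinate conventions, sequence extraction, and standard-format I/O.

All internal coordinates are 0-based half-open; the only off-by-one
conversions happen at the I/O boundary (GFF3 is 1-based closed on disk).
Strand-aware windows and sequence extraction are the primitives every
downstream module (motif scanning, Tm profiles, precursor selection) builds
on, so the conventions here are deliberately rigid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """Raised for malformed records in FASTA/BED/GFF3/TSV inputs."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    ``start`` is inclusive, ``end`` exclusive; ``strand`` is ``'+'``, ``'-'``
    or ``'.'`` for unstranded features.
    """

    contig: str
    start: int
    end: int
    strand: str = "."
    name: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise FormatError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Position of the 5' end (strand-aware; '-' uses end - 1)."""
        if self.strand == "-":
            return self.end - 1
        return self.start

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.contig, self.start + offset, self.end + offset,
            self.strand, self.name,
        )


@dataclass(frozen=True)
class ReadSite:
    """A mapped small-RNA read site with count and chemistry metadata."""

    interval: GenomicInterval
    count: int = 1
    chemistry: str = "unknown"  # {capped, monophosphate, unknown}
    unique_mapping: bool = True

    def __post_init__(self) -> None:
        if self.count < 0:
            raise FormatError("read count must be non-negative")

    @property
    def length(self) -> int:
        return len(self.interval)


class Genome:
    """A set of named contig sequences (A/C/G/T/N, uppercase on access)."""

    def __init__(self, contigs: dict[str, str]):
        self._contigs = {name: seq.upper() for name, seq in contigs.items()}
        self.lengths = {name: len(seq) for name, seq in self._contigs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def __iter__(self) -> Iterator[str]:
        return iter(self._contigs)

    def __len__(self) -> int:
        return len(self._contigs)

    def sequence(self, name: str) -> str:
        if name not in self._contigs:
            raise KeyError(f"unknown contig {name!r}")
        return self._contigs[name]

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def gc_fraction(self) -> float:
        gc = sum(s.count("G") + s.count("C") for s in self._contigs.values())
        acgt = sum(
            len(s) - s.count("N") for s in self._contigs.values()
        )
        return gc / acgt if acgt else 0.0

    def base_frequencies(self) -> dict[str, float]:
        """Genome-wide A/C/G/T frequencies over non-N positions."""
        counts = {b: 0 for b in "ACGT"}
        for seq in self._contigs.values():
            for b in "ACGT":
                counts[b] += seq.count(b)
        total = sum(counts.values())
        if total == 0:
            return {b: 0.25 for b in "ACGT"}
        return {b: c / total for b, c in counts.items()}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> Genome:
    """Load a FASTA file into a :class:`Genome`.

    Duplicate record names are an error; an empty file yields an empty
    genome with a logged warning.
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise FormatError(f"duplicate contig name {record.id!r} in {path}")
        contigs[record.id] = str(record.seq)
    if not contigs:
        logger.warning("FASTA file %s contains no records", path)
    return Genome(contigs)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            seq = genome.sequence(name)
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_intervals(
    path: str | Path, fmt: str = "BED"
) -> list[GenomicInterval]:
    """Read BED or GFF3 intervals into internal 0-based half-open coordinates.

    BED is consumed as-is (already 0-based half-open); GFF3 start is shifted
    by -1 (1-based closed on disk). For GFF3 the ``name`` attribute is taken
    from ``ID=`` when present, else the feature type.
    """
    fmt = fmt.upper()
    if fmt not in ("BED", "GFF3"):
        raise ValueError(f"unsupported interval format {fmt!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "BED":
                    contig, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3] if len(fields) > 3 else "."
                    strand = fields[5] if len(fields) > 5 else "."
                else:
                    contig = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    strand = fields[6] if len(fields) > 6 else "."
                    name = fields[2]
                    for part in (fields[8] if len(fields) > 8 else "").split(";"):
                        if part.startswith("ID="):
                            name = part[3:]
                out.append(GenomicInterval(contig, start, end, strand, name))
            except (IndexError, ValueError, FormatError) as exc:
                raise FormatError(
                    f"{path}:{lineno}: bad {fmt} record: {exc}"
                ) from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n"
            )


@dataclass
class Window:
    """An upstream/downstream window around a site, with a clipping flag."""

    interval: GenomicInterval
    clipped: bool = False


def upstream_window(
    site: GenomicInterval, up: int, down: int, genome: Genome
) -> Window:
    """Strand-aware window covering ``up`` bp upstream and ``down`` bp
    downstream of the site's 5' end.

    For a + strand site the window is ``[start-up, start+down)``; for a -
    strand site ``[end-down, end+up)``. The window is clipped to contig
    bounds, with ``clipped`` set when clipping occurred.
    """
    if site.strand not in ("+", "-"):
        raise ValueError("upstream_window requires a stranded site")
    length = genome.lengths[site.contig]
    if site.strand == "+":
        lo, hi = site.start - up, site.start + down
    else:
        lo, hi = site.end - down, site.end + up
    clipped = lo < 0 or hi > length
    lo, hi = max(lo, 0), min(hi, length)
    return Window(
        GenomicInterval(site.contig, lo, hi, site.strand, site.name), clipped
    )


def extract_sequence(genome: Genome, interval: GenomicInterval) -> str:
    """Extract the interval sequence; '-' strand returns reverse complement."""
    seq = genome.sequence(interval.contig)
    if interval.end > len(seq):
        raise ValueError(
            f"interval {interval.contig}:{interval.start}-{interval.end} "
            f"exceeds contig length {len(seq)}"
        )
    sub = seq[interval.start : interval.end]
    if interval.strand == "-":
        sub = reverse_complement(sub)
    return sub


def tss_of_21u(site: GenomicInterval) -> int:
    """Transcription start site of a 21U locus: 2 nt upstream of the mature
    21U 5' end, strand-aware (0-based position of the TSS base)."""
    if site.strand == "+":
        return site.start - 2
    if site.strand == "-":
        return site.end - 1 + 2
    raise ValueError("21U site must be stranded")


# --- read-site TSV interface -------------------------------------------------

_READSITE_COLUMNS = [
    "contig", "start", "end", "strand", "length", "count", "chemistry", "unique",
]


def read_sites_tsv(path: str | Path) -> list[ReadSite]:
    """Read a read-site table (TSV with header) into ReadSite records."""
    sites: list[ReadSite] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: header.index(c) for c in _READSITE_COLUMNS if c in header}
        missing = {"contig", "start", "end", "strand", "count"} - set(idx)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                iv = GenomicInterval(
                    f[idx["contig"]], int(f[idx["start"]]), int(f[idx["end"]]),
                    f[idx["strand"]],
                )
                sites.append(
                    ReadSite(
                        iv,
                        count=int(f[idx["count"]]),
                        chemistry=f[idx["chemistry"]] if "chemistry" in idx else "unknown",
                        unique_mapping=(
                            f[idx["unique"]] in ("1", "True", "true")
                            if "unique" in idx else True
                        ),
                    )
                )
            except (IndexError, ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return sites


def write_sites_tsv(sites: Iterable[ReadSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_READSITE_COLUMNS) + "\n")
        for s in sites:
            iv = s.interval
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{s.length}\t{s.count}\t{s.chemistry}\t{int(s.unique_mapping)}\n"
            )
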