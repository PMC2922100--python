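"""TSS-anchored regulatory-region extraction.

Regions span a fixed window around an annotated transcription start site
(default 4500 bp upstream to 500 bp downstream) and are always returned as
the gene-strand (sense) sequence, 5'->3', with the TSS base at a known offset.
Coordinates follow the BED convention: 0-based, half-open.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import pyfaidx

from .pwm import reverse_complement

DEFAULT_UPSTREAM = 4500
DEFAULT_DOWNSTREAM = 500


class BoundaryError(ValueError):
    """Requested region falls outside its contig."""


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str
    score: str
    strand: str


def read_bed6(path: Union[str, Path]) -> list[BedRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split("\t")
            if len(toks) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED fields")
            records.append(
                BedRecord(toks[0], int(toks[1]), int(toks[2]), toks[3], toks[4], toks[5])
            )
    return records


@dataclass
class RegulatoryRegion:
    """A TSS-anchored sense-strand promoter sequence with provenance."""

    gene_id: str
    species: str
    paralog: str
    sequence: str
    contig: str
    start: int  # genomic interval, 0-based half-open
    end: int
    strand: str
    tss_offset: int  # offset of the TSS base inside ``sequence``

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def region_id(self) -> str:
        return f"{self.gene_id}|{self.species}|{self.paralog}"

    def header(self) -> str:
        return (
            f"{self.gene_id}|{self.species}|{self.paralog}|"
            f"{self.contig}:{self.start}-{self.end}({self.strand})"
        )


def _tss_coordinate(rec: BedRecord) -> int:
    if rec.end - rec.start != 1:
        warnings.warn(
            f"BED record {rec.name}: width {rec.end - rec.start} != 1; using the "
            "strand-appropriate end as the TSS",
            stacklevel=2,
        )
        return rec.start if rec.strand == "+" else rec.end - 1
    return rec.start


def extract_region(
    genome: Union[str, Path, pyfaidx.Fasta],
    tss: BedRecord,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    allow_truncation: bool = False,
    species: str = "",
    paralog: str = "",
) -> RegulatoryRegion:
    """Extract the sense-strand region around a TSS.

    Forward strand: genomic interval ``[t - upstream, t + downstream)``.
    Reverse strand: interval ``[t - downstream + 1, t + upstream + 1)``,
    reverse-complemented, so that in both cases the returned sequence reads
    5'->3' on the gene strand with the TSS base at offset ``upstream``.
    """
    if isinstance(genome, (str, Path)):
        genome = pyfaidx.Fasta(str(genome))
    if tss.chrom not in genome:
        raise ValueError(f"contig {tss.chrom!r} not in genome")
    contig_len = len(genome[tss.chrom])
    t = _tss_coordinate(tss)
    if not 0 <= t < contig_len:
        raise BoundaryError(f"gene {tss.name}: TSS {t} outside contig {tss.chrom}")
    if tss.strand not in "+-":
        raise ValueError(f"gene {tss.name}: strand must be '+' or '-'")

    if tss.strand == "+":
        gstart, gend = t - upstream, t + downstream
    else:
        gstart, gend = t - downstream + 1, t + upstream + 1

    if gstart < 0 or gend > contig_len:
        if not allow_truncation:
            raise BoundaryError(
                f"gene {tss.name}: interval [{gstart}, {gend}) exceeds contig "
                f"{tss.chrom} bounds [0, {contig_len})"
            )
        gstart, gend = max(0, gstart), min(contig_len, gend)

    raw = str(genome[tss.chrom][gstart:gend]).upper()
    if tss.strand == "+":
        seq = raw
        tss_offset = t - gstart
    else:
        seq = reverse_complement(raw)
        tss_offset = gend - 1 - t
    return RegulatoryRegion(
        gene_id=tss.name,
        species=species,
        paralog=paralog,
        sequence=seq,
        contig=tss.chrom,
        start=gstart,
        end=gend,
        strand=tss.strand,
        tss_offset=tss_offset,
    )


def extract_regions(
    genome: Union[str, Path, pyfaidx.Fasta],
    bed_path: Union[str, Path],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    allow_truncation: bool = False,
) -> list[RegulatoryRegion]:
    if isinstance(genome, (str, Path)):
        genome = pyfaidx.Fasta(str(genome))
    return [
        extract_region(
            genome,
            rec,
            upstream=upstream,
            downstream=downstream,
            allow_truncation=allow_truncation,
        )
        for rec in read_bed6(bed_path)
    ]


def write_regions_fasta(regions: Iterable[RegulatoryRegion], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f">{r.header()}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")


def read_regions_fasta(path: Union[str, Path]) -> list[RegulatoryRegion]:
    """Read back a regions FASTA written by :func:`write_regions_fasta`.

    The TSS offset is not stored in the file; it is recomputed from the
    interval assuming the standard layout (upstream = length - downstream
    cannot be recovered, so the caller supplies regions of the default shape:
    offset = length - 500 when length > 500, else 0).
    """
    regions: list[RegulatoryRegion] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        m = re.fullmatch(r"([^|]+)\|([^|]*)\|([^|]*)\|(.+):(\d+)-(\d+)\(([+-])\)", header)
        if m is None:
            raise ValueError(f"malformed region header: {header}")
        gene, species, paralog, contig, start, end, strand = m.groups()
        tss_offset = len(seq) - DEFAULT_DOWNSTREAM if len(seq) > DEFAULT_DOWNSTREAM else 0
        regions.append(
            RegulatoryRegion(
                gene_id=gene,
                species=species,
                paralog=paralog,
                sequence=seq,
                contig=contig,
                start=int(start),
                end=int(end),
                strand=strand,
                tss_offset=tss_offset,
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:]
                chunks = []
            elif line:
                chunks.append(line)
    flush()
    return regions
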