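"""Readers and writers for GTF, BED6, BED12, FASTA and sidecar TSV tables.

Every parser converts to the internal 0-based half-open convention exactly
once at the format boundary; writers convert back.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from isocoupler.core import (
    GenomeInterval,
    ReadAlignment,
    SiteRecord,
    TranscriptModel,
    ValidationError,
)

logger = logging.getLogger(__name__)

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


class ParseError(ValueError):
    """Raised on malformed input, naming the offending line."""


# ---------------------------------------------------------------------------
# GTF

def parse_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    GTF coordinates are 1-based closed; they are converted to 0-based
    half-open here. Transcripts with zero exons are skipped with a warning;
    a transcript mixing strands raises :class:`ValidationError`.
    """
    exons: dict[str, list[GenomeInterval]] = {}
    genes: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature != "exon":
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            try:
                tid = attr["transcript_id"]
                gid = attr["gene_id"]
            except KeyError as exc:
                raise ParseError(f"{path}:{lineno}: missing {exc} attribute")
            iv = GenomeInterval(chrom, int(start) - 1, int(end), strand)
            if tid not in exons:
                order.append(tid)
                exons[tid] = []
                genes[tid] = gid
            exons[tid].append(iv)

    models = []
    for tid in order:
        if not exons[tid]:
            logger.warning("transcript %s has zero exons; skipped", tid)
            continue
        strands = {e.strand for e in exons[tid]}
        if len(strands) > 1:
            raise ValidationError(f"transcript {tid} mixes strands")
        models.append(TranscriptModel(tid, genes[tid], exons[tid]))
    return models


def write_gtf(models: Sequence[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            for e in m.exons:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
                fh.write(
                    f"{e.chrom}\tisocoupler\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED6 site databases (name = gene_id:site_id, score = read support)

def parse_sites_bed6(path: str | Path) -> list[SiteRecord]:
    """Read a TSS/PAS database. The single-base feature start is the site
    position (the strand boundary coordinate, see :mod:`isocoupler.core`)."""
    sites = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if not raw.strip() or raw.startswith(("#", "track")):
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start, _end, name, score, strand = f[:6]
            gene_id, _, site_id = name.partition(":")
            if not site_id:
                gene_id, site_id = "", name
            sites.append(
                SiteRecord(
                    chrom=chrom,
                    position=int(start),
                    strand=strand,
                    site_id=site_id,
                    gene_id=gene_id,
                    support=int(float(score)),
                )
            )
    return sites


def write_sites_bed6(sites: Sequence[SiteRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda s: (s.chrom, s.position, s.strand)):
            name = f"{s.gene_id}:{s.site_id}" if s.gene_id else s.site_id
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\t{name}\t"
                f"{s.support}\t{s.strand}\n"
            )


# ---------------------------------------------------------------------------
# BED12 read alignments + poly(A) sidecar TSV

def parse_read_bed12_line(
    line: str, polya_table: Mapping[str, int], lineno: int = 0
) -> ReadAlignment:
    """Parse a single BED12 record into a :class:`ReadAlignment`.

    ``polya_table`` maps read_id to tail length; membership sets the
    has_polya flag. Malformed lines raise :class:`ParseError` with the line
    number; blocks outside [chromStart, chromEnd) raise ValidationError.
    """
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise ParseError(f"line {lineno}: expected 12 BED columns, got {len(f)}")
    chrom, chrom_start, chrom_end, name, _score, strand = f[:6]
    try:
        chrom_start_i, chrom_end_i = int(chrom_start), int(chrom_end)
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}")
    if strand not in ("+", "-"):
        raise ParseError(f"line {lineno}: bad strand {strand!r}")
    if n_blocks < 1 or len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ParseError(f"line {lineno}: blockCount/sizes/starts mismatch")
    blocks = []
    for size, rel in zip(sizes, starts):
        b = GenomeInterval(chrom, chrom_start_i + rel, chrom_start_i + rel + size, strand)
        if b.end > chrom_end_i:
            raise ValidationError(
                f"line {lineno}: block {b.start}-{b.end} exceeds chromEnd"
            )
        blocks.append(b)
    tail = polya_table.get(name)
    return ReadAlignment(
        read_id=name,
        blocks=blocks,
        has_polya=name in polya_table,
        tail_length=tail,
    )


def parse_reads_bed12(
    path: str | Path, polya_table: Optional[Mapping[str, int]] = None
) -> list[ReadAlignment]:
    polya_table = polya_table or {}
    reads = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if not raw.strip() or raw.startswith(("#", "track")):
                continue
            reads.append(parse_read_bed12_line(raw, polya_table, lineno))
    return reads


def write_reads_bed12(reads: Sequence[ReadAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            start = r.blocks[0].start
            end = r.blocks[-1].end
            sizes = ",".join(str(len(b)) for b in r.blocks)
            rels = ",".join(str(b.start - start) for b in r.blocks)
            fh.write(
                f"{r.chrom}\t{start}\t{end}\t{r.read_id}\t0\t{r.strand}\t"
                f"{start}\t{end}\t0,0,0\t{len(r.blocks)}\t{sizes}\t{rels}\n"
            )


def parse_polya_tsv(path: str | Path) -> dict[str, int]:
    """Sidecar table of tailed reads: read_id <tab> tail_length."""
    table: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if not raw.strip() or raw.startswith("read_id"):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            table[parts[0]] = int(parts[1])
    return table


def write_polya_tsv(table: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttail_length\n")
        for rid in sorted(table):
            fh.write(f"{rid}\t{table[rid]}\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) FASTA into memory; order-preserving dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
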