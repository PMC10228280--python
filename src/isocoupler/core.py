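"""Domain types and configuration.

All coordinates are 0-based half-open (BED convention). 5'/3' termini are
strand-aware: on the plus strand the 5' terminus is the interval start and
the 3' terminus the (exclusive) end; on the minus strand the roles flip.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def _check_blocks(blocks: list[GenomeInterval], what: str) -> None:
    if not blocks:
        raise ValidationError(f"{what}: needs at least one block")
    for a, b in zip(blocks, blocks[1:]):
        if b.start < a.end:
            raise ValidationError(
                f"{what}: blocks overlap or are unsorted "
                f"({a.start}-{a.end} then {b.start}-{b.end})"
            )
        if a.chrom != b.chrom or a.strand != b.strand:
            raise ValidationError(f"{what}: blocks mix chromosomes or strands")


@dataclass
class TranscriptModel:
    """A gene-anchored exon chain with strand-aware termini."""

    transcript_id: str
    gene_id: str
    exons: list[GenomeInterval]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        _check_blocks(self.exons, f"transcript {self.transcript_id}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def five_prime(self) -> int:
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end

    @property
    def three_prime(self) -> int:
        return self.exons[-1].end if self.strand == "+" else self.exons[0].start

    @property
    def junctions(self) -> list[tuple[int, int]]:
        """Genomic (donor, acceptor) pairs between adjacent exons."""
        return [
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        ]

    def first_exon(self) -> GenomeInterval:
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    def last_exon(self) -> GenomeInterval:
        return self.exons[-1] if self.strand == "+" else self.exons[0]


@dataclass
class ReadAlignment:
    """One long read's aligned blocks plus poly(A)-tail evidence."""

    read_id: str
    blocks: list[GenomeInterval]
    has_polya: bool = False
    tail_length: Optional[int] = None

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks, key=lambda b: b.start)
        _check_blocks(self.blocks, f"read {self.read_id}")
        if self.tail_length is not None and not self.has_polya:
            raise ValidationError(
                f"read {self.read_id}: tail_length set without has_polya"
            )

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    @property
    def five_prime(self) -> int:
        return self.blocks[0].start if self.strand == "+" else self.blocks[-1].end

    @property
    def three_prime(self) -> int:
        return self.blocks[-1].end if self.strand == "+" else self.blocks[0].start

    @property
    def junctions(self) -> list[tuple[int, int]]:
        return [(a.end, b.start) for a, b in zip(self.blocks, self.blocks[1:])]


@dataclass(frozen=True)
class SiteRecord:
    """One validated TSS or PAS with read support."""

    chrom: str
    position: int
    strand: str
    site_id: str
    gene_id: str = ""
    support: int = 1


@dataclass
class Config:
    """All numeric thresholds of the pipeline.

    Defaults follow the published analysis; see the CLI ``--config`` option
    for overriding via a flat key=value file.
    """

    tss_window: int = 50
    pas_window: int = 150
    pas_cluster_window: int = 20
    pas_min_support: int = 2
    filter_overlap_window: int = 100
    last_bin_cover_frac: float = 0.10
    merge_tol_3p: int = 150
    merge_tol_5p: int = 50
    merge_tol_exon: int = 10
    pileup_window: int = 50
    pileup_min_cpm: float = 30.0
    ip_a_frac: float = 0.70
    ip_window: int = 10
    ip_tes_exempt: int = 250
    seq3_merge: int = 15
    seq3_min_cov: int = 5
    max_tx_len: int = 10000
    min_isoforms: int = 2
    min_reads_per_isoform: int = 2
    alpha_fly: float = 0.1
    alpha_human: float = 0.01
    tss_contrib_min: float = 0.20
    pas_contrib_min: float = 0.60
    residual_bias_cut: float = 0.7
    signal_window_scan: int = 20
    signal_window_pas: int = 50
    proximal_frac: float = 0.20
    tpm_cutoff: float = 2.0
    mc_reps: int = 2000
    msa_row_occ: float = 0.4
    msa_max_ident: float = 0.98
    peak_min_height: float = 0.2
    peak_min_distance: int = 2
    peak_min_width: int = 2
    coevo_percentile: float = 0.50
    promoter_flank: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "rng_seed":
                continue
            if f.type == "int" and v <= 0:
                raise ValidationError(f"config {f.name} must be positive, got {v}")
            if f.name.endswith(("_frac", "_ident", "_occ", "percentile")) and not (
                0.0 <= v <= 1.0
            ):
                raise ValidationError(f"config {f.name} must be in [0,1], got {v}")

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Load from a flat ``key = value`` file (# comments allowed)."""
        kwargs: dict[str, object] = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected key = value")
            key, _, val = (x.strip() for x in line.partition("="))
            if key not in types:
                raise ValidationError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = float(val) if types[key] == "float" else int(val)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def group_by_gene(items: Iterable, key=lambda x: x.gene_id) -> dict[str, list]:
    out: dict[str, list] = {}
    for it in items:
        out.setdefault(key(it), []).append(it)
    return out
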