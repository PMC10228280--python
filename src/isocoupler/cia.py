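"""Post-assembly transcript curation against the PAS database.

Three stages: 3'-end filtering (keep ends near a confident cluster, or
distal ends inside the reference annotation with an AATAAA signal), 3'-end
correction through 3' UTR bins, and tolerance-based isoform merging by
transitive closure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from isocoupler.core import Config, GenomeInterval, TranscriptModel
from isocoupler.pasdb import PasCluster, scan_polya_signal, upstream_sequence

logger = logging.getLogger(__name__)

RETAINED_DB = "retained_db_overlap"
RETAINED_DISTAL = "retained_distal_annotated_AATAAA"
DISCARDED = "discarded"
DISCARDED_NO_CLUSTER = "discarded_no_db_cluster"


@dataclass
class FilterReport:
    table: pd.DataFrame  # transcript_id, status, correction_delta

    def status(self, transcript_id: str) -> str:
        row = self.table.loc[self.table.transcript_id == transcript_id]
        return row.status.iloc[0]


def _is_distal(end: int, other: int, strand: str) -> bool:
    return end > other if strand == "+" else end < other


def _gene_clusters(
    transcripts: Sequence[TranscriptModel],
    clusters: Sequence[PasCluster],
    pad: int,
    pad_3p: int = 1000,
) -> dict[str, list[PasCluster]]:
    """Clusters within each gene's padded span (same chrom and strand).

    The 3' side is padded further (``pad_3p``) so that distal database
    clusters beyond a truncated assembly end still count as gene clusters.
    """
    spans: dict[str, list] = {}
    for t in transcripts:
        s = spans.setdefault(t.gene_id, [t.chrom, t.strand, t.span.start, t.span.end])
        s[2] = min(s[2], t.span.start)
        s[3] = max(s[3], t.span.end)
    pad_3p = max(pad, pad_3p)
    out: dict[str, list[PasCluster]] = {g: [] for g in spans}
    for c in clusters:
        for g, (chrom, strand, lo, hi) in spans.items():
            lo_pad = pad if strand == "+" else pad_3p
            hi_pad = pad_3p if strand == "+" else pad
            if (
                c.chrom == chrom
                and c.strand == strand
                and lo - lo_pad <= c.position <= hi + hi_pad
            ):
                out[g].append(c)
    return out


def filter_3prime_ends(
    transcripts: Sequence[TranscriptModel],
    clusters: Sequence[PasCluster],
    reference: Sequence[TranscriptModel],
    genome: Optional[Mapping[str, str]] = None,
    cfg: Config = Config(),
) -> tuple[list[TranscriptModel], FilterReport]:
    """Filter assembled transcripts by their 3' ends.

    A transcript is kept if its 3' end lies within ``filter_overlap_window``
    of any database cluster, or if it is more distal than every cluster of
    its gene while falling inside a same-strand reference transcript span
    and carrying an AATAAA within ``signal_window_pas`` nt upstream
    (requires ``genome``).
    """
    win = cfg.filter_overlap_window
    by_gene = _gene_clusters(transcripts, clusters, pad=cfg.merge_tol_3p)
    all_pos: dict[tuple[str, str], np.ndarray] = {}
    for c in clusters:
        all_pos.setdefault((c.chrom, c.strand), []).append(c.position)
    all_pos = {k: np.array(sorted(v)) for k, v in all_pos.items()}
    ref_spans: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for t in reference:
        ref_spans.setdefault((t.chrom, t.strand), []).append(
            (t.span.start, t.span.end)
        )

    kept, rows = [], []
    for t in transcripts:
        end = t.three_prime
        gene_cl = by_gene.get(t.gene_id, [])
        positions = all_pos.get((t.chrom, t.strand), np.array([], dtype=int))
        status = DISCARDED
        if len(positions) and np.abs(positions - end).min() <= win:
            status = RETAINED_DB
        elif not gene_cl:
            status = DISCARDED_NO_CLUSTER
        elif all(_is_distal(end, c.position, t.strand) for c in gene_cl):
            inside = any(
                lo <= min(t.five_prime, end) and max(t.five_prime, end) <= hi
                for lo, hi in ref_spans.get((t.chrom, t.strand), [])
            )
            if inside and genome is not None:
                ups = upstream_sequence(
                    genome, t.chrom, end, t.strand, cfg.signal_window_pas
                )
                if scan_polya_signal(ups, cfg.signal_window_pas).signal == "AATAAA":
                    status = RETAINED_DISTAL
        if status in (RETAINED_DB, RETAINED_DISTAL):
            kept.append(t)
        rows.append(dict(transcript_id=t.transcript_id, status=status, correction_delta=0))
    report = FilterReport(
        pd.DataFrame(rows, columns=["transcript_id", "status", "correction_delta"])
    )
    return kept, report


def _shift_end(t: TranscriptModel, new_end: int) -> TranscriptModel:
    """Move the transcript's 3' terminus to ``new_end`` (last exon only)."""
    exons = list(t.exons)
    if t.strand == "+":
        last = exons[-1]
        exons[-1] = GenomeInterval(last.chrom, last.start, new_end, last.strand)
    else:
        first = exons[0]
        exons[0] = GenomeInterval(first.chrom, new_end, first.end, first.strand)
    return TranscriptModel(t.transcript_id, t.gene_id, exons)


def correct_3prime_ends(
    transcripts: Sequence[TranscriptModel],
    clusters: Sequence[PasCluster],
    orf_ends: Mapping[str, int],
    cfg: Config = Config(),
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Snap retained 3' ends to database positions via 3' UTR bins.

    The last bin spans the two distal-most PASs of the gene; an end inside
    it moves to the distal PAS when it covers more than
    ``last_bin_cover_frac`` of the bin and to the proximal PAS otherwise.
    Other ends snap to the nearest cluster within the overlap window.
    Deltas are signed in the transcript direction (positive = lengthened).
    """
    win = cfg.filter_overlap_window
    by_gene = _gene_clusters(transcripts, clusters, pad=cfg.merge_tol_3p)
    out, rows = [], []
    for t in transcripts:
        end = t.three_prime
        gene_cl = sorted(
            (c.position for c in by_gene.get(t.gene_id, [])),
            reverse=(t.strand == "-"),
        )  # transcript order: proximal -> distal
        new_end = end
        if len(gene_cl) >= 2:
            prox, dist = gene_cl[-2], gene_cl[-1]
            lo, hi = min(prox, dist), max(prox, dist)
            if lo < end < hi:
                span = hi - lo
                covered = end - lo if t.strand == "+" else hi - end
                frac = covered / span
                new_end = dist if frac > cfg.last_bin_cover_frac else prox
        if new_end == end and gene_cl:
            deltas = np.abs(np.array(gene_cl) - end)
            k = int(deltas.argmin())
            if deltas[k] <= win:
                new_end = gene_cl[k]
        delta = (new_end - end) if t.strand == "+" else (end - new_end)
        out.append(_shift_end(t, new_end) if new_end != end else t)
        rows.append(dict(transcript_id=t.transcript_id, correction_delta=int(delta)))
    return out, pd.DataFrame(rows, columns=["transcript_id", "correction_delta"])


# ---------------------------------------------------------------------------
# isoform merging

class _DSU:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _mergeable(a: TranscriptModel, b: TranscriptModel, cfg: Config) -> bool:
    if len(a.exons) != len(b.exons):
        return False
    if abs(a.five_prime - b.five_prime) >= cfg.merge_tol_5p:
        return False
    if abs(a.three_prime - b.three_prime) >= cfg.merge_tol_3p:
        return False
    for (da, aa), (db, ab) in zip(a.junctions, b.junctions):
        if abs(da - db) >= cfg.merge_tol_exon or abs(aa - ab) >= cfg.merge_tol_exon:
            return False
    return True


def merge_isoforms(
    transcripts: Sequence[TranscriptModel],
    cfg: Config = Config(),
    support: Optional[Mapping[str, int]] = None,
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Merge isoforms by transitive closure of the pairwise tolerance rule.

    Two isoforms of the same gene and strand are mergeable when they share
    the junction count and differ by strictly less than the 5'/3'/exon
    boundary tolerances. The representative is the member with the highest
    read support (ties: longest span).
    """
    support = support or {}
    merged: list[TranscriptModel] = []
    rows = []
    by_gene: dict[tuple[str, str], list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault((t.gene_id, t.strand), []).append(t)
    for (gene, _), members in sorted(by_gene.items()):
        dsu = _DSU(len(members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if _mergeable(members[i], members[j], cfg):
                    dsu.union(i, j)
        groups: dict[int, list[TranscriptModel]] = {}
        for i, t in enumerate(members):
            groups.setdefault(dsu.find(i), []).append(t)
        for group in groups.values():
            rep = max(
                group,
                key=lambda t: (support.get(t.transcript_id, 0), len(t.span)),
            )
            merged.append(rep)
            for t in group:
                rows.append(
                    dict(
                        gene_id=gene,
                        member=t.transcript_id,
                        representative=rep.transcript_id,
                        group_size=len(group),
                    )
                )
    table = pd.DataFrame(
        rows, columns=["gene_id", "member", "representative", "group_size"]
    )
    return merged, table
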