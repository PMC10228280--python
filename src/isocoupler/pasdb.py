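"""Confident poly(A)-site database construction and 3'-end QC.

Cleavage positions are boundary coordinates: the read's strand-aware
3' terminus (nucleotide preceding the poly(A) tail). Clustering is
single-linkage chaining of sorted positions; the cluster representative is
the modal member position with ties broken 3'-most.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from isocoupler.core import Config, ReadAlignment, SiteRecord, TranscriptModel, ValidationError
from isocoupler.io import revcomp

logger = logging.getLogger(__name__)

#: poly(A) signal hexamers, strongest first
SIGNAL_HIERARCHY = (
    "AATAAA", "ATTAAA", "AATATA", "AAGAAA", "AATACA", "AATAGA",
    "AATGAA", "ACTAAA", "CATAAA", "GATAAA", "TATAAA", "TTTAAA",
)


@dataclass
class PasCluster:
    chrom: str
    strand: str
    position: int               # representative cleavage site
    support: int
    member_positions: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class SignalCall:
    position: int
    signal: str                 # hexamer or "none"
    offset: int                 # nt from hexamer end to cleavage site


def _chain_positions(positions: Sequence[int], window: int) -> list[list[int]]:
    """Split sorted positions into runs where consecutive gaps <= window."""
    out: list[list[int]] = []
    for p in sorted(positions):
        if out and p - out[-1][-1] <= window:
            out[-1].append(p)
        else:
            out.append([p])
    return out


def _representative(members: list[int], strand: str) -> int:
    counts = Counter(members)
    top = max(counts.values())
    modal = [p for p, c in counts.items() if c == top]
    return max(modal) if strand == "+" else min(modal)


def build_pas_database(
    reads: Sequence[ReadAlignment],
    window: int = 20,
    min_support: int = 2,
) -> list[PasCluster]:
    """Cluster tailed-read 3' ends into a confident PAS database.

    Reads must all carry a poly(A) tail (callers pre-filter). Clusters with
    fewer than ``min_support`` member reads are dropped.
    """
    for r in reads:
        if not r.has_polya:
            raise ValidationError(
                f"read {r.read_id} lacks a poly(A) tail; pre-filter reads"
            )
    by_key: dict[tuple[str, str], list[int]] = {}
    for r in reads:
        by_key.setdefault((r.chrom, r.strand), []).append(r.three_prime)
    clusters: list[PasCluster] = []
    for (chrom, strand), positions in sorted(by_key.items()):
        for members in _chain_positions(positions, window):
            if len(members) < min_support:
                continue
            clusters.append(
                PasCluster(
                    chrom=chrom,
                    strand=strand,
                    position=_representative(members, strand),
                    support=len(members),
                    member_positions=members,
                )
            )
    return clusters


def cluster_3seq_sites(
    coverage: pd.DataFrame,
    merge: int = 15,
    min_cov: int = 5,
) -> list[PasCluster]:
    """Cluster per-base 3'-seq counts (columns chrom, strand, pos, count).

    Sites below ``min_cov`` are discarded before chaining sites that lie
    within ``merge`` bp of each other.
    """
    kept = coverage[coverage["count"] >= min_cov]
    clusters: list[PasCluster] = []
    for (chrom, strand), grp in kept.groupby(["chrom", "strand"], sort=True):
        weight = dict(zip(grp["pos"], grp["count"]))
        for members in _chain_positions(grp["pos"].tolist(), merge):
            counts = Counter()
            for p in members:
                counts[p] = weight[p]
            top = max(counts.values())
            modal = [p for p, c in counts.items() if c == top]
            rep = max(modal) if strand == "+" else min(modal)
            clusters.append(
                PasCluster(
                    chrom=chrom,
                    strand=strand,
                    position=rep,
                    support=int(sum(counts.values())),
                    member_positions=members,
                )
            )
    return clusters


# ---------------------------------------------------------------------------
# internal-priming blacklist

def _upstream_a_counts(seq_arr: np.ndarray, strand: str, window: int) -> np.ndarray:
    """Count of read-sense A in the ``window`` nt upstream of each boundary
    position p (genomic [p-window, p) on +; T in [p, p+window) on -)."""
    n = len(seq_arr)
    target = (seq_arr == ord("A")) if strand == "+" else (seq_arr == ord("T"))
    cum = np.concatenate([[0], np.cumsum(target)])
    counts = np.zeros(n + 1, dtype=int)
    if strand == "+":
        pos = np.arange(window, n + 1)
        counts[pos] = cum[pos] - cum[pos - window]
    else:
        pos = np.arange(0, n - window + 1)
        counts[pos] = cum[pos + window] - cum[pos]
    return counts


def internal_priming_mask(
    genome: Mapping[str, str],
    transcripts: Sequence[TranscriptModel],
    a_frac: float = 0.70,
    window: int = 10,
    tes_exempt: int = 250,
) -> dict[tuple[str, str], np.ndarray]:
    """Strand-specific blacklist of A-rich cleavage positions.

    A boundary position is blacklisted iff strictly more than
    ``a_frac * window`` read-sense As occupy the ``window`` nt immediately
    upstream AND it lies more than ``tes_exempt`` bp from every annotated
    transcript 3' end on that strand. Returns sorted position arrays keyed
    by (chrom, strand).
    """
    tes: dict[tuple[str, str], list[int]] = {}
    for t in transcripts:
        if t.chrom not in genome:
            raise ValidationError(f"chromosome {t.chrom} missing from genome")
        tes.setdefault((t.chrom, t.strand), []).append(t.three_prime)

    cut = a_frac * window
    mask: dict[tuple[str, str], np.ndarray] = {}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for strand in "+-":
            counts = _upstream_a_counts(arr, strand, window)
            cand = np.flatnonzero(counts > cut)
            ends = np.array(sorted(tes.get((chrom, strand), [])), dtype=int)
            if len(ends) and len(cand):
                idx = np.searchsorted(ends, cand)
                left = np.where(idx > 0, cand - ends[np.maximum(idx - 1, 0)], np.inf)
                right = np.where(
                    idx < len(ends), ends[np.minimum(idx, len(ends) - 1)] - cand, np.inf
                )
                cand = cand[np.minimum(left, right) > tes_exempt]
            mask[(chrom, strand)] = cand
    return mask


def apply_blacklist(
    clusters: Sequence[PasCluster],
    mask: Mapping[tuple[str, str], np.ndarray],
) -> list[PasCluster]:
    """Drop clusters whose representative position is blacklisted."""
    out = []
    for c in clusters:
        banned = mask.get((c.chrom, c.strand), ())
        if len(banned) and np.isin(c.position, banned):
            continue
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# signals, profiles, tails, pile-ups

def upstream_sequence(genome: Mapping[str, str], chrom: str, position: int, strand: str, length: int) -> str:
    """Sense-strand sequence of the ``length`` nt preceding a cleavage
    boundary position."""
    seq = genome[chrom]
    if strand == "+":
        if position - length < 0:
            raise ValidationError("flank runs off contig start")
        return seq[position - length : position]
    if position + length > len(seq):
        raise ValidationError("flank runs off contig end")
    return revcomp(seq[position : position + length])


def scan_polya_signal(upstream: str, window: int, position: int = -1) -> SignalCall:
    """Highest-ranked poly(A) signal hexamer in the last ``window`` nt of a
    sense-strand upstream sequence; ``none`` if absent.

    The offset is the distance from the hexamer's 3' end to the cleavage
    site; the occurrence closest to cleavage is reported.
    """
    if window > len(upstream):
        raise ValidationError(
            f"window {window} exceeds provided sequence ({len(upstream)} nt)"
        )
    s = upstream[len(upstream) - window :].upper()
    for hexamer in SIGNAL_HIERARCHY:
        i = s.rfind(hexamer)
        if i >= 0:
            return SignalCall(position, hexamer, window - (i + 6))
    return SignalCall(position, "none", -1)


def nucleotide_profile(
    sites: Sequence[SiteRecord] | Sequence[PasCluster],
    genome: Mapping[str, str],
    flank: int = 100,
) -> pd.DataFrame:
    """Per-position base frequencies around cleavage sites (sense strand).

    Rows A/C/G/T; columns are offsets -flank..+flank relative to the
    cleavage site (offset 0 = first base downstream of the boundary on the
    sense strand). Columns each sum to 1. Sites whose flanks leave the
    contig are skipped with a warning.
    """
    width = 2 * flank + 1
    counts = np.zeros((4, width), dtype=float)
    index = {b: i for i, b in enumerate("ACGT")}
    for s in sites:
        seq = genome[s.chrom]
        if s.strand == "+":
            lo, hi = s.position - flank, s.position + flank + 1
            if lo < 0 or hi > len(seq):
                logger.warning("site at %s:%d near contig edge; skipped", s.chrom, s.position)
                continue
            window = seq[lo:hi]
        else:
            lo, hi = s.position - flank - 1, s.position + flank
            if lo < 0 or hi > len(seq):
                logger.warning("site at %s:%d near contig edge; skipped", s.chrom, s.position)
                continue
            window = revcomp(seq[lo:hi])
        for k, base in enumerate(window):
            if base in index:
                counts[index[base], k] += 1
    sums = counts.sum(axis=0)
    sums[sums == 0] = 1.0
    freq = counts / sums
    return pd.DataFrame(freq, index=list("ACGT"), columns=range(-flank, flank + 1))


def summarize_tail_lengths(
    reads: Sequence[ReadAlignment],
    groups: Mapping[str, str],
    level: str = "gene",
) -> pd.DataFrame:
    """Median tail length per group (``groups`` maps read_id -> group id).

    Tailless or unassigned reads are ignored; empty groups are omitted.
    """
    by_group: dict[str, list[int]] = {}
    for r in reads:
        if not r.has_polya or r.tail_length is None:
            continue
        g = groups.get(r.read_id)
        if g is None:
            continue
        by_group.setdefault(g, []).append(r.tail_length)
    rows = [
        {level: g, "n_tailed_reads": len(v), "median_tail_length": float(np.median(v))}
        for g, v in sorted(by_group.items())
    ]
    return pd.DataFrame(rows, columns=[level, "n_tailed_reads", "median_tail_length"])


def call_5prime_pileups(
    reads: Sequence[ReadAlignment],
    tss_db: Sequence[SiteRecord],
    window: int = 50,
    min_cpm: float = 30.0,
) -> pd.DataFrame:
    """Call 5'-end pile-ups in fixed genomic tiles and flag TSS overlaps.

    Reads are trimmed to their 5' terminus and counted in non-overlapping
    ``window``-nt bins (anchored at coordinate 0) per chrom and strand.
    Bins with CPM strictly above ``min_cpm`` are kept; a kept bin is
    flagged if a database TSS lies within ``window`` nt of its modal
    5' position.
    """
    if not reads:
        raise ValidationError("empty read library")
    library = len(reads)
    bins: dict[tuple[str, str, int], list[int]] = {}
    for r in reads:
        p = r.five_prime
        bins.setdefault((r.chrom, r.strand, p // window), []).append(p)
    tss_by_key: dict[tuple[str, str], np.ndarray] = {}
    for s in tss_db:
        tss_by_key.setdefault((s.chrom, s.strand), [])
    for s in tss_db:
        tss_by_key[(s.chrom, s.strand)].append(s.position)
    tss_by_key = {k: np.array(sorted(v)) for k, v in tss_by_key.items()}

    rows = []
    for (chrom, strand, b), positions in sorted(bins.items()):
        cpm = 1e6 * len(positions) / library
        if cpm <= min_cpm:
            continue
        peak = _representative(positions, strand)
        sites = tss_by_key.get((chrom, strand), np.array([], dtype=int))
        near = bool(len(sites)) and int(np.abs(sites - peak).min()) <= window
        rows.append(
            dict(
                chrom=chrom, strand=strand, bin_start=b * window,
                bin_end=(b + 1) * window, peak_pos=peak,
                count=len(positions), cpm=cpm, tss_overlap=near,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "strand", "bin_start", "bin_end",
            "peak_pos", "count", "cpm", "tss_overlap",
        ],
    )


def clusters_to_sites(clusters: Sequence[PasCluster], prefix: str = "pas") -> list[SiteRecord]:
    """Convert clusters to site records (ids ordered by position)."""
    out = []
    for k, c in enumerate(
        sorted(clusters, key=lambda c: (c.chrom, c.position, c.strand))
    ):
        out.append(
            SiteRecord(c.chrom, c.position, c.strand, f"{prefix}{k}", "", c.support)
        )
    return out
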