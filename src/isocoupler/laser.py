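"""LASER: TSS-junction and junction-PAS link detection.

Junction keys are orientation-free genomic (donor, acceptor) pairs.
Junctions touching alternative first or last exons are excluded so links
reflect internal splicing rather than end choice. Testing reuses the
Monte-Carlo chi-squared engine; the per-gene linkage score is the sum of
squared Pearson residuals, which equals the chi-squared statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from isocoupler.core import Config, ReadAlignment, TranscriptModel, ValidationError
from isocoupler.later import CouplingMatrix, LinkTestResult, monte_carlo_chi2
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

JunctionKey = tuple[str, int, int]  # (chrom, donor, acceptor), donor < acceptor


def extract_junction_chain(read: ReadAlignment) -> list[JunctionKey]:
    """Ordered genomic junction keys of a read; empty for single-block."""
    return [(read.chrom, d, a) for d, a in read.junctions]


def excluded_junctions(models: Sequence[TranscriptModel]) -> set[JunctionKey]:
    """Junctions flanked by an alternative first or last exon.

    Per gene: when isoforms disagree on the first (last) exon, every first
    (last) exon is "alternative"; a junction is excluded if its donor is
    such an exon's end or its acceptor such an exon's start.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in models:
        by_gene.setdefault(t.gene_id, []).append(t)
    excluded: set[JunctionKey] = set()
    for gene, txs in by_gene.items():
        firsts = {(t.first_exon().start, t.first_exon().end) for t in txs}
        lasts = {(t.last_exon().start, t.last_exon().end) for t in txs}
        alt_exons = set()
        if len(firsts) > 1:
            alt_exons |= firsts
        if len(lasts) > 1:
            alt_exons |= lasts
        if not alt_exons:
            continue
        chrom = txs[0].chrom
        for t in txs:
            for (d, a) in t.junctions:
                for (es, ee) in alt_exons:
                    if d == ee or a == es:
                        excluded.add((chrom, d, a))
    return excluded


def build_link_matrices(
    assignments: pd.DataFrame,
    reads: Sequence[ReadAlignment],
    models: Sequence[TranscriptModel],
    mode: str = "tss-exon",
    cfg: Config = Config(),
) -> list[CouplingMatrix]:
    """Joint count tables of (TSS x junction) or (junction x PAS) per gene.

    Only full-length reads contribute; junctions near alternative first or
    last exons are removed. Genes need more than one distinct junction
    combination among their reads, then the LATER-style matrix filters
    apply (>= 2 levels per axis, >= 2 cells with >= 2 reads).
    """
    if mode not in ("tss-exon", "exon-pas"):
        raise ValidationError(f"unknown mode {mode!r}")
    banned = excluded_junctions(models)
    read_by_id = {r.read_id: r for r in reads}
    fl = assignments[assignments.full_length]

    per_gene: dict[str, list[tuple[str, JunctionKey]]] = {}
    combos: dict[str, set] = {}
    for rec in fl.itertuples():
        read = read_by_id.get(rec.read_id)
        if read is None:
            continue
        chain = [j for j in extract_junction_chain(read) if j not in banned]
        combos.setdefault(rec.gene_id, set()).add(tuple(chain))
        end_label = rec.tss_id if mode == "tss-exon" else rec.pas_id
        for j in chain:
            per_gene.setdefault(rec.gene_id, []).append((end_label, j))

    out = []
    for gene in sorted(per_gene):
        if len(combos.get(gene, ())) < 2:
            continue
        pairs = per_gene[gene]
        ends = sorted({e for e, _ in pairs})
        juncs = sorted({j for _, j in pairs})
        if len(ends) < 2 or len(juncs) < 2:
            continue
        counts = np.zeros((len(ends), len(juncs)), dtype=int)
        ei = {e: k for k, e in enumerate(ends)}
        ji = {j: k for k, j in enumerate(juncs)}
        for e, j in pairs:
            counts[ei[e], ji[j]] += 1
        n_supported = int((counts >= cfg.min_reads_per_isoform).sum())
        if n_supported < cfg.min_isoforms:
            continue
        labels = [f"{c}:{d}-{a}" for (c, d, a) in juncs]
        if mode == "tss-exon":
            m = CouplingMatrix(gene, ends, labels, counts)
        else:
            m = CouplingMatrix(gene, labels, ends, counts.T.copy())
        m = m.drop_zero_margins()
        if len(m.tss_ids) >= 2 and len(m.pas_ids) >= 2:
            out.append(m)
    return out


@dataclass
class FeatureLinkResult:
    gene_id: str
    mode: str
    x2: float
    p_mc: float
    residuals: np.ndarray
    linkage_score: float
    p_adj: float = float("nan")
    biased_pairs: list[tuple[str, str]] = field(default_factory=list)


def test_feature_links(
    matrices: Sequence[CouplingMatrix],
    mode: str = "tss-exon",
    cfg: Config = Config(),
    seed: Optional[int] = None,
    null: str = "fixed-margins",
) -> list[FeatureLinkResult]:
    """Monte-Carlo chi-squared per gene; linkage score and biased pairs.

    ``linkage_score`` is the sum of squared Pearson residuals (= X2; report
    x100 for display elsewhere). A pair is biased when |residual| is
    strictly above ``residual_bias_cut``.
    """
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    results = []
    for m in matrices:
        m = m.drop_zero_margins()
        if len(m.tss_ids) < 2 or len(m.pas_ids) < 2:
            logger.warning("gene %s degenerate after margin cleanup; skipped", m.gene_id)
            continue
        x2, p_mc, resid = monte_carlo_chi2(m.counts, B=cfg.mc_reps, seed=rng, null=null)
        biased = [
            (m.tss_ids[i], m.pas_ids[j])
            for i, j in zip(*np.where(np.abs(resid) > cfg.residual_bias_cut))
        ]
        results.append(
            FeatureLinkResult(
                gene_id=m.gene_id,
                mode=mode,
                x2=x2,
                p_mc=p_mc,
                residuals=resid,
                linkage_score=float((resid**2).sum()),
                biased_pairs=biased,
            )
        )
    if results:
        _, p_adj, _, _ = multipletests([r.p_mc for r in results], method="fdr_bh")
        for r, p in zip(results, p_adj):
            r.p_adj = float(p)
    return results


def links_table(results: Sequence[FeatureLinkResult], alpha: float) -> pd.DataFrame:
    rows = [
        dict(
            gene_id=r.gene_id, mode=r.mode, x2=r.x2, p_mc=r.p_mc, p_adj=r.p_adj,
            linkage_score_x100=100.0 * r.linkage_score,
            n_biased_pairs=len(r.biased_pairs),
            biased_pairs=";".join(f"{a}|{b}" for a, b in r.biased_pairs),
            significant=r.p_adj < alpha,
        )
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "mode", "x2", "p_mc", "p_adj", "linkage_score_x100",
            "n_biased_pairs", "biased_pairs", "significant",
        ],
    )
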