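"""LATER: 5'-3' isoform quantification and promoter-dominance testing.

Full-length reads are reads assignable both to a validated TSS (within
``tss_window``) and to a validated PAS (within ``pas_window``) on the same
strand. Per gene, the TSS x PAS joint read-count table is tested for
association by Monte-Carlo chi-squared with both margins fixed
(Patefield sampling), BH-corrected across genes; dominant promoters are
cells passing the contribution thresholds in significant genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import random_table
from statsmodels.stats.multitest import multipletests

from isocoupler.core import Config, ReadAlignment, SiteRecord, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CouplingMatrix:
    """Per-gene joint read-count table over TSS rows and PAS columns."""

    gene_id: str
    tss_ids: list[str]
    pas_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.tss_ids), len(self.pas_ids)):
            raise ValidationError(f"{self.gene_id}: counts shape mismatch")
        if (self.counts < 0).any():
            raise ValidationError(f"{self.gene_id}: negative counts")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def expected(self) -> np.ndarray:
        return np.outer(self.row_totals, self.col_totals) / self.total

    def drop_zero_margins(self) -> "CouplingMatrix":
        rows = self.row_totals > 0
        cols = self.col_totals > 0
        if rows.all() and cols.all():
            return self
        return CouplingMatrix(
            self.gene_id,
            [t for t, k in zip(self.tss_ids, rows) if k],
            [p for p, k in zip(self.pas_ids, cols) if k],
            self.counts[np.ix_(rows, cols)],
        )


@dataclass
class LinkTestResult:
    gene_id: str
    x2: float
    p_mc: float
    residuals: np.ndarray
    p_adj: float = float("nan")
    dominance_score: float = 0.0


def chi_squared_stat(counts: np.ndarray) -> tuple[float, np.ndarray]:
    """X2 and the Pearson residual matrix (O-E)/sqrt(E)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / n
    resid = (counts - expected) / np.sqrt(expected)
    return float((resid**2).sum()), resid


# ---------------------------------------------------------------------------
# read assignment

def _site_arrays(sites: Sequence[SiteRecord]):
    by_key: dict[tuple[str, str], list[SiteRecord]] = {}
    for s in sites:
        by_key.setdefault((s.chrom, s.strand), []).append(s)
    out = {}
    for key, recs in by_key.items():
        recs.sort(key=lambda s: s.position)
        out[key] = (np.array([s.position for s in recs]), recs)
    return out


def _nearest_site(
    arrays, chrom: str, strand: str, pos: int, window: int, tie: str
) -> Optional[SiteRecord]:
    """Nearest in-window site; ties broken 5'-most or 3'-most strand-aware."""
    entry = arrays.get((chrom, strand))
    if entry is None:
        return None
    positions, recs = entry
    dist = np.abs(positions - pos)
    best = dist.min(initial=np.iinfo(np.int64).max)
    if best > window:
        return None
    cands = [recs[i] for i in np.flatnonzero(dist == best)]
    if len(cands) == 1:
        return cands[0]
    upstream_first = (tie == "five") == (strand == "+")
    cands.sort(key=lambda s: s.position, reverse=not upstream_first)
    return cands[0]


def assign_full_length_reads(
    reads: Sequence[ReadAlignment],
    tss_db: Sequence[SiteRecord],
    pas_db: Sequence[SiteRecord],
    cfg: Config = Config(),
) -> pd.DataFrame:
    """Assign each read to (gene, tss, pas); unassignable reads get NA.

    Nearest in-window site wins; ties go to the 5'-most TSS / 3'-most PAS.
    Reads whose TSS and PAS belong to different genes are left unassigned.
    """
    tss_arr = _site_arrays(tss_db)
    pas_arr = _site_arrays(pas_db)
    rows = []
    for r in reads:
        tss = _nearest_site(
            tss_arr, r.chrom, r.strand, r.five_prime, cfg.tss_window, tie="five"
        )
        pas = _nearest_site(
            pas_arr, r.chrom, r.strand, r.three_prime, cfg.pas_window, tie="three"
        )
        gene = tss_id = pas_id = None
        if tss is not None and pas is not None:
            if tss.gene_id and pas.gene_id and tss.gene_id != pas.gene_id:
                logger.info("read %s spans two genes; unassigned", r.read_id)
            else:
                gene = tss.gene_id or pas.gene_id
                tss_id, pas_id = tss.site_id, pas.site_id
                rows.append(
                    dict(
                        read_id=r.read_id, gene_id=gene, tss_id=tss_id,
                        pas_id=pas_id, tss_pos=tss.position, pas_pos=pas.position,
                        full_length=True,
                    )
                )
                continue
        rows.append(
            dict(
                read_id=r.read_id, gene_id=None, tss_id=None, pas_id=None,
                tss_pos=pd.NA, pas_pos=pd.NA, full_length=False,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["read_id", "gene_id", "tss_id", "pas_id", "tss_pos", "pas_pos", "full_length"],
    )


def build_coupling_matrices(
    assignments: pd.DataFrame,
    cfg: Config = Config(),
) -> list[CouplingMatrix]:
    """Tally (tss, pas) cells per gene and apply the gene-level filters.

    Cells whose genomic TSS-PAS span exceeds ``max_tx_len`` are excluded.
    A gene is kept when it clears the expression cutoff (> ``tpm_cutoff``
    transcripts per million of assigned full-length reads; each full-length
    read is one transcript) and has at least ``min_isoforms`` cells with
    >= ``min_reads_per_isoform`` reads over >= 2 TSSs and >= 2 PASs.
    """
    fl = assignments[assignments.full_length].copy()
    if fl.empty:
        return []
    total = len(fl)
    fl["span"] = (fl.pas_pos.astype(int) - fl.tss_pos.astype(int)).abs()
    fl = fl[fl.span <= cfg.max_tx_len]

    out = []
    for gene, grp in fl.groupby("gene_id", sort=True):
        tpm = 1e6 * len(grp) / total
        if tpm <= cfg.tpm_cutoff:
            continue
        cells = grp.groupby(["tss_id", "pas_id"]).size()
        n_isoforms = int((cells >= cfg.min_reads_per_isoform).sum())
        if n_isoforms < cfg.min_isoforms:
            continue
        tss_ids = sorted(grp.tss_id.unique())
        pas_ids = sorted(grp.pas_id.unique())
        if len(tss_ids) < 2 or len(pas_ids) < 2:
            continue
        counts = np.zeros((len(tss_ids), len(pas_ids)), dtype=int)
        ti = {t: k for k, t in enumerate(tss_ids)}
        pi = {p: k for k, p in enumerate(pas_ids)}
        for (t, p), c in cells.items():
            counts[ti[t], pi[p]] = c
        m = CouplingMatrix(gene, tss_ids, pas_ids, counts).drop_zero_margins()
        if len(m.tss_ids) >= 2 and len(m.pas_ids) >= 2:
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo chi-squared testing

def monte_carlo_chi2(
    counts: np.ndarray,
    B: int = 2000,
    seed: int | np.random.Generator = 0,
    null: str = "fixed-margins",
) -> tuple[float, float, np.ndarray]:
    """Monte-Carlo p-value for the chi-squared statistic of a table.

    ``null='fixed-margins'`` samples uniformly from tables with both
    margins fixed (Patefield); ``null='multinomial'`` resamples N reads
    from the expected cell probabilities. Returns (X2, p_mc, residuals)
    with p_mc = (1 + #{X2_sim >= X2_obs}) / (B + 1).
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    counts = np.asarray(counts, dtype=int)
    x2, resid = chi_squared_stat(counts)
    row, col = counts.sum(axis=1), counts.sum(axis=0)
    n = counts.sum()
    expected = np.outer(row, col) / n
    if null == "fixed-margins":
        tables = random_table(row, col).rvs(B, random_state=rng)
    elif null == "multinomial":
        draws = rng.multinomial(n, (expected / n).ravel(), size=B)
        tables = draws.reshape(B, *counts.shape)
    else:
        raise ValueError(f"unknown null model {null!r}")
    sim = ((tables - expected) ** 2 / expected).sum(axis=(1, 2))
    hits = int((sim >= x2 - 1e-12).sum())
    p_mc = (1 + hits) / (B + 1)
    return x2, p_mc, resid


def test_tss_bias(
    matrices: Sequence[CouplingMatrix],
    cfg: Config = Config(),
    seed: Optional[int] = None,
    null: str = "fixed-margins",
) -> list[LinkTestResult]:
    """Monte-Carlo chi-squared test per gene, BH-corrected across genes."""
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    results = []
    for m in matrices:
        m = m.drop_zero_margins()
        if len(m.tss_ids) < 2 or len(m.pas_ids) < 2:
            logger.warning("gene %s degenerate after margin cleanup; skipped", m.gene_id)
            continue
        x2, p_mc, resid = monte_carlo_chi2(m.counts, B=cfg.mc_reps, seed=rng, null=null)
        results.append(
            LinkTestResult(
                gene_id=m.gene_id,
                x2=x2,
                p_mc=p_mc,
                residuals=resid,
                dominance_score=float(np.abs(resid).max()),
            )
        )
    if results:
        _, p_adj, _, _ = multipletests([r.p_mc for r in results], method="fdr_bh")
        for r, p in zip(results, p_adj):
            r.p_adj = float(p)
    return results


@dataclass
class DominanceCall:
    gene_id: str
    tss_id: str
    pas_id: str
    reads: int
    tss_contribution: float
    pas_contribution: float
    is_dominant: bool


def call_promoter_dominance(
    results: Sequence[LinkTestResult],
    matrices: Sequence[CouplingMatrix],
    cfg: Config = Config(),
    alpha: Optional[float] = None,
) -> pd.DataFrame:
    """Contribution metrics for every cell; dominance calls per thresholds.

    A cell is dominant iff the gene is transcriptionally biased
    (p_adj < alpha) and its TSS contribution exceeds ``tss_contrib_min``
    and its PAS contribution exceeds ``pas_contrib_min`` (strict).
    """
    alpha = cfg.alpha_fly if alpha is None else alpha
    by_gene = {m.gene_id: m for m in matrices}
    rows = []
    for r in results:
        m = by_gene[r.gene_id].drop_zero_margins()
        col = m.col_totals
        row = m.row_totals
        biased = r.p_adj < alpha
        for i, t in enumerate(m.tss_ids):
            for j, p in enumerate(m.pas_ids):
                o = int(m.counts[i, j])
                tss_c = o / col[j]
                pas_c = o / row[i]
                rows.append(
                    dict(
                        gene_id=m.gene_id, tss_id=t, pas_id=p, reads=o,
                        tss_contribution=tss_c, pas_contribution=pas_c,
                        p_adj=r.p_adj,
                        is_dominant=bool(
                            biased
                            and tss_c > cfg.tss_contrib_min
                            and pas_c > cfg.pas_contrib_min
                        ),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "tss_id", "pas_id", "reads",
            "tss_contribution", "pas_contribution", "p_adj", "is_dominant",
        ],
    )


def subsample_reads(
    reads: Sequence[ReadAlignment], fraction: float, seed: int
) -> list[ReadAlignment]:
    """Exact floor(fraction*n) sample without replacement, original order."""
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction {fraction} outside (0, 1]")
    n = len(reads)
    k = int(np.floor(fraction * n))
    if k == n:
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(n, size=k, replace=False))
    return [reads[i] for i in idx]


def results_table(results: Sequence[LinkTestResult], alpha: float) -> pd.DataFrame:
    rows = [
        dict(
            gene_id=r.gene_id, x2=r.x2, p_mc=r.p_mc, p_adj=r.p_adj,
            dominance_score=r.dominance_score, biased=r.p_adj < alpha,
        )
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "x2", "p_mc", "p_adj", "dominance_score", "biased"]
    )
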