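"""Diversity indices, PAS position classes and poly(A)-signal skipping.

Shannon entropy uses natural log (ecology convention); the Fisher exact
test is computed by exact hypergeometric enumeration with rational
arithmetic, so p-values are exact up to one final float conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from isocoupler.core import ValidationError


def diversity_indices(counts: pd.DataFrame | Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Shannon H (nats) and Simpson D per column of a categories x genes table.

    H = -sum p_i ln p_i, D = 1 - sum p_i^2 over the column's category
    proportions. All-zero columns are excluded with a warning.
    """
    frame = pd.DataFrame(counts)
    rows = []
    for gene in frame.columns:
        v = np.asarray(frame[gene], dtype=float)
        if (v < 0).any():
            raise ValidationError(f"{gene}: negative counts")
        total = v.sum()
        if total == 0:
            import logging

            logging.getLogger(__name__).warning("%s: all-zero counts; excluded", gene)
            continue
        p = v[v > 0] / total
        rows.append(
            dict(
                gene_id=gene,
                shannon=float(-(p * np.log(p)).sum()),
                simpson=float(1.0 - (p**2).sum()),
            )
        )
    return pd.DataFrame(rows, columns=["gene_id", "shannon", "simpson"])


@dataclass(frozen=True)
class PasPositionClass:
    gene_id: str
    pas_id: str
    relative_position: float
    position_class: str  # proximal | distal


def classify_pas_position(
    gene_id: str,
    orf_end: int,
    pas_positions: Mapping[str, int],
    strand: str,
    proximal_frac: float = 0.20,
) -> list[PasPositionClass]:
    """Classify PASs along the 3' UTR (ORF end -> distal-most PAS).

    Relative position is the strand-oriented distance from the ORF end over
    the UTR span; <= ``proximal_frac`` is proximal. A zero span (single PAS
    at the ORF end) is a degenerate gene and raises.
    """
    sign = 1 if strand == "+" else -1
    dists = {p: sign * (pos - orf_end) for p, pos in pas_positions.items()}
    span = max(dists.values())
    if span <= 0:
        raise ValidationError(f"{gene_id}: degenerate 3' UTR span {span}")
    out = []
    for pas_id in sorted(pas_positions):
        rel = dists[pas_id] / span
        cls = "proximal" if rel <= proximal_frac else "distal"
        out.append(PasPositionClass(gene_id, pas_id, float(rel), cls))
    return out


def fisher_exact_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table by full enumeration.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's
    (computed with exact rationals).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("need a nonnegative 2x2 table")
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2

    def prob(a: int) -> Fraction:
        return Fraction(comb(r1, a) * comb(r2, c1 - a), comb(n, c1))

    a_obs = int(t[0, 0])
    p_obs = prob(a_obs)
    total = Fraction(0)
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(a)
        if p <= p_obs:
            total += p
    return float(min(total, Fraction(1)))


def pas_skipping_table(
    usage: pd.DataFrame,
) -> pd.DataFrame:
    """Signal-vs-usage contingency analysis per gene group.

    ``usage`` columns: group, signal (AATAAA or none at the most-proximal
    PAS), proximal_reads, distal_reads (one row per gene). Emits per group
    the 2x2 table (rows AATAAA/none, columns proximal/distal read usage)
    and a two-sided Fisher exact p; a group with an empty signal stratum
    gets p = NA.
    """
    rows = []
    for group, grp in usage.groupby("group", sort=True):
        tab = np.zeros((2, 2), dtype=int)
        for rec in grp.itertuples():
            r = 0 if rec.signal == "AATAAA" else 1
            tab[r, 0] += int(rec.proximal_reads)
            tab[r, 1] += int(rec.distal_reads)
        if tab.sum(axis=1).min() == 0 or tab.sum() == 0:
            p: Optional[float] = None
        else:
            p = fisher_exact_two_sided(tab)
        rows.append(
            dict(
                group=group,
                aataaa_proximal=int(tab[0, 0]),
                aataaa_distal=int(tab[0, 1]),
                none_proximal=int(tab[1, 0]),
                none_distal=int(tab[1, 1]),
                fisher_p=p,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "aataaa_proximal", "aataaa_distal",
            "none_proximal", "none_distal", "fisher_p",
        ],
    )
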