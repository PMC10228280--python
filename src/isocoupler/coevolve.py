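"""Promoter-3'UTR co-evolution scoring.

Pipeline: refine the alignment (row occupancy and identity filters),
compute pairwise mutual information (base 2, pairwise-complete rows) with
average product correction, reduce each TSS-region x UTR sub-matrix to a
per-UTR-column max profile, sum its local maxima above a height threshold,
and classify TSSs/genes against the score median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from isocoupler.core import ValidationError

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class RefinedMsa:
    names: list[str]
    rows: np.ndarray           # n_rows x n_cols int codes, -1 = gap
    reference_index: int
    # msa column -> reference (ungapped) coordinate
    ref_coord: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        ref = self.rows[self.reference_index]
        if (ref < 0).any():
            raise ValidationError("reference row must be ungapped")
        self.ref_coord = np.arange(self.rows.shape[1])

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, -1) for c in seq.upper()], dtype=np.int8)


def _identity(a: np.ndarray, b: np.ndarray) -> float:
    both = (a >= 0) & (b >= 0)
    if not both.any():
        return 0.0
    return float((a[both] == b[both]).mean())


def refine_msa(
    msa: Mapping[str, str],
    reference: str = "",
    row_occ: float = 0.4,
    max_ident: float = 0.98,
) -> RefinedMsa:
    """Drop gappy rows (occupancy < ``row_occ``), then greedily drop rows
    with identity > ``max_ident`` to an already-kept row (first seen kept).
    The reference row (first row by default) is never dropped.
    """
    names = list(msa)
    if not names:
        raise ValidationError("empty alignment")
    reference = reference or names[0]
    if reference not in msa:
        raise ValidationError(f"reference row {reference!r} absent")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValidationError("rows have unequal lengths")
    coded = {n: _encode(msa[n]) for n in names}
    occ = {n: float((coded[n] >= 0).mean()) for n in names}
    if occ[reference] < row_occ:
        raise ValidationError(
            f"reference occupancy {occ[reference]:.2f} below {row_occ}"
        )

    kept: list[str] = []
    for n in names:
        if n != reference and occ[n] < row_occ:
            continue
        if n != reference and any(
            _identity(coded[n], coded[k]) > max_ident for k in kept
        ):
            continue
        kept.append(n)
    rows = np.stack([coded[n] for n in kept])
    return RefinedMsa(kept, rows, kept.index(reference))


@dataclass
class CoevolutionMap:
    mi: np.ndarray
    mi_apc: np.ndarray
    columns: np.ndarray        # reference coordinates of matrix columns


def mutual_information_matrix(
    rows: np.ndarray, min_pairs: int = 3, block: int = 256
) -> np.ndarray:
    """Pairwise column MI in bits over pairwise-complete rows.

    Column pairs with fewer than ``min_pairs`` jointly ungapped rows score
    zero. Gaps are handled by one-hot encoding with all-zero gap rows, so
    joint counts automatically use complete pairs only.
    """
    n_rows, n_cols = rows.shape
    onehot = np.zeros((n_cols, 4, n_rows), dtype=np.float64)
    for b in range(4):
        mask = rows.T == b
        onehot[:, b, :] = mask
    flat = onehot.reshape(n_cols * 4, n_rows)
    mi = np.zeros((n_cols, n_cols))
    for lo in range(0, n_cols, block):
        hi = min(lo + block, n_cols)
        joint = (flat[lo * 4 : hi * 4] @ flat.T).reshape(hi - lo, 4, n_cols, 4)
        n = joint.sum(axis=(1, 3))                       # (b, C)
        with np.errstate(divide="ignore", invalid="ignore"):
            pj = joint / n[:, None, :, None]
            pa = joint.sum(axis=3) / n[:, None, :]       # (b, 4, C)
            pb = joint.sum(axis=1) / n[:, :, None]       # (b, C, 4)
            ratio = pj / (pa[:, :, :, None] * pb[:, None, :, :])
            term = np.where(joint > 0, pj * np.log2(ratio), 0.0)
        chunk = np.nansum(term, axis=(1, 3))
        chunk[n < min_pairs] = 0.0
        mi[lo:hi] = chunk
    np.fill_diagonal(mi, 0.0)
    return (mi + mi.T) / 2


def apc_correct(mi: np.ndarray) -> np.ndarray:
    """Average product correction: MIc = MI - mean_i * mean_j / mean_all,
    with row/column/grand means excluding the diagonal; negatives floored
    at zero."""
    n = mi.shape[0]
    if n < 2:
        return np.zeros_like(mi)
    off = ~np.eye(n, dtype=bool)
    row_mean = (mi.sum(axis=1) - np.diag(mi)) / (n - 1)
    grand = mi[off].mean()
    if grand == 0:
        return np.zeros_like(mi)
    corrected = mi - np.outer(row_mean, row_mean) / grand
    corrected[corrected < 0] = 0.0
    np.fill_diagonal(corrected, 0.0)
    return corrected


def mi_apc_map(msa: RefinedMsa, columns: Optional[np.ndarray] = None) -> CoevolutionMap:
    """MI + APC matrix over the given reference columns (default: all)."""
    if msa.n_rows < 3:
        raise ValidationError("need at least 3 rows after refinement")
    if columns is None:
        columns = np.arange(msa.rows.shape[1])
    columns = np.asarray(columns, dtype=int)
    sub = msa.rows[:, columns]
    mi = mutual_information_matrix(sub)
    return CoevolutionMap(mi=mi, mi_apc=apc_correct(mi), columns=columns)


# ---------------------------------------------------------------------------
# peak scoring

def find_profile_peaks(
    profile: np.ndarray,
    min_height: float = 0.2,
    min_distance: int = 2,
    min_width: int = 2,
) -> list[tuple[int, float]]:
    """Local maxima of a 1-D profile under height/width/distance rules.

    A candidate peak is a (plateau) local maximum with height >=
    ``min_height`` whose support, from the adjacent lower flank on each
    side, spans >= ``min_width`` positions. Peaks closer than
    ``min_distance`` keep only the higher one.
    """
    x = np.asarray(profile, dtype=float)
    n = len(x)
    cand: list[tuple[int, float]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        left_up = i == 0 or x[i - 1] < x[i]
        right_up = j == n - 1 or x[j + 1] < x[i]
        if left_up and right_up and x[i] >= min_height:
            left_base = i - 1 if i > 0 else i
            right_base = j + 1 if j < n - 1 else j
            if right_base - left_base + 1 >= min_width:
                cand.append(((i + j) // 2, float(x[i])))
        i = j + 1
    cand.sort(key=lambda t: (-t[1], t[0]))
    kept: list[tuple[int, float]] = []
    for pos, h in cand:
        if all(abs(pos - kp) >= min_distance for kp, _ in kept):
            kept.append((pos, h))
    kept.sort()
    return kept


def score_region_coevolution(
    cmap: CoevolutionMap,
    tss_regions: Mapping[str, tuple[int, int]],
    utr_region: tuple[int, int],
    min_height: float = 0.2,
    min_distance: int = 2,
    min_width: int = 2,
) -> dict[str, float]:
    """Sum of profile peak heights per TSS region against the 3' UTR.

    For each TSS region, the profile over UTR columns is the per-column
    maximum of corrected MI against the region's columns; the score is the
    sum of its local-maximum heights (see :func:`find_profile_peaks`).
    """
    col_index = {c: k for k, c in enumerate(cmap.columns)}

    def region_cols(name: str, lo: int, hi: int) -> np.ndarray:
        missing = [c for c in range(lo, hi) if c not in col_index]
        if missing:
            raise ValidationError(
                f"region {name} [{lo},{hi}) outside the alignment map"
            )
        return np.array([col_index[c] for c in range(lo, hi)], dtype=int)

    utr_cols = region_cols("utr", *utr_region)
    scores: dict[str, float] = {}
    for name, (lo, hi) in tss_regions.items():
        tss_cols = region_cols(name, lo, hi)
        profile = cmap.mi_apc[np.ix_(tss_cols, utr_cols)].max(axis=0)
        peaks = find_profile_peaks(profile, min_height, min_distance, min_width)
        scores[name] = float(sum(h for _, h in peaks))
    return scores


def classify_coevolution(scores: pd.DataFrame) -> pd.DataFrame:
    """Label TSSs (and genes) co-evolving when their score reaches the
    median of all TSS scores. ``scores`` columns: gene_id, tss_id, score."""
    if len(scores) < 2:
        raise ValidationError("need at least two TSS scores to take a percentile")
    cutoff = float(np.median(scores["score"]))
    out = scores.copy()
    out["coevolving"] = out["score"] >= cutoff
    gene_flag = out.groupby("gene_id")["coevolving"].any().rename("gene_coevolving")
    out = out.merge(gene_flag, on="gene_id")
    return out
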