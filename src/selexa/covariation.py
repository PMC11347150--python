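"""Covariation analysis for secondary-structure inference.

The structural core of the pipeline: an all-pairs mutual-information (MI)
matrix over alignment columns of a count table, background correction by the
average-product correction (APC), Watson-Crick-consistency classification,
greedy non-conflicting pair calling, and double-mutant-cycle coupling.

Estimator choices (the field offers several; these are this package's):
MI in bits with an additive pseudocount (default 0.5 per joint cell) and
read-count weighting capped at the 99th-percentile count, so one jackpot
clone cannot dominate the column statistics.  APC is applied before
thresholding, as is standard in covariation/contact analysis.  G.T is not
counted as Watson-Crick.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seq_io import CountTable

_BASE_ORDER = "ACGT"
_CODE = {b: k for k, b in enumerate(_BASE_ORDER)}
# joint-cell indices (a, b) that are Watson-Crick: A.T, T.A, G.C, C.G
_WC_CELLS = [(0, 3), (3, 0), (2, 1), (1, 2)]


@dataclass(frozen=True)
class CovariationScore:
    """Per-pair covariation record (positions 0-based, i < j)."""

    i: int
    j: int
    mi: float
    score: float
    wc_fraction: float
    klass: str | None = None  # pair | correlated | none


@dataclass
class SecondaryStructureModel:
    """Called pairs and non-WC correlations; optionally conserved positions."""

    pairs: list[tuple[int, int]]
    correlated: list[tuple[int, int]]
    conserved: list[int] = field(default_factory=list)

    def to_dot_bracket(self, length: int) -> str:
        out = ["."] * length
        for i, j in self.pairs:
            out[i], out[j] = "(", ")"
        return "".join(out)


class CovariationMatrix:
    """All-pairs MI/APC-score/WC-fraction matrices over L columns."""

    def __init__(self, mi: np.ndarray, score: np.ndarray, wc: np.ndarray, pseudocount: float):
        self.mi = mi
        self.score = score
        self.wc_fraction = wc
        self.pseudocount = pseudocount
        self.L = mi.shape[0]

    def iter_scores(self) -> list[CovariationScore]:
        return [
            CovariationScore(
                i, j, float(self.mi[i, j]), float(self.score[i, j]), float(self.wc_fraction[i, j])
            )
            for i in range(self.L)
            for j in range(i + 1, self.L)
        ]

    def to_frame(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(self.L, k=1)
        return pd.DataFrame(
            {
                "i": iu,
                "j": ju,
                "mi": self.mi[iu, ju],
                "score": self.score[iu, ju],
                "wc_fraction": self.wc_fraction[iu, ju],
            }
        )


def _weights(table: CountTable, cap_quantile: float | None) -> np.ndarray:
    w = np.fromiter(table.counts.values(), dtype=float)
    if cap_quantile is not None and len(w) > 1:
        w = np.minimum(w, np.quantile(w, cap_quantile))
    return w


def _joint_counts(table: CountTable, cap_quantile: float | None) -> np.ndarray:
    """Weighted joint base counts for all column pairs, shape (L, 4, L, 4)."""
    seqs = list(table.counts)
    w = _weights(table, cap_quantile)
    L = len(seqs[0])
    arr = np.array([[_CODE[c] for c in s] for s in seqs], dtype=np.int64)
    # one-hot (n, 4L) float32 gram product gives every pairwise 4x4 block at once
    onehot = np.zeros((len(seqs), 4 * L), dtype=np.float32)
    onehot[np.arange(len(seqs))[:, None], arr + 4 * np.arange(L)] = 1.0
    gram = (onehot * w[:, None].astype(np.float32)).T @ onehot
    return gram.astype(np.float64).reshape(L, 4, L, 4)


def mi_matrix(
    table: CountTable,
    pseudocount: float = 0.5,
    count_cap_quantile: float | None = 0.99,
) -> CovariationMatrix:
    """Mutual information between all column pairs, with APC correction.

    ``MI_ij = sum_ab p_ij(a,b) log2[p_ij(a,b) / (p_i(a) p_j(b))]`` with
    read-weighted joint frequencies and an additive pseudocount per joint
    cell; marginals are the row/column sums of the smoothed joint, keeping
    the estimate internally consistent.  The APC background term
    ``MI_i. * MI_.j / MI_mean`` is subtracted to give ``score``.
    """
    if len(table.counts) < 2:
        raise ValueError("mutual information requires >= 2 distinct sequences")
    joint = _joint_counts(table, count_cap_quantile)
    L = joint.shape[0]
    wc_num = sum(joint[:, a, :, b] for a, b in _WC_CELLS)
    totals = joint.sum(axis=(1, 3))
    wc = np.divide(wc_num, totals, out=np.zeros_like(wc_num), where=totals > 0)

    smoothed = joint + pseudocount
    p = smoothed / smoothed.sum(axis=(1, 3), keepdims=True)
    p_i = p.sum(axis=3, keepdims=True)  # (L, 4, L, 1)
    p_j = p.sum(axis=1, keepdims=True)  # (L, 1, L, 4)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / (p_i * p_j)), 0.0)
    mi = np.maximum(terms.sum(axis=(1, 3)), 0.0)

    offdiag = ~np.eye(L, dtype=bool)
    row_mean = (mi * offdiag).sum(axis=1) / max(L - 1, 1)
    grand_mean = mi[offdiag].mean() if L > 1 else 0.0
    apc = np.outer(row_mean, row_mean) / grand_mean if grand_mean > 0 else np.zeros((L, L))
    score = mi - apc
    np.fill_diagonal(score, 0.0)
    return CovariationMatrix(mi=mi, score=score, wc=wc, pseudocount=pseudocount)


def wc_fraction(table: CountTable, i: int, j: int) -> float:
    """Read-weighted fraction of sequences Watson-Crick at columns (i, j)."""
    if not table.counts:
        raise ValueError("empty count table")
    L = table.seq_length
    if not (0 <= i < L and 0 <= j < L):
        raise ValueError(f"positions ({i}, {j}) outside sequence length {L}")
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    num = sum(c for s, c in table.counts.items() if (s[i], s[j]) in wc)
    return num / table.total


def default_score_threshold(matrix: CovariationMatrix, n_sd: float = 5.0) -> float:
    """Mean + n_sd * SD of the off-diagonal APC-score distribution."""
    iu, ju = np.triu_indices(matrix.L, k=1)
    vals = matrix.score[iu, ju]
    return float(vals.mean() + n_sd * vals.std(ddof=1))


def call_pairs(
    matrix: CovariationMatrix,
    wc_threshold: float = 0.9,
    score_threshold: float | None = None,
    min_separation: int = 4,
    conserved: list[int] | None = None,
) -> SecondaryStructureModel:
    """Greedy non-conflicting pair calling from APC scores.

    Candidates with ``score >= score_threshold`` (default: mean + 5 SD of
    the off-diagonal scores) are visited in deterministic order (score
    descending, then i, then j) and accepted when neither position is taken
    and ``|i - j| >= min_separation`` (default 4, admitting a 3-nt loop).
    Accepted candidates with ``wc_fraction >= wc_threshold`` are base pairs;
    the rest are non-WC correlations.  Greedy rather than optimal matching:
    deterministic and adequate at the handful of pairs a hairpin carries.
    """
    if score_threshold is None:
        score_threshold = default_score_threshold(matrix)
    candidates = [
        s for s in matrix.iter_scores() if s.score >= score_threshold
    ]
    candidates.sort(key=lambda s: (-s.score, s.i, s.j))
    taken: set[int] = set()
    pairs: list[tuple[int, int]] = []
    correlated: list[tuple[int, int]] = []
    for s in candidates:
        if s.i in taken or s.j in taken or s.j - s.i < min_separation:
            continue
        taken.update((s.i, s.j))
        if s.wc_fraction >= wc_threshold:
            pairs.append((s.i, s.j))
        else:
            correlated.append((s.i, s.j))
    return SecondaryStructureModel(
        pairs=sorted(pairs), correlated=sorted(correlated), conserved=list(conserved or [])
    )


@dataclass(frozen=True)
class MutantCycle:
    """Double-mutant cycle: wild type, both singles, and the double."""

    a00: float
    a10: float
    a01: float
    a11: float
    coupling: float  # log10 units; > 0 means the double mutant rescues
    floored: bool


def mutant_cycle(
    a00: float, a10: float, a01: float, a11: float, floor: float = 1e-3
) -> MutantCycle:
    """Coupling free-energy analogue of a double-mutant cycle.

    ``coupling = log10[(a11 * a00) / (a10 * a01)]`` after flooring all
    activities at ``floor`` (keeps the log finite when a variant is dead).
    Zero coupling means multiplicative (independent) effects; strongly
    positive coupling means the double mutant restores activity, the
    signature of a base pair.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    vals = [a00, a10, a01, a11]
    if any(v < 0 for v in vals):
        raise ValueError("activities must be >= 0")
    floored = any(v < floor for v in vals)
    f00, f10, f01, f11 = (max(v, floor) for v in vals)
    coupling = float(np.log10((f11 * f00) / (f10 * f01)))
    return MutantCycle(a00=a00, a10=a10, a01=a01, a11=a11, coupling=coupling, floored=floored)
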