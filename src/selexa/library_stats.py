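"""Per-round library summary statistics.

Mutational-distance spectra relative to the reference, position-wise base
frequency / information-content (logo) matrices, between-round enrichment,
and doped-library mutational-shell coverage arithmetic.

Distances are computed over the mutagenized region only: the primer-binding
site is fixed by design and would dilute the spectrum.  Read-count weighting
is the default; one-per-unique weighting is offered because deep-sequencing
figures are sometimes drawn either way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ReferenceDesign
from .seq_io import CountTable

_BASE_ORDER = "ACGT"


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class DistanceSpectrum:
    """Histogram of mutational distances with its weighted mean."""

    histogram: dict[int, float]
    mean: float
    weighting: str  # "reads" | "unique"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.histogram.items()), columns=["d", "weight"]
        )


def distance_spectrum(
    table: CountTable, design: ReferenceDesign, weighting: str = "reads"
) -> DistanceSpectrum:
    """Mutational-distance distribution of a round relative to the reference.

    Distances are Hamming distances over the mutagenized region.  With
    ``weighting="reads"`` each sequence contributes its read count; with
    ``"unique"`` each distinct sequence contributes once.
    """
    if weighting not in ("reads", "unique"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if not table.counts:
        raise ValueError("empty count table")
    ref_region = design.region()
    hist: dict[int, float] = {}
    for seq, count in table.counts.items():
        d = hamming(design.region(seq), ref_region)
        w = count if weighting == "reads" else 1
        hist[d] = hist.get(d, 0) + w
    total = sum(hist.values())
    mean = sum(d * w for d, w in hist.items()) / total
    return DistanceSpectrum(histogram=hist, mean=mean, weighting=weighting)


@dataclass
class LogoMatrix:
    """Position x base frequencies and per-position information content."""

    freq: pd.DataFrame  # index: position, columns: A,C,G,T
    info: pd.Series  # bits in [0, 2]
    pseudocount: float

    def to_frame(self) -> pd.DataFrame:
        out = self.freq.copy()
        out["info"] = self.info
        return out


def logo_matrix(table: CountTable, pseudocount: float = 0.5) -> LogoMatrix:
    """Read-weighted base frequencies and information content per position.

    Information content is relative to the uniform DNA background:
    ``info_i = 2 + sum_b f_ib log2 f_ib`` (bits, in [0, 2]).  The additive
    pseudocount (default 0.5 per cell) avoids log(0) at desk-scale depth;
    no further small-sample correction is applied.
    """
    if not table.counts:
        raise ValueError("empty count table")
    seqs = list(table.counts)
    weights = np.fromiter(table.counts.values(), dtype=float)
    L = len(seqs[0])
    counts = np.full((L, 4), float(pseudocount))
    code = {b: k for k, b in enumerate(_BASE_ORDER)}
    arr = np.array([[code[c] for c in s] for s in seqs], dtype=np.int8)
    for k in range(4):
        counts[:, k] += ((arr == k) * weights[:, None]).sum(axis=0)
    freq = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    return LogoMatrix(
        freq=pd.DataFrame(freq, columns=list(_BASE_ORDER)),
        info=pd.Series(np.clip(info, 0.0, 2.0), name="info"),
        pseudocount=pseudocount,
    )


def enrichment(
    table_t: CountTable, table_0: CountTable, pseudocount: float = 0.5
) -> pd.Series:
    """Per-sequence log2 frequency change between two rounds.

    ``log2[(c_t + a)/T_t] - log2[(c_0 + a)/T_0]`` over the union of
    sequences; a sequence absent from a round contributes count 0 there.
    """
    if table_t.counts and table_0.counts and table_t.seq_length != table_0.seq_length:
        raise ValueError("count tables carry different sequence lengths")
    if table_t.total == 0 and table_0.total == 0:
        raise ValueError("both rounds are empty")
    union = sorted(set(table_t.counts) | set(table_0.counts))
    c_t = np.array([table_t.counts.get(s, 0) for s in union], dtype=float)
    c_0 = np.array([table_0.counts.get(s, 0) for s in union], dtype=float)
    vals = np.log2((c_t + pseudocount) / max(table_t.total, 1)) - np.log2(
        (c_0 + pseudocount) / max(table_0.total, 1)
    )
    return pd.Series(vals, index=union, name="log2_enrichment").sort_values(
        ascending=False
    )


@dataclass
class ShellCoverage:
    """Coverage of the distance-r mutational shell by a doped library.

    ``q_r`` is the probability that one doped molecule equals a *specific*
    r-mutant of the reference; ``shell_size`` counts all r-mutants;
    ``p_present`` is the chance a given r-mutant occurs at least once among
    N molecules; ``expected_covered`` = shell_size * p_present.
    """

    L: int
    mu: float
    N: int
    r: int
    q_r: float
    shell_size: int
    p_present: float
    expected_covered: float


def shell_coverage(L: int, mu: float, N: int, r: int) -> ShellCoverage:
    """Library-design arithmetic: is every r-mutation variant expected?

    ``q_r = (mu/3)^r (1-mu)^(L-r)``, ``shell_size = C(L, r) 3^r``,
    ``p_present = 1 - (1 - q_r)^N``.  At a 21% doping rate over 85
    positions, shells out to roughly four mutations are saturated by
    realistic library sizes.
    """
    if not 0 <= r <= L:
        raise ValueError("r must lie in [0, L]")
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    if r > 0 and mu == 0.0:
        q_r = 0.0
    else:
        q_r = (mu / 3.0) ** r * (1.0 - mu) ** (L - r) if mu < 1.0 or r == L else 0.0
    shell_size = math.comb(L, r) * 3**r
    # log1p form keeps precision when q_r * N is tiny
    p_present = -np.expm1(N * np.log1p(-q_r)) if q_r < 1.0 else 1.0
    return ShellCoverage(
        L=L,
        mu=mu,
        N=N,
        r=r,
        q_r=q_r,
        shell_size=shell_size,
        p_present=float(p_present),
        expected_covered=float(shell_size * p_present),
    )
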