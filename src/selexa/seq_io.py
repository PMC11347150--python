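"""Sequence I/O and read preprocessing.

Reduces raw amplicon reads to per-round unique-sequence count tables: FASTA/
FASTQ streaming (via Biopython), fixed-layout primer clipping with mismatch
tolerance and orientation unification, exact length filtering, and unique-
sequence counting.  Rejected reads are data, not errors: each carries a
reason (``no_primer``, ``bad_length``, ``ambiguous_base``) and preprocessing
reports per-reason tallies so that reads in = inserts kept + rejects.

Primer matching is Hamming distance at fixed offsets (no indel alignment):
amplicon reads have a fixed layout, so full adapter-trimming alignment is
unnecessary.  Reads containing N are rejected rather than imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .design import ReferenceDesign, reverse_complement

_FASTQ_EXT = {".fastq", ".fq"}
_VALID = set("ACGTN")


@dataclass
class CountTable:
    """Unique-sequence counts for one selection round.

    The central exchange format between pipeline stages.  Invariants:
    ``total`` equals the sum of counts, all sequences share one length, and
    sequences are over {A,C,G,T}.
    """

    round_id: int
    counts: dict[str, int]
    total: int = field(init=False)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.counts}
        if len(lengths) > 1:
            raise ValueError(f"mixed sequence lengths in count table: {sorted(lengths)}")
        for s, c in self.counts.items():
            if c <= 0:
                raise ValueError(f"non-positive count {c} for {s[:20]}...")
        self.total = sum(self.counts.values())

    @classmethod
    def from_counts(cls, counts: dict[str, int], round_id: int = 0) -> "CountTable":
        return cls(round_id=round_id, counts=dict(counts))

    @property
    def seq_length(self) -> int:
        if not self.counts:
            raise ValueError("empty count table has no sequence length")
        return len(next(iter(self.counts)))

    def slice(self, start: int, end: int) -> "CountTable":
        """Re-aggregate counts over a subsequence window (e.g. the doped region)."""
        out: dict[str, int] = {}
        for s, c in self.counts.items():
            sub = s[start:end]
            out[sub] = out.get(sub, 0) + c
        return CountTable(round_id=self.round_id, counts=out)

    def restrict_to_region(self, design: ReferenceDesign) -> "CountTable":
        return self.slice(*design.mutagenized_region)

    def items_sorted(self) -> list[tuple[str, int]]:
        """Deterministic ordering: descending count, then lexicographic."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_tsv(self, path: str | Path, seed: int | None = None) -> None:
        with open(path, "w") as fh:
            header = f"# round={self.round_id}"
            if seed is not None:
                header += f" seed={seed}"
            fh.write(header + "\n")
            for seq, count in self.items_sorted():
                fh.write(f"{seq}\t{count}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        round_id = 0
        counts: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if tok.startswith("round="):
                            round_id = int(tok.split("=", 1)[1])
                    continue
                try:
                    seq, count = line.split("\t")
                    counts[seq] = counts.get(seq, 0) + int(count)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed count row") from exc
        return cls(round_id=round_id, counts=counts)


def _sniff_format(path: Path) -> str:
    if path.suffix.lower() in _FASTQ_EXT:
        return "fastq"
    if path.suffix.lower() in {".fasta", ".fa", ".fna"}:
        return "fasta"
    with open(path) as fh:
        first = fh.read(1)
    return "fastq" if first == "@" else "fasta"


def read_fastx(path: str | Path) -> Iterator[SeqRecord]:
    """Stream records from a FASTA or FASTQ (Phred+33) file.

    Validates each record against the {A,C,G,T,N} alphabet; malformed
    records raise with the record index.  Constant memory per record.
    """
    path = Path(path)
    fmt = _sniff_format(path)
    with open(path) as fh:
        for idx, rec in enumerate(SeqIO.parse(fh, fmt)):
            bad = set(str(rec.seq).upper()) - _VALID
            if bad:
                raise ValueError(
                    f"{path} record {idx} ({rec.id}): non-ACGTN symbols {sorted(bad)}"
                )
            yield rec


def write_fastx(records: Iterable[SeqRecord], path: str | Path) -> int:
    """Write records as FASTA or FASTQ (chosen from the file extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in _FASTQ_EXT else "fasta"
    with open(path, "w") as fh:
        return SeqIO.write(records, fh, fmt)


@dataclass(frozen=True)
class Reject:
    """A read excluded by preprocessing, with the reason."""

    reason: str  # no_primer | bad_length | ambiguous_base


def _hamming_at_most(a: str, b: str, k: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > k:
                return False
    return True


def extract_insert(
    read: str, design: ReferenceDesign, max_mismatch: int = 1
) -> str | Reject:
    """Clip the 5' ligation tag and length-filter one read.

    Tries the read and its reverse complement (orientation unification).
    The tag prefix (and, when the design carries one, the 3' primer-binding
    suffix) must match within ``max_mismatch`` Hamming mismatches at their
    fixed offsets.  Returns the clipped insert only if its length equals the
    design's expected insert length; otherwise a :class:`Reject`.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    read = read.upper()
    if "N" in read:
        return Reject("ambiguous_base")
    tag = design.primer_tag5
    for oriented in (read, reverse_complement(read)):
        if tag:
            if len(oriented) < len(tag) or not _hamming_at_most(
                oriented[: len(tag)], tag, max_mismatch
            ):
                continue
            insert = oriented[len(tag) :]
        else:
            insert = oriented
        if design.primer3:
            p3 = design.primer3
            if len(insert) < len(p3) or not _hamming_at_most(
                insert[-len(p3) :], p3, max_mismatch
            ):
                continue
        if len(insert) != design.insert_length:
            return Reject("bad_length")
        return insert
    # a correctly sized read whose primers never matched in either orientation
    return Reject("no_primer")


def count_unique(inserts: Iterable[str], round_id: int = 0) -> CountTable:
    """Exact multiset count of equal-length inserts (order-invariant)."""
    counts: dict[str, int] = {}
    for s in inserts:
        counts[s] = counts.get(s, 0) + 1
    return CountTable(round_id=round_id, counts=counts)


def preprocess_reads(
    reads: Iterable[SeqRecord | str],
    design: ReferenceDesign,
    round_id: int = 0,
    max_mismatch: int = 1,
) -> tuple[CountTable, dict[str, int]]:
    """Full read-to-count-table reduction for one round.

    Returns the count table of kept inserts plus a tally
    ``{kept, no_primer, bad_length, ambiguous_base}`` whose values sum to
    the number of input reads.
    """
    tally = {"kept": 0, "no_primer": 0, "bad_length": 0, "ambiguous_base": 0}
    kept: list[str] = []
    for rec in reads:
        seq = rec if isinstance(rec, str) else str(rec.seq)
        result = extract_insert(seq, design, max_mismatch=max_mismatch)
        if isinstance(result, Reject):
            tally[result.reason] += 1
        else:
            tally["kept"] += 1
            kept.append(result)
    return count_unique(kept, round_id=round_id), tally


def write_reject_summary(tally: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(tally, fh, indent=1)
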