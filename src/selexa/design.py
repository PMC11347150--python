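"""Reference designs for doped selection libraries.

A :class:`ReferenceDesign` anchors all position numbering in the package: it
holds the full-length pool strand (mutagenized region followed by the fixed
3' primer-binding site), the half-open coordinates of the mutagenized region,
and the primer sequences used to lay out and later clip sequencing reads.

Coordinates are 0-based half-open everywhere inside the package; 1-based
numbering appears only in config files and user-facing reports, matching the
convention used when naming positions such as "11-47" in structure models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

DNA_ALPHABET = "ACGT"
COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Watson-Crick base pairs. G.T wobbles are deliberately excluded: in DNA
#: covariation analysis a G.T column pattern is treated as noncanonical.
WC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")})


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str) -> None:
    bad = set(seq) - set(DNA_ALPHABET)
    if bad:
        raise ValueError(f"{what} contains non-ACGT symbols: {sorted(bad)}")


@dataclass(frozen=True)
class ReferenceDesign:
    """Reference pool strand with mutagenized-region coordinates.

    Parameters
    ----------
    reference
        Full pool strand over {A,C,G,T}; for the shipped deoxyribozyme
        fixture this is the 85-nt catalytic region plus a 20-nt 3'
        primer-binding site (105 nt total).
    mutagenized_region
        Half-open 0-based ``(start, end)`` interval of the doped positions.
    primer3
        3' primer-binding site (suffix of ``reference``).
    primer_tag5
        5' ligation tag prepended to each molecule in sequencing reads;
        optional (empty string if the library was read without a tag).
    """

    reference: str
    mutagenized_region: tuple[int, int]
    primer3: str = ""
    primer_tag5: str = ""

    def __post_init__(self) -> None:
        if not self.reference:
            raise ValueError("reference sequence is empty")
        _check_dna(self.reference, "reference")
        if self.primer3:
            _check_dna(self.primer3, "primer3")
            if not self.reference.endswith(self.primer3):
                raise ValueError("primer3 must be a suffix of the reference strand")
        if self.primer_tag5:
            _check_dna(self.primer_tag5, "primer_tag5")
        start, end = self.mutagenized_region
        if not (0 <= start < end <= len(self.reference)):
            raise ValueError(
                f"mutagenized_region {self.mutagenized_region} out of bounds "
                f"for reference of length {len(self.reference)}"
            )

    @property
    def region_start(self) -> int:
        return self.mutagenized_region[0]

    @property
    def region_end(self) -> int:
        return self.mutagenized_region[1]

    @property
    def region_length(self) -> int:
        return self.region_end - self.region_start

    @property
    def insert_length(self) -> int:
        """Expected length of a clipped read insert (the full pool strand)."""
        return len(self.reference)

    @property
    def read_length(self) -> int:
        """Length of a full amplicon read: 5' tag + pool strand."""
        return len(self.primer_tag5) + len(self.reference)

    def region(self, seq: str | None = None) -> str:
        """Mutagenized-region slice of ``seq`` (default: of the reference)."""
        s = self.reference if seq is None else seq
        return s[self.region_start : self.region_end]

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceDesign":
        """Build from a config mapping; region coordinates are 1-based inclusive."""
        lo, hi = d["mutagenized_region"]
        return cls(
            reference=d["reference"],
            mutagenized_region=(lo - 1, hi),
            primer3=d.get("primer3", ""),
            primer_tag5=d.get("primer_tag5", ""),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceDesign":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _load_fixture(name: str = "aurora.json") -> dict:
    with resources.files("selexa.data").joinpath(name).open() as fh:
        return json.load(fh)


def aurora_design() -> ReferenceDesign:
    """Shipped deoxyribozyme fixture design.

    The 85-nt mutagenized region and 20-nt primer site mirror the published
    pool layout (105-nt strand, 125-nt tagged read); the concrete reference
    sequence is a synthetic stand-in (the study's sequence is not public),
    generated once with paired positions made Watson-Crick complementary.
    """
    return ReferenceDesign.from_dict(_load_fixture())


def aurora_fixture_config() -> dict:
    """Raw fixture config: design plus planted structural constraints.

    Keys ``pairs`` and ``conserved_blocks`` are 1-based as in published
    position numbering; convert through :func:`aurora_fitness_model` for use.
    """
    return _load_fixture()
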