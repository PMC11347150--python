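"""Synthetic selection and assay data with known ground truth.

Every input the analysis pipeline consumes can be generated here: doped
(partially randomized) libraries around a reference strand, multi-round
fitness-based selection with amplification, sequencing-read sampling with
substitution errors, control-anchored 384-well screen plates, and
saturation-kinetics curves.  The planted constraints of a
:class:`FitnessModel` serve as ground truth for structure-recovery tests.

The generator defaults state the emulated world once: a 21% per-position
doping rate over an 85-position region, five selection rounds, 1e5 molecules
and 1e5 reads (desk-scale stand-ins for the study-scale library), and a
multiplicative per-violation fitness penalty of 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import ReferenceDesign, aurora_design, aurora_fixture_config
from .seq_io import CountTable

# base codes: A=0, C=1, G=2, T=3; complement is 3 - code
_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_MU = 0.21
DEFAULT_N_MOLECULES = 100_000
DEFAULT_DEPTH = 100_000
DEFAULT_N_ROUNDS = 5
DEFAULT_PENALTY = 0.05
DEFAULT_CAPTURE = 0.5


def encode_sequences(seqs: list[str]) -> np.ndarray:
    """Encode equal-length DNA strings to a (n, L) uint8 code array."""
    raw = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    arr = _CODE[raw].reshape(len(seqs), -1)
    if (arr == 255).any():
        raise ValueError("sequences contain non-ACGT symbols")
    return arr


def decode_sequences(arr: np.ndarray) -> list[str]:
    flat = _BASES[arr].tobytes().decode()
    L = arr.shape[1]
    return [flat[i : i + L] for i in range(0, len(flat), L)]


class ExtinctionError(RuntimeError):
    """Raised when every molecule dies in a selection round."""


@dataclass(frozen=True)
class DopedLibrarySpec:
    """Parameters of a doped library: design, doping rate mu, size, seed."""

    design: ReferenceDesign
    mu: float = DEFAULT_MU
    n_molecules: int = DEFAULT_N_MOLECULES
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")


@dataclass(frozen=True)
class FitnessModel:
    """Planted constraints defining molecule fitness.

    Fitness is a product over constraints: each satisfied constraint
    contributes a factor 1, each violated one ``mismatch_penalty``.  A
    conserved constraint ``(pos, base)`` is satisfied iff the molecule
    carries ``base`` at ``pos``; a pair constraint ``(i, j)`` iff the bases
    at i and j are Watson-Crick (A.T, T.A, G.C or C.G — G.T is not
    counted).  The reference of a consistent design has fitness exactly 1.
    Per-round survival probability is ``capture * fitness``.
    """

    conserved: frozenset[tuple[int, str]] = frozenset()
    pairs: frozenset[tuple[int, int]] = frozenset()
    mismatch_penalty: float = DEFAULT_PENALTY
    capture: float = DEFAULT_CAPTURE
    length: int | None = None  # expected molecule length, if known

    def __post_init__(self) -> None:
        if not 0.0 < self.mismatch_penalty <= 1.0:
            raise ValueError("mismatch_penalty must lie in (0, 1]")
        if not 0.0 < self.capture <= 1.0:
            raise ValueError("capture must lie in (0, 1]")
        seen: set[int] = set()
        for i, j in self.pairs:
            if not i < j:
                raise ValueError(f"pair ({i}, {j}) must satisfy i < j")
            if i in seen or j in seen:
                raise ValueError(f"position in pair ({i}, {j}) appears in two pairs")
            seen.update((i, j))


@dataclass(frozen=True)
class PlateSpec:
    """Control-anchored screen plate: control stats plus planted inhibitions."""

    n_wells: int = 384
    n_pos: int = 16
    n_neg: int = 16
    mu_p: float = 100.0
    sigma_p: float = 3.0
    mu_n: float = 5.0
    sigma_n: float = 3.0
    inhibitor_table: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_p < 0 or self.sigma_n < 0:
            raise ValueError("control sigmas must be >= 0")
        if self.mu_p <= self.mu_n:
            raise ValueError("mu_p must exceed mu_n (assay otherwise uninformative)")
        if self.n_pos + self.n_neg + len(self.inhibitor_table) > self.n_wells:
            raise ValueError("controls plus compounds exceed plate capacity")
        for cid, frac in self.inhibitor_table.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"inhibition for {cid!r} outside [0, 1]")


@dataclass
class SelectionTrajectory:
    """Per-round count tables of a simulated selection (round 0 = input pool)."""

    rounds: list[CountTable]
    model: FitnessModel
    spec: DopedLibrarySpec
    sequencing_error: float = 0.0


def _generate_doped_array(spec: DopedLibrarySpec, rng: np.random.Generator) -> np.ndarray:
    ref = encode_sequences([spec.design.reference])[0]
    n, L = spec.n_molecules, len(ref)
    arr = np.tile(ref, (n, 1))
    lo, hi = spec.design.mutagenized_region
    mask = rng.random((n, hi - lo)) < spec.mu
    # a mutated base is one of the three alternatives, uniformly
    shift = rng.integers(1, 4, size=(n, hi - lo), dtype=np.uint8)
    region = arr[:, lo:hi]
    arr[:, lo:hi] = np.where(mask, (region + shift) % 4, region)
    return arr


def generate_doped_library(spec: DopedLibrarySpec) -> list[str]:
    """Randomly mutagenize the reference at rate mu per doped position.

    Inside the mutagenized region each position is independently replaced
    with probability ``spec.mu`` by one of the three other bases (uniform);
    positions outside the region are copied verbatim.  Substitution-only:
    doped synthesis is substitution-dominated and keeps positions alignable.
    """
    rng = np.random.default_rng(spec.seed)
    return decode_sequences(_generate_doped_array(spec, rng))


def _fitness_of_array(arr: np.ndarray, model: FitnessModel) -> np.ndarray:
    """Vectorized fitness for a (n, L) code array."""
    L = arr.shape[1]
    for i, j in model.pairs:
        if j >= L:
            raise ValueError(f"pair position {j} outside sequence of length {L}")
    violations = np.zeros(arr.shape[0], dtype=np.int64)
    for pos, base in model.conserved:
        if pos >= L:
            raise ValueError(f"conserved position {pos} outside sequence of length {L}")
        violations += arr[:, pos] != _CODE[ord(base)]
    for i, j in model.pairs:
        violations += (arr[:, i] + arr[:, j]) != 3  # complement codes sum to 3
    return model.mismatch_penalty ** violations


def sequence_fitness(seq: str, model: FitnessModel) -> float:
    """Fitness in (0, 1] of one molecule under the planted constraints."""
    if model.length is not None and len(seq) != model.length:
        raise ValueError(f"sequence length {len(seq)} != expected {model.length}")
    return float(_fitness_of_array(encode_sequences([seq]), model)[0])


def aurora_fitness_model(
    mismatch_penalty: float = DEFAULT_PENALTY,
    capture: float = DEFAULT_CAPTURE,
    include_conserved: bool = True,
) -> FitnessModel:
    """Fitness model of the shipped fixture: the published pair constraints
    (11-47, 12-46, 17-40, 26-30, 1-based) and the two conserved blocks
    (1-10 and 43-79), with paired positions carried by the pair constraints
    rather than fixed, so compensatory double mutants remain rescuable.

    ``include_conserved=False`` plants the pairs only.  With all ~45
    conserved positions constrained at the default penalty, a desk-scale
    pool (1e5 molecules vs the ~1e14 of a real selection) goes extinct in
    round 1; structure-recovery experiments therefore plant the pairs alone,
    and conservation experiments use a milder penalty.
    """
    cfg = aurora_fixture_config()
    design = aurora_design()
    pairs = frozenset((i - 1, j - 1) for i, j in cfg["pairs"])
    paired = {p for ij in pairs for p in ij}
    conserved = frozenset(
        (p, design.reference[p])
        for lo, hi in cfg["conserved_blocks"]
        for p in range(lo - 1, hi)
        if p not in paired
    ) if include_conserved else frozenset()
    return FitnessModel(
        conserved=conserved,
        pairs=pairs,
        mismatch_penalty=mismatch_penalty,
        capture=capture,
        length=len(design.reference),
    )


def run_selection(
    spec: DopedLibrarySpec,
    model: FitnessModel,
    n_rounds: int = DEFAULT_N_ROUNDS,
    seed: int = 0,
) -> SelectionTrajectory:
    """Simulate rounds of capture-and-amplify selection.

    Each round, every molecule survives independently with probability
    ``capture * fitness``; survivors are resampled with replacement back to
    ``n_molecules`` (amplification is error-free).  Round 0 is the input
    doped library.  Raises :class:`ExtinctionError` naming the round if all
    molecules die (over-stringent parameters).
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    lib = _generate_doped_array(spec, np.random.default_rng(spec.seed))
    # collapse to unique molecules once; amplification never mutates
    uniq, counts = np.unique(lib, axis=0, return_counts=True)
    seqs = decode_sequences(uniq)
    fitness = _fitness_of_array(uniq, model)
    p_survive = np.clip(model.capture * fitness, 0.0, 1.0)

    round_rngs = np.random.SeedSequence(seed).spawn(n_rounds)
    rounds = [CountTable.from_counts(dict(zip(seqs, counts.tolist())), round_id=0)]
    for k in range(1, n_rounds + 1):
        rng = np.random.default_rng(round_rngs[k - 1])
        survivors = rng.binomial(counts, p_survive)
        total = int(survivors.sum())
        if total == 0:
            raise ExtinctionError(f"all molecules died in round {k}")
        counts = rng.multinomial(spec.n_molecules, survivors / total)
        keep = counts > 0
        table = dict(zip((s for s, k_ in zip(seqs, keep) if k_), counts[keep].tolist()))
        rounds.append(CountTable.from_counts(table, round_id=k))
        # drop extinct molecules so later rounds shrink
        uniq, seqs = uniq[keep], [s for s, k_ in zip(seqs, keep) if k_]
        counts, p_survive = counts[keep], p_survive[keep]
    return SelectionTrajectory(rounds=rounds, model=model, spec=spec)


def simulate_reads(
    trajectory: SelectionTrajectory,
    depth: int = DEFAULT_DEPTH,
    error_rate: float = 0.0,
    seed: int = 0,
    rounds: list[int] | None = None,
    phred: int = 30,
) -> dict[int, list[SeqRecord]]:
    """Sample sequencing reads per round as FASTQ-ready records.

    Reads are a multinomial sample of ``depth`` molecules from each round's
    count table; when ``depth`` equals a round's total the whole pool is
    sequenced as a census (each molecule exactly once), so noiseless reads
    reproduce the molecule frequencies exactly.  The read layout is
    ``primer_tag5 + molecule`` and each base is substituted independently
    with probability ``error_rate``.  Quality is a constant Phred score
    (default 30).  ``rounds`` restricts output to the listed round ids.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")
    tag = encode_sequences([trajectory.spec.design.primer_tag5])[0] if trajectory.spec.design.primer_tag5 else np.empty(0, dtype=np.uint8)
    wanted = {t.round_id for t in trajectory.rounds} if rounds is None else set(rounds)
    ss = np.random.SeedSequence(seed).spawn(len(trajectory.rounds))
    out: dict[int, list[SeqRecord]] = {}
    for table, child in zip(trajectory.rounds, ss):
        if table.round_id not in wanted:
            continue
        rng = np.random.default_rng(child)
        seqs = list(table.counts)
        weights = np.fromiter(table.counts.values(), dtype=float)
        if depth == table.total:
            draws = weights.astype(np.int64)
        else:
            draws = rng.multinomial(depth, weights / weights.sum())
        mol = encode_sequences(seqs)
        reads = np.hstack([np.tile(tag, (depth, 1)), np.repeat(mol, draws, axis=0)])
        if error_rate > 0:
            mask = rng.random(reads.shape) < error_rate
            shift = rng.integers(1, 4, size=reads.shape, dtype=np.uint8)
            reads = np.where(mask, (reads + shift) % 4, reads)
        qual = [phred] * reads.shape[1]
        records = []
        for idx, s in enumerate(decode_sequences(reads)):
            rec = SeqRecord(Seq(s), id=f"r{table.round_id}_{idx}", description="")
            rec.letter_annotations["phred_quality"] = qual
            records.append(rec)
        out[table.round_id] = records
    return out


_PLATE_ROWS = "ABCDEFGHIJKLMNOP"


def simulate_screen_plate(spec: PlateSpec) -> pd.DataFrame:
    """Simulate one control-anchored screen plate.

    Negative controls (fully inhibited signal) are drawn Normal(mu_n,
    sigma_n), positive controls (uninhibited) Normal(mu_p, sigma_p), and
    each compound well Normal(mu_n + (1 - inhibition) * (mu_p - mu_n),
    sigma_p).  Returns a tidy frame with columns
    ``well,row,col,role,compound_id,fluorescence``.
    """
    rng = np.random.default_rng(spec.seed)
    n_cols = max(1, spec.n_wells // len(_PLATE_ROWS))
    wells = [f"{_PLATE_ROWS[i // n_cols]}{i % n_cols + 1}" for i in range(spec.n_wells)]
    rows = []
    i = 0
    for _ in range(spec.n_neg):
        rows.append((wells[i], "negative", "", rng.normal(spec.mu_n, spec.sigma_n)))
        i += 1
    for _ in range(spec.n_pos):
        rows.append((wells[i], "positive", "", rng.normal(spec.mu_p, spec.sigma_p)))
        i += 1
    for cid, inhib in spec.inhibitor_table.items():
        mean = spec.mu_n + (1.0 - inhib) * (spec.mu_p - spec.mu_n)
        rows.append((wells[i], "sample", cid, rng.normal(mean, spec.sigma_p)))
        i += 1
    df = pd.DataFrame(rows, columns=["well", "role", "compound_id", "fluorescence"])
    df.insert(1, "row", df["well"].str[0])
    df.insert(2, "col", df["well"].str[1:].astype(int))
    return df


def simulate_saturation_curve(
    vmax: float,
    k_half: float,
    n_hill: float = 1.0,
    S_values: np.ndarray | list[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Initial rates on a substrate grid from a Hill/Michaelis-Menten law.

    ``V0(S) = vmax * S^n / (k_half^n + S^n) + Normal(0, noise_sd)``;
    ``n_hill=1`` reduces to the hyperbolic Michaelis-Menten form.  The
    default grid spans 1-300 uM as in single-turnover substrate titrations.
    Returns a frame with columns ``S_uM, V0``.
    """
    if vmax <= 0 or k_half <= 0 or n_hill <= 0:
        raise ValueError("vmax, k_half and n_hill must be positive")
    S = np.asarray(
        [1, 3, 10, 30, 100, 300] if S_values is None else S_values, dtype=float
    )
    if (S < 0).any():
        raise ValueError("substrate concentrations must be >= 0")
    v = vmax * S**n_hill / (k_half**n_hill + S**n_hill)
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, size=S.shape)
    return pd.DataFrame({"S_uM": S, "V0": v})
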