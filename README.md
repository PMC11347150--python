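# selexa

Simulation and analysis tools for in vitro selection (SELEX) experiments on
doped deoxyribozyme libraries, and for the downstream assays such selections
feed: saturation kinetics and fluorescence-based high-throughput screens.

The package grew out of a concrete workflow — evolving a fluorogenic
deoxyribozyme from a doped library (every position of an 85-nt reference
mutagenized at 21%), inferring its secondary structure from sequence
covariation, characterizing its kinetics, and using it as a reporter in a
384-well inhibitor screen — but every stage is generic over a
`ReferenceDesign` and plain tabular inputs.

## What it does

- **`selexa.synthetic_data`** — generators with planted ground truth: doped
  libraries, multi-round fitness-based selection with amplification,
  sequencing reads with substitution errors, control-anchored screen plates,
  and Hill/Michaelis–Menten saturation curves. Fitness is a product of
  per-constraint factors (conserved bases and Watson–Crick pairs; each
  violation multiplies by a penalty), and per-round survival is
  `capture × fitness`.
- **`selexa.seq_io`** — FASTA/FASTQ streaming (Biopython), fixed-layout
  primer clipping with mismatch tolerance and orientation unification,
  exact length filtering, and unique-sequence `CountTable`s (TSV).
- **`selexa.library_stats`** — mutational-distance spectra (Hamming distance
  to the reference over the doped region), sequence-logo matrices
  (`info_i = 2 + Σ_b f_ib log2 f_ib` bits), between-round log2 enrichment,
  and mutational-shell coverage
  (`q_r = (μ/3)^r (1−μ)^{L−r}`, `p_present = 1 − (1−q_r)^N`).
- **`selexa.covariation`** — all-pairs mutual information
  `MI_ij = Σ_ab p(a,b) log2[p(a,b)/(p(a)p(b))]` with average-product
  correction, Watson–Crick-fraction classification, greedy non-conflicting
  pair calling, and double-mutant-cycle coupling
  `log10[(a11·a00)/(a10·a01)]`.
- **`selexa.kinetics`** — linear-phase initial rates and nonlinear
  least-squares fits of `V0 = Vmax[S]/(Km+[S])` (plus a Hill extension),
  `kcat = Vmax/[E]`.
- **`selexa.screen_stats`** — signal-to-noise ratios, the plate Z-factor
  `1 − 3(σp+σn)/(μp−μn)`, percent-activity normalization, counterscreen hit
  classification, the 3-SD limit of detection, 4-parameter-logistic IC50
  fits, and fluorophore brightness (ε × Φ).

## Worked example

Recover a planted secondary structure from a simulated selection:

```python
import selexa as sx
from selexa import synthetic_data as sd

design = sx.aurora_design()                               # 85-nt doped region + 20-nt primer site
model = sx.aurora_fitness_model(include_conserved=False)  # plant the four pairs
spec = sd.DopedLibrarySpec(design=design, n_molecules=100_000, seed=1)

traj = sd.run_selection(spec, model, n_rounds=5, seed=101)
reads = sd.simulate_reads(traj, depth=100_000, error_rate=0.001, seed=201, rounds=[5])[5]
table, tally = sx.preprocess_reads(reads, design, round_id=5)

matrix = sx.mi_matrix(table.restrict_to_region(design))
called = sx.call_pairs(matrix)
print([(i + 1, j + 1) for i, j in called.pairs])
```

prints

```
[(11, 47), (12, 46), (17, 40), (26, 30)]
```

— exactly the planted pairs, each with a Watson–Crick fraction above 0.99,
and no false positives: after five rounds of selection the surviving pool is
a mixture of compensatory variants at the paired positions, which mutual
information separates cleanly (top planted score ≈ 0.19 bits vs ≈ 0.004 for
the strongest background pair).

The same objects drive the rest of the pipeline, e.g.

```python
from selexa import library_stats as ls
ls.distance_spectrum(traj.rounds[0], design).mean   # 17.85 ≈ L·μ = 85 × 0.21
```

A `selexa` console script exposes each stage
(`simulate-library`, `simulate-selection`, `preprocess`, `distances`,
`logo`, `enrich`, `covary`, `kinetics-fit`, `screen-qc`, `call-hits`,
`ic50`, `lod`); run `selexa --help`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates the package's headline numbers from scratch: the empirical
per-position mutation rate of a freshly generated 10,000-sequence doped
library (percent), and the turnover number and half-saturation constant
recovered by fitting the hyperbolic rate law to a noiseless saturation curve
generated at the reference parameters. All randomness derives from
`--seed`.

See `docs/methods.md` for the statistical model, estimator choices and known
limitations.
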