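# Methods

## Model and procedure

The analysis treats a β-hairpin trajectory as a categorical time series.
Each saved frame is reduced to the geometry of four interstrand backbone
hydrogen bonds and mapped to a 4-bit open/closed fingerprint; populations,
distances, transition statistics and the folding pathway are all functions
of that series. The implicit assumptions are:

- the four named bonds fully characterize the folded topology (the
  package never infers which bonds define a hairpin — they are declared
  in the bond config);
- frames are snapshots of a stationary process, so populations estimate
  equilibrium probabilities and frame-to-frame transition frequencies at
  the saving stride estimate a one-step kernel (no lag-time scan or
  Markov-state-model validation is attempted);
- independent production runs share an equilibrium but not dynamics, so
  frame pairs spanning a run boundary are never counted as transitions.

## Geometry conventions

For a bond with donor heavy atom D, hydrogen H and acceptor A:

- **distance** = |H···A| in Å. The hydrogen–acceptor convention (rather
  than donor–acceptor) is used because closed-bond averages of ~2.1–2.4 Å
  are only consistent with H···A; O···H pair labels name the same choice.
- **angle** = ∠(D–H–A) in degrees at the hydrogen; 180° is collinear.

Coordinates from PDB files are Å natively; MDAnalysis converts nm-based
binary formats (XTC) on read. Atom identifiers are exact, case-insensitive
`RESNAME RESID ATOMNAME` triplets; zero or multiple matches are errors,
never guesses.

## Thresholds and boundary behaviour

| parameter | default | unit | role |
|---|---|---|---|
| `distance_cutoff` | 3.0 | Å | max H···A distance for a closed bond (inclusive) |
| `angle_min` | 120 | ° | min D–H–A angle for a closed bond (inclusive) |
| `folded_threshold` | 3.0 | Å | strict upper bound on the 4-bond mean distance of a folded pattern |

Detection is inclusive at both boundaries (d = 3.0 Å, θ = 120° is
closed). The folded rule is *strict* (mean < 3.0 Å): a pattern whose mean
distance is exactly 3.00 Å is unfolded. The bundled reference tables
contain exactly such a row, which grounds the choice.

Two folding-ratio modes exist. Pattern-level (default) sums the
populations of folded patterns, matching how the reference tables are
constructed; frame-level classifies every frame by its own four-distance
mean. They agree exactly when all frames of a pattern share identical
geometry and differ otherwise; both are reported in the summary.

## Reporting and rounding

Internal computation is never rounded. Reports round populations and
transition percentages to whole percent and distances to two decimals,
half away from zero. Patterns whose rounded population is ≥ 1% are
flagged "significant" and form the default report scope; `--scope full`
prints all 16 rows with `NA` distance cells for unpopulated patterns.
Transition maps are reported over the six prominently populated patterns
plus an aggregated `other` row/column by default (percentages are always
computed over the full 16-state space first, then aggregated). Reports
are byte-stable and embed the thresholds used. Reproducing a printed
overall average from *printed* per-bond values is only guaranteed to
±0.01 Å, since the original averages were taken over unrounded values.

## Pathway extraction

From the current pattern, the walk moves to the destination with the
highest off-diagonal row percentage. Deterministic tie-breaking: prefer
the destination with more closed bonds, then the lexicographically
smaller label. Already-visited states are never re-entered — the raw
greedy rule can cycle (in the bundled maps, `ccoc`'s best destination is
`cooc`, whose best is `cocc`) — but they may still appear as the reported
second-best branch. A walk with no admissible destination raises an error
carrying the partial path.

## Synthetic generator

`synthetic` emulates the statistical structure of a multi-run trajectory,
not its physics: a Markov chain over pattern labels (row-stochastic
matrix, initial distribution, independent runs, all driven by one seed)
and pattern-conditional geometry emissions per bond:

| emission | default | truncation |
|---|---|---|
| closed distance | N(2.2 Å, 0.2 Å) | > 0 and ≤ cutoff |
| closed angle | N(155°, 12°) | [angle_min, 180] |
| open distance | N(6.0 Å, 1.5 Å) | > 0 |
| open angle | U(60°, 180°) | open under the criteria |

Defaults mimic realistic closed-bond geometry (short, near-linear) and
open-bond magnitudes of ~5–9 Å; beyond that they are arbitrary. Each draw
is rejection-resampled (cap 1000 rounds, then a configuration error)
until it classifies as intended, so classify-then-assign recovers the
generating pattern exactly and the chain's analytic stationary
distribution / transition matrix are exact oracles for the pipeline. The
packaged example chain is the bundled 6-state reference map with rows
renormalized to sum to one and the stationary vector as initial
distribution.

What the generator does **not** emulate: correlated bond geometries
within a frame, pattern-dependent open-bond distances (a single open
distribution serves all patterns), fractional-Å distance drift between
patterns, solvent effects, or any energetics. Passing recovery tests
therefore shows the *bookkeeping* (classification, counting,
normalization, pathway logic) is correct under known dynamics — not that
any force field reproduces real folding ratios.

Coordinate-level output is available: `emit_coordinates` realizes a
(distance, angle) pair as three atom positions (donor at origin, hydrogen
at (1,0,0) Å, acceptor in the xy-plane), and `write_synthetic_pdb` writes
a multi-model PDB (one residue of three atoms per bond) that round-trips
through the trajectory reader to PDB precision (~10⁻³ Å).

## Statistical tolerances

Recovery tests compare estimates against analytic values at three
standard errors. For transition-matrix cells the rows are, conditional on
row counts, multinomial, so the binomial SE √(p(1−p)/nᵢ) applies. For
occupation fractions successive frames are autocorrelated and the
binomial SE is an underestimate for sticky chains; the asymptotic
variance is taken from the fundamental matrix Z = (I − P + **1**πᵀ)⁻¹ as
σ²ᵢ = πᵢ(2Zᵢᵢ − 1 − πᵢ), which reduces to the binomial value for an
i.i.d. chain (tested). Chain lengths used in tests and the acceptance
script — 50 000 frames for recovery, 20 000 for the geometry-emitting
pipeline, hundreds for determinism checks — keep every standard error
small relative to the planted margins while the whole suite runs in
seconds.

## Numerical choices

- Angle computation clips the normalized dot product to [−1, 1] before
  `arccos`, so collinear geometries are exact rather than NaN.
- The stationary distribution is the left eigenvector at the unit
  eigenvalue; reducible chains (checked via strongly connected
  components) raise by default because their stationary distribution is
  not unique.
- Rows with zero transition counts are flagged undefined (NaN
  percentages), never divided.
- Population percentages sum to 100 exactly before rounding (they are
  computed from a single shared denominator).

## Known limitations

- No trajectory alignment, PBC re-imaging or fitting: inputs are assumed
  to contain whole molecules.
- One-step transition counting at the saved stride only; no implied
  timescales, lag-time selection or transition-path-theory fluxes.
- Auxiliary-bond co-occurrence reports frequencies only; no enrichment
  test.
- The bundled reference statistics derive from microsecond-scale
  simulations that this package does not re-run; re-running such a
  protocol and feeding the frames through `analyze` is the intended
  cluster-scale benchmark (folding ratios near 66% and 43% for the two
  bundled peptides), but it is documentation, not part of the test
  suite.
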