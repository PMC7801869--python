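# Methods note

This note records the model, the numerical choices, the defaults (with
units), what the synthetic generator emulates — and what it does not —
and the known limitations.  Everything quantitative stated here is
computed by the test suite or `scripts/acceptance.py`.

## Coordinates

All sequence positions are 1-based inclusive `(start, end)` intervals:
in the API, in every TSV, and in ground-truth bookkeeping.  The single
exception is the BED export (`topology.bed`), which uses the BED
convention of 0-based half-open intervals.

## Hydropathy and per-sequence TM calling

Two hydropathy scales are built in, Kyte–Doolittle and GES.  Both are
tabulated to one decimal; `X` scores 0.0.  Where exact tie behaviour
matters (dynamic-programming segmentation), scores are handled in
integer deci-units (value × 10), so ties are resolved by integer
comparison rather than floating-point order.

**Window caller.**  The profile at a position is the trapezoid-weighted
mean over a window with a flat core (default 11 residues) and linear
tapers (default 5 residues each side); weights are normalised to sum
to 1.  Positions whose window would run off the sequence are undefined
(NaN).  Runs of positions above the lower cutoff become segments,
expanded by the half core-width at each end; a run whose expansion
would exceed the maximum TM length (30) is split at its weakest
interior position; colliding expansions of adjacent runs are trimmed at
the midpoint of the inter-run valley; segments shorter than the minimum
TM length (15) are discarded.  A segment is `certain` when some run
position exceeds the upper cutoff, else `putative`.  Default cutoffs:
Kyte–Doolittle lower 1.0 / upper 1.6; GES lower 1.0 / upper 2.0.

**DP segmenter.**  Finds the disjoint set of segments with lengths in a
configured range (within [15, 30] by default, variants may widen to
[12, 32]) maximising total hydropathy minus a per-segment penalty, with
at least one residue between segments.  Ties are broken toward fewer
segments, then lexicographically smallest start tuple.  The
implementation is exact (verified against exhaustive enumeration).

**Builtin ensemble.**  Five predictors: two window callers
(Kyte–Doolittle and GES, core 11 / taper 5) and three Kyte–Doolittle DP
segmenters (penalty 10, lengths 15–30; penalty 8, lengths 12–32;
penalty 12, lengths 15–30).  The 3-global + 2-window mix mirrors the
composition of the commonly used five-tool suites (three probabilistic/
global-optimisation tools plus two window tools) and matters in
practice: window callers share a failure mode on helices with several
polar substitutions, and with three of them a majority vote can be lost
even when the global methods all find the helix.  External predictions
can be imported from TSV (`seq_id  start  end`), validated for order,
overlap and length 12–35.

## Consensus and reconciliation

Segments are projected to alignment columns.  The vote at a column is
computed over non-gap cells only — a predictor abstains for a sequence
that is gapped there — and columns with more than 50 % gaps are
uncallable and break candidate runs.  Aggregate support is the mean
over predictors of the per-predictor fraction of non-gapped members
covered.

Candidate regions: maximal runs of callable columns with aggregate
support ≥ `min_support` (0.5), merged across gaps shorter than
`min_gap` (3) columns, kept at width ≥ `min_width` (8); the region core
is the longest run of columns supported by ≥ `core_min_predictors` (3)
predictors.

Reconciliation: candidates whose core lies entirely inside a mask
interval (projected through a reference row) are excluded and reported
as `mask-overlap`.  The parity required by the terminus anchors (odd
for opposite sides, even for equal) selects the accepted subset: the
one maximising total support, tie-broken toward fewer regions, then the
lexicographically smallest index tuple — an exhaustive search for up to
16 candidates, greedy beyond.  When the first candidate is flagged as a
possible signal anchor it is pinned into the subset (with a fallback
retry without the pin if that is unsatisfiable) and a
`signal-anchor-ambiguity` item is reported.  Loop names and sides
(NTERM, EL1, CL1, …, CTERM) alternate outward from the anchored
N-terminus; an unsatisfiable constraint set raises a `TopologyError`
carrying the discrepancy report.

Cross-family discrepancies: per accepted region and member, the mean
predictor coverage of the member's span; 0 ⇒ `missing-in-sequence`,
below `min_support` ⇒ `subthreshold`.

## Motif scanning

Column conservation is the frequency of the majority non-gap residue
among non-gap rows; columns above the gap threshold (0.5) are
undefined.  Patterns use letters, bracketed alternatives and the `x`
wildcard.  A window inside the named topology region is a hit when at
least `match_fraction` (0.8) of the rows without gaps in the window
match (rows gapped in the window are excluded from the denominator) and
at least one row matches; among hit windows the one with the highest
mean conservation is kept, ties to the leftmost.  Positions map between
members through the alignment (`map_position`), returning None across a
gap.

## Contact shells

Distances are minimum heavy-atom–to–heavy-atom (hydrogens excluded by
default) between a residue and the ligand group, computed with exact
pairwise distances (`scipy.spatial.distance.cdist`).  Shells A/B/C at
radii ≤ 5.0 / 6.0 / 7.0 Å, boundaries inclusive, innermost shell wins.
Metal coordination: O/N/S atoms within 3.0 Å of a single-atom hetero
group (chemical identity is not interpreted).  Salt bridges: Lys NZ,
Arg NE/NH1/NH2 or His ND1/NE2 within 4.0 Å of a ligand oxygen whose
atom name marks it as a phosphate oxygen (starts with `O`, contains
`P`); no bonded context is used.

## Synthetic generator

Residues are sampled from state-conditional distributions: TM cores
from a hydrophobic distribution (I 0.18, L 0.22, V 0.16, F 0.12,
A 0.14, M 0.06, G/S/T/W/Y 0.024 each) with polar residues sprinkled in
at `sprinkle_prob` (default 0.1 per TM site), loops from a polar
distribution (D/E/K/R/N/Q/S/T/P/G 0.09 each, other residues 0.01
total weight each).  Motifs are planted verbatim at a fixed offset in a
named loop, and motif sites are exempt from mutation.  Members evolve
from the unmutated root (member 1) by per-site substitution
(`substitution_prob`, default 0.05; replacements drawn from the site's
state-conditional distribution so the hydropathy contrast is
stationary) and loop-only indels of 1–3 residues (`indel_rate` 0.2 per
loop per member; deletions keep ≥ 4 loop residues and avoid motifs).
The alignment is assembled exactly from the indel history — no aligner
is involved — so degapping any row reproduces its sequence.

The toy structure is a CA-level ideal helix bundle: rise 1.5 Å, 100°
per residue, helix radius 2.3 Å, helices on a circle sized from the TM
count, alternating z-direction; loops are straight-line connectors and
terminal tails extend outward.  Polar residues get one pseudo
side-chain donor atom 2.4 Å radially outward; ligand/ion atoms are
planted at exact configured offsets pointing toward the bundle axis
(plants closer than 1 Å to each other are an error).

**What the generator does not emulate:** real substitution matrices or
phylogeny (members are independent draws from the root, not a tree);
realistic loop length evolution; signal peptides and re-entrant or
interfacial helices; real backbone geometry, side-chain rotamers or
ligand chemistry (the toy structure only guarantees exact planted
distances, helix spacing and membrane-slab layering).  It is a test
harness for the pipeline's bookkeeping and thresholds, not a biophysical
simulator.

## Defaults

| Parameter | Default | Units |
|---|---|---|
| window core / taper | 11 / 5 | residues |
| KD cutoffs lower / upper | 1.0 / 1.6 | KD units |
| GES cutoffs lower / upper | 1.0 / 2.0 | GES units |
| TM length bounds | 15–30 | residues |
| DP penalties (3 variants) | 10 / 8 / 12 | deci-scale × 0.1 |
| `min_support` | 0.5 | fraction of votes |
| `core_min_predictors` | 3 | predictors |
| `min_width` / `min_gap` | 8 / 3 | columns |
| `max_gap_fraction` | 0.5 | fraction of rows |
| `match_fraction` | 0.8 | fraction of rows |
| shell radii | 5, 6, 7 | Å |
| coordination cutoff | 3.0 | Å |
| salt-bridge cutoff | 4.0 | Å |
| sprinkle / substitution / indel | 0.1 / 0.05 / 0.2 | probabilities |

## Verification

Every core numeric routine is tested against an independently coded
brute-force oracle (weighted-mean profile, exhaustive DP enumeration in
deci-units, direct candidate-region scan, exhaustive reconciliation
subset search with the identical tie key, pairwise distance scan) on
hundreds of random instances; topology invariants (parity, strict loop
alternation, anchored terminus sides) are checked across 1–13 TM
architectures; and recovery is measured over 100 seeded families at
study conditions.  `scripts/acceptance.py --seed 1` reports agreement
1.0 on all oracle comparisons, TM-count/motif/shell recovery 1.0, and a
mean TM-boundary deviation of ≈ 0.62 residues.

## Limitations

- The builtin predictors are hydropathy-only emulations; they have no
  positive-inside bias, no signal-peptide model, and will miss
  amphipathic or marginally hydrophobic helices that profile-HMM tools
  can catch.  Real predictor output can be imported via TSV instead.
- Reconciliation assumes every member shares one family topology;
  genuinely divergent members are only surfaced as discrepancies, not
  modelled separately.
- The exhaustive subset search is exact up to 16 candidates and greedy
  beyond.
- Masks are projected through a reference row; a mask that exists only
  in a sequence absent from the alignment cannot be applied.
- One hit per motif per family is reported by design; tandem motif
  repeats are not enumerated.
- Salt-bridge and coordination detection are geometric name-convention
  heuristics with no chemistry (no protonation states, no bond orders).
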