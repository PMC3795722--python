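# Methods

This note documents the models, parameters and design choices behind
`rnu2comb`: what the simulator emulates, how each inference step works, and
what the tests do and do not demonstrate about real combed-DNA data.

## Coordinate frame and locus model

All genomic coordinates are 0-based, half-open base pairs in a
self-contained linear frame whose array start equals the Build-37
coordinate 41,399,577, so printed assembly coordinates can be used
literally without shipping a genome.  The map (`locus.default_locus_map`)
contains:

- **17 GMC barcode elements** over 200 kb (green/red/blue, 1–3 bars each).
  Published material fixes the schema but not per-element coordinates, so
  the packaged table (v1) places elements on a 12-kb raster with two pinned
  edges: the designated calibration motif — first bar of `GMC01` to last
  bar of `GMC11` — spans exactly 128,000 bp, and the BRCA1-end anchor (last
  bar of `GMC08`) sits exactly 123,700 bp centromeric of the array start.
  These are declared constants, not inferences.
- **Flanking probes** FP1 (4,393 bp), FP2 (4,860 bp) ending 7,300 bp
  centromeric of the array, FP3 (7,009 bp) starting 2,000 bp telomeric of
  it, FP4 (5,340 bp); each drawn as two green or blue bars.
- **Repeat unit**: 6,132 bp with one contiguous red labeled span of
  2,393 bp (the 434-bp and 1,959-bp unit probes target close regions and
  appear as a single signal) at declared offset 1,000 bp.  The offset is a
  named constant; any value would do, and downstream arithmetic reads it
  from the model.
- **RNU2-4P** pseudogene: a 289-bp red cross-reacting signal 63,400 bp
  telomeric of the array end.

`build_haplotype(map, n)` replaces the anchor interval with `n` adjacent
unit copies and shifts all telomeric elements, so total span grows by
exactly 6,132 bp per copy.  Strand is not a map property; orientation lives
on fibres.

## Synthetic fibre generator

`simulate_cohort` emulates, per fibre: a truncated-normal (±3 sd) fibre
length (default mean 400 kb, sd 80 kb — molecular combing routinely yields
fibres of hundreds of kb); a uniformly placed breakage window; a
truncated-normal per-fibre stretching factor (mean 2.0 kb/µm, sd 0.05 —
the combing process guarantees near-constant stretch, so ±3 sd spans
1.85–2.15); independent Gaussian jitter of sd 0.3 kb on every signal
boundary, applied in bp before µm conversion (two jittered boundaries per
signal and per gap reproduce the field's observation that gap spreads
exceed signal spreads); per-signal dropout with probability 0.02; Poisson
spurious signals (mean 0.1 per fibre, random channel, 0.5–3 kb); and
random orientation (p = 0.5).  Dropout, spurious-signal and jitter rates
have no published values; they are declared, tunable defaults chosen to be
plausible for automated spot calling on combed DNA.  Under these defaults
the signal-length sd is √2·J/stretch µm (≈ 0.21 µm at J = 0.3 kb), a
closed form the suite verifies at n ≈ 10⁴ signals.

Ground truth (haplotype, window, stretch, orientation, genotypes) is
written to separate sidecar files; the analysis path reads only the signal
table.  Reproducibility is byte-exact for a given `(config, seed)`;
per-fibre RNG substreams are derived by counter
(`[seed, 1, individual, fibre]`) so cohorts can be regenerated stably.

Because a fibre must span FP1–FP4 to be countable, large alleles (e.g.
82 copies ≈ 536 kb flank-to-flank) are covered only by the longest fibres.
The generator therefore supports `min_intact_per_haplotype`: after the base
fibres, it adds window-conditioned fibres (lengths drawn from the same
truncated normal conditioned on sufficiency) until each haplotype has the
requested number of flank-spanning fibres.  This mirrors the practice of
scanning slides until enough analysable fibres are found; it changes the
*number* of informative fibres, not the noise acting on any fibre.  If the
length distribution cannot reach the required span the generator raises a
configuration error rather than silently stretching fibres.

The packaged cohort preset (`published_cohort_config`) reconstructs the
published study conditions: 46 unrelated chromosomes carrying the published
allele multiset, paired deterministically (sorted lower half against upper
half, one (19,19) homozygote) into 23 individuals — every heterozygous pair
differs by ≥ 2 copies — plus 18 related individuals duplicating unrelated
genotypes (identity-by-descent fill-in) whose chromosomes are flagged out
of unrelated-chromosome accounting; 40 of 41 individuals are heterozygous.
The published text mentions one allele "found six times" while the printed
table's maximum occurrence is 5 and sums to 46; the package follows the
table.

## Per-fibre analysis

**Barcode matching.**  The map splits at the array into a centromeric block
(GMC + FP1/FP2) and a telomeric block (FP3/FP4), because the unknown array
length forbids one affine map across it.  For each orientation and block,
offset hypotheses are seeded from every colour-matched (observed, expected)
bar pair at the nominal stretch, deduplicated on a 2-kb grid; each
hypothesis is scored by greedy one-to-one nearest assignment within a
tolerance (default 5 kb), ranking by (matches, total error).  The top five
hypotheses are refined by iterated least squares of expected position (kb)
on observed position (µm), with the fitted scale constrained to a
physically plausible band around the nominal stretch (0.7–1.35×); the best
refined fit wins, and the orientation with more matched bars is kept (ties
are reported as orientation `unknown`).  Two safeguards matter in practice:
red bars are excluded from fitting and assigned post hoc under a tighter
tolerance, because the array supplies a red signal every ~6 kb and red
matches would otherwise reward arbitrary placements; and when the two
blocks claim the same observed signal the larger block wins, demoting
fits that wandered across the array.  Fibres matching fewer than 4 elements
(configurable) are unusable.

**Integrity gating.**  `full` requires all of FP1–FP4 matched;
`centromeric_only` / `telomeric_only` mark fibres where only one flank pair
survives; repeat counts are only ever produced from `full` fibres.

**Stretch calibration.**  The designated 128-kb motif's measured µm span
gives the fibre's exact factor (128/64.00 µm = 2.0 kb/µm).  Distances use
the per-fibre factor, never the nominal constant; without a calibrated
fibre, distance outputs are omitted.

**Repeat counting.**  Red signals strictly between the inner FP2 and FP3
edges (edges extrapolated from any matched flank bar via known intra-element
offsets) are merged when closer than `merge_gap` (default 1.0 kb — below
half the 3.739-kb inter-unit dark gap, so true gaps never merge) and
counted.  Counting signals alone is biased by dropout: a missing unit is
plainly visible as a gap widened by one 6.132-kb period, and a human
counter would never miss it.  The counter therefore imputes hidden units
from gap lengths — `round((gap − baseline)/6.132)` per gap, with baselines
8.3 kb (FP2 edge to first label), 3.739 kb (internal) and 4.739 kb (last
label to FP3 edge) — and falls back to span arithmetic when no red signal
survives.  The decision boundary (±3 kb) is an order of magnitude above
the accumulated jitter on a gap (~0.45 kb), so imputation is essentially
error-free at default noise.  The RNU2-4P cross-reaction lies outside the
FP3 edge and is excluded by construction.

**Distances.**  `brca1_to_array` is measured from the BRCA1-end anchor bar
to the first array signal minus the 1,000-bp label offset, so a noise-free
fibre returns the 123.7-kb map constant exactly.  Whether the published
+2.3-kb offset of the measured mean (126 kb) from that expected size is
measurement bias or an annotation difference cannot be decided from text;
the simulator uses the map constant as truth, and the acceptance property
treats the published value as consistent-with rather than a point target.

## Genotype calling and cohort statistics

Per-individual counts from gated fibres are clustered by single linkage
with distance ≤ `merge_tol` (default 1 copy, the documented between-counter
disagreement); clusters rank by support, representatives are medians with
ties broken low, and a second allele is called iff the runner-up has
support ≥ `min_support` (default 2 — the testable analogue of replicate
human counting) and differs from the leader by > `merge_tol`.  Individuals
with a single cluster from < 6 intact fibres are called homozygous with a
confidence note, since a missed second allele cannot be excluded.  A
consequence of the merge rule: two true alleles differing by exactly one
copy in the same individual are inherently unresolvable and collapse to a
homozygote — a known limitation, not a defect, and the reason the preset
cohort pairs alleles ≥ 2 copies apart.

Allele tables tally occurrences over chromosomes flagged unrelated
(per-chromosome flags in the manifest; how a real cohort condenses related
individuals is study metadata the pipeline does not guess).  Frequencies
round half-away-from-zero to 2 dp, which reproduces the published
frequency column exactly from the occurrence column (1/46 → 0.02, 2/46 →
0.04, 3/46 → 0.07, 5/46 → 0.11).  Observed heterozygosity is the fraction
of individuals with two distinct called alleles, reported raw and at 2 dp.
Distance summaries are sample means ± sd (n−1).

## Array placement

Alignment evidence is modelled as interval matches (running an aligner is
out of scope): segments of a contig — or of the reference itself — matching
the reference, the 6,132-bp repeat unit, or the sequenced junctions (right:
416 bp = 36 bp unit + 380 bp flank; left: 92 bp = 47 bp unit + 45 bp
flank).  The array interval is the merged reference span of repeat-unit
matches whose telomeric edge coincides, within a 50-bp tolerance (guarding
rounded inputs; the printed coordinates agree to 1 bp), with a right
junction's repeat/flank boundary; disjoint anchored candidates raise an
ambiguity error, and junction-free evidence returns status `ambiguous`.
Contigs chain by projected unique-sequence reference overlaps of at least
`min_overlap` (default 300 bp — small enough to keep the published ~500-bp
and 1.3-kb overlaps, above typical interspersed-repeat match noise).
Because precedence comes from interval order, a cyclic overlap graph is
unrepresentable in this evidence model; the corresponding error class
exists for API completeness.  A contig is flagged as mis-assembled when a
repeat-unit block sits at the same end as a unique-sequence overlap with a
chain neighbour: direct unique continuity leaves no room for an intervening
repeat block, so the block belongs at the other end.  The fixture generator
plants an array, tiles both flanks with five contigs (the two
array-adjacent ones carrying repeat matches at their array-facing ends) and
can move one repeat block to the wrong end to create the defect with known
ground truth.

## Problem sizes and numerical choices

The acceptance run simulates the full 41-individual preset (≈ 1,250 fibres
after top-up) and completes in well under two minutes on one CPU; the test
suite additionally checks zero-noise exactness for every allele 1–100 (two
fibres each), default-noise genotype recovery over 20 seeded replicates of
3-individual sub-cohorts, and mis-assembly detection over 50 seeded
fixtures.  Tie-breaks are deterministic throughout (stable sorts, lower
median, lexicographic cluster ranking); truncated normals are sampled by
rejection; µm values are written at 4 dp and bp values as integers.

## What passing tests do and do not show

The generator reproduces the statistical structure the analysis relies on —
stretch variation, boundary jitter, dropout, spurious signals, breakage,
orientation — but not image-level effects (point-spread blur, uneven
hybridisation, crossing or bundled fibres, partial digestion) or biological
complications such as somatic mosaicism and rearranged repeat patterns.
Exact genotype recovery on synthetic cohorts therefore demonstrates the
soundness of the inference chain under the declared noise model, not
expected field accuracy on microscope images; the integrity gate,
per-fibre calibration and support thresholds are the mechanisms that
transfer, since they mirror how the wet-lab analysis defends against the
same failure modes.
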