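# Methods

This note records the scientific model behind `crossprobe`, the
conventions and tunables it commits to, what the synthetic fixtures do and
do not emulate, and the numerical choices made where the design was
genuinely open.

## Probe model and window reconstruction

An Infinium probe interrogates one CpG through a 50-mer oligo. Type I
chemistry uses two probes per site (methylated/unmethylated allele); type
II uses a single probe with degenerate bases at CpG cytosines. For
cross-species mapping the relevant object is the *unconverted*
design-strand window around the target CpG: 50 nt for type I and 51 nt
for type II, where the 51st base is the G of the target dinucleotide.
Mapping uses the unconverted window against the unconverted target
genome — no bisulfite wildcarding (T≠C during comparison) — because the
question asked is sequence conservation of the design region, not
alignment of converted reads.

Canonical target offsets. Within the window the target C sits at offset
48 (of 50, type I) and 49 (of 51, type II), i.e. the window is the probe's
hybridization footprint with the CpG at its 3' end, plus the queried G for
type II. Any self-consistent convention would do — the offset only
anchors the near-target mismatch window and the reported CpG coordinate —
and this one matches the 50-mer chemistry plus the queried dinucleotide.

Two reconstruction paths exist, cross-checked in the test suite:

1. **SourceSeq trim** (preferred): the manifest's unconverted design
   sequence is centre-trimmed to 50/51 nt, then verified to carry CG at
   the canonical offset. If the centred placement fails verification, the
   unique CG-consistent placement is searched for; zero or multiple
   candidates are a consistency error. Which end of an over-long
   SourceSeq should be trimmed is not standardized anywhere we could
   anchor to, so verification-plus-search replaces any fixed rule.
2. **Reference window**: the window is cut from a design reference genome
   at MAPINFO (the manifest's 1-based plus-strand coordinate of the
   target C), honouring the F/R design-strand flag. Minus-strand designs
   return the reverse complement of the covered plus-strand span.

Degenerate bases (R/Y) occur only in the converted AlleleA probe sequence;
both paths emit pure A/C/G/T.

## Coordinates

Manifests are 1-based (Illumina convention). Everything internal is
0-based half-open. Emitted BED is 0-based half-open; the decision TSV
mirrors the manifest's 1-based convention. The reported CpG coordinate is
always the plus-strand start of the CG dinucleotide (the dinucleotide is
its own reverse complement, so this is strand-stable); the strand column
records the design strand of the accepted hit. For a minus-strand hit
with window length L and target offset t, the plus-strand CG start is
`end − t − 2`.

## Genome scan

The internal aligner enumerates **every** ungapped placement with at most
`max_mm_report` mismatches (default 5) on both strands:

- genomes up to 5 Mb (configurable): full vectorised Hamming comparison
  at every offset — exact by construction;
- larger genomes: exact k-mer anchors with full verification. The anchor
  length is `min(12, L // (max_mm_report + 1))` so that `max_mm_report+1`
  disjoint anchors fit in the window; by pigeonhole at least one anchor is
  mismatch-free in every reportable placement, making the seeded scan
  complete rather than heuristic (anchors are additionally taken at every
  probe offset). For a 50-mer at 5 mismatches the anchor is 8 nt. If the
  mismatch budget is so large that anchors would drop below 4 nt, the
  scanner falls back to the full scan.

An N in the reference counts as a mismatch during scanning; criterion (d)
re-examines the accepted span and flags ambiguity explicitly, so the two
concerns never mix. Gapped placements are not enumerated internally:
criterion (a) rejects them outright, so it suffices to *detect* that an
external aligner (BLAT, via PSL import) reported one. PSL rows with
`qNumInsert > 0` or `tNumInsert > 0` become `has_indel` hits; ungapped PSL
rows get their per-base mismatch offsets recomputed from the genome, since
PSL itself only carries counts.

`max_mm_report = 5` doubles as the suboptimal-hit ceiling: hits with 3–5
mismatches cannot pass criterion (c) but must be visible to adjudicate
criterion (b). The ceiling is configurable and recorded in every run's
config snapshot, because BLAT's own notion of "suboptimal" depends on
scoring parameters that differ between installations.

## Filter semantics

Reasons accumulate per probe; pass ⇔ no reasons. Points fixed here that a
one-line rule leaves open:

- "within 5 bp of the target site" = the CpG dinucleotide plus 5 nt each
  side (a 12-nt window, clipped at the window ends). Including the
  dinucleotide makes CpG conservation a consequence of criterion (c); the
  separate `TARGET_NOT_CPG` check makes it explicit and toggleable
  (`require_target_cpg`, on by default). Whether "target site" means the
  C alone or the dinucleotide is not decidable from the rule's usual
  statement; both are reachable via `near_target_halfwidth`.
- "only one best hit and no suboptimal hits" = a strict minimum-mismatch
  hit (tie ⇒ `MULTI_HIT`) with no other hit at ≤ `suboptimal_mm_ceiling`
  mismatches anywhere (⇒ `SUBOPTIMAL_HIT`).
- Hits on scaffolds/unplaced contigs are treated like chromosomal hits;
  the autosomal restriction is applied later, during validation, matching
  the order of operations of the published workflow.
- Unreconstructable probes (no SourceSeq, no reference) are counted and
  logged, not silently dropped into a fail reason: they represent missing
  input, not a mapping verdict.

Tightening the configuration (smaller `max_mm_rest`, larger
`near_target_halfwidth`) can only shrink the pass set; this monotonicity
is property-tested.

## Synthetic fixtures

`fixtures` plants design windows into a random i.i.d. genome (default GC
fraction 0.4, two 10-kb chromosomes for the standard fixture) under six
scenarios, each engineered to trip exactly one criterion: `perfect`,
`mismatch_at` (substitutions at stated probe offsets; verdict depends on
where they land), `duplicate` (identical window at ≥2 loci), `indel`
(secondary locus carrying the window with 1–3 bases deleted, emitted as a
gapped PSL alignment the way an external aligner would report it),
`ambiguous_base` (N written into the mapped span, outside the near-target
window so the scenario maps to a single reason), and `absent`. Planted
loci are kept ≥ 60 nt apart so uniqueness semantics stay unambiguous.
The expected verdict is derived from plant geometry alone — arithmetic on
the planted offsets against the filter thresholds — independently of the
pipeline that is being checked.

Each fixture also produces a *design reference* genome carrying the
unmutated windows, so MAPINFO points at real sequence and the two
reconstruction paths can be cross-checked; manifests carry SourceSeq as
the window plus 5 nt of genomic flank per side, so reconstruction never
*needs* the reference. Type II AlleleA probe sequences carry R at CpG
cytosines and T at converted non-CpG cytosines, mimicking the real
manifest dialect; type I allele A converts every C to T.

What the fixtures do **not** emulate: intensity-level (IDAT) data and its
preprocessing, human genome context beyond the SourceSeq flanks,
polymorphism (SNPs under probes), bisulfite-conversion artifacts, and
realistic genome repeat structure (duplicated loci are planted, not
evolved). Passing the fixture round-trip therefore demonstrates the
correctness of the mapping/filtering logic, not the biological error rate
of the selected probes on real samples.

At 10-kb scale, accidental near-matches of a random 50-mer (probability
per window ≈ 10⁻²¹ at ≤5 mismatches) are negligible, so planted truth is
exact rather than probabilistic.

## Validation stage

Detection filtering keeps a probe only when detection p < 0.01 (strict
inequality) in **every** sample; "every" is deliberate, not a tolerance
fraction, and the threshold is configurable. The optional autosomal
restriction classifies chromosome names of the form `chr<digits>` (or bare
digits) as autosomal; everything else — sex chromosomes, scaffolds — is
dropped, and a probe missing from the chromosome map is an error rather
than a guess. The report carries counts before and after each step.

Replicate concordance is the pairwise Pearson correlation of beta columns;
the average R aggregates the upper triangle only (10 pairs for 5 samples).
Constant columns yield undefined correlations, reported as NaN and
excluded from the average with a warning.

Region comparison pairs each probe's across-sample average beta with the
methylation level of every region whose half-open interval contains the
CpG's C position; probes in several overlapping regions are paired with
each and flagged. R is reported per region label, overall, and per
Infinium type.

The synthetic concordance check simulates betas as region level +
N(0, σ) clipped to [0, 1]. Clipping (rather than resampling) slightly
attenuates correlations near the boundaries, which is why the analytic
comparison in the tests — expected R = σ_L / √(σ_L² + σ²/n) for level
spread σ_L and n samples — is asserted only at small σ where clipping is
negligible. Across σ ∈ {0.3, 0.2, 0.1, 0.05, 0.02} the mean recovered R
over 20 replicates rises monotonically and exceeds 0.99 at the lowest
noise level.

## Problem sizes

The standard test fixture is 24 probes on 2 × 10 kb chromosomes; the
acceptance script uses five such fixtures (120 probes), 100 random
(50-mer, 10-kb) scanner instances, and 20 replicates per noise level for
the concordance sweep. These sizes make every check exhaustive or
near-exhaustive while keeping the whole suite in the seconds range; all
of them are parameters, and the same code paths run unchanged on a real
manifest (~10⁶ rows) and a real assembly (~3 Gb, where the seeded scanner
replaces the full scan).

## Known limitations

- The toolkit consumes exported beta/detection-p matrices; IDAT parsing
  and background correction (noob/minfi) are upstream and out of scope.
- No SNP-aware masking: polymorphisms under a probe can still produce
  false methylation signals in real samples.
- Replicating a published full-scale probe list exactly also depends on
  the external aligner's parameters (tile size, minimum score), which are
  rarely reported; the config snapshot exists precisely so that this
  package's own runs are replicable parameter-for-parameter.
- The published workflow distinguishes an autosomal detected-probe count
  from a slightly smaller "finally selected" count without describing the
  intervening step; the validation report surfaces its own counts at each
  stage and does not guess at undocumented filters.
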