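# crossprobe

Cross-species re-targeting of Illumina Infinium methylation-array probes
onto non-human genomes.

Illumina's methylation BeadChips (450K, MethylationEPIC) were designed for
the human genome, but a substantial minority of their probes hybridize
cleanly to the genomes of other primates. `crossprobe` implements the
bioinformatic selection that makes such reuse safe: it reconstructs each
probe's bisulfite-unconverted design window from the manufacturer's
manifest, maps that window onto a target reference genome (for example the
crab-eating macaque assembly macFas5), keeps only probes whose placement
is unambiguous and clean, annotates the survivors with gene and ortholog
context, and validates the resulting methylation data.

It is written for epigenomics researchers who want to run a human EPIC
array on non-human primate samples and need a defensible, auditable probe
list — plus a synthetic-fixture generator so the whole pipeline is testable
at desk scale without downloading a genome.

## The selection rule

For each probe the toolkit rebuilds the unconverted design-strand window
around the target CpG — 50 nt for Infinium type I probes, 51 nt for type
II (the extra base being the G of the target dinucleotide) — and
enumerates every ungapped placement of that window on either strand of the
target genome with at most *m* mismatches (default *m* = 5). A probe
becomes **high-confidence** only if all four criteria hold:

- **(a) no insertions/deletions** — any gapped alignment (native scan or
  imported from BLAT PSL) rejects the probe (`INDEL`);
- **(b) one best hit, no suboptimal hits** — a strict minimum-mismatch
  placement, with no other placement anywhere at ≤ *m* mismatches
  (`MULTI_HIT`, `SUBOPTIMAL_HIT`, `NO_HIT`);
- **(c) clean near the target** — no mismatch within the 12-nt window
  made of the CpG dinucleotide plus 5 nt on each side
  (`NEAR_TARGET_MISMATCH`), and at most two mismatches in the rest of the
  window (`TOO_MANY_MISMATCHES`);
- **(d) no ambiguous bases** — the mapped reference span contains no
  non-ACGT character (`AMBIGUOUS_BASE`).

A separate, on-by-default check requires the mapped target dinucleotide to
be CG (`TARGET_NOT_CPG`). Every verdict carries its machine-readable
reasons, so a probe list is an auditable artifact, not a black box.

Downstream, beta values (methylated-signal fractions in [0, 1]) from the
retained probes are validated by detection-p filtering (p < .01 in every
sample), pairwise Pearson correlation across replicates, and comparison of
per-probe average betas against published methylated regions.

## Worked example

Generate a synthetic fixture — a toy genome with 24 probes planted under
known failure scenarios — and run the selection on it:

```bash
crossprobe simulate --n-probes 24 --seed 11 --out-dir demo/fx
crossprobe select \
    --manifest demo/fx/manifest.csv \
    --genome   demo/fx/genome.fa \
    --psl      demo/fx/gapped.psl \
    --out      demo/decisions.tsv
```

which prints

```
pass 5/24 (type I 2, type II 3)
```

and writes `demo/decisions.summary.json`:

```json
{
  "n_probes": 24,
  "n_pass": 5,
  "n_pass_type_I": 2,
  "n_pass_type_II": 3,
  "n_fail": 19,
  "n_unreconstructable": 0,
  "pass_fraction": 0.20833333333333334,
  "reason_counts": {
    "MULTI_HIT": 4,
    "INDEL": 4,
    "AMBIGUOUS_BASE": 4,
    "NO_HIT": 4,
    "TOO_MANY_MISMATCHES": 3
  }
}
```

Of the 24 planted probes, 5 pass (those planted verbatim, plus those whose
planted mismatches fall outside the protected near-target window and
within the 2-mismatch allowance); each of the engineered failure modes is
rejected for exactly its intended reason. The decision table pairs every
probe with its verdict and mapped coordinate:

```
probe_id  status  reasons     infinium_type  chrom  pos_1based  strand  n_mismatches
cp00000   pass    .           II             chr2   7658        -       0
cp00001   pass    .           I              chr2   7164        +       1
cp00002   fail    MULTI_HIT   II             .      .           .       .
```

The fixture directory also contains `truth.tsv`, the planted ground truth,
which the selection output matches exactly — this round-trip is the
toolkit's central self-check.

For a real application, point `--manifest` at the manufacturer's EPIC
manifest CSV, `--genome` at the target assembly FASTA, and optionally
`--psl` at BLAT alignments of the reconstructed windows; then annotate
with `crossprobe annotate` (GFF3 + ortholog TSV) and validate exported
beta/detection-p matrices with `crossprobe validate`. `crossprobe run-all
--config run.yaml` drives all stages from one declarative config and
snapshots it next to the outputs.

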