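"""The four high-confidence selection criteria and the selection pipeline.

A probe survives cross-species re-targeting only when its placement on the
target genome is unambiguous and clean:

(a) no insertions/deletions in any reported alignment;
(b) exactly one best hit and no suboptimal hits elsewhere in the genome;
(c) no mismatches within 5 bp of the target site, and at most two
    mismatches in the rest of the window;
(d) no ambiguous bases (non-ACGT) in the mapped reference span.

"Within 5 bp of the target site" is taken as the CpG dinucleotide itself
plus 5 nt flanking on each side (a 12-nt window); with the dinucleotide
included, conservation of the target CpG follows from criterion (c), and a
separate, toggleable TARGET_NOT_CPG check makes the requirement explicit.
"Only one best hit and no suboptimal hits" is operationalised as a strict
minimum-mismatch hit with no other hit anywhere at <=
``suboptimal_mm_ceiling`` mismatches.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .aligner import (
    DEFAULT_MAX_MM_REPORT,
    GenomeHit,
    import_psl,
    scan_genome,
)
from .genome import Genome, VALID_BASES
from .manifest_io import ProbeRecord, read_manifest
from .probe_recon import (
    TargetSeq,
    UnreconstructableProbe,
    ReconstructionConsistencyError,
    reconstruct_target_seq,
)

log = logging.getLogger(__name__)


class Reason(enum.Enum):
    """Machine-readable reject reasons, one per violated criterion."""

    INDEL = "indel"                              # criterion a
    NO_HIT = "no_hit"                            # no placement at all
    MULTI_HIT = "multi_hit"                      # criterion b (tied best)
    SUBOPTIMAL_HIT = "suboptimal_hit"            # criterion b (extra hit)
    NEAR_TARGET_MISMATCH = "near_target_mismatch"  # criterion c (near window)
    TOO_MANY_MISMATCHES = "too_many_mismatches"    # criterion c (rest of window)
    AMBIGUOUS_BASE = "ambiguous_base"            # criterion d
    TARGET_NOT_CPG = "target_not_cpg"            # CpG not conserved


@dataclass(frozen=True)
class FilterConfig:
    """Tunables of the selection criteria (defaults = published rule set)."""

    near_target_halfwidth: int = 5
    max_mm_rest: int = 2
    suboptimal_mm_ceiling: int = DEFAULT_MAX_MM_REPORT
    require_target_cpg: bool = True

    def __post_init__(self) -> None:
        if min(self.near_target_halfwidth, self.max_mm_rest,
               self.suboptimal_mm_ceiling) < 0:
            raise ValueError("filter thresholds must be non-negative")
        if self.suboptimal_mm_ceiling < self.max_mm_rest:
            raise ValueError("suboptimal_mm_ceiling must be >= max_mm_rest")


@dataclass(frozen=True)
class FilterDecision:
    """Auditable verdict for one probe: pass iff no reasons."""

    probe_id: str
    status: str  # "pass" | "fail"
    reasons: frozenset[Reason]
    accepted_hit: Optional[GenomeHit] = None
    target_cpg_coord: Optional[tuple[str, int, str]] = None  # chrom, 0-based C, strand
    infinium_type: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.status == "pass") != (not self.reasons):
            raise ValueError(f"{self.probe_id}: status/reasons inconsistent")


def target_cpg_position(hit: GenomeHit, target: TargetSeq) -> int:
    """Plus-strand 0-based start of the target CG under an ungapped hit."""
    t = target.target_offset
    if hit.strand == "+":
        return hit.start + t
    return hit.end - t - 2


def near_target_window(target: TargetSeq, halfwidth: int) -> range:
    """Probe-coordinate offsets counted as 'near' the target site.

    The CpG dinucleotide plus ``halfwidth`` nt on each side, clipped to the
    window.
    """
    t = target.target_offset
    lo = max(0, t - halfwidth)
    hi = min(len(target) - 1, t + 1 + halfwidth)
    return range(lo, hi + 1)


def evaluate_probe(
    target: TargetSeq,
    hits: Sequence[GenomeHit],
    genome: Genome,
    cfg: FilterConfig = FilterConfig(),
) -> FilterDecision:
    """Apply criteria (a)-(d) to one probe's hit list.

    Reasons accumulate (a probe can fail several criteria at once); the
    verdict is independent of hit order.
    """
    reasons: set[Reason] = set()
    for h in hits:
        if not (h.chrom in genome and 0 <= h.start <= h.end <= genome.chrom_len(h.chrom)):
            raise ValueError(
                f"{target.probe_id}: hit {h.chrom}:{h.start}-{h.end} outside genome"
            )
    if any(h.has_indel for h in hits):
        reasons.add(Reason.INDEL)
    if not hits:
        reasons.add(Reason.NO_HIT)

    accepted: Optional[GenomeHit] = None
    cpg_coord: Optional[tuple[str, int, str]] = None
    ungapped = sorted(
        (h for h in hits if not h.has_indel),
        key=lambda h: (h.n_mismatches, h.chrom, h.start, h.strand),
    )
    if ungapped:
        best_mm = ungapped[0].n_mismatches
        tied = [h for h in ungapped if h.n_mismatches == best_mm]
        if len(tied) > 1:
            reasons.add(Reason.MULTI_HIT)
        else:
            best = tied[0]
            others = [h for h in ungapped if h is not best]
            if any(h.n_mismatches <= cfg.suboptimal_mm_ceiling for h in others):
                reasons.add(Reason.SUBOPTIMAL_HIT)
            near = near_target_window(target, cfg.near_target_halfwidth)
            near_mm = [o for o in best.mismatch_offsets if o in near]
            rest_mm = [o for o in best.mismatch_offsets if o not in near]
            if near_mm:
                reasons.add(Reason.NEAR_TARGET_MISMATCH)
            if len(rest_mm) > cfg.max_mm_rest:
                reasons.add(Reason.TOO_MANY_MISMATCHES)
            span = genome.fetch(best.chrom, best.start, best.end)
            if set(span) - VALID_BASES:
                reasons.add(Reason.AMBIGUOUS_BASE)
            pos = target_cpg_position(best, target)
            if cfg.require_target_cpg:
                dinuc = genome.fetch(best.chrom, pos, min(pos + 2, genome.chrom_len(best.chrom)))
                if dinuc != "CG":
                    reasons.add(Reason.TARGET_NOT_CPG)
            if not reasons:
                accepted = best
                cpg_coord = (best.chrom, pos, best.strand)

    return FilterDecision(
        probe_id=target.probe_id,
        status="pass" if not reasons else "fail",
        reasons=frozenset(reasons),
        accepted_hit=accepted,
        target_cpg_coord=cpg_coord,
        infinium_type=target.infinium_type,
    )


@dataclass
class SelectionSummary:
    n_probes: int = 0
    n_pass: int = 0
    n_pass_type_I: int = 0
    n_pass_type_II: int = 0
    n_fail: int = 0
    n_unreconstructable: int = 0
    pass_fraction: float = 0.0
    reason_counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_probes": self.n_probes,
            "n_pass": self.n_pass,
            "n_pass_type_I": self.n_pass_type_I,
            "n_pass_type_II": self.n_pass_type_II,
            "n_fail": self.n_fail,
            "n_unreconstructable": self.n_unreconstructable,
            "pass_fraction": self.pass_fraction,
            "reason_counts": dict(self.reason_counts),
        }


def run_selection(
    manifest: str | Path | Sequence[ProbeRecord],
    genome: str | Path | Genome,
    cfg: FilterConfig = FilterConfig(),
    engine: str = "internal",
    psl_path: Optional[str | Path] = None,
    reference: Optional[Genome] = None,
    max_mm_report: Optional[int] = None,
    scan_method: str = "auto",
) -> tuple[list[FilterDecision], SelectionSummary]:
    """Full pipeline: manifest -> windows -> hits -> verdicts + summary.

    ``engine`` is ``"internal"`` (scan; a supplied PSL is merged in, which
    is how externally reported gapped alignments reach criterion a) or
    ``"psl"`` (imported alignments only).  Deterministic for fixed inputs.
    """
    records = (
        read_manifest(manifest) if isinstance(manifest, (str, Path)) else list(manifest)
    )
    gen = Genome.from_fasta(genome) if isinstance(genome, (str, Path)) else genome
    max_mm = cfg.suboptimal_mm_ceiling if max_mm_report is None else max_mm_report

    targets: dict[str, TargetSeq] = {}
    decisions: list[FilterDecision] = []
    summary = SelectionSummary(n_probes=len(records))
    order: list[str] = []
    for rec in records:
        try:
            targets[rec.ilmn_id] = reconstruct_target_seq(rec, reference)
            order.append(rec.ilmn_id)
        except (UnreconstructableProbe, ReconstructionConsistencyError) as exc:
            log.warning("probe %s unreconstructable: %s", rec.ilmn_id, exc)
            summary.n_unreconstructable += 1

    psl_hits: dict[str, list[GenomeHit]] = {}
    if psl_path is not None:
        for h in import_psl(psl_path, targets, gen):
            psl_hits.setdefault(h.probe_id, []).append(h)
    elif engine == "psl":
        raise ValueError("engine='psl' requires psl_path")

    for pid in order:
        tgt = targets[pid]
        hits: list[GenomeHit] = []
        if engine == "internal":
            hits.extend(scan_genome(tgt, gen, max_mm_report=max_mm, method=scan_method))
        elif engine != "psl":
            raise ValueError(f"unknown engine {engine!r}")
        seen = {(h.chrom, h.start, h.end, h.strand, h.has_indel) for h in hits}
        for h in psl_hits.get(pid, []):
            if (h.chrom, h.start, h.end, h.strand, h.has_indel) not in seen:
                hits.append(h)
        decisions.append(evaluate_probe(tgt, hits, gen, cfg))

    for d in decisions:
        if d.status == "pass":
            summary.n_pass += 1
            if d.infinium_type == "I":
                summary.n_pass_type_I += 1
            elif d.infinium_type == "II":
                summary.n_pass_type_II += 1
        else:
            summary.n_fail += 1
            for r in d.reasons:
                summary.reason_counts[r.name] = summary.reason_counts.get(r.name, 0) + 1
    summary.pass_fraction = summary.n_pass / summary.n_probes if summary.n_probes else 0.0
    return decisions, summary
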