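"""Ungapped, mismatch-constrained placement of probe windows on a genome.

Two engines produce the same :class:`GenomeHit` records:

* an internal exhaustive/seeded scanner that enumerates every ungapped
  placement of the window on either strand with at most ``max_mm_report``
  mismatches.  Below a configurable genome size the scan is a full
  vectorised Hamming comparison at every offset (exact by construction);
  above it, exact k-mer anchors with full verification are used.  The
  anchor length is capped at ``len(window) // (max_mm_report + 1)`` so
  that by pigeonhole at least one of the disjoint anchors is mismatch-free
  in every reportable placement — the seeded scan is therefore complete,
  not heuristic (anchors are additionally taken at every probe offset);
* a PSL importer/exporter for alignments produced externally (e.g. Blat),
  where gapped placements carry ``has_indel=True`` and are never resolved
  into per-base mismatches.

An ambiguous reference base (N) under the window counts as a mismatch for
scanning purposes; the filter engine re-examines the reference span and
flags ambiguity as its own criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np

from .genome import Genome, revcomp
from .probe_recon import TargetSeq

log = logging.getLogger(__name__)

DEFAULT_MAX_MM_REPORT = 5
SEED_LEN = 12
FULL_SCAN_LIMIT = 5_000_000  # genomes below this many bp use the full scan


class PSLFormatError(ValueError):
    """A PSL line does not have the standard 21 tab-separated columns."""


@dataclass(frozen=True)
class GenomeHit:
    """One ungapped (or imported gapped) placement of a probe window.

    Coordinates are 0-based half-open on the plus strand of the target
    genome; ``mismatch_offsets`` are 0-based positions *in probe
    coordinates* (i.e. along the design-strand window).
    """

    probe_id: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" | "-"
    mismatch_offsets: tuple[int, ...] = ()
    has_indel: bool = False
    n_matches: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_offsets)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _full_scan_chrom(
    probe_fwd: np.ndarray,
    probe_rev: np.ndarray,
    chrom_arr: np.ndarray,
    max_mm: int,
) -> list[tuple[int, str, tuple[int, ...]]]:
    """All (start, strand, probe-coordinate mismatch offsets) on one chromosome."""
    L = len(probe_fwd)
    n = len(chrom_arr)
    out: list[tuple[int, str, tuple[int, ...]]] = []
    if n < L:
        return out
    windows = np.lib.stride_tricks.sliding_window_view(chrom_arr, L)
    for strand, parr in (("+", probe_fwd), ("-", probe_rev)):
        neq = windows != parr
        mm = neq.sum(axis=1)
        for i in np.nonzero(mm <= max_mm)[0]:
            offs = np.nonzero(neq[i])[0]
            if strand == "-":
                offs = L - 1 - offs  # window offset -> probe coordinate
            out.append((int(i), strand, tuple(int(o) for o in sorted(offs))))
    return out


def _seeded_scan_chrom(
    probe_fwd: np.ndarray,
    probe_rev: np.ndarray,
    chrom: str,
    chrom_seq: str,
    chrom_arr: np.ndarray,
    max_mm: int,
    seed_len: int,
) -> list[tuple[int, str, tuple[int, ...]]]:
    """Anchor-and-verify scan: exact seed index, full Hamming verification."""
    L = len(probe_fwd)
    n = len(chrom_arr)
    out: list[tuple[int, str, tuple[int, ...]]] = []
    if n < L:
        return out
    index: Dict[str, list[int]] = {}
    for i in range(n - seed_len + 1):
        index.setdefault(chrom_seq[i : i + seed_len], []).append(i)
    for strand, parr in (("+", probe_fwd), ("-", probe_rev)):
        pseq = parr.tobytes().decode("ascii")
        starts: set[int] = set()
        for s in range(L - seed_len + 1):
            for pos in index.get(pseq[s : s + seed_len], ()):
                cand = pos - s
                if 0 <= cand <= n - L:
                    starts.add(cand)
        for cand in starts:
            neq = chrom_arr[cand : cand + L] != parr
            if int(neq.sum()) <= max_mm:
                offs = np.nonzero(neq)[0]
                if strand == "-":
                    offs = L - 1 - offs
                out.append((cand, strand, tuple(int(o) for o in sorted(offs))))
    return out


def scan_genome(
    target: TargetSeq,
    genome: Genome,
    max_mm_report: int = DEFAULT_MAX_MM_REPORT,
    method: str = "auto",
    full_scan_limit: int = FULL_SCAN_LIMIT,
    seed_len: int = SEED_LEN,
) -> list[GenomeHit]:
    """Every ungapped placement of ``target`` with <= ``max_mm_report`` mismatches.

    Both strands are searched; hits are deterministic and sorted by
    (chrom, start, strand).  ``method`` is ``"full"``, ``"seeded"`` or
    ``"auto"`` (full scan when the genome is below ``full_scan_limit``).
    """
    if max_mm_report < 0:
        raise ValueError("max_mm_report must be >= 0")
    if method == "auto":
        method = "full" if genome.total_len() <= full_scan_limit else "seeded"
    probe_fwd = _encode(target.sequence)
    probe_rev = _encode(revcomp(target.sequence))
    L = len(probe_fwd)
    # pigeonhole completeness: max_mm+1 disjoint anchors must fit the window
    seed_len = min(seed_len, L // (max_mm_report + 1))
    if method == "seeded" and seed_len < 4:
        method = "full"  # mismatch budget too large for useful anchors
    hits: list[GenomeHit] = []
    for chrom in genome.chroms:
        arr = genome.encoded(chrom)
        if method == "full":
            found = _full_scan_chrom(probe_fwd, probe_rev, arr, max_mm_report)
        elif method == "seeded":
            found = _seeded_scan_chrom(
                probe_fwd, probe_rev, chrom, genome.sequence(chrom), arr,
                max_mm_report, seed_len,
            )
        else:
            raise ValueError(f"unknown scan method {method!r}")
        for start, strand, offs in found:
            hits.append(
                GenomeHit(
                    probe_id=target.probe_id,
                    chrom=chrom,
                    start=start,
                    end=start + L,
                    strand=strand,
                    mismatch_offsets=offs,
                    n_matches=L - len(offs),
                )
            )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# PSL import / export
# ---------------------------------------------------------------------------

PSL_NCOL = 21


def _is_psl_data_line(fields: Sequence[str]) -> bool:
    try:
        int(fields[0])
        return True
    except (ValueError, IndexError):
        return False


def import_psl(
    path: str | Path,
    targets: Mapping[str, TargetSeq],
    genome: Optional[Genome] = None,
) -> list[GenomeHit]:
    """Read 21-column PSL alignments into :class:`GenomeHit` records.

    Rows with query or target inserts get ``has_indel=True``.  For ungapped
    rows, per-base mismatch offsets are recomputed against ``genome`` when
    it is supplied (PSL itself only carries counts).  Unknown query names
    are logged and skipped; a wrong column count is a format error.
    """
    hits: list[GenomeHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if not _is_psl_data_line(fields):
                if lineno <= 5:  # psLayout header block
                    continue
                raise PSLFormatError(f"{path}:{lineno}: unparseable line")
            if len(fields) != PSL_NCOL:
                raise PSLFormatError(
                    f"{path}:{lineno}: expected {PSL_NCOL} columns, got {len(fields)}"
                )
            (matches, mismatches, _rep, _ncount, q_num_ins, _qbi, t_num_ins,
             _tbi, strand, q_name, _q_size, _q_start, _q_end, t_name, _t_size,
             t_start, t_end) = fields[:17]
            if q_name not in targets:
                log.warning("%s:%d: unknown probe %r, skipped", path, lineno, q_name)
                continue
            has_indel = int(q_num_ins) > 0 or int(t_num_ins) > 0
            hit = GenomeHit(
                probe_id=q_name,
                chrom=t_name,
                start=int(t_start),
                end=int(t_end),
                strand=strand[0],
                mismatch_offsets=(),
                has_indel=has_indel,
                n_matches=int(matches),
            )
            if not has_indel and genome is not None and t_name in genome:
                hit = recompute_mismatches(hit, targets[q_name], genome)
            hits.append(hit)
    return hits


def recompute_mismatches(
    hit: GenomeHit, target: TargetSeq, genome: Genome
) -> GenomeHit:
    """Fill mismatch offsets of an ungapped hit from the reference sequence."""
    span = genome.fetch(hit.chrom, hit.start, hit.end)
    probe = target.sequence if hit.strand == "+" else revcomp(target.sequence)
    if len(span) != len(probe):
        raise ValueError(f"{hit.probe_id}: span/probe length mismatch on ungapped hit")
    offs = [i for i, (a, b) in enumerate(zip(probe, span)) if a != b]
    if hit.strand == "-":
        offs = [len(probe) - 1 - i for i in offs]
    return GenomeHit(
        probe_id=hit.probe_id,
        chrom=hit.chrom,
        start=hit.start,
        end=hit.end,
        strand=hit.strand,
        mismatch_offsets=tuple(sorted(offs)),
        has_indel=False,
        n_matches=len(probe) - len(offs),
    )


def write_psl(
    hits: Iterable[GenomeHit],
    targets: Mapping[str, TargetSeq],
    genome: Genome,
    path: str | Path,
) -> None:
    """Export ungapped hits as single-block PSL rows (gapped as two blocks).

    The exporter exists for round-tripping and for interoperating with
    PSL-consuming tools; gapped hits are written as a two-block alignment
    with the insert length inferred from the span/window length difference.
    """
    with open(path, "w") as fh:
        for h in hits:
            tgt = targets[h.probe_id]
            L = len(tgt)
            t_size = genome.chrom_len(h.chrom) if h.chrom in genome else h.end
            if not h.has_indel:
                n_mm = h.n_mismatches
                row = [
                    L - n_mm, n_mm, 0, 0, 0, 0, 0, 0, h.strand, h.probe_id, L,
                    0, L, h.chrom, t_size, h.start, h.end, 1, f"{L},", "0,",
                    f"{h.start},",
                ]
            else:
                span = h.end - h.start
                if span < L:  # deletion in target: query insert
                    gap = L - span
                    b1 = span // 2
                    b2 = span - b1
                    row = [
                        span, 0, 0, 0, 1, gap, 0, 0, h.strand, h.probe_id, L,
                        0, L, h.chrom, t_size, h.start, h.end, 2,
                        f"{b1},{b2},", f"0,{b1 + gap},",
                        f"{h.start},{h.start + b1},",
                    ]
                else:  # insertion in target
                    gap = span - L
                    b1 = L // 2
                    b2 = L - b1
                    row = [
                        L, 0, 0, 0, 0, 0, 1, gap, h.strand, h.probe_id, L,
                        0, L, h.chrom, t_size, h.start, h.end, 2,
                        f"{b1},{b2},", f"0,{b1},",
                        f"{h.start},{h.start + b1 + gap},",
                    ]
            fh.write("\t".join(map(str, row)) + "\n")
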