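"""Reconstruction of the bisulfite-unconverted target window per probe.

Each Infinium probe interrogates one CpG.  The selection pipeline maps the
*unconverted* design-strand sequence around that CpG — 50 nt for type I
probes, 51 nt for type II (the extra base being the G of the target
dinucleotide) — against the target genome.  This module rebuilds that
window (the "modified SourceSeq") from the manifest.

Two reconstruction paths exist and are cross-checked in the test suite:

* SourceSeq trim (preferred): the manifest's unconverted design sequence is
  trimmed to the 50/51-nt window.  The window is centre-trimmed and then
  verified to carry CG at the canonical target offset (48 of 50 for type I,
  49 of 51 for type II); if the centred placement fails verification, the
  unique placement satisfying the CG invariant is searched for.
* Reference window: the window is cut directly from a design reference
  genome around MAPINFO (1-based plus-strand coordinate of the target C),
  honouring the design strand.

Degenerate bases (R/Y) appear only in the converted AlleleA probe sequence;
both reconstruction paths emit pure A/C/G/T, so nothing needs resolving at
this layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .genome import Genome, revcomp, VALID_BASES
from .manifest_io import ProbeRecord

TYPE_I_LEN = 50
TYPE_II_LEN = 51
#: 0-based offset of the target C within the window, by Infinium type
TARGET_OFFSET = {"I": 48, "II": 49}
WINDOW_LEN = {"I": TYPE_I_LEN, "II": TYPE_II_LEN}


class UnreconstructableProbe(ValueError):
    """SourceSeq absent/unusable and no reference genome available."""


class ReconstructionConsistencyError(ValueError):
    """The reconstructed window violates the CG-at-target invariant."""


@dataclass(frozen=True)
class TargetSeq:
    """Unconverted 50/51-nt design window with the target-CpG offset.

    ``sequence`` is on the design strand; ``origin_strand`` says whether the
    design strand is the plus (+) or minus (-) strand of the design build.
    Invariant: ``sequence[target_offset:target_offset+2] == "CG"``.
    """

    probe_id: str
    sequence: str
    target_offset: int
    infinium_type: str
    origin_strand: str = "+"

    def __post_init__(self) -> None:
        expect = WINDOW_LEN[self.infinium_type]
        if len(self.sequence) != expect:
            raise ValueError(
                f"{self.probe_id}: type {self.infinium_type} window must be "
                f"{expect} nt, got {len(self.sequence)}"
            )
        if self.sequence[self.target_offset : self.target_offset + 2] != "CG":
            raise ReconstructionConsistencyError(
                f"{self.probe_id}: no CG at target offset {self.target_offset}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _trim_source_seq(probe: ProbeRecord) -> str:
    L = WINDOW_LEN[probe.infinium_type]
    t = TARGET_OFFSET[probe.infinium_type]
    s = probe.source_seq.upper()
    if len(s) < L:
        raise UnreconstructableProbe(
            f"{probe.ilmn_id}: SourceSeq shorter ({len(s)}) than window ({L})"
        )
    if len(s) == L:
        return s
    lead = (len(s) - L) // 2
    win = s[lead : lead + L]
    if win[t : t + 2] == "CG":
        return win
    # centred placement inconsistent: fall back to the unique CG-consistent one
    candidates = [
        i for i in range(len(s) - L + 1) if s[i + t : i + t + 2] == "CG"
    ]
    if len(candidates) != 1:
        raise ReconstructionConsistencyError(
            f"{probe.ilmn_id}: {len(candidates)} CG-consistent trims of SourceSeq"
        )
    return s[candidates[0] : candidates[0] + L]


def _window_from_reference(probe: ProbeRecord, reference: Genome) -> str:
    if probe.map_info is None or not probe.chrom_design:
        raise UnreconstructableProbe(f"{probe.ilmn_id}: no MAPINFO/CHR for reference path")
    L = WINDOW_LEN[probe.infinium_type]
    t = TARGET_OFFSET[probe.infinium_type]
    c0 = probe.map_info - 1  # 0-based plus-strand position of the CG's C
    if probe.strand_design == "F":
        return reference.fetch(probe.chrom_design, c0 - t, c0 - t + L)
    # design on the minus strand: design offset i maps to plus position
    # (c0 + 1 + t) - i, so the covered plus span is [c0 + t - L + 2, c0 + t + 2)
    span = reference.fetch(probe.chrom_design, c0 + t - L + 2, c0 + t + 2)
    return revcomp(span)


def reconstruct_target_seq(
    probe: ProbeRecord, reference: Optional[Genome] = None
) -> TargetSeq:
    """Rebuild a probe's unconverted 50/51-nt target window.

    Prefers the SourceSeq path; falls back to cutting the window out of
    ``reference`` at MAPINFO.  Raises :class:`UnreconstructableProbe` when
    neither path is available and
    :class:`ReconstructionConsistencyError` when the window lacks CG at the
    canonical target offset.
    """
    if probe.is_control:
        raise UnreconstructableProbe(f"{probe.ilmn_id}: control probe")
    t = TARGET_OFFSET[probe.infinium_type]
    if probe.source_seq:
        win = _trim_source_seq(probe)
    elif reference is not None:
        win = _window_from_reference(probe, reference)
    else:
        raise UnreconstructableProbe(
            f"{probe.ilmn_id}: SourceSeq empty and no reference genome given"
        )
    if set(win) - VALID_BASES:
        raise UnreconstructableProbe(
            f"{probe.ilmn_id}: ambiguous bases in design window"
        )
    return TargetSeq(
        probe_id=probe.ilmn_id,
        sequence=win,
        target_offset=t,
        infinium_type=probe.infinium_type,
        origin_strand="+" if probe.strand_design == "F" else "-",
    )
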