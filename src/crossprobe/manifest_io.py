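"""Illumina Infinium manifest I/O and probe-table output.

The manifest is the manufacturer's sectioned CSV: a ``[Heading]`` block of
key/value pairs, an ``[Assay]`` block with one row per probe, and an
optional ``[Controls]`` block.  Only the assay columns the selection
pipeline needs are modelled; everything else in a row is ignored but
preserved on round-trip is not attempted.

Coordinate conventions: the manifest's MAPINFO is 1-based (Illumina
convention); all internal coordinates in this package are 0-based
half-open; emitted BED is 0-based half-open; the emitted decision TSV
mirrors the manifest's 1-based convention.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

log = logging.getLogger(__name__)

ASSAY_COLUMNS = [
    "IlmnID",
    "Name",
    "Infinium_Design_Type",
    "Next_Base",
    "AlleleA_ProbeSeq",
    "SourceSeq",
    "CHR",
    "MAPINFO",
    "Strand",
]

PROBE_SEQ_ALPHABET = frozenset("ACGTRYN")


class ManifestFormatError(ValueError):
    """Raised when a manifest file violates the sectioned Illumina layout."""


@dataclass
class ProbeRecord:
    """One [Assay] row of an Infinium manifest.

    ``map_info`` is the 1-based coordinate of the target cytosine on the
    design (human) build; ``strand_design`` is the manifest's F/R flag for
    the strand the design sequence lives on.
    """

    ilmn_id: str
    infinium_type: Optional[str]  # "I" | "II"; None only for control rows
    allele_a_probe_seq: str = ""
    source_seq: str = ""
    map_info: Optional[int] = None
    chrom_design: str = ""
    strand_design: str = "F"
    next_base: Optional[str] = None
    name: str = ""
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.is_control:
            return
        if self.infinium_type not in ("I", "II"):
            raise ValueError(
                f"{self.ilmn_id}: Infinium type must be I or II, got "
                f"{self.infinium_type!r}"
            )
        if len(self.allele_a_probe_seq) != 50:
            raise ValueError(
                f"{self.ilmn_id}: AlleleA_ProbeSeq must be 50 nt, got "
                f"{len(self.allele_a_probe_seq)}"
            )
        bad = set(self.allele_a_probe_seq.upper()) - PROBE_SEQ_ALPHABET
        if bad:
            raise ValueError(f"{self.ilmn_id}: invalid probe-seq characters {bad}")
        if self.infinium_type == "II" and self.next_base:
            raise ValueError(f"{self.ilmn_id}: Next_Base is a type I field")


def read_manifest(
    path: str | Path, include_controls: bool = False
) -> list[ProbeRecord]:
    """Parse the [Assay] section of a sectioned Illumina manifest.

    Control rows are excluded unless ``include_controls`` is set, in which
    case they are appended as skeletal records with ``is_control=True``.
    Assay rows missing AlleleA_ProbeSeq or MAPINFO are skipped with a
    warning (real manifests contain such rows); structurally malformed rows
    raise :class:`ManifestFormatError` naming the line number.
    """
    records: list[ProbeRecord] = []
    controls: list[ProbeRecord] = []
    section = None
    header: list[str] | None = None
    saw_assay = False
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            first = row[0].strip()
            if first.startswith("[") and first.endswith("]"):
                section = first[1:-1].lower()
                header = None
                if section == "assay":
                    saw_assay = True
                continue
            if section == "assay":
                if header is None:
                    header = [c.strip() for c in row]
                    missing = set(ASSAY_COLUMNS) - set(header)
                    if missing:
                        raise ManifestFormatError(
                            f"line {lineno}: [Assay] header missing columns "
                            f"{sorted(missing)}"
                        )
                    continue
                if len(row) < len(header):
                    raise ManifestFormatError(
                        f"line {lineno}: expected {len(header)} fields, got {len(row)}"
                    )
                d = dict(zip(header, row))
                if not d["AlleleA_ProbeSeq"].strip() or not d["MAPINFO"].strip():
                    log.warning(
                        "line %d: skipping %s (empty AlleleA_ProbeSeq/MAPINFO)",
                        lineno,
                        d.get("IlmnID", "?"),
                    )
                    continue
                try:
                    records.append(
                        ProbeRecord(
                            ilmn_id=d["IlmnID"].strip(),
                            name=d.get("Name", "").strip(),
                            infinium_type=d["Infinium_Design_Type"].strip(),
                            next_base=d["Next_Base"].strip() or None,
                            allele_a_probe_seq=d["AlleleA_ProbeSeq"].strip().upper(),
                            source_seq=d["SourceSeq"].strip().upper(),
                            chrom_design=d["CHR"].strip(),
                            map_info=int(d["MAPINFO"]),
                            strand_design=d["Strand"].strip() or "F",
                        )
                    )
                except (ValueError, KeyError) as exc:
                    raise ManifestFormatError(f"line {lineno}: {exc}") from exc
            elif section == "controls" and include_controls:
                controls.append(
                    ProbeRecord(
                        ilmn_id=row[0].strip(), infinium_type=None, is_control=True
                    )
                )
    if not saw_assay:
        raise ManifestFormatError(f"{path}: no [Assay] section found")
    return records + controls if include_controls else records


def write_manifest(
    records: Sequence[ProbeRecord],
    path: str | Path,
    heading: Optional[dict[str, str]] = None,
    controls: Optional[Sequence[str]] = None,
) -> None:
    """Write records in the sectioned Illumina CSV dialect."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["[Heading]"])
        for k, v in (heading or {"Descriptor File Name": Path(path).name}).items():
            w.writerow([k, v])
        w.writerow(["[Assay]"])
        w.writerow(ASSAY_COLUMNS)
        for r in records:
            if r.is_control:
                continue
            w.writerow(
                [
                    r.ilmn_id,
                    r.name or r.ilmn_id,
                    r.infinium_type,
                    r.next_base or "",
                    r.allele_a_probe_seq,
                    r.source_seq,
                    r.chrom_design,
                    r.map_info,
                    r.strand_design,
                ]
            )
        if controls:
            w.writerow(["[Controls]"])
            for line in controls:
                w.writerow(line.split(","))


def manifest_stats(records: Iterable[ProbeRecord]) -> dict[str, int]:
    """Probe counts by Infinium chemistry type."""
    n1 = sum(1 for r in records if r.infinium_type == "I")
    n2 = sum(1 for r in records if r.infinium_type == "II")
    return {"n_probes": n1 + n2, "n_type_I": n1, "n_type_II": n2}


# ---------------------------------------------------------------------------
# decision-table output
# ---------------------------------------------------------------------------

TABLE_COLUMNS = [
    "probe_id",
    "status",
    "reasons",
    "infinium_type",
    "chrom",
    "pos_1based",
    "strand",
    "n_mismatches",
]


def write_probe_table(decisions, path: str | Path, fmt: str = "tsv") -> None:
    """Write filter decisions as a TSV audit table or a BED6 of passing CpGs.

    BED intervals are the 2-nt target CpG on the plus strand, 0-based
    half-open, sorted by chromosome then start; the TSV mirrors the
    manifest's 1-based coordinates.
    """
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(TABLE_COLUMNS) + "\n")
            for d in decisions:
                coord = d.target_cpg_coord
                fh.write(
                    "\t".join(
                        [
                            d.probe_id,
                            d.status,
                            ",".join(sorted(r.name for r in d.reasons)) or ".",
                            d.infinium_type or ".",
                            coord[0] if coord else ".",
                            str(coord[1] + 1) if coord else ".",
                            coord[2] if coord else ".",
                            str(len(d.accepted_hit.mismatch_offsets))
                            if d.accepted_hit
                            else ".",
                        ]
                    )
                    + "\n"
                )
    elif fmt == "bed":
        rows = []
        for d in decisions:
            if d.status != "pass":
                continue
            chrom, pos, strand = d.target_cpg_coord
            rows.append((chrom, pos, pos + 2, d.probe_id, 0, strand))
        rows.sort(key=lambda r: (r[0], r[1]))
        with open(path, "w") as fh:
            for r in rows:
                fh.write("\t".join(map(str, r)) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_probe_table(path: str | Path):
    """Read back a TSV decision table (inverse of write_probe_table)."""
    from .filter_engine import FilterDecision, Reason

    decisions = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TABLE_COLUMNS:
            raise ValueError(f"{path}: unexpected decision-table header")
        for line in fh:
            f = dict(zip(header, line.rstrip("\n").split("\t")))
            coord = (
                (f["chrom"], int(f["pos_1based"]) - 1, f["strand"])
                if f["chrom"] != "."
                else None
            )
            decisions.append(
                FilterDecision(
                    probe_id=f["probe_id"],
                    status=f["status"],
                    reasons=frozenset(
                        Reason[r] for r in f["reasons"].split(",") if r != "."
                    ),
                    accepted_hit=None,
                    target_cpg_coord=coord,
                    infinium_type=None if f["infinium_type"] == "." else f["infinium_type"],
                )
            )
    return decisions
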