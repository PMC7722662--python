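"""Synthetic genomes with planted, labelled probe targets.

Every downstream stage of the selection pipeline is testable without any
download: a random genome is generated, probe design windows are planted
into it under controlled failure scenarios, and a matching Illumina-style
manifest plus a truth table of intended verdicts is emitted.  Each
scenario is engineered to trip exactly one selection criterion:

=============== =====================================================
scenario        intended verdict (at default :class:`FilterConfig`)
=============== =====================================================
perfect         pass
mismatch_at     NEAR_TARGET_MISMATCH / TOO_MANY_MISMATCHES / pass,
                depending on where and how many substitutions land
duplicate       MULTI_HIT (identical window at >= 2 loci)
indel           INDEL (secondary locus matches only with a gap;
                the gapped alignment is emitted as a PSL file, the
                way an external aligner would report it)
ambiguous_base  AMBIGUOUS_BASE (N written into the mapped span)
absent          NO_HIT (window never written to the genome)
=============== =====================================================

Besides the mutated target genome, a *design reference* genome is produced
carrying the original (unmutated) windows, so the manifest's MAPINFO/CHR
columns point at real sequence and reference-based reconstruction can be
cross-checked against the SourceSeq path.  Planted manifests always carry
a populated SourceSeq (5-nt genomic flank on each side of the window), so
reconstruction never requires the design reference.

Fixture generation is a pure function of (specs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .aligner import GenomeHit, write_psl
from .filter_engine import FilterConfig, Reason
from .genome import Genome, revcomp
from .manifest_io import ProbeRecord, write_manifest
from .probe_recon import TARGET_OFFSET, WINDOW_LEN

SOURCE_FLANK = 5          # nt of genomic context on each side of SourceSeq
MIN_LOCUS_GAP = 60        # nt between planted windows (uniqueness guard)
SCENARIO_KINDS = (
    "perfect", "mismatch_at", "duplicate", "indel", "ambiguous_base", "absent",
)


class FixtureError(ValueError):
    """Invalid plant specification (overlap, offsets, capacity...)."""


@dataclass(frozen=True)
class Scenario:
    """Planting scenario; use the classmethod constructors."""

    kind: str
    offset: Optional[int] = None   # mismatch_at / ambiguous_base
    count: int = 1                 # mismatch_at: substitutions at offset..offset+count-1
    copies: int = 1                # duplicate
    length: int = 0                # indel

    @classmethod
    def perfect(cls) -> "Scenario":
        return cls("perfect")

    @classmethod
    def mismatch_at(cls, offset: int, count: int = 1) -> "Scenario":
        if count < 1:
            raise FixtureError("mismatch count must be >= 1")
        return cls("mismatch_at", offset=offset, count=count)

    @classmethod
    def duplicate(cls, copies: int = 2) -> "Scenario":
        if copies < 2:
            raise FixtureError("duplicate needs >= 2 copies")
        return cls("duplicate", copies=copies)

    @classmethod
    def indel(cls, length: int = 1) -> "Scenario":
        if length < 1:
            raise FixtureError("indel length must be >= 1")
        return cls("indel", length=length)

    @classmethod
    def ambiguous_base(cls, offset: int) -> "Scenario":
        return cls("ambiguous_base", offset=offset)

    @classmethod
    def absent(cls) -> "Scenario":
        return cls("absent")


@dataclass(frozen=True)
class PlantSpec:
    """Where and how one probe's window is planted.

    ``position`` is the 0-based plus-strand start of the planted window;
    for minus-strand designs the reverse complement of the design window
    is written there.
    """

    probe_id: str
    infinium_type: str  # "I" | "II"
    scenario: Scenario
    strand: str         # "+" | "-"
    chrom: str
    position: int

    def __post_init__(self) -> None:
        if self.infinium_type not in WINDOW_LEN:
            raise FixtureError(f"{self.probe_id}: bad type {self.infinium_type!r}")
        if self.strand not in "+-":
            raise FixtureError(f"{self.probe_id}: bad strand {self.strand!r}")
        if self.position < 0:
            raise FixtureError(f"{self.probe_id}: negative position")
        L = WINDOW_LEN[self.infinium_type]
        t = TARGET_OFFSET[self.infinium_type]
        sc = self.scenario
        if sc.kind not in SCENARIO_KINDS:
            raise FixtureError(f"{self.probe_id}: unknown scenario {sc.kind!r}")
        if sc.kind == "mismatch_at":
            if not (0 <= sc.offset and sc.offset + sc.count <= L):
                raise FixtureError(f"{self.probe_id}: mismatch offsets outside window")
            if any(o in (t, t + 1) for o in range(sc.offset, sc.offset + sc.count)):
                raise FixtureError(
                    f"{self.probe_id}: mismatches may not hit the target CpG itself"
                )
        if sc.kind == "ambiguous_base":
            if not (0 <= sc.offset < L):
                raise FixtureError(f"{self.probe_id}: ambiguous offset outside window")
            if t - 5 <= sc.offset <= t + 6:
                raise FixtureError(
                    f"{self.probe_id}: ambiguous offset must sit outside the "
                    "near-target window so the scenario maps to one criterion"
                )


@dataclass(frozen=True)
class TruthRow:
    probe_id: str
    expected_status: str
    expected_reasons: frozenset[Reason]
    chrom: str
    cpg_start: int      # 0-based plus-strand start of the target CG
    window_start: int   # 0-based plus-strand start of the planted window
    strand: str

    def __post_init__(self) -> None:
        if (self.expected_status == "pass") != (not self.expected_reasons):
            raise FixtureError(f"{self.probe_id}: truth status/reasons inconsistent")


@dataclass
class Fixture:
    """Everything a pipeline run needs, plus the ground truth."""

    genome: Genome               # mutated target genome
    design_ref: Genome           # genome carrying the unmutated windows
    records: list[ProbeRecord]
    truth: list[TruthRow]
    psl_hits: list[GenomeHit]    # gapped alignments (indel scenarios)
    specs: list[PlantSpec] = field(default_factory=list)

    def truth_by_id(self) -> dict[str, TruthRow]:
        return {t.probe_id: t for t in self.truth}

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Materialize genome/design-ref FASTA, manifest CSV, truth TSV, PSL."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "design_ref": out / "design_ref.fa",
            "manifest": out / "manifest.csv",
            "truth": out / "truth.tsv",
        }
        self.genome.write_fasta(paths["genome"])
        self.design_ref.write_fasta(paths["design_ref"])
        write_manifest(self.records, paths["manifest"])
        write_truth_table(self.truth, paths["truth"])
        if self.psl_hits:
            from .probe_recon import reconstruct_target_seq

            targets = {r.ilmn_id: reconstruct_target_seq(r) for r in self.records}
            paths["psl"] = out / "gapped.psl"
            write_psl(self.psl_hits, targets, self.genome, paths["psl"])
        return paths


def write_truth_table(truth: Sequence[TruthRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\texpected_status\texpected_reasons\tchrom\t"
                 "cpg_start\twindow_start\tstrand\n")
        for t in truth:
            fh.write(
                "\t".join([
                    t.probe_id, t.expected_status,
                    ",".join(sorted(r.name for r in t.expected_reasons)) or ".",
                    t.chrom, str(t.cpg_start), str(t.window_start), t.strand,
                ]) + "\n"
            )


def read_truth_table(path: str | Path) -> list[TruthRow]:
    rows = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            pid, status, reasons, chrom, cpg, win, strand = line.rstrip("\n").split("\t")
            rows.append(TruthRow(
                probe_id=pid, expected_status=status,
                expected_reasons=frozenset(
                    Reason[r] for r in reasons.split(",") if r != "."),
                chrom=chrom, cpg_start=int(cpg), window_start=int(win),
                strand=strand,
            ))
    return rows


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def generate_genome(
    n_chrom: int,
    chrom_len: int,
    gc_frac: float = 0.4,
    ambiguous_frac: float = 0.0,
    seed: int = 0,
) -> Genome:
    """Random genome over {A,C,G,T,N}: i.i.d. bases at the given GC content,
    N overlaid Bernoulli(ambiguous_frac).  Deterministic for a fixed seed.
    """
    if n_chrom < 1:
        raise FixtureError("n_chrom must be >= 1")
    if chrom_len < 200:
        raise FixtureError("chrom_len must be >= 200 (must host a 51-mer window)")
    if not (0 <= gc_frac <= 1 and 0 <= ambiguous_frac <= 1):
        raise FixtureError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1 - gc_frac) / 2
    gc = gc_frac / 2
    bases = np.array([65, 67, 71, 84], dtype=np.uint8)  # A C G T
    seqs = {}
    for i in range(n_chrom):
        arr = rng.choice(bases, size=chrom_len, p=[at, gc, gc, at])
        if ambiguous_frac > 0:
            arr[rng.random(chrom_len) < ambiguous_frac] = ord("N")
        seqs[f"chr{i + 1}"] = arr.tobytes().decode("ascii")
    return Genome(seqs)


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------

_MUT = {"A": "C", "C": "A", "G": "T", "T": "G"}


def _random_window(rng: np.random.Generator, infinium_type: str) -> str:
    """Random design-strand window with CG at the canonical target offset."""
    L = WINDOW_LEN[infinium_type]
    t = TARGET_OFFSET[infinium_type]
    win = rng.choice(list("ACGT"), size=L)
    win[t], win[t + 1] = "C", "G"
    return "".join(win)


def _bisulfite_allele_a(window: str, infinium_type: str) -> str:
    """Converted AlleleA probe sequence in the manifest dialect.

    Type I (allele A = unmethylated assumption): every C reads as T after
    conversion.  Type II: CpG cytosines become degenerate R, other Cs
    become T.
    """
    probe = list(window[:50])
    if infinium_type == "I":
        return "".join("T" if b == "C" else b for b in probe)
    out = []
    for i, b in enumerate(probe):
        if b == "C" and i + 1 < len(window) and window[i + 1] == "G":
            out.append("R")
        elif b == "C":
            out.append("T")
        else:
            out.append(b)
    return "".join(out)


def _expected_reasons(spec: PlantSpec, cfg: FilterConfig) -> frozenset[Reason]:
    """Intended verdict from plant geometry alone (independent of the pipeline)."""
    sc = spec.scenario
    t = TARGET_OFFSET[spec.infinium_type]
    L = WINDOW_LEN[spec.infinium_type]
    if sc.kind == "perfect":
        return frozenset()
    if sc.kind == "duplicate":
        return frozenset({Reason.MULTI_HIT})
    if sc.kind == "indel":
        return frozenset({Reason.INDEL})
    if sc.kind == "ambiguous_base":
        return frozenset({Reason.AMBIGUOUS_BASE})
    if sc.kind == "absent":
        return frozenset({Reason.NO_HIT})
    # mismatch_at: classify each planted substitution against the window rule
    near_lo = max(0, t - cfg.near_target_halfwidth)
    near_hi = min(L - 1, t + 1 + cfg.near_target_halfwidth)
    offsets = range(sc.offset, sc.offset + sc.count)
    near = [o for o in offsets if near_lo <= o <= near_hi]
    rest = [o for o in offsets if not (near_lo <= o <= near_hi)]
    reasons = set()
    if near:
        reasons.add(Reason.NEAR_TARGET_MISMATCH)
    if len(rest) > cfg.max_mm_rest:
        reasons.add(Reason.TOO_MANY_MISMATCHES)
    return frozenset(reasons)


def _cpg_plus_start(position: int, strand: str, infinium_type: str) -> int:
    L = WINDOW_LEN[infinium_type]
    t = TARGET_OFFSET[infinium_type]
    return position + t if strand == "+" else position + L - t - 2


def plant_probes(
    genome: Genome,
    specs: Sequence[PlantSpec],
    seed: int = 0,
    cfg: FilterConfig = FilterConfig(),
) -> Fixture:
    """Plant design windows into a copy of ``genome`` per the given specs.

    Returns the mutated genome, the design reference (original windows),
    an Illumina-style manifest, gapped PSL hits for indel scenarios, and
    the truth table of intended verdicts.  Secondary loci (duplicate
    copies, gapped placements) are drawn from ``seed`` on the same
    chromosome layout, respecting the minimum inter-locus gap.
    Overlapping or too-close planted windows are rejected.
    """
    rng = np.random.default_rng(seed)
    ids = [s.probe_id for s in specs]
    if len(set(ids)) != len(ids):
        raise FixtureError("duplicate probe ids in specs")

    # reserve primary loci, checking the spacing guard
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chroms}

    def _reserve(chrom: str, start: int, length: int) -> None:
        if chrom not in occupied:
            raise FixtureError(f"unknown chromosome {chrom!r}")
        if start + length > genome.chrom_len(chrom):
            raise FixtureError(f"window [{start}, {start + length}) beyond {chrom}")
        for s, e in occupied[chrom]:
            if start < e + MIN_LOCUS_GAP and s < start + length + MIN_LOCUS_GAP:
                raise FixtureError(
                    f"planted windows closer than {MIN_LOCUS_GAP} nt on {chrom}"
                )
        occupied[chrom].append((start, start + length))

    def _pick_secondary(chrom: str, length: int) -> int:
        n = genome.chrom_len(chrom)
        for _ in range(200):
            cand = int(rng.integers(SOURCE_FLANK, n - length - SOURCE_FLANK))
            try:
                _reserve(chrom, cand, length)
                return cand
            except FixtureError:
                continue
        raise FixtureError(f"no room for a secondary locus on {chrom}")

    edits: dict[str, dict[int, str]] = {}
    ref_edits: dict[str, dict[int, str]] = {}
    records: list[ProbeRecord] = []
    truth: list[TruthRow] = []
    psl_hits: list[GenomeHit] = []

    # reserve every primary locus before any secondary is drawn, so
    # duplicate/indel side loci can never collide with a later primary
    for spec in specs:
        L = WINDOW_LEN[spec.infinium_type]
        if spec.position < SOURCE_FLANK or (
            spec.position + L + SOURCE_FLANK > genome.chrom_len(spec.chrom)
        ):
            raise FixtureError(
                f"{spec.probe_id}: window must leave {SOURCE_FLANK} nt of flank"
            )
        _reserve(spec.chrom, spec.position, L)

    for spec in specs:
        L = WINDOW_LEN[spec.infinium_type]
        sc = spec.scenario
        window = _random_window(rng, spec.infinium_type)       # design strand
        plus_window = window if spec.strand == "+" else revcomp(window)

        # design reference always carries the clean window (the "human" side)
        ref_edits.setdefault(spec.chrom, {})[spec.position] = plus_window

        genome_window = plus_window
        if sc.kind == "mismatch_at":
            gw = list(plus_window)
            for o in range(sc.offset, sc.offset + sc.count):
                p = o if spec.strand == "+" else L - 1 - o
                gw[p] = _MUT[gw[p]] if spec.strand == "+" else revcomp(_MUT[window[o]])
            genome_window = "".join(gw)
        elif sc.kind == "ambiguous_base":
            gw = list(plus_window)
            p = sc.offset if spec.strand == "+" else L - 1 - sc.offset
            gw[p] = "N"
            genome_window = "".join(gw)

        if sc.kind != "absent":
            edits.setdefault(spec.chrom, {})[spec.position] = genome_window

        if sc.kind == "duplicate":
            for _ in range(sc.copies - 1):
                pos2 = _pick_secondary(spec.chrom, L)
                edits[spec.chrom][pos2] = plus_window
        elif sc.kind == "indel":
            # secondary locus carries the window with `length` bases deleted
            # from its middle: it aligns back only with a gap (no ungapped
            # placement survives the frame shift)
            pos2 = _pick_secondary(spec.chrom, L)
            cut = L // 2
            gapped = plus_window[:cut] + plus_window[cut + sc.length:]
            edits[spec.chrom][pos2] = gapped
            psl_hits.append(GenomeHit(
                probe_id=spec.probe_id, chrom=spec.chrom, start=pos2,
                end=pos2 + len(gapped), strand=spec.strand,
                has_indel=True, n_matches=len(gapped),
            ))

        # manifest row: SourceSeq = design-strand window + 5 nt genomic flank
        lf = genome.fetch(spec.chrom, spec.position - SOURCE_FLANK, spec.position)
        rf = genome.fetch(spec.chrom, spec.position + L, spec.position + L + SOURCE_FLANK)
        plus_source = lf + plus_window + rf
        source_seq = plus_source if spec.strand == "+" else revcomp(plus_source)
        cpg_start = _cpg_plus_start(spec.position, spec.strand, spec.infinium_type)
        t = TARGET_OFFSET[spec.infinium_type]
        records.append(ProbeRecord(
            ilmn_id=spec.probe_id,
            name=spec.probe_id,
            infinium_type=spec.infinium_type,
            next_base=window[t - 1] if spec.infinium_type == "I" else None,
            allele_a_probe_seq=_bisulfite_allele_a(window, spec.infinium_type),
            source_seq=source_seq,
            chrom_design=spec.chrom,
            map_info=cpg_start + 1,
            strand_design="F" if spec.strand == "+" else "R",
        ))
        expected = _expected_reasons(spec, cfg)
        truth.append(TruthRow(
            probe_id=spec.probe_id,
            expected_status="pass" if not expected else "fail",
            expected_reasons=expected,
            chrom=spec.chrom,
            cpg_start=cpg_start,
            window_start=spec.position,
            strand=spec.strand,
        ))

    mutated = genome.with_replacements(edits)
    design_ref = genome.with_replacements(ref_edits)
    return Fixture(
        genome=mutated, design_ref=design_ref, records=records,
        truth=truth, psl_hits=psl_hits, specs=list(specs),
    )


# ---------------------------------------------------------------------------
# randomized fixtures
# ---------------------------------------------------------------------------

def _random_scenario(rng: np.random.Generator, kind: str, infinium_type: str) -> Scenario:
    t = TARGET_OFFSET[infinium_type]
    L = WINDOW_LEN[infinium_type]
    if kind == "perfect":
        return Scenario.perfect()
    if kind == "duplicate":
        return Scenario.duplicate(copies=int(rng.integers(2, 4)))
    if kind == "indel":
        return Scenario.indel(length=int(rng.integers(1, 4)))
    if kind == "absent":
        return Scenario.absent()
    if kind == "ambiguous_base":
        # anywhere left of the near-target window
        return Scenario.ambiguous_base(offset=int(rng.integers(0, t - 6)))
    if kind == "mismatch_at":
        variant = rng.choice(["near", "far_ok", "far_many"])
        if variant == "near":
            # 1 substitution in the 5'-side flank of the near-target window
            # (the 3' side is clipped by the window end for both types)
            offset = int(rng.integers(t - 5, t))
            return Scenario.mismatch_at(offset=offset, count=1)
        if variant == "far_ok":
            count = int(rng.integers(1, 3))
            offset = int(rng.integers(0, t - 5 - count))
            return Scenario.mismatch_at(offset=offset, count=count)
        count = int(rng.integers(3, 5))  # exceeds the 2-mismatch allowance
        offset = int(rng.integers(0, t - 5 - count))
        return Scenario.mismatch_at(offset=offset, count=count)
    raise FixtureError(f"unknown scenario kind {kind!r}")


def random_plant_specs(
    genome: Genome,
    n_probes: int,
    scenario_kinds: Sequence[str] = SCENARIO_KINDS,
    seed: int = 0,
    type_II_frac: float = 0.6,
) -> list[PlantSpec]:
    """Randomized specs cycling through scenario kinds, both strands.

    Primary loci are drawn uniformly, >= 60 nt apart, leaving room for the
    SourceSeq flanks.  Raises when the genome cannot host ``n_probes``
    windows at that spacing (each planted probe may additionally claim
    secondary loci inside :func:`plant_probes`).
    """
    rng = np.random.default_rng(seed)
    lmax = max(WINDOW_LEN.values())
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chroms}
    specs: list[PlantSpec] = []
    for i in range(n_probes):
        kind = scenario_kinds[i % len(scenario_kinds)]
        itype = "II" if rng.random() < type_II_frac else "I"
        strand = "+" if rng.random() < 0.5 else "-"
        placed = False
        for _ in range(500):
            chrom = genome.chroms[int(rng.integers(0, len(genome)))]
            n = genome.chrom_len(chrom)
            if n < lmax + 2 * SOURCE_FLANK:
                continue
            pos = int(rng.integers(SOURCE_FLANK, n - lmax - SOURCE_FLANK))
            if all(
                not (pos < e + MIN_LOCUS_GAP and s < pos + lmax + MIN_LOCUS_GAP)
                for s, e in taken[chrom]
            ):
                taken[chrom].append((pos, pos + lmax))
                specs.append(PlantSpec(
                    probe_id=f"cp{i:05d}",
                    infinium_type=itype,
                    scenario=_random_scenario(rng, kind, itype),
                    strand=strand,
                    chrom=chrom,
                    position=pos,
                ))
                placed = True
                break
        if not placed:
            raise FixtureError(
                f"could not place probe {i} of {n_probes}: genome too small "
                f"for the {MIN_LOCUS_GAP}-nt spacing guard"
            )
    return specs


def make_fixture(
    n_probes: int = 24,
    scenario_kinds: Sequence[str] = SCENARIO_KINDS,
    seed: int = 0,
    n_chrom: int = 2,
    chrom_len: int = 10_000,
    gc_frac: float = 0.4,
    ambiguous_frac: float = 0.0,
    type_II_frac: float = 0.6,
) -> Fixture:
    """One-call randomized fixture: genome + planted probes + truth table."""
    rng = np.random.default_rng(seed)
    g_seed, s_seed, p_seed = (int(x) for x in rng.integers(0, 2**31 - 1, 3))
    base = generate_genome(n_chrom, chrom_len, gc_frac, ambiguous_frac, seed=g_seed)
    specs = random_plant_specs(
        base, n_probes, scenario_kinds, seed=s_seed, type_II_frac=type_II_frac
    )
    return plant_probes(base, specs, seed=p_seed)


# ---------------------------------------------------------------------------
# synthetic methylation data
# ---------------------------------------------------------------------------

def simulate_region_betas(
    probe_region_levels: Mapping[str, float],
    n_samples: int = 5,
    sigma: float = 0.05,
    detection_p: float = 0.001,
    seed: int = 0,
):
    """Beta/detection-p matrices as region level + truncated Gaussian noise.

    Each probe's beta in every sample is its region's methylation level
    plus N(0, sigma) noise, clipped to [0, 1] — the generative model behind
    the concordance-recovery check: as sigma -> 0 the correlation between
    per-probe average betas and region levels approaches 1.
    """
    from .methyl_validate import BetaMatrix
    import pandas as pd

    rng = np.random.default_rng(seed)
    probe_ids = list(probe_region_levels)
    levels = np.array([probe_region_levels[p] for p in probe_ids], dtype=float)
    noise = rng.normal(0.0, sigma, size=(len(probe_ids), n_samples))
    beta = np.clip(levels[:, None] + noise, 0.0, 1.0)
    samples = [f"S{j + 1}" for j in range(n_samples)]
    return BetaMatrix(
        beta=pd.DataFrame(beta, index=probe_ids, columns=samples),
        detection_p=pd.DataFrame(
            np.full_like(beta, detection_p), index=probe_ids, columns=samples
        ),
    )
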