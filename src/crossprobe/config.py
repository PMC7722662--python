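"""Declarative run configuration and the end-to-end pipeline driver.

A run is fully described by one :class:`RunConfig` (serializable to YAML,
lossless round-trip).  ``run_pipeline`` executes selection -> annotation ->
validation for whichever inputs are configured, writes every artifact plus
the exact config used into the output directory, and records per-stage
status machine-readably.  No stage mutates its inputs; reruns with the
same config and inputs are bit-identical for the deterministic stages
(which is all of them — the seed is recorded for provenance and fixture
regeneration).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .filter_engine import FilterConfig, run_selection
from .genome import Genome
from .manifest_io import write_probe_table

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # inputs
    manifest: Optional[str] = None
    genome: Optional[str] = None
    psl: Optional[str] = None
    gff3: Optional[str] = None
    orthologs: Optional[str] = None
    betas: Optional[str] = None
    pvals: Optional[str] = None
    regions: Optional[str] = None
    out_dir: str = "crossprobe_out"
    # filter criteria
    near_target_halfwidth: int = 5
    max_mm_rest: int = 2
    suboptimal_mm_ceiling: int = 5
    require_target_cpg: bool = True
    # engine & thresholds
    engine: str = "internal"
    scan_method: str = "auto"
    p_threshold: float = 0.01
    autosomal_only: bool = False
    # misc
    seed: int = 0
    chrom_rename: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.manifest is None or self.genome is None:
            raise ConfigError("manifest and genome paths are required")
        if self.engine not in ("internal", "psl"):
            raise ConfigError(f"unknown engine {self.engine!r}")
        if not (0 < self.p_threshold <= 1):
            raise ConfigError("p_threshold must lie in (0, 1]")
        try:
            self.filter_config()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            near_target_halfwidth=self.near_target_halfwidth,
            max_mm_rest=self.max_mm_rest,
            suboptimal_mm_ceiling=self.suboptimal_mm_ceiling,
            require_target_cpg=self.require_target_cpg,
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; return the machine-readable status.

    Always produced: decisions.tsv, passing.bed, summary.json,
    chrom_distribution.tsv, config_used.yaml, status.json.  Annotation and
    validation artifacts appear when their inputs are configured.  Stage
    failures are recorded in status.json rather than aborting later
    stages that do not depend on them.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_used.yaml")
    status: dict = {"stages": {}}

    genome = Genome.from_fasta(config.genome)
    decisions, summary = run_selection(
        config.manifest,
        genome,
        cfg=config.filter_config(),
        engine=config.engine,
        psl_path=config.psl,
        scan_method=config.scan_method,
    )
    write_probe_table(decisions, out / "decisions.tsv", fmt="tsv")
    write_probe_table(decisions, out / "passing.bed", fmt="bed")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary.as_dict(), fh, indent=2)
    status["stages"]["select"] = "ok"

    from .annotation import (
        annotate_genes, chrom_distribution, join_orthologs, write_annotated,
    )

    dist = chrom_distribution(decisions)
    dist.to_csv(out / "chrom_distribution.tsv", sep="\t", index=False)
    status["stages"]["chrom_distribution"] = "ok"

    annotated = None
    if config.gff3:
        try:
            annotated = annotate_genes(
                decisions, config.gff3, chrom_rename=config.chrom_rename or None
            )
            if config.orthologs:
                annotated = join_orthologs(annotated, config.orthologs)
            write_annotated(annotated, out / "annotated.tsv")
            status["stages"]["annotate"] = "ok"
        except Exception as exc:  # recorded, not fatal to validation
            log.error("annotation failed: %s", exc)
            status["stages"]["annotate"] = f"error: {exc}"

    if config.betas and config.pvals:
        try:
            from .methyl_validate import (
                BetaMatrix, detection_filter, pairwise_pearson,
                read_regions, region_overlap_compare,
            )

            m = BetaMatrix.read_tsv(config.betas, config.pvals)
            chrom_map = {
                d.probe_id: d.target_cpg_coord[0]
                for d in decisions
                if d.target_cpg_coord is not None
            }
            filtered, report = detection_filter(
                m.subset([p for p in m.probe_ids if p in chrom_map])
                if config.autosomal_only else m,
                p_threshold=config.p_threshold,
                autosomal_only=config.autosomal_only,
                chrom_map=chrom_map,
            )
            ptypes = {d.probe_id: d.infinium_type for d in decisions}
            pearson = pairwise_pearson(filtered, probe_types=ptypes)
            validation = {
                "detection_filter": report,
                "average_r": pearson.average_r,
                "average_r_by_type": {
                    k: v[1] for k, v in pearson.by_type.items()
                },
            }
            if config.regions:
                regions = read_regions(config.regions)
                coords = {
                    d.probe_id: (d.target_cpg_coord[0], d.target_cpg_coord[1])
                    for d in decisions
                    if d.target_cpg_coord is not None
                }
                cmp_res = region_overlap_compare(
                    coords, filtered, regions, probe_types=ptypes
                )
                cmp_res.pairs.to_csv(out / "region_pairs.tsv", sep="\t", index=False)
                validation["region_overlap"] = {
                    "n_probes_in_regions": cmp_res.n_probes_in_regions,
                    "overall_r": cmp_res.overall_r,
                    "r_by_label": cmp_res.r_by_label,
                    "r_by_type": cmp_res.by_type,
                }
            with open(out / "validation.json", "w") as fh:
                json.dump(validation, fh, indent=2, default=float)
            status["stages"]["validate"] = "ok"
        except Exception as exc:
            log.error("validation failed: %s", exc)
            status["stages"]["validate"] = f"error: {exc}"

    with open(out / "status.json", "w") as fh:
        json.dump(status, fh, indent=2)
    return status
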