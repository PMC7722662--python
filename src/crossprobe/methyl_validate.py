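"""Downstream validation of methylation data from re-targeted probes.

Three checks mirror how a re-targeted probe set is vetted in practice:

* detection-p filtering — a probe is kept only when its detection p-value
  is below threshold in *every* sample (default 0.01), optionally after
  restricting to autosomal probes;
* replicate concordance — pairwise Pearson correlation of beta values
  across biological replicates, overall and stratified by Infinium type;
* external-region comparison — per-probe average betas paired with the
  methylation level of published regions containing the probe's CpG, with
  one correlation per region label.

Beta values are methylated-signal fractions in [0, 1]; matrices enter as
labelled TSV (probes x samples), preprocessing (background correction,
normalisation) is upstream of this toolkit.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

_AUTOSOME_RE = re.compile(r"^(chr)?\d+$")


class ValidationError(ValueError):
    pass


@dataclass
class BetaMatrix:
    """Probes x samples beta values paired with detection p-values."""

    beta: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.detection_p.index) or not (
            self.beta.columns.equals(self.detection_p.columns)
        ):
            raise ValidationError("beta and detection_p must share labels")
        if self.beta.index.has_duplicates or self.beta.columns.has_duplicates:
            raise ValidationError("duplicate probe or sample labels")
        for name, df in (("beta", self.beta), ("detection_p", self.detection_p)):
            vals = df.to_numpy(dtype=float)
            if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
                raise ValidationError(f"{name} values must lie in [0, 1]")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    @classmethod
    def read_tsv(cls, beta_path: str | Path, pval_path: str | Path) -> "BetaMatrix":
        read = lambda p: pd.read_csv(p, sep="\t", index_col=0)
        return cls(beta=read(beta_path), detection_p=read(pval_path))

    def write_tsv(self, beta_path: str | Path, pval_path: str | Path) -> None:
        self.beta.to_csv(beta_path, sep="\t")
        self.detection_p.to_csv(pval_path, sep="\t")

    def subset(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(
            beta=self.beta.loc[list(probe_ids)],
            detection_p=self.detection_p.loc[list(probe_ids)],
        )


@dataclass(frozen=True)
class MethylRegion:
    """A published methylated region with its methylation level."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    level: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"region {self.chrom}:{self.start}-{self.end} empty")
        if not 0 <= self.level <= 1:
            raise ValidationError("region level must lie in [0, 1]")


def read_regions(path: str | Path) -> list[MethylRegion]:
    """BED-like TSV: chrom, start, end, level, label (header optional)."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if lineno == 1 and not f[1].lstrip("-").isdigit():
                continue  # header row
            regions.append(MethylRegion(
                chrom=f[0], start=int(f[1]), end=int(f[2]),
                level=float(f[3]), label=f[4] if len(f) > 4 else "",
            ))
    return regions


def is_autosomal(chrom: str) -> bool:
    return bool(_AUTOSOME_RE.match(chrom))


def detection_filter(
    m: BetaMatrix,
    p_threshold: float = 0.01,
    autosomal_only: bool = False,
    chrom_map: Optional[Mapping[str, str]] = None,
) -> tuple[BetaMatrix, dict]:
    """Keep probes detected (p < threshold) in every sample.

    With ``autosomal_only``, probes mapping to sex chromosomes or
    scaffolds (per ``chrom_map``) are dropped first; a probe missing from
    the map cannot be classified and is an error.  Returns the filtered
    matrix and a report of counts before/after each step.
    """
    if not (0 < p_threshold <= 1):
        raise ValidationError("p_threshold must lie in (0, 1]")
    report = {"n_input": len(m.probe_ids), "p_threshold": p_threshold}
    kept = m
    if autosomal_only:
        if chrom_map is None:
            raise ValidationError("autosomal_only requires a chrom_map")
        missing = [p for p in kept.probe_ids if p not in chrom_map]
        if missing:
            raise ValidationError(
                f"{len(missing)} probes absent from chrom_map "
                f"(first: {missing[0]})"
            )
        auto = [p for p in kept.probe_ids if is_autosomal(chrom_map[p])]
        kept = kept.subset(auto)
        report["n_autosomal"] = len(auto)
    detected = (kept.detection_p < p_threshold).all(axis=1)
    kept = kept.subset(list(kept.detection_p.index[detected]))
    report["n_detected"] = len(kept.probe_ids)
    return kept, report


@dataclass
class PearsonReport:
    corr: pd.DataFrame          # sample x sample correlation table
    average_r: float            # mean of the upper triangle
    by_type: dict = field(default_factory=dict)  # "I"/"II" -> (corr, average_r)
    n_probes: int = 0


def _pairwise(beta: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    stds = beta.std(ddof=0)
    constant = list(stds.index[stds == 0])
    if constant:
        log.warning("constant sample columns excluded from average R: %s", constant)
    corr = beta.corr(method="pearson")  # pandas leaves constant columns as NaN
    iu = np.triu_indices(len(corr), k=1)
    vals = corr.to_numpy()[iu]
    avg = float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
    return corr, avg


def pairwise_pearson(
    m: BetaMatrix, probe_types: Optional[Mapping[str, str]] = None
) -> PearsonReport:
    """Replicate concordance: Pearson R for every sample pair.

    The average R aggregates the upper triangle only (10 pairs for 5
    samples).  Constant columns yield undefined correlations, reported as
    NaN and excluded from the average with a warning.  With
    ``probe_types`` the same statistics are also computed per Infinium
    type.
    """
    if len(m.sample_ids) < 2:
        raise ValidationError("need >= 2 samples")
    if len(m.probe_ids) < 2:
        raise ValidationError("need >= 2 probes")
    corr, avg = _pairwise(m.beta)
    report = PearsonReport(corr=corr, average_r=avg, n_probes=len(m.probe_ids))
    if probe_types:
        for itype in ("I", "II"):
            ids = [p for p in m.probe_ids if probe_types.get(p) == itype]
            if len(ids) >= 2:
                report.by_type[itype] = _pairwise(m.beta.loc[ids])
    return report


@dataclass
class RegionCompareResult:
    pairs: pd.DataFrame        # probe_id, label, avg_beta, region_level, ...
    n_probes_in_regions: int
    r_by_label: dict
    overall_r: float
    by_type: dict = field(default_factory=dict)


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def region_overlap_compare(
    probe_coords: Mapping[str, tuple[str, int]],
    betas: BetaMatrix,
    regions: Sequence[MethylRegion],
    probe_types: Optional[Mapping[str, str]] = None,
) -> RegionCompareResult:
    """Pair per-probe average betas with containing regions' levels.

    A probe is *in* a region when its target-C position lies in
    [start, end).  Probes contained in several overlapping regions are
    paired with each and flagged (``n_regions`` > 1).  Pearson R is
    reported per region label, overall, and per Infinium type.
    """
    trees: dict[str, IntervalTree] = {}
    for i, r in enumerate(regions):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, i)
    avg_beta = betas.beta.mean(axis=1)
    rows = []
    for pid, (chrom, pos) in probe_coords.items():
        if pid not in avg_beta.index or chrom not in trees:
            continue
        overlaps = sorted(trees[chrom].overlap(pos, pos + 1), key=lambda iv: iv.data)
        for iv in overlaps:
            reg = regions[iv.data]
            rows.append({
                "probe_id": pid,
                "label": reg.label,
                "avg_beta": float(avg_beta[pid]),
                "region_level": reg.level,
                "infinium_type": (probe_types or {}).get(pid),
                "n_regions": len(overlaps),
            })
    pairs = pd.DataFrame(
        rows,
        columns=["probe_id", "label", "avg_beta", "region_level",
                 "infinium_type", "n_regions"],
    )
    n_in = pairs["probe_id"].nunique() if len(pairs) else 0
    r_by_label = {
        lab: _safe_pearson(g["avg_beta"].to_numpy(), g["region_level"].to_numpy())
        for lab, g in pairs.groupby("label")
    } if len(pairs) else {}
    overall = (
        _safe_pearson(pairs["avg_beta"].to_numpy(), pairs["region_level"].to_numpy())
        if len(pairs)
        else float("nan")
    )
    by_type = {}
    if probe_types and len(pairs):
        for itype, g in pairs.groupby("infinium_type"):
            by_type[itype] = _safe_pearson(
                g["avg_beta"].to_numpy(), g["region_level"].to_numpy()
            )
    return RegionCompareResult(
        pairs=pairs,
        n_probes_in_regions=int(n_in),
        r_by_label=r_by_label,
        overall_r=overall,
        by_type=by_type,
    )
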