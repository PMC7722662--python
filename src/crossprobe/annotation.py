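"""Gene context, ortholog relations and chromosomal distribution of probes.

Gene annotation is a local GFF3 interval join (via gffutils + an interval
tree): a probe is annotated with every requested feature whose span
overlaps the 2-nt target CpG interval, strand-agnostically — the
methylation signal is attributed to the CpG site, not the probe footprint.
Orthology is a local two-column table join; no network lookups anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .filter_engine import FilterDecision

log = logging.getLogger(__name__)


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotatedProbe:
    probe_id: str
    chrom: str
    pos: int          # 0-based plus-strand start of the target CG
    strand: str
    infinium_type: Optional[str] = None
    gene_ids: tuple[str, ...] = ()
    gene_names: tuple[str, ...] = ()
    human_ortholog_ids: tuple[str, ...] = ()


def _dedup(items: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for x in items:
        seen.setdefault(x)
    return tuple(seen)


def _validate_gff3(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            try:
                s, e = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: bad coordinates") from exc
            if s < 1 or e < s:
                raise AnnotationError(f"{path}:{lineno}: bad interval {s}-{e}")


def build_feature_trees(
    gff3_path: str | Path,
    feature_types: frozenset[str] | set[str] = frozenset({"gene"}),
    chrom_rename: Optional[Mapping[str, str]] = None,
) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees of (gene_id, gene_name) payloads.

    GFF3 intervals are 1-based inclusive; trees are 0-based half-open.
    """
    _validate_gff3(gff3_path)
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique",
    )
    rename = dict(chrom_rename or {})
    trees: dict[str, IntervalTree] = {}
    for ftype in sorted(feature_types):
        for feat in db.features_of_type(ftype):
            gid = (feat.attributes.get("ID") or [feat.id])[0]
            gid = gid.split(":", 1)[-1] if gid.startswith(f"{ftype}:") else gid
            gname = (feat.attributes.get("Name") or [""])[0]
            chrom = rename.get(feat.seqid, feat.seqid)
            trees.setdefault(chrom, IntervalTree()).addi(
                feat.start - 1, feat.end, (gid, gname)
            )
    return trees


def annotate_genes(
    decisions: Sequence[FilterDecision],
    gff3_path: str | Path,
    feature_types: frozenset[str] | set[str] = frozenset({"gene"}),
    chrom_rename: Optional[Mapping[str, str]] = None,
) -> list[AnnotatedProbe]:
    """Attach overlapping features to every passing probe's target CpG.

    Probes on chromosomes absent from the GFF3 are logged and left with
    empty gene lists; annotation is order-independent and idempotent.
    """
    trees = build_feature_trees(gff3_path, feature_types, chrom_rename)
    out: list[AnnotatedProbe] = []
    warned: set[str] = set()
    for d in decisions:
        if d.status != "pass" or d.target_cpg_coord is None:
            continue
        chrom, pos, strand = d.target_cpg_coord
        if chrom not in trees:
            if chrom not in warned:
                log.warning("chromosome %s not in annotation; probes left bare", chrom)
                warned.add(chrom)
            hits = []
        else:
            hits = sorted(trees[chrom].overlap(pos, pos + 2))
        out.append(AnnotatedProbe(
            probe_id=d.probe_id,
            chrom=chrom,
            pos=pos,
            strand=strand,
            infinium_type=d.infinium_type,
            gene_ids=_dedup(iv.data[0] for iv in hits),
            gene_names=_dedup(iv.data[1] for iv in hits if iv.data[1]),
        ))
    return out


def join_orthologs(
    annotated: Sequence[AnnotatedProbe], ortholog_tsv: str | Path
) -> list[AnnotatedProbe]:
    """Left-join human ortholog ids onto annotated probes.

    The table has two columns (target_gene_id, human_gene_id); one-to-many
    mappings are preserved in input order, genes without an entry simply
    contribute nothing.
    """
    df = pd.read_csv(ortholog_tsv, sep="\t", dtype=str)
    required = {"target_gene_id", "human_gene_id"}
    if set(df.columns) != required:
        raise AnnotationError(
            f"{ortholog_tsv}: expected columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    mapping: dict[str, list[str]] = {}
    for tgt, hum in zip(df["target_gene_id"], df["human_gene_id"]):
        mapping.setdefault(tgt, []).append(hum)
    return [
        replace(
            a,
            human_ortholog_ids=_dedup(
                h for g in a.gene_ids for h in mapping.get(g, [])
            ),
        )
        for a in annotated
    ]


def chrom_distribution(decisions: Sequence[FilterDecision]) -> pd.DataFrame:
    """Per-chromosome passing-probe counts split by Infinium type.

    Columns: chrom, n_typeI, n_typeII, n_total; only chromosomes with at
    least one passing probe appear; row totals sum to the pass count.
    """
    rows = [
        {
            "chrom": d.target_cpg_coord[0],
            "infinium_type": d.infinium_type or "?",
        }
        for d in decisions
        if d.status == "pass" and d.target_cpg_coord is not None
    ]
    if not rows:
        return pd.DataFrame(columns=["chrom", "n_typeI", "n_typeII", "n_total"])
    df = pd.DataFrame(rows)
    counts = (
        df.groupby("chrom")["infinium_type"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["I", "II"], fill_value=0)
    )
    out = pd.DataFrame(
        {
            "chrom": counts.index,
            "n_typeI": counts["I"].to_numpy(),
            "n_typeII": counts["II"].to_numpy(),
        }
    )
    out["n_total"] = out["n_typeI"] + out["n_typeII"]
    return out.sort_values("chrom", ignore_index=True)


def plot_chrom_distribution(dist: pd.DataFrame, path: str | Path) -> None:
    """Static bar chart of per-chromosome probe counts by type."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(dist)), 3.5))
    x = range(len(dist))
    ax.bar(x, dist["n_typeI"], label="type I")
    ax.bar(x, dist["n_typeII"], bottom=dist["n_typeI"], label="type II")
    ax.set_xticks(list(x))
    ax.set_xticklabels(dist["chrom"], rotation=90, fontsize=7)
    ax.set_ylabel("high-confidence probes")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_annotated(annotated: Sequence[AnnotatedProbe], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tchrom\tpos_1based\tstrand\tinfinium_type\t"
                 "gene_ids\tgene_names\thuman_ortholog_ids\n")
        for a in annotated:
            fh.write("\t".join([
                a.probe_id, a.chrom, str(a.pos + 1), a.strand,
                a.infinium_type or ".",
                ";".join(a.gene_ids) or ".",
                ";".join(a.gene_names) or ".",
                ";".join(a.human_ortholog_ids) or ".",
            ]) + "\n")
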