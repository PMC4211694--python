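"""End-to-end orchestration: preprocess -> screen -> annotate -> profile -> qPCR.

Each stage writes its tabular outputs (TSV, deterministically sorted) before
the next stage starts, so stages can equally be run one at a time from the
CLI against the intermediate files.  The run report mirrors the per-library
tallies a small-RNA discovery study reports: usable reads, unique tags (all
sizes and 20-23 nt), screened candidates, annotated canonical sequences and
annotated types, plus global category percentages and the conservation
summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import homology, preprocess, profiling, qpcr as qpcr_mod
from .io import (
    LibraryMeta,
    ReferenceMiRNA,
    read_mirbase_fasta,
    read_reads,
    read_samplesheet,
    read_table,
    write_table,
)
from .preprocess import FilterParams, LibraryProfile, ScreeningParams, UniqueTag

logger = logging.getLogger("mirfish")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "write_tags", "load_tags",
           "write_annotations", "load_annotation_table"]


@dataclass
class RunConfig:
    """All paths and thresholds for one pipeline run."""

    samplesheet: str
    reference: str
    outdir: str
    ct_table: str | None = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    screening: ScreeningParams = field(default_factory=ScreeningParams)
    alignment: homology.AlignmentParams = field(default_factory=homology.AlignmentParams)
    criteria: homology.HitCriteria = field(default_factory=homology.HitCriteria)

    def validate(self) -> None:
        for label, p in (("samplesheet", self.samplesheet),
                         ("reference", self.reference)):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")
        if self.ct_table and not Path(self.ct_table).exists():
            raise FileNotFoundError(f"ct_table path does not exist: {self.ct_table}")


@dataclass
class RunReport:
    per_library: pd.DataFrame
    global_summary: dict
    accounting: pd.DataFrame
    conservation_summary: dict


def write_tags(tags: Sequence[UniqueTag], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"sequence": t.sequence, "count": t.count, "rpm": t.rpm} for t in tags]
    )
    if df.empty:
        df = pd.DataFrame(columns=["sequence", "count", "rpm"])
    write_table(df, path, sort_by=["count", "sequence"])


def load_tags(path: str | Path) -> list[UniqueTag]:
    df = read_table(path)
    return [
        UniqueTag(sequence=r.sequence, count=int(r.count),
                  rpm=float(r.rpm) if "rpm" in df.columns else None)
        for r in df.itertuples(index=False)
    ]


def write_annotations(
    records: Sequence[homology.AnnotationRecord], library_id: str, path: str | Path
) -> None:
    rows = []
    for rec in records:
        hit = rec.best_hit
        rows.append(
            {
                "library_id": library_id,
                "mirna_type": rec.mirna_type,
                "family": rec.family,
                "paralog_group": rec.paralog_group,
                "canonical_sequence": rec.canonical_tag.sequence,
                "count": rec.canonical_tag.count,
                "rpm": rec.canonical_tag.rpm,
                "n_variants": len(rec.supporting_variants),
                "reference_id": hit.reference.header_id,
                "matches": hit.matches,
                "mismatches": hit.mismatches,
                "score": hit.score,
                "evalue": hit.evalue,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(
            columns=["library_id", "mirna_type", "family", "paralog_group",
                     "canonical_sequence", "count", "rpm", "n_variants",
                     "reference_id", "matches", "mismatches", "score", "evalue"]
        )
    write_table(df, path, sort_by=["mirna_type", "library_id"])


def load_annotation_table(path: str | Path) -> pd.DataFrame:
    return read_table(path)


def _resolve_reads_path(meta: LibraryMeta, samplesheet_path: str) -> Path:
    if meta.path is None:
        raise ValueError(f"library {meta.library_id}: no reads path in samplesheet")
    p = Path(meta.path)
    if not p.is_absolute():
        p = Path(samplesheet_path).parent / p
    return p


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage in order; outputs land under ``config.outdir``.

    Re-running with identical config and inputs reproduces identical output
    bytes.  Any stage failure aborts with the stage name and offending input.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage reference: %s", config.reference)
    references = read_mirbase_fasta(config.reference)
    if not references:
        raise ValueError(f"stage reference: no records in {config.reference}")
    metas = read_samplesheet(config.samplesheet)

    profiles: dict[str, LibraryProfile] = {}
    screened: dict[str, list[UniqueTag]] = {}
    annotations: dict[str, list[homology.AnnotationRecord]] = {}
    stats: dict[str, homology.AnnotationStats] = {}
    for meta in metas:
        lib = meta.library_id
        reads_path = _resolve_reads_path(meta, config.samplesheet)
        logger.info("stage preprocess: %s", lib)
        try:
            profile = preprocess.profile_library(
                read_reads(reads_path), meta, config.filter_params
            )
        except Exception as exc:  # annotate failures with the stage name
            raise RuntimeError(f"stage preprocess failed for {lib}: {exc}") from exc
        profiles[lib] = profile
        write_tags(profile.tags, outdir / f"{lib}_tags.tsv")
        hist_df = pd.DataFrame(
            sorted(profile.length_histogram.items()), columns=["length", "reads"]
        )
        write_table(hist_df, outdir / f"{lib}_lengths.tsv", sort_by=["length"])

        logger.info("stage screen: %s", lib)
        screened[lib] = preprocess.screen_candidates(profile.tags, config.screening)
        write_tags(screened[lib], outdir / f"{lib}_screened.tsv")

        logger.info("stage annotate: %s (%d tags)", lib, len(screened[lib]))
        try:
            records, st = homology.annotate_library(
                screened[lib], references, config.alignment, config.criteria
            )
        except Exception as exc:
            raise RuntimeError(f"stage annotate failed for {lib}: {exc}") from exc
        annotations[lib] = records
        stats[lib] = st
        write_annotations(records, lib, outdir / f"{lib}_annotations.tsv")

    logger.info("stage profile")
    matrix = profiling.build_matrix(annotations, [
        profiles[m.library_id].meta for m in metas
    ])
    matrix.reset_index().pipe(
        write_table, outdir / "expression_matrix.tsv", sort_by=["mirna_type"]
    )
    metas_now = [profiles[m.library_id].meta for m in metas]
    calls, category_counts = profiling.classify_tissue_enrichment(matrix, metas_now)
    sex_partitions = profiling.classify_sex_enrichment(calls, matrix, metas_now)
    total_types = len(matrix)
    accounting = profiling.enrichment_accounting(category_counts, max(total_types, 1))
    write_table(accounting, outdir / "enrichment_accounting.tsv",
                sort_by=["category"])
    calls_df = pd.DataFrame(
        [
            {
                "mirna_type": c.mirna_type,
                "tissue_category": c.tissue_category,
                **{f"sex_{t}": d for t, d in c.sex_detail.items()},
            }
            for c in calls
        ]
    )
    if calls_df.empty:
        calls_df = pd.DataFrame(columns=["mirna_type", "tissue_category"])
    write_table(calls_df, outdir / "enrichment_calls.tsv", sort_by=["mirna_type"])

    venn_by_sex = {}
    pres = matrix > 0
    for sex in ("female", "male"):
        sets = {}
        for tissue in ("brain", "liver", "gonad"):
            lib_ids = [m.library_id for m in metas_now
                       if m.tissue == tissue and m.sex == sex]
            members: set[str] = set()
            for lib in lib_ids:
                members |= set(pres.index[pres[lib]])
            sets[tissue] = members
        venn_by_sex[sex] = profiling.venn_counts(sets)
    venn_df = pd.DataFrame(
        [{"sex": sex, "region": region, "count": count}
         for sex, regions in venn_by_sex.items()
         for region, count in regions.items()]
    )
    write_table(venn_df, outdir / "venn_counts.tsv", sort_by=["sex", "region"])

    cons_profiles, cons_summary = profiling.conservation_profiles(
        annotations, references, config.alignment, config.criteria
    )
    cons_df = pd.DataFrame(
        [
            {
                "mirna_type": p.mirna_type,
                "species": ",".join(sorted(p.species_set)),
                "teleost_specific": p.teleost_specific,
                "pan_model": p.pan_model,
            }
            for p in cons_profiles
        ]
    )
    if cons_df.empty:
        cons_df = pd.DataFrame(
            columns=["mirna_type", "species", "teleost_specific", "pan_model"])
    write_table(cons_df, outdir / "conservation.tsv", sort_by=["mirna_type"])

    qpcr_df = None
    if config.ct_table:
        logger.info("stage qpcr: %s", config.ct_table)
        qpcr_df = qpcr_mod.analyze_ct_table(read_table(config.ct_table))
        write_table(qpcr_df, outdir / "qpcr_results.tsv",
                    sort_by=["target", "tissue", "sex"])

    per_library = pd.DataFrame(
        [
            {
                "library_id": lib,
                "tissue": profiles[lib].meta.tissue,
                "sex": profiles[lib].meta.sex,
                "usable_reads": profiles[lib].meta.total_usable_reads,
                "unique_tags": len(profiles[lib].tags),
                "unique_tags_20_23": sum(
                    1 for t in profiles[lib].tags if 20 <= t.length <= 23
                ),
                "screened": stats[lib].screened,
                "annotated_canonical": stats[lib].annotated_canonical,
                "annotated_types": stats[lib].annotated_types,
            }
            for lib in (m.library_id for m in metas)
        ]
    )
    write_table(per_library, outdir / "run_report.tsv", sort_by=["library_id"])
    families = {profiling_rec.family for recs in annotations.values()
                for profiling_rec in recs}
    global_summary = {
        "total_types": total_types,
        "total_families": len(families),
        "category_counts": category_counts,
        "venn": venn_by_sex,
    }
    report = RunReport(
        per_library=per_library,
        global_summary=global_summary,
        accounting=accounting,
        conservation_summary=cons_summary,
    )
    _write_text_report(report, outdir / "run_report.txt")
    return report


def _write_text_report(report: RunReport, path: Path) -> None:
    lines = ["Per-library tallies", "-" * 19]
    lines.append(report.per_library.to_string(index=False))
    lines.append("")
    lines.append("Global summary")
    lines.append("-" * 14)
    g = report.global_summary
    lines.append(f"total annotated miRNA types: {g['total_types']}")
    lines.append(f"total families: {g['total_families']}")
    for _, row in report.accounting.iterrows():
        lines.append(
            f"  {row['category']}: {row['count']} ({row['percent_str']}%)"
        )
    cs = report.conservation_summary
    lines.append(
        f"conservation: {cs.get('teleost_specific', 0)} teleost-specific, "
        f"{cs.get('pan_model', 0)} in all model species, {cs.get('total', 0)} total"
    )
    path.write_text("\n".join(lines) + "\n")
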