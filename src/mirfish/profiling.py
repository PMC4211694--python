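"""Cross-library expression matrix, enrichment classes, Venn and conservation.

Six libraries (brain/liver/gonad x female/male) are combined into an RPM
matrix over annotated miRNA types.  A type present in all six libraries is
common-to-all; a type present in exactly one tissue (either sex) and absent
from both other tissues is tissue-enriched; everything else is "other".
Tissue-enriched types are further split by sex of the libraries carrying
them.  Conservation assigns each type the set of reference species whose
records it hits under the same acceptance criteria used for annotation;
a non-empty species set contained in {dre, fru, tni, ola} marks the type
teleost-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .homology import AlignmentParams, AnnotationRecord, HitCriteria, align_ungapped, db_length, evalue
from .io import LibraryMeta, ReferenceMiRNA, TISSUES

__all__ = [
    "EnrichmentCall",
    "ConservationProfile",
    "TELEOST_SPECIES",
    "MODEL_SPECIES",
    "build_matrix",
    "classify_tissue_enrichment",
    "classify_sex_enrichment",
    "venn_counts",
    "conservation_profiles",
    "conservation_from_species_sets",
    "enrichment_accounting",
    "format_percent",
]

TELEOST_SPECIES = frozenset({"dre", "fru", "tni", "ola"})
MODEL_SPECIES = frozenset({"hsa", "mmu", "dre", "fru", "tni", "ola", "cel", "dme"})

CATEGORIES = (
    "brain-enriched",
    "liver-enriched",
    "gonad-enriched",
    "common-to-all",
    "other",
)


@dataclass
class EnrichmentCall:
    mirna_type: str
    tissue_category: str
    # per tissue: "female-only" | "male-only" | "both" | "absent"
    sex_detail: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ConservationProfile:
    mirna_type: str
    species_set: frozenset[str]
    teleost_specific: bool
    pan_model: bool


def build_matrix(
    annotations: Mapping[str, Sequence[AnnotationRecord]],
    metas: Sequence[LibraryMeta],
) -> pd.DataFrame:
    """RPM matrix: rows = miRNA types, columns = library ids; absent -> 0."""
    ids = [m.library_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate library_id")
    values: dict[tuple[str, str], float] = {}
    for lib_id, records in annotations.items():
        if lib_id not in ids:
            raise ValueError(f"annotations for unknown library {lib_id!r}")
        for rec in records:
            key = (rec.mirna_type, lib_id)
            if key in values:
                raise ValueError(f"duplicate entry for {key}")
            values[key] = rec.canonical_tag.rpm or 0.0
    types = sorted({t for t, _ in values})
    mat = pd.DataFrame(0.0, index=types, columns=ids)
    for (t, lib), v in values.items():
        mat.loc[t, lib] = v
    mat.index.name = "mirna_type"
    return mat


def _presence(matrix: pd.DataFrame) -> pd.DataFrame:
    return matrix > 0


def classify_tissue_enrichment(
    matrix: pd.DataFrame, metas: Sequence[LibraryMeta]
) -> tuple[list[EnrichmentCall], dict[str, int]]:
    """Assign each miRNA type exactly one tissue category.

    Presence means annotated with RPM > 0 (detection is thresholded by the
    upstream RPM >= 6 screen).  common-to-all requires presence in all six
    libraries, not merely in all three tissues.
    """
    meta_by_id = {m.library_id: m for m in metas}
    pres = _presence(matrix)
    calls: list[EnrichmentCall] = []
    counts = {c: 0 for c in CATEGORIES}
    for mirna_type, row in pres.iterrows():
        present_ids = [lib for lib, p in row.items() if p]
        tissues = {meta_by_id[lib].tissue for lib in present_ids}
        if len(present_ids) == len(metas) and len(metas) > 0:
            category = "common-to-all"
        elif len(tissues) == 1:
            category = f"{next(iter(tissues))}-enriched"
        else:
            category = "other"
        calls.append(EnrichmentCall(mirna_type=str(mirna_type), tissue_category=category))
        counts[category] += 1
    return calls, counts


def classify_sex_enrichment(
    calls: Sequence[EnrichmentCall],
    matrix: pd.DataFrame,
    metas: Sequence[LibraryMeta],
) -> dict[str, dict[str, int]]:
    """Partition each tissue-enriched class by sex of the carrying library.

    Returns {tissue: {"female-only": n, "male-only": n, "both": n}}; the
    three partition sizes sum to the class size.  Also fills each call's
    ``sex_detail`` for every tissue.
    """
    pres = _presence(matrix)
    lib_of = {(m.tissue, m.sex): m.library_id for m in metas}
    partitions: dict[str, dict[str, int]] = {
        t: {"female-only": 0, "male-only": 0, "both": 0} for t in TISSUES
    }
    for call in calls:
        row = pres.loc[call.mirna_type]
        for tissue in TISSUES:
            f = bool(row.get(lib_of.get((tissue, "female"), ""), False))
            m = bool(row.get(lib_of.get((tissue, "male"), ""), False))
            if f and m:
                detail = "both"
            elif f:
                detail = "female-only"
            elif m:
                detail = "male-only"
            else:
                detail = "absent"
            call.sex_detail[tissue] = detail
        if call.tissue_category.endswith("-enriched"):
            tissue = call.tissue_category.removesuffix("-enriched")
            partitions[tissue][call.sex_detail[tissue]] += 1
    return partitions


def venn_counts(sets: Mapping[str, set[str]]) -> dict[str, int]:
    """All seven region counts of a 3-set Venn diagram plus the union."""
    if len(sets) != 3:
        raise ValueError("venn_counts expects exactly three sets")
    (na, a), (nb, b), (nc, c) = sets.items()
    return {
        f"{na}_only": len(a - b - c),
        f"{nb}_only": len(b - a - c),
        f"{nc}_only": len(c - a - b),
        f"{na}_{nb}": len((a & b) - c),
        f"{na}_{nc}": len((a & c) - b),
        f"{nb}_{nc}": len((b & c) - a),
        "all_three": len(a & b & c),
        "union": len(a | b | c),
    }


def conservation_from_species_sets(
    species_sets: Mapping[str, Iterable[str]]
) -> tuple[list[ConservationProfile], dict[str, int]]:
    """Build profiles and summary counts from precomputed species sets."""
    profiles = []
    for mirna_type in sorted(species_sets):
        s = frozenset(species_sets[mirna_type])
        profiles.append(
            ConservationProfile(
                mirna_type=mirna_type,
                species_set=s,
                teleost_specific=bool(s) and s <= TELEOST_SPECIES,
                pan_model=MODEL_SPECIES <= s,
            )
        )
    summary = {
        "teleost_specific": sum(p.teleost_specific for p in profiles),
        "pan_model": sum(p.pan_model for p in profiles),
        "total": len(profiles),
    }
    return profiles, summary


def conservation_profiles(
    annotations: Mapping[str, Sequence[AnnotationRecord]],
    references: Sequence[ReferenceMiRNA],
    params: AlignmentParams = AlignmentParams(),
    criteria: HitCriteria = HitCriteria(),
) -> tuple[list[ConservationProfile], dict[str, int]]:
    """Species conservation of each annotated type across the reference.

    A species belongs to a type's set when any reference record of that
    species whose name normalizes to the type is hit by the type's canonical
    tag under the annotation acceptance criteria.
    """
    refs_by_name: dict[str, list[ReferenceMiRNA]] = {}
    for ref in references:
        refs_by_name.setdefault(ref.name, []).append(ref)
    n = db_length(references)
    # one canonical sequence per type: the highest-count canonical across libraries
    canonical_seq: dict[str, str] = {}
    best_count: dict[str, int] = {}
    for records in annotations.values():
        for rec in records:
            c = rec.canonical_tag.count
            if c > best_count.get(rec.mirna_type, -1):
                best_count[rec.mirna_type] = c
                canonical_seq[rec.mirna_type] = rec.canonical_tag.sequence
    species_sets: dict[str, set[str]] = {}
    for mirna_type, seq in canonical_seq.items():
        hits: set[str] = set()
        for ref in refs_by_name.get(mirna_type, []):
            hit = align_ungapped(seq, ref, params)
            if hit is None:
                continue
            e = evalue(hit.score, len(seq), n, params.lam, params.k)
            if (
                hit.matches >= criteria.min_matches
                and hit.mismatches <= criteria.max_mismatches
                and e < criteria.max_evalue
            ):
                hits.add(ref.species)
        species_sets[mirna_type] = hits
    return conservation_from_species_sets(species_sets)


def format_percent(count: int, total: int) -> str:
    """Render 100*count/total at one decimal, dropping a trailing '.0'."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if count > total:
        raise ValueError("count exceeds total")
    s = f"{100.0 * count / total:.1f}"
    return s[:-2] if s.endswith(".0") else s


def enrichment_accounting(
    counts: Mapping[str, int], total: int
) -> pd.DataFrame:
    """Percentage table over category counts (printed-precision rendering)."""
    rows = []
    for category in counts:
        c = counts[category]
        rows.append(
            {
                "category": category,
                "count": c,
                "percent": round(100.0 * c / total, 1),
                "percent_str": format_percent(c, total),
            }
        )
    return pd.DataFrame(rows)
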