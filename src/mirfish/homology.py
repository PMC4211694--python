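"""Homology annotation of screened tags against a mature-miRNA reference.

The aligner is a seeded, ungapped local alignment: every shared word of
``word_size`` nucleotides between tag and reference defines a diagonal, and
each run of consecutive matches of at least ``word_size`` on a diagonal is
extended in both directions to the maximal-scoring segment (match +1,
mismatch -3).  Gap-free alignment is sufficient for 20-23-nt queries under a
three-mismatch acceptance cap, and the +1/-3 scoring admits the published
ungapped Karlin-Altschul parameters lambda = 1.374, K = 0.711, giving the
database-wide expectation

    E = K * m * n * exp(-lambda * S)

for a query of length m against n total reference letters.  A hit is
accepted when it has at least 15 nucleotide matches, at most 3 mismatches
and E < 0.06.  When several library tags hit the same reference name, the
most abundant tag with the highest alignment score is chosen as the
canonical candidate and the rest become its supporting variants; reference
names that normalize to the same family-plus-arm label (gene-copy paralogs
such as miR-138-1-3p / miR-138-2-3p) share one paralog group.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .io import ReferenceMiRNA, parse_mirna_id
from .preprocess import UniqueTag

__all__ = [
    "AlignmentParams",
    "HitCriteria",
    "AlignmentHit",
    "AnnotationRecord",
    "AnnotationStats",
    "evalue",
    "align_ungapped",
    "best_hit",
    "select_canonical",
    "group_paralogs",
    "annotate_library",
    "paralog_label",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and statistics for the seeded ungapped aligner."""

    word_size: int = 7
    match_score: int = 1
    mismatch_score: int = -3
    lam: float = 1.374  # Karlin-Altschul lambda for +1/-3, ungapped
    k: float = 0.711  # Karlin-Altschul K for +1/-3, ungapped

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be positive")
        if self.match_score <= 0 or self.mismatch_score >= 0:
            raise ValueError("match_score > 0 and mismatch_score < 0 required")


@dataclass(frozen=True)
class HitCriteria:
    """Acceptance rules: >=15 matches, <=3 mismatches, E < 0.06."""

    min_matches: int = 15
    max_mismatches: int = 3
    max_evalue: float = 0.06


@dataclass(frozen=True)
class AlignmentHit:
    """Best ungapped match between one tag and one reference record.

    ``offset`` is the 0-based reference position aligned to query position 0
    (negative when the query overhangs the reference 5' end); the aligned
    segment spans ``[q_start, q_end)`` on the query.
    """

    reference: ReferenceMiRNA
    offset: int
    q_start: int
    q_end: int
    matches: int
    mismatches: int
    score: int
    evalue: float = math.inf

    @property
    def overlap(self) -> int:
        return self.q_end - self.q_start


@dataclass
class AnnotationRecord:
    """One annotated miRNA type in one library."""

    mirna_type: str  # reference name without the species prefix
    family: str
    canonical_tag: UniqueTag
    best_hit: AlignmentHit
    supporting_variants: list[UniqueTag] = field(default_factory=list)
    paralog_group: str = ""


@dataclass(frozen=True)
class AnnotationStats:
    screened: int
    annotated_canonical: int
    annotated_types: int  # distinct paralog groups


def evalue(score: float, m: int, n: int, lam: float, k: float) -> float:
    """Karlin-Altschul expectation E = K*m*n*exp(-lambda*S)."""
    if m < 1 or n < 1:
        raise ValueError("search-space lengths must be >= 1")
    return k * m * n * math.exp(-lam * score)


def _segment_hits_on_diagonal(
    query: str, reference: str, offset: int, params: AlignmentParams
) -> Iterable[tuple[int, int, int, int, int]]:
    """Best extension around each seed-length match run on one diagonal.

    Yields (q_start, q_end, matches, mismatches, score) for the
    maximal-scoring segment containing each run of >= word_size consecutive
    matches.  Extending over further match positions never lowers the score,
    so the optimum containing any seed word contains its whole run.
    """
    q_lo = max(0, -offset)
    q_hi = min(len(query), len(reference) - offset)
    if q_hi - q_lo < params.word_size:
        return
    ms, mm = params.match_score, params.mismatch_score
    flags = [query[q] == reference[q + offset] for q in range(q_lo, q_hi)]
    scores = [ms if f else mm for f in flags]
    n = len(flags)
    # maximal runs of consecutive matches
    i = 0
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j < n and flags[j]:
            j += 1
        if j - i >= params.word_size:
            # extend outward to the maximal-scoring extents; score ties
            # prefer the farther extent (more matched positions)
            run_sum, best_val, a = 0, 0, i
            for p in range(i - 1, -1, -1):
                run_sum += scores[p]
                if run_sum >= best_val:
                    best_val, a = run_sum, p
            run_sum, best_val, b = 0, 0, j
            for p in range(j, n):
                run_sum += scores[p]
                if run_sum >= best_val:
                    best_val, b = run_sum, p + 1
            seg_matches = sum(flags[a:b])
            seg_mism = (b - a) - seg_matches
            score = seg_matches * ms + seg_mism * mm
            yield (q_lo + a, q_lo + b, seg_matches, seg_mism, score)
        i = j


def align_ungapped(
    query: str, reference: ReferenceMiRNA, params: AlignmentParams = AlignmentParams()
) -> AlignmentHit | None:
    """Best seeded ungapped hit of ``query`` against one reference, or None.

    Both sequences are compared T-normalized; ``query`` must already be
    T-normalized (as produced by the preprocess stage).
    """
    ref = reference.seq_t
    w = params.word_size
    if len(query) < w or len(ref) < w:
        return None
    ref_words: dict[str, list[int]] = defaultdict(list)
    for p in range(len(ref) - w + 1):
        ref_words[ref[p : p + w]].append(p)
    offsets: set[int] = set()
    for q in range(len(query) - w + 1):
        for p in ref_words.get(query[q : q + w], ()):
            offsets.add(p - q)
    best: AlignmentHit | None = None
    for off in sorted(offsets):
        for q_start, q_end, matches, mism, score in _segment_hits_on_diagonal(
            query, ref, off, params
        ):
            if best is None or (score, matches, -mism) > (
                best.score,
                best.matches,
                -best.mismatches,
            ):
                best = AlignmentHit(
                    reference=reference,
                    offset=off + q_start,
                    q_start=q_start,
                    q_end=q_end,
                    matches=matches,
                    mismatches=mism,
                    score=score,
                )
    return best


def db_length(references: Sequence[ReferenceMiRNA]) -> int:
    return sum(len(r.seq_t) for r in references)


def best_hit(
    query: str,
    references: Sequence[ReferenceMiRNA],
    params: AlignmentParams = AlignmentParams(),
    criteria: HitCriteria = HitCriteria(),
    n_letters: int | None = None,
) -> AlignmentHit | None:
    """Highest-scoring criteria-passing hit over the whole reference set.

    Ties break on (fewer mismatches, more matches, lexicographic header id).
    ``n_letters`` overrides the database size used in the E-value (it
    defaults to the total letters in ``references``).
    """
    if not references:
        raise ValueError("empty reference database")
    n = n_letters if n_letters is not None else db_length(references)
    m = len(query)
    best: AlignmentHit | None = None
    for ref in references:
        hit = align_ungapped(query, ref, params)
        if hit is None:
            continue
        e = evalue(hit.score, m, n, params.lam, params.k)
        if (
            hit.matches < criteria.min_matches
            or hit.mismatches > criteria.max_mismatches
            or e >= criteria.max_evalue
        ):
            continue
        hit = replace(hit, evalue=e)
        if best is None:
            best = hit
            continue
        key = (-hit.score, hit.mismatches, -hit.matches, hit.reference.header_id)
        best_key = (-best.score, best.mismatches, -best.matches,
                    best.reference.header_id)
        if key < best_key:
            best = hit
    return best


def select_canonical(
    hits_by_name: dict[str, list[tuple[UniqueTag, AlignmentHit]]]
) -> list[AnnotationRecord]:
    """Pick one canonical candidate per reference name.

    Within a name group, candidates order by (count desc, score desc,
    sequence); the first becomes canonical, all tags in the group become the
    supporting variants.  Output is independent of input order.
    """
    records = []
    for name in sorted(hits_by_name):
        group = sorted(
            hits_by_name[name],
            key=lambda th: (-th[0].count, -th[1].score, th[0].sequence),
        )
        canonical, hit = group[0]
        ident = parse_mirna_id(name)
        records.append(
            AnnotationRecord(
                mirna_type=name,
                family=ident.family,
                canonical_tag=canonical,
                best_hit=hit,
                supporting_variants=[t for t, _ in group],
            )
        )
    return records


def paralog_label(mirna_type: str) -> str:
    """Family-plus-arm label under which gene-copy paralogs collapse.

    miR-138-1-3p and miR-138-2-3p -> miR-138-3p; miR-122 and miR-122-3p stay
    distinct (different arms).
    """
    ident = parse_mirna_id(mirna_type)
    return ident.family + (f"-{ident.arm}" if ident.arm else "")


def group_paralogs(records: list[AnnotationRecord]) -> list[AnnotationRecord]:
    """Assign the shared paralog_group label to every record (in place)."""
    for rec in records:
        rec.paralog_group = paralog_label(rec.mirna_type)
    return records


def annotate_library(
    tags: Sequence[UniqueTag],
    references: Sequence[ReferenceMiRNA],
    params: AlignmentParams = AlignmentParams(),
    criteria: HitCriteria = HitCriteria(),
) -> tuple[list[AnnotationRecord], AnnotationStats]:
    """Annotate screened tags: best hit per tag, canonical per name.

    Uses a database-wide word index so tags sharing no word with any
    reference are dismissed cheaply.
    """
    if not references:
        raise ValueError("empty reference database")
    w = params.word_size
    n = db_length(references)
    word_index: dict[str, set[int]] = defaultdict(set)
    for idx, ref in enumerate(references):
        s = ref.seq_t
        for p in range(len(s) - w + 1):
            word_index[s[p : p + w]].add(idx)
    hits_by_name: dict[str, list[tuple[UniqueTag, AlignmentHit]]] = defaultdict(list)
    for tag in tags:
        seq = tag.sequence
        cand: set[int] = set()
        for q in range(len(seq) - w + 1):
            cand |= word_index.get(seq[q : q + w], set())
        if not cand:
            continue
        hit = best_hit(
            seq,
            [references[i] for i in sorted(cand)],
            params,
            criteria,
            n_letters=n,
        )
        if hit is not None:
            hits_by_name[hit.reference.name].append((tag, hit))
    records = group_paralogs(select_canonical(hits_by_name))
    stats = AnnotationStats(
        screened=len(tags),
        annotated_canonical=len(records),
        annotated_types=len({r.paralog_group for r in records}),
    )
    return records, stats
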