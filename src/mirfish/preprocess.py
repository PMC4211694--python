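"""Read filtering, non-redundant tag collapsing, RPM and length profiles.

Raw small-RNA reads (58 nt on the instrument used here) read through the
insert into the 3' adapter, so every genuine small-RNA read must contain the
adapter.  Filtering removes low-quality reads, ambiguous bases, adapter
dimers, homopolymer junk and reads with no detectable adapter; survivors are
collapsed into non-redundant unique tags whose relative abundance is
expressed in reads per million filtered reads (RPM).  Candidate miRNA tags
are then screened by length (20-23 nt) and abundance (RPM >= 6); strand
specificity is a property of the library construction, so only
sense-orientation reads ever enter the pipeline.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

from .io import LibraryMeta, ReadRecord, normalize_t

__all__ = [
    "FilterParams",
    "ScreeningParams",
    "UniqueTag",
    "LibraryProfile",
    "RejectionTally",
    "trim_adapter",
    "filter_reads",
    "collapse_reads",
    "compute_rpm",
    "length_distribution",
    "screen_candidates",
    "profile_library",
]

_ADAPTER_SEED_LEN = 12


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for the read-cleaning stage.

    The source protocol states only that low-quality sequences, homopolymers
    and adapter sequences were removed; the concrete thresholds below make
    that filter reproducible and tunable.
    """

    adapter_3p: str = ""
    min_length_after_trim: int = 15
    max_homopolymer_fraction: float = 0.8
    min_mean_quality: float = 20.0  # ignored for FASTA input
    max_n: int = 0

    def __post_init__(self) -> None:
        if self.min_length_after_trim < 1:
            raise ValueError("min_length_after_trim must be >= 1")
        if not 0 < self.max_homopolymer_fraction <= 1:
            raise ValueError("max_homopolymer_fraction must be in (0, 1]")
        if self.max_n < 0:
            raise ValueError("max_n must be >= 0")


@dataclass(frozen=True)
class ScreeningParams:
    """Candidate screen: length 20-23 nt and RPM >= 6 (both inclusive)."""

    min_length: int = 20
    max_length: int = 23
    min_rpm: float = 6.0


@dataclass(frozen=True)
class UniqueTag:
    """A collapsed, T-normalized unique small-RNA sequence in one library."""

    sequence: str
    count: int
    rpm: float | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be >= 1")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class RejectionTally:
    """Reads removed by the filter, partitioned by the first failing rule."""

    low_quality: int = 0
    ambiguous: int = 0
    no_adapter: int = 0
    too_short: int = 0
    homopolymer: int = 0

    @property
    def total(self) -> int:
        return (
            self.low_quality
            + self.ambiguous
            + self.no_adapter
            + self.too_short
            + self.homopolymer
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "low_quality": self.low_quality,
            "ambiguous": self.ambiguous,
            "no_adapter": self.no_adapter,
            "too_short": self.too_short,
            "homopolymer": self.homopolymer,
        }


@dataclass
class LibraryProfile:
    """Unique tags plus the read-weighted length histogram of one library."""

    meta: LibraryMeta
    tags: list[UniqueTag] = field(default_factory=list)
    length_histogram: dict[int, int] = field(default_factory=dict)
    rejections: RejectionTally = field(default_factory=RejectionTally)


def trim_adapter(sequence: str, adapter: str) -> str | None:
    """Remove the 3' adapter, returning the insert, or None if not found.

    The adapter match is anchored by an exact seed (the first 12 nt of the
    adapter, or the whole adapter when shorter) and verified over the full
    read/adapter overlap allowing one mismatch per 10 nt (floor).  The
    earliest verified seed wins, so the longest possible suffix is removed.
    A read beginning with the adapter (an adapter dimer) trims to "".
    """
    seed = adapter[:_ADAPTER_SEED_LEN]
    start = 0
    while True:
        i = sequence.find(seed, start)
        if i < 0:
            break
        overlap = min(len(adapter), len(sequence) - i)
        window = sequence[i : i + overlap]
        allowed = overlap // 10
        mismatches = sum(a != b for a, b in zip(window, adapter))
        if mismatches <= allowed:
            return sequence[:i]
        start = i + 1
    # no exact seed anywhere: exhaustive tolerant scan (rare path)
    min_overlap = min(len(adapter), 5)
    for i in range(len(sequence) - min_overlap + 1):
        overlap = min(len(adapter), len(sequence) - i)
        allowed = overlap // 10
        mismatches = 0
        for a, b in zip(sequence[i : i + overlap], adapter):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            return sequence[:i]
    return None


def _max_base_fraction(seq: str) -> float:
    n = len(seq)
    if n == 0:
        return 0.0
    return max(seq.count(b) for b in "ACGT") / n


def filter_reads(
    reads: Iterable[ReadRecord], params: FilterParams
) -> tuple[list[str], RejectionTally]:
    """Clean raw reads; returns surviving T-normalized inserts and a tally.

    Rules are applied in a fixed order (quality, ambiguous bases, adapter,
    length, homopolymer) and each rejected read is tallied under the first
    rule it fails.
    """
    adapter = normalize_t(params.adapter_3p) if params.adapter_3p else ""
    trim = bool(adapter)
    if params.adapter_3p and len(adapter) < 5:
        warnings.warn(
            f"adapter {params.adapter_3p!r} shorter than 5 nt; trimming skipped",
            stacklevel=2,
        )
        trim = False
    tally = RejectionTally()
    kept: list[str] = []
    min_len = params.min_length_after_trim
    max_frac = params.max_homopolymer_fraction
    for read in reads:
        if read.quality is not None:
            if sum(read.quality) / len(read.quality) < params.min_mean_quality:
                tally.low_quality += 1
                continue
        seq = normalize_t(read.sequence)
        if seq.count("N") > params.max_n:
            tally.ambiguous += 1
            continue
        if trim:
            insert = trim_adapter(seq, adapter)
            if insert is None:
                tally.no_adapter += 1
                continue
        else:
            insert = seq
        if len(insert) < min_len:
            tally.too_short += 1
            continue
        if _max_base_fraction(insert) > max_frac:
            tally.homopolymer += 1
            continue
        kept.append(insert)
    return kept, tally


def collapse_reads(sequences: Iterable[str]) -> list[UniqueTag]:
    """Bin filtered reads into non-redundant unique tags with counts.

    Order-independent: tags come back sorted by (descending count, sequence).
    """
    counts = Counter(sequences)
    return [
        UniqueTag(sequence=seq, count=c)
        for seq, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def compute_rpm(tags: list[UniqueTag], total_usable_reads: int) -> list[UniqueTag]:
    """Set each tag's RPM = count / total_usable_reads * 1e6."""
    if total_usable_reads <= 0:
        raise ValueError("total_usable_reads must be positive")
    scale = 1e6 / total_usable_reads
    return [replace(t, rpm=t.count * scale) for t in tags]


def length_distribution(
    profile: LibraryProfile, window: int = 3
) -> tuple[dict[int, int], tuple[int, int]]:
    """Read-weighted length histogram plus the modal length band.

    The band is the contiguous ``window``-nt length interval with maximal
    read mass; ties prefer the window centred on the modal length, then the
    leftmost window.
    """
    hist = dict(profile.length_histogram)
    if not hist:
        hist = Counter()
        for t in profile.tags:
            hist[t.length] += t.count
        hist = dict(hist)
    if not hist:
        raise ValueError("profile has no tags")
    mode = max(hist, key=lambda k: (hist[k], -k))
    lo, hi = min(hist), max(hist)
    masses = {
        start: sum(hist.get(k, 0) for k in range(start, start + window))
        for start in range(lo - window + 1, hi + 1)
    }
    best_mass = max(masses.values())
    candidates = [s for s, m in masses.items() if m == best_mass]
    centred_start = mode - window // 2
    start = centred_start if centred_start in candidates else min(candidates)
    return hist, (start, start + window - 1)


def screen_candidates(
    tags: Iterable[UniqueTag], screening: ScreeningParams = ScreeningParams()
) -> list[UniqueTag]:
    """Keep tags with 20 <= length <= 23 and RPM >= 6 (idempotent)."""
    out = []
    for t in tags:
        if t.rpm is None:
            raise ValueError("screen_candidates requires RPM to be computed")
        if screening.min_length <= t.length <= screening.max_length and (
            t.rpm >= screening.min_rpm
        ):
            out.append(t)
    return out


def profile_library(
    reads: Iterable[ReadRecord], meta: LibraryMeta, params: FilterParams
) -> LibraryProfile:
    """Filter, collapse and RPM-normalize one library into a profile."""
    kept, tally = filter_reads(reads, params)
    tags = collapse_reads(kept)
    total = len(kept)
    if total:
        tags = compute_rpm(tags, total)
    hist: Counter[int] = Counter()
    for t in tags:
        hist[t.length] += t.count
    return LibraryProfile(
        meta=replace(meta, total_usable_reads=total),
        tags=tags,
        length_histogram=dict(hist),
        rejections=tally,
    )
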