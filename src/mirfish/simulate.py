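"""Ground-truthed synthetic inputs for the discovery pipeline.

The generator emulates the statistical structure the analysis assumes:

* a multi-species mature-miRNA reference in which orthologs of a type share
  the sequence up to two substitutions, families contain letter / gene-copy
  paralog pairs and -5p/-3p arm pairs, and unrelated types share no 7-mer
  (so the planted truth is unambiguous for recall/precision accounting);
* six tissue/sex read libraries with planted, tissue- and sex-restricted
  miRNA types spanning a log-uniform 6-30,000 RPM dynamic range, isomiR end
  shifts and point-substitution noise, a gonad-specific 26-28-nt piRNA-like
  background (half the usable reads, so gonad length profiles peak at 26-28
  nt while brain/liver peak at 21-23 nt), a degradation background of random
  15-30-nt fragments, and adapter-dimer / homopolymer / low-quality
  contamination; every read is emitted as insert + 3' adapter padded to the
  58-nt instrument read length;
* two-group qPCR Ct tables (n = 10 per group, technical triplicates, dual
  endogenous controls) with configurable ddCt effects.

Everything is driven by one integer seed and is byte-deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import normalize_t

__all__ = [
    "SimulationConfig",
    "PlantedType",
    "DEFAULT_ADAPTER",
    "default_panel",
    "simulate_reference",
    "simulate_library",
    "simulate_qpcr",
    "simulate_all",
]

DEFAULT_ADAPTER = "TCGTATGCCGTCTTCTGCTTG"
# sequence the instrument reads into after the adapter (PCR primer side);
# long enough that insert + adapter + downstream always covers 58 cycles
_DOWNSTREAM = "GGAATTCTCGGGTGCCAAGGAACTCCAGTCACATCACGAT"
_BASES = "ACGT"
_SEED_LEN = 12  # exact-seed length used by the adapter trimmer

LIBRARIES: tuple[tuple[str, str], ...] = (
    ("brain", "female"),
    ("brain", "male"),
    ("liver", "female"),
    ("liver", "male"),
    ("gonad", "female"),
    ("gonad", "male"),
)

ALL6 = frozenset(LIBRARIES)


def _lib_id(tissue: str, sex: str) -> str:
    return f"{sex}_{tissue}"


@dataclass(frozen=True)
class PlantedType:
    """One reference miRNA type with its planted presence and conservation."""

    name: str
    presence: frozenset[tuple[str, str]]  # (tissue, sex) pairs with reads
    species: tuple[str, ...]  # species carrying a reference record
    related_to: str | None = None  # paralog parent sharing the sequence core

    @property
    def decoy(self) -> bool:
        return not self.presence


def _pres(*pairs: tuple[str, str]) -> frozenset[tuple[str, str]]:
    return frozenset(pairs)


_BRAIN = _pres(("brain", "female"), ("brain", "male"))
_LIVER = _pres(("liver", "female"), ("liver", "male"))
_GONAD = _pres(("gonad", "female"), ("gonad", "male"))

_PAN = ("hsa", "mmu", "dre", "fru", "tni", "ola", "cel", "dme")
_VERT = ("hsa", "mmu", "dre", "ola")
_FISH_WIDE = ("dre", "fru", "tni", "ola")


def default_panel() -> list[PlantedType]:
    """The default planted panel: 55 expressed types plus 5 decoy references.

    Composition mirrors the tissue/sex structure the pipeline must resolve:
    20 common-to-all types, 17 brain-enriched (12 both sexes / 3 female-only
    / 2 male-only), 6 liver-enriched (4/1/1), 8 gonad-enriched (4 both / 2
    ovary-only / 2 testis-only), 4 mixed (brain+liver, hence "other"), and 5
    reference-only decoys.  Ten types are teleost-specific.
    """
    panel: list[PlantedType] = []

    common = [
        ("let-7a", _PAN, None),
        ("miR-21", _PAN, None),
        ("miR-26a", _PAN, None),
        ("miR-29b", _PAN, None),
        ("miR-143", _VERT, None),
        ("miR-101", _PAN, None),
        ("miR-102", _PAN, None),
        ("miR-103a", _VERT, None),
        ("miR-103b", _VERT, "miR-103a"),
        ("miR-104", ("hsa", "dre"), None),
        ("miR-105-5p", _VERT, None),
        ("miR-105-3p", _VERT, None),
        ("miR-106", ("hsa", "mmu", "dre"), None),
        ("miR-107", ("hsa", "dre", "ola"), None),
        ("miR-108", ("mmu", "dre"), None),
        ("miR-109", ("hsa", "dre"), None),
        ("miR-110", ("dre", "ola"), None),
        ("miR-111", ("hsa", "mmu", "dre"), None),
        ("miR-112", ("hsa", "dre", "ola"), None),
        ("miR-113", _VERT, None),
    ]
    panel += [PlantedType(n, ALL6, sp, rel) for n, sp, rel in common]

    brain_both = [
        ("miR-9-3p", _PAN, None),
        ("miR-124", _PAN, None),
        ("miR-138-1-3p", _VERT, None),
        ("miR-138-2-3p", _VERT, "miR-138-1-3p"),
        ("miR-210", ("hsa", "mmu", "dre"), None),
        ("miR-211", ("hsa", "dre"), None),
        ("miR-212", ("hsa", "dre", "ola"), None),
        ("miR-213", ("dre",), None),
        ("miR-214", ("dre", "fru", "tni"), None),
        ("miR-215", ("hsa", "dre"), None),
        ("miR-216", _VERT, None),
        ("miR-217", ("mmu", "dre"), None),
    ]
    panel += [PlantedType(n, _BRAIN, sp, rel) for n, sp, rel in brain_both]
    for name, sp in (("miR-220", ("hsa", "dre")), ("miR-221", _VERT),
                     ("miR-222", ("dre", "hsa"))):
        panel.append(PlantedType(name, _pres(("brain", "female")), sp))
    for name, sp in (("miR-223", ("hsa", "dre")), ("miR-224", ("mmu", "dre"))):
        panel.append(PlantedType(name, _pres(("brain", "male")), sp))

    liver_both = [
        ("miR-122", _VERT, None),
        ("miR-122-3p", _VERT, None),
        ("miR-230", ("dre", "ola"), None),
        ("miR-231", ("hsa", "dre"), None),
    ]
    panel += [PlantedType(n, _LIVER, sp, rel) for n, sp, rel in liver_both]
    panel.append(PlantedType("miR-232", _pres(("liver", "female")), ("hsa", "dre")))
    panel.append(PlantedType("miR-233", _pres(("liver", "male")), ("dre", "mmu")))

    gonad_both = [
        ("miR-202-5p", _VERT, None),
        ("miR-240", _FISH_WIDE, None),
        ("miR-241", ("dre",), None),
        ("miR-242", ("hsa", "dre"), None),
    ]
    panel += [PlantedType(n, _GONAD, sp, rel) for n, sp, rel in gonad_both]
    panel.append(PlantedType("miR-27a", _pres(("gonad", "female")), _VERT))
    panel.append(PlantedType("miR-243", _pres(("gonad", "female")), ("dre", "ola")))
    panel.append(PlantedType("miR-2184", _pres(("gonad", "male")), ("dre",)))
    panel.append(PlantedType("miR-244", _pres(("gonad", "male")), ("dre",)))

    mixed = _BRAIN | _LIVER
    for name, sp in (("miR-250", ("dre", "fru", "tni")), ("miR-251", ("hsa", "dre")),
                     ("miR-252", _VERT), ("miR-253", ("dre", "ola"))):
        panel.append(PlantedType(name, frozenset(mixed), sp))

    for i, sp in enumerate((("dre",), ("dre", "hsa"), ("dre", "hsa"),
                            ("dre", "mmu"), ("hsa", "dre"))):
        panel.append(PlantedType(f"miR-26{i}", frozenset(), sp))
    return panel


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic run (reduced-scale by design)."""

    seed: int = 0
    reads_per_library: int = 200_000
    isomir_rate: float = 0.2
    mutation_rate: float = 0.01
    pirna_background_fraction: float = 0.5
    degradation_background_fraction: float = 0.15
    adapter_contamination: float = 0.05
    low_quality_fraction: float = 0.01
    homopolymer_fraction: float = 0.005
    adapter_3p: str = DEFAULT_ADAPTER
    read_length: int = 58
    rpm_low: float = 6.0
    rpm_high: float = 30_000.0
    min_rpm: float = 6.0
    panel: list[PlantedType] = field(default_factory=default_panel)
    qpcr_n_per_group: int = 10
    qpcr_sigma: float = 0.3
    qpcr_triplicate_sd: float = 0.05
    qpcr_effects: dict[tuple[str, str, str], float] | None = None

    def __post_init__(self) -> None:
        for name in ("isomir_rate", "mutation_rate", "pirna_background_fraction",
                     "degradation_background_fraction", "adapter_contamination",
                     "low_quality_fraction", "homopolymer_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.reads_per_library < 1000:
            raise ValueError("reads_per_library must be >= 1000")

    def effects(self) -> dict[tuple[str, str, str], float]:
        if self.qpcr_effects is not None:
            return dict(self.qpcr_effects)
        # positive ddCt = suppression under treatment; -1.0 = 2-fold induction
        return {
            ("let-7a", "liver", "female"): 1.0,
            ("let-7a", "liver", "male"): 1.0,
            ("let-7a", "brain", "female"): 1.0,
            ("let-7a", "brain", "male"): 0.0,
            ("miR-122", "liver", "female"): 1.5,
            ("miR-122", "liver", "male"): 1.5,
            ("miR-9-3p", "brain", "female"): 1.0,
            ("miR-9-3p", "brain", "male"): 0.0,
            ("miR-2184", "gonad", "male"): -1.0,
            ("miR-27a", "gonad", "female"): 0.0,
        }


# ---------------------------------------------------------------------------
# sequence helpers


def _words(seq: str, w: int = 7) -> set[str]:
    return {seq[i : i + w] for i in range(len(seq) - w + 1)}


def _max_base_fraction(seq: str) -> float:
    return max(seq.count(b) for b in _BASES) / len(seq)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    if n_subs == 0:
        return seq
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    chars = list(seq)
    for p in positions:
        chars[p] = _BASES[(_BASES.index(chars[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(chars)


def _clean(seq: str, adapter_seed: str) -> bool:
    return _max_base_fraction(seq) <= 0.7 and adapter_seed not in seq


def _random_seq_batch(
    rng: np.random.Generator, lengths: np.ndarray, adapter_seed: str
) -> list[str]:
    """Random A/C/G/T sequences, rejecting homopolymer-like ones and any
    containing the adapter seed (so filtering outcomes stay deterministic)."""
    out: list[str] = []
    base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)
    for length in np.unique(lengths):
        n = int((lengths == length).sum())
        need = n
        seqs: list[str] = []
        while need > 0:
            codes = rng.integers(0, 4, size=(need, int(length)), dtype=np.uint8)
            chars = base_arr[codes]
            counts = np.stack([(codes == b).sum(axis=1) for b in range(4)])
            ok = counts.max(axis=0) <= 0.7 * length
            for row, good in zip(chars, ok):
                if not good:
                    continue
                s = row.tobytes().decode("ascii")
                if adapter_seed in s:
                    continue
                seqs.append(s)
            need = n - len(seqs)
        out.extend(seqs[:n])
    # restore the requested order of lengths
    by_len: dict[int, list[str]] = {}
    i = 0
    for length in np.unique(lengths):
        k = int((lengths == length).sum())
        by_len[int(length)] = out[i : i + k]
        i += k
    result = []
    for length in lengths:
        result.append(by_len[int(length)].pop())
    return result


def _detectable_homolog(core: str, record: str) -> bool:
    """True when ``core`` hits ``record`` under the default acceptance rules
    (>= 15 matches, <= 3 mismatches, E < 0.06 even for a 1e5-letter db)."""
    from .homology import AlignmentParams, align_ungapped, evalue
    from .io import ReferenceMiRNA

    ref = ReferenceMiRNA(header_id="xxx-tmp", species="xxx", name="tmp",
                         family="tmp", arm=None, sequence=record, seq_t=record)
    params = AlignmentParams()
    hit = align_ungapped(core, ref, params)
    if hit is None or hit.matches < 15 or hit.mismatches > 3:
        return False
    return evalue(hit.score, len(core), 10**5, params.lam, params.k) < 0.06


# ---------------------------------------------------------------------------
# reference


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[str, dict]:
    """Build the mature-miRNA reference FASTA and its truth fragment.

    Independent sequence cores are rejection-sampled so that no two
    unrelated types share any 7-mer; paralogs declared ``related_to``
    reuse the parent core with two substitutions; each ortholog record is
    the core with 0 substitutions for dre and 1-2 for other species.
    Raises if seed-disjointness cannot be satisfied in bounded retries.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    panel = config.panel
    if len(panel) < 2:
        raise ValueError("need at least two reference types")
    adapter_seed = normalize_t(config.adapter_3p)[:_SEED_LEN]
    lengths = rng.choice([20, 21, 22, 23], size=len(panel), p=[0.1, 0.25, 0.4, 0.25])
    cores: dict[str, str] = {}
    used_words: set[str] = set()
    for ptype, length in zip(panel, lengths):
        if ptype.related_to is not None:
            parent = cores.get(ptype.related_to)
            if parent is None:
                raise ValueError(f"{ptype.name}: parent {ptype.related_to} undefined")
            cores[ptype.name] = _mutate(rng, parent, 2)
            continue
        for _ in range(200):
            cand = _random_seq(rng, int(length))
            if _clean(cand, adapter_seed) and not (_words(cand) & used_words):
                cores[ptype.name] = cand
                used_words |= _words(cand)
                break
        else:
            raise RuntimeError(
                "could not draw seed-disjoint reference cores; use fewer types"
            )
    fasta_lines: list[str] = []
    truth_species: dict[str, dict[str, str]] = {}
    for ptype in panel:
        core = cores[ptype.name]
        records: dict[str, str] = {}
        for sp in ptype.species:
            n_subs = 0 if sp == "dre" else int(rng.integers(1, 3))
            # a planted ortholog is, by construction, a detectable homolog:
            # substitution placements whose maximal-scoring segment would
            # fail the hit criteria (e.g. both near one end) are redrawn
            for _ in range(200):
                cand = _mutate(rng, core, n_subs)
                if _detectable_homolog(core, cand):
                    break
            else:
                raise RuntimeError(f"no detectable ortholog for {ptype.name}/{sp}")
            records[sp] = cand
        truth_species[ptype.name] = records
        for sp in ptype.species:
            rna = records[sp].replace("T", "U")
            fasta_lines.append(f">{sp}-{ptype.name}")
            fasta_lines.append(rna)
    truth = {
        "cores": cores,
        "species_records": truth_species,
        "decoys": [p.name for p in panel if p.decoy],
        "planted_types": [p.name for p in panel if not p.decoy],
    }
    return "\n".join(fasta_lines) + "\n", truth


# ---------------------------------------------------------------------------
# libraries


def _isomir_variants(
    rng: np.random.Generator, core: str, n_iso: int
) -> dict[str, int]:
    """Distribute n_iso reads over end-shift variants of the core."""
    if n_iso <= 0:
        return {}
    ext_base = _BASES[int(rng.integers(0, 4))]
    patterns = [core[:-1], core[:-2], core[1:], core + ext_base]
    weights = np.array([0.4, 0.2, 0.2, 0.2])
    counts = rng.multinomial(n_iso, weights)
    out: dict[str, int] = {}
    for seq, c in zip(patterns, counts):
        if c > 0 and len(seq) >= 15:
            out[seq] = out.get(seq, 0) + int(c)
    dropped = n_iso - sum(out.values())
    if dropped and out:
        first = next(iter(out))
        out[first] += dropped
    elif dropped:
        out[core[:-1]] = dropped
    return out


def _apply_mutations(
    rng: np.random.Generator, groups: dict[str, int], rate: float
) -> dict[str, int]:
    """Per-base substitution noise applied read-wise to grouped counts."""
    if rate <= 0:
        return dict(groups)
    out: dict[str, int] = {}
    for seq, count in groups.items():
        p_any = 1.0 - (1.0 - rate) ** len(seq)
        k = int(rng.binomial(count, p_any))
        if count - k > 0:
            out[seq] = out.get(seq, 0) + (count - k)
        for _ in range(k):
            mutant = _mutate(rng, seq, 1)
            out[mutant] = out.get(mutant, 0) + 1
    return out


def simulate_library(
    config: SimulationConfig,
    tissue: str,
    sex: str,
    reference_truth: Mapping,
    rng: np.random.Generator | None = None,
) -> tuple[str, dict]:
    """Generate one library's FASTQ text plus its truth fragment.

    Planted abundances are drawn log-uniformly on [rpm_low, rpm_high] and
    converted to deterministic read counts floored at the screening
    boundary, so in the noiseless limit every planted type passes the
    RPM >= 6 screen by construction.
    """
    if rng is None:
        idx = LIBRARIES.index((tissue, sex))
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, idx]))
    adapter = normalize_t(config.adapter_3p)
    adapter_seed = adapter[:_SEED_LEN]
    post = adapter + _DOWNSTREAM
    read_len = config.read_length

    n_total = config.reads_per_library
    n_lowq = round(config.low_quality_fraction * n_total)
    n_dimer = round(config.adapter_contamination * n_total)
    n_homo = round(config.homopolymer_fraction * n_total)
    usable = n_total - n_lowq - n_dimer - n_homo
    n_pirna = round(config.pirna_background_fraction * usable) if tissue == "gonad" else 0
    n_degr = round(config.degradation_background_fraction * usable)
    planted_total = usable - n_pirna - n_degr

    present = [p for p in config.panel if (tissue, sex) in p.presence]
    if not present:
        raise ValueError(f"no planted types for ({tissue}, {sex})")
    log_lo, log_hi = math.log(config.rpm_low), math.log(config.rpm_high)
    weights = np.exp(rng.uniform(log_lo, log_hi, size=len(present)))
    min_count = math.ceil(config.min_rpm * usable / 1e6)
    counts = np.maximum(
        min_count, np.round(weights / weights.sum() * planted_total)
    ).astype(int)
    counts[int(np.argmax(counts))] += planted_total - int(counts.sum())

    cores = reference_truth["cores"]
    planted_truth: dict[str, dict[str, int]] = {}
    emission: list[tuple[str, int]] = []
    for ptype, n_reads in zip(present, counts):
        core = cores[ptype.name]
        n_iso = round(config.isomir_rate * int(n_reads))
        groups = {core: int(n_reads) - n_iso}
        for seq, c in _isomir_variants(rng, core, n_iso).items():
            groups[seq] = groups.get(seq, 0) + c
        groups = {s: c for s, c in groups.items() if c > 0}
        groups = _apply_mutations(rng, groups, config.mutation_rate)
        planted_truth[ptype.name] = groups
        emission.extend(groups.items())

    # degradation background: random 15-30-nt fragments from a reused pool,
    # so a minority recur at count >= 2 and reach the screen unannotated.
    # Pool members are known failing decoys: they share no seed word with
    # any reference record, so they can never satisfy the hit criteria.
    if n_degr:
        ref_words: set[str] = set()
        for records in reference_truth["species_records"].values():
            for seq in records.values():
                ref_words |= _words(seq)
        pool_size = max(1000, n_degr // 3)
        pool: list[str] = []
        while len(pool) < pool_size:
            need = pool_size - len(pool)
            lengths = rng.integers(15, 31, size=need + 64)
            for s in _random_seq_batch(rng, lengths, adapter_seed):
                if len(pool) < pool_size and not (_words(s) & ref_words):
                    pool.append(s)
        draw = rng.multinomial(n_degr, np.full(pool_size, 1.0 / pool_size))
        emission.extend((s, int(c)) for s, c in zip(pool, draw) if c > 0)

    # piRNA-like gonadal background: independent random 26-28-nt sequences
    if n_pirna:
        pir_lengths = rng.integers(26, 29, size=n_pirna)
        emission.extend((s, 1) for s in _random_seq_batch(rng, pir_lengths, adapter_seed))

    good_qual = "I" * read_len
    low_qual = "#" * read_len
    reads: list[tuple[str, str]] = []
    read_cache: dict[str, str] = {}
    for seq, count in emission:
        read = read_cache.get(seq)
        if read is None:
            read = (seq + post)[:read_len]
            read_cache[seq] = read
        reads.extend([(read, good_qual)] * count)
    # contamination
    dimer_read = post[:read_len]
    reads.extend([(dimer_read, good_qual)] * n_dimer)
    homo_read = ("A" * 30 + post)[:read_len]
    reads.extend([(homo_read, good_qual)] * n_homo)
    if n_lowq:
        lowq_lengths = rng.integers(20, 26, size=n_lowq)
        for s in _random_seq_batch(rng, lowq_lengths, adapter_seed):
            reads.append(((s + post)[:read_len], low_qual))

    order = rng.permutation(len(reads))
    lib = _lib_id(tissue, sex)
    lines: list[str] = []
    for out_i, i in enumerate(order):
        seq, qual = reads[int(i)]
        lines.append(f"@{lib}_r{out_i}")
        lines.append(seq)
        lines.append("+")
        lines.append(qual)
    fastq_text = "\n".join(lines) + "\n"
    truth = {
        "library_id": lib,
        "tissue": tissue,
        "sex": sex,
        "usable_reads": usable,
        "rejections": {
            "low_quality": n_lowq,
            "too_short": n_dimer,
            "homopolymer": n_homo,
        },
        "n_pirna_background": n_pirna,
        "n_degradation_background": n_degr,
        "planted_counts": planted_truth,
    }
    return fastq_text, truth


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple["pd.DataFrame", dict]:
    """Two-group Ct table with technical triplicates and its truth fragment."""
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    effects = config.effects()
    n = config.qpcr_n_per_group
    sigma = config.qpcr_sigma
    rows = []
    truth = {}
    for (target, tissue, sex), effect in sorted(effects.items()):
        base = float(rng.uniform(2.0, 8.0))
        truth[f"{target}|{tissue}|{sex}"] = {
            "ddct": effect,
            "expected_fold": 2.0 ** (-effect),
            "base_dct": base,
        }
        for group, shift in (("normoxia", 0.0), ("hypoxia", effect)):
            dcts = rng.normal(base + shift, sigma, size=n)
            for i, dct in enumerate(dcts):
                sample_id = f"{sex}_{tissue}_{group}_{i + 1}"
                ct_u6 = float(rng.normal(20.0, 0.5))
                ct_5s = float(rng.normal(18.0, 0.5))
                ct_target = float(dct) + (ct_u6 + ct_5s) / 2.0
                for rep in range(3):
                    jitter = rng.normal(0.0, config.qpcr_triplicate_sd, size=3)
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "target": target,
                            "ct_target": round(ct_target + jitter[0], 4),
                            "ct_u6": round(ct_u6 + jitter[1], 4),
                            "ct_5s": round(ct_5s + jitter[2], 4),
                            "group": group,
                            "tissue": tissue,
                            "sex": sex,
                            "replicate": rep + 1,
                        }
                    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# orchestration and truth assembly


def expected_enrichment(panel: Sequence[PlantedType]) -> dict[str, dict]:
    """The generator's own enrichment truth, mirroring the classifier rules."""
    truth = {}
    for p in panel:
        if p.decoy:
            continue
        tissues = {t for t, _ in p.presence}
        if p.presence == ALL6:
            category = "common-to-all"
        elif len(tissues) == 1:
            category = f"{next(iter(tissues))}-enriched"
        else:
            category = "other"
        detail = {}
        for tissue in ("brain", "liver", "gonad"):
            f = (tissue, "female") in p.presence
            m = (tissue, "male") in p.presence
            detail[tissue] = (
                "both" if f and m else "female-only" if f else
                "male-only" if m else "absent"
            )
        truth[p.name] = {"tissue_category": category, "sex_detail": detail}
    return truth


def expected_conservation(panel: Sequence[PlantedType]) -> dict[str, dict]:
    teleost = {"dre", "fru", "tni", "ola"}
    model = {"hsa", "mmu", "dre", "fru", "tni", "ola", "cel", "dme"}
    truth = {}
    for p in panel:
        if p.decoy:
            continue
        s = set(p.species)
        truth[p.name] = {
            "species_set": sorted(s),
            "teleost_specific": bool(s) and s <= teleost,
            "pan_model": model <= s,
        }
    return truth


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write reference, six libraries, samplesheet, Ct table and truth.json.

    Returns the full truth table (also serialized as truth.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta, ref_truth = simulate_reference(config)
    (outdir / "mature.fa").write_text(fasta)

    lib_truths = {}
    sheet_lines = ["library_id\ttissue\tsex\tcondition\tpath"]
    for tissue, sex in LIBRARIES:
        fastq, truth = simulate_library(config, tissue, sex, ref_truth)
        lib = truth["library_id"]
        path = outdir / f"{lib}.fastq"
        path.write_text(fastq)
        lib_truths[lib] = truth
        sheet_lines.append(f"{lib}\t{tissue}\t{sex}\tnone\t{path.name}")
    (outdir / "samplesheet.tsv").write_text("\n".join(sheet_lines) + "\n")

    ct, qpcr_truth = simulate_qpcr(config)
    ct.to_csv(outdir / "ct.tsv", sep="\t", index=False)

    truth = {
        "seed": config.seed,
        "adapter_3p": config.adapter_3p,
        "reference": ref_truth,
        "libraries": lib_truths,
        "enrichment": expected_enrichment(config.panel),
        "conservation": expected_conservation(config.panel),
        "qpcr": qpcr_truth,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return truth
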