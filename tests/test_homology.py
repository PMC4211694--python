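"""Seeded ungapped alignment, E-values, hit criteria and canonical selection."""

import math

import numpy as np
import pytest

from mirfish.homology import (
    AlignmentParams,
    HitCriteria,
    align_ungapped,
    annotate_library,
    best_hit,
    db_length,
    evalue,
    group_paralogs,
    paralog_label,
    select_canonical,
)
from mirfish.io import ReferenceMiRNA
from mirfish.preprocess import UniqueTag

PARAMS = AlignmentParams()
BASES = "ACGT"


def _ref(seq, header="dre-miR-1"):
    return ReferenceMiRNA.from_header(header, seq)


def _random_seq(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def oracle_best_score(q, r, w=7, ms=1, mm=-3):
    """Exhaustive offset scan with full rescoring of every segment that
    contains a run of >= w consecutive matches (the aligner's contract)."""
    best = None
    for off in range(-len(q) + 1, len(r)):
        lo, hi = max(0, -off), min(len(q), len(r) - off)
        if hi - lo < w:
            continue
        flags = [q[x] == r[x + off] for x in range(lo, hi)]
        n = len(flags)
        for a in range(n):
            run = score = 0
            has_word = False
            for b in range(a, n):
                if flags[b]:
                    run += 1
                    score += ms
                    if run >= w:
                        has_word = True
                else:
                    run = 0
                    score += mm
                if has_word and (best is None or score > best):
                    best = score
    return best


class TestEvalue:
    def test_zero_score_is_kmn(self):
        assert evalue(0, 10, 100, 1.374, 0.711) == pytest.approx(0.711 * 1000)

    def test_identity_22mer(self):
        e = evalue(22, 22, 22, 1.374, 0.711)
        assert e == pytest.approx(0.711 * 484 * math.exp(-30.228), rel=1e-12)
        assert e == pytest.approx(2.55e-11, rel=0.02)

    def test_monotonicity(self):
        assert evalue(10, 22, 100, 1.374, 0.711) > evalue(11, 22, 100, 1.374, 0.711)
        assert evalue(10, 22, 200, 1.374, 0.711) == pytest.approx(
            2 * evalue(10, 22, 100, 1.374, 0.711)
        )
        assert evalue(10, 44, 100, 1.374, 0.711) == pytest.approx(
            2 * evalue(10, 22, 100, 1.374, 0.711)
        )

    def test_exact_match_passes_cut_for_large_db(self):
        # any exact match of >= 15 nt clears E < 0.06 even for a 1e5-letter db
        for length in range(15, 36):
            assert evalue(length, length, 10**5, 1.374, 0.711) < 0.06


class TestAlignUngapped:
    def test_identity(self):
        seq = "TGGAGTGTGACAATGGTGTTTG"
        hit = align_ungapped(seq, _ref(seq))
        assert (hit.matches, hit.mismatches, hit.score) == (22, 0, 22)
        assert hit.offset == 0

    def test_three_scattered_mismatches(self):
        ref = "AACCGGTTACGTACGTAACCGG"  # 22 nt
        query = list(ref)
        for pos in (0, 10, 21):  # flanked by long exact stretches
            query[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[query[pos]]
        query = "".join(query)
        hit = align_ungapped(query, _ref(ref))
        assert hit.mismatches <= 3
        assert hit.score == oracle_best_score(query, ref)

    def test_no_shared_word_returns_none(self):
        assert align_ungapped("A" * 10 + "C" * 12, _ref("G" * 11 + "T" * 11)) is None

    def test_oracle_equivalence_random_pairs(self, rng):
        """Best seeded score equals exhaustive rescoring on 1,000 pairs."""
        for trial in range(1000):
            lq, lr = rng.integers(15, 36, 2)
            q = _random_seq(rng, lq)
            r = _random_seq(rng, lr)
            if trial % 2:  # half the pairs are related (mutated copies)
                chars = list((q + _random_seq(rng, lr))[:lr])
                for p in rng.choice(lr, size=int(rng.integers(0, 4)), replace=False):
                    chars[p] = BASES[(BASES.index(chars[p]) + 1) % 4]
                r = "".join(chars)
            hit = align_ungapped(q, _ref(r))
            got = hit.score if hit else None
            assert got == oracle_best_score(q, r), (q, r)


class TestBestHit:
    def test_exact_match_passes(self):
        seq = "TGGAGTGTGACAATGGTGTTTG"
        hit = best_hit(seq, [_ref(seq)])
        assert hit is not None and hit.evalue < 0.06

    def test_fourteen_matches_rejected(self):
        ref = "ACGTACGTACGTAC" + "GGGGGGGG"  # 22 nt
        query = "ACGTACGTACGTAC" + "CACACACA"  # 14 shared then divergent
        hit = align_ungapped(query, _ref(ref))
        assert hit is not None and hit.matches == 14
        assert best_hit(query, [_ref(ref)]) is None

    def test_four_scattered_mismatches_rejected(self):
        # four mismatches spread over 22 nt leave no 7-nt exact word and no
        # sub-segment with >= 15 matches under <= 3 mismatches
        ref = "AACCGGTTACGTACGTAACCGG"
        chars = list(ref)
        for pos in (3, 9, 15, 21):
            chars[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[chars[pos]]
        query = "".join(chars)
        assert best_hit(query, [_ref(ref)]) is None

    def test_evalue_cut_is_strict(self):
        # matches=15 exact: with n chosen so E == 0.06 exactly, hit must fail
        seq = "ACGTACGTACGTACG"  # 15 nt
        n_exact = 0.06 / (0.711 * 15 * math.exp(-1.374 * 15))
        hit = best_hit(seq, [_ref(seq, "dre-miR-5")], n_letters=int(n_exact) + 1)
        assert hit is None or hit.evalue < 0.06
        # just under the boundary passes
        hit2 = best_hit(seq, [_ref(seq, "dre-miR-5")], n_letters=int(n_exact * 0.9))
        assert hit2 is not None

    def test_tie_break_lexicographic(self):
        seq = "TGGAGTGTGACAATGGTGTTTG"
        refs = [_ref(seq, "dre-miR-9"), _ref(seq, "dre-miR-1")]
        hit = best_hit(seq, refs)
        assert hit.reference.header_id == "dre-miR-1"

    def test_empty_db_errors(self):
        with pytest.raises(ValueError):
            best_hit("ACGT" * 6, [])


class TestCanonicalAndParalogs:
    def _tag(self, seq, count):
        return UniqueTag(seq, count, rpm=float(count))

    def _hit(self, seq, ref_seq, header="dre-miR-1"):
        return align_ungapped(seq, _ref(ref_seq, header))

    def test_most_abundant_wins(self):
        ref = "TGGAGTGTGACAATGGTGTTTG"
        variant = "AGGAGTGTGACAATGGTGTTTG"
        groups = {
            "miR-1": [
                (self._tag(variant, 500), self._hit(variant, ref)),
                (self._tag(ref, 40), self._hit(ref, ref)),
            ]
        }
        (rec,) = select_canonical(groups)
        assert rec.canonical_tag.count == 500
        assert len(rec.supporting_variants) == 2

    def test_score_breaks_count_ties(self):
        ref = "TGGAGTGTGACAATGGTGTTTG"
        variant = "AGGAGTGTGACAATGGTGTTAG"
        groups = {
            "miR-1": [
                (self._tag(variant, 100), self._hit(variant, ref)),
                (self._tag(ref, 100), self._hit(ref, ref)),
            ]
        }
        (rec,) = select_canonical(groups)
        assert rec.canonical_tag.sequence == ref

    def test_singleton_is_its_own_canonical(self):
        ref = "TGGAGTGTGACAATGGTGTTTG"
        (rec,) = select_canonical({"miR-1": [(self._tag(ref, 5), self._hit(ref, ref))]})
        assert rec.canonical_tag.sequence == ref
        assert rec.supporting_variants == [rec.canonical_tag]

    def test_permutation_invariance(self):
        ref = "TGGAGTGTGACAATGGTGTTTG"
        pairs = [
            (self._tag("A" + ref[1:], 10), self._hit("A" + ref[1:], ref)),
            (self._tag(ref, 10), self._hit(ref, ref)),
            (self._tag(ref[:-1] + "A", 7), self._hit(ref[:-1] + "A", ref)),
        ]
        a = select_canonical({"miR-1": pairs})
        b = select_canonical({"miR-1": pairs[::-1]})
        assert a[0].canonical_tag == b[0].canonical_tag
        assert [t.sequence for t in a[0].supporting_variants] == [
            t.sequence for t in b[0].supporting_variants
        ]

    @pytest.mark.parametrize(
        "name,label",
        [
            ("miR-138-1-3p", "miR-138-3p"),
            ("miR-138-2-3p", "miR-138-3p"),
            ("miR-122", "miR-122"),
            ("miR-122-3p", "miR-122-3p"),
            ("let-7a", "let-7"),
        ],
    )
    def test_paralog_labels(self, name, label):
        assert paralog_label(name) == label

    def test_group_paralogs_equivalence(self):
        ref = "TGGAGTGTGACAATGGTGTTTG"
        groups = {
            name: [(self._tag(ref, 5), self._hit(ref, ref, f"dre-{name}"))]
            for name in ("miR-138-1-3p", "miR-138-2-3p", "miR-122")
        }
        records = group_paralogs(select_canonical(groups))
        labels = {r.mirna_type: r.paralog_group for r in records}
        assert labels["miR-138-1-3p"] == labels["miR-138-2-3p"]
        assert labels["miR-122"] != labels["miR-138-1-3p"]


class TestAnnotateLibrary:
    def test_exact_copies_of_references(self, rng):
        refs = []
        tags = []
        seqs = set()
        while len(refs) < 5:
            seq = _random_seq(rng, 22)
            if any(seq[i : i + 7] in s for s in seqs for i in range(16)):
                continue
            seqs.add(seq)
            refs.append(_ref(seq, f"dre-miR-{100 + len(refs)}"))
            tags.append(UniqueTag(seq, count=50, rpm=50.0))
        records, stats = annotate_library(tags, refs)
        assert stats.annotated_canonical == 5 and stats.annotated_types == 5
        assert {r.canonical_tag.sequence for r in records} == seqs

    def test_no_signal_control(self, rng):
        refs = [_ref("ACGT" * 5 + "AC", "dre-miR-1")]
        tags = [UniqueTag("GT" + "TGCA" * 5, count=50, rpm=50.0)]
        records, stats = annotate_library(tags, refs)
        assert records == [] and stats.annotated_canonical == 0

    def test_planted_recovery_with_isomirs(self, small_sim):
        """Noiseless synthetic libraries: 100% type recall, no false types."""
        import pandas as pd

        truth = small_sim["truth"]
        for lib, lib_truth in truth["libraries"].items():
            ann = pd.read_csv(small_sim["outdir"] / f"{lib}_annotations.tsv", sep="\t")
            planted = set(lib_truth["planted_counts"])
            found = set(ann["mirna_type"])
            assert found == planted
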