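"""Enrichment classification, Venn accounting and conservation profiles."""

import numpy as np
import pandas as pd
import pytest

from mirfish.datasets import medaka_library_metas
from mirfish.profiling import (
    classify_sex_enrichment,
    classify_tissue_enrichment,
    conservation_from_species_sets,
    enrichment_accounting,
    format_percent,
    venn_counts,
)

METAS = medaka_library_metas()
LIBS = [m.library_id for m in METAS]


def _matrix(presence: dict[str, list[str]]) -> pd.DataFrame:
    mat = pd.DataFrame(0.0, index=sorted(presence), columns=LIBS)
    for t, libs in presence.items():
        for lib in libs:
            mat.loc[t, lib] = 10.0
    mat.index.name = "mirna_type"
    return mat


class TestTissueEnrichment:
    def test_categories(self):
        mat = _matrix(
            {
                "miR-a": ["female_brain", "male_brain"],
                "miR-b": LIBS,
                "miR-c": ["female_brain", "female_liver"],
                "miR-d": ["male_gonad"],
                "miR-e": ["female_liver", "male_liver"],
            }
        )
        calls, counts = classify_tissue_enrichment(mat, METAS)
        by_type = {c.mirna_type: c.tissue_category for c in calls}
        assert by_type == {
            "miR-a": "brain-enriched",
            "miR-b": "common-to-all",
            "miR-c": "other",
            "miR-d": "gonad-enriched",
            "miR-e": "liver-enriched",
        }
        assert counts["brain-enriched"] == 1 and counts["other"] == 1

    def test_all_tissues_but_not_all_libraries_is_other(self):
        mat = _matrix({"miR-a": [l for l in LIBS if l != "male_gonad"]})
        calls, _ = classify_tissue_enrichment(mat, METAS)
        assert calls[0].tissue_category == "other"

    def test_partition_property(self, rng):
        presence = {
            f"miR-{i}": [l for l in LIBS if rng.random() < 0.5] or [LIBS[0]]
            for i in range(80)
        }
        mat = _matrix(presence)
        calls, counts = classify_tissue_enrichment(mat, METAS)
        assert len(calls) == len(mat)
        assert sum(counts.values()) == len(mat)


class TestSexEnrichment:
    def test_partitions(self):
        mat = _matrix(
            {
                "miR-a": ["female_brain", "male_brain"],  # both
                "miR-b": ["female_brain"],  # female-only brain
                "miR-c": ["male_liver"],  # male-only liver
                "miR-d": ["female_gonad"],  # ovary only
            }
        )
        calls, _ = classify_tissue_enrichment(mat, METAS)
        parts = classify_sex_enrichment(calls, mat, METAS)
        assert parts["brain"] == {"female-only": 1, "male-only": 0, "both": 1}
        assert parts["liver"] == {"female-only": 0, "male-only": 1, "both": 0}
        assert parts["gonad"] == {"female-only": 1, "male-only": 0, "both": 0}

    def test_partition_sizes_sum_to_class_size(self, rng):
        presence = {
            f"miR-{i}": [l for l in LIBS if rng.random() < 0.4] or [LIBS[0]]
            for i in range(60)
        }
        mat = _matrix(presence)
        calls, counts = classify_tissue_enrichment(mat, METAS)
        parts = classify_sex_enrichment(calls, mat, METAS)
        for tissue in ("brain", "liver", "gonad"):
            assert sum(parts[tissue].values()) == counts[f"{tissue}-enriched"]


class TestVenn:
    def test_disjoint(self):
        out = venn_counts({"b": {"x"}, "l": {"y"}, "g": {"z"}})
        assert out["all_three"] == 0 and out["union"] == 3
        assert out["b_l"] == out["b_g"] == out["l_g"] == 0

    def test_identical(self):
        s = {"x", "y"}
        out = venn_counts({"b": set(s), "l": set(s), "g": set(s)})
        assert out["all_three"] == 2 and out["b_only"] == 0

    def test_brute_force_and_inclusion_exclusion(self, rng):
        universe = [f"m{i}" for i in range(100)]
        for _ in range(25):
            a, b, c = (
                {u for u in universe if rng.random() < p}
                for p in rng.uniform(0.1, 0.6, 3)
            )
            out = venn_counts({"A": a, "B": b, "C": c})
            # brute-force region membership
            regions = {k: 0 for k in out}
            for u in universe:
                ia, ib, ic = u in a, u in b, u in c
                if ia or ib or ic:
                    regions["union"] += 1
                key = {
                    (True, False, False): "A_only",
                    (False, True, False): "B_only",
                    (False, False, True): "C_only",
                    (True, True, False): "A_B",
                    (True, False, True): "A_C",
                    (False, True, True): "B_C",
                    (True, True, True): "all_three",
                }.get((ia, ib, ic))
                if key:
                    regions[key] += 1
            assert out == regions
            # inclusion-exclusion identity, exact
            assert len(a | b | c) == (
                len(a) + len(b) + len(c)
                - len(a & b) - len(a & c) - len(b & c)
                + len(a & b & c)
            ) == out["union"]

    def test_wrong_arity(self):
        with pytest.raises(ValueError):
            venn_counts({"a": set(), "b": set()})


class TestConservation:
    def test_flags(self):
        profiles, summary = conservation_from_species_sets(
            {
                "miR-2184": {"dre"},
                "miR-10d": {"dre", "fru", "tni", "ola"},
                "miR-124": {"hsa", "mmu", "dre"},
                "let-7a": {"hsa", "mmu", "dre", "fru", "tni", "ola", "cel", "dme"},
            }
        )
        flags = {p.mirna_type: p.teleost_specific for p in profiles}
        assert flags == {
            "miR-2184": True,
            "miR-10d": True,
            "miR-124": False,
            "let-7a": False,
        }
        pan = {p.mirna_type: p.pan_model for p in profiles}
        assert pan["let-7a"] and not pan["miR-124"]
        assert summary["teleost_specific"] == 2 and summary["pan_model"] == 1

    def test_empty_set_is_not_teleost_specific(self):
        profiles, _ = conservation_from_species_sets({"miR-x": set()})
        assert not profiles[0].teleost_specific


class TestAccounting:
    @pytest.mark.parametrize(
        "count,total,expected",
        [
            (55, 223, "24.7"),
            (106, 223, "47.5"),
            (89, 223, "39.9"),
            (8, 223, "3.6"),
            (9, 223, "4"),
            (0, 10, "0"),
        ],
    )
    def test_printed_precision(self, count, total, expected):
        assert format_percent(count, total) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            format_percent(5, 0)
        with pytest.raises(ValueError):
            format_percent(11, 10)

    def test_accounting_table(self):
        df = enrichment_accounting({"common-to-all": 55, "other": 62}, 223)
        row = df.set_index("category").loc["common-to-all"]
        assert row["percent_str"] == "24.7" and row["percent"] == 24.7
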