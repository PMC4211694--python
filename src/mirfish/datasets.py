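"""Bundled worked-example data: published marine-medaka miRNA tables.

Two small tables ship with the package: the tissue/sex-enrichment
assignments reported for *Oryzias melastigma* miRNAs (which tissues, and
which sex within a tissue, each annotated type was restricted to), and the
fish-enriched miRNA list with mature sequences and the teleost species each
is conserved in.  A toy mature-miRNA reference FASTA built from those
printed sequences supports format tests.  Loaders reconstruct pipeline-ready
objects so the set-accounting and conservation machinery can be exercised on
published inputs without any sequencing data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import LibraryMeta

__all__ = [
    "load_tissue_enrichment_table",
    "load_fish_enriched_table",
    "toy_reference_path",
    "presence_matrix_from_enrichment_table",
    "medaka_library_metas",
]

_CATEGORY_PRESENCE = {
    "brain_shared": (("brain", "female"), ("brain", "male")),
    "brain_female_only": (("brain", "female"),),
    "brain_male_only": (("brain", "male"),),
    "liver_shared": (("liver", "female"), ("liver", "male")),
    "liver_female_only": (("liver", "female"),),
    "liver_male_only": (("liver", "male"),),
    "gonad_shared": (("gonad", "female"), ("gonad", "male")),
    "ovary_only": (("gonad", "female"),),
    "testis_only": (("gonad", "male"),),
}


def _data_path(name: str):
    return resources.files("mirfish.data").joinpath(name)


def load_tissue_enrichment_table() -> pd.DataFrame:
    """Published tissue/sex-enrichment assignments (category, mirna_type)."""
    with resources.as_file(_data_path("medaka_tissue_enrichment.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_fish_enriched_table() -> pd.DataFrame:
    """Published fish-enriched miRNAs: mirna_type, sequence, species (CSV)."""
    with resources.as_file(_data_path("medaka_fish_enriched.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def toy_reference_path():
    """Context manager yielding a filesystem path to the toy reference FASTA."""
    return resources.as_file(_data_path("toy_mature.fa"))


def medaka_library_metas() -> list[LibraryMeta]:
    """The six-library tissue/sex design as LibraryMeta objects."""
    return [
        LibraryMeta(library_id=f"{sex}_{tissue}", tissue=tissue, sex=sex)
        for tissue in ("brain", "liver", "gonad")
        for sex in ("female", "male")
    ]


def presence_matrix_from_enrichment_table(
    table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Expand the published enrichment table into a 0/1 RPM-like matrix.

    Each listed type is marked present (value 1.0) exactly in the libraries
    its category names, producing input suitable for the enrichment
    classifiers; library columns follow :func:`medaka_library_metas`.
    """
    if table is None:
        table = load_tissue_enrichment_table()
    metas = medaka_library_metas()
    cols = [m.library_id for m in metas]
    mat = pd.DataFrame(
        0.0, index=sorted(table["mirna_type"].unique()), columns=cols
    )
    for row in table.itertuples(index=False):
        for tissue, sex in _CATEGORY_PRESENCE[row.category]:
            mat.loc[row.mirna_type, f"{sex}_{tissue}"] = 1.0
    mat.index.name = "mirna_type"
    return mat
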