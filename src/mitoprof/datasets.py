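"""Loaders for the packaged reference tables.

Three published tables of the Putoidae reference mitogenome ship with
the package: the 37-row gene table (coordinates, anticodons, start/stop
codons and the printed intergenic column), the 17-partition nucleotide
composition table, and the protein-coding codon-usage counts. They are
small TSV transcriptions used as ground truth by the test-suite and by
the worked examples.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .annotation_io import MitoAnnotation, read_feature_table
from .codon_usage import DEFAULT_CODE, CodonCountTable

REFERENCE_GENOME_LENGTH = 18_830


def _data_path(name: str):
    return resources.files("mitoprof.data").joinpath(name)


def load_reference_annotation() -> MitoAnnotation:
    """The 37-feature Putoidae gene table on its 18,830 bp circular genome."""
    with resources.as_file(_data_path("putoidae_features.tsv")) as p:
        return read_feature_table(p, genome_length=REFERENCE_GENOME_LENGTH)


def load_reference_feature_frame() -> pd.DataFrame:
    """The raw transcription, including the printed length/intergenic columns."""
    with resources.as_file(_data_path("putoidae_features.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_reference_composition() -> pd.DataFrame:
    """Published composition percentages and skews, one row per partition."""
    with resources.as_file(_data_path("putoidae_composition.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#").set_index("partition")


def load_reference_codon_frame() -> pd.DataFrame:
    """Published codon counts with printed RSCU (RNA codon spelling)."""
    with resources.as_file(_data_path("putoidae_codon_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_reference_codon_counts() -> CodonCountTable:
    df = load_reference_codon_frame()
    return CodonCountTable(dict(zip(df["codon"], df["count"])), DEFAULT_CODE)
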