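"""Bundled reference tables for the *Melarhaphe neritoides* mitogenome.

The package ships the published MH119311 gene annotation (coordinates,
strands, start/stop codons) and the published per-region base composition.
The genome *sequence* itself is not bundled; the coordinate-only record uses
an all-``N`` placeholder sequence, which supports every geometry and
codon-annotation computation but not sequence-derived statistics.
"""

from __future__ import annotations

import importlib.resources as resources

import pandas as pd

from .genome import FeatureKind, GeneFeature, GenomeRecord

MH119311_LENGTH = 15_676

__all__ = [
    "MH119311_LENGTH",
    "load_reference_features",
    "load_reference_record",
    "load_reference_composition",
]


def _data_path(name: str):
    return resources.files("mitoarch.data").joinpath(name)


def load_reference_features() -> pd.DataFrame:
    """The published MH119311 feature table as a DataFrame."""
    with resources.as_file(_data_path("mh119311_features.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_reference_record() -> GenomeRecord:
    """The MH119311 annotation as a coordinate-only :class:`GenomeRecord`.

    The sequence slot is filled with ``N`` (the deposited sequence is not
    redistributed); gene geometry, start/stop-codon tallies and gene order
    are fully determined by the annotation alone.
    """
    df = load_reference_features()
    features = []
    for row in df.itertuples(index=False):
        features.append(
            GeneFeature(
                name=row.gene,
                kind=FeatureKind(row.kind),
                strand=row.strand,
                start=int(row.start),
                end=int(row.end),
                start_codon=None if pd.isna(row.start_codon) else row.start_codon,
                stop_codon=None if pd.isna(row.stop_codon) else row.stop_codon,
            )
        )
    return GenomeRecord(
        id="MH119311",
        sequence="N" * MH119311_LENGTH,
        circular=True,
        features=features,
    )


def load_reference_composition() -> pd.DataFrame:
    """Published per-region base percentages (A/C/G/T, 1 decimal)."""
    with resources.as_file(_data_path("mh119311_composition.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")
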