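"""Readers and writers for GenBank, FASTA and newick files.

All parsing is delegated to Biopython / dendropy; this module only maps
between those libraries' objects and the :mod:`mitoarch.genome` data model.
"""

from __future__ import annotations

import os
from typing import IO

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .genome import FeatureKind, GeneFeature, GenomeRecord, extract_gene_sequence

__all__ = [
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "read_newick",
]

_KIND_TO_GB = {
    FeatureKind.PCG: "CDS",
    FeatureKind.TRNA: "tRNA",
    FeatureKind.RRNA: "rRNA",
    FeatureKind.CONTROL_REGION: "misc_feature",
}
_GB_TO_KIND = {
    "CDS": FeatureKind.PCG,
    "tRNA": FeatureKind.TRNA,
    "rRNA": FeatureKind.RRNA,
    "misc_feature": FeatureKind.CONTROL_REGION,
    "D-loop": FeatureKind.CONTROL_REGION,
}


class GenBankFormatError(ValueError):
    pass


def _feature_name(sf: SeqFeature) -> str:
    for key in ("gene", "product", "note"):
        if key in sf.qualifiers:
            return str(sf.qualifiers[key][0])
    return sf.type


def _location_to_coords(sf: SeqFeature, genome_length: int) -> tuple[int, int]:
    """1-based inclusive (start, end); a two-part join across the origin is
    collapsed to end < start."""
    loc = sf.location
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if len(parts) == 2 and int(parts[-1].end) == genome_length and int(parts[0].start) == 0:
            return int(parts[1].start) + 1, int(parts[0].end)
        raise GenBankFormatError(f"unsupported compound location {loc}")
    return int(loc.start) + 1, int(loc.end)


def _derive_codons(record: GenomeRecord, feat: GeneFeature) -> GeneFeature:
    """Fill start/stop codons of a PCG from its sequence when unannotated."""
    from dataclasses import replace

    cds = extract_gene_sequence(record, feat)
    start_codon = feat.start_codon or cds[:3]
    stop_codon = feat.stop_codon
    if stop_codon is None:
        r = len(cds) % 3
        if r == 0:
            stop_codon = cds[-3:]
        else:
            stop_codon = cds[-r:] + "-" * (3 - r)
    return replace(feat, start_codon=start_codon, stop_codon=stop_codon)


def read_genbank(path: str | os.PathLike | IO[str]) -> GenomeRecord:
    """Parse a GenBank flat file into a :class:`GenomeRecord`.

    One :class:`GeneFeature` is created per CDS / tRNA / rRNA /
    misc_feature (control region); ``gene``-type features duplicating a CDS
    are ignored.  Coordinates stay 1-based inclusive.
    """
    try:
        seqrec = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise GenBankFormatError(str(exc)) from exc
    sequence = str(seqrec.seq)
    if not sequence or set(sequence.upper()) <= {"N"} and len(sequence) == 0:
        raise GenBankFormatError(f"record {seqrec.id} has no sequence")
    circular = seqrec.annotations.get("topology", "circular") == "circular"
    features: list[GeneFeature] = []
    for sf in seqrec.features:
        kind = _GB_TO_KIND.get(sf.type)
        if kind is None:
            continue
        start, end = _location_to_coords(sf, len(sequence))
        if end > len(sequence) or start > len(sequence):
            raise GenBankFormatError(
                f"feature {_feature_name(sf)} at {start}..{end} exceeds "
                f"sequence length {len(sequence)}"
            )
        quality = None
        if "quality" in sf.qualifiers:
            quality = float(sf.qualifiers["quality"][0])
        feat = GeneFeature(
            name=_feature_name(sf),
            kind=kind,
            strand="-" if sf.location.strand == -1 else "+",
            start=start,
            end=end,
            start_codon=(
                str(sf.qualifiers["start_codon"][0])
                if "start_codon" in sf.qualifiers
                else None
            ),
            stop_codon=(
                str(sf.qualifiers["stop_codon"][0])
                if "stop_codon" in sf.qualifiers
                else None
            ),
            quality=quality,
        )
        features.append(feat)
    record = GenomeRecord(
        id=seqrec.id or seqrec.name, sequence=sequence, circular=circular,
        features=features,
    )
    record.features = [
        _derive_codons(record, f) if f.kind == FeatureKind.PCG else f
        for f in record.features
    ]
    return record


def write_genbank(record: GenomeRecord, path: str | os.PathLike | IO[str]) -> None:
    """Write a :class:`GenomeRecord` as a GenBank flat file.

    Start/stop codons and quality scores are stored as qualifiers so that
    ``read_genbank(write_genbank(r))`` reproduces ``r`` field by field.
    """
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id[:16].replace(" ", "_"),
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
        },
    )
    n = len(record.sequence)
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        if f.spans_origin():
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start - 1, n, strand),
                    SimpleLocation(0, f.end, strand),
                ]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        qualifiers: dict[str, list[str]] = {"gene": [f.name]}
        if f.start_codon:
            qualifiers["start_codon"] = [f.start_codon]
        if f.stop_codon:
            qualifiers["stop_codon"] = [f.stop_codon]
        if f.quality is not None:
            qualifiers["quality"] = [repr(f.quality)]
        seqrec.features.append(
            SeqFeature(loc, type=_KIND_TO_GB[f.kind], qualifiers=qualifiers)
        )
    SeqIO.write([seqrec], path, "genbank")


def read_fasta(path: str | os.PathLike | IO[str]) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence map.

    Duplicate headers are an error.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA header {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | os.PathLike | IO[str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def read_newick(path: str | os.PathLike | IO[str], *, rooted: bool = True) -> dendropy.Tree:
    """Read a newick tree with branch lengths.

    Negative branch lengths and duplicate leaf labels are rejected; unnamed
    internal nodes are accepted.
    """
    if hasattr(path, "read"):
        tree = dendropy.Tree.get(data=path.read(), schema="newick")
    else:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = rooted
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    return tree
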