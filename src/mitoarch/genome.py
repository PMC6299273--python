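"""Data model for annotated circular mitogenomes.

Coordinates on :class:`GeneFeature` are 1-based inclusive, the convention of
GenBank flat files and published gene tables.  ``end < start`` is permitted
only for features spanning the origin of a circular genome.  All internal
arithmetic converts to 0-based half-open offsets on the circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator

from Bio.Data import CodonTable

__all__ = [
    "FeatureKind",
    "GeneFeature",
    "GenomeRecord",
    "GeneticCode",
    "INVERTEBRATE_MITO",
    "extract_gene_sequence",
    "translate",
    "reverse_complement",
]


class FeatureKind(str, Enum):
    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CONTROL_REGION = "control_region"


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """A single annotated gene (or the control region) on a mitogenome.

    Parameters
    ----------
    name
        Gene symbol, e.g. ``cox1``, ``trnM(cat)``, ``rrnS``, ``CR``.
    kind
        One of PCG / tRNA / rRNA / control_region.
    strand
        ``+`` or ``-``.
    start, end
        1-based inclusive coordinates.  ``end < start`` marks an
        origin-spanning feature on a circular genome.
    start_codon, stop_codon
        Annotated codons for PCGs.  Abbreviated stops are written ``TA-``
        or ``T--`` (completed to TAA by polyadenylation of the transcript).
    quality
        Optional non-negative annotation-confidence score (e.g. from an
        automated annotator), used to resolve duplicated gene calls.
    """

    name: str
    kind: FeatureKind
    strand: str
    start: int
    end: int
    start_codon: str | None = None
    stop_codon: str | None = None
    quality: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"{self.name}: coordinates must be >= 1")
        if self.quality is not None and self.quality < 0:
            raise ValueError(f"{self.name}: quality must be non-negative")

    def spans_origin(self) -> bool:
        return self.end < self.start

    def length(self, genome_length: int | None = None) -> int:
        """Nucleotide length on the (possibly circular) genome."""
        if not self.spans_origin():
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError(
                f"{self.name}: origin-spanning feature needs genome length"
            )
        return genome_length - self.start + 1 + self.end

    def has_abbreviated_stop(self) -> bool:
        return self.stop_codon is not None and "-" in self.stop_codon


@dataclass
class GenomeRecord:
    """An annotated (usually circular) mitogenome.

    ``features`` are kept sorted ascending by start coordinate; no two
    features may share the same ``(name, start)`` pair.
    """

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
        self.sequence = self.sequence.upper()
        self._normalize_features()

    def _normalize_features(self) -> None:
        self.features.sort(key=lambda f: (f.start, f.end, f.name))
        seen: set[tuple[str, int]] = set()
        n = len(self.sequence)
        for f in self.features:
            if f.start > n or f.end > n:
                raise ValueError(
                    f"feature {f.name} at {f.start}..{f.end} outside sequence "
                    f"of length {n}"
                )
            key = (f.name, f.start)
            if key in seen:
                raise ValueError(f"duplicate feature key {key}")
            seen.add(key)
            if f.spans_origin() and not self.circular:
                raise ValueError(
                    f"origin-spanning feature {f.name} on non-circular record"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def iter_features(self, kind: FeatureKind | None = None) -> Iterator[GeneFeature]:
        for f in self.features:
            if kind is None or f.kind == kind:
                yield f

    def pcgs(self) -> list[GeneFeature]:
        return list(self.iter_features(FeatureKind.PCG))

    def get_feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r} in record {self.id}")

    def replace_feature(self, old: GeneFeature, new: GeneFeature) -> None:
        idx = self.features.index(old)
        self.features[idx] = new
        self._normalize_features()

    def copy(self) -> "GenomeRecord":
        return GenomeRecord(
            id=self.id,
            sequence=self.sequence,
            circular=self.circular,
            features=[replace(f) for f in self.features],
        )


class GeneticCode:
    """A translation table (default NCBI table 5, invertebrate mitochondrial).

    Wraps the NCBI codon table of the given id and exposes the codon ->
    amino-acid map, the start- and stop-codon sets, and the 62 (for table 5)
    sense codons.
    """

    def __init__(self, table_id: int = 5):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.stop_codons = frozenset(table.stop_codons)
        self.start_codons = frozenset(table.start_codons)
        self.codon_to_aa: dict[str, str] = dict(table.forward_table)
        self.sense_codons: tuple[str, ...] = tuple(sorted(self.codon_to_aa))
        if len(self.codon_to_aa) + len(self.stop_codons) != 64:
            raise ValueError(f"table {table_id}: codon map does not cover 64 codons")

    def amino_acid(self, codon: str) -> str:
        """One-letter amino acid for a sense codon, ``*`` for a stop."""
        codon = codon.upper().replace("U", "T")
        if codon in self.stop_codons:
            return "*"
        if "N" in codon:
            return "X"
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return codon.upper().replace("U", "T") in self.stop_codons

    def is_synonymous(self, a: str, b: str) -> bool:
        return self.amino_acid(a) == self.amino_acid(b)


INVERTEBRATE_MITO = GeneticCode(5)


def extract_gene_sequence(record: GenomeRecord, feature: GeneFeature) -> str:
    """Coding-strand nucleotide sequence of a feature.

    Plus-strand features return the genomic substring ``start..end``;
    minus-strand features its reverse complement.  Origin-spanning features
    concatenate the tail and head of the circular sequence.
    """
    if feature.spans_origin() and not record.circular:
        raise ValueError(
            f"{feature.name} spans the origin but record {record.id} is linear"
        )
    seq = record.sequence
    if feature.spans_origin():
        raw = seq[feature.start - 1 :] + seq[: feature.end]
    else:
        raw = seq[feature.start - 1 : feature.end]
    return reverse_complement(raw) if feature.strand == "-" else raw


class InternalStopError(ValueError):
    """A CDS contains an in-frame stop codon before its terminus."""

    def __init__(self, offset: int, codon: str):
        self.offset = offset
        self.codon = codon
        super().__init__(
            f"internal stop codon {codon} at nucleotide offset {offset}"
        )


def complete_abbreviated_stop(cds: str) -> str:
    """Pad a CDS whose final codon is abbreviated (TA- / T--) with adenines.

    Mirrors polyadenylation of the mature transcript: a trailing partial
    codon of 1 or 2 nucleotides is completed to length 3 with ``A``.
    """
    r = len(cds) % 3
    if r == 0:
        return cds
    return cds + "A" * (3 - r)


def translate(
    cds: str,
    code: GeneticCode = INVERTEBRATE_MITO,
    *,
    complete_stop: bool = True,
) -> str:
    """Translate an in-frame CDS; the terminal stop (full or completed) is
    dropped.  Codons containing ``N`` translate to ``X``.

    Raises
    ------
    InternalStopError
        if a stop codon occurs before the final codon.
    ValueError
        if the length is not a codon multiple and ``complete_stop`` is off.
    """
    cds = cds.upper().replace("U", "T")
    if complete_stop:
        cds = complete_abbreviated_stop(cds)
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    n_codons = len(cds) // 3
    residues: list[str] = []
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if code.is_stop(codon):
            if i != n_codons - 1:
                raise InternalStopError(3 * i, codon)
            break  # terminal stop dropped
        residues.append(code.amino_acid(codon))
    return "".join(residues)


def codons_of(cds: str) -> list[str]:
    """Split an in-frame CDS into its codons (any trailing 1-2 nt dropped)."""
    cds = cds.upper().replace("U", "T")
    return [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
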