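"""Genome records, FASTA/GenBank I/O and elementary sequence transforms.

Internal coordinates are 0-based half-open throughout; user-facing report
layers convert to 1-based inclusive (GenBank convention). Non-ACGT letters
are retained as ``N`` and every downstream window containing an ``N`` is
skipped, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Literal, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq, UndefinedSequenceError
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlphabetError",
    "CoordinateError",
    "GenomeParseError",
    "CdsFeature",
    "GenomeRecord",
    "read_fasta",
    "read_genbank",
    "write_genbank",
    "write_fasta",
    "reverse_complement",
    "gc_content",
    "linearize_provirus",
]

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
#: letters accepted on input and mapped to N (IUPAC ambiguity codes)
_AMBIGUOUS = frozenset("RYSWKMBDHVU")

Topology = Literal["linear", "circular"]


class AlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T, N}."""


class CoordinateError(ValueError):
    """An interval or offset falls outside the sequence it refers to."""


class GenomeParseError(ValueError):
    """A FASTA/GenBank file could not be parsed into a valid record."""


def _clean_sequence(raw: str, *, context: str = "") -> str:
    """Uppercase ``raw`` and map IUPAC ambiguity codes to N.

    Raises :class:`AlphabetError` for characters that are not nucleotide
    codes at all (digits, punctuation, ...).
    """
    seq = raw.upper()
    if set(seq) <= DNA_ALPHABET:
        return seq
    out = []
    for i, ch in enumerate(seq):
        if ch in DNA_ALPHABET:
            out.append(ch)
        elif ch in _AMBIGUOUS:
            out.append("N")
        else:
            where = f" in {context}" if context else ""
            raise AlphabetError(f"invalid sequence character {ch!r} at position {i}{where}")
    return "".join(out)


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature in internal (0-based, half-open) coordinates."""

    locus_tag: str
    start: int
    end: int
    strand: Literal["+", "-"]
    product: str = ""
    translation: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"CDS {self.locus_tag}: start must satisfy 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"CDS {self.locus_tag}: strand must be '+' or '-'")
        if self.translation:
            expected = (self.end - self.start) // 3 - 1  # stop codon excluded
            if abs(len(self.translation) - expected) > 1:
                raise ValueError(
                    f"CDS {self.locus_tag}: translation length {len(self.translation)} "
                    f"inconsistent with span {self.end - self.start} nt"
                )

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    def coding_sequence(self, genome_sequence: str) -> str:
        """Coding-strand nucleotide sequence of this feature."""
        segment = genome_sequence[self.start : self.end]
        return segment if self.strand == "+" else reverse_complement(segment)


@dataclass
class GenomeRecord:
    """A genome sequence with topology and optional CDS annotations."""

    id: str
    sequence: str
    description: str = ""
    topology: Topology = "linear"
    features: List[CdsFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = _clean_sequence(self.sequence, context=self.id)
        if not self.sequence:
            raise ValueError(f"record {self.id}: empty sequence")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"record {self.id}: topology must be linear or circular")
        n = len(self.sequence)
        for feat in self.features:
            if feat.end > n:
                raise CoordinateError(
                    f"record {self.id}: CDS {feat.locus_tag} end {feat.end} "
                    f"exceeds sequence length {n}"
                )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def feature_by_tag(self, locus_tag: str) -> CdsFeature:
        for feat in self.features:
            if feat.locus_tag == locus_tag:
                return feat
        raise KeyError(locus_tag)


def reverse_complement(sequence: str) -> str:
    """Reverse complement over {A, C, G, T, N}; N maps to N."""
    if not set(sequence) <= DNA_ALPHABET:
        bad = sorted(set(sequence) - DNA_ALPHABET)
        raise AlphabetError(f"cannot reverse-complement characters {bad}")
    return sequence.translate(_COMPLEMENT)[::-1]


def gc_content(record_or_sequence: Union[GenomeRecord, str]) -> float:
    """G+C fraction over the non-N positions of a sequence.

    Raises ``ValueError`` for an all-N sequence, for which the quantity
    is undefined.
    """
    seq = getattr(record_or_sequence, "sequence", record_or_sequence)
    if not seq:
        raise ValueError("gc_content of an empty sequence is undefined")
    n_informative = len(seq) - seq.count("N")
    if n_informative == 0:
        raise ValueError("gc_content undefined: sequence is all N")
    return (seq.count("G") + seq.count("C")) / n_informative


def read_fasta(path: Union[str, Path]) -> List[GenomeRecord]:
    """Read a (multi-)FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased; topology defaults to linear. An empty file
    yields an empty list.
    """
    path = Path(path)
    records: List[GenomeRecord] = []
    with path.open() as handle:
        for seqrec in SeqIO.parse(handle, "fasta"):
            if len(seqrec.seq) == 0:
                raise GenomeParseError(f"{path}: entry {seqrec.id!r} has no sequence")
            records.append(
                GenomeRecord(
                    id=seqrec.id,
                    description=seqrec.description,
                    sequence=str(seqrec.seq),
                )
            )
    return records


def _feature_from_seqfeature(feat: SeqFeature, index: int, seq_len: int, path: Path) -> CdsFeature:
    start = int(feat.location.start)
    end = int(feat.location.end)
    if end > seq_len:
        raise GenomeParseError(
            f"{path}: CDS feature at {start}..{end} extends past sequence end ({seq_len})"
        )
    strand = "-" if feat.location.strand == -1 else "+"
    quals = feat.qualifiers
    locus_tag = quals.get("locus_tag", [f"CDS_{index:04d}"])[0]
    product = quals.get("product", [""])[0]
    translation = quals.get("translation", [""])[0]
    return CdsFeature(
        locus_tag=locus_tag,
        start=start,
        end=end,
        strand=strand,
        product=product,
        translation=translation,
    )


def read_genbank(path: Union[str, Path]) -> List[GenomeRecord]:
    """Read a GenBank flat file; CDS features are captured with locus_tag,
    0-based half-open coordinates, strand, product and /translation."""
    path = Path(path)
    records: List[GenomeRecord] = []
    with path.open() as handle:
        for seqrec in SeqIO.parse(handle, "genbank"):
            try:
                seq = str(seqrec.seq)
            except UndefinedSequenceError as exc:
                raise GenomeParseError(
                    f"{path}: record {seqrec.id!r} has no ORIGIN sequence"
                ) from exc
            if not seq:
                raise GenomeParseError(f"{path}: record {seqrec.id!r} has no ORIGIN sequence")
            topology = seqrec.annotations.get("topology", "linear")
            if topology not in ("linear", "circular"):
                topology = "linear"
            features = [
                _feature_from_seqfeature(f, i, len(seq), path)
                for i, f in enumerate(seqrec.features)
                if f.type == "CDS"
            ]
            records.append(
                GenomeRecord(
                    id=seqrec.id,
                    description=seqrec.description,
                    sequence=seq,
                    topology=topology,  # type: ignore[arg-type]
                    features=features,
                )
            )
    return records


def _to_seqrecord(record: GenomeRecord) -> SeqRecord:
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id[:16].replace(" ", "_") or "genome",
        description=record.description,
        annotations={"molecule_type": "DNA", "topology": record.topology},
    )
    for feat in record.features:
        quals = {"locus_tag": [feat.locus_tag]}
        if feat.product:
            quals["product"] = [feat.product]
        if feat.translation:
            quals["translation"] = [feat.translation]
        seqrec.features.append(
            SeqFeature(
                FeatureLocation(feat.start, feat.end, strand=1 if feat.strand == "+" else -1),
                type="CDS",
                qualifiers=quals,
            )
        )
    return seqrec


def write_genbank(record: GenomeRecord, path: Union[str, Path]) -> None:
    """Write a GenBank flat file that :func:`read_genbank` parses back to an
    equal record (sequence and feature tuples)."""
    with Path(path).open("w") as handle:
        SeqIO.write(_to_seqrecord(record), handle, "genbank")


def write_fasta(records: Union[GenomeRecord, Sequence[GenomeRecord]], path: Union[str, Path]) -> None:
    """Write one or more records as multi-FASTA."""
    if isinstance(records, GenomeRecord):
        records = [records]
    with Path(path).open("w") as handle:
        for rec in records:
            handle.write(f">{rec.id} {rec.description}".rstrip() + "\n")
            seq = rec.sequence
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")


def linearize_provirus(
    host_segment: GenomeRecord,
    att_left: int,
    att_right: int,
    terminus_offset: int,
) -> GenomeRecord:
    """Excise the provirus ``[att_left, att_right)`` from a host segment and
    re-open the implied circle at ``terminus_offset``.

    Integrated proviruses are circular permutations of the packaged linear
    genome: the element between the attachment sites is conceptually
    circularized and re-opened at the genome terminus so that position
    ``terminus_offset`` of the excised segment becomes position 0 of the
    returned linear record. Features are not carried over.
    """
    n = host_segment.length_bp
    if not (0 <= att_left < att_right <= n):
        raise CoordinateError(
            f"att sites [{att_left}, {att_right}) out of range for length {n}"
        )
    circle = host_segment.sequence[att_left:att_right]
    if not (0 <= terminus_offset < len(circle)):
        raise CoordinateError(
            f"terminus_offset {terminus_offset} outside excised circle of length {len(circle)}"
        )
    rotated = circle[terminus_offset:] + circle[:terminus_offset]
    return GenomeRecord(
        id=f"{host_segment.id}_provirus",
        description=(
            f"provirus excised from {host_segment.id}[{att_left}:{att_right}], "
            f"re-opened at offset {terminus_offset}"
        ),
        sequence=rotated,
        topology="linear",
    )
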