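"""CxxC-motif (zinc-finger signature) protein census.

HF1-group halovirus genomes encode many small proteins carrying one or
more C-x-x-C motifs, the signature of zinc-finger interaction domains.
The census scans every annotated CDS translation, counts proteins with at
least one motif, and classifies those shorter than a micro-protein
threshold (default: strictly less than 100 aa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from Bio.Seq import Seq

from .genome_io import CdsFeature, CoordinateError, GenomeRecord

__all__ = ["CxxCReport", "ProteinHit", "scan_cxxc", "cxxc_census", "region_density"]

#: NCBI translation table used for haloarchaea and their viruses
TRANSLATION_TABLE = 11


@dataclass(frozen=True)
class ProteinHit:
    locus_tag: str
    length_aa: int
    motif_count: int
    motif_positions: Tuple[int, ...]  # 1-based position of the first C of each match


@dataclass(frozen=True)
class CxxCReport:
    """Per-genome census of CxxC-motif proteins."""

    genome_id: str
    per_protein: Tuple[ProteinHit, ...]
    n_cxxc_genes: int
    n_micro_cxxc: int
    micro_threshold: int
    n_skipped: int = 0


def scan_cxxc(protein_sequence: str, spacing: int = 2) -> List[int]:
    """1-based positions i with residue i == C and residue i+spacing+1 == C.

    Overlapping matches are all reported. The default spacing of 2 is the
    canonical CxxC; other spacings are available behind the flag but are
    not part of the census definition.
    """
    seq = protein_sequence.upper()
    gap = spacing + 1
    return [i + 1 for i in range(len(seq) - gap) if seq[i] == "C" and seq[i + gap] == "C"]


def _translation_of(feat: CdsFeature, genome_sequence: str) -> str:
    """Annotated /translation if present, else table-11 translation of the
    coordinates with the trailing stop trimmed. Empty string if neither works."""
    if feat.translation:
        return feat.translation
    if feat.length_nt % 3 != 0:
        return ""
    coding = feat.coding_sequence(genome_sequence)
    aa = str(Seq(coding).translate(table=TRANSLATION_TABLE))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:  # internal stop: coordinates are not a clean CDS
        return ""
    return aa


def cxxc_census(record: GenomeRecord, micro_threshold: int = 100) -> CxxCReport:
    """Census of CxxC-motif proteins in one annotated genome.

    Counts proteins carrying at least one motif (not motif totals), and
    among those the micro-proteins of length strictly below
    ``micro_threshold`` amino acids. CDS without a usable translation are
    skipped with a warning and tallied in ``n_skipped``.
    """
    hits: List[ProteinHit] = []
    skipped = 0
    for feat in record.features:
        aa = _translation_of(feat, record.sequence)
        if not aa:
            warnings.warn(
                f"{record.id}: CDS {feat.locus_tag} lacks a translation and clean "
                "coordinates; skipped from CxxC census"
            )
            skipped += 1
            continue
        positions = tuple(scan_cxxc(aa))
        hits.append(
            ProteinHit(
                locus_tag=feat.locus_tag,
                length_aa=len(aa),
                motif_count=len(positions),
                motif_positions=positions,
            )
        )
    positive = [h for h in hits if h.motif_count >= 1]
    micro = [h for h in positive if h.length_aa < micro_threshold]
    return CxxCReport(
        genome_id=record.id,
        per_protein=tuple(hits),
        n_cxxc_genes=len(positive),
        n_micro_cxxc=len(micro),
        micro_threshold=micro_threshold,
        n_skipped=skipped,
    )


def region_density(
    report: CxxCReport,
    record: GenomeRecord,
    interval: Tuple[int, int],
) -> int:
    """Number of CxxC-positive CDS overlapping a genomic interval.

    The interval is 0-based half-open; a CDS overlaps when its feature
    interval intersects the query.
    """
    start, end = interval
    if start > end:
        raise CoordinateError(f"inverted interval ({start}, {end})")
    if start < 0 or end > record.length_bp:
        raise CoordinateError(
            f"interval ({start}, {end}) outside genome of length {record.length_bp}"
        )
    positive_tags = {h.locus_tag for h in report.per_protein if h.motif_count >= 1}
    count = 0
    for feat in record.features:
        if feat.locus_tag in positive_tags and feat.start < end and feat.end > start:
            count += 1
    return count
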