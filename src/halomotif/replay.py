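"""Re-analysis of the deposited HF1-group genomes.

Given a local directory of GenBank files for the seven deposited virus
isolates, recompute the published comparative statistics: the
under-represented-tetramer odds table, terminal direct repeat lengths,
genome length / G+C / CDS summaries, the CxxC census and pairwise
identities. The library never fetches over the network;
``scripts/fetch_accessions.py`` downloads the records for users with
connectivity.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Union

import pandas as pd

from .avoidance import MotifAvoidance
from .genome_io import GenomeRecord, gc_content, read_genbank
from .protein import cxxc_census
from .tdr import find_tdr

__all__ = ["ACCESSIONS", "load_accessions", "replay_report", "TABLE3_MOTIFS"]

#: deposited accession -> virus name for the seven HF1-group isolates
ACCESSIONS: Dict[str, str] = {
    "AY190604": "HF1",
    "AF222060": "HF2",
    "MN901520": "Hardycor2",
    "MN901521": "Serpecor1",
    "KC292022": "HRTV-5",
    "KC292020": "HRTV-8",
    "KC292021": "HRTV-7",
}

TABLE3_MOTIFS = ("CTAG", "GATC", "AGCT", "TGCA", "CATG")


def load_accessions(data_dir: Union[str, Path]) -> Dict[str, GenomeRecord]:
    """Load ``<accession>.gb`` files from a directory, keyed by virus name.

    Raises ``FileNotFoundError`` naming the missing accessions, with a
    pointer to the fetch helper.
    """
    data_dir = Path(data_dir)
    genomes: Dict[str, GenomeRecord] = {}
    missing: List[str] = []
    for accession, name in ACCESSIONS.items():
        path = data_dir / f"{accession}.gb"
        if not path.exists():
            missing.append(accession)
            continue
        records = read_genbank(path)
        if len(records) != 1:
            raise ValueError(f"{path}: expected one record, found {len(records)}")
        rec = records[0]
        rec.id = name
        genomes[name] = rec
    if missing:
        raise FileNotFoundError(
            f"missing deposited genomes under {data_dir}: {', '.join(missing)}. "
            "Run scripts/fetch_accessions.py on a machine with network access."
        )
    return genomes


def replay_report(data_dir: Union[str, Path]) -> Dict[str, pd.DataFrame]:
    """All deposited-genome statistics this package recomputes.

    Returns a dict of DataFrames: ``summary`` (length, G+C%, CDS, TDR),
    ``table3`` (tetramer odds matrix) and ``cxxc`` (census counts).
    Pairwise identity is left to :func:`halomotif.compare.pairwise_identity`
    on the loaded records because it is quadratic in the number of genomes.
    """
    genomes = load_accessions(data_dir)
    ordered = [genomes[name] for name in ACCESSIONS.values()]

    summary_rows = []
    for rec in ordered:
        tdr = find_tdr(rec, min_len=50, max_mismatch=0)
        summary_rows.append(
            {
                "genome": rec.id,
                "length_bp": rec.length_bp,
                "gc_percent": round(100 * gc_content(rec), 1),
                "n_cds": len(rec.features),
                "tdr_length": tdr.length_bp,
            }
        )
    results = MotifAvoidance(ordered, motifs=list(TABLE3_MOTIFS)).fit()
    cxxc_rows = []
    for rec in ordered:
        report = cxxc_census(rec)
        cxxc_rows.append(
            {
                "genome": rec.id,
                "n_cxxc_genes": report.n_cxxc_genes,
                "n_micro_cxxc": report.n_micro_cxxc,
            }
        )
    return {
        "summary": pd.DataFrame(summary_rows),
        "table3": results.odds_matrix(),
        "table3_long": results.table,
        "cxxc": pd.DataFrame(cxxc_rows),
    }
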