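"""Terminal direct repeat (TDR) detection for linear virus genomes.

Linear dsDNA halovirus genomes carry an identical sequence copy at both
termini (250-400 bp in the HF1 group). The detector returns the largest
L <= n/2 for which the length-L prefix and suffix agree within an allowed
number of mismatches; L below ``min_len`` is reported as "no TDR".

The exact-match case is solved with the classical border (failure-function)
construction in O(n); the mismatch-tolerant case counts per-shift matches
with an FFT autocorrelation over one-hot base indicators, then verifies the
chosen L directly so FFT rounding can never misreport.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome_io import GenomeRecord, gc_content

__all__ = ["TDRResult", "TopologyError", "find_tdr", "tdr_report"]


class TopologyError(ValueError):
    """TDR detection is only defined for linear genomes."""


@dataclass(frozen=True)
class TDRResult:
    """A detected terminal direct repeat. ``length_bp`` 0 means none found."""

    length_bp: int
    repeat_sequence: str
    left_interval: Tuple[int, int]
    right_interval: Tuple[int, int]
    mismatches: int


def _border_lengths(seq: str) -> List[int]:
    """All border lengths of seq (proper prefixes that are also suffixes),
    descending, via the KMP failure function."""
    n = len(seq)
    fail = [0] * n
    j = 0
    for i in range(1, n):
        while j and seq[i] != seq[j]:
            j = fail[j - 1]
        if seq[i] == seq[j]:
            j += 1
        fail[i] = j
    borders = []
    b = fail[-1] if n else 0
    while b > 0:
        borders.append(b)
        b = fail[b - 1]
    return borders


def _hamming(seq: str, length: int) -> int:
    a = seq[:length]
    b = seq[-length:]
    return sum(x != y for x, y in zip(a, b))


def _match_counts_by_shift(seq: str) -> np.ndarray:
    """m[s] = number of positions i with seq[i] == seq[i+s], for every shift s.

    One FFT autocorrelation per base; N contributes to no indicator, so an
    N anywhere counts as a mismatch.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    size = 1
    while size < 2 * n:
        size <<= 1
    total = np.zeros(n, dtype=np.float64)
    for base in b"ACGT":
        x = (arr == base).astype(np.float64)
        fx = np.fft.rfft(x, size)
        corr = np.fft.irfft(fx * np.conj(fx), size)
        total += corr[:n]
    return np.rint(total).astype(np.int64)


def find_tdr(record: GenomeRecord, min_len: int = 50, max_mismatch: int = 0) -> TDRResult:
    """Largest terminal direct repeat of a linear genome.

    Returns the largest L <= n/2 such that the Hamming distance between
    ``sequence[:L]`` and ``sequence[-L:]`` is at most ``max_mismatch``;
    if no such L >= min_len exists, a zero-length result is returned.
    """
    if record.topology != "linear":
        raise TopologyError(f"{record.id}: TDR detection requires a linear genome")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    seq = record.sequence
    n = len(seq)
    cap = n // 2
    best = 0
    best_mm = 0
    if max_mismatch == 0:
        for b in _border_lengths(seq):
            if b <= cap:
                best = b
                break
    else:
        matches = _match_counts_by_shift(seq)
        for length in range(cap, min_len - 1, -1):
            approx_mm = length - matches[n - length]
            if approx_mm <= max_mismatch:
                exact = _hamming(seq, length)  # guard FFT rounding
                if exact <= max_mismatch:
                    best = length
                    best_mm = exact
                    break
    if best < min_len:
        return TDRResult(0, "", (0, 0), (n, n), 0)
    return TDRResult(
        length_bp=best,
        repeat_sequence=seq[:best],
        left_interval=(0, best),
        right_interval=(n - best, n),
        mismatches=best_mm,
    )


def tdr_report(
    genomes: Sequence[GenomeRecord],
    min_len: int = 50,
    max_mismatch: int = 0,
) -> pd.DataFrame:
    """One row per genome: id, TDR length and G+C of the repeat.

    Rows follow input order; a genome without a TDR reports length 0 and
    an empty repeat.
    """
    rows = []
    for genome in genomes:
        res = find_tdr(genome, min_len=min_len, max_mismatch=max_mismatch)
        rows.append(
            {
                "genome": genome.id,
                "tdr_length": res.length_bp,
                "tdr_sequence": res.repeat_sequence,
                "gc_of_tdr": (
                    round(100 * gc_content(res.repeat_sequence), 1)
                    if res.length_bp
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows, columns=["genome", "tdr_length", "tdr_sequence", "gc_of_tdr"])
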