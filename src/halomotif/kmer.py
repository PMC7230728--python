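"""k-mer counting, Markov expectations, palindrome enumeration and IUPAC
motif scans.

Counts are taken over overlapping forward-strand windows. Windows containing
``N`` are skipped. For circular records the k-1 wrap-around windows are
included, so that re-opened provirus circles and linear virions are both
well defined.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .genome_io import GenomeRecord, reverse_complement

__all__ = [
    "KmerCountTable",
    "UndefinedExpectationError",
    "count_kmers",
    "markov_expected",
    "enumerate_palindromes",
    "count_ambiguous_motif",
    "frameshift_motif_scan",
    "IUPAC_SETS",
]

#: IUPAC nucleotide ambiguity codes as base sets
IUPAC_SETS: Dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class UndefinedExpectationError(ValueError):
    """A Markov expectation is undefined because a required sub-word count is zero."""


@dataclass(frozen=True)
class KmerCountTable:
    """Overlapping k-mer counts of one genome at a fixed k.

    ``n_windows`` is the number of valid (N-free) windows; the counts sum
    to it by construction.
    """

    k: int
    counts: Mapping[str, int]
    n_windows: int
    source_id: str
    topology: str

    def frequency(self, word: str) -> float:
        """Relative frequency of ``word`` among valid windows."""
        if self.n_windows == 0:
            raise UndefinedExpectationError(
                f"{self.source_id}: no valid windows at k={self.k}"
            )
        return self.counts.get(word, 0) / self.n_windows

    def __getitem__(self, word: str) -> int:
        return self.counts.get(word, 0)


def count_kmers(record: GenomeRecord, k: int) -> KmerCountTable:
    """Count overlapping forward-strand k-mers of a genome.

    Windows containing N are skipped. For ``topology == "circular"`` the
    sequence is extended by its first k-1 bases so wrap-around windows
    are counted.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = record.length_bp
    if k > n:
        raise ValueError(f"k={k} exceeds sequence length {n} of {record.id}")
    seq = record.sequence
    if record.topology == "circular":
        seq = seq + seq[: k - 1]
    counts: Counter = Counter(seq[i : i + k] for i in range(len(seq) - k + 1))
    # drop windows containing N
    for word in [w for w in counts if "N" in w]:
        del counts[word]
    n_windows = sum(counts.values())
    return KmerCountTable(
        k=k,
        counts=dict(counts),
        n_windows=n_windows,
        source_id=record.id,
        topology=record.topology,
    )


def count_kmer_tables(record: GenomeRecord, ks: Iterable[int]) -> Dict[int, KmerCountTable]:
    """Convenience: count tables at several k for the same record."""
    return {k: count_kmers(record, k) for k in sorted(set(ks))}


def markov_expected(
    motif: str,
    tables: Mapping[int, KmerCountTable],
    null_model: str = "maximal_order",
) -> float:
    """Expected count of ``motif`` under a Markov null built from its own
    sub-word frequencies.

    maximal_order (the standard null for oligonucleotide relative-abundance
    studies):

        E(w) = N_k * f(prefix_{k-1}) * f(suffix_{k-1}) / f(core_{k-2})

    zero_order:

        E(w) = N_k * prod_i f(w_i)

    where f are frequencies from the count table at the corresponding word
    length and N_k the number of valid k-windows. ``tables`` must contain
    the table at k plus, depending on the null, k-1 and k-2 or 1.
    """
    k = len(motif)
    if k < 1:
        raise ValueError("empty motif")
    if null_model not in ("maximal_order", "zero_order"):
        raise ValueError(f"unknown null model {null_model!r}")
    if k not in tables:
        raise ValueError(f"need a k={k} count table for motif {motif}")
    nk = tables[k].n_windows
    if null_model == "zero_order":
        if 1 not in tables:
            raise ValueError("zero_order null needs the k=1 table")
        t1 = tables[1]
        expected = float(nk)
        for base in motif:
            expected *= t1.frequency(base)
        return expected
    if k < 3:
        raise ValueError("maximal_order null needs motifs of length >= 3")
    for kk in (k - 1, k - 2):
        if kk not in tables:
            raise ValueError(f"maximal_order null needs the k={kk} table for motif {motif}")
    prefix, suffix, core = motif[:-1], motif[1:], motif[1:-1]
    core_count = tables[k - 2][core]
    if core_count == 0:
        raise UndefinedExpectationError(
            f"expectation of {motif} undefined: core word {core!r} has zero count "
            f"in {tables[k - 2].source_id}"
        )
    f_prefix = tables[k - 1].frequency(prefix)
    f_suffix = tables[k - 1].frequency(suffix)
    f_core = tables[k - 2].frequency(core)
    return nk * f_prefix * f_suffix / f_core


def enumerate_palindromes(k: int) -> List[str]:
    """All reverse-complement palindromes of even length k, lexicographic.

    A word w is a reverse-complement palindrome when w == revcomp(w); it is
    then determined by its first k/2 bases, so there are exactly 4**(k/2).
    Odd k admits no such palindromes and raises ``ValueError``.
    """
    if k < 2 or k % 2 != 0:
        raise ValueError(f"reverse-complement palindromes require even k >= 2, got {k}")
    half = k // 2
    out = []
    for combo in product("ACGT", repeat=half):
        left = "".join(combo)
        out.append(left + reverse_complement(left))
    return sorted(out)


def _iupac_sets(motif: str) -> List[frozenset]:
    sets = []
    for ch in motif.upper():
        try:
            sets.append(IUPAC_SETS[ch])
        except KeyError:
            raise ValueError(f"invalid IUPAC code {ch!r} in motif {motif!r}") from None
    return sets


def _count_iupac_forward(seq: str, sets: Sequence[frozenset]) -> int:
    m = len(sets)
    count = 0
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        # sequence N matches nothing: its identity is unknown
        if all(ch in s for ch, s in zip(window, sets)):
            count += 1
    return count


def iupac_reverse_complement(motif: str) -> str:
    """Reverse complement of an IUPAC motif (W, S, N are self-complementary codes)."""
    return motif.upper().translate(_IUPAC_COMPLEMENT)[::-1]


def count_ambiguous_motif(
    record: GenomeRecord,
    iupac_motif: str,
    both_strands: bool = False,
) -> int:
    """Count overlapping matches of an IUPAC motif.

    Matching is by per-position set membership; an ``N`` in the sequence
    matches no motif position. With ``both_strands`` set, reverse-strand
    matches are added unless the motif is self-reverse-complementary under
    IUPAC expansion (counting such motifs twice would double every site).
    """
    sets = _iupac_sets(iupac_motif)
    seq = record.sequence
    if record.topology == "circular":
        seq = seq + seq[: len(sets) - 1]
    total = _count_iupac_forward(seq, sets)
    if both_strands:
        rc = iupac_reverse_complement(iupac_motif)
        if rc != iupac_motif.upper():
            total += _count_iupac_forward(seq, _iupac_sets(rc))
    return total


def frameshift_motif_scan(
    record: GenomeRecord,
    motif: str = "TTTCGN",
    window_bp: int = 30,
) -> List[Tuple[str, int]]:
    """Scan the 3' end of each CDS for a programmed-frameshift candidate motif.

    Slippery TTT-CGN signals implicated in +1 frameshifting sit on the
    coding strand just before the stop codon. For every CDS the final
    ``window_bp`` nucleotides of the coding sequence (stop codon excluded)
    are scanned for IUPAC matches of ``motif``; hits are reported as
    ``(locus_tag, position)`` with position the 1-based offset of the match
    within the coding sequence (start codon = position 1).
    """
    if not record.features:
        warnings.warn(f"{record.id}: no CDS features; frameshift scan is empty")
        return []
    sets = _iupac_sets(motif)
    m = len(sets)
    hits: List[Tuple[str, int]] = []
    for feat in record.features:
        coding = feat.coding_sequence(record.sequence)
        body = coding[:-3] if len(coding) > 3 else ""  # strip stop codon
        if len(body) < m:
            continue
        window_start = max(0, len(body) - window_bp)
        window = body[window_start:]
        for i in range(len(window) - m + 1):
            chunk = window[i : i + m]
            if all(ch in s for ch, s in zip(chunk, sets)):
                hits.append((feat.locus_tag, window_start + i + 1))
    return hits
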