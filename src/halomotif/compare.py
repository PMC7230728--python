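"""Pairwise whole-genome nucleotide identity and dot-plot match extraction.

The approach is classical seed-and-chain: exact shared k-mers are merged
along diagonals into ungapped anchors (X-drop extension), the
highest-weight collinear chain is selected by weighted
longest-increasing-subsequence, and the gaps between chained anchors are
closed by banded global alignment (edlib). Percent identity is identical
columns over all alignment columns, gap columns included — the convention
used when reading identity off a multiple alignment. Gaps larger than
``gap_cap`` are not aligned; they contribute ``max(gap_a, gap_b)``
non-identical columns, which bounds worst-case work on ~75 kb genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import edlib

from .genome_io import GenomeRecord, reverse_complement

__all__ = [
    "AnchorMatch",
    "IdentityResult",
    "seed_matches",
    "pairwise_identity",
    "dotplot_export",
    "dotplot_figure",
]


@dataclass(frozen=True)
class AnchorMatch:
    """An ungapped match between query and subject; coordinates 0-based
    half-open on the forward strand of each genome."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str  # '+' or '-'
    matches: int
    length: int
    query: str = ""
    subject: str = ""

    def __post_init__(self) -> None:
        assert self.q_end - self.q_start == self.length
        assert self.matches <= self.length


@dataclass(frozen=True)
class IdentityResult:
    """Whole-genome identity: identical columns over all alignment columns."""

    pct_identity: float
    aligned_columns: int
    identical_columns: int
    coverage_fraction: float
    strand: str = "+"


def _kmer_index(seq: str, k: int, max_occ: int) -> Dict[str, List[int]]:
    index: Dict[str, List[int]] = {}
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if "N" in word:
            continue
        index.setdefault(word, []).append(i)
    # highly repetitive words blow up seed pairing without adding signal
    return {w: ps for w, ps in index.items() if len(ps) <= max_occ}


def _count_matches(a: str, b: str) -> int:
    return sum(x == y for x, y in zip(a, b))


def _xdrop_extend(
    aseq: str, bseq: str, q_start: int, q_end: int, s_start: int, xdrop: int
) -> Tuple[int, int, int]:
    """Extend an ungapped run in both directions with +1/-1 scoring and an
    X-drop stop. Returns (q_start, q_end, s_start) of the best extension."""
    # right
    score = best = 0
    qi, si = q_end, s_start + (q_end - q_start)
    best_q = q_end
    while qi < len(aseq) and si < len(bseq):
        score += 1 if aseq[qi] == bseq[si] else -1
        qi += 1
        si += 1
        if score > best:
            best, best_q = score, qi
        elif score < best - xdrop:
            break
    q_end = best_q
    # left
    score = best = 0
    qi, si = q_start - 1, s_start - 1
    best_q = q_start
    while qi >= 0 and si >= 0:
        score += 1 if aseq[qi] == bseq[si] else -1
        if score > best:
            best, best_q = score, qi
        elif score < best - xdrop:
            break
        qi -= 1
        si -= 1
    delta = q_start - best_q
    return best_q, q_end, s_start - delta


def _anchors_one_frame(
    aseq: str,
    bseq: str,
    k: int,
    min_extend_len: int,
    xdrop: int,
    max_occ: int = 50,
) -> List[Tuple[int, int, int, int, int]]:
    """Ungapped anchors (q_start, q_end, s_start, s_end, matches) between two
    sequences taken as given (no strand logic here)."""
    index = _kmer_index(aseq, k, max_occ)
    by_diag: Dict[int, List[int]] = {}
    for j in range(len(bseq) - k + 1):
        word = bseq[j : j + k]
        positions = index.get(word)
        if positions is None:
            continue
        for i in positions:
            by_diag.setdefault(i - j, []).append(j)
    out = []
    seen = set()
    join_gap = max(xdrop, k)
    for diag, js in by_diag.items():
        js.sort()
        run_start = js[0]
        run_end = js[0] + k
        runs = []
        for j in js[1:]:
            if j <= run_end + join_gap:
                run_end = max(run_end, j + k)
            else:
                runs.append((run_start, run_end))
                run_start, run_end = j, j + k
        runs.append((run_start, run_end))
        for s0, s1 in runs:
            q0, q1 = s0 + diag, s1 + diag
            q0, q1, s0 = _xdrop_extend(aseq, bseq, q0, q1, s0, xdrop)
            s1 = s0 + (q1 - q0)
            if q1 - q0 < min_extend_len:
                continue
            key = (q0, q1, s0)
            if key in seen:
                continue
            seen.add(key)
            matches = _count_matches(aseq[q0:q1], bseq[s0:s1])
            out.append((q0, q1, s0, s1, matches))
    out.sort()
    return out


def seed_matches(
    a: GenomeRecord,
    b: GenomeRecord,
    k: int = 14,
    min_extend_len: int = 30,
    xdrop: int = 20,
) -> List[AnchorMatch]:
    """Ungapped anchors between two genomes, both strands of ``b``.

    Minus-strand anchors are reported in forward coordinates of ``b`` with
    ``strand == '-'``.
    """
    if not (8 <= k <= 32):
        raise ValueError(f"k must lie in [8, 32], got {k}")
    anchors: List[AnchorMatch] = []
    nb = b.length_bp
    for strand, bseq in (("+", b.sequence), ("-", reverse_complement(b.sequence))):
        for q0, q1, s0, s1, m in _anchors_one_frame(
            a.sequence, bseq, k, min_extend_len, xdrop
        ):
            if strand == "-":
                s0, s1 = nb - s1, nb - s0
            anchors.append(
                AnchorMatch(
                    q_start=q0,
                    q_end=q1,
                    s_start=s0,
                    s_end=s1,
                    strand=strand,
                    matches=m,
                    length=q1 - q0,
                    query=a.id,
                    subject=b.id,
                )
            )
    anchors.sort(key=lambda x: (x.q_start, x.s_start))
    return anchors


def _chain(anchors: List[Tuple[int, int, int, int, int]], slack: int) -> List[Tuple[int, int, int, int, int]]:
    """Highest-weight collinear chain (weight = matches) by quadratic DP;
    anchors may overlap up to ``slack`` and are trimmed by the caller."""
    if not anchors:
        return []
    anchors = sorted(anchors, key=lambda t: (t[0], t[2]))
    m = len(anchors)
    score = [t[4] for t in anchors]
    prev = [-1] * m
    for i in range(m):
        q0i, _, s0i, _, wi = anchors[i]
        for j in range(i):
            q0j, q1j, s0j, s1j, _ = anchors[j]
            if q1j <= q0i + slack and s1j <= s0i + slack and q0j < q0i and s0j < s0i:
                cand = score[j] + wi
                if cand > score[i]:
                    score[i] = cand
                    prev[i] = j
    best = max(range(m), key=lambda i: score[i])
    chain = []
    while best != -1:
        chain.append(anchors[best])
        best = prev[best]
    chain.reverse()
    return chain


def _banded_gap_alignment(ga_seq: str, gb_seq: str, gap_cap: int) -> Tuple[int, int, bool]:
    """Align two gap segments; returns (columns, identical, covered)."""
    ga, gb = len(ga_seq), len(gb_seq)
    if ga == 0 and gb == 0:
        return 0, 0, True
    if ga == 0 or gb == 0:
        return max(ga, gb), 0, True
    if max(ga, gb) > gap_cap:
        return max(ga, gb), 0, False
    band = int(0.2 * max(ga, gb)) + 50
    res = edlib.align(ga_seq, gb_seq, mode="NW", task="path", k=band)
    if res["editDistance"] == -1:  # more divergent than the band allows
        return max(ga, gb), 0, False
    columns = identical = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        columns += n
        if ch == "=":
            identical += n
    return columns, identical, True


def pairwise_identity(
    a: GenomeRecord,
    b: GenomeRecord,
    k: int = 14,
    min_extend_len: int = 30,
    xdrop: int = 20,
    gap_cap: int = 5000,
) -> IdentityResult:
    """Whole-genome percent identity between two linear genomes.

    Anchors are computed on both strands of ``b``; the strand with the
    larger total anchor weight is chained, inter-anchor gaps up to
    ``gap_cap`` are closed by banded global alignment, and larger gaps
    contribute unaligned (non-identical) columns. Identity is identical
    columns over all columns, terminal segments included.
    """
    if a.topology != "linear" or b.topology != "linear":
        raise ValueError("pairwise_identity requires linear genomes")
    frames = {}
    for strand, bseq in (("+", b.sequence), ("-", reverse_complement(b.sequence))):
        frames[strand] = (
            bseq,
            _anchors_one_frame(a.sequence, bseq, k, min_extend_len, xdrop),
        )
    strand = max(frames, key=lambda s: sum(t[4] for t in frames[s][1]))
    bseq, anchors = frames[strand]
    if not anchors:
        return IdentityResult(0.0, 0, 0, 0.0, strand)
    chain = _chain(anchors, slack=k)

    columns = identical = covered = 0
    prev_qe = prev_se = 0
    for q0, q1, s0, s1, _ in chain:
        # trim any small overlap left by the chain DP; anchors are ungapped
        delta = max(prev_qe - q0, prev_se - s0, 0)
        q0 += delta
        s0 += delta
        if q0 >= q1 or s0 >= s1:
            continue
        gcols, gident, gcov = _banded_gap_alignment(
            a.sequence[prev_qe:q0], bseq[prev_se:s0], gap_cap
        )
        columns += gcols
        identical += gident
        if gcov:
            covered += gcols
        seg_len = q1 - q0
        seg_matches = _count_matches(a.sequence[q0:q1], bseq[s0:s1])
        columns += seg_len
        identical += seg_matches
        covered += seg_len
        prev_qe, prev_se = q1, s1
    gcols, gident, gcov = _banded_gap_alignment(
        a.sequence[prev_qe:], bseq[prev_se:], gap_cap
    )
    columns += gcols
    identical += gident
    if gcov:
        covered += gcols
    pct = 100.0 * identical / columns if columns else 0.0
    coverage = covered / columns if columns else 0.0
    return IdentityResult(
        pct_identity=pct,
        aligned_columns=columns,
        identical_columns=identical,
        coverage_fraction=coverage,
        strand=strand,
    )


def dotplot_export(matches: Sequence[AnchorMatch], path: Union[str, Path]) -> None:
    """Write PAF-style tabular anchor records, sorted by query start."""
    header = "query\tq_start\tq_end\tstrand\tsubject\ts_start\ts_end\tmatches\tlength\n"
    with Path(path).open("w") as handle:
        handle.write(header)
        for m in sorted(matches, key=lambda x: (x.q_start, x.s_start)):
            handle.write(
                f"{m.query}\t{m.q_start}\t{m.q_end}\t{m.strand}\t{m.subject}\t"
                f"{m.s_start}\t{m.s_end}\t{m.matches}\t{m.length}\n"
            )


def dotplot_figure(matches: Sequence[AnchorMatch], title: str = ""):
    """Dot plot of anchors (forward anchors ascending, reverse descending).

    Returns a matplotlib Figure; import is deferred so headless use of the
    rest of the module never touches a plotting backend.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for m in matches:
        if m.strand == "+":
            ax.plot([m.q_start, m.q_end], [m.s_start, m.s_end], color="green", lw=1)
        else:
            ax.plot([m.q_start, m.q_end], [m.s_end, m.s_start], color="red", lw=1)
    ax.set_xlabel(matches[0].query if matches else "query (bp)")
    ax.set_ylabel(matches[0].subject if matches else "subject (bp)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig
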