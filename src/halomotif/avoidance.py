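"""Markov-null motif avoidance model.

Restriction–modification systems select against their palindromic
recognition sites in virus genomes. The statistic used to detect this is
the Markov odds ratio: the observed count of a word divided by its
expectation under a Markov null built from the word's own sub-word
frequencies (maximal-order by default). Odds near 1 indicate a word at
its compositional expectation; odds well below 1 indicate avoidance, and
zero counts indicate complete absence.

The surface follows the fitted-model convention: :class:`MotifAvoidance`
is constructed from one or more genomes plus a motif set, ``fit()``
computes the count tables and odds, and the returned
:class:`AvoidanceResults` carries the table, classifications and a
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Union

import pandas as pd

from .genome_io import GenomeRecord, reverse_complement
from .kmer import (
    KmerCountTable,
    UndefinedExpectationError,
    count_kmers,
    enumerate_palindromes,
    markov_expected,
)

__all__ = [
    "MotifAvoidance",
    "AvoidanceResults",
    "MotifOddsResult",
    "PalindromeCensus",
    "motif_odds",
    "palindrome_census",
    "DEFAULT_UNDER_THRESHOLD",
]

#: odds below this (with a non-zero count) are called under-represented;
#: the conventional cut for tetramer relative-abundance studies
DEFAULT_UNDER_THRESHOLD = 0.78


@dataclass(frozen=True)
class MotifOddsResult:
    """Observed count, Markov-expected count and odds for one motif in one genome."""

    motif: str
    observed: int
    expected: float
    odds: float
    null_model: str
    classification: str  # absent | under_represented | normal

    def __post_init__(self) -> None:
        if self.expected > 0:
            assert abs(self.odds - self.observed / self.expected) < 1e-9


@dataclass(frozen=True)
class PalindromeCensus:
    """Multi-genome census of reverse-complement palindromes at fixed k."""

    k: int
    genomes: tuple
    table: pd.DataFrame  # columns: genome, motif, observed, expected, odds, classification
    absent_in_all: FrozenSet[str]
    excluded: FrozenSet[str]


def _classify(observed: int, odds: float, threshold: float) -> str:
    if observed == 0:
        return "absent"
    if odds < threshold:
        return "under_represented"
    return "normal"


class MotifAvoidance:
    """Motif avoidance under a Markov null, fitted to one or more genomes.

    Parameters
    ----------
    genomes
        One :class:`GenomeRecord` or a sequence of them. Counts are taken
        per genome on the forward strand (every reverse-complement
        palindrome is strand-symmetric, so this loses nothing for the
        motifs of interest).
    motifs
        Explicit motif list over {A,C,G,T}. Mutually exclusive with ``k``.
    k
        Census mode: analyse all reverse-complement palindromes of even
        length ``k``.
    exclude_submotifs
        In census mode, drop every candidate palindrome containing any of
        these words as a substring. Used to separate genuinely new absent
        words from trivial super-motifs of already-absent cores (e.g.
        excluding CTAG/GTAC before reading a 6-mer census).
    null_model
        ``"maximal_order"`` (default) or ``"zero_order"``.
    under_threshold
        Odds cut below which a present motif is called under-represented.
    """

    def __init__(
        self,
        genomes: Union[GenomeRecord, Sequence[GenomeRecord]],
        motifs: Optional[Sequence[str]] = None,
        k: Optional[int] = None,
        exclude_submotifs: Sequence[str] = (),
        null_model: str = "maximal_order",
        under_threshold: float = DEFAULT_UNDER_THRESHOLD,
    ) -> None:
        if isinstance(genomes, GenomeRecord):
            genomes = [genomes]
        if not genomes:
            raise ValueError("need at least one genome")
        if (motifs is None) == (k is None):
            raise ValueError("give exactly one of motifs= or k=")
        self.genomes: List[GenomeRecord] = list(genomes)
        self.null_model = null_model
        self.under_threshold = under_threshold
        self.excluded: FrozenSet[str] = frozenset()
        if k is not None:
            candidates = enumerate_palindromes(k)
            excl = [e.upper() for e in exclude_submotifs]
            for e in excl:
                if len(e) >= k:
                    raise ValueError(f"exclude_submotifs must be shorter than k={k}")
            self.excluded = frozenset(
                w for w in candidates if any(e in w for e in excl)
            )
            self.motifs = [w for w in candidates if w not in self.excluded]
            self.census_k = k
        else:
            self.motifs = [m.upper() for m in motifs]
            for m in self.motifs:
                if not set(m) <= set("ACGT"):
                    raise ValueError(f"motif {m!r} must be over A/C/G/T")
            self.census_k = None

    def fit(self) -> "AvoidanceResults":
        """Count sub-words, compute Markov expectations and classify."""
        rows = []
        lengths = sorted({len(m) for m in self.motifs})
        needed: Set[int] = set()
        for k in lengths:
            needed.add(k)
            if self.null_model == "maximal_order":
                needed.update((k - 1, k - 2))
            else:
                needed.add(1)
        for genome in self.genomes:
            tables: Dict[int, KmerCountTable] = {
                kk: count_kmers(genome, kk) for kk in sorted(needed)
            }
            for motif in self.motifs:
                observed = tables[len(motif)][motif]
                try:
                    expected = markov_expected(motif, tables, self.null_model)
                except UndefinedExpectationError:
                    if observed > 0 or self.census_k is None:
                        raise
                    # absent core word of an absent motif: the expectation is
                    # undefined but the classification (absent) is not
                    expected = float("nan")
                odds = observed / expected if expected > 0 else 0.0
                rows.append(
                    {
                        "genome": genome.id,
                        "motif": motif,
                        "observed": observed,
                        "expected": expected,
                        "odds": odds,
                        "classification": _classify(observed, odds, self.under_threshold),
                    }
                )
        table = pd.DataFrame(
            rows,
            columns=["genome", "motif", "observed", "expected", "odds", "classification"],
        )
        return AvoidanceResults(self, table)


class AvoidanceResults:
    """Fitted motif-avoidance results: the odds table and derived summaries."""

    def __init__(self, model: MotifAvoidance, table: pd.DataFrame) -> None:
        self.model = model
        self.table = table

    @property
    def absent_in_all(self) -> FrozenSet[str]:
        """Motifs with zero observed count in every genome analysed."""
        totals = self.table.groupby("motif")["observed"].sum()
        return frozenset(totals[totals == 0].index)

    def odds_matrix(self) -> pd.DataFrame:
        """Genomes as rows, motifs as columns, odds as values."""
        return self.table.pivot(index="genome", columns="motif", values="odds").reindex(
            index=[g.id for g in self.model.genomes],
            columns=self.model.motifs,
        )

    def census(self) -> PalindromeCensus:
        """Package census-mode results; requires the model was built with k=."""
        if self.model.census_k is None:
            raise ValueError("census() requires a palindrome census model (k=...)")
        return PalindromeCensus(
            k=self.model.census_k,
            genomes=tuple(g.id for g in self.model.genomes),
            table=self.table,
            absent_in_all=self.absent_in_all,
            excluded=self.model.excluded,
        )

    def formatted_matrix(self, table3_style: bool = False) -> pd.DataFrame:
        """Odds matrix with odds formatted %.2f; with ``table3_style``,
        absent motifs render "0" and normal motifs render "."."""
        cls = self.table.pivot(index="genome", columns="motif", values="classification")
        odds = self.odds_matrix()

        def fmt(genome: str, motif: str) -> str:
            c = cls.loc[genome, motif]
            if c == "absent":
                return "0"
            if table3_style and c == "normal":
                return "."
            return f"{odds.loc[genome, motif]:.2f}"

        out = odds.copy().astype(object)
        for g in out.index:
            for m in out.columns:
                out.loc[g, m] = fmt(g, m)
        return out

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = [
            "Motif avoidance under a Markov null",
            f"  null model     : {self.model.null_model}",
            f"  genomes        : {len(self.model.genomes)}",
            f"  motifs         : {len(self.model.motifs)}"
            + (
                f" (palindrome census k={self.model.census_k}, "
                f"{len(self.model.excluded)} excluded by sub-motif)"
                if self.model.census_k is not None
                else ""
            ),
            f"  under-represented cut: odds < {self.model.under_threshold:.2f}",
            "",
        ]
        show = self.table.copy()
        show["expected"] = show["expected"].map(lambda v: f"{v:.1f}")
        show["odds"] = show["odds"].map(lambda v: f"{v:.2f}")
        lines.append(show.to_string(index=False))
        absent = sorted(self.absent_in_all)
        lines.append("")
        lines.append(f"absent in all genomes ({len(absent)}): {', '.join(absent) if absent else '-'}")
        return "\n".join(lines)


def motif_odds(
    record: GenomeRecord,
    motif: str,
    null_model: str = "maximal_order",
    under_threshold: float = DEFAULT_UNDER_THRESHOLD,
) -> MotifOddsResult:
    """Odds ratio of a single motif in a single genome."""
    res = MotifAvoidance(
        record, motifs=[motif], null_model=null_model, under_threshold=under_threshold
    ).fit()
    row = res.table.iloc[0]
    return MotifOddsResult(
        motif=row["motif"],
        observed=int(row["observed"]),
        expected=float(row["expected"]),
        odds=float(row["odds"]),
        null_model=null_model,
        classification=row["classification"],
    )


def palindrome_census(
    genomes: Sequence[GenomeRecord],
    k: int,
    exclude_submotifs: Sequence[str] = (),
    null_model: str = "maximal_order",
) -> PalindromeCensus:
    """Census of all reverse-complement k-palindromes over a genome set."""
    model = MotifAvoidance(
        genomes, k=k, exclude_submotifs=exclude_submotifs, null_model=null_model
    )
    return model.fit().census()
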