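"""Synthetic halovirus-like genomes with controllable statistical structure.

The generator emulates the features the analyses in this package assume:
69-78 kb linear dsDNA with ~55-57% G+C, Markov-structured base
composition, configurable sets of fully avoided motifs (absent on both
strands, as restriction-site avoidance produces), planted terminal direct
repeats, and annotated CDS with exact control over how many proteins
carry CxxC motifs and how many of those are micro-proteins.

Motif avoidance is enforced constructively during left-to-right sampling:
at every position, bases that would complete an avoided word (or its
reverse complement) are removed from the proposal and the Markov
transition is renormalised over the remainder. Whole-genome rejection has
vanishing acceptance at 75 kb; local constraint sampling does not.
Coding regions are emitted codon-by-codon, choosing among synonymous
table-11 codons that respect the same constraints, so planted
translations are exact ground truth for the CxxC census.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio.Data import CodonTable

from .genome_io import CdsFeature, GenomeRecord, reverse_complement, write_fasta, write_genbank

__all__ = [
    "SyntheticGenomeSpec",
    "ConstructiveFailureError",
    "generate_genome",
    "mutate",
    "fixture_suite",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
#: amino acids available to planted proteins; cysteine is reserved so that
#: CxxC content is exactly what the spec plants
_AA_NO_CYS = "ADEFGHIKLMNPQRSTVWY"

_table11 = CodonTable.unambiguous_dna_by_id[11]
_SYNONYMOUS: Dict[str, List[str]] = {}
for codon, aa in _table11.forward_table.items():
    _SYNONYMOUS.setdefault(aa, []).append(codon)
_STOP_CODONS = list(_table11.stop_codons)


class ConstructiveFailureError(RuntimeError):
    """The generator could not satisfy the spec within bounded retries."""


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of one synthetic genome.

    Defaults reproduce the conditions of an HF1-group virus isolate:
    ~75 kb linear genome at 57% G+C with order-1 Markov structure, GATC
    and CTAG fully avoided, a ~306 bp terminal direct repeat, and 126 CDS
    of which 23 encode CxxC proteins (14 of them micro-proteins).
    """

    length_bp: int = 74196
    gc: float = 0.57
    markov_order: int = 1
    avoided_motifs: Tuple[str, ...] = ("GATC", "CTAG")
    tdr_length: int = 306
    n_cds: int = 126
    cxxc_plant: Tuple[int, int] = (23, 14)
    substitution_rate: float = 0.0
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.length_bp <= 2 * self.tdr_length:
            raise ValueError("length_bp must exceed twice the TDR length")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must lie in (0, 1)")
        if self.markov_order not in (0, 1, 2):
            raise ValueError("markov_order must be 0, 1 or 2")
        if self.tdr_length < 0:
            raise ValueError("tdr_length must be >= 0")
        for m in self.avoided_motifs:
            if not m or not set(m.upper()) <= set("ACGT"):
                raise ValueError(f"avoided motif {m!r} must be a non-empty A/C/G/T word")
        n_total, n_micro = self.cxxc_plant
        if not (0 <= n_micro <= n_total <= self.n_cds):
            raise ValueError("cxxc_plant must satisfy 0 <= n_micro <= n_total <= n_cds")
        if not (0.0 <= self.substitution_rate <= 0.5):
            raise ValueError("substitution_rate must lie in [0, 0.5]")

    @property
    def genome_id(self) -> str:
        return self.name or f"syn_{self.seed}"


# ---------------------------------------------------------------------------
# Markov transition construction

def _stationary_gc(P: np.ndarray, order: int) -> float:
    """G+C of the stationary distribution of an order-m chain."""
    n_ctx = P.shape[0]
    if order == 0:
        return float(P[0, 1] + P[0, 2])
    pi = np.full(n_ctx, 1.0 / n_ctx)
    for _ in range(300):
        nxt = np.zeros(n_ctx)
        for b in range(4):
            # context c emits base b and becomes (c*4+b) mod n_ctx
            dest = (np.arange(n_ctx) * 4 + b) % n_ctx
            np.add.at(nxt, dest, pi * P[:, b])
        if np.abs(nxt - pi).sum() < 1e-12:
            pi = nxt
            break
        pi = nxt
    return float((pi[:, None] * P).sum(axis=0)[[1, 2]].sum())


def _markov_transitions(order: int, gc: float, rng: np.random.Generator, jitter: float = 0.15) -> np.ndarray:
    """Order-m transition matrix with genuine context dependence whose
    stationary G+C equals the target.

    Rows are contexts (4**order), columns next-base probabilities. Context
    dependence comes from log-normal jitter; a multiplicative reweighting
    loop then pins the stationary G+C back onto the target.
    """
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    n_ctx = 4**order
    if order == 0:
        return base[None, :]
    P = base[None, :] * np.exp(rng.normal(0.0, jitter, size=(n_ctx, 4)))
    P /= P.sum(axis=1, keepdims=True)
    for _ in range(60):
        realized = _stationary_gc(P, order)
        if abs(realized - gc) < 1e-9:
            break
        w = np.ones(4)
        w[[1, 2]] = gc / realized
        w[[0, 3]] = (1 - gc) / (1 - realized)
        P = P * w[None, :]
        P /= P.sum(axis=1, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# Constrained left-to-right emission

def _forbidden_tuples(avoided: Sequence[str]) -> List[Tuple[int, int, int]]:
    """(length, prefix-code, last-base) for every avoided word and its
    reverse complement; completing any of them is disallowed."""
    words = set()
    for m in avoided:
        m = m.upper()
        words.add(m)
        words.add(reverse_complement(m))
    out = []
    for w in sorted(words):
        code = 0
        for ch in w[:-1]:
            code = code * 4 + _BASE_INDEX[ch]
        out.append((len(w), code, _BASE_INDEX[w[-1]]))
    return out


def _codon_gc(codon: str) -> int:
    return codon.count("G") + codon.count("C")


def _solve_codon_lambda(
    aa_counts: Dict[str, int], n_stops: int, coding_nt: int, intergenic_nt: int, gc: float
) -> float:
    """Exponential-tilt parameter for synonymous codon choice.

    Synonymous codons are drawn with probability proportional to
    exp(lambda * GC(codon)); lambda is solved by bisection so the expected
    genome-wide G+C (intergenic text is already at target) matches the
    spec. Coding regions dominate a 90%-coding genome, so without this
    tilt the realized G+C would sit near 0.5 regardless of the target.
    """
    slot_sets: List[Tuple[List[int], int]] = []  # (gc per candidate codon, multiplicity)
    for aa, count in aa_counts.items():
        codons = ["ATG"] if aa == "M_start" else _SYNONYMOUS[aa]
        slot_sets.append(([_codon_gc(c) for c in codons], count))
    slot_sets.append(([_codon_gc(c) for c in _STOP_CODONS], n_stops))

    target_gc_bases = gc * (coding_nt + intergenic_nt) - gc * intergenic_nt

    def expected(lam: float) -> float:
        total = 0.0
        for gcs, count in slot_sets:
            ws = [np.exp(lam * g) for g in gcs]
            total += count * sum(g * w for g, w in zip(gcs, ws)) / sum(ws)
        return total

    lo, hi = -8.0, 8.0
    if expected(hi) < target_gc_bases:
        return hi
    if expected(lo) > target_gc_bases:
        return lo
    for _ in range(60):
        mid = (lo + hi) / 2
        if expected(mid) < target_gc_bases:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class _Emitter:
    """Stateful left-to-right sequence builder with motif constraints."""

    def __init__(
        self,
        P: np.ndarray,
        order: int,
        forbidden: List[Tuple[int, int, int]],
        rng: np.random.Generator,
        codon_lambda: float = 0.0,
    ) -> None:
        self.codon_lambda = codon_lambda
        self.P = P
        self._rows = P.tolist()  # python lists: the per-base loop dominates runtime
        self.order = order
        self.forbidden = forbidden
        self.rng = rng
        self.maxlen = max((L for L, _, _ in forbidden), default=1)
        self.seq: List[int] = []
        self.rolling = 0  # last (maxlen-1) bases, oldest at high bits
        self.ctx = 0

    def state(self) -> Tuple[int, int, int]:
        return len(self.seq), self.rolling, self.ctx

    def restore(self, state: Tuple[int, int, int]) -> None:
        n, self.rolling, self.ctx = state
        del self.seq[n:]

    def disallowed(self) -> set:
        pos = len(self.seq)
        out = set()
        for L, prefix_code, last in self.forbidden:
            if pos >= L - 1 and self.rolling % (4 ** (L - 1)) == prefix_code:
                out.add(last)
        return out

    def _push(self, b: int) -> None:
        self.seq.append(b)
        mod = 4 ** (self.maxlen - 1) if self.maxlen > 1 else 1
        self.rolling = (self.rolling * 4 + b) % mod if mod > 1 else 0
        self.ctx = (self.ctx * 4 + b) % self.P.shape[0]

    def emit_random(self, n: int) -> bool:
        """Emit n Markov-sampled bases; False if a dead end was hit."""
        for _ in range(n):
            banned = self.disallowed()
            probs = list(self._rows[self.ctx])
            for b in banned:
                probs[b] = 0.0
            total = sum(probs)
            if total <= 0.0:
                return False
            u = self.rng.random() * total
            acc = 0.0
            b = 3
            for i in range(4):
                acc += probs[i]
                if u < acc:
                    b = i
                    break
            self._push(b)
        return True

    def try_emit_word(self, word: str) -> bool:
        """Emit a fixed word if no position completes a forbidden motif."""
        state = self.state()
        for ch in word:
            b = _BASE_INDEX[ch]
            if b in self.disallowed():
                self.restore(state)
                return False
            self._push(b)
        return True

    def emit_codons(self, candidates_per_slot: List[List[str]]) -> bool:
        """Emit one codon per slot, choosing among feasible candidates with
        the GC exponential tilt; False if some slot has no feasible codon."""
        for candidates in candidates_per_slot:
            feasible = []
            weights = []
            for codon in candidates:
                state = self.state()
                ok = True
                for ch in codon:
                    b = _BASE_INDEX[ch]
                    if b in self.disallowed():
                        ok = False
                        break
                    self._push(b)
                self.restore(state)
                if ok:
                    feasible.append(codon)
                    weights.append(float(np.exp(self.codon_lambda * _codon_gc(codon))))
            if not feasible:
                return False
            u = self.rng.random() * sum(weights)
            acc = 0.0
            choice = feasible[-1]
            for codon, w in zip(feasible, weights):
                acc += w
                if u < acc:
                    choice = codon
                    break
            for ch in choice:
                self._push(_BASE_INDEX[ch])
        return True


# ---------------------------------------------------------------------------
# Protein and layout planning

_BUFFER = 120  # keeps CDS clear of the terminal repeat copy
_MIN_GAP = 30


def _cds_capacity_nt(spec: SyntheticGenomeSpec) -> int:
    region = (spec.length_bp - spec.tdr_length - _BUFFER) - _BUFFER
    return region - _MIN_GAP * (spec.n_cds + 1)


def _plan_proteins(spec: SyntheticGenomeSpec, rng: np.random.Generator) -> List[Tuple[str, bool]]:
    """(translation, is_cxxc) per CDS, in genome order.

    Micro CxxC proteins draw 40-99 aa, other CxxC proteins 100-300 aa,
    and the remaining CDS 50-300 aa — deposited HF1-group genomes average
    ~500 nt per CDS at ~90% coding density. If an unlucky draw overshoots
    the genome, lengths are rescaled down proportionally (respecting the
    size-class boundaries) rather than rejected.
    """
    n_total, n_micro = spec.cxxc_plant
    lengths: List[Tuple[int, bool, int, int]] = []  # (aa_len, is_cxxc, lo, hi)
    for _ in range(n_micro):
        lengths.append((int(rng.integers(40, 100)), True, 40, 99))
    for _ in range(n_total - n_micro):
        lengths.append((int(rng.integers(100, 301)), True, 100, 300))
    for _ in range(spec.n_cds - n_total):
        lengths.append((int(rng.integers(50, 301)), False, 20, 300))
    rng.shuffle(lengths)

    capacity = _cds_capacity_nt(spec)
    for _ in range(50):
        total = sum(3 * l + 3 for l, _, _, _ in lengths)
        if total <= capacity or not lengths:
            break
        factor = (capacity - 3 * len(lengths)) / max(total - 3 * len(lengths), 1)
        lengths = [
            (max(lo, min(hi, int(l * factor))), c, lo, hi) for l, c, lo, hi in lengths
        ]
    if lengths and sum(3 * l + 3 for l, _, _, _ in lengths) > capacity:
        raise ConstructiveFailureError(
            f"{spec.genome_id}: {spec.n_cds} CDS cannot fit in {capacity} nt "
            "even at minimal protein sizes"
        )

    proteins = []
    for aa_len, is_cxxc, _, _ in lengths:
        residues = ["M"] + [
            _AA_NO_CYS[int(i)] for i in rng.integers(0, len(_AA_NO_CYS), size=aa_len - 1)
        ]
        if is_cxxc:
            pos = int(rng.integers(1, aa_len - 4))
            residues[pos] = "C"
            residues[pos + 3] = "C"
        proteins.append(("".join(residues), is_cxxc))
    return proteins


def _plan_layout(
    spec: SyntheticGenomeSpec,
    proteins: List[Tuple[str, bool]],
    rng: np.random.Generator,
) -> List[Tuple[str, object]]:
    """Alternate intergenic and CDS segments covering the whole genome.

    CDS are kept out of the terminal ``tdr_length`` bases (plus a buffer)
    so that planting the repeat never overwrites a coding region.
    """
    n = spec.length_bp
    region_start = _BUFFER if spec.n_cds else 0
    region_end = n - spec.tdr_length - _BUFFER if spec.n_cds else n
    cds_nts = [3 * len(aa) + 3 for aa, _ in proteins]
    min_gap = _MIN_GAP
    slack = (region_end - region_start) - sum(cds_nts) - min_gap * (len(proteins) + 1)
    if spec.n_cds and slack < 0:
        raise ConstructiveFailureError(
            f"{spec.genome_id}: {spec.n_cds} CDS do not fit in {region_end - region_start} bp"
        )
    layout: List[Tuple[str, object]] = []
    if spec.n_cds == 0:
        return [("intergenic", n)]
    extras = rng.multinomial(slack, np.full(len(proteins) + 1, 1.0 / (len(proteins) + 1)))
    layout.append(("intergenic", region_start + min_gap + int(extras[0])))
    for idx, (aa, _) in enumerate(proteins):
        layout.append(("cds", aa))
        tail = n - region_end if idx == len(proteins) - 1 else 0
        layout.append(("intergenic", min_gap + int(extras[idx + 1]) + tail))
    return layout


# ---------------------------------------------------------------------------
# Public operations

def generate_genome(spec: SyntheticGenomeSpec) -> GenomeRecord:
    """Generate one genome record from a spec, reproducibly from its seed."""
    rng = np.random.default_rng(spec.seed)
    P = _markov_transitions(spec.markov_order, spec.gc, rng)
    forbidden = _forbidden_tuples(spec.avoided_motifs)
    proteins = _plan_proteins(spec, rng)
    layout = _plan_layout(spec, proteins, rng)

    codon_lambda = 0.0
    if proteins:
        aa_counts: Dict[str, int] = {"M_start": len(proteins)}
        for aa_seq, _ in proteins:
            for res in aa_seq[1:]:
                aa_counts[res] = aa_counts.get(res, 0) + 1
        coding_nt = sum(3 * len(aa_seq) + 3 for aa_seq, _ in proteins)
        intergenic_nt = spec.length_bp - coding_nt
        codon_lambda = _solve_codon_lambda(
            aa_counts, len(proteins), coding_nt, intergenic_nt, spec.gc
        )

    emitter = _Emitter(P, spec.markov_order, forbidden, rng, codon_lambda=codon_lambda)
    features: List[CdsFeature] = []
    cds_idx = 0
    for kind, payload in layout:
        state = emitter.state()
        for attempt in range(200):
            emitter.restore(state)
            if kind == "intergenic":
                if emitter.emit_random(int(payload)):
                    break
            else:
                aa: str = payload  # type: ignore[assignment]
                slots = [["ATG"]] + [list(_SYNONYMOUS[res]) for res in aa[1:]] + [list(_STOP_CODONS)]
                if emitter.emit_codons(slots):
                    break
        else:
            raise ConstructiveFailureError(
                f"{spec.genome_id}: could not emit {kind} segment under the motif constraints"
            )
        if kind == "cds":
            cds_idx += 1
            start = state[0]
            features.append(
                CdsFeature(
                    locus_tag=f"{spec.genome_id}_{cds_idx * 5:04d}",
                    start=start,
                    end=len(emitter.seq),
                    strand="+",
                    product="hypothetical protein",
                    translation=payload,  # type: ignore[arg-type]
                )
            )

    seq = list("".join(_BASES[b] for b in emitter.seq))
    if spec.tdr_length:
        _plant_tdr(seq, spec.tdr_length, forbidden, rng, spec.genome_id)
    record = GenomeRecord(
        id=spec.genome_id,
        description=(
            f"synthetic genome seed={spec.seed} gc={spec.gc} order={spec.markov_order} "
            f"avoided={','.join(spec.avoided_motifs) or '-'} tdr={spec.tdr_length}"
        ),
        sequence="".join(seq),
        topology="linear",
        features=features,
    )
    _assert_avoided(record, spec.avoided_motifs)
    return record


def _find_violations(seq_str: str, words: Sequence[str], lo: int, hi: int) -> List[Tuple[int, str]]:
    out = []
    window = seq_str[max(0, lo) : hi]
    offset = max(0, lo)
    for w in words:
        start = 0
        while True:
            p = window.find(w, start)
            if p == -1:
                break
            out.append((offset + p, w))
            start = p + 1
    return out


def _plant_tdr(
    seq: List[str],
    tdr_len: int,
    forbidden: List[Tuple[int, int, int]],
    rng: np.random.Generator,
    genome_id: str,
) -> None:
    """Copy the leading ``tdr_len`` bases over the trailing ones, then repair
    any avoided-motif occurrence created at the copy junction.

    Only windows straddling the junction can violate (the copied interior
    is identical to the already-clean prefix), and every such window
    contains core-side bases that may be freely resampled.
    """
    n = len(seq)
    seq[n - tdr_len :] = seq[:tdr_len]
    words = _forbidden_words(forbidden)
    if not words:
        return
    maxlen = max(len(w) for w in words)
    junction = n - tdr_len
    for _ in range(200):
        violations = _find_violations(
            "".join(seq), words, junction - 2 * maxlen, junction + maxlen
        )
        if not violations:
            return
        pos, word = violations[0]
        targets = [t for t in range(pos, pos + len(word)) if t < junction]
        if not targets:
            raise ConstructiveFailureError(f"{genome_id}: junction violation inside the repeat")
        t = targets[int(rng.integers(len(targets)))]
        alternatives = [b for b in _BASES if b != seq[t]]
        seq[t] = alternatives[int(rng.integers(3))]
    raise ConstructiveFailureError(f"{genome_id}: could not repair TDR junction")


def _forbidden_words(forbidden: List[Tuple[int, int, int]]) -> List[str]:
    words = []
    for L, prefix_code, last in forbidden:
        chars = []
        code = prefix_code
        for _ in range(L - 1):
            chars.append(_BASES[code % 4])
            code //= 4
        words.append("".join(reversed(chars)) + _BASES[last])
    return words


def _assert_avoided(record: GenomeRecord, avoided: Sequence[str]) -> None:
    for m in avoided:
        m = m.upper()
        for w in {m, reverse_complement(m)}:
            if w in record.sequence:
                raise ConstructiveFailureError(
                    f"{record.id}: avoided motif {w} present after construction"
                )


def mutate(record: GenomeRecord, rate: float, seed: int) -> GenomeRecord:
    """Substitute each base independently with probability ``rate`` to a
    uniformly random different base. Features are dropped (the annotation
    no longer describes the mutated sequence); N positions are untouched."""
    if not (0.0 <= rate <= 0.5):
        raise ValueError("rate must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(record.sequence.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    hit &= arr != ord("N")
    idx = np.nonzero(hit)[0]
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    code = np.zeros(256, dtype=np.int64)
    for i, b in enumerate(base_bytes):
        code[b] = i
    shifts = rng.integers(1, 4, size=idx.size)
    arr[idx] = base_bytes[(code[arr[idx]] + shifts) % 4]
    return GenomeRecord(
        id=f"{record.id}_mut",
        description=f"{record.description} | mutated rate={rate} seed={seed}",
        sequence=arr.tobytes().decode(),
        topology=record.topology,
    )


def fixture_suite(out_dir: Union[str, Path], seed: int = 0) -> Dict:
    """Write a small standard fixture battery plus a manifest of planted truths.

    Regeneration with the same seed is byte-identical. Returns the manifest
    (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    avoided = generate_genome(
        SyntheticGenomeSpec(
            length_bp=10000, gc=0.57, markov_order=1,
            avoided_motifs=("GATC", "CTAG"), tdr_length=0, n_cds=0,
            cxxc_plant=(0, 0), seed=seed * 1000 + 1, name="fx_avoided",
        )
    )
    write_fasta(avoided, out / "avoided.fasta")
    tdr_spec = SyntheticGenomeSpec(
        length_bp=8000, gc=0.56, markov_order=1, avoided_motifs=(),
        tdr_length=306, n_cds=0, cxxc_plant=(0, 0), seed=seed * 1000 + 2, name="fx_tdr",
    )
    write_fasta(generate_genome(tdr_spec), out / "tdr.fasta")
    cxxc_spec = SyntheticGenomeSpec(
        length_bp=20000, gc=0.56, markov_order=1, avoided_motifs=("GATC",),
        tdr_length=0, n_cds=12, cxxc_plant=(5, 3), seed=seed * 1000 + 3, name="fx_cxxc",
    )
    write_genbank(generate_genome(cxxc_spec), out / "cxxc.gbk")
    pair_a = generate_genome(
        SyntheticGenomeSpec(
            length_bp=10000, gc=0.57, markov_order=1, avoided_motifs=(),
            tdr_length=0, n_cds=0, cxxc_plant=(0, 0), seed=seed * 1000 + 4, name="fx_pair_a",
        )
    )
    pair_b = mutate(pair_a, 0.05, seed * 1000 + 5)
    write_fasta(pair_a, out / "pair_a.fasta")
    write_fasta(pair_b, out / "pair_b.fasta")
    manifest = {
        "seed": seed,
        "files": {
            "avoided.fasta": {"avoided_motifs": ["GATC", "CTAG"], "length_bp": 10000},
            "tdr.fasta": {"tdr_length": 306, "length_bp": 8000},
            "cxxc.gbk": {"n_cds": 12, "n_cxxc_genes": 5, "n_micro_cxxc": 3, "length_bp": 20000},
            "pair_a.fasta": {"length_bp": 10000},
            "pair_b.fasta": {"mutated_from": "pair_a.fasta", "substitution_rate": 0.05},
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
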