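"""Synonymous recoding of a target window for RNAi resistance.

A knockdown/re-expression experiment needs a rescue construct whose mRNA
escapes the shRNA that silences the endogenous gene. Because silencing
requires near-perfect guide:mRNA pairing, wobble (synonymous) edits inside
the target window break recognition while leaving the encoded protein
untouched. This module formalizes that: for each codon overlapping the
target window, synonymous codons are searched to maximize, lexicographically,

    1. mismatches at seed-pairing positions (where mismatches abolish
       silencing most effectively),
    2. total mismatches in the window,
    3. codon-preference weight (uniform by default),

subject to not introducing forbidden motifs (Type IIS recognition sites,
long homopolymer runs) in the recoded window plus 6 nt of flanking context.
Violations already present in the original at the same coordinates are not
charged to the recoding.

The search is exact (exhaustive over the product of synonym sets) when the
window spans at most 8 codons and the product stays under 200,000
combinations; otherwise greedy per-codon with one repair pass. Both paths
are deterministic, breaking objective ties toward the lexicographically
smallest codon string.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import prod

from .seqio import CodonTable, NucSequence, revcomp, translate
from .site_finder import MatchModel

__all__ = ["RecodeRequest", "RecodedCDS", "recode_resistant"]

EXHAUSTIVE_CODON_SPAN = 8
EXHAUSTIVE_COMBO_CAP = 200_000
_CONTEXT_NT = 6


@dataclass(frozen=True)
class RecodeRequest:
    """Inputs for one recoding run.

    ``start``/``end`` delimit the target window on the CDS (0-based,
    half-open). ``seed_window_indices`` are window-relative positions that
    pair with the guide seed; when None they default to the standard model
    (guide positions 2-8) if the window has a valid guide length, else to
    none. ``codon_weights`` maps codon -> preference weight (uniform when
    empty).
    """

    cds: NucSequence
    start: int
    end: int
    min_mismatches: int = 0
    seed_window_indices: tuple[int, ...] | None = None
    forbidden_motifs: tuple[str, ...] = ("CGTCTC", "GAAGAC")
    homopolymer_threshold: int = 4
    codon_table: CodonTable | None = None
    codon_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.cds.seq)
        if n % 3 != 0:
            raise ValueError(f"CDS length {n} is not divisible by 3")
        if not 0 <= self.start < self.end <= n:
            raise ValueError(
                f"target interval [{self.start}, {self.end}) outside CDS of length {n}"
            )
        if self.min_mismatches < 0:
            raise ValueError("min_mismatches must be >= 0")
        if self.seed_window_indices is None:
            Lw = self.end - self.start
            try:
                idx = MatchModel(guide_length=Lw).seed_target_indices
            except ValueError:
                idx = ()
            object.__setattr__(self, "seed_window_indices", idx)
        else:
            object.__setattr__(
                self, "seed_window_indices", tuple(sorted(self.seed_window_indices))
            )
        Lw = self.end - self.start
        for i in self.seed_window_indices:
            if not 0 <= i < Lw:
                raise ValueError(f"seed index {i} outside window of length {Lw}")

    @property
    def table(self) -> CodonTable:
        return self.codon_table or _standard()


_STANDARD: CodonTable | None = None


def _standard() -> CodonTable:
    global _STANDARD
    if _STANDARD is None:
        _STANDARD = CodonTable.standard()
    return _STANDARD


@dataclass(frozen=True)
class RecodedCDS:
    """Result of a recoding run.

    ``success`` means ``mismatch_count >= min_mismatches`` with all
    constraints met; on failure the result still carries the best
    achievable recoding for inspection.
    """

    original: NucSequence
    recoded: NucSequence
    edited_codons: tuple[int, ...]
    mismatch_count: int
    seed_mismatch_count: int
    protein_preserved: bool
    success: bool
    motif_audit: tuple[str, ...] = ()


def _runs_at_least(seq: str, threshold: int) -> set[tuple[str, int, int]]:
    out = set()
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= threshold:
            out.add((seq[i], i, j - i))
        i = j
    return out


def _motif_hits(seq: str, motifs: tuple[str, ...]) -> set[tuple[str, str, int]]:
    hits = set()
    for motif in motifs:
        for m, strand in ((motif, "+"), (revcomp(motif), "-")):
            start = 0
            while True:
                p = seq.find(m, start)
                if p < 0:
                    break
                hits.add((motif, strand, p))
                start = p + 1
    return hits


class _Problem:
    """Shared state for one recoding search."""

    def __init__(self, req: RecodeRequest):
        self.req = req
        cds = req.cds.seq
        self.cds = cds
        self.c0 = req.start // 3
        self.c1 = (req.end + 2) // 3  # exclusive codon index
        self.ctx_lo = max(0, self.c0 * 3 - _CONTEXT_NT)
        self.ctx_hi = min(len(cds), self.c1 * 3 + _CONTEXT_NT)
        self.orig_codons = [cds[3 * i:3 * i + 3] for i in range(self.c0, self.c1)]
        table = req.table
        self.choices = [tuple(sorted(table.synonymous(c))) for c in self.orig_codons]
        orig_ctx = cds[self.ctx_lo:self.ctx_hi]
        self.base_motifs = _motif_hits(orig_ctx, req.forbidden_motifs)
        self.base_runs = _runs_at_least(orig_ctx, req.homopolymer_threshold)
        self.window = cds[req.start:req.end]
        # window-relative index -> position inside the codon block
        self.block_off = self.c0 * 3

    def context(self, codons: list[str]) -> str:
        block = "".join(codons)
        return (
            self.cds[self.ctx_lo:self.block_off]
            + block
            + self.cds[self.c1 * 3:self.ctx_hi]
        )

    def introduced(self, codons: list[str]) -> list[str]:
        ctx = self.context(codons)
        new_motifs = _motif_hits(ctx, self.req.forbidden_motifs) - self.base_motifs
        new_runs = _runs_at_least(ctx, self.req.homopolymer_threshold) - self.base_runs
        out = [f"motif {m} ({s}) at context pos {p}" for m, s, p in sorted(new_motifs)]
        out += [f"homopolymer {b}x{ln} at context pos {p}"
                for b, p, ln in sorted(new_runs)]
        return out

    def feasible(self, codons: list[str]) -> bool:
        return not self.introduced(codons)

    def objective(self, codons: list[str]) -> tuple:
        block = "".join(codons)
        req = self.req
        mm = seed_mm = 0
        seed = set(req.seed_window_indices)
        for w in range(req.end - req.start):
            g = req.start + w - self.block_off
            if block[g] != self.window[w]:
                mm += 1
                if w in seed:
                    seed_mm += 1
        weight = sum(req.codon_weights.get(c, 0.0) for c in codons)
        # negated block gives lexicographically-smallest tie-break under max
        return (seed_mm, mm, weight, tuple(-ord(ch) for ch in block))


def _search_exhaustive(p: _Problem) -> list[str]:
    best: list[str] | None = None
    best_obj: tuple | None = None
    for combo in itertools.product(*p.choices):
        codons = list(combo)
        obj = p.objective(codons)
        if best_obj is not None and obj <= best_obj:
            continue
        if p.feasible(codons):
            best, best_obj = codons, obj
    if best is None:  # original is always feasible (introduces nothing)
        best = list(p.orig_codons)
    return best


def _greedy_pass(p: _Problem, codons: list[str]) -> list[str]:
    for i in range(len(codons)):
        best_c = codons[i]
        trial = list(codons)
        trial[i] = best_c
        best_obj = p.objective(trial)
        for c in p.choices[i]:
            trial[i] = c
            obj = p.objective(trial)
            if obj > best_obj and p.feasible(trial):
                best_c, best_obj = c, obj
        codons[i] = best_c
    return codons


def _search_greedy(p: _Problem) -> list[str]:
    codons = list(p.orig_codons)
    codons = _greedy_pass(p, codons)
    codons = _greedy_pass(p, codons)  # one repair pass over the final context
    return codons


def recode_resistant(req: RecodeRequest) -> RecodedCDS:
    """Maximally recode the target window under synonymous constraints.

    ``min_mismatches == 0`` is a vacuous requirement: the original CDS is
    returned unedited. Otherwise the optimizer maximizes (seed mismatches,
    total mismatches, codon preference) and success is reported when the
    achieved mismatch count reaches ``min_mismatches``; an unattainable
    requirement (e.g. a window of Met/Trp codons) yields ``success=False``
    carrying the best achievable recoding.
    """
    orig = req.cds
    if req.min_mismatches == 0:
        return RecodedCDS(
            original=orig,
            recoded=orig,
            edited_codons=(),
            mismatch_count=0,
            seed_mismatch_count=0,
            protein_preserved=True,
            success=True,
        )
    p = _Problem(req)
    n_codons = p.c1 - p.c0
    n_combos = prod(len(ch) for ch in p.choices)
    if n_codons <= EXHAUSTIVE_CODON_SPAN and n_combos <= EXHAUSTIVE_COMBO_CAP:
        codons = _search_exhaustive(p)
    else:
        codons = _search_greedy(p)

    block = "".join(codons)
    recoded_seq = orig.seq[:p.block_off] + block + orig.seq[p.c1 * 3:]
    recoded = NucSequence(
        id=f"{orig.id}_recoded", seq=recoded_seq, description=orig.description
    )
    edited = tuple(
        p.c0 + i for i, c in enumerate(codons) if c != p.orig_codons[i]
    )
    seed = set(req.seed_window_indices)
    mm = sum(
        1 for w in range(req.end - req.start)
        if recoded_seq[req.start + w] != orig.seq[req.start + w]
    )
    seed_mm = sum(
        1 for w in seed if recoded_seq[req.start + w] != orig.seq[req.start + w]
    )
    preserved = translate(recoded_seq, req.table, allow_stop=True) == translate(
        orig.seq, req.table, allow_stop=True
    )
    return RecodedCDS(
        original=orig,
        recoded=recoded,
        edited_codons=edited,
        mismatch_count=mm,
        seed_mismatch_count=seed_mm,
        protein_preserved=preserved,
        success=mm >= req.min_mismatches,
        motif_audit=tuple(p.introduced(codons)),
    )
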