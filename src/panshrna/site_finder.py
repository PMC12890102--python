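"""Candidate target-site enumeration with per-isoform coverage.

The design problem: find one L-nt window (default L=22, the length used for
the validated histone targets) on a reference isoform whose sequence is
present — exactly, or within a small mismatch budget outside an exact seed —
in every isoform of the family, so a single shRNA silences all of them.

Matching model
--------------
RNAi silencing relies on base-pairing between the guide (the reverse
complement of the target site, loaded into RISC) and the mRNA. Pairing at
guide positions 2-8, the seed, dominates target recognition, so the default
model demands zero mismatches at target positions pairing with the seed and
tolerates up to ``max_mismatches`` (default 2) elsewhere. Only the sense
strand of each isoform is scanned: shRNAs act on mRNA.

Coordinates are 0-based half-open on the reference; guide positions are
1-based 5'->3' on the guide, the field's convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .family_profile import TranscriptFamily
from .seqio import NucSequence, revcomp

__all__ = [
    "MatchModel",
    "MatchRecord",
    "CandidateSite",
    "match_isoform",
    "count_matches",
    "enumerate_candidates",
    "candidates_to_dataframe",
]


@dataclass(frozen=True)
class MatchModel:
    """Guide length, mismatch budget and seed definition.

    ``seed_start``/``seed_end`` are inclusive 1-based guide positions;
    guide position g pairs with target-window position L - g (0-based).
    """

    guide_length: int = 22
    max_mismatches: int = 2
    seed_start: int = 2
    seed_end: int = 8
    require_seed_exact: bool = True

    def __post_init__(self) -> None:
        L = self.guide_length
        if not 19 <= L <= 25:
            raise ValueError(f"guide_length must be in [19, 25], got {L}")
        if not 0 <= self.max_mismatches < L:
            raise ValueError(f"max_mismatches must be in [0, {L - 1}]")
        if not 1 <= self.seed_start <= self.seed_end <= L:
            raise ValueError(
                f"seed range [{self.seed_start}, {self.seed_end}] outside guide [1, {L}]"
            )

    @property
    def seed_target_indices(self) -> tuple[int, ...]:
        """0-based target-window positions pairing with the guide seed."""
        L = self.guide_length
        return tuple(sorted(L - g for g in range(self.seed_start, self.seed_end + 1)))

    def guide_position(self, target_index: int) -> int:
        """1-based guide position pairing with a 0-based target-window index."""
        return self.guide_length - target_index


@dataclass(frozen=True)
class MatchRecord:
    """Best hit of one target site in one isoform."""

    isoform_id: str
    position: int
    mismatches: int
    mismatch_guide_positions: tuple[int, ...] = ()


@dataclass(frozen=True)
class CandidateSite:
    """One candidate target window on the reference isoform.

    ``matches`` maps isoform id -> best :class:`MatchRecord`; isoforms with
    no admissible hit are absent. ``coverage`` is the number matched.
    """

    ref_id: str
    start: int
    end: int
    target_sense: str
    guide: str
    matches: dict[str, MatchRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.target_sense):
            raise ValueError("interval length differs from target length")
        if self.guide != revcomp(self.target_sense):
            raise ValueError("guide is not the reverse complement of target_sense")

    @property
    def coverage(self) -> int:
        return len(self.matches)

    @classmethod
    def from_target(cls, target_sense: str, ref_id: str = "ref", start: int = 0,
                    matches: dict[str, MatchRecord] | None = None) -> "CandidateSite":
        """Convenience constructor from a bare target sequence."""
        return cls(
            ref_id=ref_id,
            start=start,
            end=start + len(target_sense),
            target_sense=target_sense,
            guide=revcomp(target_sense),
            matches=matches or {},
        )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _window_view(enc: np.ndarray, L: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(enc, L)


def match_isoform(
    target_sense: str, isoform: NucSequence, model: MatchModel
) -> MatchRecord | None:
    """Best admissible hit of ``target_sense`` in one isoform, or None.

    Scans every L-window of the isoform's sense strand; a window is
    admissible if its mismatch count is within budget and, when seed
    exactness is required, the seed-pairing positions match perfectly.
    Ties on mismatch count resolve to the smallest position.
    """
    L = model.guide_length
    if len(target_sense) != L:
        raise ValueError(f"target length {len(target_sense)} != model length {L}")
    if len(isoform.seq) < L:
        return None
    t = _encode(NucSequence("t", target_sense).seq)
    win = _window_view(_encode(isoform.seq), L)
    neq = win != t
    mm = neq.sum(axis=1)
    ok = mm <= model.max_mismatches
    if model.require_seed_exact:
        seed_idx = np.asarray(model.seed_target_indices)
        ok &= ~neq[:, seed_idx].any(axis=1)
    if not ok.any():
        return None
    masked = np.where(ok, mm, L + 1)
    pos = int(masked.argmin())  # argmin returns the first (smallest) position
    bad = np.nonzero(neq[pos])[0]
    gpos = tuple(sorted(model.guide_position(int(i)) for i in bad))
    return MatchRecord(
        isoform_id=isoform.id,
        position=pos,
        mismatches=int(mm[pos]),
        mismatch_guide_positions=gpos,
    )


def count_matches(target_sense: str, isoform: NucSequence, model: MatchModel) -> int:
    """Number of admissible windows (not just the best one) in an isoform."""
    L = model.guide_length
    if len(target_sense) != L:
        raise ValueError(f"target length {len(target_sense)} != model length {L}")
    if len(isoform.seq) < L:
        return 0
    t = _encode(NucSequence("t", target_sense).seq)
    win = _window_view(_encode(isoform.seq), L)
    neq = win != t
    ok = neq.sum(axis=1) <= model.max_mismatches
    if model.require_seed_exact:
        seed_idx = np.asarray(model.seed_target_indices)
        ok &= ~neq[:, seed_idx].any(axis=1)
    return int(ok.sum())


def enumerate_candidates(
    fam: TranscriptFamily,
    ref_id: str,
    model: MatchModel = MatchModel(),
    min_coverage: int | None = None,
) -> list[CandidateSite]:
    """All reference windows whose isoform coverage meets ``min_coverage``.

    Every L-window of the reference isoform is matched against every isoform
    (including the reference itself, which always matches exactly). Default
    ``min_coverage`` is the family size: sites expected to silence all
    isoforms. Output is sorted by (coverage desc, start asc).

    The inner loop is vectorised: per isoform, the full (reference windows x
    isoform windows) mismatch-count matrix is accumulated column-by-column.
    """
    ref = fam.get(ref_id)
    n = len(fam)
    if min_coverage is None:
        min_coverage = n
    if not 1 <= min_coverage <= n:
        raise ValueError(f"min_coverage must be in [1, {n}], got {min_coverage}")
    L = model.guide_length
    if len(ref.seq) < L:
        return []
    ref_enc = _encode(ref.seq)
    R = len(ref.seq) - L + 1
    seed_idx = set(model.seed_target_indices)

    best_pos = np.full((n, R), -1, dtype=np.int64)
    best_mm = np.full((n, R), L + 1, dtype=np.int64)
    for iso_i, iso in enumerate(fam.isoforms):
        if len(iso.seq) < L:
            continue
        iso_enc = _encode(iso.seq)
        W = len(iso.seq) - L + 1
        mm = np.zeros((R, W), dtype=np.int16)
        seed_mm = np.zeros((R, W), dtype=np.int16)
        for j in range(L):
            col_ne = ref_enc[j:j + R][:, None] != iso_enc[j:j + W][None, :]
            mm += col_ne
            if j in seed_idx:
                seed_mm += col_ne
        ok = mm <= model.max_mismatches
        if model.require_seed_exact:
            ok &= seed_mm == 0
        masked = np.where(ok, mm, L + 1).astype(np.int64)
        pos = masked.argmin(axis=1)
        val = masked[np.arange(R), pos]
        hit = val <= model.max_mismatches
        best_pos[iso_i, hit] = pos[hit]
        best_mm[iso_i, hit] = val[hit]

    matched = best_mm <= model.max_mismatches
    coverage = matched.sum(axis=0)
    keep = np.nonzero(coverage >= min_coverage)[0]
    order = sorted(keep, key=lambda s: (-int(coverage[s]), int(s)))

    sites: list[CandidateSite] = []
    for s in order:
        target = ref.seq[s:s + L]
        t_enc = ref_enc[s:s + L]
        records: dict[str, MatchRecord] = {}
        for iso_i, iso in enumerate(fam.isoforms):
            if not matched[iso_i, s]:
                continue
            p = int(best_pos[iso_i, s])
            w = _encode(iso.seq)[p:p + L]
            bad = np.nonzero(w != t_enc)[0]
            records[iso.id] = MatchRecord(
                isoform_id=iso.id,
                position=p,
                mismatches=int(best_mm[iso_i, s]),
                mismatch_guide_positions=tuple(
                    sorted(model.guide_position(int(i)) for i in bad)
                ),
            )
        sites.append(
            CandidateSite(
                ref_id=ref.id,
                start=int(s),
                end=int(s) + L,
                target_sense=target,
                guide=revcomp(target),
                matches=records,
            )
        )
    return sites


def candidates_to_dataframe(sites: list[CandidateSite]) -> pd.DataFrame:
    """Tabular report: one row per candidate, 1-based coordinates included."""
    rows = []
    for c in sites:
        mm_summary = ";".join(
            f"{r.isoform_id}@{r.position}:{r.mismatches}"
            for r in c.matches.values()
        )
        rows.append(
            {
                "ref_id": c.ref_id,
                "start0": c.start,
                "end0": c.end,
                "start1": c.start + 1,
                "end1": c.end,
                "target_sense": c.target_sense,
                "guide": c.guide,
                "coverage": c.coverage,
                "matches": mm_summary,
            }
        )
    return pd.DataFrame(rows)
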