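"""Seed-complement off-target counting in a transcriptome.

A guide can repress unintended transcripts through seed pairing alone, so a
cheap triage statistic for shortlisted candidates is the number of exact
seed-complement occurrences across a transcriptome. The seed k-mer is the
guide's positions 2-8 by default (matching the site-search model); its
reverse complement is counted, overlapping occurrences included, on the
sense strand of every transcript. Optionally, full-length near-matches
(within the model's mismatch budget) are counted as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .seqio import NucSequence, revcomp
from .site_finder import MatchModel, count_matches

__all__ = ["OffTargetReport", "seed_offtarget_scan"]


@dataclass(frozen=True)
class OffTargetReport:
    """Per-transcript seed-complement hit counts for one guide."""

    guide: str
    seed_guide_range: tuple[int, int]
    seed_target_kmer: str
    per_transcript: dict[str, int] = field(default_factory=dict)
    near_matches: dict[str, int] | None = None

    @property
    def total_hits(self) -> int:
        return sum(self.per_transcript.values())

    @property
    def total_near_matches(self) -> int | None:
        if self.near_matches is None:
            return None
        return sum(self.near_matches.values())

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"transcript": t, "seed_hits": c}
            for t, c in self.per_transcript.items()
        ]
        df = pd.DataFrame(rows, columns=["transcript", "seed_hits"])
        if self.near_matches is not None:
            df["near_matches"] = [self.near_matches[t] for t in df["transcript"]]
        return df


def _count_overlapping(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        p = haystack.find(needle, start)
        if p < 0:
            return count
        count += 1
        start = p + 1


def seed_offtarget_scan(
    guide: str,
    transcripts: list[NucSequence],
    model: MatchModel = MatchModel(),
    include_near_matches: bool = False,
) -> OffTargetReport:
    """Count seed-complement occurrences of ``guide`` per transcript.

    An empty transcript set is a valid input and yields a zero-total
    report. Counts are independent per record, so they are invariant to
    transcript order and additive across transcript sets.
    """
    guide = NucSequence("g", guide).seq
    if len(guide) != model.guide_length:
        raise ValueError(
            f"guide length {len(guide)} != model length {model.guide_length}"
        )
    seed_kmer = guide[model.seed_start - 1:model.seed_end]
    target_kmer = revcomp(seed_kmer)
    per = {t.id: _count_overlapping(t.seq, target_kmer) for t in transcripts}
    near = None
    if include_near_matches:
        target_sense = revcomp(guide)
        near = {t.id: count_matches(target_sense, t, model) for t in transcripts}
    return OffTargetReport(
        guide=guide,
        seed_guide_range=(model.seed_start, model.seed_end),
        seed_target_kmer=target_kmer,
        per_transcript=per,
        near_matches=near,
    )
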