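"""Isoform-count and isoform-similarity profiling of a transcript family.

A multi-copy gene family (the motivating case: the canonical histones, with
6-22 genes per histone depending on species) is targetable by a single shRNA
only if its isoforms are similar enough that one ~22-nt window is conserved.
This module quantifies that: the full pairwise percent-identity matrix of a
family and its mean over unordered pairs.

Percent identity is computed from a global (end-to-end) alignment scored
match=+1, mismatch=0, linear gap=-1, as 100 * matches / alignment_length.
CDS isoforms of one family are near-equal length, so the end-to-end reading
is the natural one; an alternative denominator (the shorter sequence) is
config-selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from Bio import Align

from .seqio import NucSequence, SequenceError

__all__ = [
    "TranscriptFamily",
    "SimilarityReport",
    "AlignmentConfig",
    "pairwise_identity",
    "profile_family",
]


@dataclass(frozen=True)
class TranscriptFamily:
    """A named, ordered set of isoform sequences of one gene family."""

    name: str
    isoforms: tuple[NucSequence, ...]

    def __post_init__(self) -> None:
        isoforms = tuple(self.isoforms)
        object.__setattr__(self, "isoforms", isoforms)
        if not isoforms:
            raise ValueError(f"family {self.name!r} has no isoforms")
        ids = [s.id for s in isoforms]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate isoform ids in family {self.name!r}: {dupes}")

    def __len__(self) -> int:
        return len(self.isoforms)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.isoforms)

    def get(self, isoform_id: str) -> NucSequence:
        for s in self.isoforms:
            if s.id == isoform_id:
                return s
        raise KeyError(f"isoform {isoform_id!r} not in family {self.name!r}")


@dataclass(frozen=True)
class AlignmentConfig:
    """Scoring scheme for the identity metric."""

    match: float = 1.0
    mismatch: float = 0.0
    gap: float = -1.0
    #: identity denominator: full alignment length, or the shorter sequence
    denominator: Literal["alignment", "shorter"] = "alignment"

    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = "global"
        al.match_score = self.match
        al.mismatch_score = self.mismatch
        al.open_gap_score = self.gap
        al.extend_gap_score = self.gap
        return al


_DEFAULT_CONFIG = AlignmentConfig()


def pairwise_identity(
    a: NucSequence | str,
    b: NucSequence | str,
    config: AlignmentConfig = _DEFAULT_CONFIG,
) -> float:
    """Percent identity (0..100) between two sequences under global alignment.

    The first optimal alignment enumerated by the aligner is used; the
    enumeration order is deterministic, so the value is reproducible.
    Symmetric in (a, b) because scoring is symmetric.
    """
    sa = a.seq if isinstance(a, NucSequence) else a
    sb = b.seq if isinstance(b, NucSequence) else b
    if not sa or not sb:
        raise SequenceError("cannot compute identity of an empty sequence")
    if sa == sb:
        return 100.0
    aln = config.aligner().align(sa, sb)[0]
    counts = aln.counts()
    if config.denominator == "alignment":
        denom = aln.length
    else:
        denom = min(len(sa), len(sb))
    return 100.0 * counts.identities / denom


@dataclass(frozen=True)
class SimilarityReport:
    """Pairwise identity matrix and mean for one family.

    ``matrix`` is symmetric with a 100.0 diagonal, ordered as ``ids``;
    ``mean_identity`` is the mean over unordered distinct pairs (100.0 by
    definition for a single-isoform family).
    """

    family: str
    ids: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)
    mean_identity: float = 0.0

    @property
    def n_isoforms(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.ids), columns=list(self.ids))

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write(f"# family\t{self.family}\n")
            fh.write(f"# n_isoforms\t{self.n_isoforms}\n")
            fh.write(f"# mean_identity\t{self.mean_identity:.4f}\n")
            df.to_csv(fh, sep="\t", float_format="%.4f")


def profile_family(
    fam: TranscriptFamily, config: AlignmentConfig = _DEFAULT_CONFIG
) -> SimilarityReport:
    """Full pairwise identity matrix and mean identity of a family."""
    n = len(fam)
    mat = np.full((n, n), 100.0)
    vals: list[float] = []
    for i in range(n):
        for j in range(i + 1, n):
            pid = pairwise_identity(fam.isoforms[i], fam.isoforms[j], config)
            mat[i, j] = mat[j, i] = pid
            vals.append(pid)
    mean = float(np.mean(vals)) if vals else 100.0
    return SimilarityReport(
        family=fam.name, ids=fam.ids, matrix=mat, mean_identity=mean
    )
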