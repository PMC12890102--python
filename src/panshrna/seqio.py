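"""Sequence I/O and elementary sequence operations.

All sequences handled by this package live in the DNA alphabet {A, C, G, T}.
RNA input is accepted and normalized (U -> T) on the way in, because target
sites, guides and cloning oligos are conventionally written as DNA even when
they describe RNA species. IUPAC ambiguity codes are rejected: an ambiguous
base cannot be matched or scored by the design rules.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO as _BioSeqIO

__all__ = [
    "NucSequence",
    "CodonTable",
    "SequenceError",
    "read_fasta",
    "write_fasta",
    "revcomp",
    "translate",
    "gc_fraction",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_BASES = frozenset("ACGT")

#: FASTA line width on output; conventional and round-trip stable.
FASTA_WRAP = 60


class SequenceError(ValueError):
    """Raised for malformed sequence input (alphabet, framing, format)."""


def _normalize(raw: str, *, label: str = "<sequence>") -> str:
    """Uppercase, map U->T, and validate the DNA alphabet.

    Raises :class:`SequenceError` naming the offending record and 0-based
    position on the first illegal character.
    """
    seq = raw.upper().replace("U", "T")
    for pos, ch in enumerate(seq):
        if ch not in _VALID_BASES:
            raise SequenceError(
                f"illegal character {ch!r} at position {pos} in record {label!r}"
            )
    return seq


@dataclass(frozen=True)
class NucSequence:
    """A named DNA sequence.

    The sequence is normalized on construction: uppercased, U mapped to T,
    anything outside A/C/G/T is a hard error.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if not self.seq:
            raise SequenceError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "seq", _normalize(self.seq, label=self.id))

    def __len__(self) -> int:
        return len(self.seq)

    def revcomp(self) -> "NucSequence":
        return NucSequence(self.id, revcomp(self.seq), self.description)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string. ``revcomp(revcomp(s)) == s``."""
    seq = _normalize(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases in ``seq`` (0..1)."""
    seq = _normalize(seq)
    return (seq.count("G") + seq.count("C")) / len(seq)


def read_fasta(path: str | Path | TextIO) -> list[NucSequence]:
    """Read a (multi-)FASTA file into a list of :class:`NucSequence`.

    Record order is preserved. Sequences are normalized (case, U->T);
    duplicate ids, empty files and illegal characters are hard errors.
    """
    if hasattr(path, "read"):
        handle: TextIO = path  # type: ignore[assignment]
        records = list(_BioSeqIO.parse(handle, "fasta"))
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(p)
        with p.open() as fh:
            records = list(_BioSeqIO.parse(fh, "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records found in {path!r}")
    out: list[NucSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].lstrip()
        out.append(NucSequence(id=rec.id, seq=str(rec.seq), description=desc))
    return out


def write_fasta(records: Iterable[NucSequence], path: str | Path | TextIO) -> None:
    """Write records as FASTA, wrapped at ``FASTA_WRAP`` columns."""
    recs = list(records)
    buf = io.StringIO()
    for rec in recs:
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        buf.write(f">{header}\n")
        for i in range(0, len(rec.seq), FASTA_WRAP):
            buf.write(rec.seq[i:i + FASTA_WRAP] + "\n")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)  # type: ignore[union-attr]
    else:
        Path(path).write_text(text)


# ---------------------------------------------------------------------------
# Codon table


@dataclass(frozen=True)
class CodonTable:
    """Standard-genetic-code style codon table.

    ``mapping`` covers all 64 codons (stops map to ``*``); ``synonyms``
    partitions the 61 sense codons by amino acid.
    """

    mapping: dict[str, str]
    synonyms: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.mapping) != 64:
            raise SequenceError(
                f"codon table must map all 64 codons, got {len(self.mapping)}"
            )
        stops = [c for c, aa in self.mapping.items() if aa == "*"]
        if len(stops) != 3:
            raise SequenceError(f"expected 3 stop codons, found {len(stops)}")
        if not self.synonyms:
            syn: dict[str, list[str]] = {}
            for codon, aa in sorted(self.mapping.items()):
                if aa != "*":
                    syn.setdefault(aa, []).append(codon)
            object.__setattr__(
                self, "synonyms", {aa: tuple(cs) for aa, cs in syn.items()}
            )

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.mapping.items() if aa == "*"))

    def aa(self, codon: str) -> str:
        codon = _normalize(codon)
        if len(codon) != 3:
            raise SequenceError(f"codon must be a 3-mer, got {codon!r}")
        return self.mapping[codon]

    def synonymous(self, codon: str) -> tuple[str, ...]:
        """All codons encoding the same amino acid (including ``codon``)."""
        aa = self.aa(codon)
        if aa == "*":
            return tuple(c for c in self.stop_codons)
        return self.synonyms[aa]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodonTable":
        mapping: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            codon, aa = line.split("\t")
            mapping[_normalize(codon)] = aa.strip()
        return cls(mapping=mapping)

    @classmethod
    def standard(cls) -> "CodonTable":
        """The standard genetic code, loaded from the bundled TSV."""
        with resources.as_file(
            resources.files("panshrna.data") / "standard_codon_table.tsv"
        ) as p:
            return cls.from_tsv(p)


def translate(cds: str, table: CodonTable | None = None, *, allow_stop: bool = False) -> str:
    """Translate a CDS string into amino acids.

    Length must be divisible by 3. An internal stop codon is an error unless
    ``allow_stop`` is set, in which case stops appear as ``*``. A single stop
    at the very end is always allowed.
    """
    table = table or CodonTable.standard()
    cds = _normalize(cds)
    if len(cds) % 3 != 0:
        raise SequenceError(f"CDS length {len(cds)} is not divisible by 3")
    protein = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        aa = table.aa(cds[3 * i: 3 * i + 3])
        if aa == "*" and i < n_codons - 1 and not allow_stop:
            raise SequenceError(f"internal stop codon at codon index {i}")
        protein.append(aa)
    return "".join(protein)
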