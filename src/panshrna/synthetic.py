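"""Synthetic histone-family-like fixtures.

Real multi-copy gene families (e.g. the chicken canonical histones: 6-9
genes per histone at roughly 76-99% pairwise identity) are emulated by a
star-shaped substitution model: one random ancestor, each isoform derived
by i.i.d. per-site substitution at a fixed rate, substitutions drawn
uniformly among the three alternative bases. Optionally one or more windows
are planted verbatim into every isoform, emulating the conserved stretches
that make a single pan-isoform shRNA possible.

Under this model the expected pairwise identity of two isoforms at
divergence d is (1-d)^2 + d^2/3 per unplanted site (both unmutated, or both
mutated to the same alternative), which the test-suite checks empirically.

All randomness flows from the single integer seed in the spec; same spec,
same output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .family_profile import TranscriptFamily
from .seqio import NucSequence

__all__ = [
    "PlantedWindow",
    "FamilySimSpec",
    "SimulatedFamily",
    "simulate_family",
    "simulate_orf",
    "expected_identity",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedWindow:
    """A window copied into the simulated family.

    With ``required_coverage`` the window is inserted verbatim into every
    isoform at a common offset and shielded from substitution, guaranteeing
    a full-coverage target site; otherwise it is placed in the ancestor only
    and diverges like any other sequence.
    """

    seq: str
    required_coverage: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", NucSequence("w", self.seq).seq)


@dataclass(frozen=True)
class FamilySimSpec:
    """Parameters of one simulated family."""

    n_isoforms: int = 8
    length: int = 500
    per_site_divergence: float = 0.1
    planted_windows: tuple[PlantedWindow, ...] = ()
    seed: int = 0
    name: str = "simfam"

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_windows", tuple(
            w if isinstance(w, PlantedWindow) else PlantedWindow(*w)
            for w in self.planted_windows
        ))
        if not 1 <= self.n_isoforms <= 64:
            raise ValueError(f"n_isoforms must be in [1, 64], got {self.n_isoforms}")
        if not 0.0 <= self.per_site_divergence <= 1.0:
            raise ValueError("per_site_divergence must be in [0, 1]")
        longest = max((len(w.seq) for w in self.planted_windows), default=0)
        if self.length < longest:
            raise ValueError(
                f"length {self.length} shorter than longest planted window ({longest})"
            )
        if self.length < 1:
            raise ValueError("length must be positive")


@dataclass(frozen=True)
class SimulatedFamily:
    """A simulated family plus the manifest of planted-window offsets."""

    family: TranscriptFamily
    offsets: dict[str, int] = field(default_factory=dict)
    spec: FamilySimSpec | None = None

    def manifest(self) -> dict:
        return {
            "family": self.family.name,
            "n_isoforms": len(self.family),
            "planted_windows": [
                {"seq": w, "offset": off} for w, off in self.offsets.items()
            ],
        }


def expected_identity(divergence: float) -> float:
    """Closed-form expected per-site identity between two simulated isoforms."""
    d = divergence
    return (1.0 - d) ** 2 + d * d / 3.0


def _plant_offsets(spec: FamilySimSpec, rng: np.random.Generator) -> dict[str, int]:
    """Choose one non-overlapping offset per planted window."""
    taken: list[tuple[int, int]] = []
    offsets: dict[str, int] = {}
    for w in spec.planted_windows:
        L = len(w.seq)
        candidates = np.arange(spec.length - L + 1)
        rng.shuffle(candidates)
        placed = False
        for off in candidates:
            off = int(off)
            if all(off + L <= s or off >= e for s, e in taken):
                taken.append((off, off + L))
                offsets[w.seq] = off
                placed = True
                break
        if not placed:
            raise ValueError("could not place planted windows without overlap")
    return offsets


def simulate_family(spec: FamilySimSpec) -> SimulatedFamily:
    """Simulate a gene family under the star substitution model.

    Every isoform descends independently from one random ancestor; planted
    windows with ``required_coverage`` are copied verbatim into all isoforms
    at a shared offset recorded in the returned manifest.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = rng.choice(_BASES, size=spec.length)
    offsets = _plant_offsets(spec, rng)

    protected = np.zeros(spec.length, dtype=bool)
    for w in spec.planted_windows:
        off = offsets[w.seq]
        arr = np.frombuffer(w.seq.encode(), dtype=np.uint8)
        ancestor[off:off + len(arr)] = arr
        if w.required_coverage:
            protected[off:off + len(arr)] = True

    isoforms = []
    width = len(str(spec.n_isoforms))
    for i in range(spec.n_isoforms):
        seq = ancestor.copy()
        mutate = (rng.random(spec.length) < spec.per_site_divergence) & ~protected
        idx = np.nonzero(mutate)[0]
        if idx.size:
            # shift by 1..3 in base space: uniform over the 3 alternatives
            cur = np.searchsorted(_BASES, seq[idx])
            new = (cur + rng.integers(1, 4, size=idx.size)) % 4
            seq[idx] = _BASES[new]
        isoforms.append(
            NucSequence(
                id=f"{spec.name}_iso{str(i + 1).zfill(width)}",
                seq=seq.tobytes().decode(),
            )
        )
    fam = TranscriptFamily(name=spec.name, isoforms=tuple(isoforms))
    return SimulatedFamily(family=fam, offsets=offsets, spec=spec)


def simulate_orf(n_codons: int, seed: int = 0) -> NucSequence:
    """Random ORF: ATG + (n_codons - 2) random sense codons + one stop.

    ``n_codons`` counts start and stop; no internal stop codons occur, so
    the output always translates cleanly.
    """
    if n_codons < 2:
        raise ValueError(f"an ORF needs at least start + stop, got {n_codons} codons")
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(chr(b) for b in rng.choice(_BASES, size=3))
        if c not in stops:
            codons.append(c)
    codons.append(sorted(stops)[int(rng.integers(0, 3))])
    return NucSequence(id=f"orf_{n_codons}c_s{seed}", seq="".join(codons))
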