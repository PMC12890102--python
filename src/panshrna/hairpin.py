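"""miR-30 hairpin assembly and Golden-Gate-ready oligo generation.

A chosen target site is embedded into a shortened miR-30-style scaffold:

    5'flank | sense arm (= target site) | loop | antisense arm (= guide) | 3'flank

The two arms are exact reverse complements, so the transcript folds into the
stem-loop that the microRNA machinery processes into the guide. Inserts are
cloned by Golden Gate with a Type IIS enzyme (default Esp3I, recognition
CGTCTC) whose 4-nt overhangs are encoded at the flank ends; because the
enzyme cuts outside its recognition site, ligation of compatible overhangs
leaves no site behind ("self-destructing" junctions), which is what allows
scar-based multimerization of several hairpins in one cassette.

The bundled backbone is a synthetic default (canonical miR-30 arm context
and loop with this package's overhang choices), not a transcription of any
published construct; supply your own :class:`BackboneSpec` for bit-exact
cloning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .seqio import NucSequence, revcomp
from .site_finder import CandidateSite

__all__ = [
    "BackboneSpec",
    "HairpinConstruct",
    "SiteViolation",
    "build_hairpin",
    "chain_multimer",
    "scan_enzyme_sites",
    "default_backbone",
]


@dataclass(frozen=True)
class SiteViolation:
    """An enzyme recognition site found where none may be."""

    motif: str
    strand: str  # '+' or '-'
    position: int  # 0-based on the + strand of the scanned sequence


def scan_enzyme_sites(seq: str, site: str) -> list[SiteViolation]:
    """All occurrences of ``site`` on either strand of ``seq``.

    Minus-strand hits are reported at the +-strand coordinate of the
    occurrence of the reverse-complemented motif.
    """
    out: list[SiteViolation] = []
    for motif, strand in ((site, "+"), (revcomp(site), "-")):
        start = 0
        while True:
            p = seq.find(motif, start)
            if p < 0:
                break
            out.append(SiteViolation(motif=site, strand=strand, position=p))
            start = p + 1
    return sorted(out, key=lambda v: (v.position, v.strand))


def _is_palindromic(overhang: str) -> bool:
    return revcomp(overhang) == overhang


@dataclass(frozen=True)
class BackboneSpec:
    """Hairpin scaffold plus Golden Gate geometry.

    The upstream overhang is the first ``overhang_length`` nt of the 5'
    flank; the downstream overhang the last of the 3' flank (these are the
    single-stranded ends left after Type IIS excision). ``multimer_junctions``
    lists (downstream, upstream) overhang pairs declared ligatable; the
    default backbone declares its own pair, with upstream = revcomp(downstream)
    as sticky-end complementarity dictates.
    """

    name: str
    flank5: str
    loop: str
    flank3: str
    enzyme_name: str = "Esp3I"
    enzyme_site: str = "CGTCTC"
    overhang_length: int = 4
    upstream_overhang: str = ""
    downstream_overhang: str = ""
    multimer_junctions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for attr in ("flank5", "loop", "flank3", "enzyme_site"):
            object.__setattr__(self, attr, NucSequence("x", getattr(self, attr)).seq)
        ov = self.overhang_length
        up = self.upstream_overhang or self.flank5[:ov]
        down = self.downstream_overhang or self.flank3[-ov:]
        object.__setattr__(self, "upstream_overhang", up)
        object.__setattr__(self, "downstream_overhang", down)
        object.__setattr__(
            self,
            "multimer_junctions",
            tuple((d, u) for d, u in self.multimer_junctions),
        )
        if len(up) != ov or len(down) != ov:
            raise ValueError(f"overhangs must be {ov}-mers")
        if up == down:
            raise ValueError("upstream and downstream overhangs must differ")
        if _is_palindromic(up) or _is_palindromic(down):
            raise ValueError("overhangs must be non-palindromic")
        if self.flank5[:ov] != up or self.flank3[-ov:] != down:
            raise ValueError("overhangs must coincide with the flank ends")
        for part, label in ((self.flank5, "flank5"), (self.loop, "loop"),
                            (self.flank3, "flank3")):
            hits = scan_enzyme_sites(part, self.enzyme_site)
            if hits:
                raise ValueError(
                    f"{label} contains the {self.enzyme_name} recognition site"
                )

    @classmethod
    def from_json(cls, path: str | Path) -> "BackboneSpec":
        cfg = json.loads(Path(path).read_text())
        cfg.pop("comment", None)
        cfg["multimer_junctions"] = tuple(
            tuple(pair) for pair in cfg.get("multimer_junctions", [])
        )
        return cls(**cfg)


def default_backbone() -> BackboneSpec:
    """The bundled synthetic shortened-miR-30-style backbone."""
    with resources.as_file(
        resources.files("panshrna.data") / "mir30_short_backbone.json"
    ) as p:
        return BackboneSpec.from_json(p)


@dataclass(frozen=True)
class HairpinConstruct:
    """An assembled hairpin insert with its cloning oligos.

    ``top_oligo``/``bottom_oligo`` describe the annealed fragment with 5'
    overhangs at both ends: the top strand omits the last ``overhang_length``
    nt of the insert, the bottom strand is the reverse complement of the
    insert minus its first ``overhang_length`` nt. ``audit`` lists enzyme
    recognition sites found anywhere in the insert; a construct is cloneable
    only when the audit is empty.
    """

    name: str
    sense_arm: str
    loop: str
    antisense_arm: str
    insert: str
    top_oligo: str
    bottom_oligo: str
    backbone: BackboneSpec
    audit: tuple[SiteViolation, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.audit


def build_hairpin(
    site: CandidateSite | str, backbone: BackboneSpec | None = None,
    name: str | None = None,
) -> HairpinConstruct:
    """Embed a target site into the backbone and derive the cloning oligos.

    A target carrying the enzyme's recognition site still yields a
    construct, but with a non-empty audit and ``ok == False`` — the caller
    decides whether to reject it (the default rule table penalises such
    targets heavily before this point).
    """
    backbone = backbone or default_backbone()
    if isinstance(site, CandidateSite):
        sense = site.target_sense
        cname = name or f"{site.ref_id}_{site.start}_{site.end}"
    else:
        sense = NucSequence("t", site).seq
        cname = name or f"hairpin_{sense[:8]}"
    anti = revcomp(sense)
    insert = backbone.flank5 + sense + backbone.loop + anti + backbone.flank3
    ov = backbone.overhang_length
    return HairpinConstruct(
        name=cname,
        sense_arm=sense,
        loop=backbone.loop,
        antisense_arm=anti,
        insert=insert,
        top_oligo=insert[:-ov],
        bottom_oligo=revcomp(insert[ov:]),
        backbone=backbone,
        audit=tuple(scan_enzyme_sites(insert, backbone.enzyme_site)),
    )


def chain_multimer(
    constructs: list[HairpinConstruct], backbone: BackboneSpec | None = None
) -> str:
    """Concatenate hairpin inserts through scar-forming overhang junctions.

    Each junction fuses construct i's downstream overhang to construct
    i+1's upstream overhang with a 4-nt overlap, so the multimer length is
    n x insert_length - (n-1) x overhang_length. Junctions must be declared
    in the backbone's ``multimer_junctions``; an undeclared pair is an
    error naming the junction.
    """
    if not constructs:
        raise ValueError("need at least one construct")
    backbone = backbone or constructs[0].backbone
    for i, c in enumerate(constructs):
        if c.backbone != backbone:
            raise ValueError(f"construct {i} ({c.name}) uses a different backbone")
    ov = backbone.overhang_length
    pieces = [constructs[0].insert]
    for i in range(1, len(constructs)):
        pair = (backbone.downstream_overhang, backbone.upstream_overhang)
        if pair not in backbone.multimer_junctions:
            raise ValueError(
                f"junction {i} ({constructs[i-1].name} -> {constructs[i].name}): "
                f"overhang pair {pair} not declared ligatable"
            )
        pieces.append(constructs[i].insert[ov:])
    return "".join(pieces)
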