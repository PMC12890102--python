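"""Rule-based scoring and ranking of candidate target sites.

Design rules for effective shRNAs/siRNAs (moderate GC content, no long
homopolymer runs, A/U at the guide 5' end to bias strand loading, no Type
IIS recognition sites that would break Golden Gate cloning) are applied as
soft, weighted penalties and bonuses. Validated sites from the literature
violate common hard cutoffs — one histone H3 target carries a CCCC run, an
H1 target sits at 59% GC — so ranking, not exclusion, is the default; a
weight of -inf turns any rule into a hard filter.

The rule table ships as versioned JSON and every weight/parameter is
overridable; the defaults are this package's own codification of the usual
published sequence requirements.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any

import pandas as pd

from .seqio import revcomp
from .site_finder import CandidateSite

__all__ = [
    "Rule",
    "RuleContribution",
    "RuleTable",
    "RankedCandidate",
    "score_candidate",
    "rank_candidates",
    "top_k",
    "select_non_overlapping",
    "default_rules",
]

_KINDS = {"range-penalty", "motif-penalty", "position-bonus", "cloning-incompatibility"}


@dataclass(frozen=True)
class Rule:
    """One scoring rule: a kind, its parameters, and a signed weight."""

    name: str
    kind: str
    weight: float
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if math.isnan(self.weight):
            raise ValueError(f"rule {self.name!r} has NaN weight")


@dataclass(frozen=True)
class RuleContribution:
    """Points contributed by one rule, with the evidence that triggered it."""

    rule: str
    points: float
    evidence: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class RuleTable:
    """Ordered rule set plus the per-isoform coverage bonus."""

    rules: tuple[Rule, ...]
    coverage_bonus_per_isoform: float = 1.0
    name: str = "custom"
    version: str = "0"

    def __post_init__(self) -> None:
        names = [r.name for r in self.rules]
        if len(set(names)) != len(names):
            raise ValueError("rule names must be unique")

    def without(self, rule_name: str) -> "RuleTable":
        return replace(
            self, rules=tuple(r for r in self.rules if r.name != rule_name)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RuleTable":
        cfg = json.loads(Path(path).read_text())
        return cls.from_dict(cfg)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RuleTable":
        rules = tuple(
            Rule(
                name=r["name"],
                kind=r["kind"],
                weight=float(r["weight"]) if r["weight"] != "-inf" else -math.inf,
                params=r.get("params", {}),
            )
            for r in cfg["rules"]
        )
        return cls(
            rules=rules,
            coverage_bonus_per_isoform=float(cfg.get("coverage_bonus_per_isoform", 1.0)),
            name=cfg.get("name", "custom"),
            version=str(cfg.get("version", "0")),
        )


def default_rules() -> RuleTable:
    """The bundled default rule table."""
    with resources.as_file(
        resources.files("panshrna.data") / "default_rules.json"
    ) as p:
        return RuleTable.from_json(p)


@dataclass(frozen=True)
class RankedCandidate:
    """A scored candidate with its rule-by-rule breakdown.

    ``total_score == sum(contribution points) + coverage_bonus``; ``rank``
    is 1-based once assigned by :func:`rank_candidates` (None before).
    """

    site: CandidateSite
    contributions: tuple[RuleContribution, ...]
    coverage_bonus: float
    total_score: float
    rank: int | None = None


# --- rule evaluation -------------------------------------------------------


def _maximal_runs(seq: str, threshold: int) -> list[dict[str, Any]]:
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= threshold:
            runs.append({"base": seq[i], "start": i, "length": j - i})
        i = j
    return runs


def _find_motifs(seq: str, motif: str) -> list[int]:
    hits, start = [], 0
    while True:
        p = seq.find(motif, start)
        if p < 0:
            return hits
        hits.append(p)
        start = p + 1


def _eval_rule(rule: Rule, site: CandidateSite) -> RuleContribution:
    target = site.target_sense
    guide = site.guide
    p = rule.params
    if rule.kind == "range-penalty":
        gc = target.count("G") + target.count("C")
        pct = 100.0 * gc / len(target)
        fired = not (p.get("min_pct", 0.0) <= pct <= p.get("max_pct", 100.0))
        return RuleContribution(
            rule=rule.name,
            points=rule.weight if fired else 0.0,
            evidence={"gc_count": gc, "length": len(target),
                      "gc_pct": round(pct, 2), "in_range": not fired},
        )
    if rule.kind == "motif-penalty":
        runs = _maximal_runs(target, int(p.get("run_threshold", 4)))
        return RuleContribution(
            rule=rule.name,
            points=rule.weight * len(runs),
            evidence={"runs": runs},
        )
    if rule.kind == "position-bonus":
        strand = guide if p.get("strand", "guide") == "guide" else target
        bases = set(p.get("bases", ["A", "T"]))
        hits = [
            pos for pos in p.get("positions", [1, 2])
            if 1 <= pos <= len(strand) and strand[pos - 1] in bases
        ]
        return RuleContribution(
            rule=rule.name,
            points=rule.weight * len(hits),
            evidence={"positions_hit": hits, "bases": sorted(bases)},
        )
    if rule.kind == "cloning-incompatibility":
        occurrences = []
        for motif in p.get("motifs", []):
            for pos in _find_motifs(target, motif):
                occurrences.append({"motif": motif, "strand": "+", "pos": pos})
            if p.get("both_strands", True):
                rc = revcomp(motif)
                if rc != motif:
                    for pos in _find_motifs(target, rc):
                        occurrences.append({"motif": motif, "strand": "-", "pos": pos})
        return RuleContribution(
            rule=rule.name,
            points=rule.weight * len(occurrences),
            evidence={"occurrences": occurrences},
        )
    raise AssertionError(f"unhandled rule kind {rule.kind}")  # pragma: no cover


def score_candidate(site: CandidateSite, rules: RuleTable) -> RankedCandidate:
    """Evaluate every rule on one candidate; deterministic, rank unset.

    Rules are independent: each sees only the candidate, so removing one
    never changes the others' contributions.
    """
    contribs = tuple(_eval_rule(r, site) for r in rules.rules)
    bonus = rules.coverage_bonus_per_isoform * site.coverage
    total = sum(c.points for c in contribs) + bonus
    return RankedCandidate(
        site=site, contributions=contribs, coverage_bonus=bonus, total_score=total
    )


def _sort_key(rc: RankedCandidate):
    return (
        -rc.total_score,
        -rc.site.coverage,
        rc.site.start,
        rc.site.target_sense,
        rc.site.ref_id,
    )


def rank_candidates(scored: list[RankedCandidate]) -> list[RankedCandidate]:
    """Assign ranks 1..N by (score desc, coverage desc, start asc, target asc).

    The key is a total order on distinct candidates, so the output is
    invariant under permutation of the input.
    """
    if not scored:
        raise ValueError("cannot rank an empty candidate list")
    ordered = sorted(scored, key=_sort_key)
    return [replace(rc, rank=i + 1) for i, rc in enumerate(ordered)]


def top_k(ranked: list[RankedCandidate], k: int) -> list[RankedCandidate]:
    """First min(k, N) entries of a ranked list (default shortlist size: 8)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return ranked[:k]


def select_non_overlapping(
    ranked: list[RankedCandidate], max_overlap: int | None = None
) -> list[RankedCandidate]:
    """Greedily drop candidates overlapping a better-ranked one by > max_overlap.

    Default ``max_overlap`` is half the site length. Ranks are reassigned on
    the surviving subset.
    """
    if not ranked:
        return []
    if max_overlap is None:
        max_overlap = len(ranked[0].site.target_sense) // 2
    kept: list[RankedCandidate] = []
    for rc in sorted(ranked, key=_sort_key):
        clash = any(
            rc.site.ref_id == k.site.ref_id
            and min(rc.site.end, k.site.end) - max(rc.site.start, k.site.start)
            > max_overlap
            for k in kept
        )
        if not clash:
            kept.append(rc)
    return [replace(rc, rank=i + 1) for i, rc in enumerate(kept)]


def ranked_to_dataframe(ranked: list[RankedCandidate]) -> pd.DataFrame:
    """Ranked report with one evidence column per rule."""
    rows = []
    for rc in ranked:
        row = {
            "rank": rc.rank,
            "ref_id": rc.site.ref_id,
            "start0": rc.site.start,
            "end0": rc.site.end,
            "target_sense": rc.site.target_sense,
            "guide": rc.site.guide,
            "coverage": rc.site.coverage,
            "coverage_bonus": rc.coverage_bonus,
            "total_score": rc.total_score,
        }
        for c in rc.contributions:
            row[f"{c.rule}_points"] = c.points
            row[f"{c.rule}_evidence"] = json.dumps(c.evidence, sort_keys=True)
        rows.append(row)
    return pd.DataFrame(rows)
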