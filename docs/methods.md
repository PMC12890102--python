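# Methods

## Scope and model of the design problem

`panshrna` designs shRNAs against multi-copy gene families whose isoforms
are similar enough for a single guide to silence all of them, and the
matching synonymously recoded rescue ORF. The package treats design as
four coupled computations: (1) quantify family similarity, (2) enumerate
windows conserved under an RNAi-motivated matching model, (3) rank the
survivors with soft sequence rules, (4) emit the two downstream artifacts
(hairpin cloning oligos, resistant ORF). Everything operates on DNA
strings; RNA input is normalized U→T on entry because target sites,
guides and oligos are conventionally written as DNA.

## Sequence identity metric

Family similarity is the mean over unordered isoform pairs of percent
identity under global end-to-end alignment with match +1, mismatch 0,
linear gap −1, identity = matches / alignment length. CDS isoforms of one
family are near-equal length, making the end-to-end reading natural; an
alternative denominator (the shorter sequence) is selectable through
`AlignmentConfig`. Alignment is delegated to Biopython's
`PairwiseAligner`; when several paths are score-optimal the first path in
the aligner's canonical enumeration is used, which is deterministic. The
test suite checks the reported identity against an exhaustive enumeration
of all global alignments on small strings. A single-isoform family has
mean identity 100 by definition.

## Matching model

- **Guide length L = 22 nt** (default): the length of the validated
  histone target sites the package ships as test vectors. Valid range
  19–25.
- **Mismatch budget k = 2** (default): silencing tolerates a small number
  of non-seed mismatches; a family at ~90% identity cannot generally be
  covered at k = 0, while k > 2 would overstate silencing of diverged
  isoforms. Exposed in `MatchModel` because no single value is canonical.
- **Seed = guide positions 2–8, exact** (default): seed pairing dominates
  target recognition, and a seed mismatch is the most reliable way to
  abolish silencing; guide position g pairs with target-window position
  L − g (0-based).
- Only the sense strand of each isoform is scanned (shRNAs act on mRNA).
- Best hit per isoform = fewest mismatches, ties to the smallest
  position. Coordinates are 0-based half-open internally; reports add
  1-based columns.

The production enumerator accumulates the full (reference windows ×
isoform windows) mismatch-count and seed-mismatch matrices per isoform in
numpy. Correctness is established against two independent oracles: a
pure-Python all-windows × all-isoforms double loop (small inputs) and a
semi-naive per-window vector scan validated against the pure-Python one
and then run on hundreds of random families.

## Scoring rules and ranking

All rules are soft, weighted contributions — validated sites from the
literature violate common hard cutoffs (a histone H3 site contains a CCCC
run; an H1 site is ~59% GC), so ranking must not exclude them. Defaults
(versioned JSON, every number overridable; weight −inf turns a rule into
a hard filter):

| rule | default | weight |
|---|---|---|
| GC content of target | inside [30, 52]% | −2 if outside |
| homopolymer runs | maximal runs ≥ 4 nt | −1 per run |
| guide 5′ A/U (strand loading) | guide positions 1–2 | +1 per A/T position |
| Type IIS sites (Esp3I `CGTCTC`, BpiI `GAAGAC`, both strands) | none allowed | −10 per occurrence |
| isoform coverage | — | +1 per covered isoform |

Ranking sorts by (total score desc, coverage desc, start asc, target
lexicographic asc, reference id) — a total order, hence invariant under
input permutation; ranks are 1..N with no gaps. The default shortlist is
the top 8. An optional non-overlap filter greedily drops candidates
overlapping a better-ranked one by more than L/2; it is off by default so
diverse overlapping windows remain visible.

## Hairpin assembly and multimerization

An insert is `5′flank | sense arm | loop | antisense arm | 3′flank` with
the antisense arm the exact reverse complement of the sense arm. The
bundled backbone is a **synthetic default**: canonical miR-30 arm context
and loop with this package's own overhang choices; it is not a
transcription of any published construct, and users supply their own
`BackboneSpec` for bit-exact cloning. Backbone validation enforces: no
enzyme recognition site on either strand of flanks/loop; 4-nt overhangs
equal to the flank ends, distinct, and non-palindromic.

Annealed-oligo geometry: top oligo = insert minus its last 4 nt, bottom
oligo = reverse complement of the insert minus its first 4 nt, leaving
4-nt 5′ overhangs at both ends.

Multimerization is modeled at the sequence level: each junction fuses one
insert's downstream overhang to the next insert's upstream overhang with
a 4-nt overlap, so n copies give length n·|insert| − (n−1)·4 and the
enzyme recognition sites fall away ("self-destructing" junctions).
Ligatable overhang pairs are declared explicitly in
`BackboneSpec.multimer_junctions`; the default backbone declares its own
(downstream, upstream) pair, with upstream = revcomp(downstream) as
sticky-end complementarity dictates. Compatibility checking is plain
4-mer pair lookup — no enzymatic kinetics or ligation-fidelity modelling.

## Resistant recoding

For each codon overlapping the target window, synonymous alternatives are
searched to maximize, lexicographically: seed-pairing mismatches, total
window mismatches, then codon-preference weight (uniform by default; an
organism-specific table can be supplied). Constraints: the recoded window
plus 6 nt of flanking context must not contain *newly introduced*
forbidden motifs — Type IIS sites on either strand or homopolymer runs ≥
4 — where "introduced" means absent at the same coordinates in the
original, so pre-existing context artifacts cannot deadlock the search.
Edits are confined to codons overlapping the window (minimal
intervention: tags and UTR elements outside stay untouched).

Search strategy: exhaustive over the product of synonym sets when the
window spans ≤ 8 codons **and** the product is ≤ 200,000 combinations
(eight six-fold-degenerate codons would otherwise mean 6⁸ ≈ 1.7M
evaluations); greedy per-codon with one repair pass over the final
context otherwise. Both paths are deterministic; objective ties break to
the lexicographically smallest codon string. `min_mismatches = 0` is a
vacuous requirement and returns the original unedited. An unattainable
requirement (e.g. a Met/Trp window) returns `success=False` with the best
achievable count. Protein preservation is re-verified by translation on
every output.

The resistance guarantee asserted by the tests: any successful recode
with ≥ k+1 mismatches including ≥ 1 seed mismatch is no longer matched by
`match_isoform` under the designing `MatchModel`.

## Off-target triage

The guide's seed (positions 2–8, a 7-mer) is reverse-complemented and
counted — overlapping occurrences included — on the sense strand of each
transcript, independently per record (counts are therefore order-
invariant and additive). Optional full-length near-match counts reuse the
window-matching model. No expression weighting or 3′-UTR restriction is
modeled.

## Synthetic data generator

`simulate_family` emulates a histone-like family: one uniform-random
ancestor of configurable length; each of n isoforms derived independently
by i.i.d. per-site substitution at rate d, drawing uniformly among the
three alternative bases; planted windows copied verbatim into every
isoform at one shared, non-overlapping offset and shielded from
substitution (recorded in a manifest). Defaults (n = 8, length 500,
d = 0.1) mirror the chicken H2B regime of 8 genes at ~90% identity;
gap-free identity at divergence d has closed form (1−d)² + d²/3, which
the suite verifies empirically. `simulate_orf` produces start + random
sense codons + stop, guaranteed internally stop-free. All randomness
flows from a single integer seed.

What the generator does **not** emulate: indels, codon-usage bias,
selection, paralog-specific conserved blocks beyond the planted windows,
UTRs, or expression levels. Passing tests therefore demonstrate
algorithmic correctness under a clean substitution model, not performance
on annotated genomes; real families with indel-diverged isoforms will
show lower coverage than identity alone suggests.

## Problem sizes and numerical choices

The test and acceptance workloads use families of 2–8 isoforms at 60–2000
nt over a 0–0.25 divergence grid (hundreds of families), 100 planted-
window replicates, 500+ small-window recoding trials against exhaustive
search, and 1000 protein-preservation trials — sizes chosen so the entire
verification runs in minutes on one core while exercising every code
path at realistic family dimensions. Recoder optimality is compared to
the brute-force maximum with motif constraints disabled on both sides,
since the unconstrained maximum is the quantity the oracle enumerates.
Degenerate inputs are defined, not special-cased: isoforms shorter than L
simply contribute no windows; a single-isoform family has identity 100;
an empty transcriptome yields a zero-hit report.

## Known limitations

- Identity and coverage are computed on DNA; families whose similarity
  is only visible at the protein level are out of scope.
- No thermodynamic duplex stability, target accessibility/secondary
  structure, or learned efficacy prediction — the rule table codifies
  published heuristics, not a trained model.
- The bundled backbone is a labeled synthetic dialect; restriction
  behavior is modeled only as recognition-site scanning plus fixed 4-nt
  overhang geometry.
- Off-target counting is seed-exact on provided transcripts only; no
  genome-wide alignment.
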