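# panshrna

Gene-family-aware shRNA design: find a single target site conserved across
**all** isoforms of a multi-copy gene family, rank candidates with
configurable sequence-design rules, emit Golden-Gate-ready miR-30 hairpin
oligos, and produce an shRNA-resistant, synonymously recoded replacement
ORF for knockdown/re-expression (rescue) experiments.

## The problem

Canonical histones — the motivating use case — are encoded by many near-
identical genes (6–22 per histone depending on species). Silencing *all* of
them with one shRNA is only possible when the family's coding sequences are
similar enough that a ~22-nt window is conserved across every isoform, as
in chicken, where e.g. H2B is encoded by 8 genes of roughly 90% identity.
A knockdown/re-expression experiment then needs two designed molecules:

1. an shRNA whose 22-nt guide matches a window present in every isoform
   (perfect pairing at the guide **seed**, positions 2–8, is required for
   silencing; a couple of mismatches elsewhere are tolerated), and
2. a rescue cDNA carrying synonymous (wobble) edits inside that same
   window, so the re-expressed protein is identical but its mRNA escapes
   the shRNA.

`panshrna` automates both, plus the bookkeeping around them.

## What it computes

- **Family profile** — pairwise percent-identity matrix under global
  alignment (match +1, mismatch 0, gap −1; identity = matches /
  alignment length) and its mean over unordered pairs.
- **Candidate enumeration** — every L-window of a reference isoform is
  matched against every isoform; a window *covers* an isoform when it
  occurs with ≤ k mismatches (default k = 2) and an exact seed. Sites are
  reported with per-isoform hit positions and mismatch maps, sorted by
  coverage.
- **Rule scoring and ranking** — soft weighted rules (GC in [30, 52]%,
  homopolymer runs ≥ 4, A/U at the guide 5′ end, Type IIS recognition
  sites Esp3I/BpiI that would break Golden Gate cloning) plus +1 per
  covered isoform; deterministic total order, top-k shortlist (default 8).
- **Hairpin assembly** — the chosen site becomes the sense arm of a
  shortened miR-30-style scaffold (`5′flank | sense | loop | guide |
  3′flank`) with annealed-oligo 4-nt overhangs; multimerization chains
  inserts through self-destructing junctions, leaving zero enzyme sites.
- **Resistant recoding** — exhaustive (or greedy, for long spans)
  synonymous search maximizing seed mismatches first, then total
  mismatches, under no-new-motif constraints; protein preservation is
  verified on every output.
- **Off-target triage** — exact seed-complement (7-mer) counts across a
  transcriptome FASTA, optionally full-length near-match counts.
- **Synthetic families** — a star-shaped substitution model (one ancestor,
  i.i.d. per-site divergence, optional verbatim planted windows) generates
  realistic test inputs; expected pairwise identity is
  (1−d)² + d²/3 at divergence d.

## Worked example

Simulate an 8-isoform, 10%-divergence family with the validated H2B target
site planted into every isoform, then profile, rank, and build a hairpin:

```
$ panshrna simulate --n-isoforms 8 --length 400 --divergence 0.1 \
    --plant TTGACGAACGAGTTCATGATGC --seed 7 --out family.fa --manifest family.json
wrote 8 isoforms to family.fa

$ panshrna profile family.fa --out profile.tsv
family family: 8 isoforms, mean identity 82.7%

$ panshrna rank family.fa --top-k 3 --out ranked.tsv
ranked 7 candidates; shortlist of 3
 rank  start0           target_sense  coverage  total_score
    1     260 CTTGATTGACGAACGAGTTCAT         8         10.0
    2     263 GATTGACGAACGAGTTCATGAT         8         10.0
    3     261 TTGATTGACGAACGAGTTCATG         8          9.0
```

All top candidates overlap the planted conserved window (the only region
matching all 8 isoforms at 10% divergence); coverage 8 contributes +8, and
windows whose guide 5′ end is A/U collect the strand-loading bonus that
separates ranks 1–2 from 3.

```
$ panshrna hairpin TTGACGAACGAGTTCATGATGC --copies 2
insert (105 nt): AGGCTGCTGTTGACAGTGAGCGTTGACGAACGAGTTCATGATGCTAGTGAAGCCACAGATGTAGCATCATGAACTCGTTCGTCAATGCCTACTGCCTCGGAGCCT
```

The 105-nt insert is 5′ flank (22) + sense arm (22) + loop (19) + guide
(22) + 3′ flank (20); the guide `GCATCATGAACTCGTTCGTCAA` is the reverse
complement of the target. `panshrna recode` produces the matching
shRNA-resistant ORF, and `panshrna offtarget` counts seed matches in a
transcriptome.

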