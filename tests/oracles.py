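"""Independent reference implementations used only by the test suite.

These deliberately re-derive results through straightforward scans and
enumerations, sharing no code path with the package's vectorised or
optimised implementations.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from panshrna.family_profile import TranscriptFamily
from panshrna.seqio import CodonTable
from panshrna.site_finder import MatchModel


def naive_best_match(target: str, iso_seq: str, model: MatchModel):
    """Pure-Python window scan: best (pos, mismatches, mismatch indices)."""
    L = model.guide_length
    seed_idx = set(model.seed_target_indices)
    best = None
    for p in range(len(iso_seq) - L + 1):
        w = iso_seq[p:p + L]
        bad = [i for i in range(L) if w[i] != target[i]]
        if len(bad) > model.max_mismatches:
            continue
        if model.require_seed_exact and any(i in seed_idx for i in bad):
            continue
        if best is None or len(bad) < best[1]:
            best = (p, len(bad), tuple(bad))
    return best


def naive_enumerate(fam: TranscriptFamily, ref_id: str, model: MatchModel,
                    min_coverage: int):
    """Pure-Python all-windows x all-isoforms enumeration.

    Returns [(start, {iso_id: (pos, mismatches)})] sorted by
    (coverage desc, start asc).
    """
    ref = fam.get(ref_id)
    L = model.guide_length
    out = []
    for s in range(len(ref.seq) - L + 1):
        target = ref.seq[s:s + L]
        recs = {}
        for iso in fam.isoforms:
            best = naive_best_match(target, iso.seq, model)
            if best is not None:
                recs[iso.id] = (best[0], best[1])
        if len(recs) >= min_coverage:
            out.append((s, recs))
    out.sort(key=lambda t: (-len(t[1]), t[0]))
    return out


def seminaive_enumerate(fam: TranscriptFamily, ref_id: str, model: MatchModel,
                        min_coverage: int):
    """All-windows x all-isoforms oracle with a vectorised per-window compare.

    Same double-loop structure and selection logic as the pure-Python
    oracle (validated against it on small inputs) but fast enough for
    thousands of windows. Independent of the package's matrix-accumulation
    implementation.
    """
    ref = fam.get(ref_id)
    L = model.guide_length
    seed_idx = np.asarray(model.seed_target_indices)
    iso_wins = []
    for iso in fam.isoforms:
        enc = np.frombuffer(iso.seq.encode(), dtype=np.uint8)
        if len(enc) < L:
            iso_wins.append((iso.id, None))
        else:
            iso_wins.append((iso.id, np.lib.stride_tricks.sliding_window_view(enc, L)))
    out = []
    ref_enc = np.frombuffer(ref.seq.encode(), dtype=np.uint8)
    for s in range(len(ref.seq) - L + 1):
        t = ref_enc[s:s + L]
        recs = {}
        for iso_id, wins in iso_wins:
            if wins is None:
                continue
            neq = wins != t
            mm = neq.sum(axis=1)
            ok = mm <= model.max_mismatches
            if model.require_seed_exact:
                ok &= ~neq[:, seed_idx].any(axis=1)
            positions = np.nonzero(ok)[0]
            if positions.size == 0:
                continue
            # best = fewest mismatches, ties to smallest position
            best_p = min((int(mm[p]), int(p)) for p in positions)
            recs[iso_id] = (best_p[1], best_p[0])
        if len(recs) >= min_coverage:
            out.append((s, recs))
    out.sort(key=lambda t: (-len(t[1]), t[0]))
    return out


def all_global_alignments(a: str, b: str):
    """Enumerate every global alignment of two tiny strings.

    Yields (score, matches, length) under match=+1, mismatch=0, gap=-1.
    Exponential; only for len <= 7.
    """
    def rec(i, j, score, matches, length):
        if i == len(a) and j == len(b):
            yield (score, matches, length)
            return
        if i < len(a) and j < len(b):
            m = a[i] == b[j]
            yield from rec(i + 1, j + 1, score + (1 if m else 0),
                           matches + (1 if m else 0), length + 1)
        if i < len(a):
            yield from rec(i + 1, j, score - 1, matches, length + 1)
        if j < len(b):
            yield from rec(i, j + 1, score - 1, matches, length + 1)

    return list(rec(0, 0, 0, 0, 0))


def optimal_identity_set(a: str, b: str) -> set[float]:
    """Percent identities of all score-optimal global alignments."""
    alns = all_global_alignments(a, b)
    best = max(s for s, _, _ in alns)
    return {100.0 * m / ln for s, m, ln in alns if s == best}


def brute_force_max_mismatches(window: str, table: CodonTable,
                               seed_indices: tuple[int, ...] = ()):
    """Exhaustive synonymous-recoding maximum over a codon-aligned window.

    Returns (max_seed_mismatches, max_total_mismatches) under the
    lexicographic (seed, total) objective. Window length must be a
    multiple of 3.
    """
    assert len(window) % 3 == 0
    codons = [window[i:i + 3] for i in range(0, len(window), 3)]
    choices = [table.synonymous(c) for c in codons]
    seed = set(seed_indices)
    best = (-1, -1)
    for combo in product(*choices):
        cand = "".join(combo)
        mm = sum(1 for i in range(len(window)) if cand[i] != window[i])
        smm = sum(1 for i in seed if cand[i] != window[i])
        best = max(best, (smm, mm))
    return best
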