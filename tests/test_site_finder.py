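"""Window matching and candidate enumeration against naive oracles."""

import numpy as np
import pytest

from panshrna import (
    FamilySimSpec,
    MatchModel,
    NucSequence,
    PlantedWindow,
    TranscriptFamily,
    enumerate_candidates,
    match_isoform,
    revcomp,
    simulate_family,
)

from .oracles import naive_best_match, naive_enumerate, seminaive_enumerate


def random_family(rng, n, length_range=(60, 200), divergence=0.1, seed=0):
    length = int(rng.integers(*length_range))
    return simulate_family(FamilySimSpec(
        n_isoforms=n, length=length, per_site_divergence=divergence, seed=seed
    )).family


class TestMatchModel:
    def test_seed_target_indices_default(self):
        # guide positions 2..8 pair with target indices L-2..L-8
        assert MatchModel().seed_target_indices == (14, 15, 16, 17, 18, 19, 20)

    @pytest.mark.parametrize("kwargs", [
        {"guide_length": 18}, {"guide_length": 26},
        {"max_mismatches": -1}, {"max_mismatches": 22},
        {"seed_start": 0}, {"seed_end": 23}, {"seed_start": 9, "seed_end": 8},
    ])
    def test_invalid_models_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MatchModel(**kwargs)


class TestMatchIsoform:
    def test_exact_substring_found(self, default_model):
        target = "TTGACGAACGAGTTCATGATGC"
        iso = NucSequence("i", "A" * 30 + target + "C" * 30)
        rec = match_isoform(target, iso, default_model)
        assert rec.position == 30 and rec.mismatches == 0
        assert rec.mismatch_guide_positions == ()

    def test_isoform_shorter_than_window(self, default_model):
        assert match_isoform("A" * 22, NucSequence("i", "A" * 10), default_model) is None

    def test_seed_mismatch_rejected_when_exact_required(self):
        model = MatchModel()
        target = "A" * 22
        # mutate a seed-pairing position (target index 17 pairs guide pos 5)
        iso_seq = list(target)
        iso_seq[17] = "C"
        iso = NucSequence("i", "".join(iso_seq))
        assert match_isoform(target, iso, model) is None
        relaxed = MatchModel(require_seed_exact=False)
        rec = match_isoform(target, iso, relaxed)
        assert rec.mismatches == 1 and rec.mismatch_guide_positions == (5,)

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_naive_scan_on_random_isoforms(self, seed):
        rng = np.random.default_rng(seed)
        model = MatchModel(max_mismatches=2)
        iso = NucSequence("i", "".join(rng.choice(list("ACGT"), size=200)))
        # take a real window and corrupt it a little
        start = int(rng.integers(0, 178))
        target = list(iso.seq[start:start + 22])
        for p in rng.choice(22, size=int(rng.integers(0, 4)), replace=False):
            target[p] = rng.choice([b for b in "ACGT" if b != target[p]])
        target = "".join(target)
        got = match_isoform(target, iso, model)
        want = naive_best_match(target, iso.seq, model)
        if want is None:
            assert got is None
        else:
            assert (got.position, got.mismatches) == want[:2]
            assert got.mismatch_guide_positions == tuple(
                sorted(model.guide_position(i) for i in want[2])
            )


class TestEnumerateCandidates:
    def test_identical_family_all_windows_full_coverage(self):
        n, M, L = 4, 60, 22
        seq = "".join(np.random.default_rng(0).choice(list("ACGT"), size=M))
        fam = TranscriptFamily(
            "f", tuple(NucSequence(f"i{k}", seq) for k in range(n))
        )
        sites = enumerate_candidates(fam, "i0", MatchModel())
        assert len(sites) == M - L + 1
        assert all(s.coverage == n for s in sites)

    def test_planted_window_recovered_at_offset(self):
        window = "TTGACGAACGAGTTCATGATGC"
        sim = simulate_family(FamilySimSpec(
            n_isoforms=6, length=300, per_site_divergence=0.15,
            planted_windows=(PlantedWindow(window),), seed=13))
        sites = enumerate_candidates(sim.family, sim.family.isoforms[0].id)
        starts = {s.start for s in sites}
        assert sim.offsets[window] in starts
        planted = next(s for s in sites if s.start == sim.offsets[window])
        assert planted.target_sense == window and planted.coverage == 6

    def test_min_coverage_beyond_family_size_errors(self, planted_family):
        with pytest.raises(ValueError, match="min_coverage"):
            enumerate_candidates(planted_family.family,
                                 planted_family.family.isoforms[0].id,
                                 min_coverage=9)

    def test_unknown_ref_errors(self, planted_family):
        with pytest.raises(KeyError):
            enumerate_candidates(planted_family.family, "nope")

    def test_guides_are_revcomp_of_targets(self, planted_family):
        sites = enumerate_candidates(planted_family.family,
                                     planted_family.family.isoforms[0].id,
                                     min_coverage=4)
        assert sites and all(s.guide == revcomp(s.target_sense) for s in sites)

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_pure_python_oracle_small(self, seed):
        rng = np.random.default_rng(100 + seed)
        fam = random_family(rng, n=int(rng.integers(2, 5)),
                            length_range=(50, 120),
                            divergence=float(rng.uniform(0, 0.25)),
                            seed=200 + seed)
        model = MatchModel(max_mismatches=int(rng.integers(0, 3)))
        mc = int(rng.integers(1, len(fam) + 1))
        got = enumerate_candidates(fam, fam.isoforms[0].id, model, mc)
        want = naive_enumerate(fam, fam.isoforms[0].id, model, mc)
        assert [(s.start, {i: (r.position, r.mismatches)
                           for i, r in s.matches.items()}) for s in got] == want

    def test_seminaive_oracle_agrees_with_pure_python(self):
        """Validates the fast oracle used by the large equivalence suite."""
        rng = np.random.default_rng(7)
        fam = random_family(rng, n=3, length_range=(50, 100),
                            divergence=0.2, seed=77)
        model = MatchModel()
        assert seminaive_enumerate(fam, fam.isoforms[0].id, model, 1) == \
            naive_enumerate(fam, fam.isoforms[0].id, model, 1)

    def test_monotone_in_mismatch_budget_and_coverage(self):
        sim = simulate_family(FamilySimSpec(n_isoforms=5, length=250,
                                            per_site_divergence=0.1, seed=31))
        fam = sim.family
        ref = fam.isoforms[0].id
        cov_by_start_k1 = {
            s.start: s.coverage
            for s in enumerate_candidates(fam, ref, MatchModel(max_mismatches=1), 1)
        }
        cov_by_start_k3 = {
            s.start: s.coverage
            for s in enumerate_candidates(fam, ref, MatchModel(max_mismatches=3), 1)
        }
        # raising k never decreases any window's coverage
        assert all(cov_by_start_k3[st] >= c for st, c in cov_by_start_k1.items())
        # raising min_coverage never grows the output set
        starts_lo = {s.start for s in enumerate_candidates(fam, ref, MatchModel(), 2)}
        starts_hi = {s.start for s in enumerate_candidates(fam, ref, MatchModel(), 4)}
        assert starts_hi <= starts_lo
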