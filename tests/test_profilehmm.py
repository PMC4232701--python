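"""Profile-HMM construction, scoring against exact path enumeration,
Gumbel calibration, E-values, logos, and serialization."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import gumbel_r

from famscan.profilehmm import (LN2, ProfileHMM, assign_match_columns,
                                build_profile, calibrate, evalue,
                                fit_gumbel_moments, forward_batch_raw,
                                forward_bits, forward_raw, from_dict,
                                henikoff_weights, logo, to_dict, viterbi)
from famscan.seqkit import MsAlignment
from famscan.substitution import AMINO_ACIDS, BACKGROUND_FREQS
from oracles import enum_forward_viterbi, random_profile


def aa_string(rng, n):
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, n))


class TestMatchColumns:
    def test_symfrac_rule(self):
        aln = MsAlignment([("r1", "A-"), ("r2", "A-"), ("r3", "A-"),
                           ("r4", "-A")])
        mask = assign_match_columns(aln, symfrac=0.5)
        assert mask.tolist() == [True, False]

    def test_no_consensus_error(self):
        aln = MsAlignment([("r1", "A-"), ("r2", "-A")])
        with pytest.raises(ValueError, match="no consensus"):
            assign_match_columns(aln, symfrac=0.9)

    def test_mask_matches_brute_force_gap_count(self, rng):
        for _ in range(20):
            nrow, ncol = int(rng.integers(2, 8)), int(rng.integers(1, 15))
            rows = [(f"r{i}", "".join(
                "-" if rng.random() < 0.4 else AMINO_ACIDS[rng.integers(20)]
                for _ in range(ncol))) for i in range(nrow)]
            aln = MsAlignment(rows)
            symfrac = float(rng.uniform(0.2, 0.9))
            try:
                mask = assign_match_columns(aln, symfrac)
            except ValueError:
                mask = None
            expected = [sum(r[k] != "-" for _, r in rows) / nrow >= symfrac
                        for k in range(ncol)]
            if mask is None:
                assert not any(expected)
            else:
                assert mask.tolist() == expected


class TestBuildProfile:
    def test_pure_counts_with_zero_pseudocount(self):
        aln = MsAlignment([("r1", "ACD"), ("r2", "ACD")])
        hmm = build_profile(aln, tau=0.0, weighting="uniform")
        for k, aa in enumerate("ACD"):
            assert hmm.match_emit[k, AMINO_ACIDS.index(aa)] == pytest.approx(1.0)

    def test_pseudocount_limit_is_background(self):
        aln = MsAlignment([("r1", "ACD"), ("r2", "ACD")])
        hmm = build_profile(aln, tau=1e9, weighting="uniform")
        assert np.allclose(hmm.match_emit, BACKGROUND_FREQS[None, :], atol=1e-6)

    def test_weighted_counts_match_hand_tally(self):
        """Uniform-weight counts on a 5-row fixture equal a hand tally."""
        aln = MsAlignment([("r1", "AAC"), ("r2", "AAC"), ("r3", "AGC"),
                           ("r4", "CGC"), ("r5", "A-C")])
        hmm = build_profile(aln, tau=0.0, weighting="uniform")
        a, c, g = (AMINO_ACIDS.index(x) for x in "ACG")
        # column 1: A,A,A,C,A ; column 2: A,A,G,G,- ; column 3: C x5
        assert hmm.match_emit[0, a] == pytest.approx(4 / 5)
        assert hmm.match_emit[0, c] == pytest.approx(1 / 5)
        assert hmm.match_emit[1, a] == pytest.approx(2 / 4)
        assert hmm.match_emit[1, g] == pytest.approx(2 / 4)
        assert hmm.match_emit[2, c] == pytest.approx(1.0)

    def test_single_sequence_allowed(self):
        hmm = build_profile(MsAlignment([("r1", "ACDEF")]))
        assert hmm.M == 5

    def test_henikoff_weights_favor_divergent_rows(self):
        aln = MsAlignment([("r1", "AAAA"), ("r2", "AAAA"), ("r3", "CCCC")])
        mask = assign_match_columns(aln, 0.5)
        w = henikoff_weights(aln, mask)
        assert w[2] > w[0] == pytest.approx(w[1])
        assert w.sum() == pytest.approx(3.0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_normalization_invariants(self, seed):
        """Emissions and transition rows of built profiles are distributions."""
        rng = np.random.default_rng(seed)
        nrow, ncol = int(rng.integers(2, 6)), int(rng.integers(3, 12))
        rows = [(f"r{i}", "".join(
            "-" if rng.random() < 0.3 else AMINO_ACIDS[rng.integers(20)]
            for _ in range(ncol))) for i in range(nrow)]
        try:
            hmm = build_profile(MsAlignment(rows))
        except ValueError:
            return  # no consensus columns — nothing to check
        assert np.allclose(hmm.match_emit.sum(axis=1), 1.0, atol=1e-12)
        for arr in (hmm.t_m, hmm.t_i, hmm.t_d):
            assert np.allclose(arr.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(arr >= 0)


class TestScoringAgainstEnumeration:
    @pytest.mark.parametrize("seed", range(8))
    def test_forward_and_viterbi_equal_path_enumeration(self, seed):
        """DP scores match exhaustive enumeration (M <= 3, length <= 6)
        to 1e-9 in natural-log space, on random and on built profiles."""
        rng = np.random.default_rng(seed)
        profiles = [random_profile(rng, int(rng.integers(1, 4)), BACKGROUND_FREQS)
                    for _ in range(4)]
        profiles.append(build_profile(
            MsAlignment([("r1", "AC-"), ("r2", "A-D"), ("r3", "ACD")]),
            symfrac=0.5))
        for hmm in profiles:
            assert hmm.M <= 3
            for _ in range(4):
                codes = rng.integers(0, 20, size=int(rng.integers(1, 7)))
                seq = "".join(AMINO_ACIDS[c] for c in codes)
                ln_f, ln_v = enum_forward_viterbi(hmm, list(codes))
                assert forward_raw(hmm, seq) == pytest.approx(ln_f, abs=1e-9)
                assert viterbi(hmm, seq).viterbi_bits * LN2 == pytest.approx(
                    ln_v, abs=1e-9)

    def test_viterbi_never_exceeds_forward(self, rng):
        for _ in range(200):
            hmm = random_profile(rng, int(rng.integers(1, 25)), BACKGROUND_FREQS)
            seq = aa_string(rng, int(rng.integers(1, 50)))
            v = viterbi(hmm, seq).viterbi_bits
            f = forward_raw(hmm, seq) / LN2
            assert v <= f + 1e-9

    def test_deterministic_profile_forces_the_path(self):
        """With one-hot emissions/transitions and M=1 on a length-1 target
        there is exactly one legal path, so Viterbi equals forward; with
        M=3 the best path is the full match run with the expected span."""
        one = ProfileHMM(name="det1", subfamily="s", region="r", M=1,
                         match_emit=np.eye(20)[:1].copy(),
                         insert_emit=BACKGROUND_FREQS.copy(),
                         t_m=np.array([[1.0, 0.0, 0.0]]),
                         t_i=np.array([[1.0, 0.0]]),
                         t_d=np.array([[1.0, 0.0]]),
                         background=BACKGROUND_FREQS.copy())
        f = forward_raw(one, "A") / LN2
        v = viterbi(one, "A")
        assert v.viterbi_bits == pytest.approx(f, abs=1e-9)
        assert v.path == [("M", 1)]
        m = 3
        emit = np.zeros((m, 20))
        emit[:, 0] = 1.0
        hmm = ProfileHMM(name="det", subfamily="s", region="r", M=m,
                         match_emit=emit, insert_emit=BACKGROUND_FREQS.copy(),
                         t_m=np.tile([1.0, 0.0, 0.0], (m, 1)),
                         t_i=np.tile([1.0, 0.0], (m, 1)),
                         t_d=np.tile([1.0, 0.0], (m, 1)),
                         background=BACKGROUND_FREQS.copy())
        v = viterbi(hmm, "AAA")
        assert [s for s, _ in v.path] == ["M", "M", "M"]
        assert (v.target_start, v.target_end) == (0, 3)
        assert v.viterbi_bits <= forward_raw(hmm, "AAA") / LN2 + 1e-9

    def test_background_emissions_score_entry_constant_only(self):
        """An M=1 profile emitting the background has zero emission
        log-odds; on a length-1 target the score is the entry/exit
        constant, which is 0 bits for M=1."""
        hmm = ProfileHMM(name="bg", subfamily="s", region="r", M=1,
                         match_emit=BACKGROUND_FREQS[None, :].copy(),
                         insert_emit=BACKGROUND_FREQS.copy(),
                         t_m=np.array([[1.0, 0.0, 0.0]]),
                         t_i=np.array([[1.0, 0.0]]),
                         t_d=np.array([[1.0, 0.0]]),
                         background=BACKGROUND_FREQS.copy())
        assert forward_bits(hmm, "A").bit_score == pytest.approx(0.0, abs=1e-12)
        # L placements -> log2(L)
        assert forward_bits(hmm, "ACDEF").bit_score == pytest.approx(
            math.log2(5), abs=1e-12)

    def test_background_flanks_shift_score_at_most_half_bit(self, rng):
        """Appending 10 background-distributed flanking residues moves the
        bit score only through the placement sum, bounded by 0.5 bits."""
        aln = MsAlignment([("r1", aa_string(rng, 30)) for _ in range(1)] * 3)
        hmm = build_profile(aln)
        core = aln.rows[0][1]
        for _ in range(5):
            flank = "".join(AMINO_ACIDS[i] for i in
                            rng.choice(20, size=10, p=BACKGROUND_FREQS))
            delta = (forward_bits(hmm, core + flank).bit_score
                     - forward_bits(hmm, core).bit_score)
            assert abs(delta) <= 0.5


class TestCalibration:
    def test_moment_fit_recovers_known_gumbel(self):
        draws = gumbel_r.rvs(loc=5.0, scale=1 / 0.7, size=5000,
                             random_state=42)
        mu, lam = fit_gumbel_moments(draws)
        assert mu == pytest.approx(5.0, rel=0.10)
        assert lam == pytest.approx(0.7, rel=0.10)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero score variance"):
            fit_gumbel_moments(np.full(200, 3.3))

    def test_calibration_reproducible_given_seed(self, rng):
        hmm = random_profile(rng, 12, BACKGROUND_FREQS)
        g1 = calibrate(hmm, n_cal=150, seed=9)
        g2 = calibrate(hmm, n_cal=150, seed=9)
        assert (g1.mu, g1.lambda_g) == (g2.mu, g2.lambda_g)
        assert calibrate(hmm, n_cal=150, seed=10).mu != g1.mu

    def test_n_cal_minimum(self, rng):
        with pytest.raises(ValueError):
            calibrate(random_profile(rng, 5, BACKGROUND_FREQS), n_cal=50)


class TestEvalue:
    def test_closed_form_at_location(self, rng):
        hmm = random_profile(rng, 8, BACKGROUND_FREQS)
        calibrate(hmm, seed=1)
        e = evalue(hmm, hmm.calibration.mu, n_targets=1)
        assert e == pytest.approx(1 - math.exp(-1), abs=1e-12)

    def test_limits_and_monotonicity(self, rng):
        hmm = random_profile(rng, 8, BACKGROUND_FREQS)
        calibrate(hmm, seed=1)
        scores = np.linspace(-20, 200, 60)
        evals = [evalue(hmm, s, n_targets=500) for s in scores]
        assert all(a >= b for a, b in zip(evals, evals[1:]))
        assert evals[-1] < 1e-30
        assert all(e >= 0 for e in evals)

    def test_uncalibrated_profile_rejected(self, rng):
        hmm = random_profile(rng, 8, BACKGROUND_FREQS)
        with pytest.raises(ValueError, match="not calibrated"):
            evalue(hmm, 10.0, 100)

    def test_null_search_yields_about_e_hits_at_threshold(self, rng):
        """In a search of 1000 background targets, roughly one hit reaches
        E <= 1 (within 3 sqrt(e) over replicates)."""
        hmm = random_profile(rng, 15, BACKGROUND_FREQS)
        calibrate(hmm, n_cal=400, seed=3)
        counts = []
        for rep in range(5):
            r2 = np.random.default_rng(100 + rep)
            seqs = [r2.choice(20, size=30, p=BACKGROUND_FREQS)
                    for _ in range(1000)]
            bits = forward_batch_raw(hmm, seqs) / LN2
            evals = np.array([evalue(hmm, float(b), 1000) for b in bits])
            counts.append(int((evals <= 1.0).sum()))
        assert abs(np.mean(counts) - 1.0) <= 3.0


class TestLogo:
    def test_background_emissions_have_zero_relative_entropy(self):
        hmm = ProfileHMM(name="bg", subfamily="s", region="r", M=2,
                         match_emit=np.tile(BACKGROUND_FREQS, (2, 1)),
                         insert_emit=BACKGROUND_FREQS.copy(),
                         t_m=np.tile([0.9, 0.05, 0.05], (2, 1)),
                         t_i=np.tile([0.5, 0.5], (2, 1)),
                         t_d=np.tile([0.5, 0.5], (2, 1)),
                         background=BACKGROUND_FREQS.copy())
        recs = logo(hmm)
        assert all(r.relative_entropy == pytest.approx(0.0, abs=1e-12)
                   for r in recs)
        assert not any(r.indel for r in recs)

    def test_one_hot_against_uniform_background_is_log2_20(self):
        uniform = np.full(20, 1 / 20)
        emit = np.zeros((1, 20))
        emit[0, 0] = 1.0
        hmm = ProfileHMM(name="oh", subfamily="s", region="r", M=1,
                         match_emit=emit, insert_emit=uniform.copy(),
                         t_m=np.array([[0.7, 0.2, 0.1]]),
                         t_i=np.array([[0.5, 0.5]]),
                         t_d=np.array([[0.5, 0.5]]),
                         background=uniform.copy())
        rec = logo(hmm)[0]
        assert rec.relative_entropy == pytest.approx(math.log2(20), abs=1e-12)
        assert rec.letters[0] == ("A", pytest.approx(math.log2(20)))
        assert rec.indel  # M->I = 0.2 exceeds the 0.10 threshold
        # the threshold is strict: exactly 0.10 must not flag
        hmm2 = ProfileHMM(name="oh2", subfamily="s", region="r", M=1,
                          match_emit=emit.copy(), insert_emit=uniform.copy(),
                          t_m=np.array([[0.80, 0.10, 0.10]]),
                          t_i=np.array([[0.5, 0.5]]),
                          t_d=np.array([[0.5, 0.5]]),
                          background=uniform.copy())
        assert not logo(hmm2)[0].indel

    def test_relative_entropy_matches_direct_summation(self, rng):
        hmm = random_profile(rng, 10, BACKGROUND_FREQS)
        recs = logo(hmm)
        for k, rec in enumerate(recs):
            direct = sum(hmm.match_emit[k, a]
                         * math.log2(hmm.match_emit[k, a] / hmm.background[a])
                         for a in range(20) if hmm.match_emit[k, a] > 0)
            assert rec.relative_entropy == pytest.approx(direct, abs=1e-12)


class TestSerialization:
    def test_json_round_trip_is_exact(self, rng):
        hmm = random_profile(rng, 14, BACKGROUND_FREQS)
        calibrate(hmm, seed=2)
        clone = from_dict(json.loads(json.dumps(to_dict(hmm))))
        assert np.array_equal(clone.match_emit, hmm.match_emit)
        assert np.array_equal(clone.t_m, hmm.t_m)
        assert clone.calibration == hmm.calibration
        seq = aa_string(rng, 25)
        assert forward_raw(clone, seq) == forward_raw(hmm, seq)

    def test_unknown_schema_rejected(self):
        with pytest.raises(ValueError, match="schema"):
            from_dict({"schema": "other"})
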