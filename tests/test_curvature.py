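"""Curvature sum, curve, pattern construction and matched filtering."""
import itertools

import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view

from nucleocurve.core import GenomeSequence
from nucleocurve.curvature import (
    CurvatureParams,
    CurvaturePattern,
    RollTiltTable,
    build_pattern,
    curvature_at,
    curvature_curve,
    curvature_profile,
    default_table,
    idealized_pattern,
)

from conftest import STEPS, brute_force_curvature


class TestCurvatureAt:
    def test_straight_bdna_is_zero(self, zero_table, default_params):
        steps = ["AA"] * default_params.window
        assert curvature_at(steps, zero_table, default_params) == 0.0

    def test_uniform_roll_matches_complex_sum_oracle(self, roll_one_table, default_params):
        # frozen from the independent brute-force summation
        value = curvature_at(["AC"] * 10, roll_one_table, default_params)
        assert value == pytest.approx(0.42136759889042735, abs=1e-12)

    def test_agrees_with_brute_force_on_random_windows(self, rng):
        for _ in range(200):
            W = int(rng.integers(5, 31))
            table = RollTiltTable(
                {s: (float(r), float(t))
                 for s, (r, t) in zip(STEPS, rng.normal(0, 8, size=(16, 2)))}
            )
            steps = [STEPS[i] for i in rng.integers(0, 16, size=W)]
            params = CurvatureParams(window=W)
            assert curvature_at(steps, table, params) == pytest.approx(
                brute_force_curvature(steps, table), abs=1e-9
            )

    def test_in_phase_bending_beats_permutations(self, rng):
        # rolls/tilts tracing the helical phase exactly give the largest
        # modulus; any permutation of the same multiset scores lower
        # with the convention w_j = rho_j - i*tau_j, the wedge vectors all
        # align when rho_j = cos(2*pi*j/nu0) and tau_j = +sin(2*pi*j/nu0)
        nu0, W = 10.4, 10
        j = np.arange(W)
        rolls = np.cos(2 * np.pi * j / nu0)
        tilts = np.sin(2 * np.pi * j / nu0)
        # encode per-position angles through 10 distinct step labels
        labels = STEPS[:W]
        table = RollTiltTable(
            {**{s: (0.0, 0.0) for s in STEPS},
             **{l: (float(r), float(t)) for l, r, t in zip(labels, rolls, tilts)}}
        )
        params = CurvatureParams(window=W)
        in_phase = curvature_at(labels, table, params)
        for _ in range(100):
            perm = list(rng.permutation(labels))
            if perm == labels:
                continue
            assert curvature_at(perm, table, params) < in_phase

    def test_unknown_step_raises(self, zero_table, default_params):
        with pytest.raises(KeyError):
            curvature_at(["XX"] * 10, zero_table, default_params)

    def test_window_length_mismatch_raises(self, zero_table, default_params):
        with pytest.raises(ValueError):
            curvature_at(["AA"] * 5, zero_table, default_params)

    def test_literal_exponent_convention_differs(self, random_table):
        helical = CurvatureParams(exp_convention="helical")
        literal = CurvatureParams(exp_convention="literal")
        steps = ["GA", "AC", "CT", "TG", "GA", "AC", "CT", "TG", "GA", "AC"]
        assert curvature_at(steps, random_table, helical) != pytest.approx(
            curvature_at(steps, random_table, literal)
        )


class TestCurvatureCurve:
    def test_homopolymer_gives_constant_curve(self, random_table, default_params):
        seq = GenomeSequence("x", "A" * 50)
        curve = curvature_curve(seq, random_table, default_params)
        assert len(curve) == 50 - default_params.window
        assert np.allclose(curve.values, curve.values[0])

    def test_every_position_matches_per_window_oracle(self, random_table, default_params, rng):
        seq = GenomeSequence("x", "".join(rng.choice(list("ACGT"), 30)))
        curve = curvature_curve(seq, random_table, default_params)
        W = default_params.window
        assert curve.start == W // 2
        for i in range(len(curve)):
            steps = [seq.seq[i + k:i + k + 2] for k in range(W)]
            assert curve.values[i] == pytest.approx(
                brute_force_curvature(steps, random_table), abs=1e-9
            )

    def test_n_windows_masked_to_zero(self, random_table, default_params):
        seq = GenomeSequence("x", "ACGT" * 5 + "N" + "ACGT" * 5)
        curve = curvature_curve(seq, random_table, default_params)
        assert curve.mask is not None
        assert np.all(curve.values[curve.mask] == 0.0)
        # the N at index 20 invalidates steps 19 and 20, hence every
        # window touching them
        W = default_params.window
        touched = [i for i in range(len(curve)) if i <= 20 <= i + W]
        assert all(curve.mask[i] for i in touched if i < len(curve))

    def test_interior_values_unaffected_by_flanking_n(self, random_table, default_params):
        core = "ACGTACGTACGTACGTACGTACGTACGT"
        plain = curvature_curve(GenomeSequence("x", core), random_table, default_params)
        padded = curvature_curve(
            GenomeSequence("x", "NNN" + core + "NNN"), random_table, default_params
        )
        W = default_params.window
        inner = padded.values[~padded.mask]
        assert np.allclose(inner, plain.values[~plain.mask])

    def test_too_short_sequence_raises(self, random_table, default_params):
        with pytest.raises(ValueError):
            curvature_curve(GenomeSequence("x", "ACGTACGT"), random_table, default_params)

    def test_reverse_complement_reverses_curve_with_default_table(self, rng):
        # the bundled table is strand-symmetric (rc step: same roll,
        # negated tilt), so the curve of the reverse complement is the
        # reversed curve
        table = default_table()
        seq = GenomeSequence("x", "".join(rng.choice(list("ACGT"), 80)))
        fwd = curvature_curve(seq, table).values
        rev = curvature_curve(seq.reverse_complement(), table).values
        assert np.allclose(rev, fwd[::-1], atol=1e-9)

    def test_scaling_angles_scales_curve_linearly(self, random_table, default_params, rng):
        seq = GenomeSequence("x", "".join(rng.choice(list("ACGT"), 60)))
        base = curvature_curve(seq, random_table, default_params).values
        scaled = curvature_curve(seq, random_table.scaled(3.5), default_params).values
        assert np.allclose(scaled, 3.5 * base, atol=1e-9)


class TestPatterns:
    def test_single_sequence_pattern_is_own_normalized_curve(self, random_table, default_params, rng):
        seq = GenomeSequence("c", "".join(rng.choice(list("ACGT"), 146)))
        pat = build_pattern([seq], random_table, default_params)
        curve = curvature_curve(seq, random_table, default_params).values
        expect = curve - curve.mean()
        expect /= np.linalg.norm(expect)
        assert np.allclose(pat.values, expect)
        assert pat.dyad_index == len(curve) // 2

    def test_duplicated_input_equals_single_copy(self, random_table, default_params, rng):
        seq = GenomeSequence("c", "".join(rng.choice(list("ACGT"), 146)))
        one = build_pattern([seq], random_table, default_params)
        three = build_pattern([seq] * 3, random_table, default_params)
        assert np.allclose(one.values, three.values)

    def test_two_sequence_mean_matches_hand_summation(self, random_table, default_params, rng):
        seqs = [GenomeSequence(f"c{i}", "".join(rng.choice(list("ACGT"), 147)))
                for i in range(2)]
        pat = build_pattern(seqs, random_table, default_params)
        c0 = curvature_curve(seqs[0], random_table, default_params).values
        c1 = curvature_curve(seqs[1], random_table, default_params).values
        mean = (c0 + c1) / 2
        expect = (mean - mean.mean()) / np.linalg.norm(mean - mean.mean())
        assert np.allclose(pat.values, expect)

    def test_mixed_lengths_rejected(self, random_table, default_params):
        seqs = [GenomeSequence("a", "ACGT" * 37 , ), GenomeSequence("b", "ACGT" * 36)]
        with pytest.raises(ValueError):
            build_pattern(seqs, random_table, default_params)

    def test_idealized_is_mirror_symmetric_and_normalized(self):
        pat = idealized_pattern()
        assert len(pat) == 147
        assert pat.dyad_index == 73
        assert np.allclose(pat.values, pat.values[::-1], atol=1e-12)
        assert pat.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.norm(pat.values) == pytest.approx(1.0, abs=1e-12)

    def test_idealized_ends_exceed_middle(self):
        pat = idealized_pattern()
        ends = np.r_[pat.values[:50], pat.values[-50:]].mean()
        middle = pat.values[55:92].mean()
        assert ends > middle


class TestCurvatureProfile:
    def test_matched_filter_identity_peaks_at_embedding_dyad(self):
        from nucleocurve.core import ScoreTrack

        pat = idealized_pattern()
        values = np.zeros(1000)
        at = 400  # embedding start; dyad lands at at + dyad_index
        values[at:at + len(pat)] = pat.values
        curve = ScoreTrack("x", 0, values)
        prof = curvature_profile(curve, pat)
        peak_pos = prof.start + int(np.argmax(prof.values))
        assert peak_pos == at + pat.dyad_index
        assert prof.values.max() == pytest.approx(1.0)

    def test_constant_offset_invariance(self, rng):
        from nucleocurve.core import ScoreTrack

        pat = idealized_pattern()
        values = rng.normal(size=600)
        a = curvature_profile(ScoreTrack("x", 0, values), pat)
        b = curvature_profile(ScoreTrack("x", 0, values + 11.5), pat)
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_every_value_matches_sliding_dot_oracle(self, rng):
        from nucleocurve.core import ScoreTrack

        pat = idealized_pattern()
        values = rng.normal(size=500)
        prof = curvature_profile(ScoreTrack("x", 0, values), pat)
        L = len(pat)
        for p in range(len(values) - L + 1):
            oracle = float(np.dot(values[p:p + L], pat.values))
            assert prof.values[p] == pytest.approx(oracle, abs=1e-9)
        assert prof.start == pat.dyad_index

    def test_curve_shorter_than_pattern_raises(self):
        from nucleocurve.core import ScoreTrack

        pat = idealized_pattern()
        with pytest.raises(ValueError):
            curvature_profile(ScoreTrack("x", 0, np.zeros(100)), pat)


class TestTableProperties:
    def test_default_table_is_strand_symmetric(self):
        from nucleocurve.core import reverse_complement

        table = default_table()
        for step, (roll, tilt) in table.angles.items():
            rc = reverse_complement(step)
            assert table.roll(rc) == pytest.approx(roll)
            assert table.tilt(rc) == pytest.approx(-tilt)

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError):
            RollTiltTable({"AA": (1.0, 0.0)})

    def test_palindromic_window_modulus_under_rc_relabeling(self, rng):
        # a palindromic step window maps to itself under the
        # reverse-complement relabeling; modulus must be unchanged
        table = default_table()
        params = CurvatureParams(window=10)
        half = "".join(rng.choice(list("ACGT"), 6))
        from nucleocurve.core import reverse_complement
        pal = half + reverse_complement(half)  # 12-mer palindrome
        steps = [pal[i:i + 2] for i in range(10)]
        rc_steps = [reverse_complement(s) for s in reversed(steps)]
        assert curvature_at(steps, table, params) == pytest.approx(
            curvature_at(rc_steps, table, params), abs=1e-9
        )
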