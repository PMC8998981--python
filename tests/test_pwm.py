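"""PWM construction, normalization constraints, and alignment extraction."""

import numpy as np
import pytest
from scipy import optimize

from pwmsa.io import ALPHABET, ALPHABET_SIZE, MultipleAlignment, ProteinSequence, SequenceSet
from pwmsa.pwm import (
    DegeneratePWMError,
    FrequencyMatrix,
    GappyAlignmentError,
    ScoringParams,
    WeightMatrix,
    build_random_pwm,
    filter_gappy_columns,
    pwm_from_msa,
    standardize_counts,
    transform_pwm,
)
from tests.conftest import random_set


def _random_wm(rng, L, p1=None, p2=None):
    w = rng.normal(size=(ALPHABET_SIZE, L))
    if p1 is None:
        p1 = rng.dirichlet(np.ones(ALPHABET_SIZE))
    if p2 is None:
        p2 = np.full(L, 1.0 / L)
    return WeightMatrix(w, p1, p2)


class TestScoringParams:
    def test_defaults(self):
        p = ScoringParams()
        assert (p.d, p.e, p.r_l, p.k_d) == (40.0, 1.0, 5.0, -1.0)

    def test_requires_d_ge_e_gt_zero(self):
        with pytest.raises(ValueError):
            ScoringParams(d=1.0, e=2.0)
        with pytest.raises(ValueError):
            ScoringParams(d=1.0, e=0.0)


class TestTransform:
    def test_constraints_hold(self, rng, params):
        for L in (3, 5, 17):
            w = transform_pwm(_random_wm(rng, L), params)
            assert w.r2() == pytest.approx(params.r2_target(L), rel=1e-6)
            assert w.kd() == pytest.approx(params.k_d, abs=1e-6)

    def test_random_20x5_hits_printed_targets(self, rng, params):
        w = transform_pwm(_random_wm(rng, 5), params)
        assert w.r2() == pytest.approx(5 * 20 * 5, rel=1e-6)
        assert w.kd() == pytest.approx(-1.0, abs=1e-6)

    def test_already_normalized_is_fixed_point(self, rng, params):
        w = transform_pwm(_random_wm(rng, 6), params)
        again = transform_pwm(w, params)
        np.testing.assert_allclose(again.weights, w.weights, atol=1e-9)

    def test_matches_numeric_root_finding(self, rng, params):
        """Closed-form (a, b) equals an independent 2-D numeric solve."""
        for _ in range(10):
            wm = _random_wm(rng, 4)
            P = np.outer(wm.p1, wm.p2)

            def equations(ab, w=wm.weights):
                a, b = ab
                wp = a * w + b
                return [np.sum(wp ** 2) - params.r2_target(4),
                        np.sum(wp * P) - params.k_d]

            sol, _, ok, _ = optimize.fsolve(
                equations, x0=[1.0, 0.0], full_output=True
            )
            assert ok == 1
            a_num, b_num = sol
            got = transform_pwm(wm, params)
            if a_num > 0:  # fsolve found the same (order-preserving) root
                np.testing.assert_allclose(
                    got.weights, a_num * wm.weights + b_num, atol=1e-6
                )
            assert got.r2() == pytest.approx(params.r2_target(4), rel=1e-6)
            assert got.kd() == pytest.approx(params.k_d, abs=1e-6)

    def test_degenerate_flat_matrix_raises(self, params):
        w = WeightMatrix(np.ones((20, 3)),
                         np.full(20, 0.05), np.full(3, 1 / 3))
        with pytest.raises(DegeneratePWMError):
            transform_pwm(w, params)

    def test_r2_linear_in_rl(self, rng):
        wm = _random_wm(rng, 8)
        lo = transform_pwm(wm, ScoringParams(r_l=2.5))
        hi = transform_pwm(wm, ScoringParams(r_l=5.0))
        assert hi.r2() == pytest.approx(2.0 * lo.r2(), rel=1e-9)


class TestStandardization:
    def test_frequency_matrix_marginals(self, rng):
        counts = rng.integers(1, 50, size=(ALPHABET_SIZE, 6))
        fm = FrequencyMatrix(counts)
        np.testing.assert_array_equal(fm.row_sums, counts.sum(axis=1))
        np.testing.assert_array_equal(fm.col_sums, counts.sum(axis=0))
        assert fm.total == counts.sum()

    def test_standardized_cells_centered_with_unit_spread(self, rng):
        """Monte Carlo check of the binomial z-standardization.

        Multinomial column counts under the independence model should
        standardize to roughly mean-zero, unit-variance cells.
        """
        freqs = np.full(ALPHABET_SIZE, 1.0 / ALPHABET_SIZE)
        cells = []
        for _ in range(500):
            counts = rng.multinomial(200, freqs, size=4).T
            cells.append(standardize_counts(FrequencyMatrix(counts + 1)))
        cells = np.concatenate([c.ravel() for c in cells])
        assert abs(cells.mean()) < 0.05
        assert 0.5 < cells.std() < 1.5

    def test_zero_count_guard(self):
        counts = np.zeros((ALPHABET_SIZE, 3), dtype=int)
        counts[0, :] = 10
        with pytest.raises(ValueError):
            standardize_counts(FrequencyMatrix(counts))


class TestBuildRandomPwm:
    def test_invariants_after_construction(self, rng, params, small_set):
        w = build_random_pwm(small_set, 10, params, rng, k=100)
        assert w.n_columns == 10
        assert w.r2() == pytest.approx(params.r2_target(10), rel=1e-6)
        assert w.kd() == pytest.approx(params.k_d, abs=1e-6)

    def test_degenerate_composition(self, rng, params):
        """A homopolymer set standardizes to finite (all-zero) cells; the
        flat matrix then has no information to normalize, which is reported
        as a degeneracy rather than NaNs."""
        counts = np.ones((ALPHABET_SIZE, 5), dtype=int)
        counts[0, :] += 50  # every draw was 'A'
        raw = standardize_counts(FrequencyMatrix(counts))
        assert np.all(np.isfinite(raw))
        np.testing.assert_allclose(raw, 0.0, atol=1e-12)
        si = SequenceSet([ProteinSequence("a", "AAAAA"),
                          ProteinSequence("b", "AAAA")])
        with pytest.raises(DegeneratePWMError):
            build_random_pwm(si, 5, params, rng, k=50)

    def test_bad_arguments(self, rng, params, small_set):
        with pytest.raises(ValueError):
            build_random_pwm(small_set, 0, params, rng)
        with pytest.raises(ValueError):
            build_random_pwm(small_set, 5, params, rng, k=0)


class TestPwmFromMsa:
    def test_gapless_identity_column_map(self, params):
        ma = MultipleAlignment(["a", "b", "c"],
                               ["ACDEF", "ACDEG", "ACDEH"])
        w, cmap = pwm_from_msa(ma, params)
        np.testing.assert_array_equal(cmap, np.arange(5))
        assert w.n_columns == 5

    def test_majority_gap_column_removed(self, params):
        # column 2 has 1 residue of 4 rows: 1 < 4/2, dropped
        ma = MultipleAlignment(
            ["a", "b", "c", "d"],
            ["AC-DE", "AC-DE", "AC-DE", "ACWDE"],
        )
        filtered, cmap = filter_gappy_columns(ma)
        assert filtered.k == 4
        np.testing.assert_array_equal(cmap, [0, 1, 3, 4])

    def test_exact_half_kept(self, params):
        # column 2 has 2 residues of 4 rows: 2 >= 4/2, kept
        ma = MultipleAlignment(
            ["a", "b", "c", "d"],
            ["AC-DE", "AC-DE", "ACWDE", "ACWDE"],
        )
        filtered, _ = filter_gappy_columns(ma)
        assert filtered.k == 5

    def test_all_columns_gappy_raises(self, params):
        ma = MultipleAlignment(["a", "b", "c", "d"],
                               ["A---", "-C--", "--D-", "---E"])
        with pytest.raises(GappyAlignmentError):
            pwm_from_msa(ma, params)

    def test_counts_match_hand_recount(self, rng, params):
        """V and the standardized cells agree with a brute-force recount."""
        rows = ["ACDEFGHI", "ACDEFGHL", "ACWEFGHI", "GCDEFGHI", "ACDEFAHI"]
        ma = MultipleAlignment(list("abcde"), rows)
        w, cmap = pwm_from_msa(ma, params)
        # brute-force recount (independent of the library path)
        counts = np.ones((ALPHABET_SIZE, 8), dtype=float)  # pseudocount
        for row in rows:
            for j, c in enumerate(row):
                counts[ALPHABET.index(c), j] += 1
        x = counts.sum(axis=1, keepdims=True)
        y = counts.sum(axis=0, keepdims=True)
        u = counts.sum()
        p = x * y / u ** 2
        raw = (counts - u * p) / np.sqrt(u * p * (1 - p))
        # reproduce the affine map from the two constraints
        p1 = (x / u).ravel()
        p2 = np.full(8, 1 / 8)
        P = np.outer(p1, p2)
        s1 = np.sum(raw * P)
        uu = raw - s1
        a2, a1 = np.sum(uu ** 2), 2 * params.k_d * np.sum(uu)
        a0 = raw.size * params.k_d ** 2 - params.r2_target(8)
        a = (-a1 + np.sqrt(a1 ** 2 - 4 * a2 * a0)) / (2 * a2)
        expected = a * raw + (params.k_d - a * s1)
        np.testing.assert_allclose(w.weights, expected, atol=1e-9)

    def test_consensus_column_structure(self, params):
        """Identical gapless rows: one strongly positive cell per column,
        19 equal negative cells."""
        ma = MultipleAlignment(["a", "b", "c", "d"],
                               ["ACDE"] * 4)
        w, _ = pwm_from_msa(ma, params)
        absent = [i for i, aa in enumerate(ALPHABET) if aa not in "ACDE"]
        for j, consensus in enumerate("ACDE"):
            col = w.weights[:, j]
            hit = ALPHABET.index(consensus)
            assert col[hit] > 0
            assert np.all(np.delete(col, hit) < 0)
            # rows absent from the consensus share a marginal, hence a value
            np.testing.assert_allclose(col[absent], col[absent[0]], atol=1e-9)

    def test_single_row_rejected(self, params):
        with pytest.raises(ValueError):
            pwm_from_msa(MultipleAlignment(["a"], ["AC"]), params)


class TestTsvRoundTrip:
    def test_dump_load(self, tmp_path, rng, params):
        w = transform_pwm(_random_wm(rng, 4), params)
        path = tmp_path / "pwm.tsv"
        w.to_tsv(path)
        back = WeightMatrix.from_tsv(path, w.p1, w.p2)
        np.testing.assert_array_equal(back.weights, w.weights)
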