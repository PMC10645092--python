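import math

import numpy as np
import pytest
from scipy import stats

from conftest import random_incidence
from oracles import (
    brute_c_score,
    enumerate_fixed_marginal,
    exact_null_moments,
)
from traitcooc.io import IncidenceMatrix
from traitcooc.nullmodel import (
    PairSESRecord,
    curveball_trade,
    pair_c_score,
    pool_mean_ses,
    sample_null,
    watershed_pair_ses,
)


def matrix_from(cells, wid="w"):
    cells = np.asarray(cells, dtype=np.int8)
    return IncidenceMatrix(
        wid,
        tuple(f"s{i}" for i in range(cells.shape[0])),
        tuple(f"l{j}" for j in range(cells.shape[1])),
        cells,
    )


class TestPairCScore:
    def test_worked_example(self):
        # a in lakes {1,2,3}, b in {3,4}: r_a=3, r_b=2, s=1 -> 2
        m = matrix_from([[1, 1, 1, 0], [0, 0, 1, 1]])
        assert pair_c_score(m, "s0", "s1") == 2

    def test_identical_rows_score_zero(self):
        m = matrix_from([[1, 1, 0], [1, 1, 0]])
        assert pair_c_score(m, "s0", "s1") == 0

    def test_disjoint_rows(self):
        m = matrix_from([[1, 1, 0, 0, 0], [0, 0, 1, 1, 1]])
        assert pair_c_score(m, "s0", "s1") == 6

    def test_same_species_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            pair_c_score(tiny_matrix, "a", "a")

    def test_unknown_species_rejected(self, tiny_matrix):
        with pytest.raises(KeyError):
            pair_c_score(tiny_matrix, "a", "zz")

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            m = random_incidence(
                rng, int(rng.integers(2, 6)), int(rng.integers(2, 7))
            )
            i, j = rng.choice(m.n_species, size=2, replace=False)
            assert pair_c_score(
                m, m.species_ids[i], m.species_ids[j]
            ) == brute_c_score(np.asarray(m.cells), i, j)


class TestCurveballTrade:
    def test_two_state_system(self):
        m = matrix_from([[1, 0], [0, 1]])
        rng = np.random.default_rng(0)
        seen = set()
        for _ in range(50):
            out = curveball_trade(m, rng)
            assert out.row_sums().tolist() == [1, 1]
            assert out.col_sums().tolist() == [1, 1]
            seen.add(bytes(np.asarray(out.cells)))
        assert seen == {b"\x01\x00\x00\x01", b"\x00\x01\x01\x00"}

    def test_marginal_unique_matrix_unchanged(self):
        m = matrix_from([[1, 1], [1, 0]])
        rng = np.random.default_rng(1)
        for _ in range(20):
            assert np.array_equal(curveball_trade(m, rng).cells, m.cells)

    def test_conservation_over_many_trades(self):
        rng = np.random.default_rng(7)
        m = random_incidence(rng, 20, 20)
        r, c = m.row_sums(), m.col_sums()
        cur = m
        for _ in range(2_000):
            cur = curveball_trade(cur, rng)
            assert np.array_equal(cur.row_sums(), r)
            assert np.array_equal(cur.col_sums(), c)

    def test_single_row_rejected(self):
        m = matrix_from([[1, 0, 1]])
        with pytest.raises(ValueError):
            curveball_trade(m, np.random.default_rng(0))


class TestSampleNull:
    def test_uniform_over_enumerable_set(self):
        # 3×3 with row sums (1,1,2), col sums (1,1,2)
        m = matrix_from([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        base = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 1]], dtype=np.int8)
        m = matrix_from(base)
        states = enumerate_fixed_marginal(base)
        assert len(states) > 1
        keys = {s.tobytes(): k for k, s in enumerate(states)}
        counts = np.zeros(len(states))
        rng = np.random.default_rng(11)
        for s in sample_null(m, n_samples=20_000, burn_in=200, thin=5, rng=rng):
            counts[keys[np.asarray(s.cells).tobytes()]] += 1
        assert counts.sum() == 20_000
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_marginal_unique_matrix_yields_itself(self):
        m = matrix_from([[1, 1], [1, 0]])
        for s in sample_null(m, n_samples=5, burn_in=10, thin=3,
                             rng=np.random.default_rng(2)):
            assert np.array_equal(s.cells, m.cells)

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        m = random_incidence(rng, 8, 10)
        runs = []
        for _ in range(2):
            out = list(
                sample_null(m, n_samples=20, burn_in=50, thin=5,
                            rng=np.random.default_rng(99))
            )
            runs.append([np.asarray(s.cells).tobytes() for s in out])
        assert runs[0] == runs[1]

    def test_too_few_samples_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            next(sample_null(tiny_matrix, n_samples=1))


class TestWatershedPairSES:
    def test_ses_formula_and_degenerate_flag(self):
        # marginal-unique matrix: every pair degenerate (null has one state)
        m = matrix_from([[1, 1], [1, 0]])
        (rec,) = watershed_pair_ses(m, n_samples=50, burn_in=10, thin=2,
                                    rng=np.random.default_rng(0))
        assert rec.degenerate and math.isnan(rec.ses) and rec.null_sd == 0.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(123)
        n_samples, checked = 2_000, 0
        for _ in range(12):
            m = random_incidence(rng, 4, 4, fill=0.5)
            states = enumerate_fixed_marginal(np.asarray(m.cells))
            if not 2 <= len(states) <= 60:
                continue
            recs = {
                (r.species_a, r.species_b): r
                for r in watershed_pair_ses(
                    m, n_samples=n_samples, burn_in=200, thin=20, rng=rng
                )
            }
            for i in range(4):
                for j in range(i + 1, 4):
                    mean, sd, mu4 = exact_null_moments(np.asarray(m.cells), i, j)
                    rec = recs[tuple(sorted((f"s{i}", f"s{j}")))]
                    if sd == 0:
                        assert rec.degenerate
                        continue
                    checked += 1
                    # sampled SES vs exact, within 3 Monte-Carlo SEs
                    ses_exact = (rec.c_obs - mean) / sd
                    var_mean = sd**2 / n_samples
                    var_sd = max(mu4 - sd**4, 0.0) / (4 * sd**2 * n_samples)
                    se = math.sqrt(
                        var_mean / sd**2 + ses_exact**2 * var_sd / sd**2
                    )
                    assert rec.ses == pytest.approx(ses_exact, abs=3 * se + 1e-9)
        assert checked >= 10

    def test_sign_convention_max_segregation_nonnegative(self):
        # c_obs at the maximum attainable given marginals -> SES >= 0
        m = matrix_from([[1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 1, 0]])
        recs = watershed_pair_ses(m, n_samples=500, burn_in=200, thin=5,
                                  rng=np.random.default_rng(8))
        rec = next(r for r in recs if {r.species_a, r.species_b} == {"s0", "s1"})
        assert rec.c_obs == 4  # disjoint: maximal
        assert rec.degenerate or rec.ses >= 0


class TestPooling:
    @staticmethod
    def rec(wid, a, b, ses, degenerate=False):
        return PairSESRecord(wid, a, b, 0, 0.0, 0.0 if degenerate else 1.0,
                             math.nan if degenerate else ses, degenerate)

    def test_mean_and_counts(self):
        out = pool_mean_ses(
            [self.rec("w1", "a", "b", 1.0), self.rec("w2", "a", "b", -1.0),
             self.rec("w1", "a", "c", 2.5)]
        )
        ab = out[(out.species_a == "a") & (out.species_b == "b")].iloc[0]
        assert ab.mean_ses == pytest.approx(0.0) and ab.n_watersheds == 2
        ac = out[(out.species_a == "a") & (out.species_b == "c")].iloc[0]
        assert ac.mean_ses == 2.5 and ac.n_watersheds == 1

    def test_degenerate_excluded(self):
        out = pool_mean_ses(
            [self.rec("w1", "a", "b", 0.5),
             self.rec("w2", "a", "b", 0, degenerate=True)]
        )
        row = out.iloc[0]
        assert row.mean_ses == 0.5 and row.n_watersheds == 1

    def test_all_degenerate_pair_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = pool_mean_ses(
                [self.rec("w1", "a", "b", 0, degenerate=True),
                 self.rec("w1", "a", "c", 1.0)]
            )
        assert len(out) == 1 and out.iloc[0].species_b == "c"
        assert "degenerate" in caplog.text
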