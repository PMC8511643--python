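import numpy as np
import pytest

from wvmda import (
    AssociationMatrix,
    SimilarityMatrix,
    basic_weight,
    group_weight,
    score,
    voter_counts,
)
from wvmda.data_io import DataFormatError

from .conftest import random_association, random_similarity


def loop_score(a, m_sim, d_sim, e):
    """Independent scalar transcription of the weighted vote.

    Every known association (i, s) in the candidate's row, and (t, j) in
    its column, casts a vote for candidate (i, j); each vote carries the
    shared-group weight, the voter-candidate similarity, and one over
    the number of voters connected to the candidate.
    """
    n, m = a.shape
    n_mi = a.sum(axis=1)
    n_ds = a.sum(axis=0)
    f = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            den = n_mi[i] + n_ds[j] - a[i, j]
            if den <= 0:
                continue
            total = 0.0
            for s in range(m):
                if a[i, s]:
                    total += (n_mi[i] ** e) * d_sim[j, s] / den
            for t in range(n):
                if a[t, j]:
                    total += (n_ds[j] ** e) * m_sim[i, t] / den
            f[i, j] = total
    return f


class TestVoterCounts:
    def test_row_and_column_sums(self):
        assoc = AssociationMatrix(
            ["m1", "m2"], ["d1", "d2", "d3"], np.array([[1, 1, 0], [1, 0, 0]])
        )
        counts = voter_counts(assoc)
        np.testing.assert_array_equal(counts.n_mirna, [2, 1])
        np.testing.assert_array_equal(counts.n_disease, [2, 1, 0])

    def test_totals_match_known_associations(self, rng):
        assoc = random_association(rng, 7, 5)
        counts = voter_counts(assoc)
        assert counts.n_mirna.sum() == counts.n_disease.sum() == assoc.n_known


class TestBasicWeight:
    @pytest.fixture
    def assoc(self):
        return AssociationMatrix(
            ["m1", "m2"], ["d1", "d2", "d3"], np.array([[1, 1, 0], [1, 0, 0]])
        )

    def test_candidate_without_column_voters(self, assoc):
        # candidate (m1, d3): 2 row voters, 0 column voters, not itself a voter
        assert basic_weight(voter_counts(assoc), assoc, 0, 2) == 0.5

    def test_voter_candidate(self, assoc):
        # (m1, d1) is itself a voter: 2 + 2 - 1 connected voters
        assert basic_weight(voter_counts(assoc), assoc, 0, 0) == pytest.approx(1 / 3)

    def test_single_connected_voter(self):
        assoc = AssociationMatrix(
            ["m1"], ["d1", "d2"], np.array([[1, 0]])
        )
        assert basic_weight(voter_counts(assoc), assoc, 0, 1) == 1.0

    def test_isolated_candidate_weight_zero(self):
        assoc = AssociationMatrix(
            ["m1", "m2"], ["d1", "d2"], np.array([[1, 0], [0, 0]])
        )
        assert basic_weight(voter_counts(assoc), assoc, 1, 1) == 0.0


class TestGroupWeight:
    def test_cube_root(self):
        assert group_weight(8, e=1 / 3) == pytest.approx(2.0)

    def test_singleton_group(self):
        assert group_weight(1, e=0.7) == 1.0

    def test_disabled_at_zero_exponent(self):
        assert group_weight(5, e=0.0) == 1.0

    def test_empty_group_has_no_voice(self):
        assert group_weight(0, e=1 / 3) == 0.0

    def test_negative_exponent_rejected(self):
        with pytest.raises(ValueError):
            group_weight(2, e=-0.1)


class TestScore:
    def test_worked_instance(self, worked_example):
        """Smallest informative instance (A = I): the voter pair scores
        its two unit self-votes; the cross pair collects one row vote
        (similarity 0.2) and one column vote (0.5) over two connected
        voters.  Expected values frozen from the loop oracle."""
        sc = worked_example["scoring"]
        f = score(sc["association"], sc["mirna_sim"], sc["disease_sim"], sc["e"])
        oracle = loop_score(
            sc["association"].values, sc["mirna_sim"].values,
            sc["disease_sim"].values, sc["e"],
        )
        np.testing.assert_allclose(f.values, oracle, atol=1e-12)
        assert f.values[0, 0] == pytest.approx(2.0, abs=1e-12)
        assert f.values[0, 1] == pytest.approx(0.35, abs=1e-12)

    def test_all_zero_associations_score_zero(self, rng):
        assoc = AssociationMatrix(["m1", "m2"], ["d1"], np.zeros((2, 1), int))
        m_sim = random_similarity(rng, ["m1", "m2"])
        d_sim = SimilarityMatrix(["d1"], np.ones((1, 1)))
        assert (score(assoc, m_sim, d_sim).values == 0).all()

    def test_axis_mismatch_rejected(self, rng):
        assoc = AssociationMatrix(["m1", "m2"], ["d1"], np.ones((2, 1), int))
        m_sim = random_similarity(rng, ["mX", "mY"])
        d_sim = SimilarityMatrix(["d1"], np.ones((1, 1)))
        with pytest.raises(DataFormatError):
            score(assoc, m_sim, d_sim)

    @pytest.mark.parametrize("seed", range(20))
    def test_vectorized_equals_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 6), rng.integers(2, 9)
        assoc = random_association(rng, n, m, density=0.35)
        m_sim = random_similarity(rng, assoc.mirna_names)
        d_sim = random_similarity(rng, assoc.disease_names)
        e = float(rng.choice([0.0, 1 / 3, 0.5, 1.0]))
        f = score(assoc, m_sim, d_sim, e)
        np.testing.assert_allclose(
            f.values,
            loop_score(assoc.values, m_sim.values, d_sim.values, e),
            atol=1e-10,
        )


def ones_similarity(names):
    return SimilarityMatrix(list(names), np.ones((len(names), len(names))))


class TestVoteConservation:
    @pytest.mark.parametrize("seed", range(10))
    def test_candidates_receive_exactly_one_vote(self, seed):
        """With the group weight disabled and all similarities equal to 1,
        every non-voter candidate connected to at least one voter gets a
        total of exactly 1; every voter gets (N_mi+N_dj)/(N_mi+N_dj-1)."""
        rng = np.random.default_rng(seed)
        assoc = random_association(rng, 8, 6, density=0.3)
        f = score(assoc, ones_similarity(assoc.mirna_names),
                  ones_similarity(assoc.disease_names), e=0.0).values
        counts = voter_counts(assoc)
        total = counts.n_mirna[:, None] + counts.n_disease[None, :]
        nonvoter = (assoc.values == 0) & (total >= 1)
        np.testing.assert_allclose(f[nonvoter], 1.0, atol=1e-12)
        voters = assoc.values == 1
        np.testing.assert_allclose(
            f[voters], (total[voters]) / (total[voters] - 1), atol=1e-12
        )
        assert (f[voters] > 1.0).all()


class TestScoreProperties:
    def test_similarity_monotonicity(self, rng):
        """Raising D(dj, ds) where (mi, ds) is a voter never lowers F(mi, dj)."""
        assoc = random_association(rng, 6, 5, density=0.4)
        m_sim = random_similarity(rng, assoc.mirna_names)
        d_sim = random_similarity(rng, assoc.disease_names)
        base = score(assoc, m_sim, d_sim).values
        voters = np.argwhere(assoc.values == 1)
        i, s = voters[0]
        for j in range(assoc.m):
            if j == s:
                continue
            bumped = d_sim.values.copy()
            bumped[j, s] = min(1.0, bumped[j, s] + 0.3)
            d2 = SimilarityMatrix(assoc.disease_names, bumped)
            after = score(assoc, m_sim, d2).values
            assert after[i, j] >= base[i, j] - 1e-12

    def test_voter_dominance(self, rng):
        """With unit-diagonal similarities a known association's score is
        at least the larger of its two self-vote terms."""
        assoc = random_association(rng, 7, 6, density=0.3)
        m_sim = random_similarity(rng, assoc.mirna_names)
        d_sim = random_similarity(rng, assoc.disease_names)
        e = 1 / 3
        f = score(assoc, m_sim, d_sim, e).values
        counts = voter_counts(assoc)
        for i, j in np.argwhere(assoc.values == 1):
            den = counts.n_mirna[i] + counts.n_disease[j] - 1
            self_terms = max(counts.n_mirna[i] ** e, counts.n_disease[j] ** e) / den
            assert f[i, j] >= self_terms - 1e-12

    def test_nonnegative_for_nonnegative_similarities(self, rng):
        assoc = random_association(rng, 6, 6)
        f = score(assoc, random_similarity(rng, assoc.mirna_names),
                  random_similarity(rng, assoc.disease_names)).values
        assert (f >= 0).all() and np.isfinite(f).all()
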