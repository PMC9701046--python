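"""STC: profile enumeration, log-ratio transform, assignment, significance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stcpipe import (assign_profiles, enumerate_profiles,
                     profile_significance, transform_to_log_ratios)
from tests.conftest import make_matrix, pearson_oracle

PROFILES3 = enumerate_profiles(3, 1)


class TestEnumeration:
    def test_three_groups_unit_change_gives_eight_profiles(self):
        assert len(PROFILES3) == 8
        assert [p.changes for p in PROFILES3] == [
            (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1),
            (1, -1), (1, 0), (1, 1)]
        # ids must reproduce the trend semantics: 5 rises then falls,
        # 6 rises then is sustained, 0/1/2 fall first, 3/4 start flat
        assert PROFILES3[5].positions == (0, 1, 0)
        assert PROFILES3[6].positions == (0, 1, 1)
        assert all(PROFILES3[i].changes[0] == -1 for i in (0, 1, 2))
        assert all(PROFILES3[i].changes[0] == 0 for i in (3, 4))
        assert all(PROFILES3[i].changes[0] == 1 for i in (5, 6, 7))

    @pytest.mark.parametrize("m,c,expected", [
        (2, 1, 2), (3, 1, 8), (3, 2, 24), (4, 1, 26),
    ])
    def test_count_formula(self, m, c, expected):
        profiles = enumerate_profiles(m, c)
        assert len(profiles) == expected == (2 * c + 1) ** (m - 1) - 1
        assert [p.id for p in profiles] == list(range(expected))
        for p in profiles:
            assert p.positions[0] == 0
            assert p.positions == (0, *itertools.accumulate(p.changes))
            assert any(ch != 0 for ch in p.changes)

    @pytest.mark.parametrize("m,c", [(1, 1), (3, 0)])
    def test_invalid_arguments(self, m, c):
        with pytest.raises(ValueError):
            enumerate_profiles(m, c)


class TestLogRatios:
    def test_geometric_mean_ratios(self):
        # groups at 4, 8, 2 -> log2 ratios (0, 1, -1)
        matrix = make_matrix([[4, 4, 4, 8, 8, 8, 2, 2, 2]])
        ratios = transform_to_log_ratios(matrix)
        np.testing.assert_allclose(ratios.to_numpy(), [[0.0, 1.0, -1.0]])

    def test_geometric_mean_of_unequal_replicates(self):
        # geometric mean of (1, 2, 4) is 2 -> one doubling vs group 1 at 1
        matrix = make_matrix([[1, 1, 1, 1, 2, 4, 1, 1, 1]])
        ratios = transform_to_log_ratios(matrix)
        np.testing.assert_allclose(ratios.to_numpy(), [[0.0, 1.0, 0.0]])

    def test_equals_log_identity(self):
        rng = np.random.default_rng(3)
        matrix = make_matrix(np.exp2(rng.normal(8, 1, size=(40, 9))))
        ratios = transform_to_log_ratios(matrix)
        log2 = matrix.log2_values()
        means = np.column_stack([log2[matrix.samples_of(g)].mean(axis=1)
                                 for g in matrix.groups])
        np.testing.assert_allclose(ratios.to_numpy(),
                                   means - means[:, [0]], atol=1e-12)

    def test_nonpositive_signal_names_gene(self):
        matrix = make_matrix([[1, 2, 3, 4, 5, 6, 7, 8, 9]],
                             genes=["bad_gene"])
        matrix.values.iloc[0, 2] = -1.0  # bypass constructor validation
        with pytest.raises(ValueError, match="bad_gene"):
            transform_to_log_ratios(matrix)


class TestAssignment:
    def test_exact_scalar_multiple_has_unit_correlation(self):
        ratios = pd.DataFrame([[0.0, -2.0, -4.0]], index=["g"],
                              columns=list("abc"))
        out = assign_profiles(ratios, PROFILES3)
        assert out.loc["g", "profile"] == 0  # positions (0, -1, -2)
        assert out.loc["g", "correlation"] == pytest.approx(1.0)

    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(9)
        vecs = np.hstack([np.zeros((50, 1)), rng.normal(0, 1, size=(50, 2))])
        out = assign_profiles(pd.DataFrame(vecs, columns=list("abc")),
                              PROFILES3)
        for i, vec in enumerate(vecs):
            cors = [pearson_oracle(vec, p.positions) for p in PROFILES3]
            assert out["profile"].iloc[i] == int(np.argmax(cors))

    def test_specific_vector_lands_on_up_then_down(self):
        out = assign_profiles(
            pd.DataFrame([[0.0, 1.8, 0.1]], columns=list("abc")), PROFILES3)
        assert out["profile"].iloc[0] == 5

    def test_constant_vector_unassigned(self):
        out = assign_profiles(
            pd.DataFrame([[0.0, 0.0, 0.0]], columns=list("abc")), PROFILES3)
        assert out["profile"].isna().all()
        assert np.isnan(out["correlation"].iloc[0])

    def test_tie_breaks_to_lowest_id(self):
        # for m=2 both profiles have correlation -1/+1; a rising gene
        # matches profile 1 (+1) exactly, a falling one profile 0
        profiles = enumerate_profiles(2, 1)
        out = assign_profiles(
            pd.DataFrame([[0.0, 3.0], [0.0, -3.0]], columns=list("ab")),
            profiles)
        assert list(out["profile"]) == [1, 0]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=50),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        vec = np.array([[0.0, *rng.normal(0, 1, 2)]])
        a1 = assign_profiles(pd.DataFrame(vec, columns=list("abc")), PROFILES3)
        a2 = assign_profiles(pd.DataFrame(vec * scale, columns=list("abc")),
                             PROFILES3)
        assert a1["profile"].iloc[0] == a2["profile"].iloc[0]

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="enumerated for m"):
            assign_profiles(pd.DataFrame([[0.0, 1.0]], columns=list("ab")),
                            PROFILES3)


class TestSignificance:
    def _run(self, vecs, profiles, **kwargs):
        ratios = pd.DataFrame(vecs, columns=list("abc"))
        assignment = assign_profiles(ratios, profiles)
        return assignment, profile_significance(assignment, ratios, profiles,
                                                **kwargs)

    def test_partition_and_expected_from_six_orderings(self):
        rng = np.random.default_rng(1)
        vecs = np.hstack([np.zeros((60, 1)), rng.normal(0, 1, (60, 2))])
        assignment, sig = self._run(vecs, PROFILES3)
        assert sig["observed"].sum() + assignment["profile"].isna().sum() == 60
        # each of the 3! orderings contributes 1/6 to every expectation
        sixfold = sig["expected"].to_numpy() * 6
        assert np.allclose(sixfold, np.round(sixfold), atol=1e-9)

    def test_planted_profile_detected(self):
        # every gene sits exactly on the steady-rise positions (0, 1, 2),
        # scaled by a distinct magnitude: all land on profile 7
        rng = np.random.default_rng(2)
        scale = rng.uniform(0.5, 2.0, size=(40, 1))
        vecs = scale * np.array([[0.0, 1.0, 2.0]])
        _, sig = self._run(vecs, PROFILES3)
        row = sig.set_index("profile").loc[7]
        assert row["observed"] == 40
        assert row["expected"] < 40
        assert row["p_value"] < 0.05
        assert row["significant"]

    def test_observed_at_expectation_is_null(self):
        # symmetric design: every ordering is equivalent, so observed
        # equals expected for each profile and nothing is significant
        vecs = np.array([[0.0, 1.0, 2.0], [0.0, -1.0, -2.0],
                         [0.0, 2.0, 1.0], [0.0, -2.0, -1.0],
                         [0.0, 1.0, -1.0], [0.0, -1.0, 1.0]])
        _, sig = self._run(vecs, PROFILES3)
        assert not sig["significant"].any()
        assert (sig.loc[sig["observed"] > 0, "p_value"] >= 0.5).all()

    def test_binomial_alternative_agrees_directionally(self):
        rng = np.random.default_rng(4)
        scale = rng.uniform(0.5, 2.0, size=(40, 1))
        vecs = scale * np.array([[0.0, 1.0, 2.0]])
        ratios = pd.DataFrame(vecs, columns=list("abc"))
        assignment = assign_profiles(ratios, PROFILES3)
        sig = profile_significance(assignment, ratios, PROFILES3,
                                   method="binomial")
        assert sig.set_index("profile").loc[7, "significant"]

    def test_empty_input_rejected(self):
        empty = pd.DataFrame(columns=list("abc"))
        with pytest.raises(ValueError, match="no genes"):
            profile_significance(
                pd.DataFrame({"profile": pd.array([], dtype="Int64"),
                              "correlation": []}),
                empty, PROFILES3)


def test_null_simulation_rarely_flags_profiles():
    """Flat genes plus noise: counts sit near expectation and few profiles
    reach significance across seeds."""
    flagged = total = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        vecs = np.hstack([np.zeros((80, 1)), rng.normal(0, 0.3, (80, 2))])
        ratios = pd.DataFrame(vecs, columns=list("abc"))
        assignment = assign_profiles(ratios, PROFILES3)
        sig = profile_significance(assignment, ratios, PROFILES3)
        flagged += int(sig["significant"].sum())
        total += len(sig)
    assert flagged / total <= 0.05
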