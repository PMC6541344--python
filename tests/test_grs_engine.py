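import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import triogrs as tg
from triogrs.errors import AlignmentError, ValidationError
from triogrs.grs_engine import orient_dosage

from conftest import make_weight_df, naive_grs


class TestAlleleAlignment:
    def test_identity_orientation(self):
        d, flipped = orient_dosage(2.0, "A", "G", "A", "G", "rs1")
        assert d == 2.0 and not flipped

    def test_flip_orientation(self):
        d, flipped = orient_dosage(2.0, "G", "A", "A", "G", "rs1")
        assert d == 0.0 and flipped

    def test_mismatched_alleles_error(self):
        with pytest.raises(AlignmentError, match="rs1"):
            orient_dosage(1.0, "A", "G", "C", "T", "rs1")

    @given(st.floats(min_value=0, max_value=2))
    @settings(derandomize=True, max_examples=50)
    def test_flip_is_an_involution(self, dosage):
        once, _ = orient_dosage(dosage, "G", "A", "A", "G")
        twice, _ = orient_dosage(once, "A", "G", "G", "A")
        assert twice == pytest.approx(dosage)

    def test_matrix_alignment_flips_only_unoriented_columns(self, toy_dosage_matrix):
        dm, weights, _ = toy_dosage_matrix
        # make column 0 counted on the other allele
        dm.counted_allele[0], dm.other_allele[0] = dm.other_allele[0], dm.counted_allele[0]
        dm.oriented[0] = False
        aligned = tg.align_alleles(dm, weights)
        assert aligned.oriented.all()
        np.testing.assert_array_equal(aligned.dosage[:, 0], 2.0 - dm.dosage[:, 0])
        np.testing.assert_array_equal(aligned.dosage[:, 1:], dm.dosage[:, 1:])


class TestComputeGRS:
    def test_zero_dosages_give_zero_scores(self, toy_dosage_matrix):
        dm, weights, roles = toy_dosage_matrix
        dm.dosage[:] = 0.0
        grs = tg.compute_grs(dm, weights, roles)
        for col in ("score_htn", "score_obesity", "score_t2d", "score_combined"):
            assert (grs[col] == 0).all()

    def test_hand_arithmetic_three_snps(self):
        weights = make_weight_df(n_htn=3, n_obesity=1, n_t2d=1,
                                 weights=[0.5, 1.0, 0.25, 1.0, 1.0])
        dm = tg.DosageMatrix(
            sample_ids=["m"], snp_ids=list(weights["snp_id"]),
            dosage=np.array([[2, 1, 0, 0, 0]], dtype=float),
            counted_allele=list(weights["effect_allele"]),
            other_allele=list(weights["other_allele"]),
            oriented=np.ones(5, dtype=bool),
        )
        roles = pd.DataFrame({"sample_id": ["m"], "role": ["mother"], "cohort": ["CHOP"]})
        grs = tg.compute_grs(dm, weights, roles)
        assert grs["score_htn"].iloc[0] == pytest.approx(2.0)  # 0.5*2 + 1.0*1 + 0.25*0

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(42)
        weights = make_weight_df(n_htn=2, n_obesity=1, n_t2d=2, seed=42)
        dosage = rng.uniform(0, 2, size=(10, 5))
        dm = tg.DosageMatrix(
            sample_ids=[f"s{i}" for i in range(10)], snp_ids=list(weights["snp_id"]),
            dosage=dosage, counted_allele=list(weights["effect_allele"]),
            other_allele=list(weights["other_allele"]), oriented=np.ones(5, dtype=bool),
        )
        roles = pd.DataFrame({"sample_id": dm.sample_ids, "role": ["mother", "father"] * 5,
                              "cohort": ["CHOP"] * 10})
        grs = tg.compute_grs(dm, weights, roles)
        oracle = naive_grs(dosage, weights, dm.snp_ids)
        np.testing.assert_allclose(grs["score_htn"], oracle["HTN"], atol=1e-9)
        np.testing.assert_allclose(grs["score_obesity"], oracle["OBESITY"], atol=1e-9)
        np.testing.assert_allclose(grs["score_t2d"], oracle["T2D"], atol=1e-9)

    def test_linearity_in_dosage(self, toy_dosage_matrix):
        dm, weights, roles = toy_dosage_matrix
        dm.dosage = dm.dosage / 2.0  # keep doubled values inside [0, 2]
        g1 = tg.compute_grs(dm, weights, roles)
        dm2 = tg.DosageMatrix(dm.sample_ids, dm.snp_ids, dm.dosage * 2,
                              dm.counted_allele, dm.other_allele, dm.oriented)
        g2 = tg.compute_grs(dm2, weights, roles)
        np.testing.assert_allclose(g2["score_combined"], 2 * g1["score_combined"])

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(derandomize=True, max_examples=25)
    def test_scores_bounded_by_weight_sum(self, seed):
        rng = np.random.default_rng(seed)
        weights = make_weight_df(seed=seed)
        dosage = rng.uniform(0, 2, size=(4, 6))
        dm = tg.DosageMatrix(
            sample_ids=list("abcd"), snp_ids=list(weights["snp_id"]), dosage=dosage,
            counted_allele=list(weights["effect_allele"]),
            other_allele=list(weights["other_allele"]), oriented=np.ones(6, dtype=bool),
        )
        roles = pd.DataFrame({"sample_id": list("abcd"), "role": ["mother"] * 4,
                              "cohort": ["CHOP"] * 4})
        grs = tg.compute_grs(dm, weights, roles)
        for cond, col in (("HTN", "score_htn"), ("OBESITY", "score_obesity"), ("T2D", "score_t2d")):
            cap = 2 * weights.loc[weights["condition"] == cond, "weight"].sum()
            assert ((grs[col] >= 0) & (grs[col] <= cap + 1e-12)).all()

    def test_policies_identical_without_missingness(self, toy_dosage_matrix):
        dm, weights, roles = toy_dosage_matrix
        frames = [tg.compute_grs(dm, weights, roles, missing_policy=p)
                  for p in ("impute_role_mean", "drop_sample", "score_available")]
        pd.testing.assert_frame_equal(frames[0], frames[1])
        pd.testing.assert_frame_equal(frames[0], frames[2])

    def test_impute_role_mean_uses_same_role_mean(self, toy_dosage_matrix):
        dm, weights, roles = toy_dosage_matrix
        dm.dosage[0, 0] = np.nan  # s1 is a mother; the other mother (s3) has dosage 1
        grs = tg.compute_grs(dm, weights, roles, missing_policy="impute_role_mean")
        w0 = weights["weight"].iloc[0]
        w1 = weights["weight"].iloc[1]
        expected = w0 * 1.0 + w1 * dm.dosage[0, 1]  # imputed with mothers' mean (=1.0)
        assert grs.set_index("sample_id").loc["s1", "score_htn"] == pytest.approx(expected)
        assert grs.set_index("sample_id").loc["s1", "n_missing_htn"] == 1

    def test_score_available_ignores_missing_terms(self, toy_dosage_matrix):
        dm, weights, roles = toy_dosage_matrix
        dm.dosage[0, 0] = np.nan
        grs = tg.compute_grs(dm, weights, roles, missing_policy="score_available")
        expected = weights["weight"].iloc[1] * dm.dosage[0, 1]
        assert grs.set_index("sample_id").loc["s1", "score_htn"] == pytest.approx(expected)

    def test_drop_sample_removes_incomplete_samples(self, toy_dosage_matrix):
        dm, weights, roles = toy_dosage_matrix
        dm.dosage[0, 0] = np.nan
        grs = tg.compute_grs(dm, weights, roles, missing_policy="drop_sample")
        assert "s1" not in set(grs["sample_id"]) and len(grs) == 3

    def test_all_missing_sample_rejected(self, toy_dosage_matrix):
        dm, weights, roles = toy_dosage_matrix
        dm.dosage[0, :] = np.nan
        with pytest.raises(ValidationError, match="s1"):
            tg.compute_grs(dm, weights, roles, missing_policy="impute_role_mean")

    def test_condition_without_snps_rejected(self, toy_dosage_matrix):
        dm, weights, roles = toy_dosage_matrix
        with pytest.raises(ValidationError, match="zero scored SNPs"):
            tg.compute_grs(dm, weights[weights["condition"] != "T2D"], roles)


class TestCombineScores:
    def test_zero_components(self):
        grs = pd.DataFrame({"score_htn": [0.0], "score_obesity": [0.0], "score_t2d": [0.0]})
        assert tg.combine_scores(grs)["score_combined"].iloc[0] == 0.0

    def test_published_component_means_sum_to_combined(self):
        grs = pd.DataFrame({"score_htn": [17.8], "score_obesity": [3.8], "score_t2d": [4.4]})
        combined = tg.combine_scores(grs)["score_combined"].iloc[0]
        assert combined == pytest.approx(26.0, abs=1e-9)

    def test_hand_arithmetic(self):
        grs = pd.DataFrame({"score_htn": [1.25], "score_obesity": [2.50], "score_t2d": [0.25]})
        assert tg.combine_scores(grs)["score_combined"].iloc[0] == 4.00

    def test_missing_component_rejected(self):
        with pytest.raises(ValidationError, match="score_t2d"):
            tg.combine_scores(pd.DataFrame({"score_htn": [1.0], "score_obesity": [1.0]}))
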