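import math

import numpy as np
import pytest

from mirmint import diffexpr
from mirmint.data_io import ExpressionMatrix
from mirmint.errors import DomainError, UsageError


def make_matrix(values, groups, scale="log2"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        feature_ids=[f"f{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{i}" for i in range(values.shape[1])],
        groups=list(groups),
        values=values,
        scale=scale,
    )


class TestLogTransform:
    def test_value_8_gives_3(self):
        m = make_matrix([[8.0]], ["tumor"], scale="linear")
        out = diffexpr.log_transform(m)
        assert out.values[0, 0] == pytest.approx(3.0)
        assert out.scale == "log2"

    def test_zero_with_offset_one_gives_zero(self):
        m = make_matrix([[0.0]], ["tumor"], scale="linear")
        out = diffexpr.log_transform(m, offset=1.0)
        assert out.values[0, 0] == pytest.approx(0.0)

    def test_double_transform_guard(self):
        m = make_matrix([[3.0]], ["tumor"], scale="log2")
        with pytest.raises(UsageError):
            diffexpr.log_transform(m)

    def test_nonpositive_names_feature(self):
        m = make_matrix([[1.0], [-2.0]], ["tumor"], scale="linear")
        with pytest.raises(DomainError, match="f1"):
            diffexpr.log_transform(m)


def pooled_t_oracle(tumor, normal):
    """Hand-rolled pooled two-sample t, independent of the implementation."""
    n1, n2 = len(tumor), len(normal)
    m1 = sum(tumor) / n1
    m2 = sum(normal) / n2
    ss1 = sum((x - m1) ** 2 for x in tumor)
    ss2 = sum((x - m2) ** 2 for x in normal)
    s2 = (ss1 + ss2) / (n1 + n2 - 2)
    return (m1 - m2) / math.sqrt(s2 * (1 / n1 + 1 / n2))


class TestModeratedT:
    def test_identical_group_means(self):
        m = make_matrix([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], ["tumor"] * 3 + ["normal"] * 3)
        (r,) = diffexpr.moderated_t_test(m, prior_df_mode="none")
        assert r.log_fc == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_no_shrinkage_equals_pooled_t(self):
        tumor = [8.1, 9.3, 7.8]
        normal = [6.2, 6.9, 6.4]
        m = make_matrix([tumor + normal, [5.0, 5.5, 6.0, 5.2, 5.4, 5.9]],
                        ["tumor"] * 3 + ["normal"] * 3)
        results = diffexpr.moderated_t_test(m, prior_df_mode="none")
        assert results[0].t_stat == pytest.approx(pooled_t_oracle(tumor, normal), abs=1e-10)

    def test_null_type_i_error(self):
        rng = np.random.default_rng(2024)
        values = rng.normal(8.0, 1.0, size=(1000, 10))
        m = make_matrix(values, ["tumor"] * 5 + ["normal"] * 5)
        results = diffexpr.moderated_t_test(m)
        frac = np.mean([r.p_value < 0.05 for r in results])
        assert 0.03 <= frac <= 0.07

    def test_swapping_groups_negates_logfc(self, tiny_matrix):
        fwd = diffexpr.moderated_t_test(tiny_matrix)
        swapped = tiny_matrix.copy()
        swapped.groups = [
            "normal" if g == "tumor" else "tumor" for g in swapped.groups
        ]
        rev = diffexpr.moderated_t_test(swapped)
        for a, b in zip(fwd, rev):
            assert a.log_fc == pytest.approx(-b.log_fc)
            assert a.p_value == pytest.approx(b.p_value)

    def test_requires_log2_scale(self):
        m = make_matrix([[1.0, 2.0]], ["tumor", "normal"], scale="linear")
        with pytest.raises(UsageError):
            diffexpr.moderated_t_test(m)

    def test_empty_group_raises(self):
        m = make_matrix([[1.0, 2.0]], ["tumor", "tumor"])
        with pytest.raises(UsageError):
            diffexpr.moderated_t_test(m)

    def test_single_sample_group_warns(self):
        m = make_matrix([[1.0, 2.0, 3.0, 1.5]], ["tumor"] * 3 + ["normal"])
        with pytest.warns(UserWarning, match="single sample"):
            diffexpr.moderated_t_test(m)

    def test_shrinkage_monotonicity(self):
        rng = np.random.default_rng(7)
        s2 = rng.chisquare(4, size=500) / 4
        spreads = []
        for prior_df in [0.5, 2.0, 10.0, 100.0]:
            post = diffexpr.moderate_variances(s2, df=4, prior_df=prior_df, prior_var=1.0)
            spreads.append(np.var(post))
        assert all(a >= b - 1e-12 for a, b in zip(spreads, spreads[1:]))

    def test_moderation_tightens_null_extremes(self):
        # moderated |t| on tiny groups should not explode when s2 ~ 0
        rng = np.random.default_rng(3)
        values = rng.normal(8.0, 1.0, size=(500, 6))
        values[0, :3] = [5.0, 5.0 + 1e-9, 5.0 - 1e-9]  # near-zero variance feature
        m = make_matrix(values, ["tumor"] * 3 + ["normal"] * 3)
        results = diffexpr.moderated_t_test(m, prior_df_mode="moment")
        assert np.isfinite(results[0].t_stat)


class TestBHAdjust:
    def test_spec_example(self):
        out = diffexpr.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_value(self):
        assert diffexpr.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        np.testing.assert_allclose(diffexpr.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_raises(self):
        with pytest.raises(DomainError):
            diffexpr.bh_adjust([0.5, 1.2])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        p = rng.uniform(size=200)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(diffexpr.bh_adjust(p), expected, atol=1e-12)


def _result(fid, log_fc, p, fdr):
    return diffexpr.DEResult(
        feature_id=fid,
        log_fc=log_fc,
        fold_change=2.0 ** log_fc,
        mean_tumor=8 + log_fc,
        mean_normal=8.0,
        t_stat=log_fc * 3,
        p_value=p,
        fdr=fdr,
        direction="up" if log_fc > 0 else "down" if log_fc < 0 else None,
    )


class TestApplyThresholds:
    THRESH = diffexpr.DEThresholds(min_fold_change=4.0, max_p=0.01, max_fdr=0.01)

    def test_hand_enumerated_toy(self):
        # exactly r1 (fc 8 up) and r5 (fc 1/8 down) pass all three cuts
        results = [
            _result("r1", 3.0, 0.001, 0.005),   # passes
            _result("r2", 3.0, 0.05, 0.005),    # p too large
            _result("r3", 1.0, 0.001, 0.005),   # |fc|=2 below cut
            _result("r4", 3.0, 0.001, 0.02),    # fdr too large
            _result("r5", -3.0, 0.002, 0.006),  # passes
        ]
        kept = diffexpr.apply_thresholds(results, self.THRESH)
        assert [r.feature_id for r in kept] == ["r1", "r5"]

    def test_blacklist_excludes_passing_feature(self):
        results = [_result("hsa-miR-923", 3.0, 0.001, 0.001)]
        kept = diffexpr.apply_thresholds(
            results, self.THRESH, blacklist=["hsa-mir-923"]
        )
        assert kept == []

    def test_sort_order(self):
        results = [
            _result("b", 2.5, 0.001, 0.004),
            _result("a", -3.0, 0.001, 0.004),
            _result("c", 3.0, 0.0005, 0.002),
        ]
        kept = diffexpr.apply_thresholds(results, self.THRESH)
        assert [r.feature_id for r in kept] == ["c", "a", "b"]

    def test_no_fc_cut_mode(self):
        thresh = diffexpr.DEThresholds(min_fold_change=None, max_p=0.01, max_fdr=0.01)
        kept = diffexpr.apply_thresholds([_result("x", 0.5, 0.001, 0.001)], thresh)
        assert len(kept) == 1

    def test_empty_input_raises(self):
        with pytest.raises(UsageError):
            diffexpr.apply_thresholds([], self.THRESH)


class TestDEResultInvariants:
    def test_direction_must_match_sign(self):
        with pytest.raises(DomainError):
            diffexpr.DEResult(
                feature_id="x", log_fc=1.0, fold_change=2.0,
                mean_tumor=9, mean_normal=8, t_stat=2.0,
                p_value=0.01, fdr=0.02, direction="down",
            )

    def test_thresholds_validate(self):
        with pytest.raises(DomainError):
            diffexpr.DEThresholds(min_fold_change=0.5)
        with pytest.raises(DomainError):
            diffexpr.DEThresholds(max_p=0.0)


class TestDETableRoundTrip:
    def test_round_trip(self, tmp_path, tiny_matrix):
        results = diffexpr.moderated_t_test(tiny_matrix)
        path = tmp_path / "de.tsv"
        diffexpr.write_de_table(results, path)
        back = diffexpr.read_de_table(path)
        assert [r.feature_id for r in back] == [r.feature_id for r in results]
        for a, b in zip(results, back):
            assert a.log_fc == pytest.approx(b.log_fc, rel=1e-8)
            assert a.p_value == pytest.approx(b.p_value, rel=1e-8)
            assert a.direction == b.direction
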