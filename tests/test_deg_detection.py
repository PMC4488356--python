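import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemores import data_io
from chemores.deg_detection import (
    NormalRange,
    PermutationConfig,
    detect_degs,
    deviation_score,
    normal_range,
    permutation_pvalue,
)
from chemores.errors import InputError
from chemores.synthetic_data import SyntheticConfig, generate_cohort


def clamped_sum_oracle(values, lo, hi):
    """Direct per-value evaluation of the clamped deviation sum."""
    raw = absv = 0.0
    for x in values:
        c = x - hi if x > hi else (x - lo if x < lo else 0.0)
        raw += c
        absv += abs(c)
    return raw, absv


def exhaustive_pvalue(values, n1, statistic="signed"):
    """Enumerate every sensitive-set assignment of size n1 (oracle)."""
    values = list(values)
    idx = range(len(values))
    stats = []
    for sens in itertools.combinations(idx, n1):
        sens = set(sens)
        s_vals = [values[i] for i in sens]
        r_vals = [values[i] for i in idx if i not in sens]
        mu = np.mean(s_vals)
        sd = np.std(s_vals, ddof=1)
        raw, absv = clamped_sum_oracle(r_vals, mu - sd, mu + sd)
        stats.append(abs(raw) if statistic == "signed" else absv)
    return stats


class TestNormalRange:
    def test_hand_examples(self):
        nr = normal_range([1, 2, 3])
        assert (nr.x_min, nr.x_max) == (1.0, 3.0)
        nr = normal_range([0, 2])
        assert nr.x_min == pytest.approx(1 - math.sqrt(2))
        assert nr.x_max == pytest.approx(1 + math.sqrt(2))

    def test_degenerate_zero_variance_warns(self):
        with pytest.warns(RuntimeWarning):
            nr = normal_range([5, 5, 5])
        assert nr.x_min == nr.x_max == 5.0

    def test_too_few_values(self):
        with pytest.raises(InputError):
            normal_range([1.0])


class TestDeviationScore:
    @pytest.mark.parametrize(
        "values,expected_raw,expected_abs",
        [
            ([2, 2.5, 1.5], 0.0, 0.0),  # all inside the range
            ([4, 2, 0], 0.0, 2.0),  # signed cancellation: +1 and -1
            ([5, 3.5], 2.5, 2.5),  # both above
        ],
    )
    def test_hand_examples_range_1_3(self, values, expected_raw, expected_abs):
        raw, absv = deviation_score(values, NormalRange(1.0, 3.0, 3))
        assert raw == pytest.approx(expected_raw)
        assert absv == pytest.approx(expected_abs)

    def test_empty_vector_rejected(self):
        with pytest.raises(InputError):
            deviation_score([], NormalRange(0.0, 1.0, 2))

    def test_matches_clamped_sum_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            lo, hi = sorted(rng.normal(size=2))
            vals = rng.normal(size=rng.integers(1, 8))
            raw, absv = deviation_score(vals, NormalRange(lo, hi, 2))
            oraw, oabs = clamped_sum_oracle(vals, lo, hi)
            assert raw == pytest.approx(oraw, abs=1e-12)
            assert absv == pytest.approx(oabs, abs=1e-12)

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=8),
        st.lists(st.floats(-50, 50), min_size=1, max_size=8),
        st.floats(-10, 10),
        st.floats(0.1, 10),
    )
    @settings(max_examples=40, deadline=None)
    def test_translation_and_scale_behavior(self, sens, res, c, k):
        """Scores are translation invariant and positively homogeneous."""
        nr = normal_range(sens)
        raw, absv = deviation_score(res, nr)
        nr_t = normal_range([x + c for x in sens])
        raw_t, abs_t = deviation_score([x + c for x in res], nr_t)
        assert raw_t == pytest.approx(raw, abs=1e-6)
        assert abs_t == pytest.approx(absv, abs=1e-6)
        nr_s = normal_range([x * k for x in sens])
        raw_s, abs_s = deviation_score([x * k for x in res], nr_s)
        assert raw_s == pytest.approx(k * raw, rel=1e-6, abs=1e-6)
        assert abs_s == pytest.approx(k * absv, rel=1e-6, abs=1e-6)
        assert absv >= abs(raw) - 1e-12


class TestPermutationPvalue:
    def test_degenerate_identical_values_give_p_one(self):
        cfg = PermutationConfig(n_permutations=200, seed=1)
        p = permutation_pvalue([3.0] * 6, 3, 3, observed=0.0, cfg=cfg)
        assert p == 1.0

    def test_add_one_lower_bound(self):
        # observed larger than any permuted score -> p = 1/(B+1)
        cfg = PermutationConfig(n_permutations=999, seed=1)
        vals = [0.0, 0.1, -0.1, 0.05, -0.05]
        p = permutation_pvalue(vals, 3, 2, observed=1e6, cfg=cfg)
        assert p == pytest.approx(1 / 1000)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(0, 1, 3), rng.normal(2, 1, 2)])
        stats = exhaustive_pvalue(vals, 3)
        obs_raw, _ = deviation_score(vals[3:], normal_range(vals[:3]))
        p_exh = np.mean([s >= abs(obs_raw) - 1e-12 for s in stats])
        cfg = PermutationConfig(n_permutations=10_000, seed=2)
        p_mc = permutation_pvalue(vals, 3, 2, observed=obs_raw, cfg=cfg)
        assert abs(p_mc - p_exh) <= 0.02

    def test_small_n1_rejected(self):
        with pytest.raises(InputError):
            permutation_pvalue([1, 2, 3], 1, 2, 0.0, PermutationConfig(n_permutations=10))


class TestDetectDegs:
    def test_null_cohort_type_i_error_near_alpha(self):
        cfg = SyntheticConfig(n_genes=200, effect_size=0.0, n_common_de=0,
                              n_specific_de_per_subgroup=0,
                              n_sensitive_marker_per_subgroup=0, seed=0)
        expr, ann, _ = generate_cohort(cfg)
        res = detect_degs(expr, ann, PermutationConfig(n_permutations=1000, seed=0))
        frac = res["significant"].mean()
        assert 0.02 <= frac <= 0.08

    def test_planted_common_genes_detected(self):
        cfg = SyntheticConfig(seed=4)
        expr, ann, truth = generate_cohort(cfg)
        z = data_io.zscore_normalize(expr)
        res = detect_degs(z, ann, PermutationConfig(n_permutations=1000, seed=4))
        sig = set(res.index[res["significant"]])
        sens = len(sig & truth.common_de_genes) / len(truth.common_de_genes)
        assert sens >= 0.9

    def test_constant_gene_not_significant(self, tiny_ann):
        m = pd.DataFrame([[2.0, 2.0, 2.0, 2.0]], index=["g"], columns=tiny_ann.index)
        res = detect_degs(m, tiny_ann, PermutationConfig(n_permutations=100, seed=0))
        assert res.loc["g", "p_value"] == 1.0
        assert not res.loc["g", "significant"]

    def test_direction_labels(self, tiny_ann):
        m = pd.DataFrame(
            [[0.0, 1.0, 9.0, 9.5], [0.0, 1.0, -9.0, -9.5], [0.0, 1.0, 9.0, -9.0],
             [0.0, 1.0, 0.5, 0.6]],
            index=["up", "down", "mixed", "none"],
            columns=tiny_ann.index,
        )
        res = detect_degs(m, tiny_ann, PermutationConfig(n_permutations=50, seed=0))
        assert res.loc["up", "direction"] == "up"
        assert res.loc["down", "direction"] == "down"
        assert res.loc["mixed", "direction"] == "mixed"
        assert res.loc["none", "direction"] == "none"

    def test_deterministic_given_seed(self, tiny_expr, tiny_ann):
        cfg = PermutationConfig(n_permutations=200, seed=9)
        a = detect_degs(tiny_expr, tiny_ann, cfg)
        b = detect_degs(tiny_expr, tiny_ann, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_annotation_rejected(self, tiny_expr, tiny_ann):
        with pytest.raises(InputError):
            detect_degs(tiny_expr, tiny_ann.drop("s4"), PermutationConfig(n_permutations=10))

    def test_pvalues_super_uniform_under_null(self):
        # empirical CDF at alpha stays within 3 binomial SEs of alpha
        cfg = SyntheticConfig(n_genes=300, effect_size=0.0, n_common_de=0,
                              n_specific_de_per_subgroup=0,
                              n_sensitive_marker_per_subgroup=0, seed=12)
        expr, ann, _ = generate_cohort(cfg)
        res = detect_degs(expr, ann, PermutationConfig(n_permutations=500, seed=12))
        alpha = 0.05
        se = math.sqrt(alpha * (1 - alpha) / len(res))
        assert (res["p_value"] < alpha).mean() <= alpha + 3 * se + 0.01
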