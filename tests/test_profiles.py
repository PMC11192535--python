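"""Expression statistics: N99 thresholding, specialization, Z test, ordination."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from effectorscan.errors import DegenerateDistributionError, InputError
from effectorscan.profiles import (
    call_expressed,
    call_high_expression,
    cluster_profiles,
    compute_n99,
    ddct_fold_change,
    project_samples,
    specialization_index,
    specialization_table,
)

from conftest import make_matrix


def n99_oracle(values, fraction):
    """Naive sort-and-scan: walk the descending values until the running sum
    covers the requested fraction of the total."""
    desc = sorted(values, reverse=True)
    total = sum(values)
    running = 0.0
    for v in desc:
        running += v
        if running >= fraction * total:
            return v
    return desc[-1]


class TestN99:
    @pytest.mark.parametrize(
        "values,fraction,threshold,n_expressed",
        [
            ([1000.0], 0.99, 1000.0, 1),
            ([50, 30, 15, 4, 1], 0.99, 4.0, 4),
            ([99, 1], 0.99, 99.0, 1),
        ],
    )
    def test_worked_examples(self, values, fraction, threshold, n_expressed):
        thr = compute_n99(values, fraction)
        assert thr.threshold == threshold
        assert thr.n_expressed == n_expressed

    def test_strict_rule_excludes_threshold_gene(self):
        thr = compute_n99([50, 30, 15, 4, 1], 0.99, expressed_rule="strict_gt")
        assert thr.threshold == 4.0
        assert thr.n_expressed == 3

    def test_all_zero_group(self):
        thr = compute_n99([0.0, 0.0, 0.0])
        assert thr.threshold == 0.0 and thr.n_expressed == 0

    def test_bad_fraction_rejected(self):
        with pytest.raises(InputError):
            compute_n99([1.0], fraction=1.2)

    def test_matches_sort_and_scan_oracle(self, rng):
        """Exact agreement with the naive cumulative-scan on random vectors."""
        for _ in range(300):
            n = int(rng.integers(1, 200))
            vals = rng.exponential(10.0, size=n)
            vals[rng.random(n) < 0.3] = 0.0
            if vals.sum() == 0:
                continue
            frac = float(rng.uniform(0.5, 0.999))
            assert compute_n99(vals, frac).threshold == n99_oracle(vals, frac)

    def test_monotonicity_of_expressed_set(self, rng):
        """Raising one gene's TPM never drops that gene from the expressed set."""
        for _ in range(50):
            vals = pd.Series(rng.exponential(10.0, size=30),
                             index=[f"g{i}" for i in range(30)])
            thr = compute_n99(vals)
            expressed = set(vals.index[vals >= thr.threshold])
            gene = rng.choice(list(expressed))
            vals[gene] *= float(rng.uniform(1.0, 10.0))
            thr2 = compute_n99(vals)
            assert gene in set(vals.index[vals >= thr2.threshold])


class TestCallExpressed:
    def test_single_dominant_gene(self, four_group_matrix):
        out = call_expressed(four_group_matrix, ["carcass"], fraction=0.99)
        # in the carcass sample one gene pair dominates; threshold gene included
        assert "flat" in out

    def test_both_rules_on_known_vector(self):
        meta = {f"s{i}": ("venom_gland", "adult", "female", i) for i in range(1, 2)}
        values = {g: {"s1": v} for g, v in
                  zip("abcde", [50.0, 30.0, 15.0, 4.0, 1.0])}
        m = make_matrix(values, meta)
        assert call_expressed(m, ["s1"], 0.99, "inclusive_ge") == {"a", "b", "c", "d"}
        assert call_expressed(m, ["s1"], 0.99, "strict_gt") == {"a", "b", "c"}

    def test_all_zero_group_empty(self, four_group_matrix):
        m = four_group_matrix
        m.values.loc[:, "larva"] = 0.0
        assert call_expressed(m, ["larva"]) == set()

    def test_unknown_sample_rejected(self, four_group_matrix):
        with pytest.raises(InputError):
            call_expressed(four_group_matrix, ["nope"])


class TestSpecializationIndex:
    def test_flat_gene_scores_one(self, four_group_matrix):
        assert specialization_index(
            four_group_matrix, "flat", ["VG_r1", "VG_r2"]
        ).index == 1.0

    def test_group_mean_denominator(self, four_group_matrix):
        # focal mean 10; other groups each mean 2 -> ratio 5
        score = specialization_index(four_group_matrix, "vg_high", ["VG_r1", "VG_r2"])
        assert score.index == pytest.approx(5.0)

    def test_zero_numerator(self, four_group_matrix):
        m = four_group_matrix
        m.values.loc["vg_high", ["VG_r1", "VG_r2"]] = 0.0
        assert specialization_index(m, "vg_high", ["VG_r1", "VG_r2"]).index == 0.0

    def test_zero_denominator_is_infinite(self, four_group_matrix):
        assert math.isinf(
            specialization_index(four_group_matrix, "vg_only", ["VG_r1", "VG_r2"]).index
        )

    def test_zero_over_zero_undefined(self, four_group_matrix):
        assert math.isnan(
            specialization_index(four_group_matrix, "silent", ["VG_r1", "VG_r2"]).index
        )

    def test_absent_gene_rejected(self, four_group_matrix):
        with pytest.raises(InputError):
            specialization_index(four_group_matrix, "ghost", ["VG_r1"])

    def test_table_agrees_with_scalar(self, four_group_matrix):
        table = specialization_table(four_group_matrix, ["VG_r1", "VG_r2"])
        for gene in ("flat", "vg_high"):
            assert table[gene] == pytest.approx(
                specialization_index(four_group_matrix, gene, ["VG_r1", "VG_r2"]).index
            )

    def test_scale_invariance_dyadic_exact(self, rng):
        """Powers-of-two rescaling leaves indices bit-identical and scales
        thresholds exactly; arbitrary factors agree to 1e-12 relative."""
        for k in range(20):
            n_genes, n_samples = 30, 8
            meta = {
                f"s{i}": ("venom_gland" if i < 3 else f"t{i}", "adult", "mixed", 1)
                for i in range(n_samples)
            }
            values = {
                f"g{i}": dict(zip(meta, rng.exponential(20.0, n_samples)))
                for i in range(n_genes)
            }
            m = make_matrix(values, meta)
            focal = ["s0", "s1", "s2"]
            base_spec = specialization_table(m, focal)
            base_thr = compute_n99(m.values[focal].mean(axis=1))
            c = 2.0 ** int(rng.integers(-8, 9))
            ms = m.scaled(c)
            scaled_spec = specialization_table(ms, focal)
            scaled_thr = compute_n99(ms.values[focal].mean(axis=1))
            assert (scaled_spec == base_spec).all()
            assert scaled_thr.threshold == c * base_thr.threshold
            assert scaled_thr.n_expressed == base_thr.n_expressed
            c2 = float(rng.uniform(0.1, 10.0))
            approx_spec = specialization_table(m.scaled(c2), focal)
            np.testing.assert_allclose(approx_spec, base_spec, rtol=1e-12)


class TestHighExpressionZTest:
    def test_worked_example(self):
        """Transformed values [1,1,1,1,6]: top z = 4/sqrt(5), p ~ 0.0368."""
        tpm = 2.0 ** np.array([1.0, 1, 1, 1, 6]) - 1
        calls = call_high_expression(pd.Series(tpm, index=list("abcde")))
        top = calls[-1]
        assert top.z == pytest.approx(4 / math.sqrt(5))
        assert top.p == pytest.approx(stats.norm.sf(4 / math.sqrt(5)), rel=1e-12)
        assert top.p == pytest.approx(0.0368, abs=2e-4)
        assert top.called
        assert not any(c.called for c in calls[:-1])

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            call_high_expression([8.0, 8.0, 8.0, 8.0])

    def test_too_few_candidates_rejected(self):
        with pytest.raises(InputError):
            call_high_expression([1.0, 2.0])

    def test_null_calibration_smoke(self, rng):
        """Per-gene call rate near alpha under the i.i.d. normal null."""
        hits = total = 0
        for _ in range(300):
            x = rng.normal(8.0, 1.0, size=100)
            calls = call_high_expression(2.0**x - 1.0)
            hits += sum(c.called for c in calls)
            total += len(calls)
        rate = hits / total
        assert abs(rate - 0.05) < 0.01


class TestClusterProfiles:
    def _matrix(self, profiles: dict) -> "ExpressionMatrix":
        n = len(next(iter(profiles.values())))
        meta = {f"s{i}": (f"t{i}", "adult", "mixed", 1) for i in range(n)}
        values = {g: dict(zip(meta, vals)) for g, vals in profiles.items()}
        return make_matrix(values, meta)

    def test_identical_profiles_merge_at_zero(self):
        m = self._matrix({"g1": [1, 2, 3, 4], "g2": [2, 4, 6, 8]})
        ordering = cluster_profiles(m)
        assert ordering.merge_heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_correlated_pair_merges_first(self):
        m = self._matrix(
            {"g1": [1, 2, 3, 4], "g2": [1.1, 2, 3, 4.2], "g3": [4, 3, 2, 1]}
        )
        ordering = cluster_profiles(m)
        order = ordering.leaf_order
        assert abs(order.index("g1") - order.index("g2")) == 1
        assert order.index("g3") in (0, 2)

    def test_gene_order_invariance(self):
        profiles = {"g1": [1, 2, 3, 4], "g2": [1.1, 2, 3, 4.2], "g3": [4, 3, 2, 1],
                    "g4": [0.5, 1, 2, 9]}
        m1 = self._matrix(profiles)
        m2 = self._matrix(dict(reversed(list(profiles.items()))))
        assert cluster_profiles(m1).leaf_order == cluster_profiles(m2).leaf_order

    def test_constant_profiles_grouped_last(self):
        m = self._matrix({"g1": [1, 2, 3, 4], "g2": [4, 3, 2, 1], "flat": [5, 5, 5, 5]})
        assert cluster_profiles(m).leaf_order[-1] == "flat"

    def test_single_gene_trivial(self):
        m = self._matrix({"g1": [1, 2, 3, 4]})
        assert cluster_profiles(m).leaf_order == ["g1"]


class TestSampleProjection:
    def _matrix(self, arr: np.ndarray) -> "ExpressionMatrix":
        n_genes, n_samples = arr.shape
        meta = {f"s{i}": (f"t{i}", "adult", "mixed", 1) for i in range(n_samples)}
        values = {f"g{i}": dict(zip(meta, arr[i])) for i in range(n_genes)}
        return make_matrix(values, meta)

    def test_identical_samples_coincide(self, rng):
        col = rng.exponential(10.0, size=20)
        m = self._matrix(np.column_stack([col, col, rng.exponential(10.0, 20)]))
        proj = project_samples(m)
        np.testing.assert_allclose(
            proj.coordinates.loc["s0"], proj.coordinates.loc["s1"], atol=1e-9
        )

    def test_matches_eigendecomposition_oracle(self, rng):
        """Coordinates match a hand-rolled covariance eigen-solve to 1e-8."""
        arr = rng.exponential(10.0, size=(6, 3))
        m = self._matrix(arr)
        proj = project_samples(m)
        x = np.log2(arr.T + 1.0)
        x = x - x.mean(axis=0)
        cov = x @ x.T  # sample × sample Gram matrix shares nonzero eigenvalues
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for k in range(2):  # 3 samples -> 2 informative axes
            expected = evecs[:, k] * math.sqrt(evals[k])
            got = proj.coordinates.iloc[:, k].to_numpy()
            assert min(
                np.abs(got - expected).max(), np.abs(got + expected).max()
            ) < 1e-8
        total = float(np.trace(cov))
        np.testing.assert_allclose(
            proj.variance_fractions[:2], evals[:2] / total, atol=1e-10
        )

    def test_variance_fractions_non_increasing(self, rng):
        m = self._matrix(rng.exponential(5.0, size=(15, 6)))
        fr = project_samples(m).variance_fractions
        assert (np.diff(fr) <= 1e-12).all()
        assert fr.sum() <= 1.0 + 1e-9

    def test_single_sample_rejected(self):
        m = self._matrix(np.ones((4, 1)))
        with pytest.raises(InputError):
            project_samples(m)


class TestDdct:
    @pytest.mark.parametrize(
        "cts,expected",
        [
            ((20, 18, 25, 23), 1.0),       # identical ΔCt pattern
            ((20, 18, 28, 22), 16.0),      # ΔCt 2 vs 6 -> ΔΔCt −4
            ((24, 18, 24, 22), 0.0625),    # ΔCt 6 vs 2 -> ΔΔCt 4
        ],
    )
    def test_fold_changes(self, cts, expected):
        assert ddct_fold_change(*cts) == pytest.approx(expected)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(InputError):
            ddct_fold_change(math.nan, 18, 25, 23)
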