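"""Screen scoring: depletion scores, gene quantiles, robust null, hit calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from screenomics import (
    DegenerateNullError,
    GeneScore,
    ShRNACountRecord,
    Z95,
    call_hits,
    ceres_hits,
    compute_depletion_scores,
    fit_null_model,
    gene_quantile_scores,
    hit_shrna_support,
    score_screen,
)
from screenomics.simulate import simulate_screen


def _rec(shrna, gene, ref, fin):
    return ShRNACountRecord(shrna_id=shrna, gene=gene, count_ref=ref, count_final=fin)


class TestDepletionScores:
    def test_no_change_gives_unit_fold_and_zero_log(self):
        (d,) = compute_depletion_scores([_rec("s1", "A", 100, 100)], pseudocount=0)
        assert d.fold_depletion == 1.0
        assert d.log_depletion == 0.0

    def test_hand_arithmetic_with_pseudocount(self):
        (d,) = compute_depletion_scores([_rec("s1", "A", 400, 50)], pseudocount=1)
        assert d.fold_depletion == pytest.approx(401 / 51)
        assert d.log_depletion == pytest.approx(math.log2(401 / 51))

    def test_zero_final_count_without_pseudocount_names_the_shrna(self):
        with pytest.raises(ValueError, match="sh_bad"):
            compute_depletion_scores([_rec("sh_bad", "A", 400, 0)], pseudocount=0)

    def test_zero_final_count_guarded_by_pseudocount(self):
        (d,) = compute_depletion_scores([_rec("s1", "A", 400, 0)], pseudocount=1)
        assert d.fold_depletion == pytest.approx(401.0)


class TestGeneQuantileScores:
    def _scores(self, per_gene, **kw):
        deps = compute_depletion_scores(
            [
                _rec(f"{g}_{i}", g, int(round(100 * 2**v)), 100)
                for g, vals in per_gene.items()
                for i, v in enumerate(vals)
            ],
            pseudocount=0,
        )
        return gene_quantile_scores(deps, **kw)

    def test_constant_scores_give_the_constant(self):
        scores, _ = self._scores({"A": [1.0, 1.0, 1.0]})
        assert scores[0].quant_log == pytest.approx(1.0)

    def test_linear_interpolation_option_matches_hand_value(self):
        # 80th percentile of {0,1,2,3,4} under linear interpolation is 3.2
        scores, _ = self._scores(
            {"A": [0.0, 1.0, 2.0, 3.0, 4.0]}, quantile_method="linear"
        )
        assert scores[0].quant_log == pytest.approx(3.2, abs=1e-9)

    def test_default_lower_order_statistic(self):
        scores, _ = self._scores({"A": [0.0, 1.0, 2.0, 3.0, 4.0]})
        assert scores[0].quant_log == pytest.approx(3.0, abs=1e-9)

    def test_two_gene_ranking(self):
        scores, _ = self._scores({"A": [5.0, 5.0], "B": [2.0, 2.0]})
        by_gene = {s.gene: s for s in scores}
        assert by_gene["A"].rank == 1
        assert by_gene["B"].rank == 2

    def test_rank_is_permutation_and_ties_lexicographic(self):
        scores, _ = self._scores({"B": [1.0, 1.0], "A": [1.0, 1.0], "C": [2.0, 2.0]})
        assert sorted(s.rank for s in scores) == [1, 2, 3]
        by_gene = {s.gene: s.rank for s in scores}
        assert by_gene["C"] == 1 and by_gene["A"] == 2 and by_gene["B"] == 3

    def test_min_shrnas_skips_thin_genes(self):
        scores, skipped = self._scores({"A": [1.0], "B": [1.0, 2.0]}, min_shrnas=2)
        assert skipped == ["A"]
        assert [s.gene for s in scores] == ["B"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            gene_quantile_scores([])

    @pytest.mark.parametrize("method", ["lower", "linear"])
    def test_brute_force_quantile_oracle(self, method):
        """Gene scores equal a brute-force 80th percentile computed by
        explicit sort-and-index arithmetic, over >= 1000 random genes."""
        from screenomics import DepletionScore

        rng = np.random.default_rng(42)
        per_gene = {
            f"G{i}": list(rng.normal(0, 1, rng.integers(2, 12)))
            for i in range(1000)
        }
        deps = [
            DepletionScore(f"{g}_{i}", g, 2.0**v, v)
            for g, vals in per_gene.items()
            for i, v in enumerate(vals)
        ]
        scores, _ = gene_quantile_scores(deps, quantile_method=method)
        for s in scores:
            vals = sorted(per_gene[s.gene])
            h = 0.8 * (len(vals) - 1)
            lo = math.floor(h)
            if method == "lower":
                expected = vals[lo]
            else:
                hi = min(lo + 1, len(vals) - 1)
                expected = vals[lo] + (h - lo) * (vals[hi] - vals[lo])
            assert s.quant_log == pytest.approx(expected, abs=1e-12)

    def test_quantile_within_min_max(self):
        rng = np.random.default_rng(0)
        per_gene = {f"G{i}": list(rng.normal(0, 2, 5)) for i in range(50)}
        scores, _ = self._scores(per_gene)
        for s in scores:
            vals = per_gene[s.gene]
            assert min(vals) - 0.02 <= s.quant_log <= max(vals) + 0.02


class TestNullModel:
    def test_hand_interpolated_five_point_fit(self):
        # q2.5 = -1.9, q97.5 = 1.9 by linear interpolation; sigma = 3.8/4
        null = fit_null_model([-2.0, -1.0, 0.0, 1.0, 2.0], min_scores=5)
        assert null.mu == 0.0
        assert null.sigma == pytest.approx(0.95)
        assert null.threshold == pytest.approx(1.562655)

    def test_large_sample_normal_recovers_unit_sd(self):
        # q97.5 - q2.5 = 3.9199 for the standard normal, so sigma ~ 0.980
        rng = np.random.default_rng(7)
        null = fit_null_model(list(rng.normal(0, 1, 10**6)))
        assert null.mu == pytest.approx(0.0, abs=0.01)
        assert null.sigma == pytest.approx(0.980, abs=0.005)

    def test_degenerate_all_equal(self):
        with pytest.raises(DegenerateNullError):
            fit_null_model([1.0] * 100)

    def test_too_few_scores(self):
        with pytest.raises(ValueError):
            fit_null_model([0.0, 1.0, 2.0])

    def test_brute_force_sigma_oracle(self):
        """The null sd equals (q97.5 - q2.5)/4 computed by explicit
        interpolation arithmetic on the sorted scores."""
        rng = np.random.default_rng(11)
        vals = list(rng.gamma(2.0, 1.5, 5000))
        null = fit_null_model(vals)
        svals = sorted(vals)

        def brute_q(q):
            h = q * (len(svals) - 1)
            lo = math.floor(h)
            return svals[lo] + (h - lo) * (svals[lo + 1] - svals[lo])

        assert null.sigma == pytest.approx(
            (brute_q(0.975) - brute_q(0.025)) / 4, rel=1e-12
        )
        assert null.mu == pytest.approx(float(np.median(svals)), rel=1e-12)
        assert null.threshold == pytest.approx(null.mu + 1.6449 * null.sigma)


class TestHitCalls:
    def test_score_equal_to_threshold_is_not_a_hit(self):
        rng = np.random.default_rng(3)
        vals = list(rng.normal(0, 1, 200))
        scores = [GeneScore(f"G{i}", v, 5, 0) for i, v in enumerate(vals)]
        order = sorted(scores, key=lambda s: -s.quant_log)
        scores = [
            GeneScore(s.gene, s.quant_log, s.n_shrnas, i + 1)
            for i, s in enumerate(order)
        ]
        null = fit_null_model(scores)
        boundary = GeneScore("BOUND", null.threshold, 5, 0)
        calls = call_hits(scores + [boundary], null)
        assert not next(c for c in calls if c.gene == "BOUND").is_hit

    def test_hits_occupy_contiguous_top_ranks(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, 2000)
        scores = [
            GeneScore(f"G{i}", v, 5, r + 1)
            for r, (i, v) in enumerate(
                sorted(enumerate(vals), key=lambda t: -t[1])
            )
        ]
        calls = call_hits(scores, fit_null_model(scores))
        flags = [c.is_hit for c in calls]  # sorted by rank
        assert flags == sorted(flags, reverse=True)

    def test_null_calibration_on_iid_normal_scores(self):
        """With all gene scores i.i.d. normal the non-hit fraction is about
        95% (the inter-quantile sigma estimate is mildly biased low, giving
        a ~5.35% exceedance rather than exactly 5%)."""
        rng = np.random.default_rng(12)
        fracs = []
        for _ in range(20):
            vals = rng.normal(0, 1, 15000)
            scores = [GeneScore(f"G{i}", v, 5, i + 1) for i, v in enumerate(vals)]
            null = fit_null_model(scores)
            calls = call_hits(scores, null)
            fracs.append(1 - sum(c.is_hit for c in calls) / len(calls))
        assert abs(100 * float(np.mean(fracs)) - 95.0) <= 1.0

    def test_shift_equivariance(self):
        """Adding a constant to every log depletion shifts scores, mu and
        threshold by that constant and leaves every hit call unchanged."""
        rng = np.random.default_rng(9)
        base = [
            _rec(f"G{i}_s{j}", f"G{i}", int(v), 100)
            for i in range(100)
            for j, v in enumerate(rng.integers(50, 400, 4))
        ]
        shifted = [
            ShRNACountRecord(r.shrna_id, r.gene, r.count_ref * 4, r.count_final)
            for r in base
        ]  # quadrupling count_ref adds exactly 2 to each log2 depletion
        h1, n1, _ = score_screen(base, pseudocount=0)
        h2, n2, _ = score_screen(shifted, pseudocount=0)
        assert n2.mu == pytest.approx(n1.mu + 2, abs=1e-9)
        assert n2.threshold == pytest.approx(n1.threshold + 2, abs=1e-9)
        for a, b in zip(h1, h2):
            assert a.gene == b.gene and a.is_hit == b.is_hit
            assert b.quant_log == pytest.approx(a.quant_log + 2, abs=1e-9)

    def test_spiked_screen_recovery_and_shrna_support(self):
        """Planted essential genes are recovered and every called hit is
        supported by at least two hairpins above the cut (guaranteed by the
        lower-order-statistic gene quantile)."""
        records, truth = simulate_screen(
            n_genes=3000, shrnas_per_gene=5, frac_essential=0.02,
            effect_log2=4.0, seed=21,
        )
        deps = compute_depletion_scores(records)
        scores, _ = gene_quantile_scores(deps)
        null = fit_null_model(scores)
        hits = call_hits(scores, null)
        hit_genes = {h.gene for h in hits if h.is_hit}
        recovered = len(hit_genes & truth.essential_genes)
        assert recovered >= 0.95 * len(truth.essential_genes)
        support = hit_shrna_support(hits, deps, null)
        assert all(v >= 2 for v in support.values())


class TestCeresRule:
    @pytest.mark.parametrize(
        "score,expected",
        [(-0.6, True), (-0.5, True), (0.0, False), (-0.49, False)],
    )
    def test_inclusive_threshold(self, score, expected):
        (rec,) = ceres_hits({"A": score})
        assert rec.is_hit is expected

    def test_custom_threshold(self):
        (rec,) = ceres_hits({"A": -0.4}, threshold=-0.4)
        assert rec.is_hit

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ceres_hits({"A": float("nan")})


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=-5, max_value=5, allow_nan=False),
        min_size=40, max_size=200,
    ).filter(lambda v: max(v) - min(v) > 1e-6),
    st.floats(min_value=-10, max_value=10, allow_nan=False),
)
def test_null_model_shift_equivariance_property(vals, shift):
    n1 = fit_null_model(vals)
    n2 = fit_null_model([v + shift for v in vals])
    assert n2.mu == pytest.approx(n1.mu + shift, abs=1e-9)
    assert n2.sigma == pytest.approx(n1.sigma, abs=1e-9)
    assert n2.threshold == pytest.approx(n1.threshold + shift, abs=1e-9)
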