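import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tic._stats import spearman
from tic.expression_tables import DiffExprRecord
from tic.interference_stats import (
    accessibility_association,
    distance_expression_correlation,
    divergent_control,
    group_accessibility_shift,
    stratified_interference,
    upstream_expression_correlation,
)
from tic.neighbor_topology import NeighborContext


def make_inputs(distances, lfcs, upstream_expr=None, divergent=None):
    de, ctx = [], []
    for i, (d, f) in enumerate(zip(distances, lfcs)):
        gid = f"g{i}"
        de.append(DiffExprRecord(gid, 100.0, float(f), 0.5))
        ctx.append(
            NeighborContext(
                gene_id=gid,
                tandem_upstream_id=None if d is None else f"up{i}",
                tandem_distance=d,
                tandem_upstream_expression=(
                    None if upstream_expr is None or d is None else upstream_expr[i]
                ),
                divergent_partner_id=None,
                divergent_distance=None if divergent is None else divergent[i],
            )
        )
    return de, ctx


class TestSpearman:
    def test_hand_rank_example(self):
        """Distances 1..5 with log2FC {0.1,-0.2,0.3,-0.1,0.2}: rank table
        gives rho = 1 - 6*14/(5*24) = 0.3."""
        rho, p = spearman([1, 2, 3, 4, 5], [0.1, -0.2, 0.3, -0.1, 0.2])
        assert rho == pytest.approx(0.3)

    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [0.1, 0.2, 0.3, 0.4, 0.5])
        assert rho == pytest.approx(1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.integers(min_value=-1000, max_value=1000),
            min_size=4,
            max_size=8,
            unique=True,
        ).flatmap(
            lambda xs: st.tuples(
                st.just(xs),
                st.permutations(list(range(len(xs)))),
            )
        )
    )
    def test_matches_classic_formula_without_ties(self, xs_perm):
        """For distinct values, rho equals 1 - 6 sum(d_i^2) / (n(n^2-1))."""
        xs, perm = xs_perm
        ys = [xs[i] for i in perm]
        rho, _ = spearman(xs, ys)
        rx = np.argsort(np.argsort(xs)) + 1
        ry = np.argsort(np.argsort(ys)) + 1
        n = len(xs)
        expected = 1 - 6 * ((rx - ry) ** 2).sum() / (n * (n**2 - 1))
        assert rho == pytest.approx(expected)


class TestDistanceCorrelation:
    def test_too_few_genes(self):
        de, ctx = make_inputs([100] * 5, [0.1] * 5)
        with pytest.raises(ValueError, match="too few"):
            distance_expression_correlation(de, ctx)

    def test_positive_under_interference(self):
        """Repression shrinking with distance gives rho > 0."""
        rng = np.random.default_rng(0)
        d = rng.integers(0, 9999, size=2000)
        lfc = -0.8 * np.exp(-d / 2000.0) + rng.normal(0, 0.2, size=2000)
        de, ctx = make_inputs(d.tolist(), lfc.tolist())
        rho, p, n = distance_expression_correlation(de, ctx)
        assert n == 2000
        assert rho > 0
        assert p < 1e-6

    def test_null_is_small(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 9999, size=2000)
        lfc = rng.normal(0, 0.2, size=2000)
        de, ctx = make_inputs(d.tolist(), lfc.tolist())
        rho, _, _ = distance_expression_correlation(de, ctx)
        assert abs(rho) < 0.05


class TestStratified:
    def test_all_zero_fold_changes(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 50_000, size=400).tolist()
        de, ctx = make_inputs(d, [0.0] * 400, upstream_expr=[1.0 + i for i in range(400)])
        report = stratified_interference(de, ctx)
        for b in report.bins:
            if b.n:
                assert b.median_log2fc == 0.0
                if b.wilcoxon_p is not None:
                    assert b.wilcoxon_p == pytest.approx(1.0)

    def test_recovers_short_distance_high_expression_repression(self):
        rng = np.random.default_rng(3)
        n = 1200
        d = rng.integers(0, 40_000, size=n)
        expr = rng.lognormal(1.0, 1.5, size=n)
        cut = np.quantile(expr, 0.5)
        h = (expr >= cut).astype(float)
        lfc = -0.8 * h * np.exp(-d / 2000.0) + rng.normal(0, 0.2, size=n)
        de, ctx = make_inputs(d.tolist(), lfc.tolist(), upstream_expr=expr.tolist())
        report = stratified_interference(de, ctx)
        hi = next(b for b in report.bins if b.expr_stratum == "high_upstream")
        ref = next(b for b in report.bins if b.lo == 20000)
        assert hi.median_log2fc < ref.median_log2fc
        assert hi.wilcoxon_p < 0.01

    def test_monotone_in_effect_size(self):
        """Estimated repression depth in the short/high stratum deepens
        monotonically with beta over {0.2, 0.5, 0.8} (same seed schedule)."""
        meds = []
        for beta in (0.2, 0.5, 0.8):
            rng = np.random.default_rng(99)
            n = 1200
            d = rng.integers(0, 40_000, size=n)
            expr = rng.lognormal(1.0, 1.5, size=n)
            h = (expr >= np.quantile(expr, 0.5)).astype(float)
            lfc = -beta * h * np.exp(-d / 2000.0) + rng.normal(0, 0.2, size=n)
            de, ctx = make_inputs(d.tolist(), lfc.tolist(), upstream_expr=expr.tolist())
            report = stratified_interference(de, ctx)
            hi = next(b for b in report.bins if b.expr_stratum == "high_upstream")
            meds.append(hi.median_log2fc)
        assert meds[0] > meds[1] > meds[2]

    def test_type_one_error_calibrated(self):
        """Under the null the short/high-stratum test rejects at ~5%."""
        rejections = 0
        n_reps = 120
        for rep in range(n_reps):
            rng = np.random.default_rng([4, rep])
            n = 400
            d = rng.integers(0, 40_000, size=n)
            expr = rng.lognormal(1.0, 1.5, size=n)
            lfc = rng.normal(0, 0.2, size=n)
            de, ctx = make_inputs(d.tolist(), lfc.tolist(), upstream_expr=expr.tolist())
            report = stratified_interference(de, ctx)
            hi = next(b for b in report.bins if b.expr_stratum == "high_upstream")
            if hi.wilcoxon_p is not None and hi.wilcoxon_p < 0.05:
                rejections += 1
        assert 0.01 <= rejections / n_reps <= 0.11

    def test_empty_reference_bin(self):
        de, ctx = make_inputs([100, 200], [0.1, 0.2], upstream_expr=[1.0, 2.0])
        with pytest.raises(ValueError, match="reference"):
            stratified_interference(de, ctx)


class TestUpstreamExpressionCorrelation:
    def test_constant_upstream_is_degenerate(self):
        de, ctx = make_inputs([500] * 20, list(np.linspace(-1, 1, 20)),
                              upstream_expr=[5.0] * 20)
        rho, p, n = upstream_expression_correlation(de, ctx)
        assert rho is None and p is None

    def test_negative_under_log_linear_weighting(self):
        rng = np.random.default_rng(5)
        n = 1000
        d = rng.integers(0, 1999, size=n)
        expr = rng.lognormal(1.0, 1.5, size=n)
        h = np.log1p(expr) / np.log1p(expr.max())
        lfc = -0.8 * h * np.exp(-d / 2000.0) + rng.normal(0, 0.2, size=n)
        de, ctx = make_inputs(d.tolist(), lfc.tolist(), upstream_expr=expr.tolist())
        rho, p, _ = upstream_expression_correlation(de, ctx)
        assert rho < 0
        assert p < 1e-6

    def test_shuffled_pairing_null(self):
        rng = np.random.default_rng(6)
        n = 2000
        d = rng.integers(0, 1999, size=n)
        expr = rng.lognormal(1.0, 1.5, size=n)
        lfc = rng.normal(0, 0.2, size=n)
        de, ctx = make_inputs(d.tolist(), lfc.tolist(), upstream_expr=expr.tolist())
        rho, _, _ = upstream_expression_correlation(de, ctx)
        assert abs(rho) < 0.05


class TestDivergentControl:
    def test_no_divergent_pairs_is_empty(self, caplog):
        de, ctx = make_inputs([100] * 5, [0.1] * 5)
        report = divergent_control(de, ctx)
        assert report.bins == [] and report.n_genes == 0

    def test_zero_fold_changes_give_zero_medians(self):
        rng = np.random.default_rng(7)
        div = rng.integers(0, 50_000, size=300).tolist()
        de, ctx = make_inputs([None] * 300, [0.0] * 300, divergent=div)
        report = divergent_control(de, ctx)
        for b in report.bins:
            if b.n:
                assert b.median_log2fc == 0.0

    def test_weaker_than_tandem_effect(self):
        """Tandem-only interference: divergent bin medians stay far
        smaller than the tandem short/high-stratum repression."""
        rng = np.random.default_rng(8)
        n = 1000
        d = rng.integers(0, 40_000, size=n)
        div = rng.integers(0, 50_000, size=n)
        expr = rng.lognormal(1.0, 1.5, size=n)
        h = (expr >= np.quantile(expr, 0.5)).astype(float)
        lfc = -0.8 * h * np.exp(-d / 2000.0) + rng.normal(0, 0.2, size=n)
        de, ctx = make_inputs(d.tolist(), lfc.tolist(), upstream_expr=expr.tolist())
        for c, dv in zip(ctx, div):
            c.divergent_distance = int(dv)
        tandem = stratified_interference(de, ctx)
        hi = next(b for b in tandem.bins if b.expr_stratum == "high_upstream")
        div_report = divergent_control(de, ctx)
        for b in div_report.bins:
            if b.n:
                assert abs(b.median_log2fc) < abs(hi.median_log2fc)


class TestAccessibilityAssociation:
    def test_reduced_group_has_shorter_distances(self):
        rng = np.random.default_rng(9)
        n = 300
        d = rng.integers(0, 40_000, size=n)
        lfc = rng.normal(0, 0.1, size=n) - 0.5 * (d < 2000)
        de, ctx = make_inputs(d.tolist(), lfc.tolist(),
                              upstream_expr=[1.0] * n)
        expression = {f"g{i}": 10.0 for i in range(n)}
        peaks = set(expression)
        reduced = {f"g{i}" for i in range(n) if d[i] < 2000}
        assoc = accessibility_association(de, ctx, expression, reduced, peaks)
        assert (
            assoc.groups["reduced_promoters"]["median_tandem_distance"]
            < assoc.groups["other"]["median_tandem_distance"]
        )
        assert assoc.pairwise_p["log2fc"][("reduced_promoters", "other")] < 0.01

    def test_empty_reduced_set(self):
        de, ctx = make_inputs([1000, 2000], [0.1, -0.1])
        assoc = accessibility_association(
            de, ctx, {"g0": 1.0, "g1": 2.0}, set(), {"g0", "g1"}
        )
        assert assoc.groups["reduced_promoters"]["n"] == 0
        assert assoc.groups["other"]["n"] == 2
        assert assoc.pairwise_p["log2fc"][("reduced_promoters", "other")] is None

    def test_reduced_must_have_promoter_peak(self):
        de, ctx = make_inputs([1000], [0.1])
        with pytest.raises(ValueError, match="subset"):
            accessibility_association(de, ctx, {}, {"g0"}, set())


class TestGroupAccessibilityShift:
    def test_negative_shifts_detected(self):
        rng = np.random.default_rng(10)
        shifts = {f"peak{i}": float(v) for i, v in
                  enumerate(rng.normal(-0.3, 0.1, size=96))}
        genes = {f"g{i}" for i in range(96)}
        assignment = {f"g{i}": f"peak{i}" for i in range(96)}
        p, n, median = group_accessibility_shift(shifts, genes, assignment)
        assert n == 96
        assert median < 0
        assert p < 0.001

    def test_all_zero_is_degenerate(self):
        shifts = {f"p{i}": 0.0 for i in range(10)}
        genes = {f"g{i}" for i in range(10)}
        assignment = {f"g{i}": f"p{i}" for i in range(10)}
        p, n, median = group_accessibility_shift(shifts, genes, assignment)
        assert p is None and median == 0.0

    def test_symmetric_shifts_not_significant(self):
        vals = [0.4] * 8 + [-0.4] * 8
        shifts = {f"p{i}": v for i, v in enumerate(vals)}
        genes = {f"g{i}" for i in range(16)}
        assignment = {f"g{i}": f"p{i}" for i in range(16)}
        p, _, median = group_accessibility_shift(shifts, genes, assignment)
        assert median == 0.0
        assert p > 0.9

    def test_min_n(self):
        with pytest.raises(ValueError, match="too few"):
            group_accessibility_shift({"p": 0.1}, {"g"}, {"g": "p"})
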