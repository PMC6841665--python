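import numpy as np
import pytest
from scipy import stats

from tic._stats import bh_adjust
from tic.coverage_metrics import (
    CoverageTrack,
    count_enrichment,
    enrichment_table,
    exon_intron_fractions,
    metagene_profile,
    pausing_change,
    pausing_index,
    quantify_region,
    read_bedgraph,
    write_bedgraph,
)
from tic.genome_model import GeneModel, GeneRegion, region_of


def uniform_track(depth=2.0, length=100_000, library=1e7, rl=50, label="t"):
    return CoverageTrack({"chr1": np.full(length, float(depth))},
                         library_size=library, label=label, read_length=rl)


def region(start, end, kind="gene_body", gene="g"):
    return GeneRegion(gene_id=gene, kind=kind, chrom="chr1", start=start, end=end)


class TestQuantifyRegion:
    def test_uniform_depth_conversion(self):
        q = quantify_region(uniform_track(), region(1000, 2000))
        assert q.total == pytest.approx(40.0)       # 2*1000/50 reads at 1e7 lib
        assert q.density == pytest.approx(40.0)

    def test_empty_region_and_library_scaling(self):
        assert quantify_region(uniform_track(), region(500, 500)).total == 0.0
        q1 = quantify_region(uniform_track(library=1e7), region(0, 1000))
        q2 = quantify_region(uniform_track(library=2e7), region(0, 1000))
        assert q2.total == pytest.approx(q1.total / 2)

    def test_unknown_chromosome(self):
        bad = GeneRegion("g", "gene_body", "chrX", 0, 10)
        with pytest.raises(KeyError, match="chrX"):
            quantify_region(uniform_track(), bad)


class TestPausingIndex:
    def test_plugin_arithmetic(self):
        # quants constructed directly with known totals
        from tic.coverage_metrics import RegionQuant

        pq = RegionQuant("g", "promoter", total=59.5, density=59.5 / 0.601,
                         length=601, raw_reads=59.5)
        bq = RegionQuant("g", "gene_body", total=89.5, density=89.5 / 9.0,
                         length=9000, raw_reads=89.5)
        rec = pausing_index(pq, bq)
        assert rec.eligible
        assert rec.pi == pytest.approx((60 / 601) / (90 / 9000))

    def test_low_body_density_ineligible(self):
        from tic.coverage_metrics import RegionQuant

        pq = RegionQuant("g", "promoter", 10.0, 10 / 0.601, 601, 10.0)
        bq = RegionQuant("g", "gene_body", 4.9, 4.9, 1000, 4.9)  # 4.9/kb < 5
        rec = pausing_index(pq, bq)
        assert not rec.eligible and rec.pi is None

    def test_equal_density_gives_unit_index(self):
        track = uniform_track(depth=50.0)
        prom = quantify_region(track, region(10000, 10601, "promoter"))
        body = quantify_region(track, region(11000, 20000, "gene_body"))
        rec = pausing_index(prom, body)
        assert rec.pi == pytest.approx(1.0, rel=1e-3)


class TestPausingChange:
    def _rec(self, pi):
        from tic.coverage_metrics import PausingRecord

        return PausingRecord("g", pi, True, 10.0)

    @pytest.mark.parametrize(
        "wt,mut,changed", [(8, 6, True), (8, 8, False), (8, 9.9, False), (8, 10.1, True)]
    )
    def test_threshold(self, wt, mut, changed):
        lr, flag = pausing_change(self._rec(wt), self._rec(mut))
        assert flag == changed
        assert lr == pytest.approx(np.log2(mut / wt))

    def test_ineligible_rejected(self):
        from tic.coverage_metrics import PausingRecord

        bad = PausingRecord("g", None, False, 1.0)
        with pytest.raises(ValueError, match="eligible"):
            pausing_change(self._rec(8), bad)


class TestCountEnrichment:
    def _quant(self, total, raw):
        from tic.coverage_metrics import RegionQuant

        return RegionQuant("g", "tts_downstream", total, total / 2, 2000, raw)

    def test_null_is_flat(self):
        rec = count_enrichment(self._quant(40, 40), self._quant(40, 40), (1e7, 1e7))
        assert rec.log2_enrichment == pytest.approx(0.0)
        assert rec.p == pytest.approx(1.0)

    def test_exact_binomial_tail(self):
        """80 vs 20 raw reads at equal library sizes: P equals the exact
        two-sided binomial tail for k=80, n=100, p0=0.5, computed here by
        direct pmf summation."""
        rec = count_enrichment(self._quant(80, 80), self._quant(20, 20), (1e7, 1e7))
        pmf = stats.binom.pmf(np.arange(101), 100, 0.5)
        expected = pmf[pmf <= pmf[80] * (1 + 1e-12)].sum()
        assert rec.p == pytest.approx(expected, rel=1e-6)

    def test_both_zero(self):
        rec = count_enrichment(self._quant(0, 0), self._quant(0, 0), (1e7, 1e7))
        assert rec.p == 1.0 and rec.log2_enrichment == 0.0


class TestBH:
    def test_matches_direct_step_up(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            p = rng.uniform(0, 1, size=40)
            adj = bh_adjust(p)
            # direct step-up implementation
            order = np.argsort(p)
            m = len(p)
            stepped = p[order] * m / np.arange(1, m + 1)
            stepped = np.minimum.accumulate(stepped[::-1])[::-1]
            direct = np.empty(m)
            direct[order] = np.minimum(stepped, 1.0)
            assert np.allclose(adj, direct)
            assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()


def test_normalization_law():
    """Scaling a track's depths and library size by the same constant
    leaves totals, densities, pausing indices and log2 enrichments
    unchanged to 1e-9 (the exact-test P reflects raw read evidence and
    is intentionally outside this invariance)."""
    rng = np.random.default_rng(8)
    depth = rng.poisson(3.0, size=50_000).astype(float)
    base = CoverageTrack({"chr1": depth}, library_size=depth.sum() / 50)
    c = 3.7
    scaled = CoverageTrack({"chr1": depth * c}, library_size=c * depth.sum() / 50)
    prom, body = region(10000, 10601, "promoter"), region(11000, 30000, "gene_body")
    for r in (prom, body):
        q1, q2 = quantify_region(base, r), quantify_region(scaled, r)
        assert q2.total == pytest.approx(q1.total, abs=1e-9)
        assert q2.density == pytest.approx(q1.density, abs=1e-9)
    p1 = pausing_index(quantify_region(base, prom), quantify_region(base, body))
    p2 = pausing_index(quantify_region(scaled, prom), quantify_region(scaled, body))
    assert p2.pi == pytest.approx(p1.pi, abs=1e-9)
    e1 = count_enrichment(quantify_region(base, prom), quantify_region(base, body),
                          (base.library_size, base.library_size))
    e2 = count_enrichment(quantify_region(scaled, prom), quantify_region(scaled, body),
                          (scaled.library_size, scaled.library_size))
    assert e2.log2_enrichment == pytest.approx(e1.log2_enrichment, abs=1e-9)


class TestMetagene:
    def _genes(self, n=8, L=5000, expr=None):
        genes = []
        for i in range(n):
            x = 10_000 + i * 20_000
            g = GeneModel(f"g{i}", "chr1", "+", x, x + L)
            g.expression = float(expr[i]) if expr is not None else 1.0
            genes.append(g)
        return genes

    def test_uniform_coverage_gives_flat_equal_profiles(self):
        track = uniform_track(depth=4.0, length=300_000)
        genes = self._genes(expr=np.arange(8) + 1.0)
        profiles = metagene_profile(track, genes, n_bins=20, flank=1000)
        vals = np.concatenate(list(profiles.values()))
        assert np.allclose(vals, vals[0])

    def test_groups_ordered_when_coverage_tracks_expression(self):
        expr = np.arange(8) + 1.0
        depths = np.zeros(300_000)
        genes = self._genes(expr=expr)
        for g in genes:
            depths[g.start:g.end] = g.expression
        track = CoverageTrack({"chr1": depths}, library_size=1e7)
        profiles = metagene_profile(track, genes, n_bins=20, flank=1000)
        means = [profiles[q][25] for q in ("Q1", "Q2", "Q3", "Q4")]
        assert means == sorted(means)

    def test_single_gene_profile_is_its_own_coverage(self):
        depths = np.zeros(50_000)
        depths[10_000:15_000] = 7.0
        track = CoverageTrack({"chr1": depths}, library_size=1e7)
        g = GeneModel("g", "chr1", "+", 10_000, 15_000)
        g.expression = 1.0
        profiles = metagene_profile(track, [g], n_bins=10, flank=1000,
                                    expression_groups=1)
        (prof,) = profiles.values()
        scale = 1e7 / (1e7 * 50)
        assert np.allclose(prof[5:15], 7.0 * scale)
        assert np.allclose(prof[:5], 0.0)

    def test_mirror_symmetric_coverage_gives_symmetric_profile(self):
        depths = np.zeros(50_000)
        center = 12_500
        x = np.arange(50_000)
        depths[:] = np.exp(-((x - center) ** 2) / (2 * 2000.0**2)) * 10
        track = CoverageTrack({"chr1": depths}, library_size=1e7)
        # span chosen so the sampled window [7500, 17501) is exactly
        # centered on the coverage peak at base 12500
        g = GeneModel("g", "chr1", "+", 10_000, 15_001)
        g.expression = 1.0
        (prof,) = metagene_profile(track, [g], n_bins=10, flank=2500,
                                   expression_groups=1).values()
        assert np.allclose(prof, prof[::-1], rtol=1e-9)


class TestExonIntronFractions:
    def _gene_with_exons(self):
        g = GeneModel("g", "chr1", "+", 10_000, 20_000)
        g.exons = [(10_000, 10_500), (19_500, 20_000)]  # 10% exonic
        return g

    def test_exon_only_reads(self):
        depths = np.zeros(30_000)
        depths[10_000:10_500] = 5.0
        track = CoverageTrack({"chr1": depths}, library_size=1e7)
        assert exon_intron_fractions(track, [self._gene_with_exons()]) == (1.0, 0.0, 0.0)

    def test_uniform_over_10pct_exonic_gene(self):
        depths = np.zeros(30_000)
        depths[10_000:20_000] = 3.0
        track = CoverageTrack({"chr1": depths}, library_size=1e7)
        ex, intron, inter = exon_intron_fractions(track, [self._gene_with_exons()])
        assert ex == pytest.approx(0.1, abs=1e-9)
        assert intron == pytest.approx(0.9, abs=1e-9)
        assert inter == 0.0

    def test_intergenic_only(self):
        depths = np.zeros(30_000)
        depths[25_000:26_000] = 2.0
        track = CoverageTrack({"chr1": depths}, library_size=1e7)
        assert exon_intron_fractions(track, [self._gene_with_exons()]) == (0.0, 0.0, 1.0)


def test_bedgraph_roundtrip(tmp_path):
    rng = np.random.default_rng(9)
    depths = rng.poisson(1.2, size=5000).astype(float)
    track = CoverageTrack({"chr1": depths}, library_size=123.0, label="x",
                          read_length=40)
    path = tmp_path / "t.bedgraph"
    write_bedgraph(track, path)
    back = read_bedgraph(path)
    assert np.array_equal(back.depths["chr1"], depths)
    assert back.library_size == 123.0 and back.read_length == 40
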