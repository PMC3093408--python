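import numpy as np
import pytest
from scipy import stats

from ervscape import neighborhood as nb
from ervscape.model import TranscriptRecord
from conftest import make_chain
from oracles import brute_force_profile, window_coverage_bp


def tx(gene, tid, start, end, strand="+", chrom="chr1"):
    return TranscriptRecord(gene, tid, chrom, strand, start, end)


def model(gene="g", start=0, end=1000, strand="+", chrom="chr1"):
    return nb.CompositeGeneModel(gene, chrom, strand, start, end)


def random_fixture(rng, n_ervs=6, n_models=12, chrom_len=400_000):
    ervs = [
        make_chain(
            id=i + 1,
            start=(s := int(rng.integers(0, chrom_len - 10_000))),
            end=s + int(rng.integers(1_000, 10_000)),
            strand="+" if rng.random() < 0.5 else "-",
        )
        for i in range(n_ervs)
    ]
    models = [
        nb.CompositeGeneModel(
            f"g{j}", "chr1",
            "+" if rng.random() < 0.5 else "-",
            (ms := int(rng.integers(0, chrom_len - 20_000))),
            ms + int(rng.integers(500, 20_000)),
        )
        for j in range(n_models)
    ]
    return ervs, models


class TestCompositeModels:
    def test_overlapping_extension_annexed(self):
        models = nb.build_composite_models([
            tx("g1", "t1", 100, 500),
            tx("g1", "t2", 400, 900),  # longest
        ])
        assert (models[0].start, models[0].end) == (100, 900)

    def test_chained_annexation(self):
        models = nb.build_composite_models([
            tx("g1", "t1", 400, 900),  # longest
            tx("g1", "t2", 100, 500),
            tx("g1", "t3", 0, 150),  # reachable only after t2 annexed
        ])
        assert (models[0].start, models[0].end) == (0, 900)

    def test_single_transcript(self):
        models = nb.build_composite_models([tx("g1", "t1", 10, 50)])
        assert (models[0].start, models[0].end) == (10, 50)

    def test_non_overlapping_alternative_not_annexed(self):
        models = nb.build_composite_models([
            tx("g1", "t1", 0, 1000),  # longest
            tx("g1", "t2", 5000, 5400),  # disjoint: never annexed
        ])
        assert len(models) == 1
        assert (models[0].start, models[0].end) == (0, 1000)

    def test_gene_on_both_strands_split_with_warning(self):
        with pytest.warns(UserWarning, match="both strands"):
            models = nb.build_composite_models([
                tx("g1", "t1", 0, 1000, "+"),
                tx("g1", "t2", 100, 800, "-"),
            ])
        assert len(models) == 2
        assert {m.strand for m in models} == {"+", "-"}


class TestRelativePosition:
    def test_overlap_is_position_zero(self):
        erv = make_chain(start=5000, end=15_000)
        assert nb.erv_relative_position(erv, model(start=14_000, end=16_000)) == 0

    def test_downstream_on_plus_strand(self):
        erv = make_chain(start=5000, end=15_000, strand="+")
        assert nb.erv_relative_position(erv, model(start=16_000, end=17_000)) == 1001

    def test_minus_strand_flips_frame(self):
        # model 1 kb toward the chromosome start of a minus-strand element
        # lies downstream in the element's own frame: positive offset
        erv = make_chain(start=5000, end=15_000, strand="-")
        pos = nb.erv_relative_position(erv, model(start=3_000, end=4_000))
        assert pos == 1001

    def test_different_chromosome_is_none(self):
        erv = make_chain(start=0, end=100)
        assert nb.erv_relative_position(erv, model(chrom="chr9")) is None


class TestProfile:
    def test_single_model_run_counts(self):
        erv = make_chain(start=10_000, end=20_000, strand="+")
        m = model(start=20_009, end=20_019, strand="+")  # offsets +10..+19
        prof = nb.neighborhood_profile([erv], [m], window=100)
        w = 100
        assert prof.sense_counts[w + 10 : w + 20].tolist() == [1] * 10
        assert prof.sense_counts.sum() == 10
        assert prof.antisense_counts.sum() == 0

    def test_no_models_all_zero(self):
        prof = nb.neighborhood_profile([make_chain()], [], window=50)
        assert prof.total_coverage() == 0

    def test_model_beyond_window_ignored(self):
        erv = make_chain(start=0, end=1000)
        far = model(start=1000 + 100_001, end=1000 + 100_500)
        prof = nb.neighborhood_profile([erv], [far])
        assert prof.total_coverage() == 0

    def test_matches_quadratic_oracle(self, rng):
        ervs, models = random_fixture(rng, n_ervs=4, n_models=8,
                                      chrom_len=60_000)
        window = 5_000
        prof = nb.neighborhood_profile(ervs, models, window)
        sense, anti = brute_force_profile(ervs, models, window)
        np.testing.assert_array_equal(prof.sense_counts, sense)
        np.testing.assert_array_equal(prof.antisense_counts, anti)

    def test_count_conservation(self, rng):
        for _ in range(10):
            ervs, models = random_fixture(rng)
            window = 30_000
            prof = nb.neighborhood_profile(ervs, models, window)
            assert prof.total_coverage() == window_coverage_bp(
                ervs, models, window
            )

    def test_reflection_plus_strand_flip_invariance(self, rng):
        L = 400_000
        for _ in range(5):
            ervs, models = random_fixture(rng, chrom_len=L)
            window = 20_000
            flip = {"+": "-", "-": "+"}
            r_ervs = [
                make_chain(id=e.id, start=L - e.end, end=L - e.start,
                           strand=flip[e.strand])
                for e in ervs
            ]
            r_models = [
                nb.CompositeGeneModel(m.gene_id, m.chromosome,
                                      flip[m.strand], L - m.end, L - m.start)
                for m in models
            ]
            a = nb.neighborhood_profile(ervs, models, window)
            b = nb.neighborhood_profile(r_ervs, r_models, window)
            np.testing.assert_array_equal(a.sense_counts, b.sense_counts)
            np.testing.assert_array_equal(a.antisense_counts,
                                          b.antisense_counts)

    def test_erv_strand_flip_swaps_and_reverses(self, rng):
        ervs, models = random_fixture(rng)
        window = 20_000
        flip = {"+": "-", "-": "+"}
        f_ervs = [
            make_chain(id=e.id, start=e.start, end=e.end,
                       strand=flip[e.strand])
            for e in ervs
        ]
        a = nb.neighborhood_profile(ervs, models, window)
        b = nb.neighborhood_profile(f_ervs, models, window)
        np.testing.assert_array_equal(a.sense_counts,
                                      b.antisense_counts[::-1])
        np.testing.assert_array_equal(a.antisense_counts,
                                      b.sense_counts[::-1])


class TestOverUnder:
    def test_all_equal(self):
        prof = nb.NeighborhoodProfile(window_half_width=100)
        res = nb.over_under(prof)
        assert (res.over, res.under, res.equal) == (0, 0, 201)
        assert not res.defined

    def test_chi2_closed_form(self):
        w = 100
        prof = nb.NeighborhoodProfile(window_half_width=w)
        prof.antisense_counts[:150] = 5  # antisense higher at 150 positions
        prof.sense_counts[150:200] = 5  # sense higher at 50
        res = nb.over_under(prof)
        assert (res.over, res.under, res.equal) == (150, 50, 1)
        assert res.chi2 == pytest.approx(50.0)  # (50^2 + 50^2)/100

    def test_chi2_matches_formula_on_random_profiles(self, rng):
        for _ in range(20):
            w = 50
            prof = nb.NeighborhoodProfile(window_half_width=w)
            prof.sense_counts[:] = rng.integers(0, 4, size=2 * w + 1)
            prof.antisense_counts[:] = rng.integers(0, 4, size=2 * w + 1)
            res = nb.over_under(prof)
            if not res.defined:
                continue
            n = res.over + res.under
            expected = (res.over - n / 2) ** 2 / (n / 2) * 2
            assert res.chi2 == pytest.approx(expected)
            assert res.p_value == pytest.approx(
                stats.chi2.sf(expected, df=1)
            )
            assert res.over + res.under + res.equal == 2 * w + 1


class TestStratification:
    def test_all_young_equals_unstratified(self, rng):
        ervs, models = random_fixture(rng)
        ages = {e.id: "young" for e in ervs}
        strat = nb.stratified_profiles(ervs, models, ages, window=10_000)
        full = nb.neighborhood_profile(ervs, models, window=10_000)
        np.testing.assert_array_equal(
            strat["young"].sense_counts, full.sense_counts
        )
        assert strat["old"].total_coverage() == 0

    def test_stratified_profiles_sum_to_datable_total(self, rng):
        ervs, models = random_fixture(rng, n_ervs=9)
        classes = ["young", "middle", "old", "undatable"]
        ages = {e.id: classes[i % 4] for i, e in enumerate(ervs)}
        window = 10_000
        strat = nb.stratified_profiles(ervs, models, ages, window)
        datable = [e for e in ervs if ages[e.id] != "undatable"]
        full = nb.neighborhood_profile(datable, models, window)
        total_sense = sum(p.sense_counts for p in strat.values())
        total_anti = sum(p.antisense_counts for p in strat.values())
        np.testing.assert_array_equal(total_sense, full.sense_counts)
        np.testing.assert_array_equal(total_anti, full.antisense_counts)


class TestProximalGenes:
    def test_overlapping_gene_reported_contained(self):
        erv = make_chain(start=2000, end=3000)
        rows = nb.proximal_genes([erv], [model(start=1000, end=9000)])
        assert rows[0].side == "contained" and rows[0].distance == 0

    @pytest.mark.parametrize("gap,reported", [(4999, True), (5000, True),
                                              (5001, False)])
    def test_upstream_flank_boundary(self, gap, reported):
        m = model(start=50_000, end=60_000, strand="+")
        erv = make_chain(start=50_000 - gap - 1000, end=50_000 - gap)
        rows = nb.proximal_genes([erv], [m], flank=5000)
        if reported:
            assert len(rows) == 1 and rows[0].side == "upstream"
            assert rows[0].distance == gap
        else:
            assert rows == []

    def test_minus_strand_gene_sides(self):
        # for a minus-strand gene the 5' end is at the genomic right edge
        m = model(start=50_000, end=60_000, strand="-")
        left = make_chain(id=1, start=48_000, end=49_000)
        right = make_chain(id=2, start=61_000, end=62_000)
        rows = nb.proximal_genes([left, right], [m], flank=5000)
        sides = {r.erv_id: r.side for r in rows}
        assert sides == {1: "downstream", 2: "upstream"}

    def test_empty_erv_set(self):
        assert nb.proximal_genes([], [model()]) == []


class TestOrientationBiasTest:
    def test_counts_each_gene_once(self):
        erv = make_chain(start=10_000, end=20_000, strand="+")
        same = model(gene="a", start=25_000, end=30_000, strand="+")
        opp = model(gene="b", start=32_000, end=40_000, strand="-")
        res = nb.orientation_bias_test([erv], [same, opp])
        assert (res.over, res.under) == (1, 1)
        assert res.unit == "gene"

    def test_gene_outside_all_windows_not_counted(self):
        erv = make_chain(start=0, end=1000)
        far = model(start=500_000, end=510_000)
        res = nb.orientation_bias_test([erv], [far])
        assert not res.defined
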