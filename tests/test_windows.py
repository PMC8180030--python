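"""Tiling, counting, RPKM, depth filter, TSS coverage, class annotation."""

import numpy as np
import pandas as pd
import pytest

import ptcore as pt
from ptcore.io import TagSet
from ptcore.windows import (
    WindowMatrix,
    annotate_windows,
    class_enrichment,
    count_and_normalize,
    filter_windows,
    group_mean_ttest,
    tile_genome,
    tss_profile,
)


def _tags(sample, chrom_pos, strand=0):
    by = {}
    for chrom, pos in chrom_pos:
        by.setdefault(chrom, []).append(pos)
    return TagSet(sample, {
        c: (np.array(v), np.full(len(v), strand, np.int8)) for c, v in by.items()
    })


class TestTiling:
    def test_sliding_windows_with_truncated_tail(self):
        asm = pt.load_assembly("chr1\t2000")
        w = tile_genome(asm, 1000, 900)
        assert list(w["start"]) == [0, 900, 1800]
        assert list(w["end"]) == [1000, 1900, 2000]

    def test_exact_fit_single_window(self):
        asm = pt.load_assembly("chr1\t1000")
        w = tile_genome(asm, 1000, 1000)
        assert len(w) == 1 and w["end"][0] == 1000

    def test_short_tail_dropped(self):
        asm = pt.load_assembly("chr1\t2050")  # 50 bp uncovered < min_tail
        w = tile_genome(asm, 1000, 1000)
        assert list(w["end"]) == [1000, 2000]

    def test_step_must_be_positive_and_not_exceed_window(self):
        asm = pt.load_assembly("chr1\t5000")
        with pytest.raises(ValueError):
            tile_genome(asm, 1000, 0)
        with pytest.raises(ValueError):
            tile_genome(asm, 1000, 1500)


class TestCounting:
    def test_rpkm_formula(self):
        asm = pt.load_assembly("chr1\t10000")
        w = tile_genome(asm, 1000, 1000)
        tags = _tags("a", [("chr1", 500)] * 100)
        wm = count_and_normalize([tags], w, lib_sizes=np.array([10_000_000]))
        assert wm.counts[0, 0] == 100
        assert wm.rpkm[0, 0] == pytest.approx(10.0)
        assert wm.rpkm[1, 0] == 0.0

    def test_sliding_tag_counted_in_both_windows(self):
        asm = pt.load_assembly("chr1\t3000")
        w = tile_genome(asm, 1000, 900)
        tags = _tags("a", [("chr1", 950)])
        wm = count_and_normalize([tags], w)
        assert wm.counts[0, 0] == 1 and wm.counts[1, 0] == 1
        assert wm.counts[2, 0] == 0

    def test_nonoverlapping_counts_sum_to_library(self, sim_default):
        tags = pt.simulate_atac(sim_default, "sensitive", 1)
        w = tile_genome(sim_default.assembly, 1000)
        wm = count_and_normalize([tags], w)
        assert wm.counts.sum() == tags.library_size

    def test_rpkm_invariant_under_tag_duplication(self):
        asm = pt.load_assembly("chr1\t5000")
        w = tile_genome(asm, 1000, 1000)
        pos = [("chr1", p) for p in (100, 1500, 1600, 4200)]
        single = count_and_normalize([_tags("a", pos)], w)
        double = count_and_normalize([_tags("a", pos * 2)], w)
        assert np.allclose(single.rpkm, double.rpkm)

    def test_zero_library_rejected(self):
        asm = pt.load_assembly("chr1\t2000")
        w = tile_genome(asm, 1000, 1000)
        with pytest.raises(ValueError):
            count_and_normalize([TagSet("empty")], w)


class TestFilter:
    def _matrix(self, mean_rpkm):
        n = len(mean_rpkm)
        win = pd.DataFrame({"chrom": ["chr1"] * n,
                            "start": np.arange(n) * 1000,
                            "end": (np.arange(n) + 1) * 1000})
        rpkm = np.asarray(mean_rpkm, float)[:, None]
        return WindowMatrix(win, ["s"], rpkm.astype(int), np.array([1e6]), rpkm)

    def test_low_coverage_fails(self):
        wm = filter_windows(self._matrix([0.5, 3.0, 3.0, 3.0]))
        assert not wm.pass_filter[0]

    def test_example_pass_between_bounds(self):
        # window at 2.0 passes when median=3, SD=2 (upper bound 5)
        vals = [2.0, 3.0, 3.0 - 2.0, 3.0 + 2.0, 3.0]
        wm = filter_windows(self._matrix(vals))
        med = wm.metadata["filter_median"]
        sd = wm.metadata["filter_sd"]
        assert wm.pass_filter[0] == (1 < 2.0 < med + sd)
        assert wm.pass_filter[0]

    def test_planted_extreme_windows_fail_upper_bound(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1.5, 3.0, 1000)
        extreme = rng.choice(1000, 10, replace=False)
        vals[extreme] = 50.0
        wm = filter_windows(self._matrix(vals))
        med = np.median(vals[vals > 0])
        sd = np.std(vals[vals > 0], ddof=1)
        expected_fail = np.flatnonzero(~((vals > 1) & (vals < med + sd)))
        assert set(np.flatnonzero(~wm.pass_filter)) == set(expected_fail)
        assert set(extreme) <= set(expected_fail)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            filter_windows(self._matrix([0.0, 0.0]))


class TestTssProfile:
    def test_window_centered_on_tss(self):
        asm = pt.load_assembly("chr1\t100000")
        g = pt.GeneModel("G1", "chr1", "+", 5000, 9000)
        tags = _tags("a", [("chr1", 4100), ("chr1", 5900), ("chr1", 6100)])
        prof = tss_profile([tags], [g], asm)
        assert prof.loc[0, "start"] == 4000 and prof.loc[0, "end"] == 6000
        # 2 of 3 tags inside [4000, 6000), RPKM = 2 / (2 * 3e-6)
        assert prof.loc[0, "a"] == pytest.approx(2 / (2 * 3 / 1e6))

    def test_minus_strand_same_centered_window(self):
        asm = pt.load_assembly("chr1\t100000")
        g = pt.GeneModel("G1", "chr1", "-", 1000, 5001)  # TSS at 5000
        prof = tss_profile([_tags("a", [("chr1", 10)])], [g], asm)
        assert prof.loc[0, "start"] == 4000 and prof.loc[0, "end"] == 6000

    def test_edge_window_truncated_and_flagged(self):
        asm = pt.load_assembly("chr1\t100000")
        g = pt.GeneModel("G1", "chr1", "+", 300, 4000)
        prof = tss_profile([_tags("a", [("chr1", 10)])], [g], asm)
        assert prof.loc[0, "truncated"]
        assert prof.loc[0, "start"] == 0

    def test_promoter_coupled_de_genes_gain_coverage(self):
        """With DE-gene promoter accessibility doubled in the resistant
        line, mean TSS coverage shifts resistant > sensitive (t-test)."""
        cfg = pt.SimConfig(seed=3, de_promoter_boost=2.0)
        sim = pt.simulate_genome_annotation(cfg)
        reps = {ln: [pt.simulate_atac(sim, ln, r) for r in (1, 2, 3)]
                for ln in ("sensitive", "resistant")}
        de = sim.truth.de_genes
        up = set(de[de["direction"] == "up"]["gene_id"])
        genes_up = [g for g in sim.genes if g.gene_id in up]
        prof = tss_profile(reps["sensitive"] + reps["resistant"], genes_up,
                           sim.assembly)
        diff, t, p = group_mean_ttest(
            prof, [x.sample_id for x in reps["resistant"]],
            [x.sample_id for x in reps["sensitive"]])
        assert diff > 0 and p < 0.01


class TestAnnotation:
    def _genes(self):
        return [pt.GeneModel("G1", "chr1", "+", 10_000, 18_000,
                             [(10_000, 12_000), (15_000, 18_000)])]

    def _windows(self, mids):
        return pd.DataFrame({"chrom": ["chr1"] * len(mids),
                             "start": [m - 500 for m in mids],
                             "end": [m + 500 for m in mids]})

    def test_upstream_window_is_promoter(self):
        # midpoint 400 bp upstream of the + strand TSS
        labels = annotate_windows(self._windows([9600]), self._genes(), [])
        assert labels[0] == "promoter-TSS"

    def test_cpg_island_precedence_over_promoter(self):
        cpg = [pt.Interval("chr1", 9000, 10_500)]
        labels = annotate_windows(self._windows([9600]), self._genes(), cpg)
        assert labels[0] == "CpG-island"

    def test_distal_window_is_intergenic(self):
        labels = annotate_windows(self._windows([68_000]), self._genes(), [])
        assert labels[0] == "intergenic"

    def test_exon_intron_tts(self):
        labels = annotate_windows(
            self._windows([11_500, 13_500, 18_500]), self._genes(), [])
        assert list(labels) == ["exon", "intron", "TTS"]

    def test_every_window_gets_exactly_one_class(self, sim_default):
        w = tile_genome(sim_default.assembly, 1000)
        labels = annotate_windows(w, sim_default.genes, sim_default.cpg_islands)
        counts = pd.Series(labels).value_counts()
        assert counts.sum() == len(w)


class TestClassEnrichment:
    def test_cross_product_or(self):
        classes = np.array(["A"] * 100 + ["B"] * 200)
        diff = np.zeros(300, bool)
        diff[:10] = True          # 10 of class A
        diff[100:105] = True      # 5 of class B
        out = class_enrichment(diff, classes, ["A"])
        row = out.iloc[0]
        assert (row.a, row.b, row.c, row.d) == (10, 90, 5, 195)
        assert row.OR == pytest.approx((10 * 195) / (90 * 5))

    def test_symmetric_table_or_one(self):
        classes = np.array(["A"] * 100 + ["B"] * 100)
        diff = np.zeros(200, bool)
        diff[:10] = True
        diff[100:110] = True
        out = class_enrichment(diff, classes, ["A"])
        assert out.iloc[0].OR == pytest.approx(1.0)

    def test_empty_diff_set_rejected(self):
        with pytest.raises(ValueError):
            class_enrichment(np.zeros(10, bool), np.array(["A"] * 10))
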