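"""Peak calling, CORE calling, cross-line classification and the
CORE-expression association."""

import warnings

import numpy as np
import pandas as pd
import pytest

import ptcore as pt
from ptcore.cores import (
    _overlaps_any,
    call_cores,
    call_peaks,
    classify_core_changes,
    core_expression_association,
    link_genes_to_cores,
    pooled_gap_threshold,
    region_state_enrichment,
    select_gap_threshold,
)
from ptcore.io import GenomeAssembly, Interval, TagSet


def _uniform_tagset(rng, length, n, spikes=()):
    """Uniform background with optional (start, end, fold) spikes."""
    pos = [rng.integers(0, length, n)]
    density = n / length
    for s, e, fold in spikes:
        extra = rng.integers(s, e, int(density * (e - s) * (fold - 1)))
        pos.append(extra)
    pos = np.concatenate(pos)
    strand = rng.integers(0, 2, len(pos)).astype(np.int8)
    return TagSet("x", {"c": (pos, strand)})


class TestCallPeaks:
    def test_single_strong_spike_gives_one_peak_with_summit(self):
        rng = np.random.default_rng(1)
        asm = GenomeAssembly(["c"], {"c": 200_000})
        tags = _uniform_tagset(rng, 200_000, 2000,
                               spikes=[(50_000, 50_300, 1000)])
        peaks = call_peaks(tags, asm)
        assert len(peaks) == 1
        p = peaks.iloc[0]
        assert p.start < 50_300 and p.end > 50_000
        assert 50_000 - 300 <= p.summit <= 50_300 + 300

    def test_uniform_background_produces_no_peaks(self):
        asm = GenomeAssembly(["c"], {"c": 500_000})
        total = 0
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            tags = _uniform_tagset(rng, 500_000, 20_000)
            total += len(call_peaks(tags, asm))
        assert total == 0

    def test_empty_tagset_rejected(self):
        asm = GenomeAssembly(["c"], {"c": 1000})
        with pytest.raises(ValueError):
            call_peaks(TagSet("e"), asm)


def _peak_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestCallCores:
    def test_forced_run_with_given_threshold(self):
        peaks = _peak_frame([
            ("c", 0, 100), ("c", 200, 300), ("c", 400, 500),
            ("c", 100_000, 100_100),
        ])
        cores = call_cores(peaks, min_order=3, gap_threshold=150)
        assert len(cores) == 1
        core = cores.iloc[0]
        assert (core.start, core.end, core.order) == (0, 500, 3)

    def test_gap_exactly_at_threshold_is_linked(self):
        peaks = _peak_frame([("c", i * 250, i * 250 + 100) for i in range(5)])
        cores = call_cores(peaks, min_order=3, gap_threshold=150)
        assert len(cores) == 1 and cores.iloc[0].order == 5

    def test_fewer_peaks_than_min_order_warns_and_returns_empty(self):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            cores = call_cores(_peak_frame([("c", 0, 100)]), min_order=3)
        assert len(cores) == 0
        assert any("min_order" in str(x.message) for x in w)

    def test_spans_disjoint_and_orders_sum_to_clustered_peaks(self):
        rng = np.random.default_rng(2)
        rows = []
        pos = 0
        for _ in range(30):
            k = rng.integers(1, 6)
            for _ in range(k):
                rows.append(("c", pos, pos + 100))
                pos += 100 + rng.integers(50, 400)
            pos += 20_000
        cores = call_cores(_peak_frame(rows), gap_threshold=500)
        ends = None
        total_members = 0
        for row in cores.itertuples(index=False):
            if ends is not None:
                assert row.start >= ends
            ends = row.end
            total_members += row.order
            assert row.order >= 3
        member_ids = [i for row in cores["peak_indices"] for i in row]
        assert len(member_ids) == len(set(member_ids)) == total_members

    def test_planted_templates_recovered_isolated_peaks_ignored(self):
        """Clustered templates (3-10 peaks, gaps <= 2 kb) vs isolated peaks
        >= 50 kb apart: every template becomes exactly one CORE and no CORE
        arises from isolated peaks."""
        rng = np.random.default_rng(7)
        rows, truth = [], []
        cursor = 100_000
        for _ in range(40):
            k = int(rng.integers(3, 11))
            start = cursor
            pos = start
            for _ in range(k):
                w = int(rng.integers(300, 801))
                rows.append(("chr1", pos, pos + w))
                pos += w + int(rng.integers(100, 2001))
            truth.append(("chr1", start, rows[-1][2], k))
            cursor = pos + int(rng.integers(50_000, 80_000))
        for _ in range(300):
            w = int(rng.integers(300, 801))
            rows.append(("chr1", cursor, cursor + w))
            cursor += w + int(rng.integers(50_000, 80_000))
        peaks = _peak_frame(rows)
        cores = call_cores(peaks)
        tm = pd.DataFrame(truth, columns=["chrom", "start", "end", "order"])
        recovered = 0
        for row in tm.itertuples(index=False):
            sel = (cores["start"] < row.end) & (cores["end"] > row.start)
            if sel.sum() == 1 and cores[sel].iloc[0]["order"] == row.order:
                recovered += 1
        assert recovered >= 36  # >= 90% of 40
        assert int((~_overlaps_any(cores, tm)).sum()) == 0

    def test_unimodal_gaps_fall_back_to_quantile(self):
        rng = np.random.default_rng(8)
        gaps = rng.uniform(3000, 10_000, 500)
        thr = select_gap_threshold(gaps, gap_quantile=0.25)
        assert thr == pytest.approx(np.quantile(np.sort(gaps), 0.25))


class TestClassification:
    def _cores(self, spans):
        df = _peak_frame([("c", s, e) for s, e in spans])
        df["order"] = 3
        return df

    def test_identical_sets_all_shared(self):
        a = self._cores([(0, 1000), (5000, 6000)])
        la, lb = classify_core_changes(a, a.copy())
        assert (la["label"] == "shared").all()
        assert (lb["label"] == "shared").all()

    def test_disjoint_sets_all_gained_and_lost(self):
        a = self._cores([(0, 1000)])
        b = self._cores([(5000, 6000)])
        la, lb = classify_core_changes(a, b)
        assert (la["label"] == "lost").all()
        assert (lb["label"] == "gained").all()

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        def random_cores():
            starts = np.sort(rng.choice(np.arange(100) * 2000, 20, replace=False))
            return self._cores([(s, s + rng.integers(500, 1500)) for s in starts])
        a, b = random_cores(), random_cores()
        la, lb = classify_core_changes(a, b)
        lb2, la2 = classify_core_changes(b, a)
        gained_ab = set(lb.loc[lb["label"] == "gained", "start"])
        lost_ba = set(lb2.loc[lb2["label"] == "lost", "start"])
        assert gained_ab == lost_ba

    def test_end_to_end_labels_match_planted_templates(
            self, sim_default, peaks_by_line):
        thr = pooled_gap_threshold(list(peaks_by_line.values()))
        cores = {ln: call_cores(pk, gap_threshold=thr)
                 for ln, pk in peaks_by_line.items()}
        la, lb = classify_core_changes(cores["sensitive"], cores["resistant"])
        tm = sim_default.truth.core_templates
        ok = n = 0
        for labeled, present, want in (
            (la, ["shared", "lost"], {"shared": "shared", "lost": "lost"}),
            (lb, ["shared", "gained"], {"shared": "shared", "gained": "gained"}),
        ):
            for row in tm[tm["label"].isin(present)].itertuples(index=False):
                sel = ((labeled["chrom"] == row.chrom)
                       & (labeled["start"] < row.end)
                       & (labeled["end"] > row.start))
                if sel.any():
                    n += 1
                    ok += labeled[sel]["label"].iloc[0] == want[row.label]
        assert n > 0 and ok / n >= 0.8


class TestGeneLinkage:
    def _core(self):
        df = _peak_frame([("c", 50_000, 52_000)])
        return df

    def _gene(self, tss, gid="G1"):
        return pt.GeneModel(gid, "c", "+", tss, tss + 1000)

    def test_boundary_arithmetic(self):
        linked = link_genes_to_cores(self._core(), [self._gene(151_999)])
        assert len(linked) == 1
        linked = link_genes_to_cores(self._core(), [self._gene(152_000)])
        assert len(linked) == 0

    def test_all_far_genes_unlinked(self):
        genes = [self._gene(300_000 + i * 10_000, f"G{i}") for i in range(5)]
        assert len(link_genes_to_cores(self._core(), genes)) == 0

    def test_agrees_with_brute_force_on_simulation(self, sim_default):
        tm = sim_default.truth.core_templates.rename(
            columns={"core_id": "name"})
        linked = link_genes_to_cores(tm, sim_default.genes)
        brute = set()
        for ci, core in enumerate(tm.itertuples(index=False)):
            for g in sim_default.genes:
                if (g.chrom == core.chrom
                        and core.start - 100_000 <= g.tss < core.end + 100_000):
                    brute.add((ci, g.gene_id))
        assert set(map(tuple, linked.to_numpy())) == brute


class TestAssociation:
    def test_de_genes_only_near_lost_cores(self):
        cores = pd.DataFrame({
            "chrom": ["c", "c"], "start": [0, 500_000],
            "end": [2000, 502_000], "label": ["gained", "lost"],
        })
        genes = [pt.GeneModel(f"G{i}", "c", "+", 500_000 + i * 2000,
                              500_000 + i * 2000 + 1000) for i in range(20)]
        genes += [pt.GeneModel(f"H{i}", "c", "+", 50_000 + i * 2000,
                               50_000 + i * 2000 + 1000) for i in range(20)]
        rng = np.random.default_rng(4)
        dt = pd.DataFrame({
            "feature": [g.gene_id for g in genes],
            "t": rng.normal(size=40),
            "call": ["up" if g.gene_id.startswith("G") else "ns" for g in genes],
        })
        out = core_expression_association(cores, dt, genes)
        assert out["gained"]["fisher"].oddsratio <= 1.0
        assert out["lost"]["fisher"].oddsratio > 1.0


class TestStateEnrichment:
    def test_subset_inside_state_enriched(self):
        states = [Interval("c", 0, 10_000, name="Active-enhancer")]
        subset = _peak_frame([("c", 1000, 2000), ("c", 4000, 5000)])
        background = _peak_frame(
            [("c", 1000, 2000), ("c", 4000, 5000)]
            + [("c", 20_000 + i * 5000, 21_000 + i * 5000) for i in range(8)]
        )
        out = region_state_enrichment(subset, states, background)
        assert out.iloc[0]["OR"] > 1

    def test_subset_equal_background_is_null(self):
        states = [Interval("c", 0, 5000, name="S")]
        bg = _peak_frame([("c", 1000, 2000), ("c", 8000, 9000)])
        out = region_state_enrichment(bg, states, bg)
        assert out.iloc[0]["OR"] == pytest.approx(1.0)
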