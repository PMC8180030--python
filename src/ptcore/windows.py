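"""Genome tiling, window counting, RPKM normalization, depth filtering,
TSS coverage and genomic-class annotation.

Windows tile each sequence on a regular start grid (0, step, 2*step, ...).
``step == window`` gives the non-overlapping 1-kb tiling used for ATAC
differential accessibility; ``step = 900`` gives the 1-kb sliding mode used
for the adduct signal.  A truncated terminal window is emitted when at
least ``min_tail`` bp would otherwise remain uncovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenomeAssembly, GeneModel, Interval, TagSet, merge_intervals
from .stats import FisherResult, fisher_exact

GENOMIC_CLASSES = [
    "CpG-island",
    "promoter-TSS",
    "5'UTR",
    "3'UTR",
    "exon",
    "TTS",
    "intron",
    "intergenic",
]


def tile_genome(
    assembly: GenomeAssembly,
    window: int = 1000,
    step: int | None = None,
    min_tail: int = 100,
) -> pd.DataFrame:
    """Tile every sequence with fixed-size windows on a regular start grid.

    Returns a DataFrame (chrom, start, end) sorted by (chrom order, start),
    with the tiling parameters recorded in ``.attrs``.
    """
    if step is None:
        step = window
    if step <= 0 or window <= 0:
        raise ValueError("window and step must be positive")
    if step > window:
        raise ValueError("step must not exceed window")
    chroms, starts, ends = [], [], []
    for name in assembly.names:
        length = assembly.sizes[name]
        if length >= window:
            k_full = (length - window) // step + 1
            covered = (k_full - 1) * step + window
            n = k_full + (1 if length - covered >= min_tail else 0)
        else:
            n = 1 if length >= min_tail else 0
        if n == 0:
            continue
        s = np.arange(n, dtype=np.int64) * step
        e = np.minimum(s + window, length)
        chroms.append(np.full(n, name, dtype=object))
        starts.append(s)
        ends.append(e)
    df = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms) if chroms else np.array([], object),
            "start": np.concatenate(starts) if starts else np.array([], np.int64),
            "end": np.concatenate(ends) if ends else np.array([], np.int64),
        }
    )
    df.attrs.update({"window": window, "step": step, "min_tail": min_tail})
    return df


@dataclass
class WindowMatrix:
    """Windows x samples count/RPKM matrix with filter state.

    RPKM = count / (window length in kb * library size in millions).
    """

    windows: pd.DataFrame
    samples: list[str]
    counts: np.ndarray
    lib_sizes: np.ndarray
    rpkm: np.ndarray
    pass_filter: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def mean_rpkm(self) -> np.ndarray:
        return self.rpkm.mean(axis=1)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def subset_samples(self, sample_ids: list[str]) -> "WindowMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return WindowMatrix(
            self.windows,
            sample_ids,
            self.counts[:, idx],
            self.lib_sizes[idx],
            self.rpkm[:, idx],
            self.pass_filter,
            dict(self.metadata),
        )


def _window_grid_counts(
    pos: np.ndarray, n_windows: int, window: int, step: int, ends: np.ndarray
) -> np.ndarray:
    """Count 5' positions into grid windows (a tag may hit several when
    windows overlap)."""
    counts = np.zeros(n_windows, dtype=np.int64)
    n_cand = -(-window // step)  # ceil: how many windows can contain a point
    for j in range(n_cand):
        k = pos // step - j
        ok = (k >= 0) & (k < n_windows)
        kk = k[ok]
        inside = (pos[ok] >= kk * step) & (pos[ok] < ends[kk])
        np.add.at(counts, kk[inside], 1)
    return counts


def count_and_normalize(
    tagsets: list[TagSet],
    windows: pd.DataFrame,
    lib_sizes: np.ndarray | None = None,
) -> WindowMatrix:
    """Count tag 5' positions into windows and compute RPKM.

    ``windows`` must come from :func:`tile_genome` (regular grid; the
    tiling parameters are read from ``windows.attrs``).
    """
    window = windows.attrs.get("window")
    step = windows.attrs.get("step")
    if window is None or step is None:
        raise ValueError("windows must carry tiling attrs (use tile_genome)")
    chrom_arr = windows["chrom"].to_numpy()
    start_arr = windows["start"].to_numpy()
    end_arr = windows["end"].to_numpy()
    # contiguous block per chromosome
    block: dict[str, tuple[int, int]] = {}
    boundaries = np.flatnonzero(chrom_arr[1:] != chrom_arr[:-1]) + 1
    starts_idx = np.concatenate([[0], boundaries])
    ends_idx = np.concatenate([boundaries, [len(chrom_arr)]])
    for i0, i1 in zip(starts_idx, ends_idx):
        block[chrom_arr[i0]] = (int(i0), int(i1))

    counts = np.zeros((len(windows), len(tagsets)), dtype=np.int64)
    libs = np.empty(len(tagsets), dtype=float)
    for si, ts in enumerate(tagsets):
        libs[si] = ts.library_size if lib_sizes is None else lib_sizes[si]
        if libs[si] <= 0:
            raise ValueError(f"library size of {ts.sample_id!r} is zero")
        for chrom, (pos, _) in ts.data.items():
            if chrom not in block or len(pos) == 0:
                continue
            i0, i1 = block[chrom]
            counts[i0:i1, si] = _window_grid_counts(
                pos, i1 - i0, window, step, end_arr[i0:i1]
            )
    len_kb = (end_arr - start_arr) / 1000.0
    rpkm = counts / (len_kb[:, None] * (libs[None, :] / 1e6))
    return WindowMatrix(
        windows=windows,
        samples=[t.sample_id for t in tagsets],
        counts=counts,
        lib_sizes=libs,
        rpkm=rpkm,
        metadata={"window": window, "step": step},
    )


def filter_windows(matrix: WindowMatrix, min_rpkm: float = 1.0) -> WindowMatrix:
    """Depth filter: keep windows with mean RPKM above ``min_rpkm`` and
    below 1 SD above the median (median and SD over windows with mean
    RPKM > 0).  The statistics are recorded in ``metadata`` for audit.
    """
    mean = matrix.mean_rpkm
    nonzero = mean[mean > 0]
    if nonzero.size == 0:
        raise ValueError("no window has any coverage; nothing to filter")
    med = float(np.median(nonzero))
    sd = float(np.std(nonzero, ddof=1)) if nonzero.size > 1 else 0.0
    upper = med + sd
    mask = (mean > min_rpkm) & (mean < upper)
    if not mask.any():
        raise ValueError(
            f"no window passes the depth filter "
            f"(min_rpkm={min_rpkm}, median={med:.3g}, sd={sd:.3g})"
        )
    meta = dict(matrix.metadata)
    meta.update(
        {
            "filter_min_rpkm": min_rpkm,
            "filter_median": med,
            "filter_sd": sd,
            "filter_upper": upper,
            "n_pass": int(mask.sum()),
        }
    )
    return WindowMatrix(
        matrix.windows,
        matrix.samples,
        matrix.counts,
        matrix.lib_sizes,
        matrix.rpkm,
        pass_filter=mask,
        metadata=meta,
    )


def tss_profile(
    tagsets: list[TagSet],
    genes: list[GeneModel],
    assembly: GenomeAssembly,
    span: int = 2000,
) -> pd.DataFrame:
    """RPKM over the ``span`` bp centered on each gene's TSS, per sample.

    The window is strand-agnostic ([TSS - span/2, TSS + span/2)); windows
    truncated at a sequence edge are flagged in the ``truncated`` column.
    """
    half = span // 2
    rows = []
    for g in genes:
        lo = max(0, g.tss - half)
        hi = min(assembly.sizes[g.chrom], g.tss + half)
        rows.append((g.gene_id, g.chrom, lo, hi, hi - lo < span))
    meta = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "truncated"])
    vals = np.zeros((len(genes), len(tagsets)))
    for si, ts in enumerate(tagsets):
        lib_m = ts.library_size / 1e6
        for gi, (_, chrom, lo, hi, _t) in enumerate(meta.itertuples(index=False)):
            if chrom not in ts.data:
                continue
            pos, _ = ts.data[chrom]
            n = np.searchsorted(pos, hi) - np.searchsorted(pos, lo)
            vals[gi, si] = n / ((hi - lo) / 1000.0 * lib_m)
    out = pd.concat(
        [meta, pd.DataFrame(vals, columns=[t.sample_id for t in tagsets])], axis=1
    )
    return out


def _strand_aware_regions(genes, which: str) -> list[Interval]:
    """promoter-TSS: 1 kb upstream to 100 bp downstream of the TSS;
    TTS region: 100 bp upstream to 1 kb downstream of the TTS.  Both are
    strand-aware and include the anchor base."""
    out = []
    for g in genes:
        if which == "promoter":
            anchor, up, down = g.tss, 1000, 100
        else:
            anchor, up, down = g.tts, 100, 1000
        if g.strand == "+":
            lo, hi = anchor - up, anchor + down
        else:
            lo, hi = anchor - down + 1, anchor + up + 1
        if hi > 0:
            out.append(Interval(g.chrom, max(0, lo), hi))
    return out


def annotate_windows(
    windows: pd.DataFrame,
    genes: list[GeneModel],
    cpg_islands: list[Interval],
    precedence: list[str] | None = None,
) -> np.ndarray:
    """Assign each window exactly one genomic class by its midpoint.

    Precedence (first match wins): CpG-island > promoter-TSS > 5'UTR >
    3'UTR > exon > TTS > intron > intergenic.
    """
    if precedence is None:
        precedence = GENOMIC_CLASSES[:-1]
    region_sets: dict[str, list[Interval]] = {
        "CpG-island": list(cpg_islands),
        "promoter-TSS": _strand_aware_regions(genes, "promoter"),
        "TTS": _strand_aware_regions(genes, "tts"),
        "5'UTR": [Interval(g.chrom, s, e) for g in genes for s, e in g.utr5],
        "3'UTR": [Interval(g.chrom, s, e) for g in genes for s, e in g.utr3],
        "exon": [Interval(g.chrom, s, e) for g in genes for s, e in g.exons],
        "intron": [Interval(g.chrom, g.start, g.end) for g in genes],
    }
    merged = {
        cls: merge_intervals(ivs) for cls, ivs in region_sets.items() if ivs
    }
    chrom_arr = windows["chrom"].to_numpy()
    mid = ((windows["start"].to_numpy() + windows["end"].to_numpy()) // 2).astype(np.int64)
    labels = np.full(len(windows), "intergenic", dtype=object)
    unassigned = np.ones(len(windows), dtype=bool)
    for cls in precedence:
        if cls not in merged:
            continue
        for chrom, (starts, ends) in merged[cls].items():
            sel = unassigned & (chrom_arr == chrom)
            if not sel.any():
                continue
            idx = np.flatnonzero(sel)
            j = np.searchsorted(starts, mid[idx], side="right") - 1
            inside = j >= 0
            inside[inside] = mid[idx[inside]] < ends[j[inside]]
            hit = idx[inside]
            labels[hit] = cls
            unassigned[hit] = False
    return labels


def class_enrichment(
    diff_mask: np.ndarray,
    classes: np.ndarray,
    class_order: list[str] | None = None,
) -> pd.DataFrame:
    """Per-class enrichment of a differential window set against all windows.

    For each class the 2x2 table is (in-class & diff, in-class & not-diff,
    not-class & diff, not-class & not-diff); OR, two-sided p and 95% CI by
    Fisher's exact test.
    """
    diff_mask = np.asarray(diff_mask, dtype=bool)
    classes = np.asarray(classes)
    if diff_mask.shape != classes.shape:
        raise ValueError("diff_mask and classes must align")
    if not diff_mask.any():
        raise ValueError("empty differential window set")
    if class_order is None:
        class_order = [c for c in GENOMIC_CLASSES if c in set(classes)]
    rows = []
    for cls in class_order:
        in_cls = classes == cls
        a = int(np.sum(in_cls & diff_mask))
        b = int(np.sum(in_cls & ~diff_mask))
        c = int(np.sum(~in_cls & diff_mask))
        d = int(np.sum(~in_cls & ~diff_mask))
        try:
            res = fisher_exact((a, b, c, d))
        except ValueError:
            res = FisherResult(np.nan, np.nan, np.nan, np.nan, (a, b, c, d))
        rows.append((cls, a, b, c, d, res.oddsratio, res.ci_low, res.ci_high, res.p))
    return pd.DataFrame(
        rows,
        columns=["class", "a", "b", "c", "d", "OR", "ci_low", "ci_high", "p"],
    )


def group_mean_ttest(profile: pd.DataFrame, group_a: list[str], group_b: list[str]):
    """Student t-test comparing per-gene mean coverage between two sample
    groups (the TSS metaprofile comparison)."""
    a = profile[group_a].to_numpy().mean(axis=1)
    b = profile[group_b].to_numpy().mean(axis=1)
    t, p = sps.ttest_rel(a, b)
    return float(np.mean(a - b)), float(t), float(p)
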