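"""Peak calling and clusters of cis-regulatory elements (COREs).

Peaks are called with a local-Poisson model: tags extended to fixed-width
fragments, per-bp coverage tested against the most conservative of the
genome-wide rate and rates in 5-kb / 10-kb centered windows.

COREs are dense runs of peaks.  The caller is cluster-of-peaks by
gap thresholding: all inter-peak gaps on a chromosome are pooled
genome-wide and a threshold separating "within-cluster" from
"between-element" gaps is chosen adaptively (largest multiplicative jump
in the sorted gap distribution, falling back to a plain quantile when the
distribution shows no clear split); maximal runs of at least ``min_order``
consecutive peaks whose internal gaps all stay at or below the threshold
become COREs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenomeAssembly, GeneModel, Interval, TagSet, merge_intervals, points_in_merged
from .stats import FisherResult, bh_fdr, fisher_exact


def _merged_coverage(tagsets: list[TagSet], chrom: str, length: int, ext: int) -> np.ndarray:
    """Per-bp fragment coverage of the pooled tag sets (tags extended to
    ``ext`` bp in the strand direction)."""
    diff = np.zeros(length + 1, dtype=np.int64)
    for ts in tagsets:
        if chrom not in ts.data:
            continue
        pos, strand = ts.data[chrom]
        starts = np.where(strand == 0, pos, pos - ext + 1)
        starts = np.clip(starts, 0, length)
        ends = np.clip(starts + ext, 0, length)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
    return np.cumsum(diff[:-1])


def _rolling_mean(cov: np.ndarray, width: int) -> np.ndarray:
    """Centered rolling mean (edges use the available span)."""
    cs = np.concatenate([[0], np.cumsum(cov, dtype=np.float64)])
    n = len(cov)
    idx = np.arange(n)
    lo = np.clip(idx - width // 2, 0, n)
    hi = np.clip(idx + width // 2, 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def call_peaks(
    tagsets: list[TagSet] | TagSet,
    assembly: GenomeAssembly,
    ext: int = 200,
    p_cut: float = 1e-5,
    min_gap: int = 100,
    min_len: int = 50,
) -> pd.DataFrame:
    """Local-Poisson peak calling on pooled (merged-replicate) tags.

    Per-bp coverage is tested against Poisson(lambda_local) with
    ``lambda_local = max(lambda_genome, lambda_5k, lambda_10k)``;
    contiguous significant runs of >= ``min_len`` bp are kept and merged
    across gaps <= ``min_gap``.  Summit is the maximum-coverage bp
    (leftmost on ties); score is -log10 of the summit p-value.
    """
    if isinstance(tagsets, TagSet):
        tagsets = [tagsets]
    if sum(ts.library_size for ts in tagsets) == 0:
        raise ValueError("empty tag set")
    rows = []
    for chrom in assembly.names:
        L = assembly.sizes[chrom]
        cov = _merged_coverage(tagsets, chrom, L, ext)
        if cov.max() == 0:
            continue
        lam_genome = cov.mean()
        lam = np.maximum(lam_genome, _rolling_mean(cov, 5000))
        lam = np.maximum(lam, _rolling_mean(cov, 10000))
        # cheap prefilter, then exact Poisson tail on candidates
        cand = cov >= lam + 3.0 * np.sqrt(lam) + 2.0
        sig = np.zeros(L, dtype=bool)
        if cand.any():
            ci = np.flatnonzero(cand)
            sig[ci] = sps.poisson.sf(cov[ci] - 1, lam[ci]) < p_cut
        if not sig.any():
            continue
        # significant runs
        edges = np.flatnonzero(np.diff(np.concatenate([[0], sig.view(np.int8), [0]])))
        starts, ends = edges[::2], edges[1::2]
        keep = (ends - starts) >= min_len
        starts, ends = starts[keep], ends[keep]
        if len(starts) == 0:
            continue
        # merge across small gaps
        merged = [[int(starts[0]), int(ends[0])]]
        for s, e in zip(starts[1:], ends[1:]):
            if s - merged[-1][1] <= min_gap:
                merged[-1][1] = int(e)
            else:
                merged.append([int(s), int(e)])
        for s, e in merged:
            summit = s + int(np.argmax(cov[s:e]))
            p_summit = float(sps.poisson.sf(cov[summit] - 1, lam[summit]))
            score = float(-np.log10(max(p_summit, 1e-300)))
            rows.append((chrom, s, e, summit, score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "summit", "score"])
    df.attrs.update({"ext": ext, "p_cut": p_cut, "min_gap": min_gap})
    return df


def select_gap_threshold(
    gaps: np.ndarray,
    gap_quantile: float = 0.25,
    min_jump_ratio: float = 1.3,
    min_median_ratio: float = 4.0,
) -> float:
    """Within-cluster gap threshold from the pooled gap distribution.

    Clustered regulatory elements produce a bimodal gap distribution:
    short within-cluster gaps and much larger between-element gaps.  The
    split minimizing the total within-class variance of log-gaps (Otsu's
    criterion in one dimension) is located; it is accepted as the
    threshold (the largest gap of the lower class) when the classes are
    clearly separated — class medians differ by >= ``min_median_ratio``
    multiplicatively and there is a >= ``min_jump_ratio`` jump at the
    boundary.  Otherwise the distribution is treated as unimodal and the
    ``gap_quantile`` quantile is used.
    """
    gaps = np.sort(np.maximum(np.asarray(gaps, dtype=float), 1.0))
    n = len(gaps)
    if n < 4:
        return float(np.quantile(gaps, gap_quantile))
    x = np.log(gaps)
    cs, cs2 = np.cumsum(x), np.cumsum(x**2)
    tot, tot2 = cs[-1], cs2[-1]
    k = np.arange(1, n)  # lower class = x[:k]
    var_lo = cs2[k - 1] - cs[k - 1] ** 2 / k
    var_hi = (tot2 - cs2[k - 1]) - (tot - cs[k - 1]) ** 2 / (n - k)
    best = int(np.argmin(var_lo + var_hi))
    split = best + 1  # lower class size
    if 0 < split < n:
        med_lo = float(np.median(gaps[:split]))
        med_hi = float(np.median(gaps[split:]))
        jump = gaps[split] / gaps[split - 1]
        if med_hi / max(med_lo, 1.0) >= min_median_ratio and jump >= min_jump_ratio:
            return float(gaps[split - 1])
    return float(np.quantile(gaps, gap_quantile))


def pooled_gap_threshold(
    peak_tables: list[pd.DataFrame], gap_quantile: float = 0.25
) -> float:
    """Gap threshold from gaps pooled over several peak sets (e.g. the two
    lines of a pair), so that CORE calls are comparable across sets."""
    gaps = []
    for peaks in peak_tables:
        p = peaks.sort_values(["chrom", "start"])
        for _, grp in p.groupby("chrom", sort=False):
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            gaps.append(np.maximum(s[1:] - e[:-1], 0))
    pooled = np.concatenate(gaps) if gaps else np.array([])
    if len(pooled) == 0:
        return 0.0
    return select_gap_threshold(pooled, gap_quantile)


def call_cores(
    peaks: pd.DataFrame,
    min_order: int = 3,
    gap_quantile: float = 0.25,
    gap_threshold: float | None = None,
) -> pd.DataFrame:
    """Call COREs as maximal runs of >= ``min_order`` consecutive peaks
    whose internal gaps (edge-to-edge) are all <= the gap threshold
    (inclusive at the threshold).

    Returns a DataFrame (chrom, start, end, order, peak_indices) where
    ``peak_indices`` index into the input peak table; the threshold used
    is stored in ``.attrs['gap_threshold']``.
    """
    cols = ["chrom", "start", "end", "order", "peak_indices"]
    if len(peaks) < min_order:
        import warnings

        warnings.warn("fewer peaks than min_order; empty CORE set")
        out = pd.DataFrame(columns=cols)
        out.attrs["gap_threshold"] = np.nan
        return out
    peaks = peaks.sort_values(["chrom", "start"]).reset_index(drop=True)
    all_gaps = []
    per_chrom = {}
    for chrom, grp in peaks.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        gaps = np.maximum(starts[1:] - ends[:-1], 0)
        per_chrom[chrom] = (grp.index.to_numpy(), starts, ends, gaps)
        all_gaps.append(gaps)
    all_gaps = np.concatenate(all_gaps) if all_gaps else np.array([])
    if gap_threshold is None:
        if len(all_gaps) == 0:
            gap_threshold = 0.0
        else:
            gap_threshold = select_gap_threshold(all_gaps, gap_quantile)
    rows = []
    for chrom, (idx, starts, ends, gaps) in per_chrom.items():
        linked = gaps <= gap_threshold
        # runs of consecutive linked peaks
        run_start = 0
        for i in range(len(starts)):
            last = i == len(starts) - 1
            if last or not linked[i]:
                run_len = i - run_start + 1
                if run_len >= min_order:
                    members = idx[run_start:i + 1]
                    rows.append(
                        (chrom, int(starts[run_start]), int(ends[i]),
                         int(run_len), list(map(int, members)))
                    )
                run_start = i + 1
    out = pd.DataFrame(rows, columns=cols)
    out.attrs["gap_threshold"] = float(gap_threshold)
    out.attrs["min_order"] = min_order
    return out


def _overlaps_any(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """For each interval in ``a``: does it overlap (>=1 bp) any in ``b``."""
    out = np.zeros(len(a), dtype=bool)
    if len(b) == 0 or len(a) == 0:
        return out
    merged = merge_intervals(
        [Interval(c, s, e) for c, s, e in b[["chrom", "start", "end"]].itertuples(index=False)]
    )
    chrom_arr = a["chrom"].to_numpy()
    start_arr = a["start"].to_numpy()
    end_arr = a["end"].to_numpy()
    for chrom, (ms, me) in merged.items():
        sel = chrom_arr == chrom
        if not sel.any():
            continue
        i = np.searchsorted(ms, end_arr[sel], side="left") - 1
        ok = i >= 0
        ok[ok] = me[i[ok]] > start_arr[sel][ok]
        out[np.flatnonzero(sel)] = ok
    return out


def classify_core_changes(
    cores_a: pd.DataFrame, cores_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-line CORE classification by >=1 bp interval overlap.

    Returns labeled copies ``(cores_a, cores_b)``: B-COREs overlapping any
    A-CORE are ``shared`` else ``gained``; A-COREs with no B overlap are
    ``lost`` (else ``shared``).
    """
    a = cores_a.copy()
    b = cores_b.copy()
    a_hits = _overlaps_any(a, b)
    b_hits = _overlaps_any(b, a)
    a["label"] = np.where(a_hits, "shared", "lost")
    b["label"] = np.where(b_hits, "shared", "gained")
    return a, b


def link_genes_to_cores(
    cores: pd.DataFrame, genes: list[GeneModel], span: int = 100_000
) -> pd.DataFrame:
    """Link genes whose TSS lies within ``span`` bp of a CORE:
    TSS in [CORE start - span, CORE end + span), left-inclusive."""
    rows = []
    for ci, core in enumerate(cores.itertuples(index=False)):
        for g in genes:
            if g.chrom == core.chrom and core.start - span <= g.tss < core.end + span:
                rows.append((ci, g.gene_id))
    return pd.DataFrame(rows, columns=["core_index", "gene_id"])


def core_expression_association(
    cores_labeled: pd.DataFrame,
    diff_table: pd.DataFrame,
    genes: list[GeneModel],
    span: int = 100_000,
    gene_set: list[str] | None = None,
    de_only: bool = True,
) -> dict:
    """Association between CORE gains/losses and linked gene expression.

    For each changed-CORE class (gained / lost): the distribution of
    expression t-statistics of linked genes (DE-flagged genes by default,
    all linked genes also reported), a one-sample t-test of its mean
    against 0 and a two-sample KS test against the background t
    distribution; plus Fisher 2x2 enrichment of DE genes among genes near
    changed COREs.  ``gene_set`` restricts the same 2x2 machinery to a
    user-supplied panel among genes near gained COREs.
    """
    dt = diff_table.set_index("feature")
    universe = [g.gene_id for g in genes if g.gene_id in dt.index]
    t_all = dt.loc[universe, "t"].to_numpy(dtype=float)
    de_mask = dt.loc[universe, "call"].to_numpy() != "ns"
    out: dict = {"warnings": []}
    near: dict[str, set] = {}
    for label in ("gained", "lost"):
        sub = cores_labeled[cores_labeled["label"] == label]
        linked = link_genes_to_cores(sub, genes, span)
        near[label] = set(linked["gene_id"])
    uni_index = {g: i for i, g in enumerate(universe)}
    for label in ("gained", "lost"):
        ids = [g for g in near[label] if g in uni_index]
        if not ids:
            out["warnings"].append(f"no genes linked to {label} COREs; skipped")
            continue
        idx = np.array([uni_index[g] for g in ids])
        t_linked_all = t_all[idx]
        de_idx = idx[de_mask[idx]]
        t_linked = t_all[de_idx] if de_only else t_linked_all
        res: dict = {
            "n_linked": len(idx),
            "n_linked_de": int(de_mask[idx].sum()),
            "t_linked": t_linked,
            "t_linked_all": t_linked_all,
        }
        if len(t_linked) >= 2:
            t1, p1 = sps.ttest_1samp(t_linked, 0.0)
            ks = sps.ks_2samp(t_linked, t_all)
            res.update(
                mean_t=float(np.mean(t_linked)),
                one_sample_t=float(t1),
                one_sample_p=float(p1),
                ks_p=float(ks.pvalue),
            )
        else:
            out["warnings"].append(f"<2 DE genes linked to {label} COREs")
        in_near = np.zeros(len(universe), dtype=bool)
        in_near[idx] = True
        a = int(np.sum(de_mask & in_near))
        b = int(np.sum(~de_mask & in_near))
        c = int(np.sum(de_mask & ~in_near))
        d = int(np.sum(~de_mask & ~in_near))
        try:
            res["fisher"] = fisher_exact((a, b, c, d))
        except ValueError:
            res["fisher"] = FisherResult(np.nan, np.nan, np.nan, np.nan, (a, b, c, d))
        out[label] = res
    if gene_set is not None and near.get("gained"):
        ids = [g for g in near["gained"] if g in uni_index]
        in_set = np.array([g in set(gene_set) for g in universe])
        in_near = np.zeros(len(universe), dtype=bool)
        in_near[[uni_index[g] for g in ids]] = True
        a = int(np.sum(in_set & in_near))
        b = int(np.sum(~in_set & in_near))
        c = int(np.sum(in_set & ~in_near))
        d = int(np.sum(~in_set & ~in_near))
        try:
            out["gene_set"] = fisher_exact((a, b, c, d))
        except ValueError:
            out["gene_set"] = FisherResult(np.nan, np.nan, np.nan, np.nan, (a, b, c, d))
    return out


def region_state_enrichment(
    subset: pd.DataFrame,
    states: list[Interval],
    background: pd.DataFrame,
) -> pd.DataFrame:
    """Per-chromatin-state Fisher enrichment of a CORE subset against a
    background CORE set, by CORE-midpoint membership in the labeled state
    intervals (state names pass through as labels)."""
    by_state: dict[str, list[Interval]] = {}
    for iv in states:
        by_state.setdefault(iv.name or ".", []).append(iv)

    def member_mask(cores, ivs):
        merged = merge_intervals(ivs)
        mids = ((cores["start"].to_numpy() + cores["end"].to_numpy()) // 2)
        chroms = cores["chrom"].to_numpy()
        mask = np.zeros(len(cores), dtype=bool)
        for chrom, (ms, me) in merged.items():
            sel = chroms == chrom
            if sel.any():
                mask[np.flatnonzero(sel)] = points_in_merged(mids[sel], ms, me)
        return mask

    rows = []
    for state, ivs in by_state.items():
        in_sub = member_mask(subset, ivs)
        in_bg = member_mask(background, ivs)
        a, b = int(in_sub.sum()), int(len(subset) - in_sub.sum())
        c, d = int(in_bg.sum()), int(len(background) - in_bg.sum())
        try:
            res = fisher_exact((a, b, c, d))
            rows.append((state, a, b, c, d, res.oddsratio, res.ci_low, res.ci_high, res.p))
        except ValueError:
            rows.append((state, a, b, c, d, np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["state", "a", "b", "c", "d", "OR", "ci_low", "ci_high", "p"]
    )
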