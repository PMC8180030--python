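"""Pt-exo-seq computational read-out.

The assay maps cisplatin-DNA adducts by 5'->3' exonuclease digestion that
stalls at the bulky adduct: the 5' end of a sequenced read marks the
adduct position.  This module provides the adduct-anchored 5'-end
dinucleotide analysis, the windowed log2 signal:background ratio against
mock-treated samples, differential damage between lines, and
damage-by-genomic-context summaries.

Pt-exo tags are intentionally not collapsed to unique positions: the
5' stop coordinate is the signal, and many genuine adducts at the same
site produce identical tags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import COMPLEMENT, GenomeAssembly, TagSet, merge_intervals, points_in_merged
from .stats import FisherResult, bh_fdr, fisher_exact, wilcoxon_rank_sum
from .windows import WindowMatrix, count_and_normalize, class_enrichment

TARGET_DINUCS = ("GG", "AG")  # 1,2-intrastrand crosslink targets, read strand


def extract_5prime_context(
    tags: TagSet,
    assembly: GenomeAssembly,
    offset_min: int = -5,
    offset_max: int = 10,
    targets: tuple[str, ...] = TARGET_DINUCS,
) -> pd.DataFrame:
    """Count platinum-target dinucleotides around read 5' ends.

    For each tag and offset ``k``, the dinucleotide starting ``k`` bases
    3'-ward of the 5' base is read in read-strand orientation (offset 0 is
    the 5' base and its successor); minus-strand tags use the reverse
    complement.  Dinucleotides containing N or extending past the sequence
    end are excluded and counted.

    Returns a DataFrame indexed by offset with columns ``target``,
    ``other`` and ``excluded``.
    """
    if not assembly.has_sequence:
        raise ValueError("assembly must carry sequence text")
    offsets = np.arange(offset_min, offset_max + 1)
    target_codes = set()
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    for d in targets:
        target_codes.add((code[d[0]], code[d[1]]))
    tgt = np.zeros((5, 5), dtype=bool)
    for i, j in target_codes:
        tgt[i, j] = True

    n_target = np.zeros(len(offsets), dtype=np.int64)
    n_other = np.zeros(len(offsets), dtype=np.int64)
    n_excluded = np.zeros(len(offsets), dtype=np.int64)
    for chrom, (pos, strand) in tags.data.items():
        seq = assembly.seq[chrom]
        L = len(seq)
        plus = strand == 0
        for oi, k in enumerate(offsets):
            # read-strand position of the first base of the offset-k dinuc
            p1 = np.where(plus, pos + k, pos - k)
            p2 = np.where(plus, p1 + 1, p1 - 1)
            ok = (p1 >= 0) & (p1 < L) & (p2 >= 0) & (p2 < L)
            b1 = seq[np.clip(p1, 0, L - 1)]
            b2 = seq[np.clip(p2, 0, L - 1)]
            b1 = np.where(plus, b1, COMPLEMENT[b1])
            b2 = np.where(plus, b2, COMPLEMENT[b2])
            valid = ok & (b1 != 4) & (b2 != 4)
            hits = tgt[b1[valid], b2[valid]]
            n_target[oi] += int(hits.sum())
            n_other[oi] += int((~hits).sum())
            n_excluded[oi] += int((~valid).sum())
    return pd.DataFrame(
        {"target": n_target, "other": n_other, "excluded": n_excluded},
        index=pd.Index(offsets, name="offset"),
    )


def genomic_target_fraction(
    assembly: GenomeAssembly, targets: tuple[str, ...] = TARGET_DINUCS
) -> float:
    """Exhaustive genomic frequency of the target dinucleotides over both
    strands (the expected 5'-end target fraction of unenriched reads)."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    pairs = [(code[d[0]], code[d[1]]) for d in targets]
    hits = tot = 0
    for chrom in assembly.names:
        s = assembly.seq[chrom]
        a, b = s[:-1], s[1:]
        valid = (a != 4) & (b != 4)
        tot += 2 * int(valid.sum())
        for i, j in pairs:
            hits += int(np.sum(valid & (a == i) & (b == j)))          # plus strand
            hits += int(np.sum(valid & (b == (3 - i)) & (a == (3 - j))))  # minus strand
    return hits / tot


def dinuc_enrichment(treated: pd.DataFrame, untreated: pd.DataFrame) -> pd.DataFrame:
    """Per-offset Fisher's exact test of target-dinucleotide counts,
    treated versus untreated."""
    if not treated.index.equals(untreated.index):
        raise ValueError("offset ranges differ between tables")
    rows = []
    for k in treated.index:
        a, b = int(treated.loc[k, "target"]), int(treated.loc[k, "other"])
        c, d = int(untreated.loc[k, "target"]), int(untreated.loc[k, "other"])
        if a + b == 0 or c + d == 0:
            raise ValueError(f"zero evaluable reads at offset {k}")
        res = fisher_exact((a, b, c, d))
        rows.append((k, res.oddsratio, res.ci_low, res.ci_high, res.p))
    return pd.DataFrame(
        rows, columns=["offset", "OR", "ci_low", "ci_high", "p"]
    ).set_index("offset")


@dataclass
class DamageSignal:
    """Windowed log2 signal:background ratios and differential-damage calls."""

    windows: pd.DataFrame
    signal: np.ndarray              # windows x treated samples, log2 ratio
    samples: list[str]
    table: pd.DataFrame | None = None   # per-window differential results


def damage_signal(
    treated: list[TagSet],
    mock: list[TagSet],
    windows: pd.DataFrame,
    pseudocount: float = 0.5,
    pass_filter: np.ndarray | None = None,
) -> DamageSignal:
    """Per-window log2 ratio of each treated sample's RPKM over the mean
    mock RPKM (both depth-normalized), with pseudocount ``c``:
    ``log2((RPKM_t + c) / (mean RPKM_mock + c))``.

    ``pass_filter`` restricts the windows to those passing the ATAC depth
    filter (boolean mask over ``windows``).
    """
    if len(treated) < 1 or len(mock) < 2:
        raise ValueError("need >= 1 treated and >= 2 mock samples")
    wm = count_and_normalize(list(treated) + list(mock), windows)
    n_t = len(treated)
    rpkm_t = wm.rpkm[:, :n_t]
    mock_mean = wm.rpkm[:, n_t:].mean(axis=1)
    sig = np.log2((rpkm_t + pseudocount) / (mock_mean[:, None] + pseudocount))
    if pass_filter is not None:
        pass_filter = np.asarray(pass_filter, dtype=bool)
        if len(pass_filter) != len(windows):
            raise ValueError("pass_filter does not align with windows")
        windows = windows[pass_filter].reset_index(drop=True)
        sig = sig[pass_filter]
    return DamageSignal(
        windows=windows, signal=sig, samples=[t.sample_id for t in treated]
    )


def intersect_pass_regions(
    windows: pd.DataFrame, pass_windows: pd.DataFrame
) -> np.ndarray:
    """Mask of ``windows`` overlapping (>= 1 bp) any window in
    ``pass_windows`` (used to carry the ATAC filter onto the sliding
    Pt-exo windows)."""
    from .io import Interval

    merged = merge_intervals(
        [Interval(c, s, e) for c, s, e in
         pass_windows[["chrom", "start", "end"]].itertuples(index=False)]
    )
    mask = np.zeros(len(windows), dtype=bool)
    chrom_arr = windows["chrom"].to_numpy()
    start_arr = windows["start"].to_numpy()
    end_arr = windows["end"].to_numpy()
    for chrom, (ms, me) in merged.items():
        sel = chrom_arr == chrom
        if not sel.any():
            continue
        s, e = start_arr[sel], end_arr[sel]
        # overlap iff some merged interval starts before e and ends after s
        i = np.searchsorted(ms, e, side="left") - 1
        ok = i >= 0
        ok[ok] = me[i[ok]] > s[ok]
        mask[np.flatnonzero(sel)] = ok
    return mask


def differential_damage(
    signal_a: DamageSignal,
    signal_b: DamageSignal,
    delta_cut: float = 2.0,
    fdr_cut: float = 0.05,
    method: str = "moderated",
) -> pd.DataFrame:
    """Per-window t-test of replicate damage signals, line B minus line A;
    calls ``increased``/``decreased`` at |delta| > ``delta_cut`` and BH
    FDR < ``fdr_cut``.

    ``method``: ``moderated`` (default; empirical-Bayes shrinkage of the
    per-window variances, appropriate for 3 vs 3 replicates genome-wide)
    or ``welch`` (plain unequal-variance t).
    """
    if signal_a.signal.shape[1] < 2 or signal_b.signal.shape[1] < 2:
        raise ValueError("need >= 2 replicates per line")
    if not signal_a.windows[["chrom", "start"]].equals(signal_b.windows[["chrom", "start"]]):
        raise ValueError("window sets mismatch")
    a, b = signal_a.signal, signal_b.signal
    if method == "moderated":
        from .stats import moderated_two_group

        mod = moderated_two_group(a, b)
        t = mod["t"].to_numpy()
        p = mod["p"].to_numpy()
    elif method == "welch":
        t, p = sps.ttest_ind(b, a, axis=1, equal_var=False)
        t = np.nan_to_num(t)
        p = np.where(np.isnan(p), 1.0, p)
    else:
        raise ValueError("method must be 'moderated' or 'welch'")
    delta = b.mean(axis=1) - a.mean(axis=1)
    fdr = bh_fdr(p)
    call = np.where(
        (fdr < fdr_cut) & (delta > delta_cut), "increased",
        np.where((fdr < fdr_cut) & (delta < -delta_cut), "decreased", "ns"),
    )
    out = signal_a.windows.copy()
    out["mean_a"] = a.mean(axis=1)
    out["mean_b"] = b.mean(axis=1)
    out["delta"] = delta
    out["t"] = t
    out["p"] = p
    out["FDR"] = fdr
    out["call"] = call
    out.attrs["delta_cut"] = delta_cut
    out.attrs["fdr_cut"] = fdr_cut
    return out


def mean_signal_per_region(
    sig: DamageSignal, regions: pd.DataFrame
) -> np.ndarray:
    """Mean (over windows and treated samples) damage signal of the windows
    overlapping each region."""
    per_window = sig.signal.mean(axis=1)
    chrom_arr = sig.windows["chrom"].to_numpy()
    start_arr = sig.windows["start"].to_numpy()
    end_arr = sig.windows["end"].to_numpy()
    out = np.full(len(regions), np.nan)
    for i, r in enumerate(regions.itertuples(index=False)):
        sel = (chrom_arr == r.chrom) & (start_arr < r.end) & (end_arr > r.start)
        if sel.any():
            out[i] = float(per_window[sel].mean())
    return out


def damage_context_summary(
    calls: pd.DataFrame,
    classes: np.ndarray,
    delta_atac: np.ndarray,
    core_sets: dict[str, pd.DataFrame] | None = None,
    damage: DamageSignal | None = None,
) -> dict:
    """Context summaries of the differential-damage calls.

    * per-genomic-class Fisher enrichment of the increased / decreased
      call sets against all windows;
    * Wilcoxon rank-sum comparison of the ATAC accessibility change
      (``delta_atac``, resistant minus sensitive, log2 scale) between the
      increased and decreased call groups;
    * per-CORE-set (shared / gained / lost) mean damage-signal
      distributions with pairwise Wilcoxon tests.
    """
    call = calls["call"].to_numpy()
    out: dict = {"warnings": []}
    for label in ("increased", "decreased"):
        mask = call == label
        if mask.any():
            out[f"class_enrichment_{label}"] = class_enrichment(mask, classes)
        else:
            out["warnings"].append(f"empty {label} call set; class enrichment skipped")
    inc = delta_atac[call == "increased"]
    dec = delta_atac[call == "decreased"]
    if len(inc) and len(dec):
        u, p = wilcoxon_rank_sum(inc, dec)
        out["accessibility_by_call"] = {
            "mean_delta_increased": float(np.mean(inc)),
            "mean_delta_decreased": float(np.mean(dec)),
            "U": u,
            "p": p,
        }
    else:
        out["warnings"].append("a call group is empty; accessibility contrast skipped")
    if core_sets and damage is not None:
        dists = {
            name: mean_signal_per_region(damage, regions)
            for name, regions in core_sets.items()
        }
        out["core_damage"] = {
            name: {"mean": (float(np.nanmean(v)) if np.any(~np.isnan(v)) else np.nan),
                   "n": int(np.sum(~np.isnan(v)))}
            for name, v in dists.items()
        }
        pairs = {}
        names = list(dists)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                x = dists[names[i]][~np.isnan(dists[names[i]])]
                y = dists[names[j]][~np.isnan(dists[names[j]])]
                if len(x) and len(y):
                    _, p = wilcoxon_rank_sum(x, y)
                    pairs[f"{names[i]}_vs_{names[j]}"] = p
        out["core_damage_pairwise_p"] = pairs
    return out
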