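"""Synthetic genome, annotation and sequencing-tag generator with planted
ground truth.

The simulator emulates the data structure the analysis assumes for a
matched platinum-sensitive / platinum-resistant cell line pair:

* an i.i.d. nucleotide genome (default GC 0.41) with genes, CpG-rich
  islands at a subset of promoters, and blacklist regions of anomalously
  high coverage;
* per-line chromatin accessibility defined on a 1-kb bin grid: a low
  baseline, open promoters, isolated accessibility peaks, clustered peak
  templates (CORE templates, a fraction gained or lost in the resistant
  line) and planted differential windows;
* ATAC tags drawn with negative-binomial replicate noise proportional to
  accessibility;
* Pt-exo tags whose 5' ends sit on sampled GG/AG adduct positions, with
  per-site adduct probability proportional to dose x accessibility^alpha,
  plus a uniform background shared with mock (dose 0) samples;
* RNA counts with differential genes coupled to CORE gains/losses within
  100 kb.

Planted effects are split symmetrically across the two lines
(x2^(effect/2) in one line, x2^(-effect/2) in the other) so that the
planted log2 fold change equals ``effect`` while planted windows keep a
mean depth compatible with the upper depth filter.

One global seed; per-sample random streams are derived deterministically
from (seed, sample label) so adding samples never perturbs existing ones.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import (
    GeneModel,
    GenomeAssembly,
    Interval,
    TagSet,
    write_gtf,
    write_intervals,
)

LINES = ("sensitive", "resistant")
BIN = 1000   # analysis bin size (bp): NB replicate noise operates per bin
FINE = 100   # accessibility resolution (bp): peaks keep sub-kb structure


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic dataset."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    gc: float = 0.41
    n_genes: int = 400
    n_peaks: int = 600                 # accessibility peaks per line
    n_core_templates: int = 40         # clustered-peak templates
    core_order_min: int = 3
    core_order_max: int = 10
    core_gain_fraction: float = 0.25   # templates present only in resistant
    core_loss_fraction: float = 0.25   # templates present only in sensitive
    diff_window_fraction: float = 0.02
    diff_effect: float = 3.0           # planted accessibility log2FC
    atac_dispersion: float = 10.0      # NB size parameter
    atac_depth: int = 1_000_000        # expected tags per ATAC sample
    adduct_rate: float = 0.015         # per uM dose, per GG/AG site, at reference accessibility
    alpha: float = 1.0                 # accessibility-damage coupling exponent
    tags_per_adduct: float = 2.5       # Poisson mean tags emitted per adduct
    background_rate: float = 0.01      # uniform background tags per bp in treated samples
    mock_depth: int = 1_000_000        # expected tags per mock (dose-0) library; mock
                                       # libraries are pure background sequenced to the
                                       # same per-sample depth as treated libraries
    adduct_offset: int = 0             # read 5' end offset from adduct 5' base
    damage_window_fraction: float = 0.02
    damage_effect: float = 3.0         # planted damage log2FC
    rna_mean: float = 100.0
    rna_dispersion: float = 10.0
    de_effect: float = 3.0             # expression log2FC for CORE-linked genes
    de_promoter_boost: float = 1.0     # promoter accessibility fold change of DE genes
                                       # in the line where they are up (1 = uncoupled)
    baseline_accessibility: float = 0.2
    peak_boost: float = 8.0
    promoter_boost: float = 8.0
    blacklist_per_chrom: int = 2
    cpg_island_fraction: float = 0.3   # fraction of promoters with an island

    def __post_init__(self) -> None:
        for name in ("core_gain_fraction", "core_loss_fraction",
                     "diff_window_fraction", "damage_window_fraction",
                     "cpg_island_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("adduct_rate", "atac_dispersion", "rna_dispersion",
                     "background_rate", "chrom_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.chrom_length % BIN:
            raise ValueError(f"chrom_length must be a multiple of {BIN}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Planted ground truth emitted by the simulator for recovery scoring."""

    diff_windows: pd.DataFrame      # chrom, start, end, direction (up = more accessible in resistant)
    damage_windows: pd.DataFrame    # chrom, start, end, direction (up = more damage in resistant)
    core_templates: pd.DataFrame    # core_id, chrom, start, end, order, label
    de_genes: pd.DataFrame          # gene_id, direction, core_id
    open_regions: dict = field(default_factory=dict)   # line -> DataFrame of accessibility-elevated regions
    adducts: dict = field(default_factory=dict)        # sample_id -> DataFrame(chrom, pos, strand, dinuc)


@dataclass
class SimData:
    """A simulated study: genome, annotation, per-line accessibility and truth."""

    config: SimConfig
    assembly: GenomeAssembly
    genes: list[GeneModel]
    cpg_islands: list[Interval]
    blacklist: list[Interval]
    truth: SimTruth
    access: dict            # line -> {chrom: accessibility per FINE bp cell}
    damage_mult: dict       # line -> {chrom: damage multiplier per BIN bp bin}
    gene_factors: np.ndarray
    acc_ref: float
    _target_sites: dict | None = None
    _access_bin: dict | None = None

    def access_bin(self, line: str, chrom: str) -> np.ndarray:
        """Accessibility averaged to the 1-kb analysis bin grid."""
        if self._access_bin is None:
            self._access_bin = {}
        key = (line, chrom)
        if key not in self._access_bin:
            fine = self.access[line][chrom]
            self._access_bin[key] = fine.reshape(-1, BIN // FINE).mean(axis=1)
        return self._access_bin[key]

    def rng(self, label: str) -> np.random.Generator:
        """Deterministic per-sample stream: (seed, crc32(label))."""
        return np.random.default_rng(
            [self.config.seed & 0x7FFFFFFF, zlib.crc32(label.encode()) & 0x7FFFFFFF]
        )

    def total_accessibility(self, line: str) -> float:
        """Sum of 1-kb bin accessibilities (the depth-scaling denominator)."""
        return float(
            sum(self.access_bin(line, chrom).sum() for chrom in self.assembly.names)
        )

    def target_sites(self) -> dict:
        """Per-chrom GG/AG adduct target sites on both strands.

        Returns {chrom: (pos, strand, dinuc)} where ``pos`` is the genomic
        position of the 5' base of the platinum-target dinucleotide on the
        read strand (0 = +, 1 = -), and dinuc is 'GG' or 'AG'.
        """
        if self._target_sites is None:
            sites = {}
            for chrom in self.assembly.names:
                s = self.assembly.seq[chrom]
                # plus strand: G/A at i followed by G at i+1; 5' base at i
                first, second = s[:-1], s[1:]
                plus_gg = np.flatnonzero((first == 2) & (second == 2))
                plus_ag = np.flatnonzero((first == 0) & (second == 2))
                # minus strand: read dinuc starts at j going leftward;
                # GG -> CC on plus at [j-1, j]; AG -> CT on plus at [j-1, j]
                prev, cur = s[:-1], s[1:]
                minus_gg = np.flatnonzero((cur == 1) & (prev == 1)) + 1
                minus_ag = np.flatnonzero((cur == 3) & (prev == 1)) + 1
                pos = np.concatenate([plus_gg, plus_ag, minus_gg, minus_ag])
                strand = np.concatenate([
                    np.zeros(len(plus_gg) + len(plus_ag), np.int8),
                    np.ones(len(minus_gg) + len(minus_ag), np.int8),
                ])
                dinuc = np.concatenate([
                    np.repeat("GG", len(plus_gg)), np.repeat("AG", len(plus_ag)),
                    np.repeat("GG", len(minus_gg)), np.repeat("AG", len(minus_ag)),
                ])
                order = np.argsort(pos, kind="stable")
                sites[chrom] = (pos[order], strand[order], dinuc[order])
            self._target_sites = sites
        return self._target_sites


def _layout_chrom(rng, length, elements, min_gap=4500, margin=5000):
    """Place non-overlapping elements left to right with randomized gaps.

    ``elements``: list of (kind, payload, length).  Returns list of
    (kind, payload, start) in placement order.
    """
    order = rng.permutation(len(elements))
    elements = [elements[i] for i in order]
    total_len = sum(e[2] for e in elements)
    n_gaps = len(elements) + 1
    free = length - total_len - 2 * margin
    if free < n_gaps * min_gap:
        raise ValueError(
            "genome too small to place requested features "
            f"(need {total_len + 2 * margin + n_gaps * min_gap} bp, have {length})"
        )
    raw = rng.uniform(1.0, 2.0, n_gaps)
    extra = (free - n_gaps * min_gap) * raw / raw.sum()
    gaps = min_gap + extra
    placed = []
    cursor = float(margin)
    for (kind, payload, el_len), gap in zip(elements, gaps[:-1]):
        cursor += gap
        placed.append((kind, payload, int(cursor)))
        cursor += el_len
    return placed


def _split(n: int, k: int) -> list[int]:
    base = n // k
    out = [base] * k
    for i in range(n - base * k):
        out[i] += 1
    return out


def simulate_genome_annotation(config: SimConfig) -> SimData:
    """Simulate the genome, gene models, CpG islands, blacklist and the
    per-line accessibility landscape; returns a :class:`SimData` whose
    truth tables cover differential windows, CORE templates and DE genes.
    """
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, zlib.crc32(b"genome") & 0x7FFFFFFF])
    n_bins_total = config.n_chroms * (config.chrom_length // BIN)

    # -- element quotas -----------------------------------------------------
    orders = rng.integers(config.core_order_min, config.core_order_max + 1,
                          config.n_core_templates)
    n_gain = int(round(config.core_gain_fraction * config.n_core_templates))
    n_loss = int(round(config.core_loss_fraction * config.n_core_templates))
    labels = np.array(
        ["gained"] * n_gain + ["lost"] * n_loss
        + ["shared"] * (config.n_core_templates - n_gain - n_loss)
    )
    rng.shuffle(labels)
    load_sens = orders[(labels == "shared") | (labels == "lost")].sum()
    load_res = orders[(labels == "shared") | (labels == "gained")].sum()
    n_isolated = max(0, config.n_peaks - int(round((load_sens + load_res) / 2)))
    n_diff = int(round(config.diff_window_fraction * n_bins_total))
    # damage regions span 2 consecutive bins so that at least one sliding
    # (1 kb / 900 bp) window is fully contained regardless of grid phase
    n_damage = int(round(config.damage_window_fraction * n_bins_total / 2))

    per_chrom = {
        "gene": _split(config.n_genes, config.n_chroms),
        "template": _split(config.n_core_templates, config.n_chroms),
        "isolated": _split(n_isolated, config.n_chroms),
        "diffwin": _split(n_diff, config.n_chroms),
        "damagewin": _split(n_damage, config.n_chroms),
        "blacklist": [config.blacklist_per_chrom] * config.n_chroms,
    }

    # -- genome sequence ----------------------------------------------------
    p = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2])
    names, sizes, seq = [], {}, {}
    for ci in range(config.n_chroms):
        name = f"chrS{ci + 1}"
        names.append(name)
        sizes[name] = config.chrom_length
        seq[name] = rng.choice(4, size=config.chrom_length, p=p).astype(np.uint8)

    # -- placement ----------------------------------------------------------
    genes: list[GeneModel] = []
    cpg: list[Interval] = []
    blacklist: list[Interval] = []
    template_rows = []   # (core_id, chrom, start, end, order, label, peaks)
    diff_rows = []
    damage_rows = []
    peaks_by_line = {ln: [] for ln in LINES}   # (chrom, start, end)
    template_idx = 0
    tmpl_cursor = 0

    for ci, name in enumerate(names):
        elements = []
        for _ in range(per_chrom["gene"][ci]):
            # element pads the gene span by 1 kb on each side so promoter
            # and TTS regions stay inside the element footprint
            glen = int(rng.integers(2000, 8001))
            elements.append(("gene", glen, glen + 2000))
        for _ in range(per_chrom["template"][ci]):
            k = int(orders[tmpl_cursor])
            widths = rng.integers(300, 801, k)
            gaps = rng.integers(500, 1101, k - 1) if k > 1 else np.array([], int)
            span = int(widths.sum() + gaps.sum())
            elements.append(("template", (tmpl_cursor, widths, gaps), span))
            tmpl_cursor += 1
        for _ in range(per_chrom["isolated"][ci]):
            elements.append(("isolated", None, int(rng.integers(300, 801))))
        for _ in range(per_chrom["diffwin"][ci]):
            elements.append(("diffwin", None, BIN))
        for _ in range(per_chrom["damagewin"][ci]):
            elements.append(("damagewin", None, 2 * BIN))
        for _ in range(per_chrom["blacklist"][ci]):
            elements.append(("blacklist", None, 20_000))

        for kind, payload, start in _layout_chrom(rng, config.chrom_length, elements):
            if kind in ("diffwin", "damagewin"):
                b = (start // BIN) * BIN  # snap to the 1-kb analysis grid
                width = BIN if kind == "diffwin" else 2 * BIN
                row = (name, b, b + width, "up" if rng.random() < 0.5 else "down")
                (diff_rows if kind == "diffwin" else damage_rows).append(row)
            elif kind == "blacklist":
                blacklist.append(Interval(name, start, start + 20_000))
            elif kind == "isolated":
                width = int(rng.integers(300, 801))
                iv = (name, start, start + width)
                for ln in LINES:
                    peaks_by_line[ln].append(iv)
            elif kind == "template":
                t_i, widths, gaps = payload
                pos = start
                peaks = []
                for j, w in enumerate(widths):
                    peaks.append((name, pos, pos + int(w)))
                    pos += int(w) + (int(gaps[j]) if j < len(gaps) else 0)
                label = labels[t_i]
                if label in ("shared", "lost"):
                    peaks_by_line["sensitive"].extend(peaks)
                if label in ("shared", "gained"):
                    peaks_by_line["resistant"].extend(peaks)
                template_rows.append(
                    (f"T{t_i:03d}", name, peaks[0][1], peaks[-1][2],
                     len(widths), label)
                )
            elif kind == "gene":
                glen = payload
                strand = "+" if rng.random() < 0.5 else "-"
                start = start + 1000
                end = start + glen
                max_ex = max(1, min(5, int((glen / 500 + 1) // 2)))
                n_ex = int(rng.integers(1, max_ex + 1))
                n_seg = 2 * n_ex - 1
                raw = rng.uniform(1.0, 2.0, n_seg)
                extra = (glen - n_seg * 500) * raw / raw.sum()
                seg = (500 + extra).astype(int)
                seg[-1] += glen - seg.sum()
                bounds = start + np.concatenate([[0], np.cumsum(seg)])
                exons = [(int(bounds[i]), int(bounds[i + 1])) for i in range(0, n_seg, 2)]
                gid = f"G{len(genes):04d}"
                if strand == "+":
                    utr5 = [(exons[0][0], exons[0][0] + 200)]
                    utr3 = [(exons[-1][1] - 200, exons[-1][1])]
                else:
                    utr5 = [(exons[-1][1] - 200, exons[-1][1])]
                    utr3 = [(exons[0][0], exons[0][0] + 200)]
                genes.append(GeneModel(gid, name, strand, start, end, exons, utr5, utr3))
                if rng.random() < config.cpg_island_fraction:
                    tss = start if strand == "+" else end - 1
                    lo = max(0, tss - 400)
                    hi = min(config.chrom_length, tss + 400)
                    cpg.append(Interval(name, lo, hi))
                    # rewrite the island sequence as GC-rich
                    p_cpg = np.array([0.175, 0.325, 0.325, 0.175])
                    seq[name][lo:hi] = rng.choice(4, size=hi - lo, p=p_cpg).astype(np.uint8)

    assembly = GenomeAssembly(names, sizes, seq)

    # -- accessibility landscape -------------------------------------------
    n_fine = config.chrom_length // FINE
    n_bins = config.chrom_length // BIN
    base = config.baseline_accessibility
    access = {ln: {name: np.full(n_fine, base) for name in names} for ln in LINES}
    damage_mult = {ln: {name: np.ones(n_bins) for name in names} for ln in LINES}

    def add_boost(line, chrom, start, end, boost):
        f0, f1 = start // FINE, (end - 1) // FINE
        arr = access[line][chrom]
        for f in range(f0, f1 + 1):
            ov = min(end, (f + 1) * FINE) - max(start, f * FINE)
            arr[f] += base * (boost - 1.0) * ov / FINE

    open_rows = {ln: [] for ln in LINES}
    for g in genes:
        tss = g.tss
        lo, hi = max(0, tss - 1000), min(config.chrom_length, tss + 1000)
        for ln in LINES:
            add_boost(ln, g.chrom, lo, hi, config.promoter_boost)
            open_rows[ln].append((g.chrom, lo, hi, "promoter"))
    for ln in LINES:
        for chrom, s, e in peaks_by_line[ln]:
            add_boost(ln, chrom, s, e, config.peak_boost)
            open_rows[ln].append((chrom, s, e, "peak"))
    half = 2.0 ** (config.diff_effect / 2.0)
    for chrom, s, e, direction in diff_rows:
        f0, f1 = s // FINE, e // FINE
        hi_line = "resistant" if direction == "up" else "sensitive"
        lo_line = "sensitive" if direction == "up" else "resistant"
        access[hi_line][chrom][f0:f1] *= half
        access[lo_line][chrom][f0:f1] /= half
        open_rows[hi_line].append((chrom, s, e, "diffwin"))
    dhalf = 2.0 ** (config.damage_effect / 2.0)
    for chrom, s, e, direction in damage_rows:
        hi_line = "resistant" if direction == "up" else "sensitive"
        lo_line = "sensitive" if direction == "up" else "resistant"
        for b in range(s // BIN, e // BIN):
            damage_mult[hi_line][chrom][b] *= dhalf
            damage_mult[lo_line][chrom][b] /= dhalf
    for iv in blacklist:  # anomalous coverage, as in real blacklist regions
        for ln in LINES:
            add_boost(ln, iv.chrom, iv.start, iv.end, 20.0)

    acc_ref = float(np.mean(np.concatenate([access["sensitive"][nm] for nm in names])))

    # -- truth tables -------------------------------------------------------
    templates = pd.DataFrame(
        template_rows,
        columns=["core_id", "chrom", "start", "end", "order", "label"],
    )
    de_rows = []
    if config.de_effect != 0 and len(genes):
        changed = templates[templates["label"] != "shared"]
        for g in genes:
            best = None
            for t in changed.itertuples(index=False):
                if t.chrom != g.chrom:
                    continue
                if t.start - 100_000 <= g.tss < t.end + 100_000:
                    d = max(t.start - g.tss, g.tss - t.end + 1, 0)
                    if best is None or d < best[0]:
                        best = (d, t.core_id, t.label)
            if best is not None:
                de_rows.append(
                    (g.gene_id, "up" if best[2] == "gained" else "down", best[1])
                )
    if config.de_promoter_boost != 1.0 and de_rows:
        # couple DE genes' promoter accessibility to their expression change
        gene_by_id = {g.gene_id: g for g in genes}
        for gid, direction, _cid in de_rows:
            g = gene_by_id[gid]
            lo = max(0, g.tss - 1000) // FINE
            hi = min(config.chrom_length, g.tss + 1000) // FINE
            up_line = "resistant" if direction == "up" else "sensitive"
            access[up_line][g.chrom][lo:hi] *= config.de_promoter_boost
    truth = SimTruth(
        diff_windows=pd.DataFrame(diff_rows, columns=["chrom", "start", "end", "direction"]),
        damage_windows=pd.DataFrame(damage_rows, columns=["chrom", "start", "end", "direction"]),
        core_templates=templates,
        de_genes=pd.DataFrame(de_rows, columns=["gene_id", "direction", "core_id"]),
        open_regions={
            ln: pd.DataFrame(open_rows[ln], columns=["chrom", "start", "end", "kind"])
            for ln in LINES
        },
    )
    gene_factors = np.exp(rng.normal(0.0, 0.5, len(genes)))
    return SimData(
        config=config,
        assembly=assembly,
        genes=genes,
        cpg_islands=cpg,
        blacklist=blacklist,
        truth=truth,
        access=access,
        damage_mult=damage_mult,
        gene_factors=gene_factors,
        acc_ref=acc_ref,
    )


def _nb_draw(rng, mean: np.ndarray, size_param: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + np.maximum(mean, 0.0))
    return rng.negative_binomial(size_param, p)


def simulate_atac(sim: SimData, line: str, replicate: int) -> TagSet:
    """One ATAC replicate.

    Tag counts per 1-kb bin are NB(mean = depth x bin accessibility share,
    size = dispersion); within a bin tags are placed multinomially on the
    fine accessibility profile so peaks keep their sub-kb shape.
    """
    if line not in LINES:
        raise ValueError(f"unknown line {line!r}")
    cfg = sim.config
    sample_id = f"atac_{line}_r{replicate}"
    rng = sim.rng(sample_id)
    cells = BIN // FINE
    total_acc = sum(
        float(sim.access_bin(line, chrom).sum()) for chrom in sim.assembly.names
    )
    data = {}
    for chrom in sim.assembly.names:
        acc_bin = sim.access_bin(line, chrom)
        mean = cfg.atac_depth * acc_bin / total_acc
        counts = _nb_draw(rng, mean, cfg.atac_dispersion)
        total = int(counts.sum())
        if total == 0:
            continue
        bins = np.repeat(np.arange(len(acc_bin)), counts)
        # multinomial placement on the fine profile within each bin
        fine = sim.access[line][chrom].reshape(-1, cells)
        cum = np.cumsum(fine, axis=1)
        cum /= cum[:, -1:]
        u = rng.random(total)
        cell = (u[:, None] > cum[bins]).sum(axis=1)
        pos = bins * BIN + cell * FINE + rng.integers(0, FINE, total)
        strand = rng.integers(0, 2, total).astype(np.int8)
        data[chrom] = (pos.astype(np.int64), strand)
    return TagSet(sample_id, data)


def simulate_ptexo(sim: SimData, line: str, dose: float, replicate: int) -> TagSet:
    """One Pt-exo sample at the given cisplatin dose (uM).

    Adduct sites are Bernoulli-sampled per GG/AG position with probability
    ``adduct_rate * dose * (accessibility / reference)^alpha`` times the
    planted damage multiplier; each sampled adduct emits Poisson-many tags
    whose 5' base is the 5' base of the platinated dinucleotide (plus the
    configured offset).  A uniform background (shared with mock samples)
    is always added.  The sampled adduct sites are recorded in
    ``sim.truth.adducts``.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if line not in LINES:
        raise ValueError(f"unknown line {line!r}")
    cfg = sim.config
    sample_id = f"ptexo_{line}_d{dose:g}_r{replicate}"
    rng = sim.rng(sample_id)
    data = {}
    adduct_records = []
    for chrom in sim.assembly.names:
        L = sim.assembly.sizes[chrom]
        pos_list, strand_list = [], []
        # uniform background; dose-0 libraries are entirely background and
        # sequenced to the standard per-sample depth
        if dose > 0:
            bg_rate = cfg.background_rate
        else:
            bg_rate = cfg.mock_depth / sim.assembly.total_bp
        n_bg = rng.poisson(bg_rate * L)
        if n_bg:
            pos_list.append(rng.integers(0, L, n_bg).astype(np.int64))
            strand_list.append(rng.integers(0, 2, n_bg).astype(np.int8))
        if dose > 0:
            spos, sstrand, sdinuc = sim.target_sites()[chrom]
            acc = sim.access[line][chrom][spos // FINE]
            dmg = sim.damage_mult[line][chrom][spos // BIN]
            prob = np.clip(
                cfg.adduct_rate * dose * (acc / sim.acc_ref) ** cfg.alpha * dmg,
                0.0, 0.9,
            )
            hit = rng.random(len(spos)) < prob
            hpos, hstrand, hdinuc = spos[hit], sstrand[hit], sdinuc[hit]
            adduct_records.append(
                pd.DataFrame({"chrom": chrom, "pos": hpos,
                              "strand": np.where(hstrand == 0, "+", "-"),
                              "dinuc": hdinuc})
            )
            ntags = rng.poisson(cfg.tags_per_adduct, len(hpos))
            tag_pos = np.repeat(hpos, ntags)
            tag_strand = np.repeat(hstrand, ntags)
            if cfg.adduct_offset:
                tag_pos = tag_pos + np.where(tag_strand == 0,
                                             cfg.adduct_offset, -cfg.adduct_offset)
            keep = (tag_pos >= 0) & (tag_pos < L)
            pos_list.append(tag_pos[keep].astype(np.int64))
            strand_list.append(tag_strand[keep])
        if pos_list:
            pos = np.concatenate(pos_list)
            strand = np.concatenate(strand_list)
            if len(pos):
                data[chrom] = (pos, strand)
    sim.truth.adducts[sample_id] = (
        pd.concat(adduct_records, ignore_index=True)
        if adduct_records
        else pd.DataFrame(columns=["chrom", "pos", "strand", "dinuc"])
    )
    return TagSet(sample_id, data)


def simulate_rna(sim: SimData, line: str, replicate: int) -> pd.DataFrame:
    """One RNA replicate: per-gene NB counts; genes linked to gained COREs
    are up in the resistant line, genes linked to lost COREs down."""
    if line not in LINES:
        raise ValueError(f"unknown line {line!r}")
    cfg = sim.config
    rng = sim.rng(f"rna_{line}_r{replicate}")
    mean = cfg.rna_mean * sim.gene_factors.copy()
    half = 2.0 ** (cfg.de_effect / 2.0)
    de = sim.truth.de_genes
    if len(de):
        gene_index = {g.gene_id: i for i, g in enumerate(sim.genes)}
        for row in de.itertuples(index=False):
            i = gene_index[row.gene_id]
            up_in_resistant = row.direction == "up"
            if (line == "resistant") == up_in_resistant:
                mean[i] *= half
            else:
                mean[i] /= half
    counts = _nb_draw(rng, mean, cfg.rna_dispersion)
    return pd.DataFrame(
        {"gene_id": [g.gene_id for g in sim.genes], "count": counts}
    )


def write_simulation(sim: SimData, outdir: str | os.PathLike) -> dict[str, str]:
    """Write genome, annotation and truth tables as plain-text files."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    sim.assembly.write_fasta(_p("genome.fa"))
    sim.assembly.write_chrom_sizes(_p("genome.chrom.sizes"))
    write_gtf(sim.genes, _p("genes.gtf"))
    write_intervals(sim.cpg_islands, _p("cpg_islands.bed"))
    write_intervals(sim.blacklist, _p("blacklist.bed"))
    t = sim.truth
    t.diff_windows.to_csv(_p("truth_diff_windows.tsv"), sep="\t", index=False)
    t.damage_windows.to_csv(_p("truth_damage_windows.tsv"), sep="\t", index=False)
    t.core_templates.to_csv(_p("truth_core_templates.tsv"), sep="\t", index=False)
    t.de_genes.to_csv(_p("truth_de_genes.tsv"), sep="\t", index=False)
    return paths
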