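"""End-to-end orchestration: simulate (or load) -> windows -> differential
accessibility -> expression -> peaks/COREs -> Pt-exo damage -> context
summaries, with a run manifest for reproducibility auditing.

Two runs with identical configuration produce byte-identical result files
(the manifest records wall time and is excluded from that guarantee).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import cores as cores_mod
from . import ptexo as ptexo_mod
from . import simulate as sim_mod
from . import stats as stats_mod
from . import windows as win_mod
from .io import deduplicate_tags, subtract_blacklist, write_intervals

log = logging.getLogger("ptcore")

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """All thresholds of the analysis in one auditable place."""

    simulate: sim_mod.SimConfig = field(default_factory=sim_mod.SimConfig)
    n_replicates: int = 3
    ptexo_dose: float = 16.0
    atac_window: int = 1000
    damage_window: int = 1000
    damage_step: int = 900
    atac_lfc: float = 2.0
    atac_fdr: float = 0.001
    gene_lfc: float = 2.0
    gene_fdr: float = 0.05
    damage_delta: float = 2.0
    damage_fdr: float = 0.05
    core_min_order: int = 3
    core_gap_quantile: float = 0.25
    link_span: int = 100_000

    def __post_init__(self) -> None:
        for name in ("atac_lfc", "atac_fdr", "gene_lfc", "gene_fdr",
                     "damage_delta", "damage_fdr", "ptexo_dose"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim_cfg = d.pop("simulate", {})
        if isinstance(sim_cfg, dict):
            sim_cfg = sim_mod.SimConfig(**sim_cfg)
        return cls(simulate=sim_cfg, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def intersect_de(tables: list[pd.DataFrame], direction: str) -> list[str]:
    """Genes called consistently ``up`` (or ``down``) in every table."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sets = []
    universe = None
    for t in tables:
        feats = set(t["feature"])
        if universe is None:
            universe = feats
        elif feats != universe:
            raise ValueError("mismatched gene universes")
        sets.append(set(t.loc[t["call"] == direction, "feature"]))
    out = set.intersection(*sets) if sets else set()
    return sorted(out)


def run_pipeline(config: PipelineConfig, outdir: str | os.PathLike) -> dict:
    """Execute the full synthetic-study analysis; returns the manifest."""
    os.makedirs(outdir, exist_ok=True)
    outdir = str(outdir)
    t0 = time.time()
    manifest: dict = {
        "config": config.to_dict(),
        "stages": [],
        "outputs": {},
    }
    report: list[str] = ["# ptcore run report", ""]

    def out_path(name: str) -> str:
        return os.path.join(outdir, name)

    def register(name: str) -> None:
        manifest["outputs"][name] = _sha256(out_path(name))

    def stage(name: str):
        log.info("stage: %s", name)
        manifest["stages"].append(name)
        report.append(f"## {name}")

    try:
        # ------------------------------------------------------------ 1
        stage("simulate")
        sim = sim_mod.simulate_genome_annotation(config.simulate)
        sim_mod.write_simulation(sim, outdir)
        for name in ("genome.fa", "genome.chrom.sizes", "genes.gtf",
                     "cpg_islands.bed", "blacklist.bed",
                     "truth_diff_windows.tsv", "truth_damage_windows.tsv",
                     "truth_core_templates.tsv", "truth_de_genes.tsv"):
            register(name)
        reps = range(1, config.n_replicates + 1)
        atac = {
            ln: [sim_mod.simulate_atac(sim, ln, r) for r in reps]
            for ln in sim_mod.LINES
        }
        report += [
            f"- genome: {sim.assembly.total_bp:,} bp in {len(sim.assembly.names)} sequences",
            f"- genes: {len(sim.genes)}; CpG islands: {len(sim.cpg_islands)}; "
            f"blacklist: {len(sim.blacklist)}",
            "",
        ]

        # ------------------------------------------------------------ 2
        stage("atac windows")
        clean = {
            ln: [deduplicate_tags(subtract_blacklist(t, sim.blacklist)) for t in atac[ln]]
            for ln in sim_mod.LINES
        }
        tiles = win_mod.tile_genome(sim.assembly, config.atac_window)
        samples = clean["sensitive"] + clean["resistant"]
        wm = win_mod.count_and_normalize(samples, tiles)
        wm = win_mod.filter_windows(wm)
        report += [
            f"- windows: {wm.n_windows}; passing depth filter: "
            f"{int(wm.pass_filter.sum())} "
            f"(median {wm.metadata['filter_median']:.3g}, "
            f"SD {wm.metadata['filter_sd']:.3g})",
            "",
        ]

        # ------------------------------------------------------------ 3
        stage("differential accessibility")
        conditions = ["sensitive"] * config.n_replicates + ["resistant"] * config.n_replicates
        X, contrast, _ = stats_mod.make_design(conditions, baseline="sensitive")
        keep = wm.pass_filter
        atac_diff = stats_mod.moderated_fit(
            wm.counts[keep], X, contrast,
            lfc_cut=config.atac_lfc, fdr_cut=config.atac_fdr,
            lib_sizes=wm.lib_sizes,
            feature_ids=np.flatnonzero(keep),
        )
        win_pass = wm.windows[keep].reset_index(drop=True)
        atac_out = pd.concat([win_pass, atac_diff.drop(columns="feature")], axis=1)
        _write_tsv(atac_out, out_path("atac_diff.tsv"))
        register("atac_diff.tsv")
        classes = win_mod.annotate_windows(win_pass, sim.genes, sim.cpg_islands)
        n_up = int((atac_diff["call"] == "up").sum())
        n_down = int((atac_diff["call"] == "down").sum())
        enr_frames = []
        for direction in ("up", "down"):
            mask = (atac_diff["call"] == direction).to_numpy()
            if mask.any():
                enr = win_mod.class_enrichment(mask, classes)
                enr.insert(0, "direction", direction)
                enr_frames.append(enr)
        if enr_frames:
            _write_tsv(pd.concat(enr_frames), out_path("atac_class_enrichment.tsv"))
            register("atac_class_enrichment.tsv")
        corr, _Z = stats_mod.correlation_cluster(
            np.log2(wm.rpkm[keep] + 0.5), method="average"
        )
        corr.index = corr.columns = [t.sample_id for t in samples]
        corr.to_csv(out_path("atac_correlation.tsv"), sep="\t", float_format=FLOAT_FMT)
        register("atac_correlation.tsv")
        cls_series = pd.Series(classes)
        by_class = cls_series[np.asarray(atac_diff["call"] != "ns")].value_counts()
        report += [
            f"- differential windows (|log2FC|>{config.atac_lfc:g}, "
            f"FDR<{config.atac_fdr:g}): {n_up} up, {n_down} down "
            f"of {int(keep.sum())} analysed",
            "- differential windows by class: "
            + (", ".join(f"{k}: {v}" for k, v in by_class.items()) or "none"),
            "",
        ]

        # ------------------------------------------------------------ 4
        stage("expression")
        rna = {
            ln: [sim_mod.simulate_rna(sim, ln, r) for r in reps]
            for ln in sim_mod.LINES
        }
        gene_ids = rna["sensitive"][0]["gene_id"].to_numpy()
        rna_counts = np.column_stack(
            [df["count"].to_numpy() for df in rna["sensitive"] + rna["resistant"]]
        )
        if len(gene_ids):
            rna_diff = stats_mod.moderated_fit(
                rna_counts, X, contrast,
                lfc_cut=config.gene_lfc, fdr_cut=config.gene_fdr,
                feature_ids=gene_ids,
            )
            _write_tsv(rna_diff, out_path("rna_diff.tsv"))
            register("rna_diff.tsv")
            de_up = intersect_de([rna_diff], "up")
            de_down = intersect_de([rna_diff], "down")
            report += [
                f"- DE genes (|log2FC|>{config.gene_lfc:g}, FDR<{config.gene_fdr:g}): "
                f"{len(de_up)} up, {len(de_down)} down of {len(gene_ids)}",
                "",
            ]
        else:
            rna_diff = None
            report += ["- no genes simulated; expression stage skipped", ""]

        # ------------------------------------------------------------ 5
        stage("tss accessibility of DE genes")
        if rna_diff is not None and (rna_diff["call"] != "ns").any():
            de_set = set(rna_diff.loc[rna_diff["call"] != "ns", "feature"])
            de_genes = [g for g in sim.genes if g.gene_id in de_set]
            prof = win_mod.tss_profile(samples, de_genes, sim.assembly)
            _write_tsv(prof, out_path("tss_profile.tsv"))
            register("tss_profile.tsv")
            sens_ids = [t.sample_id for t in clean["sensitive"]]
            res_ids = [t.sample_id for t in clean["resistant"]]
            for direction in ("up", "down"):
                ids = set(rna_diff.loc[rna_diff["call"] == direction, "feature"])
                sub = prof[prof["gene_id"].isin(ids)]
                if len(sub) >= 2:
                    diff, t, p = win_mod.group_mean_ttest(sub, res_ids, sens_ids)
                    report.append(
                        f"- {direction}-regulated genes (n={len(sub)}): "
                        f"TSS coverage resistant-sensitive = {diff:.3g} "
                        f"(t={t:.3g}, p={p:.3g})"
                    )
            report.append("")
        else:
            report += ["- no DE genes; TSS stage skipped", ""]

        # ------------------------------------------------------------ 6
        stage("peaks and COREs")
        peaks = {}
        for ln in sim_mod.LINES:
            pk = cores_mod.call_peaks(clean[ln], sim.assembly)
            peaks[ln] = pk
            _write_tsv(pk, out_path(f"peaks_{ln}.tsv"))
            register(f"peaks_{ln}.tsv")
        # one pooled threshold keeps CORE calls comparable across the lines
        g_star = cores_mod.pooled_gap_threshold(
            list(peaks.values()), config.core_gap_quantile
        )
        core_tables = {
            ln: cores_mod.call_cores(
                peaks[ln], min_order=config.core_min_order,
                gap_quantile=config.core_gap_quantile, gap_threshold=g_star,
            )
            for ln in sim_mod.LINES
        }
        labeled_a, labeled_b = cores_mod.classify_core_changes(
            core_tables["sensitive"], core_tables["resistant"]
        )
        for ln, tab in (("sensitive", labeled_a), ("resistant", labeled_b)):
            t = tab.drop(columns="peak_indices")
            _write_tsv(t, out_path(f"cores_{ln}.tsv"))
            register(f"cores_{ln}.tsv")
        n_lost = int((labeled_a["label"] == "lost").sum())
        n_gained = int((labeled_b["label"] == "gained").sum())
        report += [
            f"- peaks: {len(peaks['sensitive'])} sensitive, {len(peaks['resistant'])} resistant",
            f"- COREs: {len(labeled_a)} sensitive, {len(labeled_b)} resistant "
            f"({n_lost} lost, {n_gained} gained in resistant)",
        ]
        changed = pd.concat(
            [labeled_a[labeled_a["label"] == "lost"],
             labeled_b[labeled_b["label"] == "gained"]]
        ).reset_index(drop=True)
        assoc = None
        if rna_diff is not None and len(changed):
            assoc = cores_mod.core_expression_association(
                changed, rna_diff, sim.genes, span=config.link_span
            )
            for label in ("gained", "lost"):
                if label in assoc and "mean_t" in assoc[label]:
                    r = assoc[label]
                    f = r["fisher"]
                    report.append(
                        f"- {label} COREs: {r['n_linked']} linked genes, "
                        f"{r['n_linked_de']} DE; mean t = {r['mean_t']:.3g} "
                        f"(one-sample p={r['one_sample_p']:.3g}); DE enrichment "
                        f"OR={f.oddsratio:.3g} [{f.ci_low:.3g}, {f.ci_high:.3g}]"
                    )
        report.append("")

        # ------------------------------------------------------------ 7
        stage("pt-exo damage")
        pt_treated = {
            ln: [sim_mod.simulate_ptexo(sim, ln, config.ptexo_dose, r) for r in reps]
            for ln in sim_mod.LINES
        }
        pt_mock = {
            ln: [sim_mod.simulate_ptexo(sim, ln, 0.0, r) for r in reps]
            for ln in sim_mod.LINES
        }
        dinuc_frames = []
        for ln in sim_mod.LINES:
            treated_tab = ptexo_mod.extract_5prime_context(pt_treated[ln][0], sim.assembly)
            mock_tab = ptexo_mod.extract_5prime_context(pt_mock[ln][0], sim.assembly)
            enr = ptexo_mod.dinuc_enrichment(treated_tab, mock_tab).reset_index()
            enr.insert(0, "line", ln)
            dinuc_frames.append(enr)
            or0 = float(enr.loc[enr["offset"] == 0, "OR"].iloc[0])
            report.append(f"- {ln}: 5'-end target-dinucleotide OR at offset 0 = {or0:.3g}")
        _write_tsv(pd.concat(dinuc_frames), out_path("dinuc_enrichment.tsv"))
        register("dinuc_enrichment.tsv")

        sliding = win_mod.tile_genome(
            sim.assembly, config.damage_window, config.damage_step
        )
        pass_regions = wm.windows[wm.pass_filter]
        sliding_mask = ptexo_mod.intersect_pass_regions(sliding, pass_regions)
        signals = {
            ln: ptexo_mod.damage_signal(
                pt_treated[ln], pt_mock[ln], sliding, pass_filter=sliding_mask
            )
            for ln in sim_mod.LINES
        }
        dmg = ptexo_mod.differential_damage(
            signals["sensitive"], signals["resistant"],
            delta_cut=config.damage_delta, fdr_cut=config.damage_fdr,
        )
        _write_tsv(dmg, out_path("damage_diff.tsv"))
        register("damage_diff.tsv")
        n_inc = int((dmg["call"] == "increased").sum())
        n_dec = int((dmg["call"] == "decreased").sum())
        report += [
            f"- damage windows analysed: {len(dmg)}; increased in resistant: "
            f"{n_inc}, decreased: {n_dec}",
        ]

        dmg_classes = win_mod.annotate_windows(
            dmg[["chrom", "start", "end"]], sim.genes, sim.cpg_islands
        )
        # accessibility change (log2 resistant/sensitive mean RPKM) per damage window
        atac_wm_sliding = win_mod.count_and_normalize(samples, sliding)
        r_mean = atac_wm_sliding.rpkm[:, config.n_replicates:].mean(axis=1)
        s_mean = atac_wm_sliding.rpkm[:, :config.n_replicates].mean(axis=1)
        delta_atac_all = np.log2(r_mean + 0.5) - np.log2(s_mean + 0.5)
        delta_atac = delta_atac_all[sliding_mask]
        core_sets = {
            "shared": labeled_b[labeled_b["label"] == "shared"],
            "gained": labeled_b[labeled_b["label"] == "gained"],
            "lost": labeled_a[labeled_a["label"] == "lost"],
        }
        ctx = ptexo_mod.damage_context_summary(
            dmg, dmg_classes, delta_atac,
            core_sets=core_sets, damage=signals["resistant"],
        )
        ctx_rows = []
        for label in ("increased", "decreased"):
            key = f"class_enrichment_{label}"
            if key in ctx:
                enr = ctx[key].copy()
                enr.insert(0, "call", label)
                ctx_rows.append(enr)
        if ctx_rows:
            _write_tsv(pd.concat(ctx_rows), out_path("damage_class_enrichment.tsv"))
            register("damage_class_enrichment.tsv")
        if "accessibility_by_call" in ctx:
            ab = ctx["accessibility_by_call"]
            report.append(
                f"- accessibility change: increased-damage windows mean "
                f"{ab['mean_delta_increased']:.3g}, decreased "
                f"{ab['mean_delta_decreased']:.3g} (Wilcoxon p={ab['p']:.3g})"
            )
        if "core_damage" in ctx:
            cd = ctx["core_damage"]
            report.append(
                "- mean damage signal per CORE set: "
                + ", ".join(f"{k}: {v['mean']:.3g} (n={v['n']})" for k, v in cd.items())
            )
        report.append("")

    except Exception as exc:  # mark failing stage, keep partial outputs
        failing = manifest["stages"][-1] if manifest["stages"] else "setup"
        manifest["failed_stage"] = failing
        manifest["error"] = str(exc)
        with open(out_path("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise RuntimeError(f"pipeline failed at stage {failing!r}: {exc}") from exc

    manifest["wall_time_s"] = round(time.time() - t0, 3)
    with open(out_path("report.md"), "w") as fh:
        fh.write("\n".join(report) + "\n")
    register("report.md")
    with open(out_path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
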