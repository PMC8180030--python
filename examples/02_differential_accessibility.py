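"""Windowed differential chromatin accessibility between the lines.

Counts ATAC tags into a 1-kb tiling, applies the depth filter, fits the
precision-weighted empirical-Bayes moderated-t model and annotates the
differential windows by genomic class.
"""

import numpy as np

import ptcore as pt
from ptcore import stats as st, windows as wn
from ptcore.io import deduplicate_tags, subtract_blacklist

sim = pt.simulate_genome_annotation(pt.SimConfig(seed=42))
samples = [
    deduplicate_tags(subtract_blacklist(pt.simulate_atac(sim, ln, r), sim.blacklist))
    for ln in ("sensitive", "resistant") for r in (1, 2, 3)
]

tiles = pt.tile_genome(sim.assembly, window=1000)
wm = wn.filter_windows(wn.count_and_normalize(samples, tiles))
print(f"{wm.n_windows} windows, {int(wm.pass_filter.sum())} pass the depth "
      f"filter (>1 RPKM, < median+1SD = {wm.metadata['filter_upper']:.1f})")

X, contrast, _ = st.make_design(["s"] * 3 + ["r"] * 3, baseline="s")
diff = st.moderated_fit(wm.counts[wm.pass_filter], X, contrast,
                        lfc_cut=2.0, fdr_cut=0.001, lib_sizes=wm.lib_sizes)
n_up = int((diff["call"] == "up").sum())
n_down = int((diff["call"] == "down").sum())
print(f"differential windows at |log2FC|>2, FDR<0.001: {n_up} up, {n_down} "
      f"down (planted: {len(sim.truth.diff_windows)})")
print(f"variance shrinkage: prior df d0 = {diff.attrs['d0']:.1f}, "
      f"prior variance s0^2 = {diff.attrs['s0_2']:.3f}")

win_pass = wm.windows[wm.pass_filter].reset_index(drop=True)
classes = wn.annotate_windows(win_pass, sim.genes, sim.cpg_islands)
enr = wn.class_enrichment((diff["call"] != "ns").to_numpy(), classes)
print("\nclass enrichment of differential windows (OR, 95% CI):")
for row in enr.itertuples(index=False):
    print(f"  {row[0]:<14} OR={row.OR:6.2f}  [{row.ci_low:.2f}, {row.ci_high:.2f}]")
# ORs > 1 mean the class is over-represented among changed windows; the
# planted changes sit in intergenic space, mirroring the biology the
# simulator emulates.
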