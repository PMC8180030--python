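"""Cisplatin-adduct mapping from exonuclease stop sites.

The 5' end of a Pt-exo read marks the platinum adduct.  This script shows
the two core read-outs: target-dinucleotide (GpG/ApG) enrichment around
read 5' ends, and the windowed log2 signal:background ratio against
mock-treated samples, including differential damage between the lines.
"""

import numpy as np

import ptcore as pt
from ptcore import ptexo as px

sim = pt.simulate_genome_annotation(pt.SimConfig(seed=42))
lines = ("sensitive", "resistant")
treated = {ln: [pt.simulate_ptexo(sim, ln, dose=16.0, replicate=r)
                for r in (1, 2, 3)] for ln in lines}
mock = {ln: [pt.simulate_ptexo(sim, ln, dose=0.0, replicate=r)
             for r in (1, 2, 3)] for ln in lines}

tab_t = px.extract_5prime_context(treated["sensitive"][0], sim.assembly)
tab_m = px.extract_5prime_context(mock["sensitive"][0], sim.assembly)
enr = px.dinuc_enrichment(tab_t, tab_m)
print("GG/AG enrichment at read 5' ends (treated vs mock):")
for k in (-5, -1, 0, 1, 5):
    print(f"  offset {k:+d}: OR = {enr.loc[k, 'OR']:.2f}")
# A large OR at offset 0 only: the adduct sits exactly at the stop site.

sliding = pt.tile_genome(sim.assembly, window=1000, step=900)
sig = {ln: px.damage_signal(treated[ln], mock[ln], sliding) for ln in lines}
calls = px.differential_damage(sig["sensitive"], sig["resistant"],
                               delta_cut=2.0, fdr_cut=0.05)
n_inc = int((calls["call"] == "increased").sum())
n_dec = int((calls["call"] == "decreased").sum())
print(f"\n{len(calls)} sliding windows; differential damage in resistant: "
      f"{n_inc} increased, {n_dec} decreased "
      f"(planted damage regions: {len(sim.truth.damage_windows)})")
# Calls exceed the planted damage regions because adduct formation is
# coupled to accessibility (alpha = 1): windows whose chromatin opens or
# closes between the lines genuinely change their damage rate too.
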