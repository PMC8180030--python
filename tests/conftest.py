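"""Shared fixtures: simulated datasets are session-scoped because the
heavier recovery tests all operate on the same planted study."""

import numpy as np
import pytest

import ptcore as pt
from ptcore.io import deduplicate_tags, subtract_blacklist

LINES = ("sensitive", "resistant")


@pytest.fixture(scope="session")
def hg19():
    return pt.packaged_hg19_chrom_sizes()


@pytest.fixture(scope="session")
def sim_default():
    """Default study conditions with planted truth."""
    return pt.simulate_genome_annotation(pt.SimConfig(seed=11))


@pytest.fixture(scope="session")
def atac_clean(sim_default):
    """Blacklist-subtracted, deduplicated ATAC replicates per line."""
    return {
        ln: [
            deduplicate_tags(
                subtract_blacklist(pt.simulate_atac(sim_default, ln, r),
                                   sim_default.blacklist)
            )
            for r in (1, 2, 3)
        ]
        for ln in LINES
    }


@pytest.fixture(scope="session")
def peaks_by_line(sim_default, atac_clean):
    return {
        ln: pt.call_peaks(atac_clean[ln], sim_default.assembly) for ln in LINES
    }


@pytest.fixture(scope="session")
def ptexo_tags(sim_default):
    treated = {
        ln: [pt.simulate_ptexo(sim_default, ln, 16.0, r) for r in (1, 2, 3)]
        for ln in LINES
    }
    mock = {
        ln: [pt.simulate_ptexo(sim_default, ln, 0.0, r) for r in (1, 2, 3)]
        for ln in LINES
    }
    return treated, mock


@pytest.fixture(scope="session")
def sim_damage_only():
    """Study in which the only true between-line difference is the planted
    damage windows (no CORE gains/losses, no accessibility changes), so
    differential-damage recovery can be scored against truth alone."""
    cfg = pt.SimConfig(
        seed=13, core_gain_fraction=0.0, core_loss_fraction=0.0,
        diff_window_fraction=0.0,
    )
    return pt.simulate_genome_annotation(cfg)


@pytest.fixture(scope="session")
def damage_calls(sim_damage_only):
    """Differential-damage table for the damage-only study plus the
    sliding-window frame it was computed on."""
    from ptcore import ptexo as px

    sim = sim_damage_only
    treated = {
        ln: [pt.simulate_ptexo(sim, ln, 16.0, r) for r in (1, 2, 3)]
        for ln in LINES
    }
    mock = {
        ln: [pt.simulate_ptexo(sim, ln, 0.0, r) for r in (1, 2, 3)]
        for ln in LINES
    }
    sliding = pt.tile_genome(sim.assembly, 1000, 900)
    sig = {
        ln: px.damage_signal(treated[ln], mock[ln], sliding) for ln in LINES
    }
    calls = px.differential_damage(sig["sensitive"], sig["resistant"])
    return {"sliding": sliding, "signals": sig, "calls": calls,
            "treated": treated, "mock": mock}


def overlaps_any(a, b):
    from ptcore.cores import _overlaps_any

    return _overlaps_any(a, b)
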