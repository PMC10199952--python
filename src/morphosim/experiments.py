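"""Canned desk-scale experiments.

The headline tissue-growth phenomenology (boundary absorbance, morphogen
decay length, receptor feedback) is probed here on deliberately scaled-down
conditions: ~20-cell tissues, a raised growth rate so the shortest cell
cycle is ~200 mechanical time units instead of ~9090, and a short horizon.
These runs reproduce directions of effects (more/fewer cells, more/less
symmetric growth), not absolute sizes.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import SimConfig, TissueConfig
from .coupling import CouplingConfig, run_coupled
from .mechanics import MechParams
from .metrics import division_angle_histogram
from .signaling import ChemParams

__all__ = ["trend_config", "run_trend", "trend_votes"]

# scaled-down study conditions (fixed; see docs/methods.md)
TREND_N_CELLS = 20
TREND_G0 = 5e-3              # shortest cycle 1/g0 = 200 mechanical time units
TREND_EXCHANGE = 25.0        # 8 chemical updates per shortest cycle
TREND_T_END = 400.0          # two shortest cycles
TREND_MITOTIC = 10.0


def trend_config(seed: int, bc: str = "absorbing", d_Dpp: float = 0.5,
                 mode: str = "simplified", k_P: float = 1.0,
                 v_max: float = 10.0) -> SimConfig:
    """SimConfig for one scaled-down trend run.

    Full-mode runs use the activating pMad Hill so pMad is a monotone
    readout of Dpp signaling, which is what the division rule requires.
    """
    cfg = SimConfig(seed=seed)
    cfg.tissue = TissueConfig(n_cells=TREND_N_CELLS, nodes_per_cell_membrane=14,
                              internal_nodes_per_cell=6, relax_steps=1500)
    cfg.mechanics = dataclasses.replace(
        MechParams(), g0_max=TREND_G0, mitotic_duration=TREND_MITOTIC)
    cfg.signaling = dataclasses.replace(
        ChemParams(), bc=bc, d_Dpp=d_Dpp, mode=mode, k_P=k_P, v_max=v_max,
        # activating pMad readout, driven hard enough that the feedback on
        # Tkv is fully engaged when k_P is small
        pmad_hill="activating" if mode == "full" else "repressive",
        v_P=4.0 if mode == "full" else 1.0)
    # full mode reads the division rule from Dpp: the receptor feedback then
    # acts through the morphogen spread it is meant to control, whereas a
    # pMad-based rule is actively buffered by the same feedback loop and
    # stalls (see docs/methods.md)
    cfg.coupling = CouplingConfig(
        exchange_interval=TREND_EXCHANGE, t_end=TREND_T_END,
        rule_signal="dpp" if mode == "full" else "auto")
    return cfg


def run_trend(cfg: SimConfig):
    """Run one trend simulation; returns a summary dict with the final cell
    count, final circularity, and the 8-sector division-angle counts."""
    snaps, events, final = run_coupled(cfg)
    last = snaps[-1]
    positions = np.array([e.position for e in events if e.position is not None]
                         ).reshape(-1, 2)
    center = final["nodes"].pos.mean(axis=0)
    sectors = division_angle_histogram(positions, center)
    return {
        "n_cells": last.n_cells,
        "circularity": last.circularity,
        "n_divisions": len(events),
        "sector_counts": sectors,
        # angular spread is undefined without division events
        "sector_var": (float(np.var(sectors / sectors.sum()))
                       if sectors.sum() > 0 else None),
    }


def trend_votes(results_a, results_b, key: str = "n_cells"):
    """Per-seed votes that condition A >= condition B on the given summary
    key; returns (votes_for_a, n_seeds)."""
    votes = sum(1 for ra, rb in zip(results_a, results_b) if ra[key] >= rb[key])
    return votes, len(results_a)


def flatness_votes(results_a, results_b):
    """Votes that A's angular division distribution is at least as flat as
    B's (lower sector-fraction variance), counted only over seeds where
    both runs actually divided; returns (votes_for_a, n_compared)."""
    pairs = [(ra["sector_var"], rb["sector_var"])
             for ra, rb in zip(results_a, results_b)
             if ra["sector_var"] is not None and rb["sector_var"] is not None]
    return sum(1 for a, b in pairs if a <= b), len(pairs)
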