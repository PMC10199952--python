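"""Readouts of simulated tissues: morphogen decay length, normalized
profiles, tissue circularity, neighbor-count histograms and the angular
distribution of division events."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .mechanics import MEMBRANE, NodeSet

__all__ = [
    "ProfileFit",
    "fit_decay_length",
    "circularity",
    "neighbor_histogram",
    "division_angle_histogram",
    "normalized_profile",
]


@dataclass
class ProfileFit:
    """Exponential fit c = amplitude * exp(-x / lambda_hat) of a morphogen
    profile outside the source region.  ``flat`` marks a non-decaying
    profile for which no decay length is reported."""

    lambda_hat: float | None
    amplitude: float | None
    residual: float
    x: np.ndarray
    c: np.ndarray
    flat: bool = False


def fit_decay_length(x, c, source_width: float = 0.0,
                     min_points: int = 5) -> ProfileFit:
    """Least-squares fit of an exponential decay to (position, concentration)
    samples with x > source_width.

    The decay length is the distance over which the profile drops to
    e^-1 (~37%) of its maximum.  Profiles with a non-negative slope (or a
    best-fit decay length exceeding 100x the domain span) are flagged flat.
    """
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    keep = x > source_width
    xs, cs = x[keep], c[keep]
    if len(xs) < min_points:
        raise ValueError(f"need at least {min_points} samples outside the source "
                         f"region, got {len(xs)}")
    span = float(xs.max() - xs.min())
    if span <= 0 or np.all(cs <= 0):
        return ProfileFit(None, None, math.inf, xs, cs, flat=True)

    # log-linear start, refined by nonlinear least squares on the raw scale
    pos = cs > 0
    slope, intercept = np.polyfit(xs[pos], np.log(cs[pos]), 1)
    if slope >= 0:
        return ProfileFit(None, None, math.inf, xs, cs, flat=True)
    p0 = (math.exp(intercept), -1.0 / slope)
    try:
        popt, _ = curve_fit(lambda xx, a, lam: a * np.exp(-xx / lam),
                            xs, cs, p0=p0, maxfev=20000)
    except RuntimeError:
        popt = p0
    amp, lam = float(popt[0]), float(popt[1])
    if lam <= 0 or lam > 100 * span:
        return ProfileFit(None, None, math.inf, xs, cs, flat=True)
    resid = float(np.sqrt(np.mean((amp * np.exp(-xs / lam) - cs) ** 2)))
    return ProfileFit(lam, amp, resid, xs, cs)


def circularity(nodes: NodeSet) -> float:
    """Tissue height over tissue width, from the bounding box of all
    membrane nodes; 1 for a symmetric tissue."""
    pts = nodes.pos[nodes.kind == MEMBRANE]
    if len(pts) == 0:
        pts = nodes.pos
    width = float(pts[:, 0].max() - pts[:, 0].min())
    height = float(pts[:, 1].max() - pts[:, 1].min())
    if width <= 0:
        raise ValueError("degenerate tissue: zero width")
    return height / width


def neighbor_histogram(adjacency: dict[int, set[int]],
                       n_max: int = 10) -> np.ndarray:
    """Fraction of cells with n neighbors, n = 0..n_max (sums to 1)."""
    counts = np.zeros(n_max + 1)
    if not adjacency:
        return counts
    for neigh in adjacency.values():
        counts[min(len(neigh), n_max)] += 1
    return counts / counts.sum()


def division_angle_histogram(positions, center, n_sectors: int = 8) -> np.ndarray:
    """Counts of division events in equal angular sectors about the tissue
    center.  Sector 0 starts at the positive x axis, counter-clockwise."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    counts = np.zeros(n_sectors, dtype=int)
    if len(positions) == 0:
        return counts
    v = positions - np.asarray(center, dtype=float)
    ang = np.mod(np.arctan2(v[:, 1], v[:, 0]), 2 * math.pi)
    sector = np.minimum((ang / (2 * math.pi / n_sectors)).astype(int), n_sectors - 1)
    np.add.at(counts, sector, 1)
    return counts


def normalized_profile(x, c, L: float):
    """Profile against relative position x/L, concentrations scaled by the
    profile maximum (the form used for gradient-shape comparisons)."""
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    cmax = c.max() if len(c) and c.max() > 0 else 1.0
    order = np.argsort(x)
    return x[order] / L, c[order] / cmax
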