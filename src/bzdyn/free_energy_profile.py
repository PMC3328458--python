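"""Histogram (Boltzmann-inversion) free-energy profiles and densities.

A sampled angular coordinate is wrapped to [-180, 180), binned into
half-open bins, and each occupied bin's relative free energy is

    G_b = -R T ln(n_b / N),   shifted so min(G) = 0,

with R = 1.987e-3 kcal/(mol K).  Empty bins carry NaN rather than a
pseudo-count: the profile reports only what was sampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from ._geom import _wrap180
from .synthetic_dynamics import GAS_CONSTANT_KCAL

__all__ = [
    "FreeEnergyProfile",
    "build_profile",
    "well_and_barrier",
    "WellBarrier",
    "density_estimate",
]


@dataclass
class FreeEnergyProfile:
    """Relative free-energy profile over a wrapped angular coordinate."""

    bin_edges: np.ndarray  # degrees, length n_bins + 1 spanning [-180, 180]
    counts: np.ndarray
    g: np.ndarray  # kcal/mol relative to the occupied minimum; NaN if empty
    temperature: float
    gas_constant: float = GAS_CONSTANT_KCAL

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
                "G_kcal_mol": self.g,
            }
        )


def build_profile(values, bin_width: float = 18.0, temperature: float = 300.0) -> FreeEnergyProfile:
    """Bin an angular series (degrees) and Boltzmann-invert the histogram.

    ``bin_width`` must divide 360; values are wrapped to [-180, 180) first,
    so an epsilon-zeta difference always occupies at most 360/bin_width
    half-open bins (20 bins at the default 18 degrees).
    """
    v = _wrap180(np.asarray(values, dtype=float))
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no data to profile")
    n_bins = 360.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin width {bin_width} does not divide 360 degrees")
    n_bins = int(round(n_bins))
    edges = -180.0 + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    with np.errstate(divide="ignore"):
        g = -GAS_CONSTANT_KCAL * temperature * np.log(counts / v.size)
    g = np.where(counts > 0, g, np.nan)
    g = g - np.nanmin(g)
    return FreeEnergyProfile(
        bin_edges=edges, counts=counts, g=g, temperature=float(temperature)
    )


@dataclass
class WellBarrier:
    """Well and barrier summary of a double-well profile."""

    delta_g: float  # G(BII-side minimum) - G(BI-side minimum), kcal/mol
    barrier_from_left: float  # barrier measured from the BI-side well
    barrier_from_right: float  # barrier measured from the BII-side well
    left_min_center: float
    right_min_center: float
    has_gap: bool  # True if an empty bin lies between the two wells


def well_and_barrier(profile: FreeEnergyProfile, boundary: float = 0.0) -> WellBarrier:
    """Free-energy difference and barrier between the two wells separated
    by ``boundary`` (degrees) on the wrapped coordinate.

    The BI-side well is the occupied minimum left of the boundary, the
    BII-side well the occupied minimum at/right of it; delta_g = G_right -
    G_left.  The barrier is the maximum occupied G between the two minima,
    reported relative to each well; interior empty bins are skipped and
    flagged.
    """
    centers = profile.bin_centers
    g = profile.g
    left = np.flatnonzero((centers < boundary) & ~np.isnan(g))
    right = np.flatnonzero((centers >= boundary) & ~np.isnan(g))
    if left.size == 0 or right.size == 0:
        raise ValueError("profile has occupied bins on one side of the boundary only")
    i_left = left[np.nanargmin(g[left])]
    i_right = right[np.nanargmin(g[right])]
    lo, hi = sorted((i_left, i_right))
    between = np.arange(lo, hi + 1)
    occupied = between[~np.isnan(g[between])]
    barrier = float(np.nanmax(g[occupied]))
    has_gap = bool(np.isnan(g[between]).any())
    return WellBarrier(
        delta_g=float(g[i_right] - g[i_left]),
        barrier_from_left=barrier - float(g[i_left]),
        barrier_from_right=barrier - float(g[i_right]),
        left_min_center=float(centers[i_left]),
        right_min_center=float(centers[i_right]),
        has_gap=has_gap,
    )


def density_estimate(values, grid) -> np.ndarray:
    """Gaussian kernel density with Silverman bandwidth, evaluated on
    ``grid``.  Needs at least two distinct values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if np.unique(v).size < 2:
        raise ValueError("zero bandwidth: need at least two distinct values")
    kde = gaussian_kde(v, bw_method="silverman")
    return kde(np.asarray(grid, dtype=float))
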